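"""Population variants: VCF parsing, bi-allelic normalization, genotype-based
minor allele frequency, and the rare-variant filter.

Allele frequencies are always computed from FORMAT/GT calls, never from
INFO tags, so the same code works across datasets with different INFO
conventions. Missing alleles ('.') are excluded from the denominator;
haploid calls contribute one allele. Multi-allelic sites are split into one
record per ALT, each ALT counted against all called alleles of the site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

from cyvcf2 import VCF

from varfold.reference_io import GenomeSequence

_VALID_ALLELE = set("ACGTN")


@dataclass(frozen=True)
class VariantRecord:
    """One normalized bi-allelic variant with its genotype-derived frequency."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_count: int
    called_allele_count: int

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - _VALID_ALLELE or set(self.alt) - _VALID_ALLELE:
            raise ValueError(f"non-ACGTN allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def alt_frequency(self) -> float:
        if self.called_allele_count == 0:
            return 0.0
        return self.alt_count / self.called_allele_count

    @property
    def maf(self) -> float:
        f = self.alt_frequency
        return min(f, 1.0 - f)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        """Last genomic position covered by the REF allele (1-based)."""
        return self.pos + len(self.ref) - 1


def parse_vcf(path) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF (v4.x, plain or bgzip).

    Multi-allelic sites are split; phased and unphased genotypes are
    treated identically; ALT alleles outside ACGTN (symbolic, breakend,
    '*') are skipped with a warning.
    """
    vcf = VCF(str(path))
    for site in vcf:
        allele_indices: list[int] = []
        for gt in site.genotypes:
            # cyvcf2 genotype: [allele, allele, ..., phased_flag]
            allele_indices.extend(a for a in gt[:-1] if a >= 0)
        called = len(allele_indices)
        ref = str(site.REF).upper()
        for alt_index, alt in enumerate(site.ALT, start=1):
            alt = str(alt).upper()
            if set(alt) - _VALID_ALLELE or set(ref) - _VALID_ALLELE:
                warnings.warn(
                    f"skipping non-sequence allele {ref}>{alt} at {site.CHROM}:{site.POS}"
                )
                continue
            alt_count = sum(1 for a in allele_indices if a == alt_index)
            yield VariantRecord(
                chrom=site.CHROM,
                pos=site.POS,
                ref=ref,
                alt=alt,
                alt_count=alt_count,
                called_allele_count=called,
            )


def maf_filter(
    records: Iterable[VariantRecord], threshold: float
) -> Iterator[VariantRecord]:
    """Retain records with maf >= threshold (threshold 0 is the identity).

    The boundary is kept inclusive: a 5% filter excludes variants with
    minor allele frequency strictly below 0.05.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    return (r for r in records if r.maf >= threshold)


def validate_against_reference(record: VariantRecord, genome: GenomeSequence) -> bool:
    """True iff the genome sequence under the REF allele matches it."""
    if record.chrom not in genome:
        raise KeyError(f"chromosome {record.chrom} absent from genome")
    return genome.subseq(record.chrom, record.pos, record.end) == record.ref
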