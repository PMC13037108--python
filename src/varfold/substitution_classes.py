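"""Sub-classification of amino-acid substitutions.

Three orthogonal labels for a missense (or synonymous) change:

* conservative vs radical — does the replacement stay inside the same
  physicochemical functional group;
* BLOSUM62 score, and the score >= 3 split used to separate highly
  exchangeable substitutions;
* common vs uncommon codon — is the resulting codon used at least as often
  as the uniform expectation within its synonymous family (RSCU >= 1),
  with codon usage counted from the species' own coding sequences.

The functional-group partition and the RSCU >= 1 cutoff are declared
module-level defaults; both are pluggable arguments, never silently
changed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Align import substitution_matrices

from varfold.reference_io import CODON_TO_AA, CodingSequence

#: physicochemical functional groups; each canonical residue in exactly one
AMINO_ACID_CLASSES: dict[str, str] = {
    **{aa: "aliphatic_nonpolar" for aa in "GAVLIPM"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "polar_uncharged" for aa in "STCNQ"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
CANONICAL_AA = set(AMINO_ACID_CLASSES)


@dataclass(frozen=True)
class CodonUsage:
    codon: str
    amino_acid: str
    count: int
    rscu: float
    common: bool


@dataclass
class CodonUsageTable:
    """Per-codon usage with relative synonymous codon usage (RSCU).

    RSCU = observed count x family size / family total, so the unweighted
    mean RSCU within each observed synonymous family is exactly 1. A codon
    is "common" when its RSCU meets the threshold (default 1: used at least
    as often as the uniform within-family expectation).
    """

    entries: dict[str, CodonUsage]
    threshold: float = 1.0

    def __getitem__(self, codon: str) -> CodonUsage:
        return self.entries[codon]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "codon": u.codon,
                    "aa": u.amino_acid,
                    "count": u.count,
                    "rscu": u.rscu,
                    "common": u.common,
                }
                for u in sorted(self.entries.values(), key=lambda u: (u.amino_acid, u.codon))
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        df = pd.read_csv(path, sep="\t")
        entries = {
            r.codon: CodonUsage(r.codon, r.aa, int(r.count), float(r.rscu), bool(r.common))
            for r in df.itertuples()
        }
        return cls(entries)


@dataclass(frozen=True)
class SubstitutionAnnotation:
    ref_aa: str
    alt_aa: str
    class_change: str  # conservative | radical
    blosum_score: int
    blosum_ge3: bool
    codon_class: str | None  # common | uncommon | None


def classify_substitution(
    ref_aa: str, alt_aa: str, table: Mapping[str, str] = AMINO_ACID_CLASSES
) -> str:
    """'conservative' if both residues share a functional group, else 'radical'."""
    for aa in (ref_aa, alt_aa):
        if aa not in table:
            raise ValueError(f"non-canonical residue {aa!r}")
    return "conservative" if table[ref_aa] == table[alt_aa] else "radical"


def blosum_score(ref_aa: str, alt_aa: str) -> int:
    """Symmetric BLOSUM62 log-odds score for a residue pair."""
    if ref_aa not in CANONICAL_AA or alt_aa not in CANONICAL_AA:
        raise ValueError(f"non-canonical residue pair ({ref_aa!r}, {alt_aa!r})")
    return int(_BLOSUM62[ref_aa, alt_aa])


def build_codon_usage(
    cds_set: Iterable[CodingSequence], threshold: float = 1.0
) -> CodonUsageTable:
    """Count codons across complete coding sequences into a usage table.

    Stop codons form their own synonymous family. Codons never observed
    get RSCU 0 (uncommon); families never observed get RSCU 0 throughout.
    """
    counts: Counter[str] = Counter()
    n_cds = 0
    for cds in cds_set:
        n_cds += 1
        nts = cds.nucleotides
        for i in range(0, len(nts) - len(nts) % 3, 3):
            codon = nts[i : i + 3]
            if "N" not in codon:
                counts[codon] += 1
    if n_cds == 0:
        raise ValueError("codon usage requires at least one coding sequence")

    families: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        families.setdefault(aa, []).append(codon)

    entries: dict[str, CodonUsage] = {}
    for aa, codons in families.items():
        family_total = sum(counts[c] for c in codons)
        size = len(codons)
        for c in codons:
            rscu = counts[c] * size / family_total if family_total > 0 else 0.0
            entries[c] = CodonUsage(c, aa, counts[c], rscu, rscu >= threshold)
    return CodonUsageTable(entries, threshold=threshold)


def classify_codon_change(alt_codon: str, table: CodonUsageTable) -> str:
    """'common' or 'uncommon' for the codon a mutation produces."""
    if "N" in alt_codon or alt_codon not in table.entries:
        raise ValueError(f"cannot classify codon {alt_codon!r}")
    return "common" if table[alt_codon].common else "uncommon"


def annotate_substitution(
    ref_aa: str,
    alt_aa: str,
    alt_codon: str | None = None,
    usage: CodonUsageTable | None = None,
    classes: Mapping[str, str] = AMINO_ACID_CLASSES,
) -> SubstitutionAnnotation:
    """Full annotation of one amino-acid change."""
    score = blosum_score(ref_aa, alt_aa)
    codon_class = None
    if alt_codon is not None and usage is not None:
        codon_class = classify_codon_change(alt_codon, usage)
    return SubstitutionAnnotation(
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        class_change=classify_substitution(ref_aa, alt_aa, classes),
        blosum_score=score,
        blosum_ge3=score >= 3,
        codon_class=codon_class,
    )
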