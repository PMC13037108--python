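"""Reference genome and annotation: FASTA/GFF3 parsing, transcript models,
CDS assembly and translation.

Coordinate convention (stated once, asserted in tests): all genomic
coordinates are 1-based inclusive, matching GFF3 and VCF. CDS offsets are
1-based along the coding sequence in 5'->3' coding orientation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Mapping of sequence id -> uppercase nucleotide string (ACGTN)."""

    sequences: dict[str, str]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def base(self, chrom: str, pos: int) -> str:
        """Single base at a 1-based position."""
        seq = self.sequences[chrom]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} outside {chrom} (length {len(seq)})")
        return seq[pos - 1]

    def subseq(self, chrom: str, start: int, end: int) -> str:
        """Substring over the 1-based inclusive interval [start, end]."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"interval [{start},{end}] outside {chrom} (length {len(seq)})")
        return seq[start - 1 : end]


@dataclass
class TranscriptModel:
    """Strand-aware chain of CDS intervals for one transcript.

    ``cds_intervals`` are 1-based inclusive genomic intervals sorted by
    genomic start, non-overlapping, all on one chromosome.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in {self.transcript_id}")
        self.cds_intervals = ivs
        if self.cds_length < 3:
            raise ValueError(f"total CDS length < 3 in {self.transcript_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint: first CDS start to last CDS end."""
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive CDS intervals (1-based inclusive)."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.cds_intervals, self.cds_intervals[1:])
        ]


@dataclass
class CodingSequence:
    transcript_id: str
    nucleotides: str
    complete: bool = field(default=False)

    def __post_init__(self) -> None:
        n = self.nucleotides
        self.complete = (
            len(n) % 3 == 0
            and len(n) >= 6
            and n.startswith("ATG")
            and CODON_TO_AA.get(n[-3:], "") == "*"
        )

    def __len__(self) -> int:
        return len(self.nucleotides)

    def codon(self, residue_index: int) -> str:
        """Codon for a 1-based residue index."""
        return self.nucleotides[3 * (residue_index - 1) : 3 * residue_index]


@dataclass
class ProteinSequence:
    transcript_id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def parse_fasta(path) -> GenomeSequence:
    """Read a multi-record FASTA into a GenomeSequence.

    Ids are the header token before the first whitespace; sequences are
    uppercased. Duplicate ids and empty sequences are hard errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id: {record.id}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id: {record.id}")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(sequences)


def build_transcript_models(gff_path, keep: str = "primary_only") -> list[TranscriptModel]:
    """Assemble TranscriptModels from a GFF3 file.

    CDS features are grouped by their Parent (mRNA) attribute; the gene id
    is the mRNA's own Parent when present, else the mRNA id. With
    ``keep="primary_only"`` one transcript per gene is retained: the one
    with the longest total CDS, ties broken by lexicographically smallest
    transcript id (a deterministic proxy for annotation-designated primary
    transcripts, which GFF3 dialects encode inconsistently).
    """
    if keep not in {"primary_only", "all"}:
        raise ValueError(f"keep must be 'primary_only' or 'all', got {keep!r}")
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    mrna_gene: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        mrna_gene[mrna.id] = parents[0] if parents else mrna.id

    per_transcript: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents:
            warnings.warn(f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no Parent; skipped")
            continue
        for tid in parents:
            entry = per_transcript.setdefault(
                tid, {"chrom": cds.seqid, "strand": cds.strand, "intervals": []}
            )
            if entry["strand"] != cds.strand:
                raise ValueError(f"mixed-strand CDS under transcript {tid}")
            if entry["chrom"] != cds.seqid:
                raise ValueError(f"multi-chromosome CDS under transcript {tid}")
            entry["intervals"].append((cds.start, cds.end))

    models = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=mrna_gene.get(tid, tid),
            chrom=entry["chrom"],
            strand=entry["strand"],
            cds_intervals=sorted(entry["intervals"]),
        )
        for tid, entry in per_transcript.items()
    ]
    models.sort(key=lambda m: (m.chrom, m.span[0], m.transcript_id))
    for m in models:
        if m.cds_length % 3 != 0:
            warnings.warn(
                f"CDS length of {m.transcript_id} ({m.cds_length}) is not a multiple of 3"
            )
    if keep == "all":
        return models

    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.cds_length > cur.cds_length
            or (m.cds_length == cur.cds_length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    primary = sorted(best.values(), key=lambda m: (m.chrom, m.span[0], m.transcript_id))
    for m in primary:
        m.is_primary = True
    return primary


def extract_cds(model: TranscriptModel, genome: GenomeSequence) -> CodingSequence:
    """Splice the CDS out of the genome, 5'->3' in coding orientation.

    Plus strand: concatenation of interval substrings in genomic order.
    Minus strand: reverse complement of that concatenation.
    """
    parts = [genome.subseq(model.chrom, s, e) for s, e in model.cds_intervals]
    seq = "".join(parts)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return CodingSequence(model.transcript_id, seq)


def translate(cds: CodingSequence) -> ProteinSequence:
    """Translate with the standard nuclear code.

    Stops at the first stop codon; codons containing N become 'X'. A
    trailing partial codon is ignored with a warning.
    """
    nts = cds.nucleotides
    if len(nts) < 3:
        raise ValueError("coding sequence shorter than one codon")
    if len(nts) % 3 != 0:
        warnings.warn(f"{cds.transcript_id}: trailing partial codon ignored")
    residues = []
    for i in range(0, len(nts) - len(nts) % 3, 3):
        codon = nts[i : i + 3]
        if "N" in codon:
            residues.append("X")
            continue
        aa = CODON_TO_AA[codon]
        if aa == "*":
            break
        residues.append(aa)
    return ProteinSequence(cds.transcript_id, "".join(residues))


def genomic_to_cds_position(model: TranscriptModel, genomic_pos: int) -> int | None:
    """1-based CDS offset of a genomic position, or None outside the CDS.

    For the minus strand the offset counts from the genomically-last base
    (the coding 5' end).
    """
    offset = 0
    inside = False
    for s, e in model.cds_intervals:
        if genomic_pos > e:
            offset += e - s + 1
        elif genomic_pos >= s:
            offset += genomic_pos - s + 1
            inside = True
            break
        else:
            break
    if not inside:
        return None
    if model.strand == "-":
        return model.cds_length - offset + 1
    return offset


def cds_position_to_genomic(model: TranscriptModel, cds_offset: int) -> int:
    """Inverse of :func:`genomic_to_cds_position` (1-based both ways)."""
    if not 1 <= cds_offset <= model.cds_length:
        raise ValueError(f"CDS offset {cds_offset} outside 1..{model.cds_length}")
    plus_offset = (
        cds_offset if model.strand == "+" else model.cds_length - cds_offset + 1
    )
    remaining = plus_offset
    for s, e in model.cds_intervals:
        width = e - s + 1
        if remaining <= width:
            return s + remaining - 1
        remaining -= width
    raise AssertionError("unreachable")


def cds_to_codon(cds_offset: int) -> tuple[int, int]:
    """(1-based residue index, codon position in {1,2,3}) of a CDS offset."""
    if cds_offset < 1:
        raise ValueError("CDS offset must be >= 1")
    return math.ceil(cds_offset / 3), (cds_offset - 1) % 3 + 1
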