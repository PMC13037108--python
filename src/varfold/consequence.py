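"""Native variant-consequence engine with snpEff-style severity grades.

Each variant is classified against a transcript model into one of 13
consequence types which map onto four grades:

* LOW       — synonymous
* MODERATE  — missense, in-frame insertion/deletion
* HIGH      — stop gained/lost, start lost, frameshift, splice donor/acceptor
* MODIFIER  — intronic, intergenic, non-coding (excluded from statistics
  by default downstream)

Simplifications relative to a full annotation engine, all deliberate:
indels are typed by net length change only (the shifted tail is not
re-translated); the splice region is the 2-bp canonical GT/AG intron core;
a variant spanning an exon–intron junction is graded HIGH as a frameshift
with a warning flag; UTRs are not modelled, so positions outside the CDS
footprint of a gene are intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from varfold.reference_io import (
    CODON_TO_AA,
    GenomeSequence,
    TranscriptModel,
    cds_to_codon,
    extract_cds,
    genomic_to_cds_position,
)
from varfold.variant_io import VariantRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
SPLICE_CORE = 2  # intronic bases at each boundary treated as splice site


class ConsequenceType(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    FRAMESHIFT = "frameshift"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    NON_CODING = "non_coding"


class Grade(str, Enum):
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"
    MODIFIER = "MODIFIER"


GRADE_OF: dict[ConsequenceType, Grade] = {
    ConsequenceType.SYNONYMOUS: Grade.LOW,
    ConsequenceType.MISSENSE: Grade.MODERATE,
    ConsequenceType.INFRAME_INSERTION: Grade.MODERATE,
    ConsequenceType.INFRAME_DELETION: Grade.MODERATE,
    ConsequenceType.STOP_GAINED: Grade.HIGH,
    ConsequenceType.STOP_LOST: Grade.HIGH,
    ConsequenceType.START_LOST: Grade.HIGH,
    ConsequenceType.FRAMESHIFT: Grade.HIGH,
    ConsequenceType.SPLICE_DONOR: Grade.HIGH,
    ConsequenceType.SPLICE_ACCEPTOR: Grade.HIGH,
    ConsequenceType.INTRONIC: Grade.MODIFIER,
    ConsequenceType.INTERGENIC: Grade.MODIFIER,
    ConsequenceType.NON_CODING: Grade.MODIFIER,
}


@dataclass
class ConsequenceCall:
    variant: VariantRecord
    transcript_id: str
    consequence_type: ConsequenceType
    residue_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    warning: str | None = None

    @property
    def grade(self) -> Grade:
        return GRADE_OF[self.consequence_type]


def _altered_span(record: VariantRecord) -> tuple[int, int]:
    """Genomic span of bases actually changed by the variant.

    For anchored indels (shared leading base) the anchor is excluded; a
    pure insertion changes the junction after the anchor, modelled as the
    anchor position + 1.
    """
    if record.is_snv:
        return record.pos, record.pos
    if record.ref[0] == record.alt[0]:
        start = record.pos + 1
        end = max(record.end, start)
        return start, end
    return record.pos, record.end


def _splice_positions(model: TranscriptModel) -> dict[int, ConsequenceType]:
    """Map genomic positions of the 2-bp intron cores to donor/acceptor.

    The donor is the intron side adjacent to the coding-upstream exon
    (5' of the intron in coding orientation); the acceptor is the other.
    """
    out: dict[int, ConsequenceType] = {}
    for s, e in model.introns:
        if e - s + 1 < 2 * SPLICE_CORE:
            continue
        left = {s, s + 1}
        right = {e - 1, e}
        if model.strand == "+":
            donor, acceptor = left, right
        else:
            donor, acceptor = right, left
        for p in donor:
            out[p] = ConsequenceType.SPLICE_DONOR
        for p in acceptor:
            out[p] = ConsequenceType.SPLICE_ACCEPTOR
    return out


def _classify_cds_snv(
    record: VariantRecord, model: TranscriptModel, genome: GenomeSequence
) -> ConsequenceCall:
    cds = extract_cds(model, genome)
    offset = genomic_to_cds_position(model, record.pos)
    assert offset is not None
    residue_index, codon_pos = cds_to_codon(offset)
    ref_codon = cds.codon(residue_index)
    alt_base = record.alt
    if model.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[: codon_pos - 1] + alt_base + ref_codon[codon_pos:]

    def aa_of(codon: str) -> str:
        return "X" if "N" in codon else CODON_TO_AA[codon]

    ref_aa, alt_aa = aa_of(ref_codon), aa_of(alt_codon)
    n_codons = len(cds) // 3
    if residue_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        ctype = ConsequenceType.START_LOST
    elif ref_aa == "*" and alt_aa != "*":
        ctype = ConsequenceType.STOP_LOST
    elif alt_aa == "*" and ref_aa != "*" and residue_index < n_codons:
        ctype = ConsequenceType.STOP_GAINED
    elif alt_aa == "*" and ref_aa != "*":
        # stop introduced in the terminal codon position (already a stop
        # codon slot only when ref was not stop): still a premature stop
        ctype = ConsequenceType.STOP_GAINED
    elif ref_aa == alt_aa:
        ctype = ConsequenceType.SYNONYMOUS
    else:
        ctype = ConsequenceType.MISSENSE
    return ConsequenceCall(
        variant=record,
        transcript_id=model.transcript_id,
        consequence_type=ctype,
        residue_index=residue_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
    )


def _cds_overlap(model: TranscriptModel, start: int, end: int) -> bool:
    return any(s <= end and start <= e for s, e in model.cds_intervals)


def classify_variant(
    record: VariantRecord, model: TranscriptModel, genome: GenomeSequence
) -> ConsequenceCall:
    """Classify one variant against one transcript model."""
    span_start, span_end = model.span
    a_start, a_end = _altered_span(record)

    if a_end < span_start or a_start > span_end:
        return ConsequenceCall(record, model.transcript_id, ConsequenceType.INTERGENIC)

    in_cds = _cds_overlap(model, a_start, a_end)

    if record.is_snv:
        if in_cds:
            return _classify_cds_snv(record, model, genome)
        splice = _splice_positions(model).get(record.pos)
        if splice is not None:
            return ConsequenceCall(record, model.transcript_id, splice)
        return ConsequenceCall(record, model.transcript_id, ConsequenceType.INTRONIC)

    # indel
    net = len(record.alt) - len(record.ref)
    if not in_cds:
        return ConsequenceCall(record, model.transcript_id, ConsequenceType.INTRONIC)

    spans_junction = any(
        (a_start < s <= a_end) or (a_start <= e < a_end)
        for s, e in model.cds_intervals
        if not (s <= a_start and a_end <= e)
    ) and not any(s <= a_start and a_end <= e for s, e in model.cds_intervals)
    if spans_junction:
        return ConsequenceCall(
            record,
            model.transcript_id,
            ConsequenceType.FRAMESHIFT,
            warning="spans_exon_intron_junction",
        )

    offset = genomic_to_cds_position(model, a_start if model.strand == "+" else a_end)
    residue_index = cds_to_codon(offset)[0] if offset is not None else None

    # an indel disturbing the start codon loses the start
    start_codon_positions = {
        _cds_genomic(model, o) for o in (1, 2, 3)
    }
    if start_codon_positions & set(range(a_start, a_end + 1)):
        return ConsequenceCall(
            record,
            model.transcript_id,
            ConsequenceType.START_LOST,
            residue_index=1,
        )

    if net % 3 != 0:
        ctype = ConsequenceType.FRAMESHIFT
    elif net > 0:
        ctype = ConsequenceType.INFRAME_INSERTION
    else:
        ctype = ConsequenceType.INFRAME_DELETION
    return ConsequenceCall(
        record, model.transcript_id, ctype, residue_index=residue_index
    )


def _cds_genomic(model: TranscriptModel, cds_offset: int) -> int:
    from varfold.reference_io import cds_position_to_genomic

    return cds_position_to_genomic(model, cds_offset)


@dataclass
class _ModelIndex:
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def build(cls, models: Iterable[TranscriptModel]) -> "_ModelIndex":
        idx = cls()
        for m in models:
            s, e = m.span
            idx.trees.setdefault(m.chrom, IntervalTree()).addi(s, e + 1, m)
        return idx

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        hits.sort(key=lambda m: m.transcript_id)
        return hits


def classify_all(
    records: Iterable[VariantRecord],
    models: Iterable[TranscriptModel],
    genome: GenomeSequence,
) -> Iterator[ConsequenceCall]:
    """Classify every variant against every overlapping transcript.

    Variants overlapping no transcript yield a single intergenic call with
    transcript id '.'. Output order is (chrom, pos, transcript_id).
    """
    index = _ModelIndex.build(models)
    buffered = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    for record in buffered:
        hits = index.overlapping(record.chrom, record.pos, record.end)
        if not hits:
            yield ConsequenceCall(record, ".", ConsequenceType.INTERGENIC)
            continue
        for model in hits:
            yield classify_variant(record, model, genome)


CODING_GRADES = (Grade.LOW, Grade.MODERATE, Grade.HIGH)

TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "maf",
    "transcript_id",
    "consequence_type",
    "grade",
    "residue_index",
    "ref_aa",
    "alt_aa",
    "ref_codon",
    "alt_codon",
]


def call_to_row(call: ConsequenceCall) -> dict:
    """Flatten a call into the TSV schema ('.' for nulls)."""
    v = call.variant
    return {
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "maf": v.maf,
        "transcript_id": call.transcript_id,
        "consequence_type": call.consequence_type.value,
        "grade": call.grade.value,
        "residue_index": call.residue_index if call.residue_index is not None else ".",
        "ref_aa": call.ref_aa or ".",
        "alt_aa": call.alt_aa or ".",
        "ref_codon": call.ref_codon or ".",
        "alt_codon": call.alt_codon or ".",
    }
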