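"""Consequence classification: codon substitution, indels, splice sites,
grades, and agreement with the brute-force re-translation oracle."""

import pytest

from conftest import snv_oracle
from varfold.consequence import (
    ConsequenceType,
    Grade,
    GRADE_OF,
    classify_all,
    classify_variant,
)
from varfold.reference_io import (
    GenomeSequence,
    TranscriptModel,
    extract_cds,
    genomic_to_cds_position,
    reverse_complement,
)
from varfold.variant_io import VariantRecord


def snv(pos, ref, alt, chrom="chr1"):
    return VariantRecord(chrom, pos, ref, alt, 1, 20)


class TestSnvClassification:
    def test_synonymous(self, toy_gene):
        genome, model = toy_gene
        call = classify_variant(snv(6, "A", "G"), model, genome)
        assert call.consequence_type == ConsequenceType.SYNONYMOUS
        assert call.grade == Grade.LOW
        assert call.residue_index == 2
        assert (call.ref_codon, call.alt_codon) == ("AAA", "AAG")

    def test_missense(self, toy_gene):
        genome, model = toy_gene
        call = classify_variant(snv(4, "A", "G"), model, genome)
        assert call.consequence_type == ConsequenceType.MISSENSE
        assert (call.ref_aa, call.alt_aa) == ("K", "E")
        assert call.residue_index == 2

    def test_start_lost(self, toy_gene):
        genome, model = toy_gene
        call = classify_variant(snv(1, "A", "G"), model, genome)
        assert call.consequence_type == ConsequenceType.START_LOST
        assert call.grade == Grade.HIGH

    def test_stop_gained_and_lost(self):
        genome = GenomeSequence({"chr1": "ATGAAAAAATAG"})
        model = TranscriptModel("t", "g", "chr1", "+", [(1, 12)])
        gained = classify_variant(snv(4, "A", "T"), model, genome)  # AAA->TAA
        assert gained.consequence_type == ConsequenceType.STOP_GAINED
        lost = classify_variant(snv(10, "T", "C"), model, genome)  # TAG->CAG
        assert lost.consequence_type == ConsequenceType.STOP_LOST
        assert lost.grade == Grade.HIGH

    def test_minus_strand_synonymous(self, toy_gene_minus):
        genome, model = toy_gene_minus
        call = classify_variant(snv(4, "T", "C"), model, genome)
        assert call.consequence_type == ConsequenceType.SYNONYMOUS
        assert (call.ref_codon, call.alt_codon) == ("AAA", "AAG")


class TestIndelClassification:
    def test_frameshift_deletion(self, toy_gene):
        genome, model = toy_gene
        call = classify_variant(VariantRecord("chr1", 4, "AA", "A", 1, 20), model, genome)
        assert call.consequence_type == ConsequenceType.FRAMESHIFT
        assert call.grade == Grade.HIGH

    def test_inframe_deletion(self):
        genome = GenomeSequence({"chr1": "ATGAAAAAATAG"})
        model = TranscriptModel("t", "g", "chr1", "+", [(1, 12)])
        call = classify_variant(VariantRecord("chr1", 3, "GAAA", "G", 1, 20), model, genome)
        assert call.consequence_type == ConsequenceType.INFRAME_DELETION
        assert call.grade == Grade.MODERATE
        assert call.residue_index == 2

    def test_inframe_insertion(self, toy_gene):
        genome, model = toy_gene
        call = classify_variant(VariantRecord("chr1", 4, "A", "AGGG", 1, 20), model, genome)
        assert call.consequence_type == ConsequenceType.INFRAME_INSERTION

    def test_deletion_of_start_codon(self, toy_gene):
        genome, model = toy_gene
        call = classify_variant(VariantRecord("chr1", 1, "ATGA", "A", 1, 20), model, genome)
        assert call.consequence_type == ConsequenceType.START_LOST

    def test_junction_spanning_deletion_flagged(self, intron_gene):
        genome, model = intron_gene
        call = classify_variant(VariantRecord("chr1", 2, "TGGTC", "T", 1, 20), model, genome)
        assert call.consequence_type == ConsequenceType.FRAMESHIFT
        assert call.grade == Grade.HIGH
        assert call.warning == "spans_exon_intron_junction"


class TestSpliceAndNoncoding:
    def test_donor_acceptor_and_intron(self, intron_gene):
        genome, model = intron_gene
        assert classify_variant(snv(5, "T", "A"), model, genome).consequence_type == ConsequenceType.SPLICE_DONOR
        assert classify_variant(snv(4, "G", "A"), model, genome).consequence_type == ConsequenceType.SPLICE_DONOR
        assert classify_variant(snv(33, "G", "T"), model, genome).consequence_type == ConsequenceType.SPLICE_ACCEPTOR
        assert classify_variant(snv(20, "C", "T"), model, genome).consequence_type == ConsequenceType.INTRONIC
        assert classify_variant(snv(20, "C", "T"), model, genome).grade == Grade.MODIFIER

    def test_minus_strand_donor_is_high_coordinate_side(self):
        # mirror of intron_gene: intron at 10..39, exon2 coding-first at 40..42
        plus = "ATG" + "GT" + "C" * 26 + "AG" + "AAATTTTAG" + "ACGTACGT"
        genome = GenomeSequence({"chr1": reverse_complement(plus)})
        L = len(plus)
        model = TranscriptModel(
            "t", "g", "chr1", "-",
            [(L - 42 + 1, L - 34 + 1), (L - 3 + 1, L)],
        )
        intron = model.introns[0]
        donor_call = classify_variant(
            snv(intron[1], genome.base("chr1", intron[1]), "A"), model, genome
        )
        assert donor_call.consequence_type == ConsequenceType.SPLICE_DONOR
        acceptor_call = classify_variant(
            snv(intron[0], genome.base("chr1", intron[0]), "A"), model, genome
        )
        assert acceptor_call.consequence_type == ConsequenceType.SPLICE_ACCEPTOR

    def test_intergenic(self, intron_gene):
        genome, model = intron_gene
        call = classify_variant(snv(47, "C", "T"), model, genome)
        assert call.consequence_type == ConsequenceType.INTERGENIC


class TestGradePartition:
    def test_every_type_has_exactly_one_grade(self):
        assert set(GRADE_OF) == set(ConsequenceType)
        low = [t for t, g in GRADE_OF.items() if g == Grade.LOW]
        assert low == [ConsequenceType.SYNONYMOUS]


class TestClassifyAll:
    def test_variant_overlapping_two_genes(self, toy_gene):
        genome = GenomeSequence({"chr1": "ATGAAATAGATGAAATAG"})
        m1 = TranscriptModel("t1", "g1", "chr1", "+", [(1, 9)])
        m2 = TranscriptModel("t2", "g2", "chr1", "+", [(5, 13)])
        calls = list(classify_all([snv(6, "A", "G")], [m1, m2], genome))
        assert [c.transcript_id for c in calls] == ["t1", "t2"]

    def test_no_overlap_yields_single_intergenic(self, toy_gene):
        genome, model = toy_gene
        calls = list(classify_all([snv(9, "G", "A", chrom="chrX")], [model], GenomeSequence({"chrX": "ATGAAATAGC"})))
        assert len(calls) == 1
        assert calls[0].consequence_type == ConsequenceType.INTERGENIC
        assert calls[0].transcript_id == "."

    def test_empty_stream(self, toy_gene):
        genome, model = toy_gene
        assert list(classify_all([], [model], genome)) == []


def _all_snvs(model, genome):
    seq = genome[model.chrom]
    for s, e in model.cds_intervals:
        for pos in range(s, e + 1):
            ref = seq[pos - 1]
            for alt in "ACGT":
                if alt != ref:
                    yield pos, ref, alt


@pytest.mark.parametrize("strand", ["+", "-"])
def test_exhaustive_snv_agreement_with_oracle(strand, null_bundle):
    """Every possible coding SNV of fixture genes matches the full mutant
    re-translation oracle, on both strands."""
    _, sim = null_bundle
    genome = sim.reference.genome
    genes = [g for g in sim.reference.genes if g.strand == strand][:2]
    assert genes, "fixture should contain genes on both strands"
    for gene in genes:
        model = gene.model()
        for pos, ref, alt in _all_snvs(model, genome):
            expected = snv_oracle(pos, alt, model, genome)
            got = classify_variant(snv(pos, ref, alt), model, genome)
            assert got.consequence_type.value == expected, (gene.transcript_id, pos, ref, alt)


def test_strand_symmetry_on_fixture_variants(null_bundle):
    """Classifying on a minus-strand gene equals classifying the mirrored
    variant on the plus-strand construction over the flipped chromosome."""
    _, sim = null_bundle
    genome = sim.reference.genome
    L = len(genome["chr1"])
    mirrored = GenomeSequence({"chr1": reverse_complement(genome["chr1"])})
    genes = {g.transcript_id: g for g in sim.reference.genes}
    for t in sim.variant_truth:
        if t.transcript_id is None or len(t.ref) != 1 or len(t.alt) != 1:
            continue
        gene = genes[t.transcript_id]
        model = gene.model()
        flipped = TranscriptModel(
            gene.transcript_id, gene.gene_id, "chr1",
            "+" if gene.strand == "-" else "-",
            [(L - e + 1, L - s + 1) for s, e in gene.cds_intervals],
        )
        mirrored_rec = VariantRecord(
            "chr1", L - t.pos + 1,
            reverse_complement(t.ref), reverse_complement(t.alt), 1, 20,
        )
        direct = classify_variant(snv(t.pos, t.ref, t.alt), model, genome)
        flipped_call = classify_variant(mirrored_rec, flipped, mirrored)
        assert direct.consequence_type == flipped_call.consequence_type
        assert direct.residue_index == flipped_call.residue_index


def test_fixture_round_trip_all_types(null_bundle):
    """classify_all recovers 100% of planted consequence types."""
    _, sim = null_bundle
    genome = sim.reference.genome
    models = [g.model() for g in sim.reference.genes]
    from varfold.variant_io import parse_vcf

    records = list(parse_vcf(sim.vcf_path))
    calls = {}
    for c in classify_all(records, models, genome):
        calls.setdefault((c.variant.pos, c.variant.ref, c.variant.alt), set()).add(
            (c.consequence_type.value, c.residue_index)
        )
    for t in sim.variant_truth:
        got = calls[(t.pos, t.ref, t.alt)]
        assert (t.consequence_type, t.residue_index) in got, (t, got)
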