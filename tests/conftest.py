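"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check:

* ``snv_oracle`` re-classifies an SNV by mutating the chromosome and
  re-translating the full mutant coding sequence, instead of the engine's
  single-codon substitution;
* ``exact_mannwhitney_p`` enumerates every arrangement of the pooled
  sample to get the permutation p-value, instead of calling scipy.
"""

from __future__ import annotations

import math
from itertools import combinations

import pytest

from varfold.fixtures import FixtureConfig, simulate
from varfold.reference_io import (
    GenomeSequence,
    TranscriptModel,
    extract_cds,
    genomic_to_cds_position,
    translate,
)


# --- oracles ---------------------------------------------------------------


def snv_oracle(pos: int, alt: str, model: TranscriptModel, genome: GenomeSequence) -> str:
    """Brute-force consequence of a coding SNV by full mutant re-translation."""
    offset = genomic_to_cds_position(model, pos)
    assert offset is not None, "oracle only covers CDS positions"
    chrom_seq = genome[model.chrom]
    mutant = GenomeSequence(
        {model.chrom: chrom_seq[: pos - 1] + alt + chrom_seq[pos:]}
    )
    ref_cds = extract_cds(model, genome)
    alt_cds = extract_cds(model, mutant)
    ref_prot = translate(ref_cds).residues
    alt_prot = translate(alt_cds).residues
    if ref_cds.nucleotides[:3] == "ATG" and alt_cds.nucleotides[:3] != "ATG":
        return "start_lost"
    if len(alt_prot) < len(ref_prot):
        return "stop_gained"
    if len(alt_prot) > len(ref_prot):
        return "stop_lost"
    return "synonymous" if ref_prot == alt_prot else "missense"


def exact_mannwhitney_p(x: list[float], y: list[float]) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration (untied data)."""
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = []
    idx = list(range(len(pooled)))
    for comb in combinations(idx, n):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in chosen]
        us.append(u_stat(xs, ys))
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def holm_oracle(pvals: list[float]) -> list[float]:
    """Step-down Holm adjustment, written out longhand."""
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    m = len(pvals)
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, i in enumerate(order):
        adj = min(1.0, (m - rank) * pvals[i])
        running_max = max(running_max, adj)
        adjusted[i] = running_max
    return adjusted


# --- shared toy constructions ---------------------------------------------


@pytest.fixture()
def toy_gene():
    """Single-exon plus-strand gene: ATG AAA TAG at chr1:1-9."""
    genome = GenomeSequence({"chr1": "ATGAAATAG"})
    model = TranscriptModel("t1", "g1", "chr1", "+", [(1, 9)])
    return genome, model


@pytest.fixture()
def toy_gene_minus():
    """Minus-strand twin of toy_gene: plus strand reads CTATTTCAT."""
    genome = GenomeSequence({"chr1": "CTATTTCAT"})
    model = TranscriptModel("t1", "g1", "chr1", "-", [(1, 9)])
    return genome, model


@pytest.fixture()
def intron_gene():
    """Two-exon plus-strand gene with intron 4..33 (GT..AG)."""
    exon1 = "ATG"
    intron = "GT" + "C" * 26 + "AG"
    exon2 = "AAATTTTAG"
    genome = GenomeSequence({"chr1": exon1 + intron + exon2 + "ACGTACGT"})
    model = TranscriptModel("t1", "g1", "chr1", "+", [(1, 3), (34, 42)])
    return genome, model


# --- simulated bundles (session-scoped: reused across modules) -------------


@pytest.fixture(scope="session")
def null_bundle(tmp_path_factory):
    """Fixture bundle with no planted MAF-exposure coupling."""
    cfg = FixtureConfig(seed=11, selection_effect=0.0)
    out = simulate(cfg, tmp_path_factory.mktemp("null_fix"))
    return cfg, out


SELECTION_PLAN = {
    "synonymous": 60, "missense": 60, "stop_gained": 16, "frameshift": 16,
    "start_lost": 4, "stop_lost": 4, "inframe_deletion": 12,
    "inframe_insertion": 12, "splice_donor": 3, "splice_acceptor": 3,
    "intronic": 6, "intergenic": 6,
}


@pytest.fixture(scope="session")
def selection_bundle(tmp_path_factory):
    """Bundle with purifying-selection caricature planted (effect 2.0)."""
    cfg = FixtureConfig(
        seed=7, selection_effect=2.0, n_genes=10, variant_plan=dict(SELECTION_PLAN)
    )
    out = simulate(cfg, tmp_path_factory.mktemp("sel_fix"))
    return cfg, out
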