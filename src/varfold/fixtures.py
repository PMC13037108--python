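"""Synthetic genome / annotation / population / structure generator.

Emits a self-consistent quartet — FASTA genome, GFF3 annotation, VCF
genotypes, and one PDB per transcript — with full ground truth, so every
pipeline stage is testable without external data.

What the generator emulates and what it does not:

* Genes are ATG...stop CDS chains with optional canonical GT/AG introns on
  both strands, so coordinate math, splicing and strand handling are
  exercised for real.
* Variants are constructed bottom-up from their intended consequence type
  (e.g. a degenerate third-position change for a synonymous SNV), so the
  intended type is ground truth by construction, not by re-annotation.
* Allele frequencies are planted through diploid GT fields. With
  ``selection_effect > 0`` damaging (HIGH/MODERATE) variants are placed
  preferentially at exposed residues and their allele frequency is coupled
  to exposure linearly on the logit scale — a caricature of purifying
  selection strong enough for ordering/recovery tests, not a coalescent
  simulation.
* Structures are geometric caricatures: four compact heavy pseudo-atoms
  per residue on a widely spaced chain; buried residues get a 12-atom
  occluding shell (extra 'SHL' placeholder residues) so their computed
  rASA is low while exposed residues stay high. B-factors carry the
  planted pLDDT, which dips toward the termini.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqUtils import seq3

from varfold.reference_io import (
    CODON_TO_AA,
    GenomeSequence,
    TranscriptModel,
    cds_position_to_genomic,
    cds_to_codon,
    reverse_complement,
)

BASES = "ACGT"
_AA20 = sorted(set(CODON_TO_AA.values()) - {"*"})
_SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _SYNONYMOUS.setdefault(_aa, []).append(_codon)

#: default variant counts; desk-scale stand-in for a population callset
DEFAULT_VARIANT_PLAN: dict[str, int] = {
    "synonymous": 30,
    "missense": 30,
    "stop_gained": 8,
    "stop_lost": 4,
    "start_lost": 4,
    "frameshift": 8,
    "inframe_deletion": 6,
    "inframe_insertion": 6,
    "splice_donor": 3,
    "splice_acceptor": 3,
    "intronic": 6,
    "intergenic": 6,
}

_GRADE_OF_TYPE = {
    "synonymous": "LOW",
    "missense": "MODERATE",
    "inframe_deletion": "MODERATE",
    "inframe_insertion": "MODERATE",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift": "HIGH",
    "splice_donor": "HIGH",
    "splice_acceptor": "HIGH",
    "intronic": "MODIFIER",
    "intergenic": "MODIFIER",
}

#: exposure-placement weight exponents per grade (scaled by selection_effect)
_PLACEMENT_COEF = {"HIGH": 1.0, "MODERATE": 0.4, "LOW": -0.5, "MODIFIER": 0.0}

CHAIN_SPACING = 10.0  # Å between consecutive CA pseudo-atoms
SHELL_RADIUS = 4.3  # Å, occluding shell around buried residues
RASA_BURIED_MAX = 0.25
RASA_EXPOSED_MIN = 0.5


@dataclass
class FixtureConfig:
    n_genes: int = 8
    gene_length_range: tuple[int, int] = (20, 45)  # residues incl. initial Met
    intron_probability: float = 0.4
    minus_strand_fraction: float = 0.5
    n_samples: int = 20
    variant_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_PLAN)
    )
    selection_effect: float = 0.0
    seed: int = 0
    plddt_scale: str = "0-100"  # or "0-1" to emulate that B-factor dialect
    chrom: str = "chr1"


@dataclass
class GeneTruth:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    cds: str  # coding orientation, incl. stop codon
    protein: str
    exposure: list[bool]  # per residue: True = exposed
    plddt: list[float]

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def model(self) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand=self.strand,
            cds_intervals=list(self.cds_intervals),
        )


@dataclass
class VariantTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str | None
    consequence_type: str
    grade: str
    residue_index: int | None
    planted_af: float
    exposure: bool | None


@dataclass
class ReferenceFixture:
    genome: GenomeSequence
    gff_text: str
    genes: list[GeneTruth]
    intergenic_positions: list[int]


def _plddt_plan(rng: np.random.Generator, exposure: list[bool]) -> list[float]:
    L = len(exposure)
    vals = []
    for i, exposed in enumerate(exposure):
        base = 60.0 if exposed else 86.0
        dip = 4.0 * max(0, 6 - min(i, L - 1 - i))
        v = base - dip + rng.uniform(-4.0, 4.0)
        vals.append(round(float(np.clip(v, 25.0, 98.0)), 2))
    return vals


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def generate_reference(config: FixtureConfig) -> ReferenceFixture:
    """Build the genome, its GFF3 annotation and per-gene ground truth."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    chrom = config.chrom
    chunks: list[str] = []
    cursor = 0  # 0-based length so far
    genes: list[GeneTruth] = []
    intergenic: list[int] = []

    def add_spacer() -> None:
        nonlocal cursor
        length = int(rng.integers(30, 61))
        chunks.append(_random_spacer(rng, length))
        intergenic.extend(range(cursor + 6, cursor + length - 5))
        cursor += length

    for g in range(config.n_genes):
        add_spacer()
        L = int(rng.integers(lo, hi + 1))
        protein = "M" + "".join(rng.choice(_AA20) for _ in range(L - 1))
        exposure = [
            True if (i < 2 or i >= L - 2) else bool(rng.random() < 0.45)
            for i in range(L)
        ]
        plddt = _plddt_plan(rng, exposure)
        codons = ["ATG"] + [
            str(rng.choice(_SYNONYMOUS[aa])) for aa in protein[1:]
        ]
        stop = str(rng.choice(["TAA", "TAG", "TGA"]))
        cds = "".join(codons) + stop

        # optional single intron, canonical GT..AG, inserted mid-CDS
        pieces: list[tuple[str, str]]
        if rng.random() < config.intron_probability and len(cds) > 14:
            k = int(rng.integers(6, len(cds) - 6))
            ilen = int(rng.integers(20, 41))
            intron_seq = "GT" + _random_spacer(rng, ilen - 4) + "AG"
            pieces = [("exon", cds[:k]), ("intron", intron_seq), ("exon", cds[k:])]
        else:
            pieces = [("exon", cds)]

        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        gene_plus = "".join(seq for _, seq in pieces)
        total = len(gene_plus)
        genomic_seg = gene_plus if strand == "+" else reverse_complement(gene_plus)
        g0 = cursor + 1  # 1-based genomic start of the gene segment

        cds_intervals: list[tuple[int, int]] = []
        intron_intervals: list[tuple[int, int]] = []
        c0 = 0
        for kind, seq in pieces:
            clen = len(seq)
            if strand == "+":
                iv = (g0 + c0, g0 + c0 + clen - 1)
            else:
                iv = (g0 + total - c0 - clen, g0 + total - c0 - 1)
            (cds_intervals if kind == "exon" else intron_intervals).append(iv)
            c0 += clen
        cds_intervals.sort()
        intron_intervals.sort()

        chunks.append(genomic_seg)
        cursor += total
        genes.append(
            GeneTruth(
                gene_id=f"g{g:03d}",
                transcript_id=f"t{g:03d}",
                chrom=chrom,
                strand=strand,
                cds_intervals=cds_intervals,
                introns=intron_intervals,
                cds=cds,
                protein=protein,
                exposure=exposure,
                plddt=plddt,
            )
        )
    add_spacer()

    genome = GenomeSequence({chrom: "".join(chunks)})
    gff_lines = ["##gff-version 3"]
    for gene in genes:
        s, e = gene.span
        gff_lines.append(
            f"{chrom}\tvarfold_sim\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\tID={gene.gene_id}"
        )
        gff_lines.append(
            f"{chrom}\tvarfold_sim\tmRNA\t{s}\t{e}\t.\t{gene.strand}\t.\t"
            f"ID={gene.transcript_id};Parent={gene.gene_id}"
        )
        ivs = gene.cds_intervals
        coding_order = ivs if gene.strand == "+" else list(reversed(ivs))
        cum = 0
        phases = {}
        for iv in coding_order:
            phases[iv] = (3 - cum % 3) % 3
            cum += iv[1] - iv[0] + 1
        for iv in ivs:
            gff_lines.append(
                f"{chrom}\tvarfold_sim\tCDS\t{iv[0]}\t{iv[1]}\t.\t{gene.strand}\t"
                f"{phases[iv]}\tID=cds-{gene.transcript_id};Parent={gene.transcript_id}"
            )
    return ReferenceFixture(genome, "\n".join(gff_lines) + "\n", genes, intergenic)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _snv_candidates(gene: GeneTruth, ctype: str) -> list[dict]:
    """All single-base coding changes of a gene producing the given type."""
    model = gene.model()
    n_codons = len(gene.cds) // 3
    out = []
    for offset in range(1, len(gene.cds) + 1):
        ri, cp = cds_to_codon(offset)
        codon = gene.cds[3 * (ri - 1) : 3 * ri]
        aa = CODON_TO_AA[codon]
        for b in BASES:
            if b == codon[cp - 1]:
                continue
            alt_codon = codon[: cp - 1] + b + codon[cp:]
            alt_aa = CODON_TO_AA[alt_codon]
            if ri == 1:
                t = "start_lost"
            elif aa == "*":
                t = "stop_lost" if alt_aa != "*" else None
            elif alt_aa == "*":
                t = "stop_gained"
            elif alt_aa == aa:
                t = "synonymous"
            else:
                t = "missense"
            if t != ctype:
                continue
            pos = cds_position_to_genomic(model, offset)
            ref = gene.cds[offset - 1]
            alt = b
            if gene.strand == "-":
                ref = ref.translate(_COMPLEMENT)
                alt = alt.translate(_COMPLEMENT)
            exposure = gene.exposure[ri - 1] if ri <= len(gene.protein) else None
            out.append(
                dict(
                    pos=pos, ref=ref, alt=alt, ctype=ctype,
                    transcript_id=gene.transcript_id,
                    residue_index=ri, exposure=exposure,
                )
            )
    _ = n_codons
    return out


def _indel_candidates(gene: GeneTruth, ctype: str, rng: np.random.Generator) -> list[dict]:
    model = gene.model()
    out = []
    if ctype in {"frameshift", "inframe_deletion"}:
        width = 1 if ctype == "frameshift" else 3
        for o in range(4, len(gene.cds) - 1 - width):
            gpos = [cds_position_to_genomic(model, o + j) for j in range(width)]
            if max(gpos) - min(gpos) + 1 != width:
                continue  # straddles an intron
            anchor = min(gpos) - 1
            if anchor < 1:
                continue
            ri = cds_to_codon(o)[0]
            out.append(
                dict(
                    pos=anchor, width=width, ctype=ctype,
                    transcript_id=gene.transcript_id,
                    residue_index=ri,
                    exposure=gene.exposure[ri - 1] if ri <= len(gene.protein) else None,
                )
            )
    elif ctype == "inframe_insertion":
        for o in range(4, len(gene.cds) - 3):
            g_o = cds_position_to_genomic(model, o)
            g_next = cds_position_to_genomic(model, o + 1)
            if abs(g_next - g_o) != 1:
                continue
            if gene.strand == "+":
                pos, ri = g_o, cds_to_codon(o + 1)[0]
            else:
                pos, ri = g_next, cds_to_codon(o)[0]
            out.append(
                dict(
                    pos=pos, width=0, ctype=ctype,
                    transcript_id=gene.transcript_id,
                    residue_index=ri,
                    exposure=gene.exposure[ri - 1] if ri <= len(gene.protein) else None,
                )
            )
    _ = rng
    return out


def _noncoding_candidates(
    gene: GeneTruth, ctype: str
) -> list[dict]:
    out = []
    for s, e in gene.introns:
        if e - s + 1 < 7:
            continue
        left, right = {s, s + 1}, {e - 1, e}
        if gene.strand == "+":
            donor, acceptor = left, right
        else:
            donor, acceptor = right, left
        if ctype == "splice_donor":
            positions: list[int] = sorted(donor)
        elif ctype == "splice_acceptor":
            positions = sorted(acceptor)
        else:  # intronic
            positions = list(range(s + 3, e - 2))
        for p in positions:
            out.append(
                dict(
                    pos=p, ctype=ctype, transcript_id=gene.transcript_id,
                    residue_index=None, exposure=None,
                )
            )
    return out


def _planted_af(
    rng: np.random.Generator,
    grade: str,
    exposure: bool | None,
    selection_effect: float,
    n_samples: int,
) -> tuple[float, int]:
    """Planted allele frequency and alt-allele count (diploid)."""
    p0 = float(rng.uniform(0.08, 0.45))
    p = p0
    if selection_effect > 0 and grade in {"HIGH", "MODERATE"} and exposure is not None:
        proxy = 0.8 if exposure else 0.15
        logit = math.log(p0 / (1 - p0)) + selection_effect * (proxy - 0.5)
        p = 1.0 / (1.0 + math.exp(-logit))
    k = int(round(p * 2 * n_samples))
    k = max(1, min(k, n_samples))  # keep alt the minor-or-equal allele
    return k / (2 * n_samples), k


def generate_variants(
    reference: ReferenceFixture, config: FixtureConfig
) -> tuple[str, list[VariantTruth]]:
    """Construct the population VCF and its per-variant ground truth."""
    rng = np.random.default_rng(config.seed + 1)
    genome = reference.genome
    chrom = config.chrom
    seq = genome[chrom]
    used: set[int] = set()
    truths: list[VariantTruth] = []
    vcf_rows: list[tuple[int, str]] = []
    sample_names = [f"S{i:03d}" for i in range(config.n_samples)]

    candidates_by_type: dict[str, list[dict]] = {}
    for ctype in sorted(config.variant_plan):
        cands: list[dict] = []
        for gene in reference.genes:
            if ctype in {"splice_donor", "splice_acceptor", "intronic"}:
                cands.extend(_noncoding_candidates(gene, ctype))
            elif ctype in {"frameshift", "inframe_deletion", "inframe_insertion"}:
                cands.extend(_indel_candidates(gene, ctype, rng))
            elif ctype == "intergenic":
                continue
            else:
                cands.extend(_snv_candidates(gene, ctype))
        if ctype == "intergenic":
            cands = [
                dict(pos=p, ctype="intergenic", transcript_id=None,
                     residue_index=None, exposure=None)
                for p in reference.intergenic_positions
            ]
        candidates_by_type[ctype] = cands

    s = config.selection_effect
    for ctype in sorted(config.variant_plan):
        want = config.variant_plan[ctype]
        grade = _GRADE_OF_TYPE[ctype]
        pool = candidates_by_type[ctype]
        for _ in range(want):
            valid = []
            for c in pool:
                span = _candidate_span(c, seq)
                if span is None or any(p in used for p in span):
                    continue
                valid.append(c)
            if not valid:
                break  # requested type exhausted on this fixture
            if s > 0:
                coef = _PLACEMENT_COEF[grade]
                w = np.array(
                    [
                        math.exp(s * coef) if c["exposure"] else 1.0
                        for c in valid
                    ]
                )
                probs = w / w.sum()
                choice = valid[int(rng.choice(len(valid), p=probs))]
            else:
                choice = valid[int(rng.choice(len(valid)))]
            pos, ref, alt = _materialize(choice, seq, rng)
            af, k = _planted_af(rng, grade, choice["exposure"], s, config.n_samples)
            carriers = set(rng.choice(config.n_samples, size=k, replace=False).tolist())
            gts = ["0/1" if i in carriers else "0/0" for i in range(config.n_samples)]
            vcf_rows.append(
                (pos, f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
            )
            used.update(range(pos, pos + len(ref) + 1))
            truths.append(
                VariantTruth(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    transcript_id=choice["transcript_id"],
                    consequence_type=ctype, grade=grade,
                    residue_index=choice["residue_index"],
                    planted_af=af, exposure=choice["exposure"],
                )
            )

    vcf_rows.sort(key=lambda r: r[0])
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={len(seq)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
    ]
    vcf_text = "\n".join(header + [row for _, row in vcf_rows]) + "\n"
    truths.sort(key=lambda t: t.pos)
    return vcf_text, truths


def _candidate_span(c: dict, seq: str) -> range | None:
    width = c.get("width")
    if width is None:  # SNV
        return range(c["pos"], c["pos"] + 1)
    if width == 0:  # insertion anchored at pos
        return range(c["pos"], c["pos"] + 1)
    return range(c["pos"], c["pos"] + width + 1)  # deletion incl. anchor


def _materialize(c: dict, seq: str, rng: np.random.Generator) -> tuple[int, str, str]:
    pos = c["pos"]
    width = c.get("width")
    if width is None:
        if "ref" in c:
            return pos, c["ref"], c["alt"]
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        return pos, ref, alt
    anchor = seq[pos - 1]
    if width == 0:  # 3-bp insertion after the anchor
        ins = "".join(rng.choice(list(BASES), size=3))
        return pos, anchor, anchor + ins
    ref = seq[pos - 1 : pos + width]
    return pos, ref, anchor


# --- structures ------------------------------------------------------------

_ICOSAHEDRON = None


def _icosahedron() -> np.ndarray:
    global _ICOSAHEDRON
    if _ICOSAHEDRON is None:
        phi = (1 + math.sqrt(5)) / 2
        v = []
        for a in (1.0, -1.0):
            for b in (phi, -phi):
                v += [(0, a, b), (a, b, 0), (b, 0, a)]
        arr = np.array(v)
        _ICOSAHEDRON = arr / np.linalg.norm(arr, axis=1, keepdims=True)
    return _ICOSAHEDRON


def structure_pdb_text(gene: GeneTruth, plddt_scale: str = "0-100") -> str:
    """PDB text for one gene: 4 pseudo-atoms per residue plus occluding
    shells ('SHL' placeholder residues) around buried residues."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    L = len(gene.protein)
    names, elements, res_ids, res_names, coords, bfac = [], [], [], [], [], []
    scale = 0.01 if plddt_scale == "0-1" else 1.0
    for i, aa in enumerate(gene.protein):
        ca = np.array([CHAIN_SPACING * i, 0.0, 0.0])
        for name, element, offset in (
            ("N", "N", (-1.0, 0.5, 0.0)),
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.0, 0.5, 0.0)),
            ("O", "O", (0.0, 1.0, 0.6)),
        ):
            names.append(name)
            elements.append(element)
            res_ids.append(i + 1)
            res_names.append(seq3(aa).upper())
            coords.append(ca + np.array(offset))
            bfac.append(gene.plddt[i] * scale)
    shell_res = L
    for i, exposed in enumerate(gene.exposure):
        if exposed:
            continue
        shell_res += 1
        ca = np.array([CHAIN_SPACING * i, 0.0, 0.0])
        for k, vertex in enumerate(_icosahedron()):
            names.append(f"S{k:02d}")
            elements.append("C")
            res_ids.append(shell_res)
            res_names.append("SHL")
            coords.append(ca + SHELL_RADIUS * vertex)
            bfac.append(gene.plddt[i] * scale)

    n = len(names)
    atoms = struc.AtomArray(n)
    atoms.coord = np.array(coords)
    atoms.chain_id = np.array(["A"] * n)
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.array(res_names)
    atoms.atom_name = np.array(names)
    atoms.element = np.array(elements)
    atoms.hetero = np.array([False] * n)
    atoms.set_annotation("b_factor", np.array(bfac))
    pdb = pdbio.PDBFile()
    pdb.set_structure(atoms)
    return "\n".join(pdb.lines) + "\n"


def generate_structures(
    reference: ReferenceFixture, config: FixtureConfig
) -> dict[str, str]:
    """PDB text per transcript id."""
    return {
        gene.transcript_id: structure_pdb_text(gene, config.plddt_scale)
        for gene in reference.genes
    }


# --- top-level -------------------------------------------------------------


@dataclass
class SimulationResult:
    fasta_path: Path
    gff_path: Path
    vcf_path: Path
    structure_dir: Path
    variant_truth_path: Path
    residue_truth_path: Path
    reference: ReferenceFixture
    variant_truth: list[VariantTruth]


def _wrap_fasta(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def simulate(config: FixtureConfig, outdir) -> SimulationResult:
    """Generate and write the full fixture bundle; deterministic per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    vcf_text, variant_truth = generate_variants(reference, config)
    structures = generate_structures(reference, config)

    fasta_path = outdir / "genome.fasta"
    seqs = reference.genome.sequences
    fasta_path.write_text(
        "".join(f">{cid}\n{_wrap_fasta(s)}\n" for cid, s in seqs.items())
    )
    gff_path = outdir / "annotation.gff3"
    gff_path.write_text(reference.gff_text)
    vcf_path = outdir / "variants.vcf"
    vcf_path.write_text(vcf_text)
    structure_dir = outdir / "structures"
    structure_dir.mkdir(exist_ok=True)
    for tid, text in sorted(structures.items()):
        (structure_dir / f"{tid}.pdb").write_text(text)

    vt_path = outdir / "variants_truth.tsv"
    with open(vt_path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\ttranscript_id\tconsequence_type\tgrade\t"
            "residue_index\tplanted_af\texposure\n"
        )
        for t in variant_truth:
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.transcript_id or '.'}\t"
                f"{t.consequence_type}\t{t.grade}\t"
                f"{t.residue_index if t.residue_index is not None else '.'}\t"
                f"{t.planted_af:.6f}\t"
                f"{'.' if t.exposure is None else int(t.exposure)}\n"
            )
    rt_path = outdir / "residues_truth.tsv"
    with open(rt_path, "w") as fh:
        fh.write("transcript_id\tresidue_index\taa\texposure\tplddt\n")
        for gene in reference.genes:
            for i, aa in enumerate(gene.protein):
                fh.write(
                    f"{gene.transcript_id}\t{i + 1}\t{aa}\t"
                    f"{int(gene.exposure[i])}\t{gene.plddt[i]:.2f}\n"
                )
    return SimulationResult(
        fasta_path, gff_path, vcf_path, structure_dir, vt_path, rt_path,
        reference, variant_truth,
    )
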