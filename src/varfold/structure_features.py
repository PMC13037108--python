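"""Per-residue structural features from predicted PDB structures.

Three features per residue:

* pLDDT — the predictor's confidence, read from the B-factor column and
  averaged over the residue's atoms; files on the 0-1 scale (file-wide
  maximum B-factor <= 1) are rescaled to 0-100;
* rASA — solvent-accessible surface area (Shrake–Rupley, 1.4 Å probe)
  divided by the residue's theoretical maximum (Tien et al. 2013,
  "theoretical" column), clamped to [0, 1];
* proportional position — residue index rescaled to [0, 1] so both termini
  hit the endpoints exactly.

The SASA implementation places a deterministic Fibonacci-spiral point set
on each heavy atom's probe-expanded sphere (no RNG). Instead of the hard
in/out occlusion indicator, each point contributes a weight that ramps
linearly from 0 to 1 as its signed distance to the nearest occluding
sphere surface crosses one point-spacing — an antialiased occlusion
boundary that preserves the exact closed forms (no neighbours -> full
area; deep burial -> zero) and monotonicity, while suppressing the
orientation jitter of the raw point count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from Bio.SeqUtils import seq1

#: van der Waals radii (Å) for elements seen in predictor output
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: theoretical maximum accessible surface area per residue (Å²),
#: Tien et al. 2013, "theoretical" column
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    coords: tuple[float, float, float]
    b_factor: float


@dataclass
class ResidueFeature:
    residue_index: int
    aa: str
    plddt: float
    sasa: float
    rasa: float | None
    proportional_position: float


def parse_pdb(path) -> list[AtomRecord]:
    """Read ATOM records of the first model of a PDB file.

    HETATM records are ignored; hydrogens are retained here (SASA excludes
    them later). A file with no ATOM records is a hard error.
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        atoms = pdb_file.get_structure(model=1, extra_fields=["b_factor", "atom_id"])
    except Exception as exc:  # malformed fixed-column content
        raise ValueError(f"unparsable PDB file {path}: {exc}") from exc
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"no ATOM records in {path}")
    records = []
    for i in range(atoms.array_length()):
        records.append(
            AtomRecord(
                serial=int(atoms.atom_id[i]),
                name=str(atoms.atom_name[i]),
                element=str(atoms.element[i]).upper(),
                residue_index=int(atoms.res_id[i]),
                residue_name=str(atoms.res_name[i]),
                coords=tuple(float(x) for x in atoms.coord[i]),
                b_factor=float(atoms.b_factor[i]),
            )
        )
    return records


def residue_plddt(atoms: list[AtomRecord]) -> dict[int, float]:
    """Mean B-factor per residue, rescaled to 0-100 if on the 0-1 dialect."""
    if not atoms:
        return {}
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for a in atoms:
        sums[a.residue_index] = sums.get(a.residue_index, 0.0) + a.b_factor
        counts[a.residue_index] = counts.get(a.residue_index, 0) + 1
    means = {ri: sums[ri] / counts[ri] for ri in sums}
    if max(a.b_factor for a in atoms) <= 1.0:
        means = {ri: v * 100.0 for ri, v in means.items()}
    return means


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (generalized spiral)."""
    i = np.arange(n_points)
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    atoms: list[AtomRecord],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[int, float]:
    """Per-residue solvent-accessible surface area (Å²), heavy atoms only."""
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    heavy = [a for a in atoms if a.element not in {"H", "D"}]
    if not heavy:
        raise ValueError("structure has no heavy atoms")

    coords = np.array([a.coords for a in heavy])
    radii = np.empty(len(heavy))
    for i, a in enumerate(heavy):
        r = VDW_RADII.get(a.element)
        if r is None:
            warnings.warn(
                f"unknown element {a.element!r}; using default radius {DEFAULT_RADIUS} Å"
            )
            r = DEFAULT_RADIUS
        radii[i] = r
    expanded = radii + probe_radius

    sphere = fibonacci_sphere(n_points)
    spacing = np.sqrt(4.0 * np.pi / n_points)  # on the unit sphere
    tree = cKDTree(coords)
    residue_sasa: dict[int, float] = {}
    for i, atom in enumerate(heavy):
        points = coords[i] + expanded[i] * sphere
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], expanded[i] + expanded.max())
            if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]
        ]
        if neighbors:
            ncoords = coords[neighbors]
            nrad = expanded[neighbors]
            dist = np.sqrt(((points[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2))
            signed = (dist - nrad[None, :]).min(axis=1)  # <0 inside an occluder
            weight = np.clip(0.5 + signed / (spacing * expanded[i]), 0.0, 1.0)
            frac = float(weight.mean())
        else:
            frac = 1.0
        area = 4.0 * np.pi * expanded[i] ** 2 * frac
        residue_sasa[atom.residue_index] = residue_sasa.get(atom.residue_index, 0.0) + area
    return residue_sasa


def relative_asa(sasa: float, aa: str) -> float:
    """SASA over the theoretical maximum for that residue, clamped to [0,1]."""
    if sasa < 0:
        raise ValueError("SASA must be non-negative")
    if aa not in MAX_ASA:
        raise ValueError(f"no theoretical maximum ASA for residue {aa!r}")
    return min(1.0, sasa / MAX_ASA[aa])


def proportional_position(residue_index: int, length: int) -> float:
    """(i-1)/(L-1): 0 at the N-terminus, 1 at the C-terminus, 0.5 for L=1."""
    if not 1 <= residue_index <= length:
        raise ValueError(f"residue index {residue_index} outside 1..{length}")
    if length == 1:
        return 0.5
    return (residue_index - 1) / (length - 1)


def residue_features(
    path,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> list[ResidueFeature]:
    """Parse a PDB and compute all per-residue features.

    Residues with non-standard names get aa 'X' and a null rASA; they carry
    no proportional position along the protein (downstream consumers drop
    them). Proportional position is computed over standard residues only.
    """
    atoms = parse_pdb(path)
    plddt = residue_plddt(atoms)
    sasa = shrake_rupley_sasa(atoms, probe_radius=probe_radius, n_points=n_points)

    res_names: dict[int, str] = {}
    for a in atoms:
        res_names.setdefault(a.residue_index, a.residue_name)

    def one_letter(name: str) -> str:
        aa = seq1(name.capitalize(), undef_code="X")
        return aa if aa in MAX_ASA else "X"

    standard = sorted(ri for ri, nm in res_names.items() if one_letter(nm) != "X")
    rank = {ri: k + 1 for k, ri in enumerate(standard)}
    length = len(standard)

    features = []
    for ri in sorted(res_names):
        aa = one_letter(res_names[ri])
        s = sasa.get(ri, 0.0)
        features.append(
            ResidueFeature(
                residue_index=ri,
                aa=aa,
                plddt=plddt.get(ri, 0.0),
                sasa=s,
                rasa=relative_asa(s, aa) if aa != "X" else None,
                proportional_position=(
                    proportional_position(rank[ri], length) if aa != "X" else float("nan")
                ),
            )
        )
    return features
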