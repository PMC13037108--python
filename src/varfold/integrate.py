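"""Join mutation consequences with residue features and compute the
population-genetic summary statistics.

The joined table (one row per mutation x residue) is the substrate for all
statistics: MAF-binned means and standard errors of rASA per effect grade
or substitution subclass, pairwise Mann–Whitney rank tests between grades
(Holm-adjusted), and feature correlations. Mixed-effects modelling is not
performed here; the exported joined TSV is the surface for external model
fitting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from varfold.consequence import CODING_GRADES, ConsequenceCall
from varfold.structure_features import ResidueFeature

JOINED_COLUMNS = [
    "chrom", "pos", "ref", "alt", "maf", "transcript_id", "consequence_type",
    "grade", "residue_index", "ref_aa", "alt_aa", "ref_codon", "alt_codon",
    "plddt", "sasa", "rasa", "proportional_position",
    "class_change", "blosum_score", "codon_class",
]


@dataclass
class JoinStats:
    joined: int = 0
    no_structure: int = 0
    out_of_range: int = 0
    ref_aa_mismatch: int = 0
    non_coding_skipped: int = 0
    mismatched_transcripts: set = field(default_factory=set)


def join_mutations_to_structures(
    calls: Iterable[ConsequenceCall],
    features: Mapping[str, Sequence[ResidueFeature]],
    annotations: Mapping[int, object] | None = None,
) -> tuple[pd.DataFrame, JoinStats]:
    """One row per call that lands on a residue of an available structure.

    ``features`` maps transcript id -> residue feature list. Calls without
    a residue index (MODIFIER grades) are skipped; calls whose residue
    index falls outside the structure are dropped and counted; a ref_aa
    disagreement with the structure's residue identity is joined but
    flagged and counted. ``annotations`` optionally maps ``id(call)`` to a
    SubstitutionAnnotation for subclass columns.
    """
    stats_out = JoinStats()
    rows = []
    indexed: dict[str, dict[int, ResidueFeature]] = {}
    for tid, feats in features.items():
        standard = [f for f in feats if f.aa != "X"]
        indexed[tid] = {k + 1: f for k, f in enumerate(standard)}

    for call in calls:
        if call.residue_index is None or call.grade.value == "MODIFIER":
            stats_out.non_coding_skipped += 1
            continue
        resmap = indexed.get(call.transcript_id)
        if resmap is None:
            stats_out.no_structure += 1
            continue
        feat = resmap.get(call.residue_index)
        if feat is None:
            stats_out.out_of_range += 1
            stats_out.mismatched_transcripts.add(call.transcript_id)
            continue
        if call.ref_aa is not None and call.ref_aa in "ACDEFGHIKLMNPQRSTVWY":
            if feat.aa != call.ref_aa:
                stats_out.ref_aa_mismatch += 1
        ann = (annotations or {}).get(id(call))
        v = call.variant
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "maf": v.maf, "transcript_id": call.transcript_id,
                "consequence_type": call.consequence_type.value,
                "grade": call.grade.value,
                "residue_index": call.residue_index,
                "ref_aa": call.ref_aa, "alt_aa": call.alt_aa,
                "ref_codon": call.ref_codon, "alt_codon": call.alt_codon,
                "plddt": feat.plddt, "sasa": feat.sasa, "rasa": feat.rasa,
                "proportional_position": feat.proportional_position,
                "class_change": getattr(ann, "class_change", None),
                "blosum_score": getattr(ann, "blosum_score", None),
                "codon_class": getattr(ann, "codon_class", None),
            }
        )
        stats_out.joined += 1
    df = pd.DataFrame(rows, columns=JOINED_COLUMNS)
    return df, stats_out


def sample_residues(
    features: Mapping[str, Sequence[ResidueFeature]], n: int, seed: int
) -> list[ResidueFeature]:
    """Uniform sample of residues across all structures, without replacement.

    Returns every residue when n exceeds the total. Reproducible under a
    fixed seed; 'X' placeholder residues are never sampled.
    """
    pool = [
        f
        for tid in sorted(features)
        for f in features[tid]
        if f.aa != "X"
    ]
    if not pool:
        raise ValueError("no residues to sample")
    if n >= len(pool):
        return pool
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def binned_summary(
    records: pd.DataFrame,
    group_by: str = "grade",
    n_bins: int = 10,
    value: str = "rasa",
) -> pd.DataFrame:
    """Mean and standard error of ``value`` per (group, MAF bin).

    Equal-width bins partition [0, 0.5]; the first bin is closed on the
    left, all bins closed on the right. Empty bins are omitted; a
    single-record bin reports se 0 with ``single_record=True``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if records.empty:
        return pd.DataFrame(
            columns=[group_by, "bin_left", "bin_right", "n", f"mean_{value}", f"se_{value}", "single_record"]
        )
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    df = records.dropna(subset=[group_by, value, "maf"]).copy()
    df["_bin"] = pd.cut(df["maf"], bins=edges, include_lowest=True)
    out = []
    for (key, interval), grp in df.groupby([group_by, "_bin"], observed=True, sort=True):
        vals = grp[value].to_numpy(dtype=float)
        n = len(vals)
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            {
                group_by: key,
                "bin_left": float(interval.left if interval.left > 0 else 0.0),
                "bin_right": float(interval.right),
                "n": n,
                f"mean_{value}": float(vals.mean()),
                f"se_{value}": se,
                "single_record": n == 1,
            }
        )
    return pd.DataFrame(out)


def _exact_applicable(x: np.ndarray, y: np.ndarray) -> bool:
    both = np.concatenate([x, y])
    return len(x) <= 8 and len(y) <= 8 and len(np.unique(both)) == len(both)


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]],
    adjust: str = "holm",
) -> pd.DataFrame:
    """Two-sided Mann–Whitney rank-sum test for every pair of groups.

    The exact null distribution is used when both groups have <= 8
    observations and no ties occur; otherwise the normal approximation
    with tie and continuity corrections. P-values are Holm-adjusted across
    all pairs by default.
    """
    if adjust not in {"holm", "none"}:
        raise ValueError(f"adjust must be 'holm' or 'none', got {adjust!r}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {label!r} is empty")
    labels = list(groups)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        method = "exact" if _exact_applicable(x, y) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "group_a": a, "group_b": b, "n_a": len(x), "n_b": len(y),
                "statistic": float(res.statistic), "p_raw": float(res.pvalue),
            }
        )
    df = pd.DataFrame(rows)
    if adjust == "holm":
        df["p_adjusted"] = multipletests(df["p_raw"], method="holm")[1]
    else:
        df["p_adjusted"] = df["p_raw"]
    return df


def grade_rasa_groups(joined: pd.DataFrame) -> dict[str, np.ndarray]:
    """rASA values split by effect grade (LOW/MODERATE/HIGH only)."""
    out = {}
    for grade in CODING_GRADES:
        vals = joined.loc[joined["grade"] == grade.value, "rasa"].dropna().to_numpy()
        if len(vals):
            out[grade.value] = vals
    return out


def feature_correlation(
    features: Sequence[ResidueFeature] | pd.DataFrame,
    x: str,
    y: str,
    method: str = "pearson",
) -> float | None:
    """Correlation between two residue features (pearson or spearman).

    Returns None with a warning when either feature has zero variance.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown method {method!r}")
    if isinstance(features, pd.DataFrame):
        df = features[[x, y]].dropna()
        xv, yv = df[x].to_numpy(dtype=float), df[y].to_numpy(dtype=float)
    else:
        pairs = [
            (getattr(f, x), getattr(f, y))
            for f in features
            if getattr(f, x) is not None and getattr(f, y) is not None
        ]
        arr = np.array(pairs, dtype=float)
        arr = arr[np.isfinite(arr).all(axis=1)]
        xv, yv = arr[:, 0], arr[:, 1]
    if len(xv) < 3:
        raise ValueError("correlation needs at least 3 complete records")
    if np.std(xv) == 0 or np.std(yv) == 0:
        warnings.warn("zero variance in a correlation input; returning None")
        return None
    if method == "pearson":
        return float(stats.pearsonr(xv, yv).statistic)
    return float(stats.spearmanr(xv, yv).statistic)


def terminal_trim(records: pd.DataFrame, trim_fraction: float) -> pd.DataFrame:
    """Drop rows whose proportional position lies in the terminal tails.

    Keeps proportional_position in [trim_fraction, 1 - trim_fraction].
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    if trim_fraction == 0.0:
        return records
    pp = records["proportional_position"]
    return records[(pp >= trim_fraction) & (pp <= 1.0 - trim_fraction)]
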