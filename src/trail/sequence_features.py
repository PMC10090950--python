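"""Physicochemical sequence features and their correlation with turnover.

Features mirror the classic descriptors used in proteome-stability work:
grand average of hydropathy (GRAVY, Kyte-Doolittle), isoelectric point
(Henderson-Hasselbalch with the EMBOSS pKa set), amino-acid-class mole
percentages, molecular weight, and long intrinsically disordered regions
(runs of >= 40 residues with disorder score > 0.5).  Correlations with
rate constants use Spearman's rank coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KYTE_DOOLITTLE",
    "EMBOSS_PKA",
    "POLAR_SET",
    "ACIDIC_SET",
    "BASIC_SET",
    "FeatureVector",
    "gravy",
    "isoelectric_point",
    "polar_mole_percent",
    "class_mole_percent",
    "molecular_weight",
    "find_idrs",
    "compute_features",
    "feature_rate_correlation",
]

logger = logging.getLogger(__name__)

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# EMBOSS pKa values (as used by the pepstats program family)
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

# average (monoisotopic-free) residue masses in Da; water added per chain
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.01524

POLAR_SET = set("DEHKNQRST")
ACIDIC_SET = set("DE")
BASIC_SET = set("KRH")

#: IDR definition: maximal runs of disorder score strictly above this
#: threshold, at least this many residues long
IDR_THRESHOLD = 0.5
IDR_MIN_LENGTH = 40


@dataclass(frozen=True)
class FeatureVector:
    protein_id: str
    gravy: float
    pI: float
    polar_mole_pct: float
    acidic_mole_pct: float
    basic_mole_pct: float
    mol_weight: float
    has_long_idr: bool | None = None
    idr_spans: tuple[tuple[int, int], ...] = ()


def _clean(seq: str) -> str:
    """Uppercase and drop non-canonical residues (X, B, Z, U, ...) with a log."""
    s = seq.upper()
    kept = [c for c in s if c in CANONICAL]
    dropped = len(s) - len(kept)
    if dropped:
        logger.info("excluded %d non-canonical residue(s) from feature math", dropped)
    if not kept:
        raise ValueError("sequence has no canonical residues")
    return "".join(kept)


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle score per residue."""
    s = _clean(seq)
    return float(np.mean([KYTE_DOOLITTLE[c] for c in s]))


def _net_charge(pH: float, counts: dict[str, int]) -> float:
    pos = 0.0
    for group in ("Nterm", "K", "R", "H"):
        n = counts.get(group, 0)
        if n:
            pos += n / (1.0 + 10 ** (pH - EMBOSS_PKA[group]))
    neg = 0.0
    for group in ("Cterm", "D", "E", "C", "Y"):
        n = counts.get(group, 0)
        if n:
            neg += n / (1.0 + 10 ** (EMBOSS_PKA[group] - pH))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the Henderson-Hasselbalch net charge crosses zero.

    Charge sums run over the termini and the ionizable side chains
    (D, E, C, Y, H, K, R) with the EMBOSS pKa set; the root is found by
    bisection to ``|charge| < tol``.  A sequence with no ionizable side
    chains still carries its termini, so a pI is always defined.
    """
    s = _clean(seq)
    counts: dict[str, int] = {"Nterm": 1, "Cterm": 1}
    for aa in "KRHDECY":
        n = s.count(aa)
        if n:
            counts[aa] = n
    lo, hi = 0.0, 14.0
    charge_lo = _net_charge(lo, counts)
    if charge_lo <= 0:  # pathological; charge is decreasing in pH
        return lo
    # bisect the pH interval to convergence; the charge at the root is then
    # far below tol even on flat titration curves
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if _net_charge(mid, counts) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(_net_charge(mid, counts)) >= tol:
        logger.warning("pI charge residual above tolerance (flat titration curve)")
    return mid


def class_mole_percent(seq: str, residue_set) -> float:
    """100 x fraction of (canonical) residues belonging to ``residue_set``."""
    s = _clean(seq)
    return 100.0 * sum(c in residue_set for c in s) / len(s)


def polar_mole_percent(seq: str) -> float:
    """Mole percent of the polar/charged residues D, E, H, K, N, Q, R, S, T."""
    return class_mole_percent(seq, POLAR_SET)


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da over canonical residues."""
    s = _clean(seq)
    return float(sum(_RESIDUE_MASS[c] for c in s) + _WATER)


def find_idrs(
    scores,
    threshold: float = IDR_THRESHOLD,
    min_len: int = IDR_MIN_LENGTH,
) -> list[tuple[int, int]]:
    """Maximal runs of per-residue disorder score strictly above threshold.

    Returns 0-based half-open ``(start, end)`` spans of length >=
    ``min_len``.  Scores at exactly the threshold do not count as
    disordered.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1:
        raise ValueError("scores must be a 1-D array")
    above = x > threshold
    spans: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                spans.append((start, i))
            start = None
    if start is not None and x.size - start >= min_len:
        spans.append((start, x.size))
    return spans


def compute_features(
    protein_id: str,
    seq: str,
    disorder_scores=None,
) -> FeatureVector:
    """All sequence features for one protein.

    ``disorder_scores`` (per-residue, in [0, 1], same length as the raw
    sequence) enable IDR detection; without them the IDR fields are left
    undetermined (None).
    """
    spans: tuple[tuple[int, int], ...] = ()
    has_idr: bool | None = None
    if disorder_scores is not None:
        scores = np.asarray(disorder_scores, dtype=float)
        if scores.size != len(seq):
            raise ValueError(
                f"{protein_id}: {scores.size} disorder scores for {len(seq)} residues"
            )
        spans = tuple(find_idrs(scores))
        has_idr = bool(spans)
    return FeatureVector(
        protein_id=protein_id,
        gravy=gravy(seq),
        pI=isoelectric_point(seq),
        polar_mole_pct=polar_mole_percent(seq),
        acidic_mole_pct=class_mole_percent(seq, ACIDIC_SET),
        basic_mole_pct=class_mole_percent(seq, BASIC_SET),
        mol_weight=molecular_weight(seq),
        has_long_idr=has_idr,
        idr_spans=spans,
    )


def feature_rate_correlation(features: pd.DataFrame, k_values: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each feature column with the rate constants.

    ``features`` is indexed by protein_id with numeric feature columns;
    ``k_values`` is a protein_id-indexed rate series.  Proteins present in
    both are paired; at least 10 pairs are required.  Constant features
    have an undefined correlation and are flagged NaN.
    """
    common = features.index.intersection(k_values.index)
    if common.size < 10:
        raise ValueError("need >=10 paired observations for correlation")
    rows = []
    k = k_values.loc[common].to_numpy(dtype=float)
    for col in features.columns:
        x = features.loc[common, col].to_numpy(dtype=float)
        if np.unique(x).size == 1:
            logger.warning("feature %s is constant; correlation undefined", col)
            rows.append({"feature": col, "rho": float("nan"), "p_value": float("nan"), "n": common.size})
            continue
        rho, p = stats.spearmanr(x, k)
        rows.append({"feature": col, "rho": float(rho), "p_value": float(p), "n": common.size})
    return pd.DataFrame(rows)
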