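"""Cell-division rate estimation from genomic-DNA nucleotide isotopologues.

During continuous 15N labeling, newly replicated DNA strands draw
nucleotides from a precursor pool that is a mixture of fully/partially
labeled species (diet-derived and de novo synthesized) and recycled,
fully unlabeled nucleotides.  Mononucleoside spectra alone cannot separate
old strands from new strands built with recycled nucleotides: both
contribute to the monoisotopic (m=0) peak.  Dinucleotides resolve the
ambiguity because two adjacent nucleotides on one strand were synthesized
together — the labeled envelope of a new strand is the self-convolution of
the per-position precursor distribution, which shifts measurably when the
pool contains recycled unlabeled species.

The per-position precursor distribution for a base with N nitrogen sites is

    pi(0) = r,   pi(m) = (1 - r) * p_lab(m)   for m = 1..N,

with ``r`` the recycled-unlabeled fraction.  Observed (natural-abundance
corrected, normalized) spectra are then

    mono(m) = (1 - f_new) * delta0 + f_new * pi
    di(m)   = (1 - f_new) * delta0 + f_new * (pi (*) pi)

where ``f_new`` is the fraction of newly synthesized strands.  Fitting
(r, f_new) to the dinucleotide envelope, with p_lab read off the labeled
mononucleoside peaks, yields the fraction of new strands per timepoint;
aggregated over all four bases and both units these follow
``f_new(t) = 1 - exp(-k_div t)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .kinetic_core import LN2

__all__ = [
    "NITROGEN_SITES",
    "NATURAL_15N_ABUNDANCE",
    "IsotopologueSpectrum",
    "PrecursorPool",
    "DivisionFit",
    "n_sites",
    "natural_abundance_matrix",
    "natural_abundance_convolve",
    "natural_abundance_correct",
    "precursor_distribution",
    "predict_dinucleotide",
    "estimate_pool",
    "fraction_new_strands",
    "fit_kdiv",
    "analyze_dna_table",
]

logger = logging.getLogger(__name__)

#: nitrogen atoms per deoxynucleoside (the deoxyribose contributes none)
NITROGEN_SITES = {"dA": 5, "dG": 5, "dC": 3, "dT": 2}

#: natural abundance of 15N; 13C isotopes are resolved away by
#: high-resolution acquisition and are not modeled
NATURAL_15N_ABUNDANCE = 0.00364


def n_sites(base: str, unit: str = "mono") -> int:
    """Number of nitrogen sites for a base ('mono') or its homodimer ('di')."""
    if base not in NITROGEN_SITES:
        raise ValueError(f"unknown base {base!r}; expected one of {sorted(NITROGEN_SITES)}")
    if unit not in ("mono", "di"):
        raise ValueError(f"unit must be 'mono' or 'di', got {unit!r}")
    n = NITROGEN_SITES[base]
    return n if unit == "mono" else 2 * n


@dataclass(frozen=True)
class IsotopologueSpectrum:
    """Intensity vector over 15N mass shifts m = 0..N for one analyte.

    ``unit`` is 'mono' for free deoxynucleosides (N = nitrogen count of the
    base) or 'di' for homodimeric dinucleotides (N doubled).
    """

    base: str
    unit: str
    intensities: np.ndarray
    timepoint: float = float("nan")
    tissue: str = ""
    replicate: str | int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        expected = n_sites(self.base, self.unit) + 1
        if x.ndim != 1 or x.size != expected:
            raise ValueError(
                f"{self.base}/{self.unit} spectrum must have {expected} bins, got {x.size}"
            )
        if np.any(x < 0):
            raise ValueError("isotopologue intensities must be non-negative")
        object.__setattr__(self, "intensities", x)

    def normalized(self) -> "IsotopologueSpectrum":
        total = self.intensities.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return IsotopologueSpectrum(
            self.base, self.unit, self.intensities / total,
            self.timepoint, self.tissue, self.replicate,
        )


@dataclass(frozen=True)
class PrecursorPool:
    """Precursor-pool composition and strand mixture at one timepoint.

    ``r``: fraction of fully unlabeled (recycled) nucleotides among those
    incorporated into new strands.  ``p_lab``: distribution over labeled
    species m = 1..N (sums to 1).  ``f_new``: fraction of strands newly
    synthesized since labeling began.  ``identifiable`` is False for
    samples without labeled signal, where r cannot be determined.
    """

    r: float
    p_lab: np.ndarray | None
    f_new: float
    identifiable: bool = True
    residual: float = float("nan")
    base: str = ""
    timepoint: float = float("nan")

    def distribution(self) -> np.ndarray:
        """Per-position precursor distribution pi over m = 0..N."""
        if not self.identifiable:
            raise ValueError("precursor pool is unidentifiable (no labeled signal)")
        return precursor_distribution(self.r, self.p_lab)


@dataclass(frozen=True)
class DivisionFit:
    """Cell-division rate for one tissue."""

    k_div: float
    se: float
    doubling_time: float
    n_observations: int
    flagged: bool = False


# ---------------------------------------------------------------------------
# natural isotope abundance


def natural_abundance_matrix(sites: int, a15n: float) -> np.ndarray:
    """Lower-triangular mixing matrix of the binomial natural-15N envelope.

    ``A[i, j]`` is the probability that a molecule with ``j`` label-derived
    heavy nitrogens is observed at shift ``i``, each of the remaining
    ``sites - j`` positions being naturally heavy independently with
    probability ``a15n``.
    """
    if not 0 <= a15n <= 0.05:
        raise ValueError(f"a15n out of plausible range [0, 0.05]: {a15n!r}")
    A = np.zeros((sites + 1, sites + 1))
    for j in range(sites + 1):
        A[j:, j] = stats.binom.pmf(np.arange(sites + 1 - j), sites - j, a15n)
    return A


def natural_abundance_convolve(spec: IsotopologueSpectrum, a15n: float = NATURAL_15N_ABUNDANCE) -> IsotopologueSpectrum:
    """Forward-apply the natural-abundance envelope (simulation direction)."""
    A = natural_abundance_matrix(spec.intensities.size - 1, a15n)
    return IsotopologueSpectrum(
        spec.base, spec.unit, A @ spec.intensities,
        spec.timepoint, spec.tissue, spec.replicate,
    )


def natural_abundance_correct(spec: IsotopologueSpectrum, a15n: float = NATURAL_15N_ABUNDANCE) -> IsotopologueSpectrum:
    """Deconvolve the natural-15N envelope from an observed spectrum.

    Solves the lower-triangular mixing system exactly; small negative
    artifacts (noise near empty bins) are clamped to zero and the spectrum
    renormalized to its original total.
    """
    y = spec.intensities
    if a15n == 0:
        return spec
    A = natural_abundance_matrix(y.size - 1, a15n)
    x = linalg.solve_triangular(A, y, lower=True)
    neg = x < 0
    if np.any(neg):
        x = np.where(neg, 0.0, x)
        total = y.sum()
        if x.sum() > 0 and total > 0:
            x = x * (total / x.sum())
    return IsotopologueSpectrum(
        spec.base, spec.unit, x, spec.timepoint, spec.tissue, spec.replicate
    )


# ---------------------------------------------------------------------------
# precursor pool model


def precursor_distribution(r: float, p_lab: np.ndarray) -> np.ndarray:
    """pi over m = 0..N: mass r at m=0, (1-r)*p_lab on the labeled species."""
    p_lab = np.asarray(p_lab, dtype=float)
    if not 0 <= r <= 1:
        raise ValueError(f"r must lie in [0, 1], got {r!r}")
    if p_lab.ndim != 1 or np.any(p_lab < 0):
        raise ValueError("p_lab must be a non-negative 1-D distribution")
    s = p_lab.sum()
    if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"p_lab must sum to 1, sums to {s}")
    pi = np.empty(p_lab.size + 1)
    pi[0] = r
    pi[1:] = (1.0 - r) * p_lab
    return pi


def predict_dinucleotide(pi: np.ndarray) -> np.ndarray:
    """Labeled-strand dinucleotide distribution: the self-convolution pi (*) pi.

    Two adjacent positions of a newly synthesized strand draw independently
    from the same precursor pool.
    """
    pi = np.asarray(pi, dtype=float)
    return np.convolve(pi, pi)


def _di_model(r: float, f_new: float, p_lab: np.ndarray) -> np.ndarray:
    conv = predict_dinucleotide(precursor_distribution(r, p_lab))
    out = f_new * conv
    out[0] += 1.0 - f_new
    return out


def estimate_pool(mono: IsotopologueSpectrum, di: IsotopologueSpectrum) -> PrecursorPool:
    """Estimate (r, f_new) from a mono/dinucleotide spectrum pair.

    ``p_lab`` is read off the renormalized labeled peaks of the
    mononucleoside spectrum.  (r, f_new) are then estimated by least
    squares on the full dinucleotide envelope: for each candidate r the
    optimal f_new is available in closed form (the model is linear in
    f_new), so the search is a dense scan over r followed by bounded local
    refinement.  The estimate is invariant to rescaling the raw
    intensities of either spectrum.
    """
    if mono.base != di.base:
        raise ValueError(f"base mismatch: {mono.base} vs {di.base}")
    if mono.unit != "mono" or di.unit != "di":
        raise ValueError("estimate_pool expects a (mono, di) spectrum pair")
    m = mono.normalized().intensities
    y = di.normalized().intensities

    labeled = m[1:]
    lab_total = labeled.sum()
    if lab_total <= 1e-9:
        # fully unlabeled sample: no new-strand signal, r unidentifiable
        return PrecursorPool(
            r=float("nan"), p_lab=None, f_new=0.0, identifiable=False,
            residual=0.0, base=mono.base, timepoint=mono.timepoint,
        )
    p_lab = labeled / lab_total

    delta0 = np.zeros_like(y)
    delta0[0] = 1.0

    def best_f(r: float) -> tuple[float, float]:
        d = predict_dinucleotide(precursor_distribution(r, p_lab)) - delta0
        denom = float(d @ d)
        f = float(np.clip((d @ (y - delta0)) / denom, 0.0, 1.0)) if denom > 0 else 0.0
        resid = y - delta0 - f * d
        return f, float(resid @ resid)

    r_grid = np.linspace(0.0, 0.99, 100)
    losses = np.array([best_f(r)[1] for r in r_grid])
    r0 = float(r_grid[np.argmin(losses)])

    res = optimize.minimize_scalar(
        lambda r: best_f(r)[1],
        bounds=(max(0.0, r0 - 0.02), min(0.999, r0 + 0.02)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat = float(res.x)
    f_hat, loss = best_f(r_hat)
    return PrecursorPool(
        r=r_hat, p_lab=p_lab, f_new=f_hat, identifiable=True,
        residual=loss, base=mono.base, timepoint=mono.timepoint,
    )


def fraction_new_strands(pool: PrecursorPool) -> float:
    """Fraction of newly synthesized strands implied by a fitted pool."""
    if not pool.identifiable and pool.f_new > 0:
        raise ValueError("pool is unidentifiable")
    return pool.f_new


def mono_fraction_new(mono: IsotopologueSpectrum, r: float = 0.0) -> float:
    """New-strand fraction from a mononucleoside spectrum alone.

    The labeled (non-monoisotopic) fraction equals ``f_new * (1 - r)``;
    with the empirically observed regime of negligible recycling (r = 0)
    it is the new-strand fraction directly.
    """
    m = mono.normalized().intensities
    lab = float(m[1:].sum())
    if r >= 1:
        raise ValueError("r must be < 1")
    return min(lab / (1.0 - r), 1.0)


# ---------------------------------------------------------------------------
# rate fitting


def fit_kdiv(times, fractions_new) -> DivisionFit:
    """Fit ``f_new(t) = 1 - exp(-k_div t)`` to aggregated observations.

    Observations from all four bases and both units are weighted equally.
    Samples with no labeling signal anywhere yield k_div ~ 0 with a wide
    standard error and are flagged.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions_new, dtype=float)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("times and fractions must be 1-D arrays of equal length")
    if np.unique(t).size < 3:
        raise ValueError("need >=3 distinct timepoints to fit k_div")
    if np.any((f < -1e-9) | (f > 1 + 1e-9)):
        raise ValueError("fractions must lie in [0, 1]")

    if np.all(f < 1e-9):
        return DivisionFit(
            k_div=0.0, se=float("inf"), doubling_time=float("inf"),
            n_observations=t.size, flagged=True,
        )

    def model(tt, k):
        return 1.0 - np.exp(-k * tt)

    with np.errstate(over="ignore"):
        popt, pcov = optimize.curve_fit(
            model, t, f, p0=[0.05], bounds=(0.0, 10.0),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=10000,
        )
    k = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    doubling = LN2 / k if k > 0 else float("inf")
    return DivisionFit(k_div=k, se=se, doubling_time=doubling, n_observations=t.size, flagged=False)


def analyze_dna_table(
    table: pd.DataFrame,
    a15n: float = NATURAL_15N_ABUNDANCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue division-rate estimation from a long isotopologue table.

    Expects columns ``tissue, timepoint_days, replicate, base, unit,
    m_shift, intensity``.  For every (tissue, timepoint, replicate, base)
    the mono/di pair is natural-abundance corrected and the precursor pool
    fitted; new-strand fractions from both units then enter a single
    aggregated exponential fit per tissue.

    Returns ``(division_fits, pool_diagnostics)`` DataFrames.
    """
    fits = []
    diags = []
    if "replicate" not in table.columns:
        table = table.assign(replicate=0)
    for tissue, tissue_block in table.groupby("tissue", sort=False):
        obs_t, obs_f = [], []
        for (tp, rep, base), grp in tissue_block.groupby(
            ["timepoint_days", "replicate", "base"], sort=False
        ):
            spectra = {}
            for unit, ugrp in grp.groupby("unit", sort=False):
                vec = np.zeros(n_sites(base, unit) + 1)
                vec[ugrp["m_shift"].to_numpy(dtype=int)] = ugrp["intensity"].to_numpy(dtype=float)
                spec = IsotopologueSpectrum(base, unit, vec, timepoint=tp, tissue=tissue, replicate=rep)
                spectra[unit] = natural_abundance_correct(spec, a15n)
            if "mono" not in spectra or "di" not in spectra:
                logger.warning("tissue %s t=%s base %s: incomplete mono/di pair, skipped", tissue, tp, base)
                continue
            pool = estimate_pool(spectra["mono"], spectra["di"])
            f_di = pool.f_new
            f_mono = mono_fraction_new(spectra["mono"], r=pool.r if pool.identifiable else 0.0)
            obs_t.extend([tp, tp])
            obs_f.extend([f_mono, f_di])
            diags.append({
                "tissue": tissue, "timepoint_days": tp, "replicate": rep, "base": base,
                "r": pool.r, "f_new_di": f_di, "f_new_mono": f_mono,
                "identifiable": pool.identifiable, "residual": pool.residual,
            })
        fit = fit_kdiv(obs_t, obs_f)
        fits.append({
            "tissue": tissue, "k_div": fit.k_div, "se": fit.se,
            "doubling_time": fit.doubling_time, "n_observations": fit.n_observations,
            "flagged": fit.flagged,
        })
    return pd.DataFrame(fits), pd.DataFrame(diags)
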