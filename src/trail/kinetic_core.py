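"""First-order kinetic model shared by the protein and DNA arms of TRAIL.

In a continuous-labeling experiment the unlabeled fraction of a protein
pool decays as a single exponential.  Because a subpopulation of the signal
may never label (e.g. contamination of dissected tissue with slowly
perfused extracellular material), the fitting model carries a constant
fractional baseline::

    y(t) = baseline + (1 - baseline) * exp(-k_t * t)

The observed clearance rate decomposes additively,

    k_t = k_deg + k_div,

where ``k_deg`` is proteolytic degradation and ``k_div`` dilution by cell
division.  All times are in days and all rates in 1/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LN2",
    "DecaySeries",
    "TurnoverFit",
    "CorrectedRate",
    "InsufficientDataError",
    "half_life",
    "rate_from_half_life",
    "fit_first_order_decay",
    "goodness_stats",
    "correct_kdeg",
]

LN2 = math.log(2.0)

#: optimizer bounds: rates in (1e-6, 10] / day, baseline in [0, 0.95)
K_BOUNDS = (1e-6, 10.0)
BASELINE_BOUNDS = (0.0, 0.95)


class InsufficientDataError(ValueError):
    """Raised when a decay series has fewer than 3 distinct timepoints."""


@dataclass(frozen=True)
class DecaySeries:
    """Normalized unlabeled-fraction observations for one protein.

    ``times`` are labeling durations in days (non-negative, should include
    0), ``values`` the t0-normalized unlabeled signal, and
    ``replicate_ids`` a per-observation replicate label.  Observations from
    all replicates are pooled into a single curve before fitting.
    """

    times: np.ndarray
    values: np.ndarray
    replicate_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(t < 0):
            raise ValueError("labeling times must be non-negative")
        r = self.replicate_ids
        if r is None:
            r = np.zeros(t.shape, dtype=int)
        else:
            r = np.asarray(r)
            if r.shape != t.shape:
                raise ValueError("replicate_ids must match times in length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "replicate_ids", r)

    @property
    def n_distinct_timepoints(self) -> int:
        return np.unique(self.times).size

    @property
    def n_replicates(self) -> int:
        return np.unique(self.replicate_ids).size


@dataclass(frozen=True)
class TurnoverFit:
    """Result of fitting the baseline-plus-exponential decay model."""

    k_t: float
    se_k: float
    baseline: float
    r2: float
    t_stat: float
    p_value: float
    n_points: int
    n_replicates: int = 1
    n_psm_total: int = 0
    half_life: float = float("nan")
    converged: bool = True

    def with_counts(self, n_replicates: int, n_psm_total: int) -> "TurnoverFit":
        return replace(self, n_replicates=n_replicates, n_psm_total=n_psm_total)


@dataclass(frozen=True)
class CorrectedRate:
    """Cell-cycle-corrected degradation rate for one protein in one tissue.

    ``t_half_corr`` is NaN when ``k_deg <= 0`` (turnover fully accounted
    for by dilution; a degradative half-life is then undefined).
    """

    k_deg: float
    t_half_corr: float
    division_dominated: bool


def half_life(k: float) -> float:
    """Half-life in days of a first-order process with rate ``k`` (1/day)."""
    if not k > 0:
        raise ValueError(f"rate must be positive, got {k!r}")
    return LN2 / k


def rate_from_half_life(t_half: float) -> float:
    """Inverse of :func:`half_life`."""
    if not t_half > 0:
        raise ValueError(f"half-life must be positive, got {t_half!r}")
    return LN2 / t_half


def _model(t: np.ndarray, k: float, baseline: float) -> np.ndarray:
    return baseline + (1.0 - baseline) * np.exp(-k * t)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Baseline from the smallest observed value; rate from a log-linear
    # regression of the baseline-subtracted signal.
    b0 = float(np.clip(np.min(y) * 0.9, 0.0, 0.9))
    resid = y - b0
    mask = resid > 1e-3
    if mask.sum() >= 2 and np.unique(t[mask]).size >= 2:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        k0 = float(np.clip(-slope, 1e-3, K_BOUNDS[1]))
    else:
        k0 = 0.1
    return k0, b0


def _failed_fit(n_points: int) -> TurnoverFit:
    nan = float("nan")
    return TurnoverFit(
        k_t=nan, se_k=nan, baseline=nan, r2=nan, t_stat=nan, p_value=nan,
        n_points=n_points, converged=False,
    )


def fit_first_order_decay(series: DecaySeries) -> TurnoverFit:
    """Least-squares fit of ``baseline + (1 - baseline) exp(-k t)``.

    Uses a bounded trust-region solver; the standard error of ``k`` comes
    from the Jacobian-based covariance estimate at the optimum (residual
    variance scaled).  Non-convergence is reported as a flagged failed fit
    (``converged=False``) rather than an exception, so batch runs over
    thousands of proteins continue.

    Raises
    ------
    InsufficientDataError
        If the series has fewer than 3 distinct timepoints.
    """
    t = series.times
    y = series.values
    if series.n_distinct_timepoints < 3:
        raise InsufficientDataError(
            f"need >=3 distinct timepoints, got {series.n_distinct_timepoints}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("decay values must be finite")
    if np.any(y < -0.1) or np.any(y > 1.5):
        raise ValueError("normalized values out of tolerated range [-0.1, 1.5]")

    n = t.size
    k0, b0 = _initial_guess(t, y)
    try:
        popt, pcov = optimize.curve_fit(
            _model, t, y,
            p0=[k0, b0],
            bounds=([K_BOUNDS[0], BASELINE_BOUNDS[0]], [K_BOUNDS[1], BASELINE_BOUNDS[1]]),
            method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return _failed_fit(n)

    k_hat, b_hat = float(popt[0]), float(popt[1])
    se_k = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")

    resid = y - _model(t, k_hat, b_hat)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    t_stat, p_value = goodness_stats(k_hat, se_k, n)
    return TurnoverFit(
        k_t=k_hat,
        se_k=se_k,
        baseline=b_hat,
        r2=r2,
        t_stat=t_stat,
        p_value=p_value,
        n_points=n,
        n_replicates=series.n_replicates,
        half_life=half_life(k_hat) if k_hat > 0 else float("nan"),
        converged=True,
    )


def goodness_stats(k_t: float, se_k: float, n_points: int) -> tuple[float, float]:
    """t-statistic and one-sided p-value for a fitted rate.

    ``t_stat = k_t / se_k``; the p-value is the upper tail of a Student-t
    reference with ``n_points - 2`` degrees of freedom (two fitted
    parameters), i.e. the probability of observing a rate this far above
    zero if the true rate were zero.  A vanishing standard error yields the
    ``(+inf, 0)`` sentinel.
    """
    if se_k < 0 or not np.isfinite(k_t):
        return float("nan"), float("nan")
    if se_k == 0:
        return float("inf"), 0.0
    t_stat = k_t / se_k
    df = max(n_points - 2, 1)
    p_value = float(stats.t.sf(t_stat, df))
    return float(t_stat), p_value


def correct_kdeg(k_t: float, k_div: float) -> CorrectedRate:
    """Subtract the cell-division rate from the observed turnover rate.

    ``k_deg = k_t - k_div``.  A protein is flagged division-dominated when
    ``k_t <= k_div``: its clearance is explained by dilution during cell
    division, and a corrected degradative half-life is undefined.
    """
    if not k_t > 0:
        raise ValueError(f"k_t must be positive, got {k_t!r}")
    if k_div < 0:
        raise ValueError(f"k_div must be non-negative, got {k_div!r}")
    k_deg = k_t - k_div
    dominated = k_t <= k_div
    t_half_corr = LN2 / k_deg if k_deg > 0 else float("nan")
    return CorrectedRate(k_deg=k_deg, t_half_corr=t_half_corr, division_dominated=bool(dominated))
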