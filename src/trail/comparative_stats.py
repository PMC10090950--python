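"""Cross-tissue and within-complex statistics on fitted turnover rates.

The central quantity is the index of dispersion of a set of rate
constants: the population variance divided by the mean.  Computed across
tissues for one protein it measures how variable that protein's
degradation rate is from tissue to tissue (D); computed within one tissue
across the subunits of a multiprotein complex it measures how coherently
the complex turns over (d).  Complex-level dispersions are benchmarked
against nulls built from random subsets of the detected proteome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .kinetic_core import TurnoverFit

__all__ = [
    "MIN_COMPLEX_SUBUNITS",
    "dispersion",
    "intracomplex_dispersion",
    "random_complex_null",
    "coherence_test",
    "rate_difference_test",
    "division_dominated_fraction",
    "subset_vs_proteome_test",
    "complex_median_decile",
    "cross_tissue_dispersion_table",
]

logger = logging.getLogger(__name__)

#: complexes enter dispersion analyses only with >= 5 detected subunits
MIN_COMPLEX_SUBUNITS = 5


def dispersion(values, sample: bool = False) -> float:
    """Index of dispersion: variance divided by mean.

    The variance is the population variance (average squared deviation
    from the mean, i.e. divide by n); set ``sample=True`` for the n-1
    variant.  Undefined (NaN) when the mean is not positive.  Note the
    scaling behavior: dispersion(c*x) = c*dispersion(x) for c > 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >=2 finite values")
    mean = x.mean()
    if mean <= 0:
        logger.warning("dispersion undefined for non-positive mean %.4g", mean)
        return float("nan")
    if np.ptp(x) == 0:  # exactly zero for all-equal input
        return 0.0
    var = x.var(ddof=1 if sample else 0)
    return float(var / mean)


def intracomplex_dispersion(
    subunit_rates: dict[str, float] | pd.Series,
    min_subunits: int = MIN_COMPLEX_SUBUNITS,
) -> float | None:
    """Dispersion of a complex's subunit rates within one tissue.

    Returns None (complex skipped, logged) with fewer than ``min_subunits``
    detected subunits.
    """
    rates = pd.Series(subunit_rates).dropna()
    if rates.size < min_subunits:
        logger.info("complex skipped: %d < %d detected subunits", rates.size, min_subunits)
        return None
    return dispersion(rates.to_numpy())


def random_complex_null(
    n_subunits: int,
    proteome_rates,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null dispersion distribution from random proteome subsets.

    Each draw picks ``n_subunits`` proteins uniformly without replacement
    from the detected proteome and records their dispersion.  Reproducible
    for a given seed.
    """
    rates = np.asarray(proteome_rates, dtype=float)
    if rates.size < n_subunits:
        raise ValueError("proteome smaller than requested subset size")
    if n_draws < 100:
        raise ValueError("need at least 100 null draws")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n_draws)
    for i in range(n_draws):
        out[i] = dispersion(rng.choice(rates, size=n_subunits, replace=False))
    return out


def coherence_test(observed_d, null_d) -> float:
    """One-sided test that complexes are more coherent than random sets.

    Rank-sum (Mann-Whitney) comparison of the observed per-complex
    dispersions against the random null, alternative: observed lower.
    With a single observed complex, falls back to the empirical percentile
    ``(1 + #null <= d) / (1 + n_null)``.  Degenerate all-tied input yields
    p = 1 with a warning.
    """
    obs = np.atleast_1d(np.asarray(observed_d, dtype=float))
    null = np.asarray(null_d, dtype=float)
    if obs.size < 1 or null.size < 100:
        raise ValueError("need >=1 observed dispersion and >=100 null draws")
    pooled = np.concatenate([obs, null])
    if np.unique(pooled).size == 1:
        logger.warning("coherence test degenerate: all dispersions tied")
        return 1.0
    if obs.size == 1:
        return float((1 + np.sum(null <= obs[0])) / (1 + null.size))
    return float(stats.mannwhitneyu(obs, null, alternative="less", method="asymptotic").pvalue)


def rate_difference_test(fit1: TurnoverFit, fit2: TurnoverFit) -> float:
    """Welch-type two-sample test on the difference of two fitted rates.

    Uses each fit's standard error with Welch-Satterthwaite degrees of
    freedom (per-fit df = n_points - 2); two-sided, symmetric in argument
    order.  Fits without a usable standard error cannot be tested.
    """
    for f in (fit1, fit2):
        if not (np.isfinite(f.se_k) and f.se_k > 0):
            raise ValueError("rate difference test requires positive finite standard errors")
    v1, v2 = fit1.se_k**2, fit2.se_k**2
    df1 = max(fit1.n_points - 2, 1)
    df2 = max(fit2.n_points - 2, 1)
    t = (fit1.k_t - fit2.k_t) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)
    return float(2.0 * stats.t.sf(abs(t), df))


def division_dominated_fraction(k_t_values, k_div: float) -> float:
    """Fraction of proteins cleared primarily by dilution (k_t <= k_div)."""
    k = np.asarray(k_t_values, dtype=float)
    if k.size == 0:
        raise ValueError("empty rate collection")
    if k_div < 0:
        raise ValueError("k_div must be non-negative")
    return float(np.mean(k <= k_div))


def subset_vs_proteome_test(subset_values, proteome_values) -> tuple[float, str]:
    """Two-sided Mann-Whitney test of a protein subset against its complement.

    Returns ``(p_value, direction)`` with direction 'higher' or 'lower'
    comparing subset median to complement median.  The subset must be a
    proper part of the proteome with at least 5 members.
    """
    sub = np.asarray(subset_values, dtype=float)
    prot = np.asarray(proteome_values, dtype=float)
    if sub.size < MIN_COMPLEX_SUBUNITS:
        raise ValueError("subset too small (need >= 5)")
    if sub.size >= prot.size:
        raise ValueError("subset must be a proper subset of the proteome")
    # complement by multiset removal
    comp = prot.copy()
    for v in sub:
        idx = np.nonzero(comp == v)[0]
        if idx.size:
            comp = np.delete(comp, idx[0])
    if comp.size == 0:
        raise ValueError("complement is empty")
    p = float(stats.mannwhitneyu(sub, comp, alternative="two-sided", method="asymptotic").pvalue)
    direction = "higher" if np.median(sub) > np.median(comp) else "lower"
    return p, direction


def complex_median_decile(
    subunit_deciles,
    proteome_median_decile: float = 5.5,
    min_subunits: int = MIN_COMPLEX_SUBUNITS,
) -> tuple[float, float] | None:
    """Median turnover decile of a complex plus a one-sample test.

    Returns ``(median_decile, p_value)`` where the p-value is a two-sided
    one-sample t-test of the subunit deciles against the proteome median
    decile (5.5 for deciles 1..10).  Complexes with fewer than
    ``min_subunits`` subunits are skipped (None).
    """
    d = np.asarray(subunit_deciles, dtype=float)
    if d.size < min_subunits:
        logger.info("complex skipped in decile analysis: %d subunits", d.size)
        return None
    res = stats.ttest_1samp(d, proteome_median_decile)
    return float(np.median(d)), float(res.pvalue)


def cross_tissue_dispersion_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-protein cross-tissue dispersion D of k_deg.

    ``rates`` is long format with columns ``protein_id, tissue, k_deg``;
    only proteins detected in at least two tissues with positive mean rate
    receive a D value.
    """
    rows = []
    for pid, block in rates.groupby("protein_id", sort=False):
        k = block["k_deg"].to_numpy(dtype=float)
        k = k[np.isfinite(k)]
        if k.size < 2:
            continue
        rows.append({"protein_id": pid, "n_tissues": k.size, "D": dispersion(k) if k.mean() > 0 else float("nan")})
    return pd.DataFrame(rows)
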