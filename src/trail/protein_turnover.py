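"""TMT-SILAM proteome processing: coverage filtering, t0 normalization,
per-protein turnover fitting with quality gates, decile assignment, and
relative-abundance scoring.

The input is a long-format reporter table with one row per
(protein, replicate, channel): columns ``protein_id``, ``replicate``,
``channel``, ``timepoint_days``, ``reporter_sn`` (summed reporter-ion
signal-to-noise) and ``psm_count``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetic_core import DecaySeries, InsufficientDataError, fit_first_order_decay

__all__ = [
    "QualityConfig",
    "REPORTER_COLUMNS",
    "filter_coverage",
    "normalize_to_t0",
    "fit_protein_kt",
    "process_reporter_table",
    "assign_deciles",
    "relative_abundance",
]

logger = logging.getLogger(__name__)

REPORTER_COLUMNS = [
    "protein_id", "replicate", "channel", "timepoint_days", "reporter_sn", "psm_count",
]


@dataclass(frozen=True)
class QualityConfig:
    """Quality gates applied to per-protein fits.

    ``min_psm_per_channel``: a protein is retained within a replicate only
    if every channel of that replicate carries at least this many PSMs.
    ``min_total_psm``: minimum PSMs summed over the pooled fit.
    ``min_t_stat``: the fitted rate must exceed this many standard errors.
    ``min_replicates``: minimum replicates contributing to the pooled fit.
    """

    min_psm_per_channel: int = 3
    min_total_psm: int = 4
    min_t_stat: float = 3.0
    min_replicates: int = 2

    def __post_init__(self) -> None:
        for name in ("min_psm_per_channel", "min_total_psm", "min_t_stat", "min_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_coverage(table: pd.DataFrame, cfg: QualityConfig | None = None) -> pd.DataFrame:
    """Retain, per replicate, proteins covered in every channel.

    A (protein, replicate) block survives only if it has a row for every
    channel observed in that replicate's run and every channel carries at
    least ``cfg.min_psm_per_channel`` PSMs.  Blocks missing channels are
    dropped with a logged warning.
    """
    if table.empty:
        raise ValueError("reporter table is empty")
    cfg = cfg or QualityConfig()
    keys = ["protein_id", "replicate"]

    expected = table.groupby("replicate", sort=False)["channel"].agg(frozenset)
    info = table.groupby(keys, sort=False).agg(
        min_psm=("psm_count", "min"),
        channels=("channel", frozenset),
    )
    complete = pd.Series(
        [chans == expected[rep] for (_, rep), chans in info["channels"].items()],
        index=info.index,
    )
    for pid, rep in info.index[~complete]:
        logger.warning("dropping protein %s replicate %s: missing channel(s)", pid, rep)
    ok = complete & (info["min_psm"] >= cfg.min_psm_per_channel)

    row_keys = pd.MultiIndex.from_frame(table[keys])
    out = table[ok.reindex(row_keys).to_numpy()].reset_index(drop=True)
    logger.info(
        "coverage filter: %d/%d protein-replicate blocks retained", int(ok.sum()), len(ok)
    )
    return out


def normalize_to_t0(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each channel's signal by its replicate's t=0 signal.

    Adds a ``frac_unlabeled`` column; the t0 channel maps to exactly 1.
    (protein, replicate) blocks whose t0 signal is zero or absent are
    excluded with a warning.  The operation is idempotent on its output.
    """
    out = []
    for (pid, rep), block in table.groupby(["protein_id", "replicate"], sort=False):
        t0 = block.loc[block["timepoint_days"] == 0, "reporter_sn"]
        if t0.empty or not (t0 > 0).all():
            logger.warning("excluding protein %s replicate %s: no positive t0 signal", pid, rep)
            continue
        t0_value = float(t0.mean())  # multiple t0 channels: use their mean
        b = block.copy()
        b["frac_unlabeled"] = b["reporter_sn"] / t0_value
        out.append(b)
    if not out:
        return table.iloc[0:0].assign(frac_unlabeled=pd.Series(dtype=float))
    return pd.concat(out, ignore_index=True)


def _series_from_rows(block: pd.DataFrame) -> DecaySeries:
    return DecaySeries(
        times=block["timepoint_days"].to_numpy(dtype=float),
        values=block["frac_unlabeled"].to_numpy(dtype=float),
        replicate_ids=block["replicate"].to_numpy(),
    )


def fit_protein_kt(normalized: pd.DataFrame, cfg: QualityConfig | None = None) -> pd.DataFrame:
    """Fit one pooled decay curve per protein and apply quality gates.

    Replicate observations are aggregated into a single kinetic curve per
    protein.  A fit PASSes only if it converged with ``t_stat >
    min_t_stat``, carries ``>= min_total_psm`` PSMs in total, and pools
    ``>= min_replicates`` replicates.

    Returns a table with one row per protein: the fit parameters, QC
    counts, and a boolean ``passed`` column.
    """
    cfg = cfg or QualityConfig()
    rows = []
    for pid, block in normalized.groupby("protein_id", sort=False):
        n_psm = int(block["psm_count"].sum())
        n_rep = int(block["replicate"].nunique())
        try:
            fit = fit_first_order_decay(_series_from_rows(block))
        except (InsufficientDataError, ValueError) as exc:
            logger.warning("protein %s: skipped (%s)", pid, exc)
            continue
        fit = fit.with_counts(n_replicates=n_rep, n_psm_total=n_psm)
        passed = (
            fit.converged
            and fit.t_stat > cfg.min_t_stat
            and n_psm >= cfg.min_total_psm
            and n_rep >= cfg.min_replicates
        )
        rows.append({
            "protein_id": pid,
            "k_t": fit.k_t,
            "se_k": fit.se_k,
            "baseline": fit.baseline,
            "r2": fit.r2,
            "t_stat": fit.t_stat,
            "p_value": fit.p_value,
            "t_half": fit.half_life,
            "n_points": fit.n_points,
            "n_replicates": n_rep,
            "n_psm_total": n_psm,
            "converged": fit.converged,
            "passed": bool(passed),
        })
    return pd.DataFrame(rows)


def process_reporter_table(table: pd.DataFrame, cfg: QualityConfig | None = None) -> pd.DataFrame:
    """Full per-tissue pipeline: coverage filter, t0 normalization, pooled fits."""
    cfg = cfg or QualityConfig()
    filtered = filter_coverage(table, cfg)
    if filtered.empty:
        return pd.DataFrame()
    normalized = normalize_to_t0(filtered)
    return fit_protein_kt(normalized, cfg)


def assign_deciles(k_values) -> np.ndarray:
    """Decile index (1..10) per rate: 1 = slowest 10%, 10 = fastest 10%.

    Deciles differ in size by at most one; ties are broken by stable input
    order so the assignment is reproducible.  Any strictly monotone
    transform of the rates yields the same assignment.
    """
    k = np.asarray(k_values, dtype=float)
    if k.ndim != 1 or k.size < 10:
        raise ValueError("need at least 10 values for decile assignment")
    order = np.argsort(k, kind="stable")
    deciles = np.empty(k.size, dtype=int)
    for i, chunk in enumerate(np.array_split(order, 10)):
        deciles[chunk] = i + 1
    return deciles


def relative_abundance(
    wt_table: pd.DataFrame,
    lengths: dict[str, int] | pd.Series,
) -> pd.Series:
    """Relative protein abundance from unlabeled (wild-type) channels.

    Expects columns ``protein_id``, ``bio_replicate``, ``channel``,
    ``intensity``.  Procedure: equalize per-channel column sums within each
    biological replicate (channel normalization of technical replicates),
    geometric-mean the channels per biological replicate, divide by protein
    length in residues, rescale each biological replicate by its maximum,
    then geometric-mean across biological replicates.  Proteins with
    zero/absent signal in any contributing channel are excluded.
    """
    lengths = pd.Series(lengths, dtype=float)
    df = wt_table.copy()
    df = df[df["protein_id"].isin(lengths.index)]
    if df.empty:
        raise ValueError("no proteins with known lengths in abundance table")

    per_bio = []
    for bio, block in df.groupby("bio_replicate", sort=False):
        mat = block.pivot_table(index="protein_id", columns="channel", values="intensity")
        mat = mat.dropna()
        mat = mat[(mat > 0).all(axis=1)]
        if mat.empty:
            continue
        col_sums = mat.sum(axis=0)
        mat = mat * (col_sums.mean() / col_sums)      # channel normalization
        gm = np.exp(np.log(mat).mean(axis=1))          # geometric mean over channels
        gm = gm / lengths.reindex(gm.index)            # per-residue abundance
        gm = gm / gm.max()                             # scale replicate to its max
        gm.name = bio
        per_bio.append(gm)
    if not per_bio:
        raise ValueError("no usable biological replicate in abundance table")
    joined = pd.concat(per_bio, axis=1).dropna()
    score = np.exp(np.log(joined).mean(axis=1))        # geometric mean across replicates
    score.name = "relative_abundance"
    return score
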