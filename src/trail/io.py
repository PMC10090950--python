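"""Readers and writers for the delimited-text formats the pipeline uses.

Canonical dialect is tab-separated UTF-8 with a header row and stable
column order; comma-separated input is accepted on read.  FASTA ids are
the first whitespace-delimited token of the description line (UniProt
convention).  Disorder-score files use 1-based residue positions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .dna_turnover import n_sites
from .protein_turnover import REPORTER_COLUMNS

__all__ = [
    "read_reporter_table",
    "write_reporter_table",
    "read_isotopologue_table",
    "write_isotopologue_table",
    "read_fasta_lengths",
    "read_fasta_sequences",
    "read_disorder_scores",
    "read_membership",
    "write_table",
]

logger = logging.getLogger(__name__)

ISOTOPOLOGUE_COLUMNS = ["tissue", "timepoint_days", "replicate", "base", "unit", "m_shift", "intensity"]


def _read_delimited(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_reporter_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format TMT reporter table."""
    df = _read_delimited(path, REPORTER_COLUMNS)
    for col in ("timepoint_days", "reporter_sn"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if bad.size:
            raise ValueError(f"{path}: unparseable {col} in rows {list(bad[:10])}")
        df[col] = pd.to_numeric(df[col])
    df["psm_count"] = pd.to_numeric(df["psm_count"], errors="raise").astype(int)
    if (df["psm_count"] < 0).any() or (df["reporter_sn"] < 0).any():
        raise ValueError(f"{path}: negative PSM counts or signals")
    dup = df.duplicated(subset=["protein_id", "replicate", "channel"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["protein_id", "replicate", "channel"]].drop_duplicates()
        raise ValueError(
            f"{path}: duplicate (protein, replicate, channel) rows:\n{offenders.to_string(index=False)}"
        )
    return df[REPORTER_COLUMNS + [c for c in df.columns if c not in REPORTER_COLUMNS]]


def write_reporter_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = REPORTER_COLUMNS + [c for c in df.columns if c not in REPORTER_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def read_isotopologue_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format isotopologue intensity table.

    Each (base, unit) spectrum's mass shifts must fit the base's nitrogen
    count (e.g. mono dT allows only m = 0..2).
    """
    required = [c for c in ISOTOPOLOGUE_COLUMNS if c != "replicate"]
    df = _read_delimited(path, required)
    if "replicate" not in df.columns:
        df["replicate"] = 0
    df["m_shift"] = pd.to_numeric(df["m_shift"], errors="raise").astype(int)
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    df["timepoint_days"] = pd.to_numeric(df["timepoint_days"], errors="raise")
    if (df["intensity"] < 0).any():
        raise ValueError(f"{path}: negative intensities")
    for (base, unit), grp in df.groupby(["base", "unit"]):
        limit = n_sites(base, unit)
        too_big = grp.loc[grp["m_shift"] > limit]
        if not too_big.empty:
            raise ValueError(
                f"{path}: m_shift beyond {limit} for {base}/{unit} "
                f"(rows {list(too_big.index[:10])})"
            )
        if (grp["m_shift"] < 0).any():
            raise ValueError(f"{path}: negative m_shift for {base}/{unit}")
    return df[ISOTOPOLOGUE_COLUMNS + [c for c in df.columns if c not in ISOTOPOLOGUE_COLUMNS]]


def write_isotopologue_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = ISOTOPOLOGUE_COLUMNS + [c for c in df.columns if c not in ISOTOPOLOGUE_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; id is the first whitespace token."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    return {pid: len(s) for pid, s in read_fasta_sequences(path).items()}


def read_disorder_scores(path: str | Path) -> dict[str, np.ndarray]:
    """Per-residue disorder scores: columns protein_id, position (1-based), score."""
    df = _read_delimited(path, ["protein_id", "position", "score"])
    out: dict[str, np.ndarray] = {}
    for pid, block in df.groupby("protein_id", sort=False):
        pos = block["position"].to_numpy(dtype=int)
        if pos.min() < 1:
            raise ValueError(f"{path}: positions are 1-based; got {pos.min()} for {pid}")
        scores = np.full(pos.max(), np.nan)
        scores[pos - 1] = block["score"].to_numpy(dtype=float)
        out[pid] = scores
    return out


def read_membership(path: str | Path) -> dict[str, list[str]]:
    """Two-column membership table (group_id, protein_id) -> {group: [ids]}."""
    df = _read_delimited(path, ["group_id", "protein_id"])
    return {g: list(b["protein_id"]) for g, b in df.groupby("group_id", sort=False)}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic TSV writer with header and stable column order."""
    df.to_csv(path, sep="\t", index=False)
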