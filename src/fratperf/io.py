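"""CSV / YAML input handling for the three longitudinal tables.

Schemas (UTF-8, header required, ISO 8601 timestamps):

``residents.csv``
    resident_id, sex, age_at_admission, admission_at, exit_at (blank =
    still resident at study end), resident_type (permanent/respite),
    status (active/deceased; informational).

``assessments.csv``
    resident_id, assessed_at, recent_falls_score, medications_score,
    psychological_score, cognitive_score, total_score (optional).

``falls.csv``
    resident_id, fell_at.

Validation is fail-loud: a row carrying both subscores and a precomputed
total that disagree is rejected rather than silently preferring one.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .scoring import COMPONENT_LEVELS, SCORE_MAX, SCORE_MIN

log = logging.getLogger(__name__)

COMPONENT_COLUMNS = list(COMPONENT_LEVELS)

__all__ = [
    "read_residents",
    "read_assessments",
    "read_falls",
    "read_config",
    "COMPONENT_COLUMNS",
]


def read_residents(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"resident_id": str})
    _require(df, ["resident_id", "admission_at", "resident_type"], path)
    df["admission_at"] = pd.to_datetime(df["admission_at"])
    if "exit_at" in df.columns:
        df["exit_at"] = pd.to_datetime(df["exit_at"])
    else:
        df["exit_at"] = pd.NaT
    missing = df["admission_at"].isna()
    if missing.any():
        log.warning(
            "dropping %d resident record(s) with missing admission date",
            int(missing.sum()),
        )
        df = df[~missing]
    bad_exit = df["exit_at"].notna() & (df["exit_at"] < df["admission_at"])
    if bad_exit.any():
        raise ValueError(
            f"{int(bad_exit.sum())} resident(s) exit before admission"
        )
    return df.reset_index(drop=True)


def read_assessments(path: str | Path) -> pd.DataFrame:
    """Load and validate assessments; derive ``total_score`` if absent.

    Rows where a supplied total disagrees with the component sum are
    rejected (ValueError): silently preferring one would hide data errors.
    """
    df = pd.read_csv(path, dtype={"resident_id": str})
    _require(df, ["resident_id", "assessed_at"], path)
    df["assessed_at"] = pd.to_datetime(df["assessed_at"])
    has_components = all(c in df.columns for c in COMPONENT_COLUMNS)
    has_total = "total_score" in df.columns and df["total_score"].notna().all()
    if not has_components and not has_total:
        raise ValueError(
            f"{path}: need the four component columns or total_score"
        )
    if has_components:
        for col, levels in COMPONENT_LEVELS.items():
            bad = ~df[col].isin(levels)
            if bad.any():
                raise ValueError(
                    f"{path}: {int(bad.sum())} row(s) with {col} outside "
                    f"admissible levels {levels}"
                )
        derived = df[COMPONENT_COLUMNS].sum(axis=1).astype(int)
        if has_total:
            clash = derived != df["total_score"].astype(int)
            if clash.any():
                raise ValueError(
                    f"{path}: {int(clash.sum())} row(s) where total_score "
                    "disagrees with the component sum"
                )
        df["total_score"] = derived
    df["total_score"] = df["total_score"].astype(int)
    out_of_range = (df["total_score"] < SCORE_MIN) | (df["total_score"] > SCORE_MAX)
    if out_of_range.any():
        raise ValueError(
            f"{path}: {int(out_of_range.sum())} total score(s) outside "
            f"[{SCORE_MIN}, {SCORE_MAX}]"
        )
    return df.reset_index(drop=True)


def read_falls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"resident_id": str})
    _require(df, ["resident_id", "fell_at"], path)
    df["fell_at"] = pd.to_datetime(df["fell_at"])
    return df.reset_index(drop=True)


def read_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML analysis config (window_days, cutoff, study window...)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _require(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
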