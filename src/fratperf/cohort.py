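"""Cohort eligibility filtering and assessment-anchored follow-up windows.

Each PH-FRAT administration (baseline = first, or the k-th follow-up)
anchors a follow-up window running from the assessment to at most a fixed
horizon (default 183 days, a six-month period), truncated by discharge,
death or the study end.  Falls strictly after the assessment and within the
window are counted; falls at or before the assessment time are excluded, so
the evaluation is genuinely predictive.  Cross-classifying the predicted
faller status against the observed one, while also accumulating fall counts
and resident-days per predicted row, yields the extended 2x2 table that
drives both the standard and the event-rate metric families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import DEFAULT_CUTOFF

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_HORIZON_DAYS",
    "ExtendedContingency",
    "filter_eligible",
    "link_windows",
    "build_contingency",
    "split_by_type",
]

#: Six-month follow-up horizon in days.
DEFAULT_HORIZON_DAYS = 183.0

WINDOW_COLUMNS = [
    "resident_id",
    "assessment_index",
    "assessed_at",
    "window_end",
    "total_score",
    "n_falls",
    "resident_days",
    "observed_faller",
]


@dataclass(frozen=True)
class ExtendedContingency:
    """2x2 faller table extended with per-predicted-row event totals.

    Resident counts (tp, fp, fn, tn) follow the usual convention with
    "predicted faller" as the positive prediction and "observed faller"
    (>= 1 fall in the window) as the positive outcome.  ``falls_pred_pos``
    and ``days_pred_pos`` are the total fall count and resident-days
    accumulated over windows in the predicted-faller row (likewise
    ``*_pred_neg``); these are the numerators/denominators of the
    event-rate metrics.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    falls_pred_pos: int
    falls_pred_neg: int
    days_pred_pos: float
    days_pred_neg: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "falls_pred_pos", "falls_pred_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.days_pred_pos < 0 or self.days_pred_neg < 0:
            raise ValueError("resident-day totals must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_observed_fallers(self) -> int:
        return self.tp + self.fn

    @property
    def n_observed_nonfallers(self) -> int:
        return self.fp + self.tn

    @property
    def falls_total(self) -> int:
        return self.falls_pred_pos + self.falls_pred_neg

    @property
    def days_total(self) -> float:
        return self.days_pred_pos + self.days_pred_neg


def filter_eligible(
    residents: pd.DataFrame,
    assessments: pd.DataFrame,
    min_age: float = 65.0,
    min_stay_hours: float = 24.0,
    study_end: pd.Timestamp | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort eligibility filters.

    Retains residents who (a) were at least ``min_age`` years old at
    admission, (b) stayed longer than ``min_stay_hours`` (strict; same-day
    discharges and interim/temporary stays fall out here), and (c) received
    at least one assessment.  Returns the retained residents and a
    flow-chart style dict of counts excluded per criterion (applied in that
    order, each count relative to the survivors of the previous step).
    """
    flow: dict[str, int] = {"total": len(residents)}
    df = residents

    if "age_at_admission" not in df.columns:
        raise ValueError("residents table lacks age_at_admission")
    young = df["age_at_admission"] < min_age
    flow["excluded_age"] = int(young.sum())
    df = df[~young]

    end = study_end
    if end is None:
        end = df["exit_at"].max()
        if pd.isna(end):
            end = pd.Timestamp.max
    exit_eff = df["exit_at"].fillna(end)
    stay_hours = (exit_eff - df["admission_at"]) / pd.Timedelta(hours=1)
    short = stay_hours <= min_stay_hours
    flow["excluded_short_stay"] = int(short.sum())
    df = df[~short]

    assessed_ids = set(assessments["resident_id"])
    unassessed = ~df["resident_id"].isin(assessed_ids)
    flow["excluded_no_assessment"] = int(unassessed.sum())
    df = df[~unassessed]

    flow["included"] = len(df)
    log.info("eligibility flow: %s", flow)
    return df.reset_index(drop=True), flow


def _clean_falls(residents: pd.DataFrame, falls: pd.DataFrame,
                 study_end: pd.Timestamp) -> pd.DataFrame:
    """Drop falls outside the recorded stay of their resident (warn)."""
    merged = falls.merge(
        residents[["resident_id", "admission_at", "exit_at"]],
        on="resident_id",
        how="left",
    )
    exit_eff = merged["exit_at"].fillna(study_end)
    ok = (
        merged["admission_at"].notna()
        & (merged["fell_at"] >= merged["admission_at"])
        & (merged["fell_at"] <= exit_eff)
    )
    if (~ok).any():
        log.warning(
            "dropping %d fall record(s) outside their resident's stay",
            int((~ok).sum()),
        )
    return merged.loc[ok, ["resident_id", "fell_at"]]


def link_windows(
    residents: pd.DataFrame,
    assessments: pd.DataFrame,
    falls: pd.DataFrame,
    assessment_index: int = 1,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    study_end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Link the k-th assessment of each resident to its follow-up window.

    For every resident with at least ``assessment_index`` assessments
    (1 = baseline), the window runs from the assessment timestamp to
    ``min(assessed_at + horizon_days, exit_at, study_end)``.  Falls
    strictly after the assessment and at or before the window end are
    counted; a fall timestamped exactly at the assessment counts as
    pre-completion and is excluded.  Resident-days are real-valued day
    differences, so date-only data yield whole numbers and censoring
    yields fractions of the horizon.

    Returns a window table with one row per linked assessment, carrying
    the total score (the prediction input), fall count, resident-days and
    the observed-faller flag.
    """
    if assessment_index < 1:
        raise ValueError("assessment_index must be >= 1")
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    if study_end is None:
        candidates = [assessments["assessed_at"].max()]
        if len(falls):
            candidates.append(falls["fell_at"].max())
        if residents["exit_at"].notna().any():
            candidates.append(residents["exit_at"].max())
        study_end = max(candidates)

    a = assessments.copy()
    dup = a.duplicated(
        subset=["resident_id", "assessed_at", "total_score"], keep="first"
    )
    if dup.any():
        log.warning(
            "dropping %d duplicate assessment record(s) "
            "(same resident, timestamp and score)",
            int(dup.sum()),
        )
        a = a[~dup]
    # stable sort: same-timestamp assessments keep file order and get
    # distinct indices
    a = a.sort_values(["resident_id", "assessed_at"], kind="stable")
    a["assessment_index"] = a.groupby("resident_id").cumcount() + 1
    kth = a[a["assessment_index"] == assessment_index]
    kth = kth.merge(
        residents[["resident_id", "exit_at"]], on="resident_id", how="inner"
    )

    horizon = pd.Timedelta(days=float(horizon_days))
    exit_eff = kth["exit_at"].fillna(study_end)
    window_end = (kth["assessed_at"] + horizon).where(
        lambda s: s <= exit_eff, exit_eff
    ).clip(upper=pd.Timestamp(study_end))
    windows = pd.DataFrame(
        {
            "resident_id": kth["resident_id"].to_numpy(),
            "assessment_index": assessment_index,
            "assessed_at": kth["assessed_at"].to_numpy(),
            "window_end": window_end.to_numpy(),
            "total_score": kth["total_score"].to_numpy(),
        }
    )

    clean = _clean_falls(residents, falls, study_end)
    merged = clean.merge(
        windows[["resident_id", "assessed_at", "window_end"]],
        on="resident_id",
        how="inner",
    )
    in_window = (merged["fell_at"] > merged["assessed_at"]) & (
        merged["fell_at"] <= merged["window_end"]
    )
    counts = (
        merged[in_window].groupby("resident_id").size().rename("n_falls")
    )
    windows = windows.merge(counts, on="resident_id", how="left")
    windows["n_falls"] = windows["n_falls"].fillna(0).astype(int)
    windows["resident_days"] = (
        (windows["window_end"] - windows["assessed_at"])
        / pd.Timedelta(days=1)
    ).clip(lower=0.0)
    windows["observed_faller"] = windows["n_falls"] >= 1
    return windows[WINDOW_COLUMNS].reset_index(drop=True)


def build_contingency(
    windows: pd.DataFrame, cutoff: int = DEFAULT_CUTOFF
) -> ExtendedContingency:
    """Cross-classify windows into the extended 2x2 table at a cut-off.

    Predicted faller means ``total_score > cutoff``.  Fall counts and
    resident-days accumulate into the predicted row their window belongs
    to; the observed-non-faller column contributes no falls by definition.
    """
    if len(windows) == 0:
        raise ValueError("no windows to evaluate")
    predicted = windows["total_score"].to_numpy() > cutoff
    observed = windows["observed_faller"].to_numpy()
    n_falls = windows["n_falls"].to_numpy()
    days = windows["resident_days"].to_numpy(dtype=float)
    return ExtendedContingency(
        tp=int((predicted & observed).sum()),
        fp=int((predicted & ~observed).sum()),
        fn=int((~predicted & observed).sum()),
        tn=int((~predicted & ~observed).sum()),
        falls_pred_pos=int(n_falls[predicted].sum()),
        falls_pred_neg=int(n_falls[~predicted].sum()),
        days_pred_pos=float(days[predicted].sum()),
        days_pred_neg=float(days[~predicted].sum()),
    )


def split_by_type(
    windows: pd.DataFrame, residents: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Partition windows by resident type (permanent vs respite)."""
    types = residents.set_index("resident_id")["resident_type"]
    labels = windows["resident_id"].map(types)
    known = labels.isin(["permanent", "respite"])
    if (~known).any():
        log.warning(
            "dropping %d window(s) with unknown resident type",
            int((~known).sum()),
        )
    return {
        t: windows[known & (labels == t)].reset_index(drop=True)
        for t in ("permanent", "respite")
    }
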