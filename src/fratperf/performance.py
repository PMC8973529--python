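"""Predictive-performance metrics for recurrent falls.

Two metric families are computed from the extended contingency table:

Standard (resident-counting)
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV, NPV and
    Youden's index (sensitivity + specificity - 1), with Wilson score 95%
    intervals for the four proportions.  A resident is a faller if they
    fell at least once in the follow-up window, so a resident with ten
    falls counts the same as one with a single fall.

Event-rate (ER)
    sensitivity_ER = share of all falls that occurred in predicted-faller
    windows, and specificity_ER = share of all resident-days spent in
    predicted-non-faller windows.  These weight the table by events and
    person-time instead of heads, respecting the recurrent nature of
    falls: a tool that flags the residents who generate most of the falls
    scores high sensitivity_ER even if many one-off fallers are missed.
    Confidence intervals come from a resident-level (cluster) bootstrap,
    since falls within a resident are dependent.

AUROC is the tie-corrected probability that a randomly chosen faller
outscores a randomly chosen non-faller, equal to the trapezoidal area
under the empirical ROC over the integer score range.  Crude fall
incidence is reported per 1000 resident-days with an exact Poisson
(Garwood) interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .cohort import (
    DEFAULT_HORIZON_DAYS,
    ExtendedContingency,
    build_contingency,
    link_windows,
)
from .scoring import DEFAULT_CUTOFF

__all__ = [
    "MetricResult",
    "RocCurve",
    "STANDARD_METRICS",
    "EVENT_RATE_METRICS",
    "compute_metric",
    "standard_metrics",
    "event_rate_metrics",
    "bootstrap_ci",
    "bootstrap_auroc_ci",
    "roc_and_auroc",
    "optimal_cutoff",
    "incidence_rate",
    "followup_sequence_eval",
]

STANDARD_METRICS = ("sensitivity", "specificity", "ppv", "npv", "youden")
EVENT_RATE_METRICS = ("sensitivity_er", "specificity_er", "youden_er")
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class MetricResult:
    """A named performance estimate with its interval.

    ``estimate`` is NaN when the metric is undefined (zero denominator);
    undefined metrics are flagged, never silently reported as 0.
    ``ci_method`` is one of wilson, bootstrap_percentile, poisson_exact,
    none.
    """

    name: str
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    ci_method: str = "none"
    n_effective: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)

    def __post_init__(self) -> None:
        if self.ci_method != "none" and self.defined:
            if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
                raise ValueError(
                    f"{self.name}: interval [{self.ci_low}, {self.ci_high}] "
                    f"does not cover estimate {self.estimate}"
                )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metric(table: ExtendedContingency, name: str) -> float:
    """Point estimate of one metric from the extended table (NaN if undefined)."""
    if name == "sensitivity":
        return _ratio(table.tp, table.tp + table.fn)
    if name == "specificity":
        return _ratio(table.tn, table.tn + table.fp)
    if name == "ppv":
        return _ratio(table.tp, table.tp + table.fp)
    if name == "npv":
        return _ratio(table.tn, table.tn + table.fn)
    if name == "youden":
        return (
            compute_metric(table, "sensitivity")
            + compute_metric(table, "specificity")
            - 1.0
        )
    if name == "sensitivity_er":
        return _ratio(table.falls_pred_pos, table.falls_total)
    if name == "specificity_er":
        return _ratio(table.days_pred_neg, table.days_total)
    if name == "youden_er":
        return (
            compute_metric(table, "sensitivity_er")
            + compute_metric(table, "specificity_er")
            - 1.0
        )
    raise ValueError(f"unknown metric {name!r}")


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def standard_metrics(table: ExtendedContingency) -> dict[str, MetricResult]:
    """Resident-counting metrics with Wilson 95% CIs.

    Youden's index is reported without an interval under this method.
    """
    pieces = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.tn + table.fn),
    }
    out: dict[str, MetricResult] = {}
    for name, (count, nobs) in pieces.items():
        est = _ratio(count, nobs)
        if math.isnan(est):
            out[name] = MetricResult(name, math.nan, n_effective=nobs)
        else:
            lo, hi = _wilson(count, nobs)
            out[name] = MetricResult(name, est, lo, hi, "wilson", nobs)
    out["youden"] = MetricResult(
        "youden", compute_metric(table, "youden"), n_effective=table.n_windows
    )
    return out


def event_rate_metrics(table: ExtendedContingency) -> dict[str, MetricResult]:
    """Event-rate metrics (point estimates; CIs via :func:`bootstrap_ci`)."""
    out = {}
    for name in EVENT_RATE_METRICS:
        n_eff = (
            table.falls_total if name == "sensitivity_er" else table.n_windows
        )
        out[name] = MetricResult(
            name, compute_metric(table, name), n_effective=n_eff
        )
    return out


# ---------------------------------------------------------------------------
# resident-level bootstrap

_CELL_FIELDS = (
    "tp",
    "fp",
    "fn",
    "tn",
    "falls_pred_pos",
    "falls_pred_neg",
    "days_pred_pos",
    "days_pred_neg",
)


def _per_resident_cells(windows: pd.DataFrame, cutoff: int) -> np.ndarray:
    """Additive contingency contributions, one row per resident.

    Because every cell of the extended table is a sum over windows and all
    windows of a resident move together under resident-level resampling,
    a bootstrap replicate's table is just a sum of resampled rows.
    """
    predicted = windows["total_score"].to_numpy() > cutoff
    observed = windows["observed_faller"].to_numpy()
    parts = pd.DataFrame(
        {
            "resident_id": windows["resident_id"].to_numpy(),
            "tp": (predicted & observed).astype(float),
            "fp": (predicted & ~observed).astype(float),
            "fn": (~predicted & observed).astype(float),
            "tn": (~predicted & ~observed).astype(float),
            "falls_pred_pos": np.where(predicted, windows["n_falls"], 0.0),
            "falls_pred_neg": np.where(~predicted, windows["n_falls"], 0.0),
            "days_pred_pos": np.where(predicted, windows["resident_days"], 0.0),
            "days_pred_neg": np.where(~predicted, windows["resident_days"], 0.0),
        }
    )
    return parts.groupby("resident_id").sum().to_numpy()


def _metric_from_cells(cells: np.ndarray, name: str) -> np.ndarray:
    """Vectorised metric over stacked cell arrays of shape (..., 8)."""
    c = {f: cells[..., i] for i, f in enumerate(_CELL_FIELDS)}
    with np.errstate(invalid="ignore", divide="ignore"):
        if name == "sensitivity":
            return c["tp"] / (c["tp"] + c["fn"])
        if name == "specificity":
            return c["tn"] / (c["tn"] + c["fp"])
        if name == "ppv":
            return c["tp"] / (c["tp"] + c["fp"])
        if name == "npv":
            return c["tn"] / (c["tn"] + c["fn"])
        if name == "youden":
            return (
                _metric_from_cells(cells, "sensitivity")
                + _metric_from_cells(cells, "specificity")
                - 1.0
            )
        if name == "sensitivity_er":
            return c["falls_pred_pos"] / (c["falls_pred_pos"] + c["falls_pred_neg"])
        if name == "specificity_er":
            return c["days_pred_neg"] / (c["days_pred_pos"] + c["days_pred_neg"])
        if name == "youden_er":
            return (
                _metric_from_cells(cells, "sensitivity_er")
                + _metric_from_cells(cells, "specificity_er")
                - 1.0
            )
    raise ValueError(f"unknown metric {name!r}")


def bootstrap_ci(
    windows: pd.DataFrame,
    cutoff: int,
    metric_name: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling residents with replacement.

    The resampling unit is the resident: all of a resident's windows and
    falls move together, so within-resident dependence of recurrent falls
    is respected.  Replicates where the metric is undefined (e.g. no falls
    drawn) are dropped; if more than half are, an error is raised.  A fixed
    seed gives a bit-reproducible interval.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    per_res = _per_resident_cells(windows, cutoff)
    n_res = per_res.shape[0]
    if n_res == 1:
        est = float(_metric_from_cells(per_res.sum(axis=0), metric_name))
        return est, est
    idx = rng.integers(0, n_res, size=(n_boot, n_res))
    replicate_cells = per_res[idx].sum(axis=1)  # (n_boot, 8)
    values = _metric_from_cells(replicate_cells, metric_name)
    values = values[~np.isnan(values)]
    if len(values) < n_boot / 2:
        raise ValueError(
            f"{metric_name}: {n_boot - len(values)} of {n_boot} bootstrap "
            "replicates undefined"
        )
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def bootstrap_auroc_ci(
    windows: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Resident-level percentile bootstrap CI for the AUROC."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    groups = windows.groupby("resident_id").indices
    keys = list(groups)
    if len(keys) == 1:
        a = _auroc(windows)
        return a, a
    scores = windows["total_score"].to_numpy()
    observed = windows["observed_faller"].to_numpy()
    values = []
    for _ in range(n_boot):
        picked = rng.integers(0, len(keys), size=len(keys))
        rows = np.concatenate([groups[keys[i]] for i in picked])
        y = observed[rows]
        if y.all() or not y.any():
            continue  # one class absent: AUROC undefined in this replicate
        values.append(roc_auc_score(y, scores[rows]))
    if len(values) < n_boot / 2:
        raise ValueError("AUROC undefined in more than half the replicates")
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# ROC / cut-off optimisation

CUTOFF_GRID = tuple(range(4, 21))


@dataclass(frozen=True)
class RocCurve:
    """Per-cutoff operating points over the integer score range, plus AUROC."""

    points: pd.DataFrame = field(repr=False)
    auroc: float

    def criterion(self, name: str) -> pd.Series:
        return self.points.set_index("cutoff")[name]


def _auroc(windows: pd.DataFrame) -> float:
    y = windows["observed_faller"].to_numpy()
    if y.all() or not y.any():
        raise ValueError("AUROC needs both observed classes present")
    return float(roc_auc_score(y, windows["total_score"].to_numpy()))


def roc_and_auroc(windows: pd.DataFrame) -> RocCurve:
    """Evaluate every integer cut-off 4..20 and the tie-corrected AUROC.

    Cut-off 4 predicts everyone a faller (sensitivity 1, specificity 0);
    cut-off 20 predicts nobody (sensitivity 0, specificity 1), so the
    curve always spans both ROC endpoints.
    """
    rows = []
    for cutoff in CUTOFF_GRID:
        table = build_contingency(windows, cutoff)
        rows.append(
            {
                "cutoff": cutoff,
                **{m: compute_metric(table, m) for m in STANDARD_METRICS},
                **{m: compute_metric(table, m) for m in EVENT_RATE_METRICS},
            }
        )
    return RocCurve(points=pd.DataFrame(rows), auroc=_auroc(windows))


def optimal_cutoff(curve: RocCurve, criterion: str = "youden_er") -> int:
    """Cut-off maximising a Youden criterion; ties go to the smallest
    cut-off (which maximises sensitivity among the optima)."""
    if criterion not in ("youden", "youden_er"):
        raise ValueError("criterion must be 'youden' or 'youden_er'")
    values = curve.criterion(criterion)
    if values.empty:
        raise ValueError("empty ROC curve")
    return int(values.index[np.argmax(values.to_numpy())])


# ---------------------------------------------------------------------------
# incidence

def incidence_rate(
    n_falls: int, resident_days: float, per: float = 1000.0
) -> MetricResult:
    """Crude fall incidence per ``per`` resident-days with Garwood CI.

    The exact Poisson interval on the count k is
    [chi2.ppf(.025, 2k)/2, chi2.ppf(.975, 2k+2)/2], scaled by
    ``per / resident_days``; the lower bound is 0 when k = 0.
    """
    if resident_days <= 0:
        raise ValueError("resident_days must be positive")
    if n_falls < 0:
        raise ValueError("n_falls must be non-negative")
    scale = per / resident_days
    lo = 0.0 if n_falls == 0 else float(stats.chi2.ppf(0.025, 2 * n_falls)) / 2
    hi = float(stats.chi2.ppf(0.975, 2 * n_falls + 2)) / 2
    return MetricResult(
        name="incidence_rate",
        estimate=n_falls * scale,
        ci_low=lo * scale,
        ci_high=hi * scale,
        ci_method="poisson_exact",
        n_effective=n_falls,
    )


# ---------------------------------------------------------------------------
# follow-up assessment sequence

def followup_sequence_eval(
    residents: pd.DataFrame,
    assessments: pd.DataFrame,
    falls: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    cutoff: int = DEFAULT_CUTOFF,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    n_boot: int = 0,
    seed: int | None = None,
    study_end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Tool performance at the k-th assessment, for each k.

    For each k the cohort restricts to residents with >= k assessments;
    the k-th assessment anchors a fresh follow-up window (falls before it
    are excluded) and both metric families are computed, with resident-
    level bootstrap CIs for the ER metrics when ``n_boot`` > 0.  A k that
    no resident reaches yields no rows rather than an error.

    Returns a tidy frame: one row per (k, metric).
    """
    rng = np.random.default_rng(seed)
    records = []
    for k in k_range:
        windows = link_windows(
            residents,
            assessments,
            falls,
            assessment_index=k,
            horizon_days=horizon_days,
            study_end=study_end,
        )
        if len(windows) == 0:
            continue
        table = build_contingency(windows, cutoff)
        results = {**standard_metrics(table), **event_rate_metrics(table)}
        for name, res in results.items():
            lo, hi, method = res.ci_low, res.ci_high, res.ci_method
            if n_boot > 0 and name in EVENT_RATE_METRICS:
                lo, hi = bootstrap_ci(
                    windows, cutoff, name, n_boot=n_boot, seed=rng
                )
                method = "bootstrap_percentile"
            records.append(
                {
                    "assessment_index": k,
                    "n_windows": len(windows),
                    "metric": name,
                    "estimate": res.estimate,
                    "ci_low": lo,
                    "ci_high": hi,
                    "ci_method": method,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "assessment_index",
            "n_windows",
            "metric",
            "estimate",
            "ci_low",
            "ci_high",
            "ci_method",
        ],
    )
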