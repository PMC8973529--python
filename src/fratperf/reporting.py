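"""Report assembly and serialisation for a full evaluation run.

``evaluate`` runs the whole pipeline -- eligibility flow, window linkage,
extended contingency tables at each requested cut-off, both metric
families with intervals, ROC/AUROC, within-window incidence, resident-type
subgroups and the follow-up assessment sequence -- into one
:class:`EvaluationReport` that serialises losslessly to JSON and renders
to CSV and markdown.  Display rounding (percentages to 1 d.p., indices to
3 d.p.) happens only at render time; the JSON keeps full precision, and a
reloaded report re-derives every metric from its stored contingency
tables as a self-consistency check.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_HORIZON_DAYS,
    ExtendedContingency,
    build_contingency,
    filter_eligible,
    link_windows,
    split_by_type,
)
from .performance import (
    EVENT_RATE_METRICS,
    MetricResult,
    bootstrap_auroc_ci,
    bootstrap_ci,
    compute_metric,
    event_rate_metrics,
    followup_sequence_eval,
    incidence_rate,
    roc_and_auroc,
    standard_metrics,
)

log = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "evaluate", "render_report"]

_ROW_LABELS = {
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "ppv": "PPV",
    "npv": "NPV",
    "youden": "Youden's index",
    "sensitivity_er": "Sensitivity_ER",
    "specificity_er": "Specificity_ER",
    "youden_er": "Youden's index_ER",
}
_INDEX_METRICS = {"youden", "youden_er", "auroc"}


@dataclass
class EvaluationReport:
    """Everything a run produced, in JSON-serialisable form."""

    config: dict
    flow: dict[str, int]
    tables: dict[str, dict]  # str(cutoff) -> contingency cells
    metrics: dict[str, dict[str, dict]]  # str(cutoff) -> metric -> fields
    auroc: dict
    roc_points: list[dict]
    incidence: dict
    subgroups: dict[str, dict] = field(default_factory=dict)
    followup: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvaluationReport":
        """Load a report and verify it is self-consistent.

        Every point estimate stored in ``metrics`` must be re-derivable
        from the stored contingency cells; a mismatch means the file was
        edited or corrupted and raises.
        """
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        report = cls(**json.loads(text))
        for cutoff, cells in report.tables.items():
            table = ExtendedContingency(**cells)
            for name, m in report.metrics[cutoff].items():
                expected = compute_metric(table, name)
                got = m["estimate"]
                if not (
                    (math.isnan(expected) and math.isnan(got))
                    or abs(expected - got) < 1e-9
                ):
                    raise ValueError(
                        f"report inconsistent: {name} at cutoff {cutoff} "
                        f"stored {got}, derived {expected}"
                    )
        return report


def _metric_dict(res: MetricResult) -> dict:
    return dataclasses.asdict(res)


def _cells_dict(table: ExtendedContingency) -> dict:
    return dataclasses.asdict(table)


def _metrics_block(
    windows: pd.DataFrame,
    cutoff: int,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[dict, dict]:
    table = build_contingency(windows, cutoff)
    results = {**standard_metrics(table), **event_rate_metrics(table)}
    if n_boot > 0:
        for name in EVENT_RATE_METRICS:
            if not results[name].defined:
                continue
            lo, hi = bootstrap_ci(windows, cutoff, name, n_boot=n_boot, seed=rng)
            results[name] = dataclasses.replace(
                results[name], ci_low=lo, ci_high=hi,
                ci_method="bootstrap_percentile",
            )
    return _cells_dict(table), {k: _metric_dict(v) for k, v in results.items()}


def evaluate(
    residents: pd.DataFrame,
    assessments: pd.DataFrame,
    falls: pd.DataFrame,
    cutoffs: tuple[int, ...] = (14, 10),
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    assessment_index: int = 1,
    n_boot: int = 1000,
    seed: int | None = None,
    subgroups: bool = True,
    followup_k: tuple[int, ...] = (),
    study_end: pd.Timestamp | None = None,
) -> EvaluationReport:
    """Run the full evaluation pipeline and assemble the report."""
    rng = np.random.default_rng(seed)
    eligible, flow = filter_eligible(residents, assessments, study_end=study_end)
    assessments = assessments[
        assessments["resident_id"].isin(eligible["resident_id"])
    ]
    falls = falls[falls["resident_id"].isin(eligible["resident_id"])]
    windows = link_windows(
        eligible, assessments, falls,
        assessment_index=assessment_index,
        horizon_days=horizon_days, study_end=study_end,
    )

    tables, metrics = {}, {}
    for cutoff in cutoffs:
        cells, block = _metrics_block(windows, cutoff, n_boot, rng)
        tables[str(cutoff)] = cells
        metrics[str(cutoff)] = block

    curve = roc_and_auroc(windows)
    auroc = {"estimate": curve.auroc, "ci_low": math.nan,
             "ci_high": math.nan, "ci_method": "none"}
    if n_boot > 0:
        lo, hi = bootstrap_auroc_ci(windows, n_boot=n_boot, seed=rng)
        auroc.update(ci_low=lo, ci_high=hi, ci_method="bootstrap_percentile")

    any_table = ExtendedContingency(**tables[str(cutoffs[0])])
    inc = incidence_rate(any_table.falls_total, any_table.days_total)

    sub_blocks: dict[str, dict] = {}
    if subgroups and "resident_type" in eligible.columns:
        for label, sub in split_by_type(windows, eligible).items():
            if len(sub) == 0:
                log.info("subgroup %s empty; omitted from report", label)
                continue
            sub_blocks[label] = {"tables": {}, "metrics": {}, "n_windows": len(sub)}
            for cutoff in cutoffs:
                cells, block = _metrics_block(sub, cutoff, n_boot, rng)
                sub_blocks[label]["tables"][str(cutoff)] = cells
                sub_blocks[label]["metrics"][str(cutoff)] = block
            y = sub["observed_faller"]
            if 0 < y.sum() < len(y):
                sub_curve = roc_and_auroc(sub)
                sub_blocks[label]["auroc"] = {"estimate": sub_curve.auroc}

    followup_records: list[dict] = []
    if followup_k:
        fu = followup_sequence_eval(
            eligible, assessments, falls, k_range=tuple(followup_k),
            cutoff=cutoffs[0], horizon_days=horizon_days,
            n_boot=n_boot, seed=rng, study_end=study_end,
        )
        followup_records = fu.to_dict(orient="records")

    return EvaluationReport(
        config={
            "cutoffs": list(cutoffs),
            "horizon_days": horizon_days,
            "assessment_index": assessment_index,
            "n_boot": n_boot,
        },
        flow=flow,
        tables=tables,
        metrics=metrics,
        auroc=auroc,
        roc_points=curve.points.to_dict(orient="records"),
        incidence=_metric_dict(inc),
        subgroups=sub_blocks,
        followup=followup_records,
        provenance={
            "seed": seed,
            "created_at": datetime.now(timezone.utc).isoformat(),
            "n_windows": int(len(windows)),
        },
    )


# ---------------------------------------------------------------------------
# rendering

def _fmt(name: str, value: float, pct_dp: int = 1, idx_dp: int = 3) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "undefined"
    if name in _INDEX_METRICS:
        return f"{value:.{idx_dp}f}"
    return f"{100 * value:.{pct_dp}f}"


def _markdown_metrics(report: EvaluationReport) -> str:
    cutoffs = list(report.metrics)
    lines = [
        "| Metric | " + " | ".join(f"Cut-off {c}" for c in cutoffs) + " |",
        "|---" * (len(cutoffs) + 1) + "|",
    ]
    lines.append(
        "| AUROC | "
        + " | ".join(_fmt("auroc", report.auroc["estimate"], idx_dp=2)
                     for _ in cutoffs)
        + " |"
    )
    for name, label in _ROW_LABELS.items():
        cells = []
        for c in cutoffs:
            m = report.metrics[c][name]
            text = _fmt(name, m["estimate"])
            if m["ci_method"] != "none":
                text += (
                    f" ({_fmt(name, m['ci_low'])}-{_fmt(name, m['ci_high'])})"
                )
            cells.append(text)
        lines.append(f"| {label} | " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_report(
    report: EvaluationReport,
    format: str = "json",
    out_dir: str | Path = ".",
) -> list[Path]:
    """Serialise a report; returns the paths written.

    json -> results.json; csv -> table2.csv (headline metrics), roc.csv,
    and, when present, table3.csv (subgroups) and fig3.csv (follow-up
    sequence); markdown -> report.md with the conventional row labels.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "json":
        path = out / "results.json"
        report.to_json(path)
        written.append(path)
    elif format == "csv":
        rows = [
            {"cutoff": c, "metric": name, **fields}
            for c, block in report.metrics.items()
            for name, fields in block.items()
        ]
        path = out / "table2.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
        path = out / "roc.csv"
        pd.DataFrame(report.roc_points).to_csv(path, index=False)
        written.append(path)
        if report.subgroups:
            rows = [
                {"subgroup": g, "cutoff": c, "metric": name, **fields}
                for g, blk in report.subgroups.items()
                for c, block in blk["metrics"].items()
                for name, fields in block.items()
            ]
            path = out / "table3.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            written.append(path)
        if report.followup:
            path = out / "fig3.csv"
            pd.DataFrame(report.followup).to_csv(path, index=False)
            written.append(path)
    elif format == "markdown":
        flow_lines = "\n".join(f"- {k}: {v}" for k, v in report.flow.items())
        inc = report.incidence
        text = (
            "# PH-FRAT predictive performance\n\n"
            "## Eligibility flow\n\n" + flow_lines + "\n\n"
            "## Performance\n\n" + _markdown_metrics(report) + "\n\n"
            f"Within-window crude incidence: {inc['estimate']:.1f} "
            f"falls/1000 resident-days "
            f"(95% CI {inc['ci_low']:.1f}-{inc['ci_high']:.1f})\n"
        )
        path = out / "report.md"
        path.write_text(text, encoding="utf-8")
        written.append(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return written
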