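"""Shared fixtures: hand-built toy cohorts and a small simulated one."""

from __future__ import annotations

import pandas as pd
import pytest

from fratperf import SimulationConfig, simulate_cohort


def _ts(day: float, origin: str = "2020-01-01") -> pd.Timestamp:
    return pd.Timestamp(origin) + pd.Timedelta(days=float(day))


@pytest.fixture
def ts():
    """Day-offset timestamp helper (day 0 = 2020-01-01)."""
    return _ts


@pytest.fixture
def toy_cohort():
    """Three residents exercising censoring, pre-assessment falls and types.

    A: assessed day 0 (score 16), falls days -1 and 10, exits day 400
       -> one counted fall, full 183-day window.
    B: assessed day 0 (score 12), no falls, exits day 30
       -> censored window of 30 days, non-faller.
    C: assessed days 0 and 50 (scores 9 then 15), falls days 20, 60, 70,
       exits day 300 -> baseline counts 3 falls; second assessment 2.
    """
    residents = pd.DataFrame(
        {
            "resident_id": ["A", "B", "C"],
            "sex": ["female", "male", "female"],
            "age_at_admission": [85.0, 78.0, 91.0],
            "admission_at": [_ts(-5), _ts(-2), _ts(-10)],
            "exit_at": [_ts(400), _ts(30), _ts(300)],
            "resident_type": ["permanent", "respite", "permanent"],
            "status": ["deceased", "active", "deceased"],
        }
    )
    assessments = pd.DataFrame(
        {
            "resident_id": ["A", "B", "C", "C"],
            "assessed_at": [_ts(0), _ts(0), _ts(0), _ts(50)],
            "total_score": [16, 12, 9, 15],
        }
    )
    falls = pd.DataFrame(
        {
            "resident_id": ["A", "A", "C", "C", "C"],
            "fell_at": [_ts(-1), _ts(10), _ts(20), _ts(60), _ts(70)],
        }
    )
    return residents, assessments, falls


@pytest.fixture(scope="session")
def sim_cohort():
    """A 400-resident simulated cohort shared across read-only tests."""
    cfg = SimulationConfig(n_residents=400)
    return simulate_cohort(cfg, seed=20140701)


def make_windows(rows):
    """Build a window table from (resident_id, score, n_falls, days) tuples."""
    df = pd.DataFrame(
        rows, columns=["resident_id", "total_score", "n_falls", "resident_days"]
    )
    df["assessment_index"] = 1
    df["assessed_at"] = _ts(0)
    df["window_end"] = df["resident_days"].map(_ts)
    df["observed_faller"] = df["n_falls"] >= 1
    return df
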