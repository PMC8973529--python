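"""Metric families, bootstrap, ROC/AUROC, cut-off search and incidence."""

import math

import numpy as np
import pandas as pd
import pytest

from fratperf import (
    ExtendedContingency,
    bootstrap_ci,
    compute_metric,
    event_rate_metrics,
    followup_sequence_eval,
    incidence_rate,
    link_windows,
    optimal_cutoff,
    roc_and_auroc,
    standard_metrics,
)
from fratperf.performance import RocCurve

from conftest import make_windows

# Published evaluation of the tool on ~5.9k aged-care residents: the
# extended 2x2 tables of the baseline assessment at the two cut-offs.
TABLE_CUTOFF_14 = ExtendedContingency(
    tp=627, fp=388, fn=1782, tn=3091,
    falls_pred_pos=2512, falls_pred_neg=4975,
    days_pred_pos=147_454.0, days_pred_neg=673_298.0,
)
TABLE_CUTOFF_10 = ExtendedContingency(
    tp=1626, fp=1559, fn=783, tn=1920,
    falls_pred_pos=5570, falls_pred_neg=1917,
    days_pred_pos=446_080.0, days_pred_neg=374_672.0,
)


def naive_auroc(scores, outcomes):
    """Exhaustive pairwise concordance with half-credit for ties."""
    pos = [s for s, y in zip(scores, outcomes) if y]
    neg = [s for s, y in zip(scores, outcomes) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestStandardMetrics:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (
                TABLE_CUTOFF_14,
                {"sensitivity": 26.0, "specificity": 88.8, "ppv": 61.8,
                 "npv": 63.4},
            ),
            (
                TABLE_CUTOFF_10,
                {"sensitivity": 67.5, "specificity": 55.2, "ppv": 51.1,
                 "npv": 71.0},
            ),
        ],
    )
    def test_published_cell_counts_reproduce(self, table, expected):
        got = standard_metrics(table)
        for name, pct in expected.items():
            assert round(100 * got[name].estimate, 1) == pct
            assert got[name].ci_method == "wilson"
            assert got[name].ci_low <= got[name].estimate <= got[name].ci_high

    def test_youden_from_published_cells(self):
        assert compute_metric(TABLE_CUTOFF_14, "youden") == pytest.approx(
            0.1487, abs=5e-4
        )
        assert compute_metric(TABLE_CUTOFF_10, "youden") == pytest.approx(
            0.227, abs=5e-4
        )

    def test_perfect_classifier(self):
        t = ExtendedContingency(1, 0, 0, 1, 1, 0, 0.0, 100.0)
        got = standard_metrics(t)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert got[name].estimate == 1.0
        assert got["youden"].estimate == 1.0

    def test_complement_identities(self):
        t = TABLE_CUTOFF_14
        assert compute_metric(t, "sensitivity") == pytest.approx(
            1 - t.fn / (t.tp + t.fn)
        )
        assert compute_metric(t, "specificity") == pytest.approx(
            1 - t.fp / (t.fp + t.tn)
        )

    def test_zero_denominator_flagged_not_zero(self):
        t = ExtendedContingency(0, 3, 0, 5, 0, 0, 100.0, 200.0)
        got = standard_metrics(t)
        assert not got["sensitivity"].defined
        assert got["specificity"].defined


class TestEventRateMetrics:
    def test_published_cell_counts_reproduce(self):
        got14 = event_rate_metrics(TABLE_CUTOFF_14)
        assert round(100 * got14["sensitivity_er"].estimate, 1) == 33.6
        assert round(100 * got14["specificity_er"].estimate, 1) == 82.0
        assert got14["youden_er"].estimate == pytest.approx(0.156, abs=5e-4)
        got10 = event_rate_metrics(TABLE_CUTOFF_10)
        assert round(100 * got10["sensitivity_er"].estimate, 1) == 74.4
        assert round(100 * got10["specificity_er"].estimate, 1) == 45.6
        # full precision is 0.20045; the printed 0.201 reflects rounding order
        assert got10["youden_er"].estimate == pytest.approx(0.201, abs=1e-3)

    def test_perfect_event_concentration(self):
        t = ExtendedContingency(2, 0, 0, 3, 10, 0, 0.0, 500.0)
        got = event_rate_metrics(t)
        assert got["sensitivity_er"].estimate == 1.0
        assert got["specificity_er"].estimate == 1.0

    def test_coincides_with_standard_in_analytic_limit(self):
        """One fall per faller and equal window lengths collapse the ER
        metrics onto the standard ones."""
        w = make_windows(
            [("A", 16, 1, 183.0), ("B", 15, 1, 183.0), ("C", 18, 0, 183.0),
             ("D", 10, 1, 183.0), ("E", 8, 0, 183.0), ("F", 12, 0, 183.0)]
        )
        from fratperf import build_contingency

        t = build_contingency(w, 14)
        assert compute_metric(t, "sensitivity_er") == pytest.approx(
            compute_metric(t, "sensitivity")
        )
        # specificity_ER weights by days over ALL windows, so it equals the
        # fraction of windows predicted negative, not TN/(TN+FP); with equal
        # days it matches specificity only when prediction and outcome are
        # independent in the faller column too -- check the days identity:
        assert compute_metric(t, "specificity_er") == pytest.approx(
            (t.tn + t.fn) / t.n_windows
        )


class TestBootstrap:
    def test_single_resident_zero_width(self):
        w = make_windows([("A", 16, 2, 100.0)])
        lo, hi = bootstrap_ci(w, 14, "sensitivity_er", n_boot=50, seed=0)
        assert lo == hi == 1.0

    def test_seed_determinism(self, sim_cohort):
        residents, assessments, falls = sim_cohort
        w = link_windows(residents, assessments, falls)
        a = bootstrap_ci(w, 14, "sensitivity_er", n_boot=200, seed=42)
        b = bootstrap_ci(w, 14, "sensitivity_er", n_boot=200, seed=42)
        assert a == b
        c = bootstrap_ci(w, 14, "sensitivity_er", n_boot=200, seed=43)
        assert a != c

    def test_row_order_invariance(self, sim_cohort):
        residents, assessments, falls = sim_cohort
        w = link_windows(residents, assessments, falls)
        shuffled = w.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = bootstrap_ci(w, 14, "specificity_er", n_boot=100, seed=5)
        b = bootstrap_ci(shuffled, 14, "specificity_er", n_boot=100, seed=5)
        assert a == b  # per-resident aggregation sorts by resident id

    def test_interval_brackets_estimate(self, sim_cohort):
        residents, assessments, falls = sim_cohort
        w = link_windows(residents, assessments, falls)
        from fratperf import build_contingency

        est = compute_metric(build_contingency(w, 14), "sensitivity_er")
        lo, hi = bootstrap_ci(w, 14, "sensitivity_er", n_boot=500, seed=9)
        assert lo <= est <= hi

    def test_mostly_undefined_replicates_error(self):
        # no falls at all: sensitivity_ER undefined in every replicate
        w = make_windows([("A", 16, 0, 50.0), ("B", 10, 0, 60.0)])
        with pytest.raises(ValueError, match="undefined"):
            bootstrap_ci(w, 14, "sensitivity_er", n_boot=20, seed=0)


class TestRoc:
    def test_perfect_separation(self):
        w = make_windows(
            [("A", 20, 1, 50.0), ("B", 20, 2, 60.0), ("C", 5, 0, 70.0),
             ("D", 5, 0, 80.0)]
        )
        assert roc_and_auroc(w).auroc == 1.0

    def test_ties_only(self):
        w = make_windows([("A", 14, 1, 50.0), ("B", 14, 0, 60.0)])
        assert roc_and_auroc(w).auroc == 0.5

    def test_one_class_absent_errors(self):
        w = make_windows([("A", 14, 1, 50.0), ("B", 16, 2, 60.0)])
        with pytest.raises(ValueError):
            roc_and_auroc(w)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for n in (30, 200):
            scores = rng.integers(5, 21, size=n)
            outcomes = rng.random(n) < 0.4
            if outcomes.all() or not outcomes.any():
                outcomes[0] = not outcomes[0]
            w = make_windows(
                [(f"R{i}", int(s), int(y), 100.0)
                 for i, (s, y) in enumerate(zip(scores, outcomes))]
            )
            got = roc_and_auroc(w).auroc
            assert got == pytest.approx(naive_auroc(scores, outcomes))

    def test_curve_shape_and_endpoints(self, sim_cohort):
        residents, assessments, falls = sim_cohort
        w = link_windows(residents, assessments, falls)
        curve = roc_and_auroc(w)
        pts = curve.points
        assert pts["cutoff"].tolist() == list(range(4, 21))
        sens = pts["sensitivity"].to_numpy()
        spec = pts["specificity"].to_numpy()
        assert (np.diff(sens) <= 1e-12).all()  # non-increasing in cutoff
        assert (np.diff(spec) >= -1e-12).all()  # non-decreasing
        assert sens[0] == 1.0 and spec[0] == 0.0  # cutoff 4
        assert sens[-1] == 0.0 and spec[-1] == 1.0  # cutoff 20

    def test_trapezoid_equals_concordance(self, sim_cohort):
        """Trapezoidal area under the empirical ROC equals the AUROC."""
        residents, assessments, falls = sim_cohort
        w = link_windows(residents, assessments, falls)
        curve = roc_and_auroc(w)
        fpr = 1.0 - curve.points["specificity"].to_numpy()
        tpr = curve.points["sensitivity"].to_numpy()
        area = -np.trapezoid(tpr, fpr)  # cutoff ascending -> fpr descending
        assert area == pytest.approx(curve.auroc, abs=1e-12)


class TestOptimalCutoff:
    def _curve(self, values):
        pts = pd.DataFrame(
            {"cutoff": range(4, 4 + len(values)), "youden_er": values}
        )
        return RocCurve(points=pts, auroc=0.5)

    def test_unique_maximum(self):
        values = [0.0] * 17
        values[6] = 0.3  # cutoff 10
        assert optimal_cutoff(self._curve(values)) == 10

    def test_constant_criterion_breaks_tie_low(self):
        assert optimal_cutoff(self._curve([0.1] * 17)) == 4

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            values = rng.random(17)
            curve = self._curve(list(values))
            best = max(range(17), key=lambda i: (values[i], -i)) + 4
            assert optimal_cutoff(curve) == best

    def test_rejects_unknown_criterion(self):
        with pytest.raises(ValueError):
            optimal_cutoff(self._curve([0.1] * 17), "accuracy")


class TestIncidence:
    def test_published_totals_reproduce(self):
        # whole study: 27,696 falls over 3,689,561 resident-days
        r = incidence_rate(27_696, 3_689_561.0)
        assert round(r.estimate, 1) == 7.5
        assert round(r.ci_low, 1) == 7.4 and round(r.ci_high, 1) == 7.6
        # first six months after baseline: 7487 falls over 820,752 days
        r6 = incidence_rate(7_487, 820_752.0)
        assert round(r6.estimate, 1) == 9.1

    def test_zero_events(self):
        r = incidence_rate(0, 1000.0)
        assert r.estimate == 0.0 and r.ci_low == 0.0 and r.ci_high > 0.0

    def test_scale_invariance(self):
        a = incidence_rate(50, 10_000.0)
        b = incidence_rate(100, 20_000.0)
        assert a.estimate == pytest.approx(b.estimate)

    def test_rejects_nonpositive_persontime(self):
        with pytest.raises(ValueError):
            incidence_rate(5, 0.0)


class TestFollowupSequence:
    def test_everyone_single_assessment_gives_empty(self, toy_cohort):
        residents, assessments, falls = toy_cohort
        single = assessments.drop_duplicates("resident_id", keep="first")
        out = followup_sequence_eval(residents, single, falls, k_range=(2,))
        assert len(out) == 0

    def test_toy_k2_matches_enumeration(self, toy_cohort):
        residents, assessments, falls = toy_cohort
        out = followup_sequence_eval(
            residents, assessments, falls, k_range=(2,), cutoff=14
        )
        # only C has a second assessment (score 15 > 14, 2 falls after):
        # the single window is a true positive
        sens = out[out["metric"] == "sensitivity"].iloc[0]
        assert sens["estimate"] == 1.0
        assert sens["n_windows"] == 1
        ser = out[out["metric"] == "sensitivity_er"].iloc[0]
        assert ser["estimate"] == 1.0
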