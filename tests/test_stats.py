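import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pronelung.analytics import MovementSummary, SubjectResult, VolumeReport
from pronelung.core_io import SubjectRecord
from pronelung.errors import DegenerateInputError, ValidationError
from pronelung.stats import (
    GroupingRule,
    cohort_tables,
    holm_adjust,
    oneway_anova,
    paired_t,
    spearman,
    welch_t,
)

from oracles import anova_oracle, paired_t_oracle, spearman_oracle, welch_t_oracle


class TestPairedT:
    def test_symmetric_deltas(self):
        res = paired_t([1.0, -1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = paired_t([2.0, 0.0, 2.0, 0.0])
        assert res.statistic == pytest.approx(1.0 / (1.1547005 / 2.0), rel=1e-6)
        assert res.dof == 3

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([5.0, 5.0, 5.0])


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        a, b = [0.0, 0.0, 1.0, 1.0], [10.0, 10.0, 11.0, 11.0]
        res = welch_t(a, b)
        t, dof, p = welch_t_oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.dof == pytest.approx(dof, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p, abs=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])


class TestAnova:
    def test_three_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = oneway_anova([g, g, g])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_sum_of_squares_oracle(self):
        groups = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [101.0, 102.0, 103.0]]
        res = oneway_anova(groups)
        f, d1, d2, p = anova_oracle(groups)
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert (res.dof, res.n - len(groups)) == (d1, d2)
        assert res.p_two_sided == pytest.approx(p, abs=1e-12)

    def test_two_groups_redirected(self):
        with pytest.raises(ValidationError, match="welch"):
            oneway_anova([[1.0, 2.0], [3.0, 4.0]])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).estimate == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3]).estimate == pytest.approx(-1.0)

    def test_tied_example_matches_rank_oracle(self):
        x, y = [1.0, 2.0, 2.0, 3.0], [1.0, 3.0, 2.0, 4.0]
        res = spearman(x, y)
        rho, p = spearman_oracle(x, y)
        assert res.estimate == pytest.approx(rho, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p, abs=1e-9)

    def test_missing_values_dropped_pairwise(self):
        res = spearman([1, 2, np.nan, 4, 5], [2, 4, 6, np.nan, 10])
        assert res.n == 3
        assert res.estimate == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman(x, y).estimate
        assert spearman(np.exp(x), y).estimate == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).estimate == pytest.approx(base, abs=1e-12)


class TestGrouping:
    def test_exactly_thirty_percent_is_severe(self):
        rule = GroupingRule("fibrosis_dichotomy_30")
        rec = SubjectRecord("S1", 30.0, "normal")
        assert rule.assign(rec) == "severe"

    def test_dichotomy_splits_two_two(self):
        rule = GroupingRule("fibrosis_dichotomy_30")
        recs = [SubjectRecord(f"S{i}", e, "normal") for i, e in enumerate((10, 20, 30, 40))]
        groups = [rule.assign(r) for r in recs]
        assert groups.count("mild") == 2 and groups.count("severe") == 2

    def test_three_level_none_is_zero_only(self):
        rule = GroupingRule("fibrosis_three_level")
        assert rule.assign(SubjectRecord("a", 0.0, "normal")) == "none"
        assert rule.assign(SubjectRecord("b", 10.0, "normal")) == "mild"
        assert rule.assign(SubjectRecord("c", 30.0, "normal")) == "severe"


def test_holm_adjustment_is_monotone_and_bounded():
    adj = holm_adjust([0.01, 0.04, 0.03, 0.6])
    assert all(0 <= p <= 1 for p in adj)
    assert adj[0] == pytest.approx(0.04)


def _fake_cohort(n=12, couple=True, seed=0):
    rng = np.random.default_rng(seed)
    results, records = [], []
    for i in range(n):
        extent = float(rng.choice([0, 10, 20, 30, 40, 50]))
        amp = 20 - 0.2 * extent + rng.normal(0, 1)
        fvc = 1.5 + (0.08 * amp if couple else 0.0) + rng.normal(0, 0.1)
        delta = {r: rng.normal(10, 5) for r in ("whole", "right", "left", "RUL", "RML", "RLL", "LUL", "LLL")}
        supine = {r: 500.0 for r in delta}
        supine["whole"] = supine["right"] + supine["left"]
        prone = {r: supine[r] + delta[r] for r in delta}
        prone["whole"] = prone["right"] + prone["left"]
        delta["whole"] = prone["whole"] - supine["whole"]
        vr = VolumeReport(supine, prone, delta)
        mv = MovementSummary(amp / 20, amp / 15, amp / 18, amp / 10)
        results.append(SubjectResult(f"S{i}", True, [], volume_report=vr, movement=mv))
        pattern = "normal" if extent == 0 else "UIP_or_probable"
        records.append(SubjectRecord(f"S{i}", extent, pattern, round(fvc, 3)))
    return results, records


class TestCohortTables:
    def test_coupled_cohort_shows_positive_fvc_movement_correlation(self):
        results, records = _fake_cohort(couple=True)
        tables = cohort_tables(results, records)
        corr = tables["correlations"]
        row = corr[corr["pair"] == "FVC vs 3D plane (cm)"].iloc[0]
        assert row["rho"] > 0

    def test_zero_delta_cohort_flagged_degenerate(self):
        results, records = _fake_cohort()
        for r in results:
            r.volume_report.delta_ml = {k: 0.0 for k in r.volume_report.delta_ml}
        tables = cohort_tables(results, records)
        vol = tables["volume_changes"]
        assert (vol["flag"] == "degenerate (zero variance)").all()
        assert vol["p_value"].isna().all()

    def test_grouped_movement_table_has_group_means(self):
        results, records = _fake_cohort()
        tables = cohort_tables(results, records)
        t4 = tables["movement_by_fibrosis_dichotomy_30"]
        assert {"mild_mean", "severe_mean", "p_value"} <= set(t4.columns)
        assert len(t4) == 4  # 3D + three axes
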