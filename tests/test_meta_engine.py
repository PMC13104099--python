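"""Trial effects and inverse-variance pooling against step-by-step oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ria_impact.exceptions import NoComparisonError, UnassessedStudyError
from ria_impact.meta_engine import (
    Comparison,
    LogEffect,
    Measure,
    TrialOutcomeTable,
    pool,
    select_comparison,
    sensitivity_reanalysis,
    trial_effect,
)
from ria_impact.ria_engine import AssessorTier

from .conftest import AW, EX, NC, assessment


def dl_oracle(ys, vs):
    """Step-by-step DerSimonian-Laird pooling, independent of the library."""
    k = len(ys)
    w = [1.0 / v for v in vs]
    sw = sum(w)
    y_f = sum(wi * yi for wi, yi in zip(w, ys)) / sw
    q = sum(wi * (yi - y_f) ** 2 for wi, yi in zip(w, ys))
    if k > 1:
        tau2 = max(0.0, (q - (k - 1)) / (sw - sum(x * x for x in w) / sw))
    else:
        tau2 = 0.0
    ws = [1.0 / (v + tau2) for v in vs]
    pooled = sum(wi * yi for wi, yi in zip(ws, ys)) / sum(ws)
    se = math.sqrt(1.0 / sum(ws))
    return pooled, se, tau2, q


class TestTrialEffect:
    def test_equal_risks_give_null_rr(self):
        t = TrialOutcomeTable("s", 10, 100, 10, 100)
        e = trial_effect(t, "RR")
        assert e.y == pytest.approx(0.0)

    def test_rr_closed_form(self):
        t = TrialOutcomeTable("s", 15, 100, 10, 100)
        e = trial_effect(t, "RR")
        assert math.exp(e.y) == pytest.approx(1.5)
        assert e.se == pytest.approx(
            math.sqrt(1 / 15 - 1 / 100 + 1 / 10 - 1 / 100)
        )

    def test_or_closed_form(self):
        t = TrialOutcomeTable("s", 15, 100, 10, 100)
        e = trial_effect(t, "OR")
        assert math.exp(e.y) == pytest.approx((15 * 90) / (85 * 10))
        assert e.se == pytest.approx(
            math.sqrt(1 / 15 + 1 / 85 + 1 / 10 + 1 / 90)
        )

    def test_zero_cell_continuity_correction(self):
        t = TrialOutcomeTable("s", 0, 50, 5, 50)
        e = trial_effect(t, "RR")
        assert e.zero_corrected
        assert math.isfinite(e.y) and math.isfinite(e.se)
        # corrected cells: a=0.5, n1=51, c=5.5, n2=51
        assert math.exp(e.y) == pytest.approx((0.5 / 51) / (5.5 / 51))

    def test_double_zero_flagged_non_contributing(self):
        t = TrialOutcomeTable("s", 0, 50, 0, 50)
        assert not trial_effect(t, "RR").estimable

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            TrialOutcomeTable("s", 12, 10, 3, 10)
        with pytest.raises(ValueError):
            TrialOutcomeTable("s", 1, 0, 3, 10)


class TestPool:
    def test_single_study_identity(self):
        e = LogEffect("s", Measure.RR, -0.105, 0.04)
        r = pool([e], "random_dl")
        assert r.pooled_log == pytest.approx(-0.105)
        assert r.tau_squared == 0.0
        assert r.effect.k_trials == 1

    def test_two_identical_studies_narrow_the_ci(self):
        e = LogEffect("a", Measure.RR, -0.2, 0.1)
        e2 = LogEffect("b", Measure.RR, -0.2, 0.1)
        single = pool([e])
        both = pool([e, e2])
        assert both.pooled_log == pytest.approx(-0.2)
        width_single = single.effect.ci_high - single.effect.ci_low
        width_both = both.effect.ci_high - both.effect.ci_low
        assert width_both < width_single
        assert both.tau_squared == 0.0

    def test_three_study_set_matches_external_reference(self):
        """Frozen values computed independently with metafor 4.8-0 (DL)."""
        tables = [
            TrialOutcomeTable("s1", 15, 100, 10, 100),
            TrialOutcomeTable("s2", 8, 120, 12, 115),
            TrialOutcomeTable("s3", 30, 300, 45, 310),
        ]
        r = pool([trial_effect(t, "RR") for t in tables], "random_dl")
        assert r.pooled_log == pytest.approx(-0.173172811526, abs=1e-10)
        assert r.pooled_se == pytest.approx(0.252331582860, abs=1e-10)
        assert r.tau_squared == pytest.approx(0.081563028435, abs=1e-10)
        assert r.q_statistic == pytest.approx(3.414796846765, abs=1e-10)
        rf = pool([trial_effect(t, "RR") for t in tables], "fixed_iv")
        assert rf.pooled_log == pytest.approx(-0.221339162440, abs=1e-10)
        assert rf.pooled_se == pytest.approx(0.175532869486, abs=1e-10)

    def test_no_studies_not_estimable(self):
        r = pool([])
        assert not r.effect.estimable
        assert r.effect.k_trials == 0

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-1.5, 1.5), st.floats(0.02, 1.0)
            ),
            min_size=1, max_size=10,
        ),
        method=st.sampled_from(["fixed_iv", "random_dl"]),
    )
    @settings(max_examples=300, deadline=None)
    def test_random_sets_match_oracle(self, data, method):
        ys = [y for y, _ in data]
        vs = [s * s for _, s in data]
        effects = [
            LogEffect(f"s{i}", Measure.RR, y, math.sqrt(v))
            for i, (y, v) in enumerate(zip(ys, vs))
        ]
        r = pool(effects, method)
        if method == "random_dl":
            pooled, se, tau2, _ = dl_oracle(ys, vs)
        else:
            w = [1 / v for v in vs]
            pooled = sum(wi * yi for wi, yi in zip(w, ys)) / sum(w)
            se = math.sqrt(1 / sum(w))
            tau2 = 0.0
        assert r.pooled_log == pytest.approx(pooled, abs=1e-10)
        assert r.pooled_se == pytest.approx(se, abs=1e-10)
        assert r.tau_squared == pytest.approx(tau2, abs=1e-10)
        # pooled estimate stays within the span of the study effects
        assert min(ys) - 1e-9 <= r.pooled_log <= max(ys) + 1e-9

    @given(
        data=st.lists(
            st.tuples(st.floats(-1.5, 1.5), st.floats(0.02, 1.0)),
            min_size=2, max_size=8,
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_random_effects_ci_at_least_as_wide(self, data):
        effects = [
            LogEffect(f"s{i}", Measure.RR, y, s)
            for i, (y, s) in enumerate(data)
        ]
        fixed = pool(effects, "fixed_iv")
        random = pool(effects, "random_dl")
        assert random.pooled_se >= fixed.pooled_se - 1e-12

    def test_identical_effects_have_zero_tau2(self):
        effects = [LogEffect(f"s{i}", Measure.RR, 0.3, 0.1 + 0.05 * i)
                   for i in range(4)]
        assert pool(effects, "random_dl").tau_squared == 0.0


class TestSensitivityReanalysis:
    tables = [
        TrialOutcomeTable("t1", 12, 80, 15, 80),
        TrialOutcomeTable("t2", 9, 60, 11, 60),
        TrialOutcomeTable("t3", 20, 150, 25, 150),
        TrialOutcomeTable("t4", 5, 40, 9, 40),
    ]

    def finals(self, passing):
        out = []
        for t in self.tables:
            v = [NC] * 6 if t.study_id in passing else [NC, EX]
            out.append(assessment(t.study_id, v, "A3", AssessorTier.SENIOR))
        return out

    def test_single_survivor_is_its_own_pool(self):
        res = sensitivity_reanalysis(self.tables, self.finals({"t2"}))
        assert res.result.effect.k_trials == 1
        single = trial_effect(self.tables[1], "RR")
        assert res.result.pooled_log == pytest.approx(single.y)
        assert res.excluded_ids == ("t1", "t3", "t4")

    def test_no_survivors_not_estimable(self):
        res = sensitivity_reanalysis(self.tables, self.finals(set()))
        assert not res.result.effect.estimable
        assert res.result.effect.k_trials == 0

    def test_all_pass_equals_original_pooling(self):
        res = sensitivity_reanalysis(
            self.tables, self.finals({t.study_id for t in self.tables})
        )
        original = pool([trial_effect(t, "RR") for t in self.tables])
        assert res.result.pooled_log == pytest.approx(original.pooled_log)
        assert res.excluded_ids == ()

    def test_awaiting_trials_are_excluded_too(self):
        finals = [
            assessment("t1", [NC] * 6, "A3", AssessorTier.SENIOR),
            assessment("t2", [NC, AW, NC, NC, NC, NC], "A3",
                       AssessorTier.SENIOR),
            assessment("t3", [NC] * 6, "A3", AssessorTier.SENIOR),
            assessment("t4", [NC, EX], "A3", AssessorTier.SENIOR),
        ]
        res = sensitivity_reanalysis(self.tables, finals)
        assert res.included_ids == ("t1", "t3")

    def test_unassessed_study_raises(self):
        with pytest.raises(UnassessedStudyError):
            sensitivity_reanalysis(self.tables, self.finals({"t1"})[:2])


class TestSelectComparison:
    def c(self, cid, n_trials, per_arm):
        tables = tuple(
            TrialOutcomeTable(f"{cid}-{i}", 1, per_arm, 1, per_arm)
            for i in range(n_trials)
        )
        return Comparison(cid, tables)

    def test_trial_count_dominates_participants(self):
        a = self.c("A", 3, 80)     # 3 trials, 480 participants
        b = self.c("B", 2, 1250)   # 2 trials, 5000 participants
        assert select_comparison([a, b]).comparison_id == "A"

    def test_participants_break_ties(self):
        a = self.c("A", 3, 80)
        b = self.c("B", 3, 100)
        assert select_comparison([a, b]).comparison_id == "B"

    def test_lexicographic_final_tie_break(self):
        a = self.c("B", 2, 50)
        b = self.c("A", 2, 50)
        assert select_comparison([a, b]).comparison_id == "A"

    def test_single_comparison(self):
        only = self.c("X", 1, 10)
        assert select_comparison([only]) is only

    def test_empty_rejected(self):
        with pytest.raises(NoComparisonError):
            select_comparison([])
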