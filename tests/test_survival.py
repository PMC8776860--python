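"""Cohort filtering, KM/log-rank, per-IQR Cox, interaction models, c-index."""

import math

import numpy as np
import pandas as pd
import pytest

from mxproximity import (CohortTable, ConvergenceError,
                         DegenerateStatisticError, ValidationError,
                         c_index_optimism, cox_per_iqr, filter_tcga_cohort,
                         kaplan_meier, linear_interaction, log_rank, lr_test,
                         median_split, stratified_cox_interaction,
                         subgroup_expression_tests)
from mxproximity.simulate import SurvSimConfig, simulate_survival_cohort
from mxproximity.survival import SurvivalFitResult


def make_cohort(n=10, os_months=None, os_event=None, stage=None, **extra):
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "os_months": os_months if os_months is not None else rng.uniform(1, 60, n),
        "os_event": os_event if os_event is not None else np.ones(n, bool),
        "stage_group": stage if stage is not None else ["early"] * n,
        "sex": ["Female"] * n,
        "immune_score": rng.normal(size=n),
        "sox10_z": rng.normal(size=n),
        "mlana_z": rng.normal(size=n),
        "cd8a_expr": rng.lognormal(2, 1, n),
    })
    for k, v in extra.items():
        df[k] = v
    return CohortTable(df)


class TestFilter:
    def test_printed_exclusion_rules_on_toy_table(self):
        c = make_cohort(
            n=10,
            os_months=[-1.0, np.nan, 5, 6, 7, 8, 9, 10, 11, 12],
            os_event=np.ones(10, bool),
            stage=["early", "early", "excluded"] + ["late"] * 7,
        )
        # one OS<0, one missing OS, one excluded stage -> 7 retained
        out = filter_tcga_cohort(c)
        assert len(out) == 7
        # a missing OS status is a fourth, independent exclusion
        c.df["os_event"] = [1, 1, 1, np.nan, 1, 0, 1, 0, 1, 1]
        assert len(filter_tcga_cohort(c)) == 6

    def test_clean_table_unchanged_and_idempotent(self):
        c = make_cohort(n=8)
        once = filter_tcga_cohort(c)
        twice = filter_tcga_cohort(once)
        assert once.df.equals(c.df)
        assert twice.df.equals(once.df)

    def test_all_removed_is_error(self):
        c = make_cohort(n=3, stage=["excluded"] * 3)
        with pytest.raises(ValidationError):
            filter_tcga_cohort(c)


class TestMedianSplit:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4], ["low", "low", "high", "high"]),
        ([1, 2, 2, 3], ["low", "low", "low", "high"]),  # ties go low
        ([1, 2, 3], ["low", "low", "high"]),
    ])
    def test_split(self, values, expected):
        assert list(median_split(values)) == expected

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            median_split([2, 2, 2])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        times = [1.0, 2.0, 3.0, 4.0]
        km = kaplan_meier(times, [True] * 4)
        assert km.survival_at(2.0) == pytest.approx(0.5)
        for t, s in [(0.5, 1.0), (1.0, 0.75), (3.0, 0.25), (4.0, 0.0)]:
            assert km.survival_at(t) == pytest.approx(s)

    def test_censoring_keeps_subjects_at_risk(self):
        km = kaplan_meier([1, 2, 3, 4], [True, False, True, True])
        # after censoring at 2, the event at 3 removes 1 of 2 at risk
        assert km.survival_at(3) == pytest.approx(0.75 * 0.5)

    def test_no_events_flat_curve(self):
        km = kaplan_meier([1, 2, 3], [False] * 3)
        assert (km.survival == 1.0).all()
        assert math.isinf(km.median)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 4, 5] * 2
        groups = ["a"] * 5 + ["b"] * 5
        res = log_rank(times, [True] * 10, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(1)
        t_a = rng.exponential(10, 200)
        t_b = rng.exponential(10 / 3, 200)   # hazard ratio 3
        res = log_rank(np.r_[t_a, t_b], [True] * 400,
                       ["a"] * 200 + ["b"] * 200)
        assert res.p_value < 1e-3

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            log_rank([1, 2, 3], [True] * 3, ["a"] * 3)


class TestCoxPerIqr:
    def test_recovers_programmed_hazard_ratio(self):
        iqr_normal = 1.34898  # IQR of the standard normal
        cfg = SurvSimConfig(
            n=800, betas={"x": math.log(2) / iqr_normal},
            covariate_distributions={"x": ("normal", 0, 1)},
            baseline_hazard=0.02, censor_rate=0.005, seed=7)
        cohort = simulate_survival_cohort(cfg)
        fit = cox_per_iqr(cohort.df["os_months"], cohort.df["os_event"],
                          cohort.df["x"], "x")
        hr, lo, hi, iqr = fit.hr_per_iqr["x"]
        assert 1.6 < hr < 2.4
        assert lo < hr < hi

    def test_scale_invariance_of_per_iqr_hr(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        a = cox_per_iqr(t, np.ones(n, bool), x, "x")
        b = cox_per_iqr(t, np.ones(n, bool), 37.0 * x, "x")
        assert a.hr_per_iqr["x"][0] == pytest.approx(b.hr_per_iqr["x"][0],
                                                     rel=1e-6)

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            cox_per_iqr([1, 2, 3], [False] * 3, [1.0, 2.0, 3.0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            cox_per_iqr([1, 2, 3], [True] * 3, [1.0, 1.0, 1.0])


class TestInteractionModels:
    def test_interaction_coefficient_recovered(self):
        cfg = SurvSimConfig(
            n=1000,
            betas={"score": -0.4, "marker": 0.3, "stage_late": 0.6},
            covariate_distributions={"score": ("normal", 0, 1),
                                     "marker": ("normal", 0, 1)},
            interaction=("score", "marker", 0.8),
            baseline_hazard=0.02, censor_rate=0.005, seed=3)
        cohort = simulate_survival_cohort(cfg)
        full, reduced = stratified_cox_interaction(cohort, "score", "marker")
        beta = full.coefficients["score:marker"][0]
        assert beta == pytest.approx(0.8, abs=0.2)
        lr = lr_test(full, reduced)
        assert lr.df == 1
        assert lr.p_value < 0.001

    def test_null_interaction_small_lr_statistic(self):
        cfg = SurvSimConfig(
            n=600, betas={"score": -0.4, "marker": 0.3, "stage_late": 0.6},
            covariate_distributions={"score": ("normal", 0, 1),
                                     "marker": ("normal", 0, 1)},
            baseline_hazard=0.02, censor_rate=0.005, seed=4)
        cohort = simulate_survival_cohort(cfg)
        full, reduced = stratified_cox_interaction(cohort, "score", "marker")
        lr = lr_test(full, reduced)
        assert lr.statistic >= 0
        assert lr.statistic < 9  # O(1) chi-square noise under the null

    def test_reduced_gives_score_adjusted_marker_hr(self):
        cohort = simulate_survival_cohort(SurvSimConfig(n=400, seed=5))
        full, reduced = stratified_cox_interaction(
            cohort, "immune_score", "sox10_z")
        assert set(reduced.coefficients) == {"immune_score", "sox10_z"}
        hr, lo, hi, iqr = reduced.hr_per_iqr["sox10_z"]
        assert lo < hr < hi and iqr > 0
        assert reduced.strata == ("stage_group",)

    def test_empty_stratum_rejected(self):
        c = make_cohort(n=6, stage=["early"] * 6)
        c.df.loc[0:2, "os_event"] = False
        c2 = CohortTable(pd.concat(
            [c.df, c.df.assign(stage_group="late", os_event=False,
                               patient_id=[f"Q{i}" for i in range(6)])],
            ignore_index=True))
        with pytest.raises(ValidationError, match="stratum"):
            stratified_cox_interaction(c2, "immune_score", "sox10_z")

    def test_lr_identical_models_is_null(self):
        fit = SurvivalFitResult(coefficients={"a": (0.1, 0.1)}, loglik=-10.0)
        res = lr_test(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 0

    def test_lr_nesting_violation_detected(self):
        full = SurvivalFitResult(coefficients={"a": (0, 1)}, loglik=-12.0)
        red = SurvivalFitResult(coefficients={"a": (0, 1), "b": (0, 1)},
                                loglik=-10.0)
        with pytest.raises(ValidationError):
            lr_test(full, red)
        with pytest.raises(ConvergenceError):
            lr_test(SurvivalFitResult(coefficients={"a": (0, 1), "b": (0, 1)},
                                      loglik=-13.0),
                    SurvivalFitResult(coefficients={"a": (0, 1)},
                                      loglik=-10.0))


class TestCIndex:
    def test_perfect_risk_ordering(self):
        n = 40
        times = np.arange(1, n + 1, dtype=float)
        c = make_cohort(n=n, os_months=times, os_event=np.ones(n, bool),
                        risk=-times)  # higher risk, shorter survival
        # ridge penalizer keeps the perfectly separating fit finite; the
        # risk ordering (hence the c-index) is unaffected
        res = c_index_optimism(c, ["risk"], B=50, seed=0, penalizer=0.5)
        assert res.apparent == pytest.approx(1.0)

    def test_random_risk_score_near_half(self):
        rng = np.random.default_rng(8)
        n = 500
        c = make_cohort(n=n, os_months=rng.exponential(20, n),
                        os_event=np.ones(n, bool), noise=rng.normal(size=n))
        res = c_index_optimism(c, ["noise"], B=50, seed=1)
        assert 0.45 < res.apparent < 0.55

    def test_deterministic_given_seed(self):
        c = simulate_survival_cohort(SurvSimConfig(n=150, seed=9))
        a = c_index_optimism(c, ["immune_score", "sox10_z"], B=50, seed=3)
        b = c_index_optimism(c, ["immune_score", "sox10_z"], B=50, seed=3)
        assert a == b

    def test_small_bootstrap_rejected(self):
        c = simulate_survival_cohort(SurvSimConfig(n=100, seed=1))
        with pytest.raises(ValidationError):
            c_index_optimism(c, ["sox10_z"], B=10, seed=0)


class TestSubgroupExpression:
    def test_identical_response_all_adjusted_p_one(self):
        rng = np.random.default_rng(3)
        c = make_cohort(n=40, flat=np.ones(40))
        res = subgroup_expression_tests(c, "sox10_z", "cd8a_expr", ["flat"])
        assert len(res) == 6
        assert (res["p_bonferroni"] == 1.0).all()

    def test_shifted_subgroup_detected_and_bonferroni_exact(self):
        rng = np.random.default_rng(4)
        n = 200
        sox = rng.normal(size=n)
        cd8 = rng.normal(size=n)
        resp = rng.normal(size=n)
        shifted = (sox > np.median(sox)) & (cd8 <= np.median(cd8))
        resp[shifted] += 30.0
        c = make_cohort(n=n, os_months=rng.uniform(1, 50, n))
        c.df["sox10_z"] = sox
        c.df["cd8a_expr"] = cd8
        c.df["resp"] = resp
        res = subgroup_expression_tests(c, "sox10_z", "cd8a_expr", ["resp"],
                                        label_a="SOX10", label_b="CD8")
        hi_lo = "SOX10_hi_CD8_low"
        involved = res[(res["group1"] == hi_lo) | (res["group2"] == hi_lo)]
        assert len(involved) == 3
        assert (involved["p_bonferroni"] < 0.01).all()
        ok = res["p_raw"].notna()
        np.testing.assert_allclose(res.loc[ok, "p_bonferroni"],
                                   np.minimum(1.0, 6 * res.loc[ok, "p_raw"]))

    def test_tiny_subgroup_flagged_not_computed(self):
        n = 9
        c = make_cohort(n=n)
        c.df["sox10_z"] = [0, 0, 0, 0, 1, 1, 1, 1, 2]
        c.df["cd8a_expr"] = [0, 0, 1, 1, 0, 0, 1, 1, 2]
        c.df["g"] = np.arange(n, dtype=float)
        res = subgroup_expression_tests(c, "sox10_z", "cd8a_expr", ["g"])
        assert (res["flag"] == "subgroup too small").any()


class TestLinearInteraction:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(5)
        n = 50
        x1 = rng.normal(size=n)
        log2_cd8 = rng.normal(3, 1, n)
        y = 1.0 + 0.5 * x1 + 0.0 * log2_cd8
        c = make_cohort(n=n)
        c.df["sox10_z"] = x1
        c.df["cd8a_expr"] = 2.0 ** log2_cd8
        c.df["resp"] = 2.0 ** y
        table, n_exc = linear_interaction(c, "resp")
        assert n_exc == 0
        np.testing.assert_allclose(
            table.set_index("term")["coef"][
                ["intercept", "sox10_z", "log2_cd8a_expr", "interaction"]],
            [1.0, 0.5, 0.0, 0.0], atol=1e-8)

    def test_interaction_recovery_with_noise(self):
        rng = np.random.default_rng(6)
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(3, 1, n)
        y = 0.2 + 0.3 * x1 + 0.6 * x2 + 0.5 * x1 * x2 + rng.normal(0, 0.1, n)
        c = make_cohort(n=n)
        c.df["sox10_z"] = x1
        c.df["cd8a_expr"] = 2.0 ** x2
        c.df["resp"] = 2.0 ** y
        table, _ = linear_interaction(c, "resp")
        coef = table.set_index("term")["coef"]["interaction"]
        assert coef == pytest.approx(0.5, abs=0.05)

    def test_nonpositive_rows_excluded_with_count(self):
        c = make_cohort(n=20)
        c.df["resp"] = np.r_[np.zeros(3), np.ones(17) * 4.0]
        table, n_exc = linear_interaction(c, "resp")
        assert n_exc == 3
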