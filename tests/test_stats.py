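import numpy as np
import pytest
from scipy import stats as sps

from rdocpheno import (
    CohortTable,
    baseline_table,
    cochran_q,
    covariate_regression,
    cox_secondary,
    los_logistic,
    rdoc_group_comparison,
)
from rdocpheno.errors import ValidationError

from tests._oracles import crossproduct_or, efron_grid_argmax, ols_normal_equations
from tests.conftest import make_cohort_df


def two_group_cohort(n_a=30, n_b=25, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    df = make_cohort_df(
        n_a + n_b,
        rng=rng,
        diagnosis=["depression"] * n_a + ["schizophrenia"] * n_b,
        scores={"negval": np.concatenate([rng.normal(0.15 + shift, 0.05, n_a), rng.normal(0.15, 0.05, n_b)])},
    )
    return CohortTable(df)


class TestBaselineTable:
    def test_two_group_anova_f_equals_t_squared(self):
        cohort = two_group_cohort()
        rows = baseline_table(cohort)
        age_row = next(r for r in rows if r.variable == "age")
        a = cohort.df[cohort.df["diagnosis"] == "depression"]["age"]
        b = cohort.df[cohort.df["diagnosis"] == "schizophrenia"]["age"]
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert age_row.statistic == pytest.approx(t**2, rel=1e-10)

    def test_constant_flag_gives_statistic_zero_p_one(self):
        rows = baseline_table(two_group_cohort())
        htn = next(r for r in rows if r.variable == "htn")  # all zero in the factory
        assert htn.statistic == 0.0 and htn.p_value == 1.0

    def test_zero_variance_continuous_flagged_degenerate_not_crash(self, cohort_factory):
        df = cohort_factory(20, diagnosis=["depression"] * 10 + ["schizophrenia"] * 10)
        df["cci"] = 1
        rows = baseline_table(CohortTable(df))
        cci = next(r for r in rows if r.variable == "cci")
        assert cci.degenerate

    def test_single_group_rejected(self, cohort_factory):
        with pytest.raises(ValidationError):
            baseline_table(CohortTable(cohort_factory(10)))


class TestCochranQ:
    def test_identical_treatments_give_p_one(self):
        x = np.random.default_rng(0).integers(0, 2, size=(20, 1))
        data = np.repeat(x, 3, axis=1)  # same binary response under all 3 conditions
        stat, p = cochran_q(data)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestGroupComparison:
    def test_planted_shift_detected_with_direction(self):
        cohort = two_group_cohort(n_a=200, n_b=100, shift=0.05, seed=3)
        rows, posthoc = rdoc_group_comparison(cohort)
        assert rows[0].p_value < 0.05
        assert posthoc and posthoc[0].direction == "depression > schizophrenia"

    def test_identical_groups_give_t_zero_p_one(self):
        df = make_cohort_df(20, diagnosis=["depression"] * 10 + ["schizophrenia"] * 10,
                            scores={"negval": np.tile([0.1, 0.2], 10)})
        # groups are element-wise identical -> mean difference exactly 0
        df["negval"] = np.concatenate([df["negval"][:10], df["negval"][:10]])
        rows, posthoc = rdoc_group_comparison(CohortTable(df), alpha=1.1)
        assert posthoc[0].t_statistic == pytest.approx(0.0)
        assert posthoc[0].p_value == pytest.approx(1.0)

    def test_posthoc_gated_on_omnibus_significance(self):
        cohort = two_group_cohort(shift=0.0, seed=8)
        rows, posthoc = rdoc_group_comparison(cohort)
        if rows[0].p_value >= 0.05:
            assert posthoc == []

    def test_bonferroni_inflates_posthoc_p(self):
        cohort = two_group_cohort(n_a=200, n_b=100, shift=0.05, seed=3)
        _, raw = rdoc_group_comparison(cohort)
        _, adj = rdoc_group_comparison(cohort, bonferroni=True)
        assert adj[0].p_value >= raw[0].p_value


class TestCovariateRegression:
    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(4)
        n = 12
        age = rng.integers(20, 70, n)
        sex = np.array(["female", "male"] * 6)
        cci = rng.poisson(0.5, n)
        score = rng.uniform(0.05, 0.3, n)
        df = make_cohort_df(n, age=age, sex=sex, cci=cci, scores={"negval": score})
        effects = covariate_regression(CohortTable(df), scale=100)
        X = np.column_stack([np.ones(n), age, (sex == "female").astype(float), cci])
        beta = ols_normal_equations(X, score * 100)
        got = {e.term: e.estimate for e in effects}
        for i, term in enumerate(["const", "age", "sex_female", "cci"]):
            assert got[term] == pytest.approx(beta[i], rel=1e-8)

    def test_noiseless_linear_data_recovered_exactly(self):
        rng = np.random.default_rng(5)
        n = 40
        age = rng.integers(20, 70, n).astype(float)
        df = make_cohort_df(n, age=age, scores={"negval": (0.5 * age) / 100})
        effects = covariate_regression(CohortTable(df), scale=100)
        age_eff = next(e for e in effects if e.term == "age")
        assert age_eff.estimate == pytest.approx(0.5, abs=1e-9)
        assert age_eff.ci_high - age_eff.ci_low == pytest.approx(0.0, abs=1e-7)

    def test_planted_slope_recovered_within_3_se(self):
        rng = np.random.default_rng(6)
        n = 500
        age = rng.integers(18, 80, n).astype(float)
        score = (0.5 * age + rng.normal(0, 1, n)) / 100
        df = make_cohort_df(n, rng=rng, age=age, scores={"negval": score})
        effects = covariate_regression(CohortTable(df), scale=100)
        age_eff = next(e for e in effects if e.term == "age")
        se = (age_eff.ci_high - age_eff.ci_low) / (2 * 1.96)
        assert abs(age_eff.estimate - 0.5) < 3 * se

    def test_constant_covariate_flags_model(self):
        df = make_cohort_df(30, cci=np.zeros(30, dtype=int), scores={"negval": np.linspace(0.1, 0.2, 30)})
        effects = covariate_regression(CohortTable(df))
        assert all(e.flag == "collinear_design" for e in effects)


class TestLosLogistic:
    def test_single_binary_predictor_matches_crossproduct_or(self):
        # exposed: 30 long / 20 short; unexposed: 10 long / 40 short
        x = np.array([1] * 50 + [0] * 50, dtype=float)
        los = np.array([5.0] * 30 + [1.0] * 20 + [5.0] * 10 + [1.0] * 40)
        df = make_cohort_df(100, los=los, scores={"negval": x / 100})
        effects = los_logistic(CohortTable(df), "depression", domains=["negval"], adjust=())
        or_hat = next(e for e in effects if e.term == "negval").or_or_hr
        assert or_hat == pytest.approx(crossproduct_or(30, 20, 10, 40), rel=1e-6)
        assert or_hat == pytest.approx(6.0, rel=1e-6)

    def test_separation_is_flagged_not_silent(self):
        x = np.array([1.0] * 20 + [0.0] * 20)
        los = np.where(x == 1, 10.0, 1.0)  # outcome perfectly determined by x
        df = make_cohort_df(40, los=los, scores={"negval": x / 100})
        effects = los_logistic(CohortTable(df), "depression", domains=["negval"], adjust=())
        assert all(e.flag for e in effects)
        assert all(np.isnan(e.estimate) for e in effects)

    def test_unknown_group_rejected(self, cohort_factory):
        with pytest.raises(ValidationError):
            los_logistic(CohortTable(cohort_factory(10, scores={"negval": np.full(10, 0.1)})), "anxiety")


class TestCoxSecondary:
    def test_beta_matches_gridsearched_efron_partial_likelihood(self):
        # 4 subjects, one tie, binary covariate
        times = np.array([2.0, 2.0, 5.0, 7.0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        df = make_cohort_df(4, los=times, age=np.full(4, 40), sex=["female"] * 4,
                            cci=np.zeros(4, dtype=int), scores={"negval": x / 100})
        eff = cox_secondary(CohortTable(df), "negval", scale=100)
        beta_grid = efron_grid_argmax(times, x)
        assert eff.estimate == pytest.approx(beta_grid, abs=5e-3)

    def test_exponential_rate_ratio_two_recovered(self):
        rng = np.random.default_rng(11)
        n = 1000
        x = (rng.random(n) < 0.5).astype(float)
        los = rng.exponential(1.0, n) / np.where(x == 1, 2.0, 1.0)  # hazard ratio 2 for x=1
        df = make_cohort_df(n, los=np.maximum(los, 1e-4), age=np.full(n, 40), sex=["male"] * n,
                            cci=np.zeros(n, dtype=int), scores={"negval": x / 100})
        eff = cox_secondary(CohortTable(df), "negval", scale=100)
        se = (np.log(eff.ci_high) - np.log(eff.ci_low)) / (2 * 1.96)
        assert abs(eff.estimate - np.log(2.0)) < 3 * se

    def test_zero_variance_domain_flagged(self):
        df = make_cohort_df(30, scores={"negval": np.full(30, 0.1)})
        eff = cox_secondary(CohortTable(df), "negval")
        assert eff.flag == "zero_variance"
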