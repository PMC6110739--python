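"""Survival core: product-limit estimator, log-rank test, Cox regression.

Independent oracles live in this file: a per-event-time hypergeometric
summation for the log-rank test, a brute-force grid maximiser for the Cox
partial likelihood, and lifelines for fitted-model agreement.
"""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from survmeta.errors import (
    GroupExplosionError,
    IdentifiabilityError,
    SeparationError,
)
from survmeta.survival import (
    SurvivalFormula,
    SurvivalSample,
    coxph_by_formula,
    fit_coxph,
    km_by_formula,
    km_estimate,
    logrank_test,
    median_survival,
)


# ---------------------------------------------------------------------------
# independent oracles


def logrank_oracle(time, event, group):
    """Direct per-event-time O / E / Var summation for two groups."""
    time, event, group = map(np.asarray, (time, event, group))
    levels = np.unique(group)
    assert levels.size == 2
    O2 = E2 = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n2 = (at_risk & (group == levels[1])).sum()
        d = ((time == t) & (event == 1)).sum()
        d2 = ((time == t) & (event == 1) & (group == levels[1])).sum()
        O2 += d2
        E2 += d * n2 / n
        if n > 1:
            V += d * (n - d) / (n - 1) * (n2 / n) * (1 - n2 / n)
    return O2, E2, V


def cox_partial_nll(beta, time, event, x):
    """Untied partial log-likelihood for one scalar covariate, by definition."""
    ll = 0.0
    for i in np.nonzero(event == 1)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_hand_oracle_with_censoring(self):
        # times 1,2,3 with the middle subject censored: risk sets 3 then 1
        c = km_estimate(SurvivalSample([1, 2, 3], [1, 0, 1]))
        assert np.allclose(c.event_times, [1, 3])
        assert np.allclose(c.n_at_risk, [3, 1])
        assert np.allclose(c.survival, [2 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, 50)
        c = km_estimate(SurvivalSample(t, np.ones(50, int)))
        emp = [(t > tt).mean() for tt in c.event_times]
        assert np.allclose(c.survival, emp, atol=1e-12)

    def test_greenwood_closed_form_without_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1.0, 80)
        c = km_estimate(SurvivalSample(t, np.ones(80, int)))
        assert np.allclose(c.greenwood_var, c.survival * (1 - c.survival) / 80,
                           atol=1e-12)

    def test_all_censored_curve_is_constant_one(self):
        with pytest.warns(UserWarning, match="censored"):
            c = km_estimate(SurvivalSample([1, 2, 3], [0, 0, 0]))
        assert c.event_times.size == 0
        assert c.survival_at(10.0) == 1.0

    def test_survival_monotone_and_product_of_conditionals(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.exponential(1.0, 120), 1)  # force ties
        e = rng.binomial(1, 0.7, 120)
        c = km_estimate(SurvivalSample(t, e))
        assert np.all(np.diff(c.survival) <= 1e-15)
        assert np.all((c.survival >= 0) & (c.survival <= 1))
        assert np.allclose(c.survival, np.cumprod(c.conditional_prob))
        assert np.all(np.diff(c.n_at_risk) < 0)

    def test_confidence_band_brackets_estimate_within_unit_interval(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1.0, 60)
        e = rng.binomial(1, 0.6, 60)
        c = km_estimate(SurvivalSample(t, e))
        inner = (c.survival > 0) & (c.survival < 1)
        assert np.all(c.ci_lower[inner] <= c.survival[inner])
        assert np.all(c.ci_upper[inner] >= c.survival[inner])
        assert np.all((c.ci_lower >= 0) & (c.ci_upper <= 1))

    def test_matches_lifelines_on_censored_tied_data(self):
        rng = np.random.default_rng(7)
        t = np.round(rng.exponential(1.0, 150), 1) + 0.05
        e = rng.binomial(1, 0.6, 150)
        mine = km_estimate(SurvivalSample(t, e))
        from lifelines import KaplanMeierFitter

        ref = KaplanMeierFitter().fit(t, e)
        sf = ref.survival_function_.loc[mine.event_times, "KM_estimate"].to_numpy()
        assert np.allclose(mine.survival, sf, atol=1e-12)
        ci = ref.confidence_interval_.loc[mine.event_times].to_numpy()
        assert np.allclose(np.column_stack([mine.ci_lower, mine.ci_upper]), ci,
                           atol=1e-10)


class TestMedian:
    def test_first_crossing(self):
        c = km_estimate(SurvivalSample([1, 2, 3], [1, 1, 1]))
        assert median_survival(c) == 2.0

    def test_undefined_when_never_reached(self):
        with pytest.warns(UserWarning):
            c = km_estimate(SurvivalSample([5.0, 6.0], [0, 0]))
        assert median_survival(c) is None

    def test_exact_half_counts_as_reached(self):
        c = km_estimate(SurvivalSample([5.0, 8.0], [1, 1]))  # S(5) = 0.5
        assert median_survival(c) == 5.0


# ---------------------------------------------------------------------------
# log-rank


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.repeat([0, 1], 4)
        r = logrank_test(SurvivalSample(t, e, group=g))
        assert abs(r.observed[1] - r.expected[1]) < 1e-12
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == 1.0

    def test_four_subject_hand_summation(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.ones(4, int)
        g = np.array([0, 0, 1, 1])
        r = logrank_test(SurvivalSample(t, e, group=g))
        O2, E2, V = logrank_oracle(t, e, g)
        assert (O2, E2) == (2.0, pytest.approx(19 / 6))
        assert r.observed[1] == O2
        assert r.expected[1] == pytest.approx(E2, abs=1e-12)
        assert r.variance[1, 1] == pytest.approx(V, abs=1e-12)
        assert r.statistic == pytest.approx(49 / 17, abs=1e-12)

    def test_two_group_matches_oracle_on_random_censored_data(self):
        rng = np.random.default_rng(11)
        t = np.round(rng.exponential(1.0, 100), 1) + 0.05
        e = rng.binomial(1, 0.7, 100)
        g = rng.binomial(1, 0.5, 100)
        r = logrank_test(SurvivalSample(t, e, group=g))
        O2, E2, V = logrank_oracle(t, e, g)
        assert r.statistic == pytest.approx((O2 - E2) ** 2 / V, rel=1e-12)

    def test_observed_minus_expected_sums_to_zero(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(1.0, 90)
        e = rng.binomial(1, 0.8, 90)
        g = rng.integers(0, 3, 90)
        r = logrank_test(SurvivalSample(t, e, group=g))
        assert np.sum(r.observed - r.expected) == pytest.approx(0.0, abs=1e-10)
        assert r.df == 2

    def test_multigroup_matches_lifelines(self):
        rng = np.random.default_rng(13)
        t = np.round(rng.exponential(1.0, 200), 1) + 0.05
        e = rng.binomial(1, 0.7, 200)
        g = rng.integers(0, 3, 200)
        r = logrank_test(SurvivalSample(t, e, group=g))
        ref = multivariate_logrank_test(t, g, e)
        assert r.statistic == pytest.approx(ref.test_statistic, rel=1e-10)
        assert r.p_value == pytest.approx(ref.p_value, rel=1e-10)

    def test_stratified_equals_per_stratum_accumulation(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(1.0, 120)
        e = rng.binomial(1, 0.7, 120)
        g = rng.binomial(1, 0.5, 120)
        s = rng.binomial(1, 0.5, 120)
        r = logrank_test(SurvivalSample(t, e, group=g, strata=s))
        O2 = E2 = V = 0.0
        for lev in (0, 1):
            o, ex, v = logrank_oracle(t[s == lev], e[s == lev], g[s == lev])
            O2, E2, V = O2 + o, E2 + ex, V + v
        assert r.statistic == pytest.approx((O2 - E2) ** 2 / V, rel=1e-10)


# ---------------------------------------------------------------------------
# Cox proportional hazards


class TestCox:
    def test_symmetric_arms_give_zero_coefficient(self):
        # both arms share the event pattern: partial likelihood is symmetric
        t = np.array([1.0, 3.0, 1.0, 3.0])
        e = np.ones(4, int)
        x = np.array([0.0, 0.0, 1.0, 1.0])
        m = fit_coxph(SurvivalSample(t, e), x, ties="breslow")
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_maximiser_small_sample(self):
        rng = np.random.default_rng(21)
        n = 15
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / np.exp(0.8 * x))  # continuous: no ties
        e = np.ones(n, int)
        m = fit_coxph(SurvivalSample(t, e), x)
        grid = np.arange(-3.0, 3.0, 1e-4)
        nll = np.array([cox_partial_nll(b, t, e, x) for b in grid])
        beta_grid = grid[np.argmin(nll)]
        assert m.coefficients[0] == pytest.approx(beta_grid, abs=1e-4)

    def test_score_at_zero_equals_logrank_breslow_no_ties(self):
        rng = np.random.default_rng(22)
        n = 120
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / np.exp(0.5 * x))
        c = rng.exponential(2.0, n)
        tt, e = np.minimum(t, c), (t <= c).astype(int)
        m = fit_coxph(SurvivalSample(tt, e), x, ties="breslow")
        r = logrank_test(SurvivalSample(tt, e, group=x.astype(int)))
        assert m.score_at_zero == pytest.approx(r.statistic, abs=1e-8)

    def test_matches_lifelines_with_ties_both_corrections(self):
        rng = np.random.default_rng(23)
        n = 250
        x1 = rng.binomial(1, 0.5, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t = rng.exponential(1 / np.exp(0.7 * x1 - 0.3 * x2))
        c = rng.exponential(2.0, n)
        tt = np.round(np.minimum(t, c), 1) + 0.05
        e = (t <= c).astype(int)
        m = fit_coxph(SurvivalSample(tt, e), np.column_stack([x1, x2]))
        df = pd.DataFrame({"t": tt, "e": e, "x1": x1, "x2": x2})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(m.coefficients, ref.params_.to_numpy(), atol=1e-6)
        assert np.allclose(m.standard_errors, ref.standard_errors_.to_numpy(),
                           atol=1e-6)
        assert m.log_likelihood == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_stratified_fit_matches_lifelines(self):
        rng = np.random.default_rng(24)
        n = 200
        x = rng.normal(0, 1, n)
        s = rng.binomial(1, 0.5, n)
        t = rng.exponential(1 / np.exp(0.4 * x + 0.8 * s))
        e = np.ones(n, int)
        m = fit_coxph(SurvivalSample(t, e, strata=s), x)
        df = pd.DataFrame({"t": t, "e": e, "x": x, "s": s})
        ref = CoxPHFitter().fit(df, "t", "e", strata=["s"])
        assert m.coefficients[0] == pytest.approx(ref.params_.iloc[0], abs=1e-6)

    def test_loglik_trace_is_nondecreasing(self):
        rng = np.random.default_rng(25)
        n = 150
        x = rng.normal(0, 1, (n, 2))
        t = rng.exponential(1 / np.exp(x @ [1.0, -0.5]))
        e = rng.binomial(1, 0.8, n)
        m = fit_coxph(SurvivalSample(t, e), x)
        assert np.all(np.diff(m.loglik_trace) >= -1e-9)
        assert np.allclose(m.hazard_ratios, np.exp(m.coefficients))
        ci = m.confint()
        assert np.all(ci[:, 0] <= m.coefficients) and np.all(
            m.coefficients <= ci[:, 1]
        )

    def test_constant_covariate_is_rejected(self):
        with pytest.raises(IdentifiabilityError, match="constant"):
            fit_coxph(
                SurvivalSample([1.0, 2, 3, 4], [1, 1, 1, 1]),
                np.ones(4),
            )

    def test_separation_is_detected(self):
        # all x=1 subjects fail strictly before all x=0: monotone likelihood
        t = np.concatenate([np.arange(1, 11), np.arange(11, 21)]).astype(float)
        e = np.ones(20, int)
        x = np.concatenate([np.ones(10), np.zeros(10)])
        with pytest.raises(SeparationError):
            fit_coxph(SurvivalSample(t, e), x)


@pytest.mark.parametrize("scale", [0.1, 1.0, 7.3])
def test_time_rescaling_invariance(scale):
    """Rank-based statistics are unchanged by a positive rescaling of time."""
    rng = np.random.default_rng(31)
    n = 100
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1 / np.exp(0.6 * x))
    e = rng.binomial(1, 0.8, n)
    base_km = km_estimate(SurvivalSample(t, e))
    base_lr = logrank_test(SurvivalSample(t, e, group=x.astype(int)))
    base_cox = fit_coxph(SurvivalSample(t, e), x)
    km2 = km_estimate(SurvivalSample(t * scale, e))
    lr2 = logrank_test(SurvivalSample(t * scale, e, group=x.astype(int)))
    cox2 = fit_coxph(SurvivalSample(t * scale, e), x)
    assert np.allclose(km2.survival, base_km.survival)
    assert lr2.statistic == pytest.approx(base_lr.statistic, rel=1e-12)
    assert cox2.coefficients[0] == pytest.approx(base_cox.coefficients[0], abs=1e-8)


# ---------------------------------------------------------------------------
# formula-driven entry points


class TestFormula:
    def test_binary_covariate_two_curves_one_df(self, small_cohort, fixture_dir):
        from survmeta.etl import load_dataset
        from survmeta.metadata import read_metadata

        bundle = read_metadata(
            fixture_dir / "layer1.csv",
            fixture_dir / "layer2.csv",
            fixture_dir / "layer3.csv",
        )
        ds = load_dataset(fixture_dir / "Dataset.csv", bundle)
        curves, test = km_by_formula(
            ds, SurvivalFormula("TimeOS", "EventDeath", ["rx"])
        )
        assert len(curves) == 2
        assert test.df == 1

    def test_treatment_by_sex_expands_to_four_groups(self, fixture_dir):
        from survmeta.etl import load_dataset
        from survmeta.metadata import read_metadata

        bundle = read_metadata(
            fixture_dir / "layer1.csv",
            fixture_dir / "layer2.csv",
            fixture_dir / "layer3.csv",
        )
        ds = load_dataset(fixture_dir / "Dataset.csv", bundle)
        curves, test = km_by_formula(
            ds, SurvivalFormula("TimeOS", "EventDeath", ["rx", "sex"])
        )
        assert len(curves) == 4
        assert test.df == 3

    def test_numeric_covariate_expands_over_unique_values(self, fixture_dir):
        from survmeta.etl import load_dataset
        from survmeta.metadata import read_metadata

        bundle = read_metadata(
            fixture_dir / "layer1.csv",
            fixture_dir / "layer2.csv",
            fixture_dir / "layer3.csv",
        )
        ds = load_dataset(fixture_dir / "Dataset.csv", bundle)
        curves, test = km_by_formula(
            ds, SurvivalFormula("TimeOS", "EventDeath", ["differ"])
        )
        assert len(curves) == 3
        assert test.df == 2

    def test_group_explosion_is_refused(self, fixture_dir):
        from survmeta.etl import load_dataset
        from survmeta.metadata import read_metadata

        bundle = read_metadata(
            fixture_dir / "layer1.csv",
            fixture_dir / "layer2.csv",
            fixture_dir / "layer3.csv",
        )
        ds = load_dataset(fixture_dir / "Dataset.csv", bundle)
        with pytest.raises(GroupExplosionError):
            km_by_formula(ds, SurvivalFormula("TimeOS", "EventDeath", ["age"]))

    def test_coxph_by_formula_eliminates_missing_and_fits(self, fixture_dir):
        from survmeta.etl import load_dataset
        from survmeta.metadata import read_metadata

        bundle = read_metadata(
            fixture_dir / "layer1.csv",
            fixture_dir / "layer2.csv",
            fixture_dir / "layer3.csv",
        )
        ds = load_dataset(fixture_dir / "Dataset.csv", bundle)
        ds.data.loc[0:4, "nodes"] = np.nan
        model = coxph_by_formula(
            ds,
            SurvivalFormula("TimeOS", "EventDeath", ["rx", "nodes"], strata=["sex"]),
        )
        assert model.n == ds.n_rows - 5
        assert model.converged
        assert len(model.strata_levels) == 2
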