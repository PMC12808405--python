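import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import OLSInfluence

from cohortlink.stats import (
    DesignSpec,
    ModelError,
    bh_adjust,
    build_design,
    cohort_slopes,
    dffits,
    fit_linear_model,
    fit_ols,
    paired_t_test,
    partial_f_test,
    sample_skewness,
    tukey_pairwise,
)

COHORT_LEVELS = ("A", "B", "C")


def _toy_data(rng, n=60):
    return pd.DataFrame(
        {
            "age": rng.normal(40, 10, n),
            "day": rng.uniform(0, 1000, n),
            "gender": rng.choice(["F", "M"], n),
            "cohort": rng.choice(COHORT_LEVELS, n),
            "x": rng.normal(0, 1, n),
        }
    )


FULL_SPEC = DesignSpec(
    response="y",
    terms=(
        ("age", "numeric"),
        ("gender", "categorical"),
        ("cohort", "categorical"),
        ("x", "numeric"),
        ("x:cohort", "interaction"),
    ),
    levels={"gender": ("F", "M"), "cohort": COHORT_LEVELS},
)


class TestBuildDesign:
    def test_column_names_and_treatment_coding(self, rng):
        data = _toy_data(rng)
        X, names = build_design(data, FULL_SPEC)
        assert names == [
            "(Intercept)",
            "age",
            "gender[M]",
            "cohort[B]",
            "cohort[C]",
            "x",
            "x:cohort[B]",
            "x:cohort[C]",
        ]
        j = names.index("cohort[B]")
        np.testing.assert_array_equal(X[:, j], (data["cohort"] == "B").astype(float))
        j = names.index("x:cohort[C]")
        np.testing.assert_allclose(
            X[:, j], data["x"] * (data["cohort"] == "C").astype(float)
        )

    def test_absent_level_contributes_no_column(self, rng):
        data = _toy_data(rng)
        data = data[data["cohort"] != "B"].reset_index(drop=True)
        _, names = build_design(data, FULL_SPEC)
        assert "cohort[B]" not in names
        assert "cohort[C]" in names

    def test_interaction_requires_declared_parts(self):
        with pytest.raises(ModelError, match="undeclared"):
            DesignSpec("y", (("x:cohort", "interaction"),))

    def test_dropping_removes_interactions_too(self):
        reduced = FULL_SPEC.dropping("x")
        assert [n for n, _ in reduced.terms] == ["age", "gender", "cohort"]


class TestFitOls:
    def test_against_statsmodels(self, rng):
        data = _toy_data(rng)
        X, names = build_design(data, FULL_SPEC)
        y = rng.normal(0, 1, len(data))
        ours = fit_ols(X, y, names)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-10)
        np.testing.assert_allclose(ours.rss, ref.ssr, rtol=1e-12)
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(
            ours.leverage, OLSInfluence(ref).hat_matrix_diag, atol=1e-10
        )
        assert ours.df_residual == int(ref.df_resid)
        assert not ours.rank_deficient

    def test_rank_deficiency_flagged_fit_unchanged(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = rng.normal(size=n)
        fit = fit_ols(X, y)
        assert fit.rank_deficient
        assert fit.rank == 2
        # fitted values still match the projection onto the column space
        ref = sm.OLS(y, np.column_stack([np.ones(n), x])).fit()
        np.testing.assert_allclose(fit.rss, ref.ssr, rtol=1e-10)

    def test_too_few_rows_rejected(self, rng):
        data = _toy_data(rng, n=8)
        with pytest.raises(ModelError, match="too small"):
            fit_linear_model(np.zeros(8), FULL_SPEC, data)


class TestPartialF:
    def test_against_statsmodels_compare_f(self, rng):
        data = _toy_data(rng)
        y = rng.normal(size=len(data))
        Xf, nf = build_design(data, FULL_SPEC)
        Xr, nr = build_design(data, FULL_SPEC.dropping("x"))
        cmp_ = partial_f_test(fit_ols(Xf, y, nf), fit_ols(Xr, y, nr))
        ref_f = sm.OLS(y, Xf).fit()
        ref_r = sm.OLS(y, Xr).fit()
        f_ref, p_ref, df_ref = ref_f.compare_f_test(ref_r)
        assert cmp_.F == pytest.approx(f_ref, rel=1e-10)
        assert cmp_.p == pytest.approx(p_ref, rel=1e-10, abs=1e-15)
        assert cmp_.df_num == int(df_ref)

    def test_rss_identity_random_nested_fits(self, rng):
        # F computed from the RSS identity must match F computed from the
        # explained-sum difference of projections, across random designs
        for _ in range(25):
            n = int(rng.integers(25, 60))
            p_extra = int(rng.integers(1, 4))
            X_r = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            X_f = np.column_stack([X_r, rng.normal(size=(n, p_extra))])
            y = rng.normal(size=n)
            full, red = fit_ols(X_f, y), fit_ols(X_r, y)
            cmp_ = partial_f_test(full, red)
            num = (red.rss - full.rss) / p_extra
            den = full.rss / full.df_residual
            assert cmp_.F == pytest.approx(num / den, rel=1e-10)
            assert 0.0 <= cmp_.p <= 1.0

    def test_saturated_full_model_convention(self):
        X = np.column_stack([np.ones(4), np.eye(4)[:, :3]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        full = fit_ols(X, y)
        red = fit_ols(np.ones((4, 1)), y)
        cmp_ = partial_f_test(full, red)
        assert cmp_.degenerate and cmp_.p == 0.0

    def test_wrong_nesting_rejected(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = rng.normal(size=20)
        fit = fit_ols(X, y)
        with pytest.raises(ModelError, match="residual df"):
            partial_f_test(fit, fit)


class TestCohortSlopes:
    def test_releveling_oracle(self, rng):
        """The slope in cohort L must equal the main-effect x coefficient
        when the factor is re-referenced to L, with identical se and p."""
        data = _toy_data(rng, n=90)
        y = (
            1.0
            + data["x"] * data["cohort"].map({"A": 0.5, "B": -1.0, "C": 2.0})
            + rng.normal(0, 1, len(data))
        )
        full = fit_linear_model(y, FULL_SPEC, data)
        slopes = cohort_slopes(full, "x", "cohort", COHORT_LEVELS)
        assert [s.level for s in slopes] == list(COHORT_LEVELS)
        for lev, est in zip(COHORT_LEVELS, slopes):
            order = (lev,) + tuple(c for c in COHORT_LEVELS if c != lev)
            spec = DesignSpec(
                "y", FULL_SPEC.terms, {"gender": ("F", "M"), "cohort": order}
            )
            refit = fit_linear_model(y, spec, data)
            j = refit.names.index("x")
            assert est.slope == pytest.approx(refit.beta[j], rel=1e-9)
            assert est.se == pytest.approx(refit.se[j], rel=1e-9)
            t = abs(refit.beta[j]) / refit.se[j]
            p_ref = 2.0 * scipy.stats.t.sf(t, refit.df_residual)
            assert est.p == pytest.approx(p_ref, rel=1e-9)

    def test_missing_interaction_column_rejected(self, rng):
        data = _toy_data(rng)
        y = rng.normal(size=len(data))
        red = fit_linear_model(y, FULL_SPEC.dropping("x:cohort"), data)
        with pytest.raises(ModelError, match="interaction"):
            cohort_slopes(red, "x", "cohort", COHORT_LEVELS)


class TestBH:
    def test_against_statsmodels_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_frozen_value(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_grouped_equals_separate_calls(self, rng):
        p = rng.uniform(size=30)
        g = rng.integers(0, 3, size=30)
        out = bh_adjust(p, group=g)
        for k in range(3):
            np.testing.assert_allclose(out[g == k], bh_adjust(p[g == k]))

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ModelError):
            bh_adjust([0.5, 1.5])


class TestDffits:
    def test_against_statsmodels(self, rng):
        data = _toy_data(rng)
        X, names = build_design(data, FULL_SPEC)
        y = rng.normal(size=len(data))
        fit = fit_ols(X, y, names)
        ref = OLSInfluence(sm.OLS(y, X).fit()).dffits[0]
        np.testing.assert_allclose(dffits(fit), ref, atol=1e-10)

    def test_leave_one_out_definition(self, rng):
        """DFFITS_i = (yhat_i - yhat_i(-i)) / (s_(i) * sqrt(h_i)) via actual
        row deletion and refit."""
        n = 25
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        fit = fit_ols(X, y)
        vals = dffits(fit)
        for i in range(0, n, 5):
            mask = np.arange(n) != i
            loo = fit_ols(X[mask], y[mask])
            yhat_loo = X[i] @ loo.beta
            yhat = X[i] @ fit.beta
            h_i = fit.leverage[i]
            s_loo = np.sqrt(loo.sigma2)
            ref = (yhat - yhat_loo) / (s_loo * np.sqrt(h_i))
            assert vals[i] == pytest.approx(ref, rel=1e-8)

    def test_perfect_fit_returns_zeros(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = 2.0 + 3.0 * np.arange(6.0)
        np.testing.assert_array_equal(dffits(fit_ols(X, y)), np.zeros(6))


class TestSkewness:
    def test_against_scipy_bias_corrected(self, rng):
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(5, 100))) ** 2
            assert sample_skewness(x) == pytest.approx(
                scipy.stats.skew(x, bias=False), rel=1e-12
            )

    def test_frozen_value(self):
        # for (0,0,0,1): g1 = (3/4*(1/4)+1/4*(3/4)... ) works out to exactly 2
        assert sample_skewness([0.0, 0.0, 0.0, 1.0]) == pytest.approx(2.0)

    def test_zero_variance_convention(self):
        assert sample_skewness([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_sign_flips_with_reflection(self, rng):
        x = rng.exponential(size=50)
        assert sample_skewness(-x) == pytest.approx(-sample_skewness(x), rel=1e-12)


class TestTukey:
    def test_oneway_against_statsmodels(self, rng):
        """With no covariates the adjusted-mean differences are raw group
        mean differences; compare against pairwise_tukeyhsd."""
        g = np.repeat(list(COHORT_LEVELS), (12, 9, 15))
        y = rng.normal(0, 1, g.size) + np.repeat([0.0, 1.0, 0.3], (12, 9, 15))
        data = pd.DataFrame({"cohort": g})
        spec = DesignSpec(
            "y", (("cohort", "categorical"),), {"cohort": COHORT_LEVELS}
        )
        fit = fit_linear_model(y, spec, data)
        ours = tukey_pairwise(fit, "cohort", COHORT_LEVELS)
        ref = pairwise_tukeyhsd(y, g, alpha=0.05)
        # statsmodels orders pairs the same way (sorted levels here)
        for c, diff, p_adj in zip(ours, ref.meandiffs, ref.pvalues):
            assert -c.estimate == pytest.approx(diff, rel=1e-9)
            assert c.adjusted_p == pytest.approx(p_adj, abs=2e-4)

    def test_adjusted_p_never_below_unadjusted(self, rng):
        data = _toy_data(rng, n=80)
        y = rng.normal(size=80)
        fit = fit_linear_model(y, FULL_SPEC.dropping("x"), data)
        for c in tukey_pairwise(fit, "cohort", COHORT_LEVELS):
            assert c.adjusted_p >= c.p_unadjusted - 1e-12


class TestPairedT:
    def test_against_scipy(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        t, p = paired_t_test(a, b)
        ref = scipy.stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_conventions(self):
        assert paired_t_test([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)
        t, p = paired_t_test([2.0, 3.0], [1.0, 2.0])
        assert t == np.inf and p == 0.0
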