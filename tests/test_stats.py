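"""Weighted regression and test machinery."""

import numpy as np
import pytest
from scipy import stats as sps

from pepfit import (
    adjusted_r2,
    lrt,
    quantile_effect_size,
    random_intercept_fit,
    weighted_pearson,
    weighted_quantile,
    weighted_welch_ttest,
    wls_fit,
)
from pepfit.stats import aa_frequency_design
from pepfit.types import AMINO_ACIDS, CompositionRecord


def _design(x):
    return np.column_stack([np.ones(len(x)), x])


class TestWLS:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0])
        fit = wls_fit(_design(x), x.copy(), np.ones(3))
        assert fit.coefficients == pytest.approx([0.0, 1.0], abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_adjusted_r2_formula(self):
        assert adjusted_r2(0.5, 11, 1) == pytest.approx(1 - 0.5 * 10 / 9)

    def test_matches_closed_form_simple_regression(self, rng):
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 10.0, size=n)
            fit = wls_fit(_design(x), y, w)
            xb = np.average(x, weights=w)
            yb = np.average(y, weights=w)
            slope = np.sum(w * (x - xb) * (y - yb)) / np.sum(w * (x - xb) ** 2)
            assert fit.coefficients[1] == pytest.approx(slope, abs=1e-10)
            assert fit.coefficients[0] == pytest.approx(yb - slope * xb, abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        # either member of the collinear pair may be reported
        with pytest.raises(ValueError, match=r"collinear columns: \['(x|twice_x)'\]"):
            wls_fit(X, rng.normal(size=20), np.ones(20),
                    names=["intercept", "x", "twice_x"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            wls_fit(np.ones((2, 2)), np.zeros(2), np.ones(2))

    def test_weight_scale_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        w = rng.uniform(0.5, 5.0, size=30)
        f1 = wls_fit(_design(x), y, w)
        f2 = wls_fit(_design(x), y, 1000 * w)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-10)
        assert f1.r2 == pytest.approx(f2.r2)

    def test_aa_frequency_design_has_19_frequency_columns(self, rng):
        comps = []
        for i in range(40):
            counts = dict(zip(AMINO_ACIDS, rng.multinomial(50, np.ones(20) / 20)))
            comps.append(CompositionRecord(id=f"c{i}", aa_counts=counts,
                                           region_length=50))
        X, names = aa_frequency_design(comps)
        assert X.shape[1] == 20  # intercept + 19
        assert "freq_A" not in names
        # full 20-column design would be rank-deficient against the intercept
        full = np.column_stack(
            [np.ones(40)] + [[c.freq_vector()[i] for c in comps] for i in range(20)]
        )
        assert np.linalg.matrix_rank(full) < 21


class TestLRT:
    def test_identical_models_give_unit_p(self, rng):
        x = rng.normal(size=20)
        f = wls_fit(_design(x), rng.normal(size=20), np.ones(20))
        res = lrt(f, f)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_nested_models_give_positive_statistic(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        w = np.ones(20)
        null = wls_fit(np.ones((20, 1)), y, w)
        full = wls_fit(_design(x), y, w)
        stat, df, p = lrt(null, full)
        assert stat >= 0 and df == 1 and 0 <= p <= 1

    def test_different_weights_rejected(self, rng):
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        f1 = wls_fit(np.ones((20, 1)), y, np.ones(20))
        f2 = wls_fit(_design(x), y, np.full(20, 2.0))
        with pytest.raises(ValueError):
            lrt(f1, f2)

    def test_chi2_quantile(self):
        assert sps.chi2.sf(3.841458820694124, 1) == pytest.approx(0.05)

    def test_p_values_uniform_under_null(self, rng):
        pvals = []
        for _ in range(1000):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            w = rng.uniform(0.5, 2.0, size=30)
            null = wls_fit(np.ones((30, 1)), y, w)
            full = wls_fit(_design(x), y, w)
            pvals.append(lrt(null, full).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestRandomIntercept:
    def test_zero_group_variance_reduces_to_wls(self, rng):
        x = rng.normal(size=60)
        y = 2 * x + rng.normal(size=60)
        w = rng.uniform(0.5, 2.0, size=60)
        groups = np.arange(60) // 3
        mixed = random_intercept_fit(_design(x), y, w, groups)
        flat = wls_fit(_design(x), y, w)
        if mixed.group_var < 1e-8:
            np.testing.assert_allclose(mixed.coefficients, flat.coefficients,
                                       atol=1e-6)
        assert mixed.loglik >= flat.loglik - 1e-9  # nesting

    def test_recovers_group_variance(self, rng):
        n_groups, per = 200, 5
        groups = np.repeat(np.arange(n_groups), per)
        u = rng.normal(0, 1.0, size=n_groups)
        x = rng.normal(size=n_groups * per)
        y = 1.0 + 0.5 * x + u[groups] + rng.normal(0, 1.0, size=n_groups * per)
        fit = random_intercept_fit(_design(x), y, np.ones(len(y)), groups)
        assert 0.7 <= fit.group_var <= 1.3
        assert fit.sigma2 == pytest.approx(1.0, rel=0.25)

    def test_matches_statsmodels_mixedlm_on_equal_weights(self, rng):
        import statsmodels.api as sm

        groups = np.repeat(np.arange(40), 4)
        u = rng.normal(0, 0.7, size=40)
        x = rng.normal(size=160)
        y = 0.3 + 1.2 * x + u[groups] + rng.normal(0, 0.5, size=160)
        ours = random_intercept_fit(_design(x), y, np.ones(160), groups)
        ref = sm.MixedLM(y, _design(x), groups=groups).fit(reml=False)
        np.testing.assert_allclose(ours.coefficients, ref.params[:2], rtol=1e-4)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-3)

    def test_single_group_falls_back_to_wls(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        fit = random_intercept_fit(_design(x), y, np.ones(20), np.zeros(20))
        flat = wls_fit(_design(x), y, np.ones(20))
        np.testing.assert_allclose(fit.coefficients, flat.coefficients)


class TestWeightedPearson:
    def test_reduces_to_ordinary_pearson(self, rng):
        for _ in range(100):
            n = rng.integers(5, 50)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            ref_r, ref_p = sps.pearsonr(x, y)
            got = weighted_pearson(x, y, np.ones(n))
            assert got.r == pytest.approx(ref_r, abs=1e-12)
            assert got.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_exact_linear_relation(self, rng):
        x = rng.normal(size=20)
        w = rng.uniform(0.1, 5.0, size=20)
        assert weighted_pearson(x, 2 * x + 1, w).r == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        w = rng.uniform(0.1, 5.0, size=30)
        xb = np.average(x, weights=w)
        yb = np.average(y, weights=w)
        direct = np.sum(w * (x - xb) * (y - yb)) / np.sqrt(
            np.sum(w * (x - xb) ** 2) * np.sum(w * (y - yb) ** 2)
        )
        assert weighted_pearson(x, y, w).r == pytest.approx(direct, abs=1e-12)

    def test_weight_scale_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        w = rng.uniform(0.1, 5.0, size=15)
        assert weighted_pearson(x, y, w).r == pytest.approx(
            weighted_pearson(x, y, 42.0 * w).r, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            weighted_pearson([1, 1, 1], [1, 2, 3], [1, 1, 1])


class TestWeightedWelch:
    def test_reduces_to_classic_welch(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, size=2)
            x1 = rng.normal(size=n1)
            x2 = rng.normal(1.0, 2.0, size=n2)
            ref = sps.ttest_ind(x1, x2, equal_var=False)
            got = weighted_welch_ttest(x1, np.ones(n1), x2, np.ones(n2))
            assert got.t == pytest.approx(ref.statistic, abs=1e-10)
            assert got.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_groups(self):
        res = weighted_welch_ttest([1.0, 1.0], [1, 1], [1.0, 1.0], [1, 1])
        assert res.t == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_matches_independent_transcription(self, rng):
        x1 = rng.normal(size=8)
        w1 = rng.uniform(0.5, 3.0, size=8)
        x2 = rng.normal(size=12)
        w2 = rng.uniform(0.5, 3.0, size=12)

        def norm_moments(x, w):
            w = w * len(x) / w.sum()
            m = np.sum(w * x) / len(x)
            v = np.sum(w * (x - m) ** 2) / (len(x) - 1)
            return m, v, len(x)

        m1, v1, n1 = norm_moments(x1, w1)
        m2, v2, n2 = norm_moments(x2, w2)
        t = (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)
        got = weighted_welch_ttest(x1, w1, x2, w2)
        assert got.t == pytest.approx(t, abs=1e-10)

    def test_weight_scale_invariance(self, rng):
        x1, x2 = rng.normal(size=6), rng.normal(size=9)
        w1 = rng.uniform(0.5, 3.0, size=6)
        w2 = rng.uniform(0.5, 3.0, size=9)
        a = weighted_welch_ttest(x1, w1, x2, w2)
        b = weighted_welch_ttest(x1, 7 * w1, x2, 7 * w2)
        assert a.t == pytest.approx(b.t, abs=1e-12)


class TestWeightedQuantiles:
    def test_equal_weights_match_numpy_type7(self, rng):
        x = rng.normal(size=37)
        for q in (0.1, 0.25, 0.5, 0.9):
            assert weighted_quantile(x, np.ones(37), q) == pytest.approx(
                np.quantile(x, q), abs=1e-12
            )

    def test_matches_independent_ecdf_inversion(self, rng):
        x = rng.normal(size=25)
        w = rng.uniform(0.2, 4.0, size=25)
        order = np.argsort(x)
        xs, ws = x[order], w[order]
        h = np.cumsum(ws) - ws / 2
        for q in (0.1, 0.5, 0.9):
            target = h[0] + q * (h[-1] - h[0])
            # scan for bracketing knots and interpolate by hand
            k = np.searchsorted(h, target)
            if k == 0:
                expect = xs[0]
            else:
                frac = (target - h[k - 1]) / (h[k] - h[k - 1])
                expect = xs[k - 1] + frac * (xs[k] - xs[k - 1])
            assert weighted_quantile(x, w, q) == pytest.approx(expect, abs=1e-12)

    def test_effect_size_on_uniform_predictor(self, rng):
        x = np.linspace(0, 1, 2001)
        fit = wls_fit(_design(x), x.copy(), np.ones(len(x)))
        lo, hi = quantile_effect_size(fit, x, np.ones(len(x)))
        assert lo == pytest.approx(0.1, abs=0.01)
        assert hi == pytest.approx(0.9, abs=0.01)

    def test_all_weight_on_one_point(self):
        x = np.array([0.0, 0.5, 1.0])
        w = np.array([0.0, 5.0, 0.0])
        fit = wls_fit(_design(np.array([0.0, 0.5, 1.0, 0.2])),
                      np.array([0.0, 0.5, 1.0, 0.2]), np.ones(4))
        lo, hi = quantile_effect_size(fit, x, w)
        assert lo == pytest.approx(hi) == pytest.approx(0.5)
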