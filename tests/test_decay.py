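"""Decay-model fits: exact recovery, oracles, exclusion rule, SMA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpspace.decay import (
    LAMBDA_CAP_UM,
    compare_models,
    exclude_low_count_bins,
    fit_exponential,
    fit_gaussian,
    fit_linear,
    fit_powerlaw,
    type2_regression,
)

D = np.arange(600.0, 4201.0, 600.0)  # 600 .. 4200 um bin labels
W = np.full(len(D), 10.0)


def _grid_search_exponential(d, z, w, A_grid, lam_grid):
    """Brute-force weighted log-domain SSE minimization."""
    best = (np.inf, None, None)
    logz = np.log(z)
    for A in A_grid:
        for lam in lam_grid:
            pred = np.log(A) - d / lam
            sse = np.sum(w * (logz - pred) ** 2)
            if sse < best[0]:
                best = (sse, A, lam)
    return best[1], best[2]


def _grid_search_powerlaw(d, z, w, A_grid, b_grid):
    best = (np.inf, None, None)
    logz = np.log(z)
    logd = np.log(d)
    for A in A_grid:
        for b in b_grid:
            sse = np.sum(w * (logz - (np.log(A) - b * logd)) ** 2)
            if sse < best[0]:
                best = (sse, A, b)
    return best[1], best[2]


class TestExponential:
    def test_exact_recovery_on_noiseless_data(self):
        z = 1.2 * np.exp(-D / 4000.0)
        fit = fit_exponential(D, z, W)
        assert fit.A == pytest.approx(1.2, abs=1e-9)
        assert fit.lambda_um == pytest.approx(4000.0, abs=1e-6)
        assert fit.mse == pytest.approx(0.0, abs=1e-18)

    def test_flat_profile_capped(self):
        fit = fit_exponential(D, np.full(len(D), 0.8), W)
        assert fit.flat
        assert fit.lambda_um == LAMBDA_CAP_UM
        assert fit.A == pytest.approx(0.8)

    def test_zero_weight_bin_equals_omission(self):
        rng = np.random.default_rng(0)
        z = 1.0 * np.exp(-D / 3000.0) * np.exp(0.05 * rng.standard_normal(len(D)))
        w = W.copy()
        w[3] = 0.0
        fit_w = fit_exponential(D, z, w)
        keep = w > 0
        fit_o = fit_exponential(D[keep], z[keep], w[keep])
        assert fit_w.A == pytest.approx(fit_o.A, rel=1e-12)
        assert fit_w.lambda_um == pytest.approx(fit_o.lambda_um, rel=1e-12)

    def test_matches_grid_search_oracle_on_noisy_data(self):
        rng = np.random.default_rng(1)
        z = 1.3 * np.exp(-D / 3500.0) * np.exp(0.1 * rng.standard_normal(len(D)))
        w = np.array([30.0, 25, 20, 15, 10, 5, 3])
        fit = fit_exponential(D, z, w)
        A_grid = np.linspace(fit.A * 0.9, fit.A * 1.1, 121)
        lam_grid = np.linspace(fit.lambda_um * 0.9, fit.lambda_um * 1.1, 121)
        A_star, lam_star = _grid_search_exponential(D, z, w, A_grid, lam_grid)
        assert fit.A == pytest.approx(A_star, rel=0.01)
        assert fit.lambda_um == pytest.approx(lam_star, rel=0.01)

    def test_nonpositive_bins_dropped_with_warning(self):
        z = np.array([1.0, 0.5, -0.1, 0.2, 0.1, 0.05, 0.02])
        with pytest.warns(UserWarning):
            fit = fit_exponential(D, z, W)
        assert fit.bins_used == 6

    def test_too_few_bins_flags_failure(self):
        fit = fit_exponential(D[:1], np.array([0.5]), W[:1])
        assert fit.failed

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.5, 3.0))
    def test_distance_scale_equivariance(self, c):
        """Scaling distances by c scales lambda by c, A unchanged."""
        rng = np.random.default_rng(2)
        z = 0.9 * np.exp(-D / 2500.0) * np.exp(0.05 * rng.standard_normal(len(D)))
        f1 = fit_exponential(D, z, W)
        f2 = fit_exponential(c * D, z, W)
        assert f2.lambda_um == pytest.approx(c * f1.lambda_um, rel=1e-9)
        assert f2.A == pytest.approx(f1.A, rel=1e-9)


class TestPowerlaw:
    def test_exact_recovery(self):
        z = 50.0 * D**-0.6
        fit = fit_powerlaw(D, z, W)
        assert fit.A == pytest.approx(50.0, rel=1e-9)
        assert fit.b == pytest.approx(0.6, abs=1e-12)

    def test_constant_profile_gives_zero_exponent(self):
        fit = fit_powerlaw(D, np.full(len(D), 0.7), W)
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        z = 30.0 * D**-0.5 * np.exp(0.08 * rng.standard_normal(len(D)))
        w = np.array([30.0, 25, 20, 15, 10, 5, 3])
        fit = fit_powerlaw(D, z, w)
        A_star, b_star = _grid_search_powerlaw(
            D, z, w,
            np.linspace(fit.A * 0.9, fit.A * 1.1, 121),
            np.linspace(fit.b * 0.9, fit.b * 1.1, 121),
        )
        assert fit.A == pytest.approx(A_star, rel=0.01)
        assert fit.b == pytest.approx(b_star, rel=0.01)

    def test_scale_invariant_exponent(self):
        z = 40.0 * D**-0.4
        assert fit_powerlaw(2 * D, z, W).b == pytest.approx(0.4, abs=1e-9)


class TestGaussianLinear:
    def test_linear_exact(self):
        z = -2e-4 * D + 1.5
        fit = fit_linear(D, z, W)
        assert fit.params["slope"] == pytest.approx(-2e-4, rel=1e-9)
        assert fit.params["intercept"] == pytest.approx(1.5, rel=1e-9)
        assert fit.mse == pytest.approx(0.0, abs=1e-18)

    def test_gaussian_self_recovery(self):
        z = 1.1 * np.exp(-(D**2) / (2 * 2500.0**2)) + 0.3
        fit = fit_gaussian(D, z, W)
        assert fit.params["A"] == pytest.approx(1.1, abs=1e-6)
        assert fit.params["sigma_um"] == pytest.approx(2500.0, abs=1e-2)
        assert fit.params["c"] == pytest.approx(0.3, abs=1e-6)

    def test_linear_worse_than_exponential_on_exponential_data(self):
        z = 1.4 * np.exp(-D / 2000.0)
        mse_exp = fit_exponential(D, z, W).mse
        mse_lin = fit_linear(D, z, W).mse
        assert mse_exp < mse_lin


class TestLowCountExclusion:
    def test_spec_example(self):
        keep = exclude_low_count_bins([100, 100, 100, 100, 5], 0.2)
        assert keep.tolist() == [True, True, True, True, False]

    def test_uniform_counts_untouched(self):
        assert exclude_low_count_bins([50] * 6, 0.2).all()

    def test_noop_on_high_count_data(self):
        z = 1.2 * np.exp(-D / 4000.0)
        counts = np.full(len(D), 100.0)
        keep = exclude_low_count_bins(counts, 0.2)
        f_all = fit_exponential(D, z, counts)
        f_kept = fit_exponential(D[keep], z[keep], counts[keep])
        assert f_all.lambda_um == pytest.approx(f_kept.lambda_um)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            exclude_low_count_bins([1, 2, 3], 1.5)


class TestCompareModels:
    def test_mean_linearity(self):
        import pandas as pd

        fits = pd.DataFrame(
            {
                "model": ["a"] * 4 + ["b"] * 4,
                "mse": [1.0, 2, 3, 4, 2.0, 4, 6, 8],
                "failed": [False] * 8,
            }
        )
        cmp = compare_models(fits)
        assert cmp["a"]["mean"] == pytest.approx(cmp["b"]["mean"] / 2)

    def test_degenerate_distribution_reports_point_mass(self):
        import pandas as pd

        fits = pd.DataFrame(
            {"model": ["a"] * 3, "mse": [0.5] * 3, "failed": [False] * 3}
        )
        cmp = compare_models(fits)
        assert cmp["a"]["mean"] == 0.5
        assert cmp["a"]["density"] is None


class TestType2Regression:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        res = type2_regression(x, 2 * x + 1, n_boot=200, seed=0)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)

    def test_sd_ratio_closed_form_with_negative_r(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2000)
        y = -3.0 * x + 0.1 * rng.standard_normal(2000)
        res = type2_regression(x, y, n_boot=200, seed=0)
        assert res.slope == pytest.approx(-y.std(ddof=1) / x.std(ddof=1), rel=1e-9)
        assert res.slope == pytest.approx(-3.0, rel=0.01)

    def test_bootstrap_ci_brackets_estimate_and_excludes_zero(self):
        rng = np.random.default_rng(5)
        A = rng.normal(1.0, 0.2, 300)
        lam = 6000.0 - 2000.0 * A + rng.normal(0, 150, 300)
        res = type2_regression(A, lam, n_boot=500, seed=1)
        lo, hi = res.ci_slope
        assert lo <= res.slope <= hi
        assert hi < 0  # anticorrelated cloud: slope CI excludes zero

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            type2_regression(np.ones(10), np.arange(10.0), n_boot=100, seed=0)
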