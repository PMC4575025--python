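"""Analytic FPR/TPR, lognormal histogram fit, and the optimal interval."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from vctgrowth import (
    InsufficientDataError,
    LognormalGrowthModel,
    ValidationError,
    blurred_density,
    fit_lognormal_to_histogram,
    malignant_window,
    optimal_interval,
    rate_curve,
    sigma_k_proportional,
    stable_fpr,
    tpr_blurred,
    tpr_pure,
)

LN2 = math.log(2)


class TestWindow:
    def test_default_window_constants(self, window):
        assert window.k_low == pytest.approx(0.001733, abs=5e-7)
        assert window.k_high == pytest.approx(0.023105, abs=5e-7)
        assert window.k_low * window.dt_max == pytest.approx(LN2, rel=1e-12)
        assert window.k_high * window.dt_min == pytest.approx(LN2, rel=1e-12)

    def test_ratio_law(self):
        w = malignant_window(100, 200)
        assert w.k_high / w.k_low == pytest.approx(2.0, rel=1e-12)

    def test_custom_window(self):
        w = malignant_window(50, 500)
        assert w.k_low == pytest.approx(0.0013863, abs=5e-8)
        assert w.k_high == pytest.approx(0.0138629, abs=5e-8)

    def test_rejects_bad_limits(self):
        with pytest.raises(ValidationError):
            malignant_window(400, 30)
        with pytest.raises(ValidationError):
            malignant_window(0, 30)


class TestStableFpr:
    def test_noiseless_never_misclassifies(self, window):
        for dt in (1, 30, 81, 400):
            assert stable_fpr(dt, 0.0, window) == 0.0

    @pytest.mark.parametrize(
        "dt, expected",
        [(81, 0.0408201), (30, 0.2594938)],  # frozen from normal-CDF oracle
    )
    def test_oracle_values(self, dt, expected, window):
        assert stable_fpr(dt, 0.057, window) == pytest.approx(expected, abs=1e-6)

    def test_decreasing_in_interval_one_sided_regime(self, window):
        # beyond sigma_k < k_low the upper tail is negligible: monotone decay
        grid = np.arange(50, 400, 10)
        vals = [stable_fpr(dt, 0.057, window) for dt in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert stable_fpr(5000, 0.057, window) < 1e-12


class TestTpr:
    def test_total_mass_window(self, malignant_model):
        wide = malignant_window(1e-9, 1e12)
        assert tpr_pure(malignant_model, wide) == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_inside_window(self, window):
        mid = math.sqrt(window.k_low * window.k_high)
        model = LognormalGrowthModel(mu_log=math.log(mid), sigma_log=1e-6)
        assert tpr_pure(model, window) == pytest.approx(1.0, abs=1e-12)

    def test_default_mass(self, malignant_model, window):
        # normal-CDF oracle on z = (ln k - mu)/sigma at the band edges
        assert tpr_pure(malignant_model, window) == pytest.approx(0.6939772, abs=1e-6)

    def test_blurred_equals_pure_without_noise(self, malignant_model, window):
        assert tpr_blurred(malignant_model, 0.0, 81, window) == tpr_pure(
            malignant_model, window
        )

    def test_blurred_vanishing_kernel_limit(self, malignant_model, window):
        pure = tpr_pure(malignant_model, window)
        # kernel SD = k_low/10: residual leakage ~1.4e-3, frozen from oracle
        dt10 = 10 * 0.057 * math.sqrt(2) / window.k_low
        assert tpr_blurred(malignant_model, 0.057, dt10, window) == pytest.approx(
            pure, abs=2e-3
        )
        # kernel SD = k_low/100: leakage drops two orders of magnitude
        assert tpr_blurred(malignant_model, 0.057, 10 * dt10, window) == pytest.approx(
            pure, abs=1e-4
        )

    def test_blurring_loses_band_mass_at_short_interval(self, malignant_model, window):
        assert tpr_blurred(malignant_model, 0.057, 30, window) < tpr_pure(
            malignant_model, window
        )

    def test_blurred_monotone_to_pure_limit(self, malignant_model, window):
        vals = [
            tpr_blurred(malignant_model, 0.057, dt, window)
            for dt in (100, 1000, 10000)
        ]
        pure = tpr_pure(malignant_model, window)
        assert vals[0] < vals[1] < vals[2] < pure
        assert vals[2] == pytest.approx(pure, abs=1e-4)

    def test_blurred_matches_monte_carlo(self, malignant_model, window):
        """Dual route: quadrature TPR vs direct simulation of noisy k."""
        rng = np.random.default_rng(11)
        n = 200_000
        dt, a = 60.0, 0.057
        k_true = rng.lognormal(malignant_model.mu_log, malignant_model.sigma_log, n)
        k_obs = k_true + rng.normal(0, sigma_k_proportional(a, dt), n)
        mc = np.mean((window.k_low < k_obs) & (k_obs < window.k_high))
        exact = tpr_blurred(malignant_model, a, dt, window)
        assert mc == pytest.approx(exact, abs=3 * math.sqrt(exact * (1 - exact) / n))

    def test_blurred_density_normalized_and_consistent(self, malignant_model, window):
        a, dt = 0.057, 81.0
        sigma_k = sigma_k_proportional(a, dt)
        pdf = malignant_model.frozen.pdf
        # exchanged-order total mass over effectively all of k-space
        total, err = integrate.quad(
            lambda x: pdf(x)
            * (
                stats.norm.cdf((10.0 - x) / sigma_k)
                - stats.norm.cdf((-1.0 - x) / sigma_k)
            ),
            0,
            math.exp(malignant_model.mu_log + 10 * malignant_model.sigma_log),
            limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)
        # pointwise blurred density agrees with a dense fixed-grid oracle
        for k in (0.0, 0.005, 0.02, 0.1):
            t = np.linspace(-12, 12, 40001)
            oracle = integrate.simpson(
                pdf(k - sigma_k * t) * stats.norm.pdf(t), x=t
            )
            assert blurred_density(k, malignant_model, a, dt) == pytest.approx(
                oracle, rel=1e-6, abs=1e-9
            )


class TestOptimalInterval:
    def test_degenerate_large_alpha(self, window):
        assert optimal_interval(0.057, alpha=0.999, window=window) == 1

    def test_paper_conditions(self, window):
        day = optimal_interval(0.057, alpha=0.05, window=window)
        assert day == 77
        assert stable_fpr(day, 0.057, window) < 0.05
        assert stable_fpr(day - 1, 0.057, window) >= 0.05

    def test_interval_scales_with_slope(self, window):
        base = optimal_interval(0.057, 0.05, window)
        doubled = optimal_interval(0.114, 0.05, window)
        assert abs(doubled - 2 * base) <= 1

    def test_agrees_with_exhaustive_scan(self, window):
        for a, alpha in [(0.03, 0.05), (0.057, 0.05), (0.057, 0.01), (0.09, 0.10)]:
            brute = next(
                dt for dt in range(1, 3651) if stable_fpr(dt, a, window) < alpha
            )
            assert optimal_interval(a, alpha, window) == brute


class TestLognormalHistogramFit:
    def test_noiseless_self_consistency(self, malignant_model):
        k = np.geomspace(0.002, 0.1, 20)
        counts = malignant_model.frozen.pdf(k)
        fit = fit_lognormal_to_histogram(k, counts)
        assert fit.mu_log == pytest.approx(math.log(0.015), abs=1e-6)
        assert fit.sigma_log == pytest.approx(0.83, abs=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)

    def test_amplitude_separates_from_shape(self, malignant_model):
        k = np.geomspace(0.002, 0.1, 20)
        counts = malignant_model.frozen.pdf(k)
        fit = fit_lognormal_to_histogram(k, 50 * counts)
        assert fit.mu_log == pytest.approx(math.log(0.015), abs=1e-6)
        assert fit.sigma_log == pytest.approx(0.83, abs=1e-6)
        assert fit.amplitude == pytest.approx(50.0, rel=1e-6)

    def test_recovery_from_sampled_histogram(self, malignant_model):
        """120 sampled k values, 12 log-spaced bins: parameters recovered."""
        rng = np.random.default_rng(9)
        k = rng.lognormal(malignant_model.mu_log, malignant_model.sigma_log, 120)
        # equal-width bins: raw counts are then proportional to the density
        # at the centers (log-spaced bins would need a bin-width correction)
        edges = np.linspace(0, np.quantile(k, 0.98), 13)
        counts, _ = np.histogram(k, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        fit = fit_lognormal_to_histogram(centers, counts)
        assert fit.mu_log == pytest.approx(malignant_model.mu_log, abs=0.15)
        assert fit.sigma_log == pytest.approx(malignant_model.sigma_log, abs=0.15)

    def test_degenerate_histograms_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_lognormal_to_histogram([0.01, 0.02], [1, 2])
        with pytest.raises(InsufficientDataError):
            fit_lognormal_to_histogram([0.01, 0.02, 0.04], [0, 5, 0])


class TestRateCurve:
    def test_noiseless_curve(self, malignant_model, window):
        curve = rate_curve(0.0, malignant_model, window, [30, 60, 90])
        pure = tpr_pure(malignant_model, window)
        assert all(p.fpr == 0.0 for p in curve)
        assert all(p.tpr == pytest.approx(pure, rel=1e-12) for p in curve)

    def test_singleton_consistent_with_direct_calls(self, malignant_model, window):
        (pt,) = rate_curve(0.057, malignant_model, window, [81])
        assert pt.fpr == stable_fpr(81, 0.057, window)
        assert pt.tpr == tpr_blurred(malignant_model, 0.057, 81, window)

    def test_fpr_strictly_decreasing_on_grid(self, malignant_model, window):
        grid = list(range(30, 181, 10))
        curve = rate_curve(0.057, malignant_model, window, grid)
        assert len(curve) == 16
        fprs = [p.fpr for p in curve]
        assert all(a > b for a, b in zip(fprs, fprs[1:]))
        assert all(0 <= p.fpr <= 1 and 0 <= p.tpr <= 1 for p in curve)
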