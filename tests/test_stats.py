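import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rupturekit import (
    dip_statistic,
    dip_test,
    fit_two_component_mixture,
    linear_fit_r2,
    sample_halftimes,
    tipping_point,
)
from rupturekit.stats import MixtureFit, bootstrap_mixture_ci

from dip_lp_oracle import dip_lp


def make_fit(means, sds, weights):
    return MixtureFit(
        means=np.asarray(means, float),
        sds=np.asarray(sds, float),
        weights=np.asarray(weights, float),
        log_likelihood=0.0,
        converged=True,
        n_iter=1,
        n=100,
    )


class TestDipStatistic:
    def test_two_point_masses_exact(self):
        # {0,0,1,1}: any unimodal CDF must pass within 1/4 of both jumps
        assert dip_statistic([0.0, 0.0, 1.0, 1.0]) == pytest.approx(0.25)

    def test_matches_exact_lp_oracle_on_random_samples(self):
        rng = np.random.default_rng(0)
        for i in range(30):
            n = int(rng.integers(4, 15))
            if i % 3 == 0:
                s = rng.normal(size=n)
            elif i % 3 == 1:
                s = np.concatenate(
                    [rng.normal(0, 0.5, n // 2), rng.normal(5, 0.5, n - n // 2)]
                )
            else:
                s = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            assert dip_statistic(s) == pytest.approx(dip_lp(s), abs=1e-8), s

    def test_lower_bound_half_over_n(self):
        rng = np.random.default_rng(1)
        for n in (4, 9, 40):
            s = rng.normal(size=n)
            assert dip_statistic(s) >= 1.0 / (2 * n) - 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=40),
        st.floats(0.1, 3.0),
        st.floats(-10, 10),
    )
    def test_invariant_under_monotone_affine_transform(self, xs, a, b):
        from hypothesis import assume

        xs = np.asarray(xs)
        ys = a * xs + b
        # float rounding may merge nearly-equal points; only the exact
        # affine image (same tie pattern) is a valid comparison
        assume(len(np.unique(ys)) == len(np.unique(xs)))
        assert dip_statistic(xs) == pytest.approx(dip_statistic(ys), abs=1e-9)

    def test_reflection_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0.1, 4.0, 60)
        assert dip_statistic(s) == pytest.approx(dip_statistic(-s), abs=1e-12)


class TestDipTest:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            dip_test([1.0, 2.0, 3.0])

    def test_calibration_unimodal_rarely_rejects(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            dip_test(rng.normal(50, 10, 200), n_boot=200, seed=i).pvalue < 0.05
            for i in range(40)
        )
        assert rejections <= 4  # ~ nominal 5% level

    def test_power_on_separated_mixture(self):
        rejections = sum(
            dip_test(
                sample_halftimes((10, 70), (5, 5), (0.5, 0.5), 200, seed=100 + i),
                n_boot=200,
                seed=i,
            ).pvalue
            < 0.05
            for i in range(40)
        )
        assert rejections >= 36  # >= 90% power


class TestMixtureFit:
    def test_parameter_recovery_within_15_percent(self):
        x = sample_halftimes((10, 70), (5, 5), (0.5, 0.5), 400, seed=3)
        fit = fit_two_component_mixture(x, seed=0)
        assert fit.converged
        assert fit.means[0] == pytest.approx(10, rel=0.15)
        assert fit.means[1] == pytest.approx(70, rel=0.15)

    def test_identical_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_two_component_mixture(np.full(50, 3.0))

    def test_components_sorted_and_start_order_irrelevant(self):
        x = sample_halftimes((10, 70), (5, 5), (0.5, 0.5), 200, seed=9)
        fits = [fit_two_component_mixture(x, seed=s) for s in (0, 1, 2)]
        for fit in fits:
            assert fit.means[0] < fit.means[1]
        assert np.allclose(fits[0].means, fits[1].means, rtol=1e-4)
        assert np.allclose(fits[1].means, fits[2].means, rtol=1e-4)

    def test_loglik_monotone_every_iteration(self):
        x = sample_halftimes((13, 67), (6, 43), (0.5, 0.5), 300, seed=2)
        fit = fit_two_component_mixture(x, seed=0)
        assert np.all(np.diff(fit.loglik_history) >= -1e-8)

    def test_agrees_with_sklearn_reference(self):
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        x = sample_halftimes((10, 70), (5, 8), (0.4, 0.6), 500, seed=8)
        fit = fit_two_component_mixture(x, seed=0)
        gm = sklearn_mixture.GaussianMixture(
            2, n_init=5, random_state=0, tol=1e-8
        ).fit(x[:, None])
        ref_means = np.sort(gm.means_.ravel())
        assert np.allclose(fit.means, ref_means, rtol=0.02)

    def test_bootstrap_ci_covers_point_estimate(self):
        x = sample_halftimes((10, 70), (5, 5), (0.5, 0.5), 150, seed=5)
        fit = fit_two_component_mixture(x, seed=0)
        ci = bootstrap_mixture_ci(x, n_boot=30, seed=0, n_starts=3)
        lo, hi = ci["means"]["lower"], ci["means"]["upper"]
        assert lo[0] <= fit.means[0] <= hi[0]
        assert lo[1] <= fit.means[1] <= hi[1]


class TestTippingPoint:
    def test_symmetric_components_give_midpoint(self):
        fit = make_fit([10, 30], [4, 4], [0.5, 0.5])
        assert tipping_point(fit) == pytest.approx(20.0)

    def test_matches_dense_grid_oracle(self):
        from scipy.stats import norm

        fit = make_fit([13, 67], [6, 43], [0.5, 0.5])
        tp = tipping_point(fit)
        grid = np.linspace(13, 67, 540001)
        diff = np.abs(
            0.5 * norm.pdf(grid, 13, 6) - 0.5 * norm.pdf(grid, 67, 43)
        )
        assert tp == pytest.approx(grid[np.argmin(diff)], abs=0.1)

    def test_monotone_in_fast_weight(self):
        tps = [
            tipping_point(make_fit([10, 70], [5, 10], [w, 1 - w]))
            for w in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a < b for a, b in zip(tps, tps[1:]))

    def test_coincident_means_rejected(self):
        with pytest.raises(ValueError):
            tipping_point(make_fit([20, 20], [4, 8], [0.5, 0.5]))


class TestLinearFit:
    def test_collinear_points_r2_one(self):
        x = np.arange(10, dtype=float)
        fit = linear_fit_r2(x, 3 * x - 2)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3.0)

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 1000)
        y = rng.normal(5, 1, 1000)
        assert linear_fit_r2(x, y).r2 < 0.01

    def test_known_slope_within_confidence_band(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 300)
        y = 2 * x + rng.normal(0, 6.3, 300)  # SNR chosen for R^2 ~ 0.5
        fit = linear_fit_r2(x, y)
        assert 0.3 < fit.r2 < 0.7
        se = fit.residual_sd / np.sqrt(fit.x_ss)
        assert abs(fit.slope - 2.0) < 3 * se
        lo, hi = fit.confidence_band(np.array([5.0]))
        assert lo[0] < fit.predict(5.0) < hi[0]

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_fit_r2(np.full(10, 2.0), np.arange(10.0))
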