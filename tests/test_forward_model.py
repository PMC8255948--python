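import numpy as np
import pytest

from petdect import (ImageGrid, ScannerGeometry, attenuation_factors,
                     build_system, expected_counts, log_likelihood,
                     make_phantom, poisson_loglik, simulate_scan)


class TestAttenuationFactors:
    def test_zero_attenuation_gives_unity(self, small_system):
        n = attenuation_factors(np.zeros(small_system.shape[1]), small_system)
        np.testing.assert_array_equal(n, np.ones_like(n))

    def test_single_pixel_hand_trace(self):
        grid = ImageGrid(8, 8, 0.5)
        geom = ScannerGeometry(n_angles=1, n_radial=8, radial_spacing=0.5,
                               n_tof=1, tof_fwhm=5.0, tof_bin_width=10.0)
        sys = build_system(grid, geom)
        mu = np.zeros(grid.shape)
        mu[3, 4] = 0.7  # one attenuating pixel; horizontal ray row 3
        n = attenuation_factors(mu, sys)
        assert n[3, 0] == pytest.approx(np.exp(-0.7 * 0.5), rel=1e-12)
        assert n[5, 0] == pytest.approx(1.0)

    def test_doubling_mu_squares_factors(self, small_system):
        rng = np.random.default_rng(0)
        mu = rng.random(small_system.shape[1]) * 0.1
        n1 = attenuation_factors(mu, small_system)
        n2 = attenuation_factors(2 * mu, small_system)
        np.testing.assert_allclose(n2, n1 ** 2, rtol=1e-12)

    def test_monotone_in_mu(self, small_system):
        rng = np.random.default_rng(1)
        mu = rng.random(small_system.shape[1]) * 0.1
        bumped = mu.copy()
        bumped[40] += 0.05
        assert np.all(attenuation_factors(bumped, small_system)
                      <= attenuation_factors(mu, small_system) + 1e-15)

    def test_negative_mu_rejected(self, small_system):
        with pytest.raises(ValueError):
            attenuation_factors(np.full(small_system.shape[1], -1.0),
                                small_system)


class TestExpectedCounts:
    def test_zero_activity_gives_background(self, small_system):
        shape = (small_system.shape[0], small_system.geometry.n_tof)
        r = np.full(shape, 0.5)
        ybar = expected_counts(np.zeros(small_system.shape[1]),
                               np.zeros(small_system.shape[1]), r, small_system)
        np.testing.assert_array_equal(ybar, r)

    def test_linearity_in_activity(self, small_system):
        rng = np.random.default_rng(2)
        lam = rng.random(small_system.shape[1])
        mu = rng.random(small_system.shape[1]) * 0.05
        r = np.full((small_system.shape[0], small_system.geometry.n_tof), 0.2)
        y1 = expected_counts(lam, mu, r, small_system) - r
        y2 = expected_counts(2 * lam, mu, r, small_system) - r
        np.testing.assert_allclose(y2, 2 * y1, rtol=1e-12, atol=1e-14)


class TestLogLikelihood:
    def test_saturated_model_is_maximal(self, random_instance, small_system):
        lam, mu, r, y = random_instance
        from petdect import expected_counts as ec
        ybar = ec(lam, mu, r, small_system)
        saturated = poisson_loglik(y, np.maximum(y, 1e-12))
        assert poisson_loglik(y, ybar) <= saturated

    def test_zero_counts_reduce_to_minus_expectation(self, small_system):
        shape = (small_system.shape[0], small_system.geometry.n_tof)
        ybar = np.full(shape, 0.7)
        assert poisson_loglik(np.zeros(shape), ybar) == pytest.approx(
            -ybar.sum(), rel=1e-12)

    def test_three_bin_hand_sum(self):
        y = np.array([[2.0, 0.0, 5.0]])
        ybar = np.array([[1.5, 0.4, 6.0]])
        expected = sum(yi * np.log(ybi) - ybi
                       for yi, ybi in zip(y[0], ybar[0]))
        assert poisson_loglik(y, ybar) == pytest.approx(expected, rel=1e-14)

    def test_impossible_datum_rejected(self):
        with pytest.raises(ValueError):
            poisson_loglik(np.array([[1.0]]), np.array([[0.0]]))

    def test_invariant_to_empty_bins(self):
        y = np.array([[2.0, 3.0]])
        ybar = np.array([[1.8, 3.3]])
        base = poisson_loglik(y, ybar)
        padded = poisson_loglik(np.hstack([y, [[0.0]]]),
                                np.hstack([ybar, [[0.0]]]))
        assert padded == base

    def test_wrapper_checks_counts(self, random_instance, small_system):
        lam, mu, r, y = random_instance
        assert np.isfinite(log_likelihood(y, lam, mu, r, small_system))
        with pytest.raises(ValueError):
            log_likelihood(y - 10.0, lam, mu, r, small_system)


class TestSimulateScan:
    def test_background_fraction_of_prompts(self, phantom64, sys64):
        y, r, scale, _ = simulate_scan(phantom64, total_events=2e5,
                                       background_fraction=0.4, seed=0,
                                       sys=sys64)
        n = attenuation_factors(phantom64.mu511, sys64)
        ybar = scale * n * sys64.tof_project(phantom64.activity) + r
        assert r.sum() / ybar.sum() == pytest.approx(0.4, rel=1e-9)
        assert ybar.sum() == pytest.approx(2e5, rel=1e-9)

    def test_seeded_reproducibility(self, phantom64, sys64):
        y1, *_ = simulate_scan(phantom64, 1e5, 0.4, seed=5, sys=sys64)
        y2, *_ = simulate_scan(phantom64, 1e5, 0.4, seed=5, sys=sys64)
        np.testing.assert_array_equal(y1, y2)
        y3, *_ = simulate_scan(phantom64, 1e5, 0.4, seed=6, sys=sys64)
        assert not np.array_equal(y1, y3)

    def test_counts_match_poisson_mean(self):
        grid = ImageGrid(48, 48, 63.0 / 48.0)
        from petdect import test_scale_geometry
        phantom = make_phantom(grid, seed=0)
        geom = test_scale_geometry(grid, n_tof=3)
        sys = build_system(grid, geom)
        samples = []
        n = attenuation_factors(phantom.mu511, sys)
        for seed in range(200):
            y, r, scale, _ = simulate_scan(phantom, 5e4, 0.4, seed=seed,
                                           sys=sys)
            samples.append(y)
        ybar = scale * n * sys.tof_project(phantom.activity) + r
        stack = np.stack(samples)
        idx = np.unravel_index(np.argmax(ybar), ybar.shape)
        mean = stack[(slice(None),) + idx].mean()
        se = np.sqrt(ybar[idx] / 200)
        assert abs(mean - ybar[idx]) <= 5 * se

    def test_parameter_validation(self, phantom64, sys64):
        with pytest.raises(ValueError):
            simulate_scan(phantom64, -1.0, 0.4, seed=0, sys=sys64)
        with pytest.raises(ValueError):
            simulate_scan(phantom64, 1e5, 1.5, seed=0, sys=sys64)
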