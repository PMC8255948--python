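import numpy as np
import pytest
from scipy.sparse import random as sparse_random

from petdect import (MLAA, KernelMLAA, SparseKernelMatrix, attenuation_factors,
                     expected_counts, kernel_sps_alpha_update, log_likelihood,
                     mlaa_reconstruct, mlem_lambda_update, sps_mu_update)


def _random_row_stochastic(n, seed=0):
    rng = np.random.default_rng(seed)
    K = sparse_random(n, n, density=0.05, random_state=rng,
                      data_rvs=rng.random).tocsr()
    K = K + 0.1 * np.abs(sparse_random(n, n, density=0.0, random_state=rng).tocsr())
    K.setdiag(K.diagonal() + 0.5)  # keep rows nonempty
    inv = 1.0 / np.asarray(K.sum(axis=1)).ravel()
    from scipy.sparse import diags
    return (diags(inv) @ K).tocsr()


class TestFixedPoints:
    def test_mlem_fixed_point_at_saturation(self, random_instance, small_system):
        lam, mu, r, _ = random_instance
        ybar = expected_counts(lam, mu, r, small_system)
        n = attenuation_factors(mu, small_system)
        out = mlem_lambda_update(lam, ybar, r, n, small_system)
        np.testing.assert_allclose(out, lam, rtol=1e-10)

    def test_mlem_zero_pixels_stay_zero(self, random_instance, small_system):
        lam, mu, r, y = random_instance
        lam = lam.copy()
        lam[::7] = 0.0
        n = attenuation_factors(mu, small_system)
        out = mlem_lambda_update(lam, y, r, n, small_system)
        assert np.all(out[::7] == 0.0)
        assert np.all(out >= 0.0)

    def test_sps_fixed_point_at_saturation(self, random_instance, small_system):
        lam, mu, r, _ = random_instance
        ybar = expected_counts(lam, mu, r, small_system)
        out = sps_mu_update(mu, ybar, r, lam, small_system)
        np.testing.assert_allclose(out, mu, rtol=1e-10, atol=1e-14)

    def test_sps_reduces_mu_when_counts_exceed_model(self, random_instance,
                                                     small_system):
        lam, mu, r, _ = random_instance
        ybar = expected_counts(lam, mu, r, small_system)
        out = sps_mu_update(mu, ybar * 1.5, r, lam, small_system)
        # uniformly more counts than modelled means less attenuation overall
        assert out.sum() < mu.sum()

    def test_kernel_update_fixed_point(self, random_instance, small_system):
        lam, mu, r, _ = random_instance
        K = _random_row_stochastic(mu.size, seed=3)
        alpha = np.abs(np.random.default_rng(4).random(mu.size))
        ybar = expected_counts(K @ alpha, lam * 0 + lam, r, small_system)
        ybar = expected_counts(lam, K @ alpha, r, small_system)
        out = kernel_sps_alpha_update(alpha, ybar, r, lam, K, small_system)
        np.testing.assert_allclose(out, alpha, rtol=1e-10, atol=1e-14)


class TestMonotonicity:
    def test_mlem_step_increases_likelihood(self, random_instance, small_system):
        lam, mu, r, y = random_instance
        n = attenuation_factors(mu, small_system)
        before = log_likelihood(y, lam, mu, r, small_system)
        lam2 = mlem_lambda_update(lam, y, r, n, small_system)
        after = log_likelihood(y, lam2, mu, r, small_system)
        assert after >= before

    def test_sps_step_does_not_decrease_likelihood(self, random_instance,
                                                   small_system):
        lam, mu, r, y = random_instance
        before = log_likelihood(y, lam, mu, r, small_system)
        mu2 = sps_mu_update(mu, y, r, lam, small_system)
        after = log_likelihood(y, lam, mu2, r, small_system)
        assert after >= before
        assert np.all(mu2 >= 0.0)

    def test_kernel_step_does_not_decrease_likelihood(self, random_instance,
                                                      small_system):
        lam, mu, r, y = random_instance
        K = _random_row_stochastic(mu.size, seed=5)
        alpha = np.abs(np.random.default_rng(6).random(mu.size)) * 0.05
        before = log_likelihood(y, lam, K @ alpha, r, small_system)
        alpha2 = kernel_sps_alpha_update(alpha, y, r, lam, K, small_system)
        after = log_likelihood(y, lam, K @ alpha2, r, small_system)
        assert after >= before
        assert np.all(alpha2 >= 0.0)

    def test_full_trace_non_decreasing(self, random_instance, small_system):
        lam, mu, r, y = random_instance
        est = MLAA(sys=small_system, n_outer=30).fit(y, r=r, init_mu=mu * 0.5)
        trace = np.array(est.loglik_trace_)
        assert np.all(np.diff(trace) >= -1e-9 * np.abs(trace[:-1]))


class TestReconstruction:
    def test_zero_outer_returns_initial_state(self, random_instance,
                                              small_system):
        lam, mu, r, y = random_instance
        state = mlaa_reconstruct(y, r, small_system, init_mu=mu, n_outer=0)
        np.testing.assert_array_equal(state.mu, mu)
        assert state.loglik_trace == []

    def test_truth_is_joint_stationary_point(self, random_instance,
                                             small_system):
        lam, mu, r, _ = random_instance
        ybar = expected_counts(lam, mu, r, small_system)
        est = MLAA(sys=small_system, n_outer=3).fit(ybar, r=r, init_mu=mu,
                                                    init_lam=lam)
        np.testing.assert_allclose(est.lam_, lam, rtol=1e-8)
        np.testing.assert_allclose(est.mu_, mu, rtol=1e-8, atol=1e-12)

    def test_identity_kernel_matches_standard_mlaa(self, random_instance,
                                                   small_system):
        lam, mu, r, y = random_instance
        K = SparseKernelMatrix.identity(mu.size)
        std = MLAA(sys=small_system, n_outer=5).fit(y, r=r, init_mu=mu)
        ker = KernelMLAA(sys=small_system, kernel=K, n_outer=5).fit(
            y, r=r, init_mu=mu)
        np.testing.assert_array_equal(std.mu_, ker.mu_)
        np.testing.assert_array_equal(std.lam_, ker.lam_)
        assert std.loglik_trace_ == ker.loglik_trace_

    def test_kernel_contract_mu_equals_K_alpha(self, random_instance,
                                               small_system):
        lam, mu, r, y = random_instance
        K = _random_row_stochastic(mu.size, seed=9)
        est = KernelMLAA(sys=small_system, kernel=K, n_outer=5).fit(
            y, r=r, init_mu=mu)
        np.testing.assert_allclose(est.mu_, K @ est.alpha_, atol=1e-12)
        assert np.all(est.alpha_ >= 0.0)

    def test_snapshots_recorded_at_requested_iterations(self, random_instance,
                                                        small_system):
        lam, mu, r, y = random_instance
        est = MLAA(sys=small_system, n_outer=6).fit(
            y, r=r, init_mu=mu, snapshot_iters=(0, 3, 6))
        assert set(est.snapshots_) == {0, 3, 6}
        np.testing.assert_array_equal(est.snapshots_[0], mu)
        np.testing.assert_array_equal(est.snapshots_[6], est.mu_)
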