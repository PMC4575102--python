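"""Spike-and-slab shrinkage: closed forms, MMLE, posterior, sampler."""

import numpy as np
import pytest
from scipy.stats import norm

from lswspec.shrinkage import (
    denoise_row,
    fit_hyperparameters,
    marginal_loglik,
    posterior_moments,
    q_moments,
    sample_posterior,
)
from lswspec.wavelets import build_filter, dwt

from oracles import loglik_quad, posterior_moments_quad, q_moment_quad


class TestQMoments:
    def test_q1_zero_at_origin(self):
        for nu, tau in [(0.5, 1.0), (1.0, 3.0), (2.0, 0.2)]:
            _, q1, _ = q_moments(0.0, nu, tau)
            assert abs(q1) < 1e-15

    @pytest.mark.parametrize(
        "h,nu,tau",
        [(1.0, 1.0, 1.0), (3.0, 0.5, 2.0), (-2.5, 0.2, 10.0), (0.3, 2.0, 0.1)],
    )
    def test_matches_quadrature(self, h, nu, tau):
        q = q_moments(h, nu, tau)
        for i in range(3):
            ref = q_moment_quad(h, nu, tau, i)
            assert abs(q[i] - ref) <= 1e-8 * abs(ref)

    def test_cauchy_schwarz_and_positivity(self, rng):
        for _ in range(50):
            h = rng.uniform(-5, 5)
            nu = 10 ** rng.uniform(-2, 1)
            tau = 10 ** rng.uniform(-2, 1)
            q0, q1, q2 = q_moments(h, nu, tau)
            assert q0 > 0
            assert q2 >= q1**2 / q0 - 1e-12 * q2

    def test_large_tau_collapses_slab_to_spike(self):
        # tau -> inf: slab tends to delta_0, so Q0 -> phi_nu(h)
        q0, _, _ = q_moments(1.0, 1.0, 1e3)
        assert abs(q0 - norm.pdf(1.0)) / norm.pdf(1.0) < 0.01

    def test_finite_deep_in_tails(self):
        q = q_moments(np.array([-50.0, 50.0]), 1.0, 1.0)
        assert np.all(np.isfinite(q))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            q_moments(1.0, -1.0, 1.0)


class TestMarginalLoglik:
    def test_empty_is_zero(self):
        assert marginal_loglik(0.5, 1.0, 1.0, []) == 0.0

    def test_matches_quadrature_on_random_points(self, rng):
        h = rng.normal(0, 2, 20)
        ll = marginal_loglik(0.5, 1.0, 1.0, h)
        assert abs(ll - loglik_quad(0.5, 1.0, 1.0, h)) < 1e-6 * abs(ll)

    def test_single_point_at_zero(self):
        ll = marginal_loglik(0.5, 1.0, 1.0, [0.0])
        q0 = q_moment_quad(0.0, 1.0, 1.0, 0)
        assert abs(ll - np.log(0.5 * norm.pdf(0.0) + 0.5 * q0)) < 1e-8

    def test_boundary_alpha_limits(self, rng):
        h = rng.normal(0, 1, 10)
        assert np.isfinite(marginal_loglik(0.0, 1.0, 1.0, h))
        assert abs(
            marginal_loglik(1.0, 1.0, 1.0, h) - np.sum(norm.logpdf(h))
        ) < 1e-9


class TestPosteriorMoments:
    def test_zero_observation_has_zero_mean(self):
        m, v, w0 = posterior_moments(0.0, 0.5, 1.0, 1.0)
        assert m == pytest.approx(0.0, abs=1e-15)
        assert v >= 0
        assert 0 < w0 < 1

    def test_spike_dominates_as_alpha_to_one(self):
        m, v, w0 = posterior_moments(3.0, 1.0 - 1e-12, 1.0, 1.0)
        assert abs(m) < 1e-6
        assert w0 > 1 - 1e-6

    @pytest.mark.parametrize("h", [0.5, 3.0, -7.0])
    def test_matches_quadrature(self, h):
        m, v, w0 = posterior_moments(h, 0.5, 1.0, 1.0)
        mo, vo, wo = posterior_moments_quad(h, 0.5, 1.0, 1.0)
        assert abs(m - mo) < 1e-7 * max(1, abs(mo))
        assert abs(v - vo) < 1e-7 * max(1, abs(vo))
        assert abs(w0 - wo) < 1e-7

    def test_shrinkage_bound_and_monotonicity(self):
        alpha, tau, nu = 0.7, 1.5, 0.8
        hs = np.linspace(0, 30, 301)
        means = posterior_moments(hs, alpha, tau, nu)[0]
        assert np.all(np.abs(means) <= np.abs(hs) + nu**2 * tau + 1e-9)
        assert np.all(np.diff(means) >= -1e-9)  # |mean| nondecreasing in |h|
        assert np.all(means[1:] >= 0)  # sign preserving

    def test_variance_nonnegative_everywhere(self, rng):
        hs = rng.uniform(-40, 40, 200)
        _, v, _ = posterior_moments(hs, 0.9, 2.0, 0.5)
        assert np.all(v >= 0)


class TestSampler:
    def test_alpha_one_gives_all_zeros(self, rng):
        d = sample_posterior(2.0, 1.0, 1.0, 1.0, 100, rng)
        assert np.all(d == 0)

    def test_spike_mass_matches_w0(self, rng):
        h, alpha, tau, nu = 1.0, 0.6, 1.0, 1.0
        _, _, w0 = posterior_moments(h, alpha, tau, nu)
        d = sample_posterior(h, alpha, tau, nu, 40000, rng)
        se = np.sqrt(w0 * (1 - w0) / d.size)
        assert abs((d == 0).mean() - w0) < 4 * se

    def test_moments_match_closed_forms(self, rng):
        h, alpha, tau, nu = 2.0, 0.5, 1.0, 1.0
        m, v, _ = posterior_moments(h, alpha, tau, nu)
        d = sample_posterior(h, alpha, tau, nu, 100000, rng).ravel()
        se_m = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - m) < 4 * se_m
        m4 = np.mean((d - d.mean()) ** 4)
        se_v = np.sqrt(max(m4 - d.var() ** 2, 0) / d.size)
        assert abs(d.var(ddof=1) - v) < 4 * se_v

    def test_reproducible_under_seed(self):
        a = sample_posterior(1.0, 0.5, 1.0, 1.0, 50, 7)
        b = sample_posterior(1.0, 0.5, 1.0, 1.0, 50, 7)
        assert np.array_equal(a, b)


def _simulate_prior_sample(seed, n, alpha, tau, nu):
    r = np.random.default_rng(seed)
    beta = np.where(r.random(n) < alpha, 0.0, r.laplace(0, 1 / tau, n))
    return beta + r.normal(0, nu, n)


class TestFitHyperparameters:
    def test_recovery_in_identifiable_regime(self):
        # slab sd well above the noise sd: all three parameters recover
        fits = np.array(
            [
                fit_one_scale(_simulate_prior_sample(s, 4096, 0.8, 0.5, 1.0))
                for s in range(10)
            ]
        )
        med = np.median(fits, axis=0)
        assert abs(med[0] - 0.8) < 0.1
        assert abs(med[1] / 0.5 - 1) < 0.3
        assert abs(med[2] / 1.0 - 1) < 0.1

    def test_pure_noise_drives_alpha_high(self):
        alphas = [
            fit_one_scale(np.random.default_rng(s).normal(0, 1, 2048))[0]
            for s in range(9)
        ]
        assert np.median(alphas) > 0.9

    def test_all_zero_row_flagged_not_crashing(self):
        details = [np.zeros(2**l) for l in range(6)]
        p = fit_hyperparameters(details)
        assert p.degenerate.all()
        assert p.n_scales == 6

    def test_coarse_grouping_ladder(self, rng):
        details = [rng.normal(0, 1, 2**l) for l in range(8)]
        p = fit_hyperparameters(details)
        # coarsest four scales share one fit, laddered by factors of two
        assert p.alpha[2] == pytest.approx(p.alpha[3] / 2)
        assert p.alpha[0] == pytest.approx(p.alpha[3] / 8)
        assert p.tau[2] == pytest.approx(p.tau[3] * 2)
        assert p.nu[0] == p.nu[3]

    def test_tied_nu_mode_scaling(self, rng):
        details = [rng.normal(0, 1, 2**l) for l in range(6)]
        p = fit_hyperparameters(details, tied_nu=True)
        assert p.nu[4] == pytest.approx(p.nu[5] * np.sqrt(2))


def fit_one_scale(h):
    from lswspec.shrinkage import _fit_one

    a, t, n, _ = _fit_one(h)
    return np.array([a, t, n])


class TestDenoiseRow:
    def test_constant_row_passes_through(self, la6, rng):
        row = np.full(64, 4.2)
        mean, draws, _ = denoise_row(row, la6, n_samples=5, rng=rng)
        assert np.allclose(mean, 4.2, atol=1e-8)
        assert np.allclose(draws, 4.2, atol=1e-8)

    def test_denoising_beats_noisy_input(self, la6):
        T = 512
        z = np.arange(T) / T
        signal = np.where(z < 0.3, 1.0, np.where(z < 0.7, 3.0, 0.5))
        ratios = []
        for s in range(8):
            r = np.random.default_rng(s)
            noisy = signal + r.normal(0, 0.5, T)
            mean, _, _ = denoise_row(noisy, la6)
            ratios.append(np.mean((mean - signal) ** 2) / np.mean((noisy - signal) ** 2))
        assert np.median(ratios) < 1.0

    def test_pointwise_interval_coverage(self, la6):
        # approximate empirical-Bayes intervals: 90% pointwise bands should
        # cover a piecewise-constant signal at >= 75% of locations
        T = 1024
        z = np.arange(T) / T
        signal = np.where(z < 0.3, 1.0, np.where(z < 0.7, 3.0, 0.5))
        cover = []
        for s in range(10):
            r = np.random.default_rng(100 + s)
            noisy = signal + r.normal(0, 0.5, T)
            _, draws, _ = denoise_row(noisy, la6, n_samples=300, rng=r)
            lo = np.quantile(draws, 0.05, axis=0)
            hi = np.quantile(draws, 0.95, axis=0)
            cover.append(np.mean((lo <= signal) & (signal <= hi)))
        assert np.median(cover) >= 0.75
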