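"""Schedules, forward process, exact posterior and ancestral sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piddpm.diffusion import (
    ancestral_sample,
    conditioned_loss,
    make_schedule,
    mu_from_eps,
    posterior_params,
    q_sample,
)


@pytest.fixture(scope="module")
def schedule():
    return make_schedule(50, beta_range=(1e-3, 0.2))


def brute_force_posterior(schedule, y0, yt, t, half_width=8.0, n=200_001):
    """Numerically integrate q(y_{t-1} | y_0) q(y_t | y_{t-1}) on a 1-D grid."""
    g_prev = schedule.gamma_at(t - 1)
    a_t = schedule.alpha_at(t)
    b_t = schedule.beta_at(t)
    grid = np.linspace(-half_width, half_width, n)
    prior = np.exp(-(grid - np.sqrt(g_prev) * y0) ** 2 / (2 * (1 - g_prev))) \
        if g_prev < 1 else None
    lik = np.exp(-(yt - np.sqrt(a_t) * grid) ** 2 / (2 * b_t))
    post = lik if prior is None else prior * lik
    post = post / np.trapezoid(post, grid)
    mean = np.trapezoid(grid * post, grid)
    var = np.trapezoid((grid - mean) ** 2 * post, grid)
    return mean, var


class TestSchedule:
    def test_invariants(self, schedule):
        s = schedule
        assert np.all((s.beta > 0) & (s.beta < 1))
        assert np.all(np.diff(s.gamma) < 0)
        np.testing.assert_allclose(s.gamma[1:], s.alpha[1:] * s.gamma[:-1],
                                   rtol=1e-15)
        gamma_prev = np.concatenate([[1.0], s.gamma[:-1]])
        np.testing.assert_allclose(
            s.beta_tilde, (1 - gamma_prev) / (1 - s.gamma) * s.beta)

    def test_single_step(self):
        s = make_schedule(1, beta_range=(0.5, 0.5))
        assert s.gamma_at(1) == pytest.approx(0.5)

    def test_long_linear_schedule_destroys_signal(self):
        s = make_schedule(1000, beta_range=(1e-4, 0.02))
        assert s.gamma[-1] < 1e-4

    def test_zero_beta_warns(self):
        with pytest.warns(UserWarning):
            s = make_schedule(10, beta_range=(0.0, 0.0))
        assert np.all(s.gamma == 1.0)

    def test_cosine_schedule_valid(self):
        s = make_schedule(100, kind="cosine")
        assert np.all((s.beta >= 0) & (s.beta < 1))
        assert s.gamma[-1] < 0.05

    def test_sigma_choices(self):
        up = make_schedule(20, beta_range=(1e-3, 0.3), sigma="beta")
        lo = make_schedule(20, beta_range=(1e-3, 0.3), sigma="beta_tilde")
        np.testing.assert_array_equal(up.sigma2, up.beta)
        np.testing.assert_array_equal(lo.sigma2, lo.beta_tilde)
        assert np.all(lo.sigma2 <= up.sigma2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_schedule(0)
        with pytest.raises(ValueError):
            make_schedule(10, beta_range=(0.5, 0.1))
        with pytest.raises(ValueError):
            make_schedule(10, beta_range=(1e-4, 1.5))


class TestForwardProcess:
    def test_extreme_gamma_limits(self, rng):
        y0 = rng.standard_normal((8, 8))
        eps = rng.standard_normal((8, 8))
        with pytest.warns(UserWarning):
            s = make_schedule(10, beta_range=(0.0, 0.0))  # gamma = 1 everywhere
        np.testing.assert_array_equal(q_sample(s, y0, 5, eps), y0)

    def test_q_sample_moments(self, schedule, rng):
        y0 = rng.standard_normal((4, 4))
        n = 10_000
        for t in (1, 10, 25, 40, 50):
            g = schedule.gamma_at(t)
            draws = np.stack([
                q_sample(schedule, y0, t, rng.standard_normal((4, 4)))
                for _ in range(n)
            ])
            se_mean = np.sqrt(1 - g) / np.sqrt(n)
            assert np.all(np.abs(draws.mean(0) - np.sqrt(g) * y0)
                          < 3 * se_mean + 1e-12)
            sd = draws.std(0, ddof=1)
            se_sd = np.sqrt(1 - g) / np.sqrt(2 * (n - 1)) if g < 1 else 0.0
            assert np.all(np.abs(sd - np.sqrt(1 - g)) < 3 * se_sd + 1e-12)

    def test_stepwise_chain_matches_closed_form(self, rng):
        """Composing Markov steps reproduces the closed-form moments."""
        s = make_schedule(5, beta_range=(0.05, 0.3))
        y0 = rng.standard_normal((2, 2))
        n = 10_000
        ys = np.broadcast_to(y0, (n, 2, 2)).copy()
        for t in range(1, 6):
            b = s.beta_at(t)
            ys = np.sqrt(1 - b) * ys + np.sqrt(b) * rng.standard_normal(ys.shape)
        g = s.gamma_at(5)
        se_mean = np.sqrt(1 - g) / np.sqrt(n)
        assert np.all(np.abs(ys.mean(0) - np.sqrt(g) * y0) < 3 * se_mean)
        sd = ys.std(0, ddof=1)
        se_sd = np.sqrt(1 - g) / np.sqrt(2 * (n - 1))
        assert np.all(np.abs(sd - np.sqrt(1 - g)) < 3 * se_sd)

    def test_t_out_of_range(self, schedule):
        with pytest.raises(ValueError):
            q_sample(schedule, np.zeros((2, 2)), 51, np.zeros((2, 2)))


class TestPosterior:
    def test_t1_returns_data(self, schedule, rng):
        y0 = rng.standard_normal((3, 3))
        yt = rng.standard_normal((3, 3))
        mean, var = posterior_params(schedule, y0, yt, 1)
        np.testing.assert_allclose(mean, y0, atol=1e-12)
        assert var == 0.0

    def test_matches_brute_force_bayes(self, schedule, rng):
        for _ in range(20):
            t = int(rng.integers(2, schedule.T + 1))
            y0 = float(rng.uniform(-1, 1))
            yt = float(rng.uniform(-1.5, 1.5))
            mean_bf, var_bf = brute_force_posterior(schedule, y0, yt, t)
            mean, var = posterior_params(schedule, np.array(y0),
                                         np.array(yt), t)
            assert float(mean) == pytest.approx(mean_bf, abs=1e-6)
            assert var == pytest.approx(var_bf, abs=1e-6)

    def test_t0_rejected(self, schedule):
        with pytest.raises(ValueError):
            posterior_params(schedule, np.zeros(1), np.zeros(1), 0)

    @settings(max_examples=25, deadline=None)
    @given(t=st.integers(2, 50))
    def test_coefficients_algebraic_identity(self, t):
        s = make_schedule(50, beta_range=(1e-3, 0.2))
        g_t, g_p = s.gamma_at(t), s.gamma_at(t - 1)
        b, a = s.beta_at(t), s.alpha_at(t)
        coef_sum = (np.sqrt(g_p) * b + np.sqrt(a) * (1 - g_p)) / (1 - g_t)
        mean, _ = posterior_params(s, np.ones(1), np.ones(1), t)
        assert float(mean[0]) == pytest.approx(coef_sum, rel=1e-12)


class TestMuFromEps:
    def test_consistent_with_posterior(self, schedule, rng):
        y0 = rng.standard_normal((6, 6))
        for t in (2, 17, 50):
            eps = rng.standard_normal((6, 6))
            yt = q_sample(schedule, y0, t, eps)
            mu_direct, _ = posterior_params(schedule, y0, yt, t)
            mu_eps = mu_from_eps(schedule, yt, t, eps)
            np.testing.assert_allclose(mu_eps, mu_direct, atol=1e-6)

    def test_linearity_in_eps(self, schedule, rng):
        yt = rng.standard_normal((4, 4))
        e1 = rng.standard_normal((4, 4))
        e2 = rng.standard_normal((4, 4))
        t = 10
        m = lambda e: mu_from_eps(schedule, yt, t, e)
        np.testing.assert_allclose(m(e1) + m(e2) - m(e1 * 0),
                                   m(e1 + e2), atol=1e-10)


class TestConditionedLoss:
    def test_oracle_denoiser_zero_loss(self, schedule, rng):
        y0 = rng.standard_normal((8, 8))
        eps = rng.standard_normal((8, 8))
        oracle = lambda yt, x, g: eps
        assert conditioned_loss(schedule, oracle, None, y0, 7, eps) == 0.0

    def test_zero_denoiser_loss_is_eps_power(self, schedule, rng):
        y0 = rng.standard_normal((8, 8))
        eps = rng.standard_normal((8, 8))
        zero = lambda yt, x, g: np.zeros_like(yt)
        assert conditioned_loss(schedule, zero, None, y0, 7, eps) == \
            pytest.approx(np.mean(eps ** 2))


class TestAncestralSampling:
    def test_one_step_inversion(self, rng):
        s = make_schedule(1, beta_range=(0.3, 0.3))
        y0 = rng.standard_normal((8, 8))
        # the exact epsilon for whatever y_1 the sampler draws
        oracle = lambda yt, x, g: (yt - np.sqrt(g) * y0) / np.sqrt(1 - g)
        out = ancestral_sample(s, oracle, None, rng_seed=5, shape=(8, 8))
        np.testing.assert_allclose(out, y0, atol=1e-5)

    def test_exact_posterior_oracle_recovers_y0(self, rng):
        """1-pixel reconstruction error vanishes as T grows."""
        y0 = np.array([[0.37]])
        oracle = lambda yt, x, g: (yt - np.sqrt(g) * y0) / max(
            np.sqrt(1 - g), 1e-12)
        errs = []
        for T in (5, 20, 80):
            s = make_schedule(T, beta_range=(1e-3, 0.3))
            outs = [ancestral_sample(s, oracle, None, rng_seed=k,
                                     shape=(1, 1))[0, 0] for k in range(50)]
            errs.append(np.mean((np.array(outs) - 0.37) ** 2))
        assert errs[-1] == pytest.approx(0.0, abs=1e-6)

    def test_zero_denoiser_output_centred(self):
        s = make_schedule(30, beta_range=(1e-3, 0.2))
        zero = lambda yt, x, g: np.zeros_like(yt)
        means = [ancestral_sample(s, zero, None, rng_seed=k,
                                  shape=(6, 6)).mean() for k in range(200)]
        assert abs(np.mean(means)) < 3 * np.std(means) / np.sqrt(200)

    def test_deterministic_given_seed(self, schedule):
        zero = lambda yt, x, g: np.zeros_like(yt)
        a = ancestral_sample(schedule, zero, None, rng_seed=9, shape=(4, 4))
        b = ancestral_sample(schedule, zero, None, rng_seed=9, shape=(4, 4))
        np.testing.assert_array_equal(a, b)
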