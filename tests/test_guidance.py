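"""Physics-informed gradient, annealing, PI loss and guided sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piddpm.acquisition import AcquisitionModel, apply_A, to_diffusion_range
from piddpm.diffusion import ancestral_sample, conditioned_loss, make_schedule
from piddpm.guidance import (
    GuidanceConfig,
    anneal,
    data_fidelity_gradient,
    pi_sample,
    pi_training_loss,
    regulariser_gradient,
    restore,
)
from piddpm.optics import PSFVolume


@pytest.fixture(scope="module")
def schedule():
    return make_schedule(40, beta_range=(1e-3, 0.15))


class TestDataFidelityGradient:
    def test_residual_vanishes_at_solution(self, blur_model, rng):
        y = rng.random((16, 16))
        x_tilde = apply_A(blur_model, y)
        g = data_fidelity_gradient(blur_model, y, x_tilde, noiseless=True)
        assert np.abs(g).max() < 1e-10

    def test_matches_finite_differences(self, blur_model, rng):
        yt = rng.standard_normal((16, 16))
        x = rng.standard_normal((16, 16))
        xi = 0.3
        g = data_fidelity_gradient(blur_model, yt, x, xi=xi, noiseless=False)

        def objective(y):
            r = apply_A(blur_model, y) - (x - xi)
            return -0.5 * np.sum(r * r) / xi ** 2

        h = 1e-6
        for _ in range(10):
            i, j = rng.integers(0, 16, size=2)
            yp, ym = yt.copy(), yt.copy()
            yp[i, j] += h
            ym[i, j] -= h
            fd = (objective(yp) - objective(ym)) / (2 * h)
            assert abs(fd - g[i, j]) / max(abs(fd), 1e-12) < 1e-4

    def test_delta_kernel_elementwise(self, delta_model, rng):
        yt = rng.standard_normal((8, 8))
        x = rng.standard_normal((8, 8))
        xi = 0.5
        g = data_fidelity_gradient(delta_model, yt, x, xi=xi, noiseless=False)
        np.testing.assert_allclose(g, (x - xi - yt) / xi ** 2, atol=1e-12)

    def test_zero_xi_with_noisy_target_rejected(self, blur_model, rng):
        yt = rng.standard_normal((8, 8))
        with pytest.raises(ZeroDivisionError):
            data_fidelity_gradient(blur_model, yt, yt, xi=None,
                                   noiseless=False)

    def test_descent_direction_property(self, blur_model, rng):
        """g always has non-positive inner product with the residual gradient."""
        for _ in range(20):
            yt = rng.standard_normal((12, 12))
            x_tilde = rng.standard_normal((12, 12))
            g = data_fidelity_gradient(blur_model, yt, x_tilde, noiseless=True)
            # gradient of 1/2 ||A y - x~||^2
            up = -g
            assert np.sum(g * up) <= 1e-12


class TestAnneal:
    def test_norm_equals_eta_sqrt_gamma(self, schedule, rng):
        for t in (1, 10, 40):
            g = rng.standard_normal((16, 16))
            ann = anneal(g, t, schedule, eta=10.0)
            expected = 10.0 * np.sqrt(schedule.gamma_at(t))
            assert np.linalg.norm(ann.g) == pytest.approx(expected, abs=1e-10)

    def test_default_strength_at_full_signal(self, rng):
        """With gamma_t = 1 and the default eta = 10 the norm is exactly 10."""
        with pytest.warns(UserWarning):
            s = make_schedule(5, beta_range=(0.0, 0.0))
        g = rng.standard_normal((8, 8))
        ann = anneal(g, 3, s, eta=10.0)
        assert np.linalg.norm(ann.g) == pytest.approx(10.0, abs=1e-10)

    def test_scale_invariance(self, schedule, rng):
        g = rng.standard_normal((8, 8))
        a = anneal(g, 7, schedule, eta=5.0).g
        b = anneal(7.0 * g, 7, schedule, eta=5.0).g
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_gradient_handled(self, schedule):
        ann = anneal(np.zeros((4, 4)), 3, schedule, eta=10.0)
        assert ann.nu_t == 0.0 and np.all(ann.g == 0)

    def test_norm_monotone_decreasing_in_t(self, schedule, rng):
        g = rng.standard_normal((8, 8))
        norms = [np.linalg.norm(anneal(g, t, schedule, 10.0).g)
                 for t in range(1, schedule.T + 1)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))


class TestRegulariser:
    def test_zero_input_zero_gradient(self):
        y = np.zeros((4, 4))
        assert np.all(regulariser_gradient(y, "l1", 0.5) == 0)
        assert np.all(regulariser_gradient(y, "l2", 0.5) == 0)

    def test_l2_matches_finite_differences(self, rng):
        y = rng.standard_normal((8, 8))
        lam = 0.3
        g = regulariser_gradient(y, "l2", lam)
        h = 1e-6
        for _ in range(5):
            i, j = rng.integers(0, 8, size=2)
            yp, ym = y.copy(), y.copy()
            yp[i, j] += h
            ym[i, j] -= h
            fd = (lam * np.sum(yp ** 2) - lam * np.sum(ym ** 2)) / (2 * h)
            assert abs(fd - g[i, j]) < 1e-6

    def test_zero_lambda(self, rng):
        y = rng.standard_normal((4, 4))
        assert np.all(regulariser_gradient(y, "l1", 0.0) == 0)

    def test_unknown_kind(self, rng):
        with pytest.raises(ValueError):
            regulariser_gradient(rng.standard_normal((2, 2)), "tv", 1.0)


class TestBaselineEquivalence:
    """eta = 0 must collapse the PI objects onto the conditioned DDPM ones."""

    def test_loss_reduces_to_conditioned_loss(self, schedule, blur_model, rng):
        y0 = rng.uniform(-1, 1, (16, 16))
        x = rng.uniform(-1, 1, (16, 16))
        eps = rng.standard_normal((16, 16))
        net = lambda yt, xc, g: 0.3 * yt  # any deterministic stub
        cfg = GuidanceConfig(eta=0.0)
        for t in (1, 10, 40):
            pi = pi_training_loss(schedule, net, blur_model, x, y0, t, eps,
                                  cfg, x_tilde=apply_A(blur_model, y0))
            base = conditioned_loss(schedule, net, x, y0, t, eps)
            assert pi == base  # bitwise

    def test_sampler_trajectory_identical(self, schedule, blur_model, rng):
        x = rng.uniform(-1, 1, (16, 16))
        net = lambda yt, xc, g: 0.1 * yt
        cfg = GuidanceConfig(eta=0.0)
        guided = pi_sample(schedule, net, blur_model, x, cfg, rng_seed=3)
        plain = ancestral_sample(schedule, net, x, rng_seed=3)
        np.testing.assert_array_equal(guided, plain)

    def test_oracle_pi_loss_zero(self, schedule, blur_model, rng):
        """A denoiser returning eps + sigma^2 g nulls the PI objective."""
        y0 = rng.uniform(-1, 1, (16, 16))
        x_tilde = apply_A(blur_model, y0)
        eps = rng.standard_normal((16, 16))
        t = 12
        cfg = GuidanceConfig(eta=10.0)
        from piddpm.guidance import _guidance_raw

        def oracle(yt, xc, g):
            raw = _guidance_raw(blur_model, yt, x_tilde, cfg, schedule, t, True)
            ann = anneal(raw, t, schedule, cfg.eta)
            return eps + schedule.sigma2_at(t) * ann.g

        loss = pi_training_loss(schedule, oracle, blur_model, y0 * 0, y0, t,
                                eps, cfg, x_tilde=x_tilde)
        assert loss == pytest.approx(0.0, abs=1e-20)

    def test_pi_loss_reproducible(self, schedule, blur_model, rng):
        y0 = rng.uniform(-1, 1, (8, 8))
        eps = rng.standard_normal((8, 8))
        cfg = GuidanceConfig(eta=10.0)
        net = lambda yt, xc, g: 0.2 * yt
        args = (schedule, net, blur_model, y0 * 0, y0, 5, eps, cfg)
        a = pi_training_loss(*args, x_tilde=apply_A(blur_model, y0))
        b = pi_training_loss(*args, x_tilde=apply_A(blur_model, y0))
        assert a == b


class TestGuidedSampling:
    def test_guidance_pulls_toward_measurement(self, delta_model, rng):
        """With A = I and a blind stub denoiser, guidance must reduce MSE."""
        schedule = make_schedule(60, beta_range=(1e-3, 0.15))
        y0 = np.clip(rng.random((16, 16)), 0, 1)
        x = to_diffusion_range(y0)  # noiseless observation, delta kernel
        zero = lambda yt, xc, g: np.zeros_like(yt)
        mses = {eta: [] for eta in (0.0, 20.0)}
        for seed in range(10):
            for eta in mses:
                out = pi_sample(schedule, zero, delta_model, x,
                                GuidanceConfig(eta=eta), rng_seed=seed)
                mses[eta].append(np.mean((out - x) ** 2))
        assert np.mean(mses[20.0]) < np.mean(mses[0.0])

    def test_same_seed_bit_identical(self, schedule, blur_model, rng):
        x = rng.uniform(-1, 1, (8, 8))
        net = lambda yt, xc, g: 0.05 * yt
        cfg = GuidanceConfig(eta=10.0)
        a = pi_sample(schedule, net, blur_model, x, cfg, rng_seed=11)
        b = pi_sample(schedule, net, blur_model, x, cfg, rng_seed=11)
        np.testing.assert_array_equal(a, b)

    def test_restore_outputs_mean_and_std(self, delta_model, rng):
        schedule = make_schedule(10, beta_range=(1e-2, 0.3))
        zero = lambda yt, xc, g: np.zeros_like(yt)
        obs = rng.random((8, 8))
        res = restore(schedule, zero, delta_model, obs,
                      GuidanceConfig(eta=5.0), n_samples=4, rng_seed=0)
        assert res["samples"].shape == (4, 8, 8)
        np.testing.assert_allclose(res["mean"], res["samples"].mean(0))
        assert res["std"].max() > 0
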