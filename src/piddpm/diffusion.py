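"""Denoising-diffusion core: schedules, forward process, posterior, sampler.

Forward noising  q(y_t | y_{t-1}) = N(sqrt(1-beta_t) y_{t-1}, beta_t I)
admits the closed form  y_t = sqrt(gamma_t) y_0 + sqrt(1-gamma_t) eps  with
gamma_t the running product of alpha_t = 1 - beta_t.  The exact posterior
q(y_{t-1} | y_t, y_0) is Gaussian with

    mean = sqrt(gamma_{t-1}) beta_t / (1-gamma_t) * y0
         + sqrt(alpha_t) (1-gamma_{t-1}) / (1-gamma_t) * y_t
    var  = (1-gamma_{t-1}) / (1-gamma_t) * beta_t        (beta-tilde)

The conditional model predicts the injected noise, eps_theta(y_t, x, gamma_t),
with the observation x channel-concatenated and the continuous gamma_t as the
time conditioning.  Ancestral sampling follows the standard recurrence with
the per-step variance sigma_t^2 chosen as beta_t (upper bound, default) or
beta-tilde (lower bound).  Timesteps are 1-based: t runs from 1 to T, and
gamma_0 := 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "DiffusionSchedule",
    "make_schedule",
    "q_sample",
    "posterior_params",
    "mu_from_eps",
    "conditioned_loss",
    "ancestral_sample",
]

# denoiser callable signature: (y_t, x, gamma_t) -> eps_hat
Denoiser = Callable[[np.ndarray, Optional[np.ndarray], float], np.ndarray]


@dataclass(frozen=True)
class DiffusionSchedule:
    """Per-timestep quantities of one variance schedule (arrays index t-1)."""

    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    beta_tilde: np.ndarray
    sigma2: np.ndarray
    kind: str = "linear"

    @property
    def T(self) -> int:
        return len(self.beta)

    def _check_t(self, t: int) -> None:
        if not (1 <= t <= self.T):
            raise ValueError(f"timestep t={t} outside 1..{self.T}")

    def gamma_at(self, t: int) -> float:
        """gamma_t with the convention gamma_0 = 1."""
        if t == 0:
            return 1.0
        self._check_t(t)
        return float(self.gamma[t - 1])

    def beta_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.beta[t - 1])

    def alpha_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha[t - 1])

    def sigma2_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.sigma2[t - 1])


def make_schedule(
    T: int,
    kind: str = "linear",
    beta_range: tuple[float, float] = (1e-4, 0.02),
    sigma: str = "beta",
) -> DiffusionSchedule:
    """Build a variance schedule.

    ``kind='linear'`` interpolates beta between ``beta_range``;
    ``kind='cosine'`` uses the squared-cosine signal schedule (beta_range is
    then only a clipping bound for beta_max).  ``sigma`` selects the sampling
    variance: ``'beta'`` (upper bound) or ``'beta_tilde'`` (lower bound).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    b_min, b_max = beta_range
    if not (0.0 <= b_min <= b_max < 1.0):
        raise ValueError("require 0 <= beta_min <= beta_max < 1")
    if kind == "linear":
        beta = np.linspace(b_min, b_max, T)
    elif kind == "cosine":
        s = 0.008
        ts = np.arange(T + 1) / T
        abar = np.cos((ts + s) / (1 + s) * np.pi / 2) ** 2
        abar /= abar[0]
        beta = np.clip(1.0 - abar[1:] / abar[:-1], 0.0, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    if np.all(beta == 0):
        warnings.warn("all-zero beta schedule: the chain never adds noise",
                      stacklevel=2)
    alpha = 1.0 - beta
    gamma = np.cumprod(alpha)
    if gamma[-1] >= 0.05:
        warnings.warn(
            f"gamma_T = {gamma[-1]:.3g} >= 0.05: y_T is far from pure noise",
            stacklevel=2,
        )
    gamma_prev = np.concatenate([[1.0], gamma[:-1]])
    denom = np.where(1.0 - gamma > 0, 1.0 - gamma, 1.0)
    beta_tilde = (1.0 - gamma_prev) / denom * beta
    if sigma == "beta":
        sigma2 = beta.copy()
    elif sigma == "beta_tilde":
        sigma2 = beta_tilde.copy()
    else:
        raise ValueError("sigma must be 'beta' or 'beta_tilde'")
    return DiffusionSchedule(beta, alpha, gamma, beta_tilde, sigma2, kind)


def q_sample(schedule: DiffusionSchedule, y0: np.ndarray, t: int,
             eps: np.ndarray) -> np.ndarray:
    """Closed-form forward sample  sqrt(gamma_t) y0 + sqrt(1-gamma_t) eps."""
    g = schedule.gamma_at(t)
    return np.sqrt(g) * y0 + np.sqrt(1.0 - g) * eps


def posterior_params(schedule: DiffusionSchedule, y0: np.ndarray,
                     yt: np.ndarray, t: int) -> tuple[np.ndarray, float]:
    """Mean and variance of the exact posterior q(y_{t-1} | y_t, y_0)."""
    if t < 1:
        raise ValueError("posterior undefined for t < 1")
    schedule._check_t(t)
    g_t = schedule.gamma_at(t)
    g_prev = schedule.gamma_at(t - 1)
    b_t = schedule.beta_at(t)
    a_t = schedule.alpha_at(t)
    coef0 = np.sqrt(g_prev) * b_t / (1.0 - g_t)
    coeft = np.sqrt(a_t) * (1.0 - g_prev) / (1.0 - g_t)
    var = (1.0 - g_prev) / (1.0 - g_t) * b_t
    return coef0 * y0 + coeft * yt, float(var)


def mu_from_eps(schedule: DiffusionSchedule, yt: np.ndarray, t: int,
                eps_hat: np.ndarray) -> np.ndarray:
    """Posterior mean re-expressed through the predicted noise."""
    if t < 1:
        raise ValueError("t must be >= 1")
    schedule._check_t(t)
    a_t = schedule.alpha_at(t)
    b_t = schedule.beta_at(t)
    g_t = schedule.gamma_at(t)
    return (yt - b_t / np.sqrt(1.0 - g_t) * eps_hat) / np.sqrt(a_t)


def conditioned_loss(schedule: DiffusionSchedule, denoiser: Denoiser,
                     x: Optional[np.ndarray], y0: np.ndarray, t: int,
                     eps: np.ndarray) -> float:
    """Simple epsilon-matching objective, mean over pixels."""
    if eps.shape != y0.shape:
        raise ValueError("eps must be shaped like y0")
    yt = q_sample(schedule, y0, t, eps)
    eps_hat = denoiser(yt, x, schedule.gamma_at(t))
    if eps_hat.shape != y0.shape:
        raise ValueError("denoiser output shape mismatch")
    return float(np.mean((eps - eps_hat) ** 2))


def _reverse_loop(
    schedule: DiffusionSchedule,
    denoiser: Denoiser,
    x: Optional[np.ndarray],
    shape: tuple[int, ...],
    rng: np.random.Generator,
    mean_shift: Optional[Callable[[np.ndarray, int], np.ndarray]] = None,
) -> np.ndarray:
    """Shared ancestral loop; ``mean_shift(y_t, t)`` adds guidance if given."""
    y = rng.standard_normal(shape)
    for t in range(schedule.T, 0, -1):
        eps_hat = denoiser(y, x, schedule.gamma_at(t))
        mean = mu_from_eps(schedule, y, t, eps_hat)
        if mean_shift is not None:
            shift = mean_shift(y, t)
            if shift is not None:
                mean = mean + shift
        if t > 1:
            y = mean + np.sqrt(schedule.sigma2_at(t)) * rng.standard_normal(shape)
        else:
            y = mean
    return y


def ancestral_sample(
    schedule: DiffusionSchedule,
    denoiser: Denoiser,
    x: Optional[np.ndarray],
    rng_seed: int,
    shape: Optional[tuple[int, ...]] = None,
) -> np.ndarray:
    """Conditioned ancestral sampling from y_T ~ N(0, I) down to y_0.

    No noise is added at the final step t = 1 (the mean is returned), and the
    whole trajectory is determined by ``rng_seed``.
    """
    if shape is None:
        if x is None:
            raise ValueError("shape is required when no conditioning is given")
        shape = x.shape
    rng = np.random.default_rng(rng_seed)
    return _reverse_loop(schedule, denoiser, x, shape, rng)
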