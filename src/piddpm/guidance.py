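"""Physics-informed guidance: data-fidelity gradient, annealing, training.

The reverse transition of a guided diffusion model is the unconditioned
Gaussian with its mean shifted by sigma_t^2 * g, where
g = grad_{y_t} log p(x | y_t).  For a measurement x = A y + n with
n ~ N(xi, xi*I) the gradient is approximated by

    g ~= A^T (x - xi - A y_t) / xi^2 ,

and when the noiseless measurement x~ = A y_0 is available (synthetic
training data) the xi shift is dropped and the 1/xi^2 prefactor is absorbed
by the annealing, which rescales g to the norm

    ||nu_t * g||_2 = eta * sqrt(gamma_t) ,

so guidance weakens at high noise levels (small gamma_t) and any constant
scale of g is irrelevant.  An optional L1/L2 regulariser joins the data term
inside the same annealed gradient.  Training minimises

    || eps - eps_theta(y_t, x, gamma_t) + sigma_t^2 * g ||^2     (C = 1)

which reduces exactly to the conditioned-DDPM objective when eta = 0; the
guided sampler likewise reduces to plain ancestral sampling at eta = 0 with
identical random-number consumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import nn
from .acquisition import (AcquisitionModel, ImagePair, apply_A_adjoint,
                          apply_A, from_diffusion_range, to_diffusion_range)
from .denoiser import UNetDenoiser
from .diffusion import DiffusionSchedule, _reverse_loop, q_sample

__all__ = [
    "GuidanceConfig",
    "GuidanceGradient",
    "data_fidelity_gradient",
    "anneal",
    "regulariser_gradient",
    "pi_training_loss",
    "pi_sample",
    "restore",
    "train",
    "TrainResult",
]


@dataclass(frozen=True)
class GuidanceConfig:
    """Guidance strength, noise offset and regulariser settings.

    eta : guidance strength (default 10); eta = 0 disables guidance.
    xi : Gaussian noise offset of the measurement model; only needed when
        the guidance target is a noisy observation and a literal Eq-14
        gradient scale is wanted (annealing cancels it otherwise).
    regulariser : 'none', 'l1' or 'l2'.
    lambda_weight : constant regulariser weight lambda.
    lambda_scaled : if True, lambda_t = lambda * sqrt(gamma_t).
    use_noiseless_target : training-time substitution of x - xi by the
        noiseless measurement A y_0.
    """

    eta: float = 10.0
    xi: Optional[float] = None
    regulariser: str = "none"
    lambda_weight: float = 0.0
    lambda_scaled: bool = False
    use_noiseless_target: bool = True

    def __post_init__(self):
        if not np.isfinite(self.eta) or self.eta < 0:
            raise ValueError("eta must be finite and >= 0")
        if self.regulariser not in ("none", "l1", "l2"):
            raise ValueError(f"unknown regulariser {self.regulariser!r}")

    def lambda_at(self, schedule: DiffusionSchedule, t: int) -> float:
        lam = self.lambda_weight
        if self.lambda_scaled:
            lam *= np.sqrt(schedule.gamma_at(t))
        return float(lam)


@dataclass
class GuidanceGradient:
    g: np.ndarray
    nu_t: float
    t: int


def data_fidelity_gradient(model: AcquisitionModel, yt: np.ndarray,
                           x_tilde: np.ndarray, xi: Optional[float] = None,
                           noiseless: bool = True) -> np.ndarray:
    """Gradient of log p(x | y_t) under the Gaussian measurement surrogate.

    Returns A^T (x_tilde - xi - A y_t) / xi^2, or, with ``noiseless=True``
    (the x_tilde = A y_0 substitution), A^T (x_tilde - A y_t) with the
    xi-dependent scale treated as 1.
    """
    if yt.shape != x_tilde.shape:
        raise ValueError("y_t and target must share a shape")
    if noiseless:
        residual = x_tilde - apply_A(model, yt)
        return apply_A_adjoint(model, residual)
    if xi is None:
        xi = model.gaussian_offset
    if xi is None or xi <= 0:
        raise ZeroDivisionError("xi must be positive for a noisy target")
    residual = x_tilde - xi - apply_A(model, yt)
    return apply_A_adjoint(model, residual) / (xi ** 2)


def anneal(gradient: np.ndarray, t: int, schedule: DiffusionSchedule,
           eta: float) -> GuidanceGradient:
    """Rescale g so its L2 norm equals eta * sqrt(gamma_t)."""
    norm = float(np.linalg.norm(gradient))
    if norm == 0.0 or eta == 0.0:
        return GuidanceGradient(np.zeros_like(gradient), 0.0, t)
    nu = eta * np.sqrt(schedule.gamma_at(t)) / norm
    return GuidanceGradient(nu * gradient, nu, t)


def regulariser_gradient(yt: np.ndarray, kind: str, lambda_t: float) -> np.ndarray:
    """Subgradient of lambda_t * R(y): lambda*sign(y) for L1, 2*lambda*y for L2."""
    if kind == "none":
        return np.zeros_like(yt)
    if kind == "l1":
        return lambda_t * np.sign(yt)
    if kind == "l2":
        return 2.0 * lambda_t * yt
    raise ValueError(f"unknown regulariser kind {kind!r}")


def _guidance_raw(model: AcquisitionModel, yt: np.ndarray, target: np.ndarray,
                  config: GuidanceConfig, schedule: DiffusionSchedule, t: int,
                  noiseless: bool) -> np.ndarray:
    """Combined raw gradient: data term minus regulariser descent direction."""
    g = data_fidelity_gradient(model, yt, target, xi=config.xi,
                               noiseless=noiseless)
    if config.regulariser != "none" and config.lambda_weight != 0.0:
        g = g - regulariser_gradient(yt, config.regulariser,
                                     config.lambda_at(schedule, t))
    return g


def pi_training_loss(schedule: DiffusionSchedule, denoiser, model: AcquisitionModel,
                     pair_x: np.ndarray, pair_y0: np.ndarray, t: int,
                     eps: np.ndarray, config: GuidanceConfig,
                     x_tilde: Optional[np.ndarray] = None) -> float:
    """Physics-informed epsilon objective (C = 1), mean over pixels.

    ``x_tilde`` is the noiseless measurement A y_0 in the diffusion value
    convention; required when guidance is active with a noiseless target.
    """
    yt = q_sample(schedule, pair_y0, t, eps)
    target_eps = eps
    if config.eta > 0.0:
        if config.use_noiseless_target:
            if x_tilde is None:
                raise ValueError("noiseless measurement required when "
                                 "use_noiseless_target is set")
            guide_target, noiseless = x_tilde, True
        else:
            guide_target, noiseless = pair_x, False
        raw = _guidance_raw(model, yt, guide_target, config, schedule, t,
                            noiseless)
        ann = anneal(raw, t, schedule, config.eta)
        target_eps = eps + schedule.sigma2_at(t) * ann.g
    eps_hat = denoiser(yt, pair_x, schedule.gamma_at(t))
    return float(np.mean((target_eps - eps_hat) ** 2))


def pi_sample(schedule: DiffusionSchedule, denoiser, model: AcquisitionModel,
              x: np.ndarray, config: GuidanceConfig, rng_seed: int,
              x_tilde: Optional[np.ndarray] = None) -> np.ndarray:
    """Guided ancestral sampling with the transition mean shifted by sigma_t^2 g.

    The guidance target defaults to the observed x (the noiseless measurement
    may be passed for oracle experiments).  With eta = 0 and no regulariser
    the trajectory is identical, seed for seed, to the conditioned sampler.
    """
    target = x if x_tilde is None else x_tilde
    noiseless = x_tilde is not None or config.xi is None

    def mean_shift(yt: np.ndarray, t: int):
        if config.eta == 0.0 and (config.regulariser == "none"
                                  or config.lambda_weight == 0.0):
            return None
        raw = _guidance_raw(model, yt, target, config, schedule, t, noiseless)
        ann = anneal(raw, t, schedule, config.eta)
        if ann.nu_t == 0.0:
            return None
        return schedule.sigma2_at(t) * ann.g

    rng = np.random.default_rng(rng_seed)
    return _reverse_loop(schedule, denoiser, x, x.shape, rng,
                         mean_shift=mean_shift)


def restore(schedule: DiffusionSchedule, denoiser, model: AcquisitionModel,
            observation: np.ndarray, config: GuidanceConfig, n_samples: int,
            rng_seed: int) -> dict[str, np.ndarray]:
    """Repeated guided restorations of one observation (photon units).

    Draws ``n_samples`` independent reconstructions and returns them together
    with their pixel-wise mean and standard deviation, the model's estimate
    of the restoration and its uncertainty.  Outputs are mapped back to the
    [0, 1] intensity convention.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    x = to_diffusion_range(observation)
    samples = []
    for k in range(n_samples):
        y = pi_sample(schedule, denoiser, model, x, config,
                      rng_seed=rng_seed + k)
        samples.append(from_diffusion_range(y))
    stack = np.stack(samples)
    return {"samples": stack, "mean": stack.mean(axis=0),
            "std": stack.std(axis=0)}


@dataclass
class TrainResult:
    denoiser: UNetDenoiser
    losses: np.ndarray
    config: GuidanceConfig
    schedule: DiffusionSchedule


def _pair_tensors(pair: ImagePair) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a photon-unit pair into the [-1, 1] diffusion convention."""
    x = to_diffusion_range(pair.observation)
    y0 = to_diffusion_range(pair.truth)
    if pair.noiseless is not None:
        xt = to_diffusion_range(pair.noiseless)
    else:
        xt = None
    return x, y0, xt


def train(dataset: Sequence[ImagePair], denoiser: UNetDenoiser,
          schedule: DiffusionSchedule, config: GuidanceConfig = GuidanceConfig(),
          pi: bool = True, steps: int = 1000, batch_size: int = 4,
          lr: float = 2e-3, seed: int = 0) -> TrainResult:
    """Stochastic training loop minimising the (physics-informed) objective.

    Each step samples a batch of pairs, per-sample timesteps t ~ U{1..T} and
    noise eps ~ N(0, I), forms the target eps + sigma_t^2 * g (g detached:
    no learning signal flows through the physics term) and takes one Adam
    step on the pixel-mean squared error.  Fully seeded and reproducible.
    With ``pi=False`` (or eta = 0) the loop is the conditioned-DDPM baseline,
    consuming the randomness in exactly the same order.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(denoiser.params, lr=lr)
    losses = np.empty(steps)
    T = schedule.T
    use_guidance = pi and config.eta > 0.0
    for step in range(steps):
        idx = rng.integers(0, len(dataset), size=batch_size)
        ts = rng.integers(1, T + 1, size=batch_size)
        xs, y0s, gts, sig2s, targets = [], [], [], [], []
        for i, t in zip(idx, ts):
            pair = dataset[i]
            x, y0, xt = _pair_tensors(pair)
            eps = rng.standard_normal(y0.shape)
            yt = q_sample(schedule, y0, int(t), eps)
            target = eps
            if use_guidance:
                if config.use_noiseless_target:
                    if xt is None:
                        raise ValueError("dataset pair lacks the noiseless "
                                         "measurement required for guidance")
                    guide_target, noiseless = xt, True
                else:
                    guide_target, noiseless = x, False
                raw = _guidance_raw(pair.model, yt, guide_target, config,
                                    schedule, int(t), noiseless)
                ann = anneal(raw, int(t), schedule, config.eta)
                target = eps + schedule.sigma2_at(int(t)) * ann.g
            xs.append(x)
            y0s.append(yt)
            gts.append(schedule.gamma_at(int(t)))
            targets.append(target)
        yt_b = np.stack(y0s)[:, None].astype(denoiser.dtype)
        x_b = np.stack(xs)[:, None].astype(denoiser.dtype)
        tgt_b = np.stack(targets)[:, None].astype(denoiser.dtype)
        out = denoiser.forward(yt_b, x_b, np.array(gts))
        diff = out - nn.Tensor(tgt_b)
        loss = (diff * diff).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses[step] = float(loss.data)
    return TrainResult(denoiser, losses, config, schedule)
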