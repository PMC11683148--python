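"""Conditional epsilon-prediction network.

An encoder-decoder with skip connections: downsampling levels are pairs of
3x3 convolutions with instance normalisation and SiLU, upsampling levels
mirror them with an additional bilinear 2x upsampling operator.  The noisy
state y_t and the observation x enter channel-concatenated; the continuous
signal-retention level gamma_t conditions every block through a sinusoidal
embedding projected to a per-channel bias.  Default size (3 levels, 32 base
channels, no attention) is chosen to train on a CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["DenoiserSpec", "UNetDenoiser", "eps_predict"]


@dataclass(frozen=True)
class DenoiserSpec:
    depth: int = 3
    base_channels: int = 32
    in_channels: int = 2          # y_t concatenated with x
    gamma_embedding_dim: int = 64

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.gamma_embedding_dim % 2:
            raise ValueError("gamma_embedding_dim must be even")


def _gamma_features(gamma: np.ndarray, dim: int, dtype) -> np.ndarray:
    """Sinusoidal features of the continuous gamma_t in (0, 1]."""
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = 1000.0 * np.asarray(gamma, dtype=float)[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(dtype)


class UNetDenoiser:
    """Instantiated network; deterministic given weights and inputs."""

    def __init__(self, spec: DenoiserSpec = DenoiserSpec(), seed: int = 0,
                 dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        ch = [spec.base_channels * 2 ** l for l in range(spec.depth)]
        self._ch = ch
        E = spec.gamma_embedding_dim

        def conv_param(name, c_in, c_out, k=3, scale=None):
            std = scale if scale is not None else np.sqrt(2.0 / (c_in * k * k))
            self.params[f"{name}.w"] = Tensor(
                (rng.standard_normal((c_out, c_in, k, k)) * std).astype(dtype),
                requires_grad=True)
            self.params[f"{name}.b"] = Tensor(
                np.zeros(c_out, dtype=dtype), requires_grad=True)

        def norm_param(name, c):
            self.params[f"{name}.g"] = Tensor(
                np.ones((1, c, 1, 1), dtype=dtype), requires_grad=True)
            self.params[f"{name}.s"] = Tensor(
                np.zeros((1, c, 1, 1), dtype=dtype), requires_grad=True)

        def dense_param(name, n_in, n_out):
            std = np.sqrt(1.0 / n_in)
            self.params[f"{name}.w"] = Tensor(
                (rng.standard_normal((n_in, n_out)) * std).astype(dtype),
                requires_grad=True)
            self.params[f"{name}.b"] = Tensor(
                np.zeros(n_out, dtype=dtype), requires_grad=True)

        def block_params(name, c_in, c_out):
            conv_param(f"{name}.conv1", c_in, c_out)
            norm_param(f"{name}.norm1", c_out)
            dense_param(f"{name}.emb", E, c_out)
            conv_param(f"{name}.conv2", c_out, c_out)
            norm_param(f"{name}.norm2", c_out)

        dense_param("embed.fc1", E, E)
        dense_param("embed.fc2", E, E)
        conv_param("conv_in", spec.in_channels, ch[0])
        prev = ch[0]
        for l in range(spec.depth):
            block_params(f"enc{l}", prev, ch[l])
            prev = ch[l]
        block_params("mid", ch[-1], ch[-1])
        for l in reversed(range(spec.depth - 1)):
            block_params(f"dec{l}", ch[l + 1] + ch[l], ch[l])
        conv_param("conv_out", ch[0], 1, scale=1e-4)

    # -- forward -----------------------------------------------------------

    def _dense(self, name: str, x: Tensor) -> Tensor:
        return x.matmul(self.params[f"{name}.w"]) + self.params[f"{name}.b"]

    def _inorm(self, name: str, x: Tensor) -> Tensor:
        m = x.mean(axis=(2, 3), keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=(2, 3), keepdims=True)
        y = xc * (v + 1e-5).pow(-0.5)
        return y * self.params[f"{name}.g"] + self.params[f"{name}.s"]

    def _block(self, name: str, h: Tensor, emb: Tensor) -> Tensor:
        h = nn.conv2d(h, self.params[f"{name}.conv1.w"],
                      self.params[f"{name}.conv1.b"])
        h = self._inorm(f"{name}.norm1", h)
        bias = self._dense(f"{name}.emb", emb)
        B, C = bias.shape
        h = h + bias.reshape(B, C, 1, 1)
        h = h.silu()
        h = nn.conv2d(h, self.params[f"{name}.conv2.w"],
                      self.params[f"{name}.conv2.b"])
        h = self._inorm(f"{name}.norm2", h)
        return h.silu()

    def forward(self, yt: np.ndarray, x: np.ndarray, gamma) -> Tensor:
        """Batched forward pass; yt, x: (B, 1, H, W); gamma: scalar or (B,)."""
        yt = np.asarray(yt, dtype=self.dtype)
        x = np.asarray(x, dtype=self.dtype)
        if yt.shape != x.shape:
            raise ValueError("y_t and conditioning image must share a shape")
        B = yt.shape[0]
        gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (B,))
        emb = Tensor(_gamma_features(gamma, self.spec.gamma_embedding_dim,
                                     self.dtype))
        emb = self._dense("embed.fc1", emb).silu()
        emb = self._dense("embed.fc2", emb)

        h = nn.concat([Tensor(yt), Tensor(x)], axis=1)
        h = nn.conv2d(h, self.params["conv_in.w"], self.params["conv_in.b"])
        skips = []
        for l in range(self.spec.depth):
            h = self._block(f"enc{l}", h, emb)
            if l < self.spec.depth - 1:
                skips.append(h)
                h = nn.avg_pool2x(h)
        h = self._block("mid", h, emb)
        for l in reversed(range(self.spec.depth - 1)):
            h = nn.upsample_bilinear2x(h)
            h = nn.concat([h, skips[l]], axis=1)
            h = self._block(f"dec{l}", h, emb)
        return nn.conv2d(h, self.params["conv_out.w"], self.params["conv_out.b"])

    def __call__(self, yt: np.ndarray, x: np.ndarray | None, gamma) -> np.ndarray:
        """Inference on a single 2-D image (or a batch); returns numpy."""
        single = np.asarray(yt).ndim == 2
        if x is None:
            x = np.zeros_like(np.asarray(yt))
        if single:
            yt = np.asarray(yt)[None, None]
            x = np.asarray(x)[None, None]
        with nn.no_grad():
            out = self.forward(yt, x, gamma).data.astype(float)
        return out[0, 0] if single else out

    # -- (de)serialisation ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=self.dtype)

    def spec_dict(self) -> dict:
        return asdict(self.spec)


def eps_predict(net: UNetDenoiser, yt: np.ndarray, x: np.ndarray,
                gamma_t: float) -> np.ndarray:
    """Predict the injected noise for one image; validates the contract."""
    if yt.shape != x.shape:
        raise ValueError("shape mismatch between y_t and x")
    if not (0.0 < gamma_t <= 1.0):
        raise ValueError("gamma_t must lie in (0, 1]")
    out = net(yt, x, gamma_t)
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite network output")
    return out
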