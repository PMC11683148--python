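"""Image acquisition model  I = phi(h * y + b)  and its linear operator.

The linear part A is periodic (circular) convolution with the focal-plane
slice of the PSF, carried out with FFTs so that A is exactly linear, its
adjoint is convolution with the flipped kernel, and a unit-sum kernel
preserves the image mean.  ``acquire`` applies photon (Poisson) noise on top:
x = Poisson(s * (h*y + b)) / s with photon scale s, giving per-pixel Fano
factor 1 in photon units.  A periodic Richardson-Lucy deconvolver is included
as a classical baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .optics import PSFVolume

__all__ = [
    "AcquisitionModel",
    "ImagePair",
    "apply_A",
    "apply_A_adjoint",
    "acquire",
    "richardson_lucy",
    "embed_kernel",
    "to_diffusion_range",
    "from_diffusion_range",
]


def embed_kernel(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Centre a 2-D kernel inside an array of the target shape (crop or pad)."""
    ky, kx = kernel.shape
    ny, nx = shape
    out = np.zeros(shape, dtype=float)
    # crop if the kernel is larger than the image
    if ky > ny:
        off = (ky - ny) // 2
        kernel = kernel[off:off + ny]
        ky = ny
    if kx > nx:
        off = (kx - nx) // 2
        kernel = kernel[:, off:off + nx]
        kx = nx
    oy = ny // 2 - ky // 2
    ox = nx // 2 - kx // 2
    out[oy:oy + ky, ox:ox + kx] = kernel
    return out


@dataclass
class AcquisitionModel:
    """Forward model of one microscope: PSF blur, background, photon noise.

    Parameters
    ----------
    psf : PSFVolume
        The system PSF; its focal slice (unit sum) is the 2-D kernel of A.
    background : float
        Constant background b, in the same normalised intensity units as y.
    photon_scale : float
        Expected photons per unit intensity (sets the Poisson noise level).
    gaussian_offset : float, optional
        xi of the Gaussian surrogate n ~ N(xi, xi*I) used by guidance when
        the measurement is noisy; estimated from the signal if omitted.
    """

    psf: PSFVolume
    background: float = 0.0
    photon_scale: float = 1000.0
    gaussian_offset: Optional[float] = None
    _tf_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if np.any(np.asarray(self.background) < 0):
            raise ValueError("background must be non-negative")
        if self.psf.focal_slice.sum() <= 0:
            raise ValueError("PSF kernel must have positive sum")

    def transfer(self, shape: tuple[int, int]) -> np.ndarray:
        """FFT of the centred kernel embedded at the image shape (cached)."""
        if shape not in self._tf_cache:
            k = embed_kernel(self.psf.focal_slice, shape)
            self._tf_cache[shape] = np.fft.fft2(np.fft.ifftshift(k))
        return self._tf_cache[shape]


@dataclass
class ImagePair:
    """A degraded observation and its ground truth, plus provenance."""

    observation: np.ndarray        # x, photon-normalised units
    truth: np.ndarray              # y0 in [0, 1]
    model: AcquisitionModel
    noiseless: Optional[np.ndarray] = None   # h*y0 + b, before Poisson noise
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observation.shape != self.truth.shape:
            raise ValueError("observation and truth must share a shape")
        if not (np.isfinite(self.observation).all() and np.isfinite(self.truth).all()):
            raise ValueError("images must be finite")


def apply_A(model: AcquisitionModel, y: np.ndarray) -> np.ndarray:
    """h * y — noiseless, background-free periodic convolution."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("apply_A expects a 2-D image")
    return np.real(np.fft.ifft2(np.fft.fft2(y) * model.transfer(y.shape)))


def apply_A_adjoint(model: AcquisitionModel, x: np.ndarray) -> np.ndarray:
    """A^T x — correlation with the PSF (conjugate transfer function)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("apply_A_adjoint expects a 2-D image")
    return np.real(np.fft.ifft2(np.fft.fft2(x) * np.conj(model.transfer(x.shape))))


def acquire(model: AcquisitionModel, y: np.ndarray, rng_seed: int) -> ImagePair:
    """Simulate one acquisition  x = Poisson(s*(h*y + b)) / s, seeded."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("object intensities must be non-negative")
    clean = apply_A(model, y) + model.background
    # FFT round-off can leave tiny negative values in an all-positive image
    rate = np.clip(clean, 0.0, None) * model.photon_scale
    rng = np.random.default_rng(rng_seed)
    x = rng.poisson(rate).astype(float) / model.photon_scale
    return ImagePair(observation=x, truth=y, model=model, noiseless=clean,
                     meta={"seed": int(rng_seed)})


def richardson_lucy(x: np.ndarray, psf: PSFVolume, iterations: int = 10,
                    eps: float = 1e-12) -> np.ndarray:
    """Multiplicative Richardson-Lucy deconvolution, periodic boundaries.

    Flux-preserving for a unit-sum kernel: the total intensity of the
    estimate equals that of the data at every iteration.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    model = AcquisitionModel(psf=psf, photon_scale=1.0)
    x = np.asarray(x, dtype=float)
    est = np.full_like(x, max(x.mean(), eps))
    for _ in range(iterations):
        denom = np.clip(apply_A(model, est), eps, None)
        est = est * apply_A_adjoint(model, x / denom)
    return est


def to_diffusion_range(img: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Affine map of [lo, hi] intensities onto the [-1, 1] diffusion range."""
    return 2.0 * (np.asarray(img, dtype=float) - lo) / (hi - lo) - 1.0


def from_diffusion_range(img: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Inverse of :func:`to_diffusion_range`."""
    return (np.asarray(img, dtype=float) + 1.0) * 0.5 * (hi - lo) + lo
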