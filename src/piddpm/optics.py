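"""Scalar Fourier optics: pupils, OTFs and widefield/confocal PSFs.

The imaging model is built from the complex pupil function
``Q(m) = A(m) e^{i phi(m)}`` defined over the transverse spatial-frequency
plane.  ``A`` is a top-hat of radius ``NA / lambda`` (the aperture) and
``phi`` an optional aberration phase.  The coherent amplitude point-spread
function at defocus ``z`` follows from angular-spectrum propagation,

    u(x, y, z) = IFT2[ Q(kx, ky) * exp(2*pi*i * kz * z) ],

with the axial frequency taken on the Ewald spherical cap
``kz = sqrt((n/lambda)^2 - k_perp^2)``.  The incoherent widefield PSF for a
fluorophore excited at ``lambda_ex`` and detected at ``lambda_em`` is

    h(x, y, z) = |u_ex|^2 * |u_em|^2 ,

the Airy diffraction pattern when the two wavelengths coincide.  A confocal
pinhole of radius R acts as a field stop in the image plane: the emission
amplitude is masked by the disk T(x, y) = 1_{x^2+y^2 <= R^2} plane by plane
before taking the modulus square, so an all-pass pinhole recovers the
widefield PSF exactly and a small pinhole truncates the emission spot.

All distances are micrometres except wavelengths, which are stored in
nanometres; spatial frequencies are cycles per micrometre.  Arrays holding
k-space quantities use a centred layout (zero frequency at ``(n//2, n//2)``),
and PSFs are centred on the pixel ``(nz//2, ny//2, nx//2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "PupilField",
    "OTF",
    "PSFVolume",
    "InvalidApertureError",
    "SamplingError",
    "make_pupil",
    "otf_from_pupil",
    "amplitude_psf",
    "amplitude_field",
    "widefield_psf",
    "pinhole_mask",
    "confocal_psf",
    "lateral_fwhm",
    "radial_profile",
]


class InvalidApertureError(ValueError):
    """Numerical aperture not smaller than the refractive index."""


class SamplingError(ValueError):
    """The k-grid is too coarse to resolve the pupil aperture."""


@dataclass(frozen=True)
class OpticalConfig:
    """Physical parameters of one simulated microscope.

    Parameters
    ----------
    numerical_aperture : float
        NA of the objective, dimensionless, in (0, 1.5].
    lambda_ex, lambda_em : float
        Excitation / emission wavelengths in **nanometres**.
    pinhole_radius : float or None
        Confocal pinhole radius in micrometres. ``None`` or ``inf`` means
        widefield (no pinhole).
    refractive_index : float
        Immersion refractive index; must exceed the NA.
    pixel_size_xy, pixel_size_z : float
        Sampling in micrometres per pixel (lateral / axial).
    grid_shape : tuple of int
        ``(nz, ny, nx)`` of the simulated volume.
    """

    numerical_aperture: float
    lambda_ex: float
    lambda_em: float
    pinhole_radius: float | None = None
    refractive_index: float = 1.33
    pixel_size_xy: float = 0.1
    pixel_size_z: float = 0.25
    grid_shape: tuple[int, int, int] = (1, 64, 64)

    def __post_init__(self) -> None:
        if not (0.0 < self.numerical_aperture <= 1.5):
            raise ValueError("numerical_aperture must lie in (0, 1.5]")
        if self.numerical_aperture >= self.refractive_index:
            raise InvalidApertureError(
                f"NA={self.numerical_aperture} must be < refractive index "
                f"{self.refractive_index}"
            )
        if self.lambda_ex <= 0 or self.lambda_em <= 0:
            raise ValueError("wavelengths must be positive")
        if self.pixel_size_xy <= 0 or self.pixel_size_z <= 0:
            raise ValueError("pixel sizes must be positive")
        nz, ny, nx = self.grid_shape
        if min(nz, ny, nx) < 1:
            raise ValueError("grid_shape entries must be positive")
        if self.pinhole_radius is not None and self.pinhole_radius <= 0:
            raise ValueError("pinhole_radius must be positive (or None)")

    @property
    def is_widefield(self) -> bool:
        return self.pinhole_radius is None or not np.isfinite(self.pinhole_radius)


@dataclass
class PupilField:
    """Complex pupil Q over the centred lateral k-grid (cycles/um)."""

    values: np.ndarray                 # (ny, nx) complex, centred layout
    k_spacing: tuple[float, float]     # (dky, dkx)
    wavelength: float                  # nm
    refractive_index: float = 1.33

    def k_grids(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        ky = np.fft.fftshift(np.fft.fftfreq(ny, d=1.0 / (ny * self.k_spacing[0])))
        kx = np.fft.fftshift(np.fft.fftfreq(nx, d=1.0 / (nx * self.k_spacing[1])))
        return ky[:, None], kx[None, :]

    def kz(self) -> np.ndarray:
        """Axial frequency on the Ewald cap, zero outside the sphere."""
        ky, kx = self.k_grids()
        lam_um = self.wavelength * 1e-3
        k2 = (self.refractive_index / lam_um) ** 2 - (kx ** 2 + ky ** 2)
        return np.sqrt(np.clip(k2, 0.0, None))


@dataclass
class OTF:
    """Optical transfer function C(K) on the centred k-grid."""

    values: np.ndarray
    k_spacing: tuple[float, float]


@dataclass
class PSFVolume:
    """Discretised non-negative PSF, unit sum over the volume."""

    values: np.ndarray                    # (nz, ny, nx), real
    pixel_size: tuple[float, float, float]  # (dz, dy, dx) um
    mode: str = "widefield"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None]

    @property
    def focal_slice(self) -> np.ndarray:
        """The z = 0 plane, renormalised to unit sum (2-D kernel)."""
        sl = self.values[self.values.shape[0] // 2]
        return sl / sl.sum()


def _lateral_k_spacing(config: OpticalConfig) -> tuple[float, float]:
    _, ny, nx = config.grid_shape
    return (1.0 / (ny * config.pixel_size_xy), 1.0 / (nx * config.pixel_size_xy))


def make_pupil(
    config: OpticalConfig,
    wavelength: float,
    aberration_phase: np.ndarray | None = None,
) -> PupilField:
    """Build the pupil Q = A e^{i phi} for one wavelength (nm).

    ``A`` is 1 inside the circular aperture ``|k_perp| <= NA/lambda`` and 0
    outside; ``aberration_phase`` (radians, same lateral grid) fills phi.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if config.numerical_aperture >= config.refractive_index:
        raise InvalidApertureError("NA must be smaller than the refractive index")
    _, ny, nx = config.grid_shape
    dky, dkx = _lateral_k_spacing(config)
    lam_um = wavelength * 1e-3
    k_cut = config.numerical_aperture / lam_um
    # Require at least 3 samples across the aperture diameter.
    if 2.0 * k_cut / min(dky, dkx) < 2.0:
        raise SamplingError(
            "k-grid too coarse to resolve the aperture; enlarge the grid or "
            "shrink the pixel size"
        )
    ky = np.fft.fftshift(np.fft.fftfreq(ny, d=config.pixel_size_xy))[:, None]
    kx = np.fft.fftshift(np.fft.fftfreq(nx, d=config.pixel_size_xy))[None, :]
    support = (ky ** 2 + kx ** 2) <= k_cut ** 2
    if support.sum() < 3:
        raise SamplingError("aperture support covers fewer than 3 k-samples")
    amp = support.astype(float)
    if aberration_phase is not None:
        aberration_phase = np.asarray(aberration_phase, dtype=float)
        if aberration_phase.shape != (ny, nx):
            raise ValueError("aberration_phase must live on the lateral k-grid")
        values = amp * np.exp(1j * aberration_phase)
    else:
        values = amp.astype(complex)
    return PupilField(values, (dky, dkx), wavelength, config.refractive_index)


def otf_from_pupil(pupil: PupilField) -> OTF:
    """OTF as the autocorrelation of the pupil, evaluated via FFT.

    ``C(K) = sum_m Q(m + K) Q*(m)`` on the periodic k-grid, which equals the
    half-shifted form ``sum_m Q(m + K/2) Q*(m - K/2)`` after substitution.
    """
    dky, dkx = pupil.k_spacing
    if not np.isfinite([dky, dkx]).all() or dky <= 0 or dkx <= 0:
        raise ValueError("unsupported (non-uniform) k-grid")
    q = np.fft.ifftshift(pupil.values)
    # ifft2(|fft2(q)|^2)[K] = sum_m q(m + K) q*(m)  (circular autocorrelation)
    c = np.fft.ifft2(np.abs(np.fft.fft2(q)) ** 2)
    return OTF(np.fft.fftshift(c), pupil.k_spacing)


def amplitude_psf(otf: OTF) -> np.ndarray:
    """Inverse Fourier transform of the OTF, centred on (ny//2, nx//2)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(otf.values)))


def amplitude_field(config: OpticalConfig, wavelength: float,
                    aberration_phase: np.ndarray | None = None) -> np.ndarray:
    """Coherent amplitude PSF u(x, y, z) for one wavelength.

    Angular-spectrum propagation of the pupil through the z planes of the
    configured volume; shape ``(nz, ny, nx)``, centred layout.
    """
    pupil = make_pupil(config, wavelength, aberration_phase)
    nz, ny, nx = config.grid_shape
    kz = pupil.kz()
    q = pupil.values
    out = np.empty((nz, ny, nx), dtype=complex)
    for iz in range(nz):
        z = (iz - nz // 2) * config.pixel_size_z
        defocused = q * np.exp(2j * np.pi * kz * z)
        out[iz] = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(defocused)))
    return out


def _normalise(h: np.ndarray) -> np.ndarray:
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate PSF with non-positive total energy")
    return h / s


def widefield_psf(config: OpticalConfig,
                  aberration_phase: np.ndarray | None = None) -> PSFVolume:
    """Widefield fluorescence PSF  h = |u_ex|^2 |u_em|^2, unit sum."""
    u_ex = amplitude_field(config, config.lambda_ex, aberration_phase)
    u_em = amplitude_field(config, config.lambda_em, aberration_phase)
    h = (np.abs(u_ex) ** 2) * (np.abs(u_em) ** 2)
    return PSFVolume(
        _normalise(h),
        (config.pixel_size_z, config.pixel_size_xy, config.pixel_size_xy),
        mode="widefield",
        meta={"na": config.numerical_aperture, "lambda_ex": config.lambda_ex,
              "lambda_em": config.lambda_em},
    )


def pinhole_mask(config: OpticalConfig) -> np.ndarray:
    """Binary disk T(x, y) = 1_{x^2+y^2 <= R^2} on the lateral grid.

    Hard pixel-centre rasterisation; a radius below half a pixel degenerates
    to the single centre pixel (with a warning).
    """
    if config.pinhole_radius is None or not np.isfinite(config.pinhole_radius):
        raise ValueError("pinhole_mask requires a finite pinhole radius")
    R = float(config.pinhole_radius)
    _, ny, nx = config.grid_shape
    y = (np.arange(ny) - ny // 2)[:, None] * config.pixel_size_xy
    x = (np.arange(nx) - nx // 2)[None, :] * config.pixel_size_xy
    mask = ((x ** 2 + y ** 2) <= R ** 2).astype(float)
    if R < 0.5 * config.pixel_size_xy:
        warnings.warn(
            "pinhole radius below half a pixel; using a single-pixel mask",
            stacklevel=2,
        )
        mask[:] = 0.0
        mask[ny // 2, nx // 2] = 1.0
    return mask


def confocal_psf(config: OpticalConfig,
                 aberration_phase: np.ndarray | None = None) -> PSFVolume:
    """Confocal PSF with the pinhole masking the emission amplitude.

    h = |T * u_em|^2 |u_ex|^2 with the pinhole applied laterally plane by
    plane; an all-pass pinhole (R beyond the field of view) reduces exactly
    to the widefield PSF.
    """
    if config.is_widefield:
        raise ValueError("confocal_psf requires a finite pinhole_radius")
    T = pinhole_mask(config)
    u_ex = amplitude_field(config, config.lambda_ex, aberration_phase)
    u_em = amplitude_field(config, config.lambda_em, aberration_phase)
    h = (np.abs(T[None, :, :] * u_em) ** 2) * (np.abs(u_ex) ** 2)
    return PSFVolume(
        _normalise(h),
        (config.pixel_size_z, config.pixel_size_xy, config.pixel_size_xy),
        mode="confocal",
        meta={"na": config.numerical_aperture, "lambda_ex": config.lambda_ex,
              "lambda_em": config.lambda_em, "pinhole_radius": config.pinhole_radius},
    )


def radial_profile(plane: np.ndarray, oversample: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated profile along +x through the centre pixel.

    Returns (radii in pixels, values), cubic-spline sampled at 1/oversample
    pixel steps — used to locate Airy zeros and half-max crossings.
    """
    from scipy.ndimage import map_coordinates

    ny, nx = plane.shape
    cy, cx = ny // 2, nx // 2
    r = np.arange(0, (nx - cx - 2) * oversample) / oversample
    coords = np.vstack([np.full_like(r, float(cy)), cx + r])
    vals = map_coordinates(plane, coords, order=3, mode="nearest")
    return r, vals


def lateral_fwhm(psf: PSFVolume) -> float:
    """Full width at half maximum of the focal-plane profile, micrometres."""
    plane = psf.focal_slice
    r, vals = radial_profile(plane)
    half = vals[0] / 2.0
    below = np.nonzero(vals < half)[0]
    if below.size == 0:
        raise ValueError("profile never falls below half maximum")
    i = below[0]
    # linear interpolation between the bracketing samples
    r_half = np.interp(half, [vals[i], vals[i - 1]], [r[i], r[i - 1]])
    return 2.0 * r_half * psf.pixel_size[2]
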