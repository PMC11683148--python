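"""Synthetic training corpus: random microscopes, phantoms, degraded pairs.

PSF parameters are drawn per instrument from physically plausible ranges —
numerical aperture 0.4-1.0, excitation 320-400 nm, emission 450-550 nm,
pinhole radius 0.1-1000 um, refractive index fixed at 1.33 — and each PSF is
rendered with the scalar pupil model.  Ground-truth phantoms (bars, points,
disks, filaments, a Shepp-Logan-like head) take values in [0, 1] and carry
their construction metadata so downstream scoring can locate structures.
Degraded observations follow the acquisition model with Poisson noise at a
configurable photon budget (default grid 50 / 500 / 5000 expected peak
photons, emulating low- to high-light imaging).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .acquisition import AcquisitionModel, ImagePair, acquire
from .optics import OpticalConfig, PSFVolume, confocal_psf, widefield_psf

__all__ = [
    "PSFSamplingRanges",
    "PSFBank",
    "PhantomSpec",
    "sample_psf_bank",
    "make_phantom",
    "generate_pairs",
    "build_dataset",
    "load_dataset",
]

DEFAULT_PHOTON_LEVELS = (50.0, 500.0, 5000.0)


@dataclass(frozen=True)
class PSFSamplingRanges:
    """Sampling ranges of the simulated microscope parameters."""

    na: tuple[float, float] = (0.4, 1.0)
    lambda_ex: tuple[float, float] = (320.0, 400.0)   # nm
    lambda_em: tuple[float, float] = (450.0, 550.0)   # nm
    pinhole: tuple[float, float] = (0.1, 1000.0)      # um
    refractive_index: float = 1.33


@dataclass
class PSFBank:
    psfs: list[PSFVolume]
    params: list[dict]
    ranges: PSFSamplingRanges
    seed: int


@dataclass(frozen=True)
class PhantomSpec:
    kind: str = "points"       # bars | points | disks | filaments | shepp_logan
    size: int = 32
    count: int = 3
    contrast: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.size < 8:
            raise ValueError("phantom size must be >= 8")
        if self.kind not in ("bars", "points", "disks", "filaments",
                             "shepp_logan"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")


def sample_psf_bank(ranges: PSFSamplingRanges, n: int, seed: int,
                    grid: tuple[int, int] = (33, 33),
                    pixel_size_xy: float = 0.1) -> PSFBank:
    """Draw ``n`` microscopes and render their (2-D focal-plane) PSFs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    psfs, params = [], []
    fov_radius = 0.5 * max(grid) * pixel_size_xy
    for i in range(n):
        p = {
            "na": float(rng.uniform(*ranges.na)),
            "lambda_ex": float(rng.uniform(*ranges.lambda_ex)),
            "lambda_em": float(rng.uniform(*ranges.lambda_em)),
            "pinhole_radius": float(rng.uniform(*ranges.pinhole)),
            "refractive_index": ranges.refractive_index,
        }
        config = OpticalConfig(
            numerical_aperture=p["na"],
            lambda_ex=p["lambda_ex"],
            lambda_em=p["lambda_em"],
            pinhole_radius=p["pinhole_radius"],
            refractive_index=p["refractive_index"],
            pixel_size_xy=pixel_size_xy,
            grid_shape=(1,) + grid,
        )
        # a pinhole wider than the field of view acts as no pinhole at all
        if p["pinhole_radius"] >= fov_radius:
            psf = widefield_psf(config)
        else:
            psf = confocal_psf(config)
        p["mode"] = psf.mode
        p["psf_id"] = i
        psfs.append(psf)
        params.append(p)
    return PSFBank(psfs, params, ranges, seed)


# -- phantoms ----------------------------------------------------------------

def _phantom_points(rng, size, count, contrast):
    img = np.zeros((size, size))
    coords = []
    for _ in range(count):
        y, x = rng.integers(2, size - 2, size=2)
        img[y, x] = contrast * rng.uniform(0.5, 1.0)
        coords.append((int(y), int(x)))
    return img, {"coordinates": coords}


def _phantom_bars(rng, size, count, contrast):
    img = np.zeros((size, size))
    bars = []
    for _ in range(count):
        horizontal = bool(rng.integers(0, 2))
        width = int(rng.integers(1, max(2, size // 10)))
        length = int(rng.integers(size // 3, size))
        pos = int(rng.integers(0, size - width))
        start = int(rng.integers(0, size - length + 1))
        val = contrast * rng.uniform(0.5, 1.0)
        if horizontal:
            img[pos:pos + width, start:start + length] = val
        else:
            img[start:start + length, pos:pos + width] = val
        bars.append({"horizontal": horizontal, "width": width,
                     "length": length, "pos": pos, "start": start})
    return np.clip(img, 0, 1), {"bars": bars}


def _phantom_disks(rng, size, count, contrast):
    from skimage.draw import disk as sk_disk

    img = np.zeros((size, size))
    disks = []
    for _ in range(count):
        r = int(rng.integers(2, max(3, size // 6)))
        cy, cx = rng.integers(r, size - r, size=2)
        rr, cc = sk_disk((int(cy), int(cx)), r, shape=img.shape)
        img[rr, cc] = contrast * rng.uniform(0.4, 1.0)
        disks.append({"center": (int(cy), int(cx)), "radius": r})
    return np.clip(img, 0, 1), {"disks": disks}


def _draw_filament(rng, size):
    """One smooth random-walk curve as a pixel mask."""
    mask = np.zeros((size, size), dtype=bool)
    y, x = rng.uniform(2, size - 2, size=2)
    angle = rng.uniform(0, 2 * np.pi)
    n_steps = int(rng.integers(size, 2 * size))
    for _ in range(n_steps):
        mask[int(np.clip(round(y), 0, size - 1)),
             int(np.clip(round(x), 0, size - 1))] = True
        angle += rng.normal(0, 0.25)
        y = np.clip(y + np.sin(angle), 1, size - 2)
        x = np.clip(x + np.cos(angle), 1, size - 2)
    return mask


def _phantom_filaments(rng, size, count, contrast):
    from scipy.ndimage import binary_dilation

    total = np.zeros((size, size), dtype=bool)
    placed = 0
    attempts = 0
    while placed < count and attempts < 200:
        attempts += 1
        fil = _draw_filament(rng, size)
        # keep filaments disjoint so components stay countable
        if (binary_dilation(fil, iterations=1) & total).any():
            continue
        total |= fil
        placed += 1
    if placed < count:
        raise RuntimeError("could not place disjoint filaments; lower count")
    img = total.astype(float) * contrast
    return np.clip(img, 0, 1), {"n_filaments": placed}


def _phantom_shepp_logan(rng, size, count, contrast):
    from skimage.data import shepp_logan_phantom
    from skimage.transform import resize

    base = shepp_logan_phantom()
    img = resize(base, (size, size), anti_aliasing=True)
    img = np.clip(img / img.max() * contrast, 0, 1)
    return img, {"source": "shepp_logan"}


_PHANTOMS = {
    "points": _phantom_points,
    "bars": _phantom_bars,
    "disks": _phantom_disks,
    "filaments": _phantom_filaments,
    "shepp_logan": _phantom_shepp_logan,
}


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    """Deterministic phantom in [0, 1] plus its construction metadata."""
    rng = np.random.default_rng(spec.seed)
    img, meta = _PHANTOMS[spec.kind](rng, spec.size, spec.count, spec.contrast)
    if img.max() <= 0:
        raise RuntimeError("degenerate phantom without structure")
    meta.update({"kind": spec.kind, "seed": spec.seed, "size": spec.size})
    return img, meta


# -- dataset -----------------------------------------------------------------

def generate_pairs(n_pairs: int, bank: PSFBank, seed: int, size: int = 32,
                   phantom_mix: Sequence[str] = ("points", "bars", "disks"),
                   photon_levels: Sequence[float] = DEFAULT_PHOTON_LEVELS,
                   phantom_seed_offset: int = 0) -> list[ImagePair]:
    """In-memory corpus of degraded/clean pairs with noiseless measurements."""
    if not bank.psfs:
        raise ValueError("empty PSF bank")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        kind = phantom_mix[int(rng.integers(0, len(phantom_mix)))]
        pspec = PhantomSpec(kind=kind, size=size,
                            count=int(rng.integers(2, 6)),
                            seed=phantom_seed_offset + i)
        y0, meta = make_phantom(pspec)
        psf_id = int(rng.integers(0, len(bank.psfs)))
        photons = float(photon_levels[int(rng.integers(0, len(photon_levels)))])
        model = AcquisitionModel(psf=bank.psfs[psf_id], photon_scale=photons)
        pair = acquire(model, y0, rng_seed=int(rng.integers(0, 2 ** 31 - 1)))
        pair.meta.update(meta)
        pair.meta.update({"psf_id": psf_id, "photons": photons,
                          "phantom_seed": pspec.seed})
        pairs.append(pair)
    return pairs


def build_dataset(n_pairs: int, out_dir: str | Path, seed: int,
                  bank: Optional[PSFBank] = None, size: int = 32,
                  phantom_mix: Sequence[str] = ("points", "bars", "disks"),
                  photon_levels: Sequence[float] = DEFAULT_PHOTON_LEVELS,
                  n_psfs: int = 8, test_fraction: float = 0.2) -> dict:
    """Write NPZ shards plus a JSON manifest; train/test split by seed.

    Test phantoms use a disjoint seed range so no ground-truth structure is
    shared between the splits, and the test PSF bank is drawn independently.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bank is None:
        bank = sample_psf_bank(PSFSamplingRanges(), n_psfs, seed=seed)
    n_test = max(1, int(round(n_pairs * test_fraction))) if n_pairs > 1 else 0
    n_train = n_pairs - n_test
    test_bank = sample_psf_bank(bank.ranges, max(1, n_psfs // 2),
                                seed=seed + 10_000)
    records = []
    specs = [("train", n_train, bank, seed + 1, 0),
             ("test", n_test, test_bank, seed + 2, 1_000_000)]
    for split, n, b, s, offset in specs:
        pairs = generate_pairs(n, b, seed=s, size=size,
                               phantom_mix=phantom_mix,
                               photon_levels=photon_levels,
                               phantom_seed_offset=offset)
        for j, pair in enumerate(pairs):
            fname = f"{split}_{j:05d}.npz"
            np.savez(
                out_dir / fname,
                x=pair.observation.astype(np.float32),
                y0=pair.truth.astype(np.float32),
                x_noiseless=pair.noiseless.astype(np.float32),
                psf=pair.model.psf.focal_slice.astype(np.float32),
                photon_scale=pair.model.photon_scale,
            )
            records.append({"file": fname, "split": split, **pair.meta})
    manifest = {
        "seed": seed,
        "n_pairs": n_pairs,
        "size": size,
        "phantom_mix": list(phantom_mix),
        "photon_levels": list(photon_levels),
        "ranges": asdict(bank.ranges),
        "records": records,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(path: str | Path, split: str = "train") -> list[ImagePair]:
    """Read pairs back from a build_dataset directory."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    pairs = []
    for rec in manifest["records"]:
        if rec["split"] != split:
            continue
        with np.load(path / rec["file"]) as z:
            psf = PSFVolume(z["psf"][None], (1.0, 0.1, 0.1))
            model = AcquisitionModel(psf=psf,
                                     photon_scale=float(z["photon_scale"]))
            pairs.append(ImagePair(
                observation=z["x"].astype(float),
                truth=z["y0"].astype(float),
                model=model,
                noiseless=z["x_noiseless"].astype(float),
                meta=dict(rec),
            ))
    return pairs
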