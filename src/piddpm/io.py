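"""Image and checkpoint I/O.

Float TIFF and NPZ round-trip losslessly; PNG is written as 16-bit with the
value range scaled to [0, 65535] (the scale is recorded in a sidecar when
saving via the CLI).  Checkpoints are single NPZ files carrying the network
weights together with a JSON header describing the architecture, the
diffusion schedule and the guidance configuration, so a checkpoint is
self-describing for restoration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .denoiser import DenoiserSpec, UNetDenoiser
from .diffusion import DiffusionSchedule, make_schedule
from .guidance import GuidanceConfig

__all__ = ["load_image", "save_image", "save_checkpoint", "load_checkpoint"]

_PNG_MAX = 65535


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write TIFF (float32), PNG (16-bit, range-scaled) or NPZ by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    img = np.asarray(img)
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.astype(np.float32))
    elif suffix == ".png":
        import imageio.v3 as iio

        lo, hi = float(img.min()), float(img.max())
        scale = hi - lo if hi > lo else 1.0
        q = np.round((img - lo) / scale * _PNG_MAX).astype(np.uint16)
        iio.imwrite(path, q)
        path.with_suffix(".png.json").write_text(
            json.dumps({"min": lo, "max": hi}))
    elif suffix == ".npz":
        np.savez(path, image=img)
    else:
        raise ValueError(f"unknown image extension {suffix!r}")


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    if suffix == ".png":
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path)).astype(float) / _PNG_MAX
        sidecar = path.with_suffix(".png.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            img = img * (meta["max"] - meta["min"]) + meta["min"]
        return img
    if suffix == ".npz":
        with np.load(path) as z:
            return np.asarray(z[z.files[0]], dtype=float)
    raise ValueError(f"unknown image extension {suffix!r}")


def save_checkpoint(path: str | Path, denoiser: UNetDenoiser,
                    schedule: DiffusionSchedule,
                    config: GuidanceConfig) -> None:
    header = {
        "spec": denoiser.spec_dict(),
        "schedule": {"T": schedule.T, "kind": schedule.kind,
                     "beta_min": float(schedule.beta[0]),
                     "beta_max": float(schedule.beta[-1]),
                     "sigma": "beta" if np.allclose(schedule.sigma2, schedule.beta)
                              else "beta_tilde"},
        "guidance": {"eta": config.eta, "xi": config.xi,
                     "regulariser": config.regulariser,
                     "lambda_weight": config.lambda_weight,
                     "lambda_scaled": config.lambda_scaled,
                     "use_noiseless_target": config.use_noiseless_target},
    }
    arrays = {f"param/{k}": v for k, v in denoiser.state_dict().items()}
    np.savez(path, header=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[UNetDenoiser, DiffusionSchedule,
                                               GuidanceConfig]:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    spec = DenoiserSpec(**header["spec"])
    net = UNetDenoiser(spec)
    net.load_state_dict(state)
    sch = header["schedule"]
    schedule = make_schedule(sch["T"], kind=sch["kind"],
                             beta_range=(sch["beta_min"], sch["beta_max"]),
                             sigma=sch["sigma"])
    config = GuidanceConfig(**header["guidance"])
    return net, schedule, config
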