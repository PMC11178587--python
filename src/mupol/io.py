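"""Stack file formats and run configuration.

Intensity and Mueller stacks are stored either as multi-page float TIFF
(pages are the 16 polarisation-state channels) or as ``.npz`` array
archives; in memory they are channels-last H x W x 16, with the states
ordered row-major over (analyser state, generator state).  That order is
declared in the file metadata and asserted on load, preventing silent
transposition.  Calibration pairs live in ``.npz`` archives under keys
"G" and "A" (shape (4,4) or (H,W,4,4)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .mueller import CHANNEL_ORDER, CalibrationPair

__all__ = ["read_stack", "write_stack", "read_calibration",
           "write_calibration", "RunConfig"]


def write_stack(path, data: np.ndarray, meta: dict | None = None,
                layout: str = "pages") -> None:
    """Write an H x W x 16 stack (or H x W x 4 x 4, reshaped) to TIFF/npz.

    TIFF stores float pages, either pages-as-channels (``layout='pages'``)
    or a single channels-last page (``layout='channels-last'``); metadata
    (wavelength, shot count, seed, ...) goes into the image description /
    archive.  Values must be finite.
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 4 and data.shape[-2:] == (4, 4):
        data = data.reshape(data.shape[:2] + (16,))
    if data.ndim != 3 or data.shape[-1] != 16:
        raise ValueError(f"expected 16 channels, got shape {data.shape}")
    bad = ~np.isfinite(data)
    if bad.any():
        ch = int(np.argwhere(bad)[0][2])
        raise ValueError(f"non-finite values in channel {ch}")
    meta = dict(meta or {})
    meta.setdefault("channel_order", CHANNEL_ORDER)
    meta["layout"] = layout
    if path.suffix.lower() in (".tif", ".tiff"):
        desc = json.dumps(meta)
        if layout == "pages":
            tifffile.imwrite(path, np.moveaxis(data, -1, 0), description=desc)
        else:
            tifffile.imwrite(path, data, description=desc)
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(path, data=data, meta=json.dumps(meta))
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a stack written by :func:`write_stack`.

    Returns (H x W x 16 channels-last array, metadata dict); both TIFF
    layouts normalise to channels-last.  Errors on missing files, wrong
    channel counts, unexpected channel order and non-finite values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc) if desc else {}
        if data.ndim == 3 and data.shape[0] == 16 and data.shape[-1] != 16:
            data = np.moveaxis(data, 0, -1)  # pages-as-channels
    elif path.suffix.lower() == ".npz":
        with np.load(path) as z:
            data = z["data"]
            meta = json.loads(str(z["meta"])) if "meta" in z else {}
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")
    if data.ndim != 3 or data.shape[-1] != 16:
        n = data.shape[0] if data.ndim == 3 else data.shape[-1]
        raise ValueError(f"expected 16 channels, got {n}")
    order = meta.get("channel_order", CHANNEL_ORDER)
    if order != CHANNEL_ORDER:
        raise ValueError(f"unexpected channel order {order!r}")
    bad = ~np.isfinite(data)
    if bad.any():
        ch = int(np.argwhere(bad)[0][2])
        raise ValueError(f"non-finite values in channel {ch}")
    return np.asarray(data), meta


def write_calibration(path, calib: CalibrationPair) -> None:
    np.savez_compressed(path, G=calib.G, A=calib.A)


def read_calibration(path) -> CalibrationPair:
    with np.load(path) as z:
        return CalibrationPair(z["G"], z["A"])


@dataclass
class RunConfig:
    """Flat, serialisable document of every pipeline tunable.

    Every key has a default; unknown keys are rejected; the document
    round-trips through YAML unchanged.
    """

    # phantom / study conditions
    height: int = 64
    width: int = 64
    sigma: float = 0.012
    kappa: float = 0.05
    noise_w: float = 3.0
    n_shots: int = 16
    lesion: bool = True
    seed: int = 0
    # inputs (phantom is used when no stack is named)
    input_stack: str = ""
    calib_path: str = ""
    roi_path: str = ""
    # denoising; the default runs without a trained model (pddn needs one)
    method: str = "gblr"         # pddn | medf | gblr | grad | none
    model_path: str = ""
    t_star: int = 1
    # diffusion training
    preset: str = "desk"
    train_steps: int = 3000
    train_patch: int = 48
    train_width: int = 8
    diffusion_T: int = 200
    beta_start: float = 1e-4
    beta_end: float = 0.02
    train_batch: int = 4
    train_lr: float = 1e-3
    # decomposition / evaluation
    m11_eps: float = 1e-12
    delta_literal_4x4: bool = False
    csd_window: int = 5
    csd_max: float = 1e3
    ssim_window: int = 7
    reflection_quantile: float = 0.999
    out_dir: str = ""

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def updated(self, **kw) -> "RunConfig":
        d = self.to_dict()
        unknown = set(kw) - set(d)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d.update(kw)
        return RunConfig(**d)
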