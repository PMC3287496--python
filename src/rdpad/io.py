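"""Image and configuration I/O.

Images travel through the pipeline as float64 arrays regardless of the
on-disk depth; all metrics are computed on the float pipeline so that
8-bit export cannot perturb reported numbers.  Supported formats:
single-channel 8/16-bit PNG and TIFF, 32/64-bit float TIFF (lossless),
and plain comma-separated matrices.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = ["read_image", "write_image", "read_mask", "RunConfig",
           "load_config", "save_config"]

logger = logging.getLogger(__name__)

_CSV_SUFFIXES = {".csv", ".txt"}
_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D image as float64.

    Multi-channel input is converted to a single channel by averaging the
    channels (with a warning); the alpha channel, if any, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    suffix = path.suffix.lower()
    if suffix in _CSV_SUFFIXES:
        delim = "," if suffix == ".csv" else None
        arr = np.loadtxt(path, delimiter=delim, ndmin=2)
    elif suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r}: {path}")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        logger.warning("%s has %d channels; averaging to grayscale", path, arr.shape[2])
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret {path} as a 2-D image (shape {arr.shape})")
    return arr


def read_mask(path: str | Path, label: int | None = None) -> np.ndarray:
    """Read a mask image; nonzero (or == label) pixels are True."""
    arr = read_image(path)
    if label is None:
        return arr != 0
    return arr == label


def write_image(
    img: np.ndarray,
    path: str | Path,
    depth: str = "8",
    fixed_range: tuple[float, float] | None = None,
) -> Path:
    """Write an image at the requested depth.

    depth "8" / "16": linear rescale from [min, max] of the image (or
    ``fixed_range`` if given) onto the full integer range.  depth
    "float": lossless float TIFF (requires a .tif/.tiff path).  CSV
    paths write the raw float values.
    """
    img = np.asarray(img, dtype=float)
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _CSV_SUFFIXES:
        np.savetxt(path, img, delimiter=",", fmt="%.10g")
        return path
    if suffix not in _IMAGE_SUFFIXES:
        raise ValueError(f"unsupported image format {suffix!r}: {path}")
    if depth == "float":
        if suffix == ".png":
            raise ValueError("float depth requires a TIFF path")
        tifffile.imwrite(path, img)
        return path
    if depth not in {"8", "16"}:
        raise ValueError(f"depth must be '8', '16' or 'float', got {depth!r}")
    lo, hi = fixed_range if fixed_range is not None else (img.min(), img.max())
    span = hi - lo
    scaled = np.zeros_like(img) if span <= 0 else (img - lo) / span
    maxval = 255 if depth == "8" else 65535
    dtype = np.uint8 if depth == "8" else np.uint16
    quant = np.clip(np.rint(scaled * maxval), 0, maxval).astype(dtype)
    if suffix == ".png":
        iio.imwrite(path, quant)
    else:
        tifffile.imwrite(path, quant)
    return path


@dataclass
class RunConfig:
    """Flat end-to-end run configuration; round-trips through YAML."""

    method: str = "rdpad"
    n_iter: int = 300
    dt: float = 0.05
    q0_mode: str = "decay"
    q0_initial: float = 1.0
    rho: float = 1.0 / 6.0
    record_every: int = 0
    input: str = ""
    output: str = ""
    mask: str = ""
    profile_row: int = -1
    log_level: str = "WARNING"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path
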