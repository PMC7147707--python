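"""Thermogram containers and raster/CSV input-output.

A thermogram is a per-pixel temperature matrix (degrees Celsius) over the
plantar region, optionally restricted by a binary foot mask.  Supported
encodings are plain CSV matrices, 16-bit TIFF (centi-kelvin-free: raw
temperature scaled to the uint16 range) and 8-bit grayscale PNG mapped
linearly onto a configurable temperature range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "Thermogram",
    "GrayImage",
    "to_gray",
    "read_thermogram",
    "write_thermogram",
]

#: default temperature range (°C) for 8-bit gray <-> temperature mapping
DEFAULT_TEMP_RANGE: Tuple[float, float] = (18.0, 38.0)


class ThermogramFormatError(ValueError):
    """Raised when a file cannot be parsed in the requested dialect."""


class ValidationError(ValueError):
    """Raised when container invariants are violated."""


@dataclass
class Thermogram:
    """A per-pixel temperature field with optional plantar mask.

    Parameters
    ----------
    temps
        2-D float array of temperatures in °C.
    mask
        Optional boolean array of the same shape; True marks plantar pixels.
    subject_id, group, side
        Free metadata; ``group`` is ``"control"`` or ``"dm"``, ``side`` is
        ``"left"`` or ``"right"``.
    """

    temps: np.ndarray
    mask: Optional[np.ndarray] = None
    subject_id: str = ""
    group: str = "dm"
    side: str = "right"

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps.ndim != 2:
            raise ValidationError("temps must be a 2-D matrix")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.temps.shape:
                raise ValidationError(
                    f"mask shape {self.mask.shape} != temps shape {self.temps.shape}"
                )
            if not self.mask.any():
                raise ValidationError("mask has no plantar pixel set")
            if not np.isfinite(self.temps[self.mask]).all():
                raise ValidationError("non-finite temperature under the mask")
        elif not np.isfinite(self.temps).all():
            raise ValidationError("non-finite temperature values")
        if self.group not in ("control", "dm"):
            raise ValidationError(f"group must be 'control' or 'dm', got {self.group!r}")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.temps.shape


@dataclass
class GrayImage:
    """Integer gray-level image with ``levels`` possible values [0, L-1]."""

    pixels: np.ndarray
    levels: int
    #: set when quantization degenerated (constant source image)
    constant_warning: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.issubdtype(self.pixels.dtype, np.integer):
            self.pixels = self.pixels.astype(np.int64)
        if self.levels < 2:
            raise ValidationError("levels must be >= 2")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() >= self.levels):
            raise ValidationError("pixel values outside [0, levels-1]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


def to_gray(t: Thermogram, levels: int = 256) -> GrayImage:
    """Min-max quantize a temperature field onto ``levels`` gray levels.

    Pixel value is ``floor((T - Tmin) / (Tmax - Tmin) * levels)`` clipped to
    ``levels - 1``, so the coldest pixel maps to 0 and the hottest to
    ``levels - 1``.  A constant image maps everywhere to 0 and sets
    ``constant_warning``.
    """
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    temps = t.temps
    tmin, tmax = float(temps.min()), float(temps.max())
    if tmax == tmin:
        warnings.warn("constant thermogram: all pixels map to gray 0", stacklevel=2)
        return GrayImage(np.zeros(temps.shape, dtype=np.int64), levels, constant_warning=True)
    scaled = (temps - tmin) / (tmax - tmin) * levels
    pixels = np.clip(np.floor(scaled).astype(np.int64), 0, levels - 1)
    return GrayImage(pixels, levels)


def _mask_path(path: Path) -> Path:
    return path.with_name(path.stem + "_mask.png")


def _load_mask(path: Path, shape: Tuple[int, int]) -> Optional[np.ndarray]:
    mpath = _mask_path(path)
    if not mpath.exists():
        return None
    mask = np.asarray(iio.imread(mpath)) > 0
    if mask.ndim == 3:
        mask = mask[..., 0]
    if mask.shape != shape:
        raise ValidationError(f"mask shape {mask.shape} != temps shape {shape}")
    return mask


def read_thermogram(
    path: str | Path,
    format: str = "csv",
    temp_range: Tuple[float, float] = DEFAULT_TEMP_RANGE,
    **meta,
) -> Thermogram:
    """Read a thermogram from ``path`` in the named dialect.

    ``format`` is one of ``csv`` (comma-separated temperatures, no header),
    ``tiff16`` (uint16 linearly mapped onto ``temp_range``) or ``png8``
    (uint8 linearly mapped onto ``temp_range``).  A sibling file
    ``<stem>_mask.png`` is loaded as the foot mask when present.
    """
    path = Path(path)
    if not path.exists():
        raise ThermogramFormatError(f"no such file: {path}")
    try:
        if format == "csv":
            temps = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
        elif format == "tiff16":
            raw = tifffile.imread(path).astype(float)
            lo, hi = temp_range
            temps = lo + raw / 65535.0 * (hi - lo)
        elif format == "png8":
            raw = np.asarray(iio.imread(path)).astype(float)
            if raw.ndim == 3:
                raw = raw[..., 0]
            lo, hi = temp_range
            temps = lo + raw / 255.0 * (hi - lo)
        else:
            raise ThermogramFormatError(f"unknown format {format!r}")
    except ThermogramFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap parser failures uniformly
        raise ThermogramFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    mask = _load_mask(path, temps.shape)
    return Thermogram(temps=temps, mask=mask, **meta)


def write_thermogram(
    t: Thermogram,
    path: str | Path,
    format: str = "csv",
    temp_range: Tuple[float, float] = DEFAULT_TEMP_RANGE,
) -> Path:
    """Write a thermogram; the mask (if any) goes to ``<stem>_mask.png``."""
    path = Path(path)
    lo, hi = temp_range
    if format == "csv":
        np.savetxt(path, t.temps, delimiter=",", fmt="%.6f")
    elif format == "tiff16":
        raw = np.clip((t.temps - lo) / (hi - lo) * 65535.0, 0, 65535)
        tifffile.imwrite(path, np.round(raw).astype(np.uint16))
    elif format == "png8":
        raw = np.clip((t.temps - lo) / (hi - lo) * 255.0, 0, 255)
        iio.imwrite(path, np.round(raw).astype(np.uint8))
    else:
        raise ThermogramFormatError(f"unknown format {format!r}")
    if t.mask is not None:
        iio.imwrite(_mask_path(path), (t.mask.astype(np.uint8)) * 255)
    return path
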