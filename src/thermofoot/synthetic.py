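"""Synthetic plantar thermograms with controlled thermal structure.

The generator emulates the two canonical situations seen in plantar
infrared imaging:

* ``butterfly`` — the healthy control pattern: a warm plateau along the
  medial arch, a cooler periphery (temperature decays toward the foot
  outline), and a cold, narrow-banded background well separated from the
  plantar region in the histogram;
* ``hot_region`` — a diabetic-type pattern: the butterfly arch is absent
  and a number of Gaussian hot blobs are placed inside the sole, with a
  global amplitude calibrated by bisection so that the Thermal Change
  Index against the generator's own control reference lands inside the
  requested class interval (classes 1-5).

All randomness is driven by ``spec.seed``; equal specs give bit-identical
outputs.  The foot outline is the union of two ellipses (forefoot and
heel), which is enough geometry for the angiosome partition and the
segmentation pipeline to operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from . import angiosome as ang
from .angiosome import DEFAULT_BOUNDARIES, angiosome_means, assign_level, compute_tci, partition_angiosomes
from .thermogram import Thermogram, ValidationError

__all__ = [
    "SyntheticSpec",
    "generate_synthetic",
    "synthetic_reference",
    "arch_band_mask",
    "foot_mask",
    "separable_patches",
    "GenerationError",
]


class GenerationError(ValueError):
    """Raised when the requested class interval cannot be reached."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic thermogram.

    Temperatures in °C.  ``target_class`` only applies to the
    ``hot_region`` pattern; ``hot_region_count`` Gaussian blobs are scaled
    so the subject's TCI against the control reference falls in that
    class.  ``noise_sd`` is additive white Gaussian sensor noise.
    """

    image_shape: Tuple[int, int] = (120, 60)
    pattern: str = "butterfly"
    target_class: int = 1
    background_temp: float = 20.0
    base_foot_temp: float = 30.0
    hot_region_count: int = 3
    noise_sd: float = 0.2
    seed: int = 0
    side: str = "right"
    #: arch plateau height above the foot base (°C), control pattern
    arch_amp: float = 3.5
    #: temperature drop from foot interior to outline (°C)
    peripheral_drop: float = 1.5
    #: sd (°C) of the smooth within-foot temperature texture
    texture_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.pattern not in ("butterfly", "hot_region"):
            raise ValidationError(f"unknown pattern {self.pattern!r}")
        if not 1 <= self.target_class <= 5:
            raise ValidationError("target_class must be in 1..5")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.background_temp >= self.base_foot_temp:
            raise ValidationError("background_temp must be below base_foot_temp")


def foot_mask(shape: Tuple[int, int]) -> np.ndarray:
    """Foot outline as the union of a forefoot and a heel ellipse."""
    h, w = shape
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    fore = (((r - 0.38 * h) / (0.32 * h)) ** 2 + ((c - 0.5 * w) / (0.40 * w)) ** 2) <= 1.0
    heel = (((r - 0.78 * h) / (0.18 * h)) ** 2 + ((c - 0.5 * w) / (0.28 * w)) ** 2) <= 1.0
    return fore | heel


def arch_band_mask(spec: SyntheticSpec) -> np.ndarray:
    """Planted medial-arch band of the butterfly pattern (deterministic)."""
    h, w = spec.image_shape
    mask = foot_mask(spec.image_shape)
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    rows = (r >= 0.30 * h) & (r <= 0.66 * h)
    if spec.side == "right":          # medial at low column indices
        colband = (c >= 0.12 * w) & (c <= 0.48 * w)
    else:
        colband = (c >= 0.52 * w) & (c <= 0.88 * w)
    return mask & rows & colband


def _base_field(spec: SyntheticSpec, mask: np.ndarray) -> np.ndarray:
    """Foot-base temperature field: warm interior, cooler periphery.

    A smooth spatial texture (low-frequency Gaussian random field, sd
    ``texture_sd``) emulates the gentle physiological variation of skin
    temperature, so the plantar gray-level histogram is broad rather than
    a bare spike.  The texture is derived from ``spec.seed`` and is
    shared between a subject and its own control reference.
    """
    dist = ndimage.distance_transform_edt(mask)
    interior = np.minimum(dist / 4.0, 1.0)
    field = np.full(spec.image_shape, spec.background_temp, dtype=float)
    field[mask] = spec.base_foot_temp - spec.peripheral_drop * (1.0 - interior[mask])
    if spec.texture_sd > 0:
        trng = np.random.default_rng([spec.seed, 7])
        texture = ndimage.gaussian_filter(trng.normal(0.0, 1.0, spec.image_shape), 4.0)
        field[mask] += spec.texture_sd * texture[mask] / texture.std()
    return field


def _smooth_within(field: np.ndarray, mask: np.ndarray, background: float,
                   sigma: float = 1.2) -> np.ndarray:
    """Gaussian-smooth the field, then re-impose the cold background."""
    out = ndimage.gaussian_filter(field, sigma)
    out[~mask] = background
    return out


def _blob_field(spec: SyntheticSpec, mask: np.ndarray) -> np.ndarray:
    """Unit-amplitude sum of Gaussian hot blobs seeded inside the mask."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    rows, cols = np.nonzero(mask)
    idx = rng.choice(len(rows), size=max(spec.hot_region_count, 0), replace=False)
    r = np.arange(h)[:, None, None]
    c = np.arange(w)[None, :, None]
    sigma = 0.09 * max(h, w)
    blob = np.exp(-((r - rows[idx]) ** 2 + (c - cols[idx]) ** 2) / (2 * sigma**2))
    return blob.sum(axis=2) if blob.size else np.zeros((h, w))


def synthetic_reference(spec: SyntheticSpec) -> ang.AngiosomeTemps:
    """Control-group angiosome reference for this generator geometry.

    Deterministic: the noiseless butterfly field with the same shape,
    temperatures and side as ``spec``.
    """
    control = replace(spec, pattern="butterfly", noise_sd=0.0)
    temps = _control_field(control)
    mask = foot_mask(spec.image_shape)
    amap = partition_angiosomes(mask, side=spec.side)
    return angiosome_means(Thermogram(temps=temps, mask=mask, side=spec.side), amap)


def _control_field(spec: SyntheticSpec) -> np.ndarray:
    mask = foot_mask(spec.image_shape)
    field = _base_field(spec, mask)
    field[arch_band_mask(spec)] += spec.arch_amp
    return _smooth_within(field, mask, spec.background_temp)


def _class_interval(level: int, boundaries=DEFAULT_BOUNDARIES) -> Tuple[float, float]:
    edges = (0.0,) + tuple(boundaries) + (float("inf"),)
    return edges[level - 1], edges[level]


def generate_synthetic(spec: SyntheticSpec) -> Thermogram:
    """Generate one synthetic thermogram according to ``spec``.

    For ``hot_region`` the blob amplitude is found by bisection on the
    noiseless field until the TCI against :func:`synthetic_reference`
    lies inside the requested class interval; noise is added afterwards,
    so noisy realizations may straddle a boundary just like real repeat
    acquisitions do.
    """
    mask = foot_mask(spec.image_shape)
    rng = np.random.default_rng(spec.seed)

    if spec.pattern == "butterfly":
        temps = _control_field(spec)
    else:
        temps = _hot_region_field(spec, mask)

    if spec.noise_sd > 0:
        temps = temps + rng.normal(0.0, spec.noise_sd, size=temps.shape)

    group = "control" if spec.pattern == "butterfly" else "dm"
    return Thermogram(temps=temps, mask=mask,
                      subject_id=f"synth-{spec.pattern}-{spec.seed}",
                      group=group, side=spec.side)


def _hot_region_field(spec: SyntheticSpec, mask: np.ndarray) -> np.ndarray:
    reference = synthetic_reference(spec)
    amap = partition_angiosomes(mask, side=spec.side)
    base = _smooth_within(_base_field(spec, mask), mask, spec.background_temp)
    blobs = _blob_field(spec, mask)
    blobs = _smooth_within(blobs * 1.0, mask, 0.0)

    lo, hi = _class_interval(spec.target_class)
    # target the interval midpoint; open top interval targets last edge + 0.5
    target = (lo + hi) / 2.0 if np.isfinite(hi) else lo + 0.5

    def tci_at(scale: float) -> float:
        t = Thermogram(temps=base + scale * blobs, mask=mask, side=spec.side)
        return compute_tci(angiosome_means(t, amap), reference)

    # TCI(scale) decreases linearly in scale (hotter subject); bisect on
    # |TCI| = target on the negative branch.
    f0 = tci_at(0.0)
    if spec.hot_region_count <= 0:
        if assign_level(f0) != spec.target_class:
            raise GenerationError(
                f"target_class {spec.target_class} needs |TCI| in [{lo}, {hi}) "
                f"but without hot regions |TCI| is fixed at {abs(f0):.3f}")
        scale = 0.0
    else:
        s_lo, s_hi = 0.0, 1.0
        for _ in range(80):
            if tci_at(s_hi) <= -target:
                break
            s_hi *= 2.0
            if s_hi > 1e6:
                raise GenerationError(
                    f"cannot reach |TCI| >= {lo} for target_class {spec.target_class}")
        for _ in range(60):
            mid = 0.5 * (s_lo + s_hi)
            if tci_at(mid) > -target:
                s_lo = mid
            else:
                s_hi = mid
        scale = 0.5 * (s_lo + s_hi)

    field = base + scale * blobs
    t = Thermogram(temps=field, mask=mask, side=spec.side)
    tci = compute_tci(angiosome_means(t, amap), reference)
    level = assign_level(tci)
    if level != spec.target_class:
        raise GenerationError(
            f"calibrated TCI {tci:.3f} lands in class {level}, "
            f"not the requested class {spec.target_class} [{lo}, {hi})")
    return field


def separable_patches(
    n: int,
    size: int = 64,
    n_classes: int = 2,
    channels: int = 3,
    seed: int = 0,
    gap: float = 0.2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Linearly separable patch dataset for training sanity checks.

    Class ``c`` (1-based) draws pixel intensities uniformly from a band of
    width ``(1 - gap * (n_classes - 1)) / n_classes`` around its own mean,
    so classes occupy disjoint intensity ranges.  Returns ``(X, y)`` with
    ``X`` of shape (n, size, size, channels) in [0, 1] and 1-based labels.
    """
    rng = np.random.default_rng(seed)
    band = (1.0 - gap * (n_classes - 1)) / n_classes
    X = np.empty((n, size, size, channels), dtype=np.float32)
    y = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = i % n_classes
        lo = c * (band + gap)
        X[i] = rng.uniform(lo, lo + band, size=(size, size, channels))
        y[i] = c + 1
    return X, y
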