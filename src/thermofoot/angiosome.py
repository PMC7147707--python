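"""Angiosome partition of the foot sole and the Thermal Change Index.

An angiosome is the tissue territory supplied by one artery.  Four plantar
angiosomes are used for localized temperature analysis: the medial and
lateral plantar artery territories (MPA, LPA) over the fore/mid-foot and
the medial and lateral calcaneal artery territories (MCA, LCA) over the
heel.  The Thermal Change Index (TCI) is the mean, over the four
angiosomes, of the difference between control-reference and subject mean
temperatures; its magnitude is graded into five change levels.

The anatomical atlas prints no pixel coordinates, so the partition is a
configurable proportional rule: a heel band (a fraction of the mask's
bounding-box height, default 27%) is split at the per-row mask midline
into MCA/LCA, and the remaining region into MPA/LPA, with the medial side
chosen from the foot side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from skimage import measure

from .thermogram import Thermogram, ValidationError

__all__ = [
    "BACKGROUND", "MPA", "LPA", "MCA", "LCA",
    "AngiosomeMap", "AngiosomeTemps", "TCIResult", "DEFAULT_BOUNDARIES",
    "partition_angiosomes", "angiosome_means", "compute_tci",
    "assign_level", "grade_thermogram",
]

BACKGROUND, MPA, LPA, MCA, LCA = 0, 1, 2, 3, 4
REGION_NAMES = {MPA: "MPA", LPA: "LPA", MCA: "MCA", LCA: "LCA"}

#: default class cut points (°C) for the five change levels; the original
#: population-derived cut points are not public, so these equally spaced
#: values ship as replaceable configuration.
DEFAULT_BOUNDARIES: Tuple[float, float, float, float] = (1.0, 2.0, 3.0, 4.0)


@dataclass
class AngiosomeMap:
    """Label image over the foot mask with values in {BACKGROUND..LCA}."""

    labels: np.ndarray

    def region_mask(self, region: int) -> np.ndarray:
        return self.labels == region


@dataclass
class AngiosomeTemps:
    """Mean temperature (°C) of each of the four plantar angiosomes."""

    mpa: float
    lpa: float
    mca: float
    lca: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mpa, self.lpa, self.mca, self.lca], dtype=float)


@dataclass
class TCIResult:
    tci: float
    level: int
    boundaries_used: Tuple[float, ...] = field(default=DEFAULT_BOUNDARIES)


def partition_angiosomes(
    mask: np.ndarray,
    side: str = "right",
    heel_fraction: float = 0.27,
) -> AngiosomeMap:
    """Split a foot mask into the four plantar angiosome territories.

    The proximal ``heel_fraction`` of the bounding-box rows forms the heel
    band (MCA medial / LCA lateral); the rest is MPA medial / LPA lateral.
    Rows are split at the midline of each row's mask extent.  For a right
    foot imaged sole-up the medial side is at lower column indices; for a
    left foot at higher ones.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty foot mask")
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    if measure.label(mask, connectivity=2).max() != 1:
        raise ValidationError("foot mask must be a single connected region")

    rows = np.flatnonzero(mask.any(axis=1))
    r0, r1 = rows[0], rows[-1]
    height = r1 - r0 + 1
    n_heel = int(round(heel_fraction * height))
    heel_start = r1 + 1 - n_heel

    labels = np.zeros(mask.shape, dtype=np.int8)
    cols = np.arange(mask.shape[1])
    for r in range(r0, r1 + 1):
        row = mask[r]
        if not row.any():
            continue
        rc = np.flatnonzero(row)
        mid = (rc[0] + rc[-1]) / 2.0
        medial = cols < mid if side == "right" else cols > mid
        in_heel = r >= heel_start
        labels[r, row & medial] = MCA if in_heel else MPA
        labels[r, row & ~medial] = LCA if in_heel else LPA
    return AngiosomeMap(labels=labels)


def angiosome_means(t: Thermogram, a: AngiosomeMap) -> AngiosomeTemps:
    """Arithmetic mean temperature over each angiosome region."""
    if a.labels.shape != t.temps.shape:
        raise ValidationError("angiosome map shape differs from thermogram")
    means = {}
    for region, name in REGION_NAMES.items():
        sel = a.labels == region
        if not sel.any():
            raise ValidationError(f"angiosome region {name} is empty")
        means[name.lower()] = float(t.temps[sel].mean())
    return AngiosomeTemps(**means)


def compute_tci(
    subject: AngiosomeTemps,
    reference: AngiosomeTemps,
    absolute: bool = False,
) -> float:
    """Thermal Change Index: mean over angiosomes of (reference - subject).

    The signed convention is control minus subject, so a subject hotter
    than the reference yields a negative TCI.  With ``absolute=True`` the
    per-angiosome differences are taken in magnitude before averaging.
    """
    diff = reference.as_array() - subject.as_array()
    if absolute:
        diff = np.abs(diff)
    return float(diff.mean())


def assign_level(
    tci: float,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    signed: bool = False,
) -> int:
    """Grade a TCI value into one of five change levels.

    Level is 1 plus the number of boundaries strictly below ``|tci|``
    (or below ``tci`` itself in signed mode).  Boundaries must be strictly
    increasing and of length 4.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.ndim != 1 or len(b) != 4 or not np.all(np.diff(b) > 0):
        raise ValidationError("boundaries must be 4 strictly increasing values")
    value = tci if signed else abs(tci)
    return 1 + int(np.sum(b < value))


def grade_thermogram(
    t: Thermogram,
    reference: AngiosomeTemps,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    heel_fraction: float = 0.27,
) -> TCIResult:
    """Full grading pipeline: partition, mean temperatures, TCI, level."""
    if t.mask is None:
        raise ValidationError("thermogram has no foot mask")
    amap = partition_angiosomes(t.mask, side=t.side, heel_fraction=heel_fraction)
    subject = angiosome_means(t, amap)
    tci = compute_tci(subject, reference)
    return TCIResult(tci=tci, level=assign_level(tci, boundaries),
                     boundaries_used=tuple(boundaries))
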