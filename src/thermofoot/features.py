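"""ROI feature extraction and patch augmentation.

The classical classifiers consume a five-element feature vector describing
the segmented hottest region: pixel count, mean gray value, variance,
the maximum fuzzy entropy reached by the segmentation, and a gray-level
index value.  "Index value" is implemented as the modal gray level of the
ROI by default, with the ROI's segment index available as an alternative.

Patches are square tiles cut on a regular grid and kept when the foot
mask covers at least a minimum fraction of the tile.  Augmentation
produces the seven dihedral variants listed for patch-based training:
the original, rotations by 90/180/270 degrees, and horizontal, vertical
and combined flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .fuzzy import SegmentationResult
from .thermogram import GrayImage, ValidationError

__all__ = ["FeatureVector", "PatchSet", "extract_features", "extract_patches", "augment",
           "AUGMENT_ORDER"]

#: deterministic ordering of the seven augmentation variants
AUGMENT_ORDER: Tuple[str, ...] = ("original", "r90", "r180", "r270", "fh", "fv", "fhv")


@dataclass
class FeatureVector:
    """Five-element descriptor of a segmented ROI."""

    n_pixels: int
    mean_value: float
    variance: float
    max_entropy: float
    index_value: float

    def as_array(self) -> np.ndarray:
        return np.array([self.n_pixels, self.mean_value, self.variance,
                         self.max_entropy, self.index_value], dtype=float)


@dataclass
class PatchSet:
    """Square tiles cut from one source image, with provenance."""

    patches: List[np.ndarray]
    origins: List[Tuple[int, int]]
    source_id: str = ""
    label: int = 1
    transforms: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.patches}
        if len(shapes) > 1:
            raise ValidationError(f"patches have mixed shapes: {shapes}")
        if not self.transforms:
            self.transforms = ["original"] * len(self.patches)

    def __len__(self) -> int:
        return len(self.patches)


def extract_features(
    seg: SegmentationResult,
    img: GrayImage,
    index_mode: str = "modal",
) -> FeatureVector:
    """Compute the five ROI features from a segmentation result.

    ``index_mode='modal'`` reports the modal gray level inside the ROI;
    ``'segment'`` reports the ROI's segment index (the top label).
    Variance is the population variance.
    """
    roi = seg.roi_mask
    if not roi.any():
        raise ValidationError("empty ROI: no pixels in the hottest segment")
    if roi.shape != img.shape:
        raise ValidationError("ROI shape differs from image shape")
    vals = img.pixels[roi]
    if index_mode == "modal":
        index_value = float(np.bincount(vals, minlength=img.levels).argmax())
    elif index_mode == "segment":
        index_value = float(len(seg.thresholds))
    else:
        raise ValidationError(f"unknown index_mode {index_mode!r}")
    return FeatureVector(
        n_pixels=int(roi.sum()),
        mean_value=float(vals.mean()),
        variance=float(vals.var()),
        max_entropy=float(seg.entropy),
        index_value=index_value,
    )


def extract_patches(
    img: np.ndarray | GrayImage,
    mask: Optional[np.ndarray],
    patch_size: int,
    stride: int,
    min_mask_fraction: float = 0.5,
    source_id: str = "",
    label: int = 1,
) -> PatchSet:
    """Cut square tiles on a regular row-major grid.

    A tile at (r, c) covers ``[r, r+patch_size) x [c, c+patch_size)`` and
    is kept when the mask covers at least ``min_mask_fraction`` of it
    (no mask = full coverage).  An empty result only warns.
    """
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    h, w = arr.shape[:2]
    if patch_size > h or patch_size > w:
        raise ValidationError("patch_size exceeds image dimensions")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ValidationError("mask shape differs from image shape")
    patches, origins = [], []
    area = patch_size * patch_size
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            if mask is not None:
                cover = mask[r:r + patch_size, c:c + patch_size].sum() / area
                if cover < min_mask_fraction:
                    continue
            patches.append(arr[r:r + patch_size, c:c + patch_size].copy())
            origins.append((r, c))
    if not patches:
        warnings.warn("no patch satisfied the mask-coverage requirement", stacklevel=2)
    return PatchSet(patches=patches, origins=origins, source_id=source_id, label=label)


_TRANSFORMS = {
    "original": lambda x: x,
    "r90": lambda x: np.rot90(x, 1),
    "r180": lambda x: np.rot90(x, 2),
    "r270": lambda x: np.rot90(x, 3),
    "fh": lambda x: np.fliplr(x),
    "fv": lambda x: np.flipud(x),
    "fhv": lambda x: np.flipud(np.fliplr(x)),
}


def augment(p: PatchSet) -> PatchSet:
    """Expand every patch into its 7 rotation/flip variants.

    Output order per input patch follows :data:`AUGMENT_ORDER`; origins,
    source and label are inherited.  Purely geometric, so it applies to
    gray-valued and temperature-valued patches alike.  Requires square
    patches (rotations must preserve shape).
    """
    for patch in p.patches:
        if patch.shape[0] != patch.shape[1]:
            raise ValidationError("augmentation requires square patches")
    patches, origins, transforms = [], [], []
    for patch, origin in zip(p.patches, p.origins):
        for name in AUGMENT_ORDER:
            patches.append(np.ascontiguousarray(_TRANSFORMS[name](patch)))
            origins.append(origin)
            transforms.append(name)
    return PatchSet(patches=patches, origins=origins, source_id=p.source_id,
                    label=p.label, transforms=transforms)
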