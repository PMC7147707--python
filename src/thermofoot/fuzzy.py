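"""Fuzzy-entropy multilevel thresholding optimised with Differential Evolution.

The gray-level histogram is partitioned into ``n`` overlapping fuzzy
segments described by complementary trapezoidal membership functions.
Segment ``i`` is parameterized by a breakpoint pair ``(a_i, c_i)``: its
membership is 1 up to ``a_i``, descends linearly to 0 at ``c_i``, and the
next segment's membership rises complementarily, so the memberships form
a partition of unity at every gray level.  The 2(n-1) breakpoints are
chosen to maximize the total fuzzy entropy

    P_i = sum_k p_k mu_i(k)
    H_i = -sum_k (p_k mu_i(k) / P_i) ln(p_k mu_i(k) / P_i)
    H   = sum_i H_i / (n ln L)        (normalized form, default)

with a seeded DE/rand/1/bin optimizer.  Candidate vectors are repaired by
clipping to [0, L-1] and sorting, and are rounded to integer gray levels
inside the objective so the search space matches exhaustive integer
search.  The n-1 crisp thresholds sit at the middle of each fuzzy-set
overlap, T_i = round((a_i + c_i) / 2).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure

from .thermogram import GrayImage, ValidationError

__all__ = [
    "Histogram", "FuzzyPartition", "ThresholdSet", "SegmentationResult",
    "DEConfig", "compute_histogram", "membership", "membership_matrix",
    "total_fuzzy_entropy", "optimize_partition", "extract_thresholds",
    "segment", "select_segmentation_level", "exhaustive_best_partition",
]


@dataclass
class Histogram:
    """Normalized gray-level frequency vector of length ``levels``."""

    probs: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or len(self.probs) != self.levels:
            raise ValidationError("probs must be a vector of length `levels`")
        if (self.probs < 0).any():
            raise ValidationError("negative histogram probability")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValidationError("histogram probabilities must sum to 1")


@dataclass
class FuzzyPartition:
    """Breakpoints (a_1, c_1, ..., a_{n-1}, c_{n-1}) of n fuzzy segments."""

    n_segments: int
    breakpoints: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if self.n_segments < 2:
            raise ValidationError("need at least 2 segments")
        if len(self.breakpoints) != 2 * (self.n_segments - 1):
            raise ValidationError("expected 2(n-1) breakpoints")
        if (np.diff(self.breakpoints) < 0).any():
            raise ValidationError("breakpoints must be sorted non-decreasing")
        if self.breakpoints.min() < 0 or self.breakpoints.max() > self.levels - 1:
            raise ValidationError("breakpoints outside [0, L-1]")

    @property
    def pairs(self) -> np.ndarray:
        """(n-1, 2) array of (a_i, c_i) pairs."""
        return self.breakpoints.reshape(-1, 2)


@dataclass
class ThresholdSet:
    """Sorted integer thresholds; n-1 cut points define n segments."""

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.int64)
        if len(self.thresholds) and (np.diff(self.thresholds) <= 0).any():
            raise ValidationError("thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass
class SegmentationResult:
    labels: np.ndarray
    thresholds: ThresholdSet
    entropy: float
    roi_mask: np.ndarray
    partition: Optional[FuzzyPartition] = None
    #: populated by select_segmentation_level: {n_segments: entropy}
    entropy_table: Dict[int, float] = field(default_factory=dict)
    warning: Optional[str] = None


@dataclass(frozen=True)
class DEConfig:
    """DE/rand/1/bin hyperparameters (robust defaults, all overridable)."""

    population_size: int = 30
    mutation_factor: float = 0.5
    crossover_rate: float = 0.9
    generations: int = 150
    seed: int = 0
    strategy: str = "rand1bin"

    def __post_init__(self) -> None:
        if not 0 < self.mutation_factor <= 2:
            raise ValidationError("mutation_factor must be in (0, 2]")
        if not 0 <= self.crossover_rate <= 1:
            raise ValidationError("crossover_rate must be in [0, 1]")
        if self.population_size < 4:
            raise ValidationError("population_size must be >= 4")
        if self.strategy != "rand1bin":
            raise ValidationError("only the rand1bin strategy is implemented")


def compute_histogram(img: GrayImage, restrict_to: Optional[np.ndarray] = None) -> Histogram:
    """Normalized histogram of a gray image, optionally under a mask."""
    pixels = img.pixels
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to, dtype=bool)
        if restrict_to.shape != pixels.shape:
            raise ValidationError("mask shape differs from image shape")
        if not restrict_to.any():
            raise ValidationError("empty mask")
        pixels = pixels[restrict_to]
    counts = np.bincount(pixels.ravel(), minlength=img.levels).astype(float)
    return Histogram(probs=counts / counts.sum(), levels=img.levels)


def membership_matrix(p: FuzzyPartition, levels: Optional[int] = None) -> np.ndarray:
    """(n, L) matrix of membership degrees at every gray level.

    Row i is mu_i evaluated at k = 0..L-1.  Memberships are piecewise
    linear, clipped to [0, 1], and complementary across consecutive
    segments, so columns sum to 1 exactly.
    """
    L = levels or p.levels
    k = np.arange(L, dtype=float)
    pairs = p.pairs
    n = p.n_segments

    def falling(a: float, c: float) -> np.ndarray:
        # 1 below a, 0 above c, linear in between; step when a == c
        if c == a:
            return (k <= a).astype(float)
        return np.clip((c - k) / (c - a), 0.0, 1.0)

    mu = np.empty((n, L))
    prev_fall = falling(*pairs[0])
    mu[0] = prev_fall
    for i in range(1, n - 1):
        fall = falling(*pairs[i])
        mu[i] = fall - prev_fall
        prev_fall = fall
    mu[n - 1] = 1.0 - prev_fall
    return mu


def membership(p: FuzzyPartition, k: int) -> np.ndarray:
    """Membership degrees of gray level ``k`` in each of the n segments."""
    if not 0 <= k <= p.levels - 1:
        raise ValidationError(f"gray level {k} outside [0, {p.levels - 1}]")
    return membership_matrix(p)[:, int(k)].copy()


def total_fuzzy_entropy(h: Histogram, p: FuzzyPartition, normalize: bool = True) -> float:
    """Total fuzzy entropy of a histogram under a fuzzy partition.

    Normalized by ``n ln L`` by default so that values are comparable
    across different segment counts; ``normalize=False`` returns the raw
    sum of per-segment Shannon entropies.
    """
    if h.levels != p.levels:
        raise ValidationError("histogram and partition use different L")
    mu = membership_matrix(p)
    return _entropy_from_mu(h.probs, mu, p.n_segments, h.levels, normalize)


def _entropy_from_mu(probs: np.ndarray, mu: np.ndarray, n: int, L: int,
                     normalize: bool = True) -> float:
    w = probs[None, :] * mu                      # (n, L) fuzzy mass
    P = w.sum(axis=1)                            # per-segment mass
    if not (P > 0).any():
        raise ValidationError("empty histogram: all segment masses are zero")
    H = 0.0
    for i in range(n):
        if P[i] <= 0:
            continue
        q = w[i][w[i] > 0] / P[i]
        H -= float(np.sum(q * np.log(q)))
    return H / (n * np.log(L)) if normalize else H


def _objective(probs: np.ndarray, n: int, L: int):
    """Entropy of an integer-rounded, repaired breakpoint vector."""

    def f(x: np.ndarray) -> float:
        b = np.sort(np.clip(np.round(x), 0, L - 1))
        p = FuzzyPartition(n_segments=n, breakpoints=b, levels=L)
        return _entropy_from_mu(probs, membership_matrix(p), n, L)

    return f


def optimize_partition(h: Histogram, n_segments: int, cfg: DEConfig = DEConfig()) -> FuzzyPartition:
    """Maximize total fuzzy entropy over breakpoints with DE/rand/1/bin.

    Candidates live in [0, L-1]^(2(n-1)); infeasible vectors are repaired
    by clipping and sorting rather than rejected, and the objective rounds
    them to integer gray levels.  Deterministic for a fixed ``cfg.seed``.
    """
    if n_segments < 2:
        raise ValidationError("n_segments must be >= 2")
    L = h.levels
    dim = 2 * (n_segments - 1)
    if dim > L:
        raise ValidationError(f"{n_segments} segments need {dim} breakpoints but L={L}")

    rng = np.random.default_rng(cfg.seed)
    obj = _objective(h.probs, n_segments, L)
    npop, F, CR = cfg.population_size, cfg.mutation_factor, cfg.crossover_rate

    pop = np.sort(rng.uniform(0, L - 1, size=(npop, dim)), axis=1)
    fitness = np.array([obj(x) for x in pop])

    for _ in range(cfg.generations):
        for i in range(npop):
            r1, r2, r3 = rng.choice([j for j in range(npop) if j != i], size=3, replace=False)
            mutant = pop[r1] + F * (pop[r2] - pop[r3])
            cross = rng.random(dim) < CR
            cross[rng.integers(dim)] = True
            trial = np.where(cross, mutant, pop[i])
            trial = np.sort(np.clip(trial, 0, L - 1))    # repair
            f_trial = obj(trial)
            if f_trial >= fitness[i]:
                pop[i], fitness[i] = trial, f_trial

    best = pop[int(np.argmax(fitness))]
    best = np.sort(np.clip(np.round(best), 0, L - 1))
    return FuzzyPartition(n_segments=n_segments, breakpoints=best, levels=L)


def exhaustive_best_partition(h: Histogram, n_segments: int = 2) -> Tuple[FuzzyPartition, float]:
    """Global optimum by brute force over all integer breakpoint tuples.

    Only practical for small L and n; serves as the independent check of
    the DE optimizer.
    """
    L = h.levels
    dim = 2 * (n_segments - 1)
    best, best_h = None, -np.inf
    for combo in itertools.combinations_with_replacement(range(L), dim):
        p = FuzzyPartition(n_segments=n_segments, breakpoints=np.array(combo, float), levels=L)
        val = _entropy_from_mu(h.probs, membership_matrix(p), n_segments, L)
        if val > best_h:
            best, best_h = p, val
    return best, best_h


def extract_thresholds(p: FuzzyPartition) -> ThresholdSet:
    """Crisp thresholds at the middle of each fuzzy-set overlap.

    ``T_i = round((a_i + c_i) / 2)``; duplicates after rounding are
    repaired by incrementing upward so the set stays strictly increasing.
    """
    mids = np.round(p.pairs.mean(axis=1)).astype(np.int64)
    mids = np.clip(mids, 1, p.levels - 2)
    for i in range(1, len(mids)):
        if mids[i] <= mids[i - 1]:
            mids[i] = mids[i - 1] + 1
    return ThresholdSet(thresholds=mids)


def segment(
    img: GrayImage,
    t: ThresholdSet,
    mask: Optional[np.ndarray] = None,
    entropy: float = float("nan"),
    partition: Optional[FuzzyPartition] = None,
) -> SegmentationResult:
    """Label pixels by threshold bin; ROI is the hottest segment.

    A pixel's label is the number of thresholds strictly below its gray
    value, so gray <= T_1 gives label 0.  The ROI mask is the top segment
    intersected with the foot mask (when given).
    """
    th = t.thresholds
    if len(th) and (th.min() < 0 or th.max() > img.levels - 1):
        raise ValidationError("thresholds outside [0, L-1]")
    labels = np.searchsorted(th, img.pixels.ravel(), side="left").reshape(img.shape)
    roi = labels == len(th)
    if mask is not None:
        roi = roi & np.asarray(mask, dtype=bool)
    return SegmentationResult(labels=labels, thresholds=t, entropy=entropy,
                              roi_mask=roi, partition=partition)


def segment_thermogram(
    t,
    n_segments: int = 3,
    cfg: DEConfig = DEConfig(),
    levels: int = 256,
) -> SegmentationResult:
    """Standard pipeline: quantize, optimize the partition, segment.

    The histogram is restricted to the foot mask when the thermogram has
    one, so the fuzzy segments describe plantar structure (periphery,
    base, hot region) rather than being dominated by the cold background;
    without a mask the background forms its own segment and ``n_segments``
    should be raised by one.
    """
    from .thermogram import to_gray

    img = to_gray(t, levels=levels)
    h = compute_histogram(img, restrict_to=t.mask)
    p = optimize_partition(h, n_segments, cfg)
    return segment(img, extract_thresholds(p), mask=t.mask,
                   entropy=total_fuzzy_entropy(h, p), partition=p)


def _roi_acceptable(roi: np.ndarray, total: int, min_fraction: float) -> bool:
    if roi.sum() < max(1, min_fraction * total):
        return False
    return measure.label(roi, connectivity=2).max() == 1


def select_segmentation_level(
    img: GrayImage,
    candidates: Sequence[int],
    cfg: DEConfig = DEConfig(),
    mask: Optional[np.ndarray] = None,
    min_roi_fraction: float = 0.01,
) -> SegmentationResult:
    """Segment at several candidate segment counts and pick one.

    The selection trades entropy against ROI usability: a one-threshold
    split often maximizes entropy yet yields a shapeless ROI.  The default
    rule picks the largest ``n`` whose hottest-segment ROI is a single
    connected region covering at least ``min_roi_fraction`` of the
    (masked) area; if no candidate qualifies it falls back to the
    max-entropy candidate and records a warning.  The per-n entropies are
    reported in ``entropy_table`` either way.
    """
    if not candidates:
        raise ValidationError("no candidate segment counts")
    results: Dict[int, SegmentationResult] = {}
    table: Dict[int, float] = {}
    h = compute_histogram(img, restrict_to=None)
    total = img.pixels.size if mask is None else int(np.asarray(mask, bool).sum())
    for n in sorted(set(candidates)):
        p = optimize_partition(h, n, cfg)
        entropy = total_fuzzy_entropy(h, p)
        res = segment(img, extract_thresholds(p), mask=mask, entropy=entropy, partition=p)
        results[n], table[n] = res, entropy

    chosen = None
    for n in sorted(results, reverse=True):
        if _roi_acceptable(results[n].roi_mask, total, min_roi_fraction):
            chosen = results[n]
            break
    if chosen is None:
        n_best = max(table, key=table.get)
        chosen = results[n_best]
        chosen.warning = "no candidate produced a usable ROI; max-entropy fallback"
        warnings.warn(chosen.warning, stacklevel=2)
    chosen.entropy_table = table
    return chosen
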