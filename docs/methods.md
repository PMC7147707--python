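# Methods

This note records the models implemented in `thermofoot`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Fuzzy-entropy multilevel thresholding

A gray image with *L* levels is summarized by its normalized histogram
*p*.  A partition into *n* fuzzy segments is parameterized by 2(n−1)
breakpoints a₁ ≤ c₁ ≤ … ≤ a_{n−1} ≤ c_{n−1} in [0, L−1].  Membership
μ₁ is 1 up to a₁ and falls linearly to 0 at c₁; each next membership
rises complementarily, is 1 on [cᵢ₋₁, aᵢ] and falls across (aᵢ, cᵢ);
μₙ mirrors μ₁.  Because consecutive memberships are complements on each
overlap, Σᵢ μᵢ(k) = 1 holds exactly at every gray level — the partition
of unity is structural, not a constraint to be checked.  A pair with
aᵢ = cᵢ degenerates to a crisp step, so crisp thresholding is a special
case of the search space.

The objective is the total fuzzy entropy: per segment the Shannon
entropy of the membership-weighted conditional distribution,

P_i = Σ_k p_k μ_i(k),  H_i = −Σ_k (p_k μ_i(k)/P_i) ln(p_k μ_i(k)/P_i),

summed over segments and (by default) normalized by n·ln L so values at
different n are on one scale; a raw mode exists (`normalize=False`).
Segments with zero mass contribute nothing; an all-zero histogram is
rejected.

### Optimizer

Differential Evolution, strategy rand/1/bin: population 30, mutation
factor F = 0.5, crossover rate CR = 0.9, 150 generations, all seeded
and configurable.  These are standard robust DE settings for
low-dimensional continuous problems; the search space here is 2(n−1) ≤ 8
dimensions.  Infeasible candidates are repaired by clipping to [0, L−1]
and sorting rather than rejected, which keeps the population feasible
without biasing the sampler.  Inside the objective, candidates are
rounded to integer gray levels; consequently the optimum is directly
comparable with exhaustive search over integer breakpoint tuples, and
the test suite checks that at L = 32, n = 2 the DE optimum equals the
global optimum of all 528 integer pairs to 1e−9 (in practice exactly).

Thresholds are extracted at the middle of each fuzzy overlap,
Tᵢ = round((aᵢ+cᵢ)/2), clipped to [1, L−2]; duplicates after rounding
are repaired by incrementing upward, a deterministic tie-break that
preserves strict ordering.  A pixel's segment label is the number of
thresholds strictly below its gray value.

### Histogram scope

When a foot mask is available, the standard pipeline
(`segment_thermogram`) computes the histogram over plantar pixels only.
This matters: the cold background is a massive near-degenerate mode, and
because the objective sums *unweighted* per-segment entropies, a
full-image 3-segment optimum prefers spending one segment on the
background spike and merging the foot base with the hot region (their
union has the largest conditional entropy).  Restricted to the foot, the
three segments align with periphery / base / hot region and the hottest
segment is a usable ROI.  Without a mask, raise `n_segments` by one and
expect the bottom segment to absorb the background.

### Choosing the number of segments

`select_segmentation_level` runs the optimizer for each candidate n,
reports the entropy table, and by default picks the largest n whose ROI
is a single connected region covering at least `min_roi_fraction`
(default 1%) of the masked area, falling back to the max-entropy
candidate with a warning.  Entropy alone always favors the coarsest
split (it is highest for one threshold), but the coarse ROI is
shapeless; the connectedness rule is our formalization of "high entropy
*and* a defined ROI pattern", and it is explicitly a heuristic —
substitute your own rule where a different usability notion applies.

## Angiosomes and the Thermal Change Index

The sole is divided into the territories of the medial plantar (MPA),
lateral plantar (LPA), medial calcaneal (MCA) and lateral calcaneal
(LCA) arteries.  Published angiosome atlases are drawings, not
coordinates, so the partition is a configurable proportional rule: the
proximal `heel_fraction` (default 0.27) of the bounding-box rows forms
the heel band, split at each row's mask midline into MCA (medial) and
LCA (lateral); the remaining rows split the same way into MPA/LPA.  The
medial side follows the declared foot side, and mirroring the mask while
flipping the side mirrors the labels exactly.  The 27% default places
the heel band proportionally where calcaneal territories sit on adult
feet; both it and the midline rule are tunable to any atlas.

TCI is the signed mean over the four angiosomes of (control reference −
subject):  a subject hotter than the reference gives negative TCI.  The
index is linear under uniform temperature shifts.  Grading uses |TCI|
because the five categories express *degree of change*, not direction; a
signed mode is available (`signed=True`), and an absolute-difference
variant of the index itself (`absolute=True`) for users who want
per-angiosome magnitudes.  The five-class cut points ship as
configuration, default (1, 2, 3, 4) °C, equally spaced; the original
population-derived boundaries are not public, so supply your own for
fidelity to any particular reference cohort.

## Synthetic thermograms

The generator is the test bed for every downstream stage.  The foot
outline is the union of a forefoot and a heel ellipse on a default
120×60 grid.  The control ("butterfly") field is:

* background at 20 °C (cold, narrow mode, clearly separable);
* foot base at 30 °C with a 1.5 °C ramp toward the outline over ~4 px
  (cooler periphery);
* a smooth low-frequency texture (Gaussian random field, sd 0.5 °C)
  emulating physiological variation — without it the plantar histogram
  is a set of bare spikes no histogram method behaves sensibly on;
* an arch-band plateau at +3.5 °C on the medial side (the butterfly);
* Gaussian smoothing (σ = 1.2 px) and white sensor noise (sd 0.2 °C).

The diabetic-type ("hot region") field drops the arch and adds
`hot_region_count` Gaussian blobs (σ ≈ 0.09·max(H, W)) at seeded
positions inside the mask.  The blob amplitude is calibrated by
bisection on the noiseless field until the TCI against the generator's
own control reference hits the midpoint of the requested class interval;
noise is added afterwards, so noisy realizations can straddle a boundary
exactly as repeat acquisitions of a borderline patient would.  A
requested class that cannot be reached (e.g. class 5 with zero blobs)
raises a generation error naming the violated bound.

What the generator does **not** emulate: toe geometry, inter-subject
shape variation, ulcer texture, camera vignetting or calibration drift,
and bilateral asymmetry.  Tests passing on this generator therefore
demonstrate algorithmic correctness (the pipeline recovers structure it
is pointed at, indices compute what their formulas say), not clinical
performance on real thermograms.

## Patches, augmentation, features

Patches are square tiles on a regular row-major grid, kept when the
mask covers at least `min_mask_fraction` of the tile; the grid replaces
expert patch selection for reproducibility (supply coordinates manually
for parity with hand-picked patches).  Augmentation emits exactly seven
variants per patch in a fixed order — original, rotations by 90/180/270,
horizontal, vertical and combined flips — and is purely geometric, so it
applies identically to gray and temperature patches.

The ROI feature vector is (n_pixels, mean, population variance, max
entropy, index value).  "Index value" is under-determined in common
usage; we default to the modal gray level of the ROI, with the ROI's
segment index available via `index_mode="segment"`, and the choice is
recorded in the vector's metadata position (the last element).

## The convolutional network

The nine-layer stack is fixed: conv 7×7/32, pool 3×3 s2, conv 1×1/64,
conv 3×3/64, pool 3×3 s2, conv 3×3/32, pool 2×2 s2, conv 3×3/32, FC to
n_classes.  Reconstructed details, since layer tables rarely state them:
ReLU after every convolution and no batch normalization; convolutions
same-padded (stride 1), pools valid — under this convention a 64×64
input flows 64 → 31 → 15 → 7 and survives the cascade, which is the
reason for the choice; softmax after the FC layer; categorical
cross-entropy loss.  Default input is 64×64×3 with grayscale replicated
across channels.  Training uses Adam (lr 0.001), minibatch 64, up to 100
epochs, with an optional threshold-based early stop.

Initialization is seeded He-uniform for convolutions; the FC layer is
scaled down by 100× with zero bias so the initial prediction is uniform
and the starting loss is ln(n_classes) — useful as a built-in sanity
check and harmless to convergence.  The implementation is plain NumPy
(im2col convolutions, argmax-scatter pooling, full backprop) in float32;
one epoch over 200 patches of 64×64×3 takes ~10 s on one CPU, and
intensity-separable data is learned in 2-4 epochs.

A leakage control is part of the contract: permute all labels, train,
and score validation against the permuted labels.  Scoring against the
*permuted* labels (not the true ones) is essential — predictions on
separable clusters are themselves clustered, and against true labels the
control is an all-or-nothing coin flip rather than a concentration at
chance.

## Classical baselines and evaluation

Each unordered pair of classes forms one binary task (10 for 5 classes),
ordered by decreasing class distance and then descending upper class —
the customary report order.  Per task, 85% trains, 5% is held out for
validation and 10% for testing; cross-validated tables use stratified
k-fold with accumulated confusion counts and pooled scores for AUC.  At
these task sizes the 5% validation portion is a few samples, so it is
*scored and reported*, not used as a stopping monitor: a score-based
stopper saturates instantly on 4 samples and restores near-initial,
underfit weights.  The MLP (one hidden layer of 10 units inside an
input–hidden–output topology, configurable) trains to loss convergence;
the SVM uses a linear kernel.  Features are z-scored on the training
portion — required for scale-sensitive margins, harmless for the MLP.

Metrics follow the standard confusion-matrix forms; accuracy is
(TP+TN)/total.  Zero-denominator metrics are reported as 0 and flagged
by name, never dropped, so table averages remain auditable.  AUC is the
trapezoid over thresholds at every distinct score, which equals the
tied-rank Mann–Whitney statistic; the tests verify this against a
brute-force pair-counting oracle.

## Problem sizes used in the checks

The bundled checks run at deliberately small scale so the whole suite
completes on one CPU in minutes: oracle equivalence at L = 32 over 20
histograms, threshold recovery over 50 seeded two-mode histograms,
1000 random angiosome quadruples, the full {0..10}⁴ confusion-count
grid, 200 AUC instances of ≤ 50 samples, one 200-patch training run and
a 100-patch shuffle control, and 20 seeded butterfly pipelines.  These
sizes are choices, not limits of the method.

## Known limitations

* The entropy objective sums unweighted per-segment entropies; on
  histograms with one dominant degenerate mode the optimum can waste a
  segment on it (see "Histogram scope").
* The angiosome partition is proportional geometry, not an anatomical
  registration; per-subject atlas fitting is out of scope.
* TCI grading needs a control reference; the package computes one from
  its own generator but real cohorts must provide population values.
* The NumPy network is single-threaded and CPU-bound; it is meant for
  patch-scale experiments, not large-scale training.
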