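# thermofoot

Analysis toolkit for **infrared plantar thermograms** in diabetic-foot
screening.  An increase in sole temperature is associated with a higher
risk of ulceration, but diabetic feet show no single spatial pattern, so
the toolkit measures change rather than shape: it isolates the hottest
region of the sole by histogram segmentation, quantifies the deviation
from the healthy reference pattern with an angiosome-based index, and
classifies patches of the thermogram with both classical and
convolutional models.  It is aimed at researchers prototyping
thermogram-analysis pipelines; every stage is importable and testable on
the bundled synthetic-thermogram generator.

## What it computes

**Fuzzy-entropy multilevel thresholding.**  The gray-level histogram
(*L* levels, probabilities *p\_k*) is covered by *n* overlapping
trapezoidal membership functions μ₁…μₙ forming a partition of unity,
parameterized by breakpoint pairs (aᵢ, cᵢ).  The breakpoints maximize
the total fuzzy entropy

  Pᵢ = Σₖ p_k μᵢ(k),  Hᵢ = −Σₖ (p_k μᵢ(k)/Pᵢ) ln(p_k μᵢ(k)/Pᵢ),
  H = Σᵢ Hᵢ / (n ln L)

via a seeded Differential Evolution (DE/rand/1/bin) optimizer with
sort-and-clip repair.  Crisp thresholds sit mid-overlap,
Tᵢ = round((aᵢ+cᵢ)/2); the hottest segment is the region of interest.

**Thermal Change Index (TCI).**  The sole is split into four angiosomes
(MPA, LPA, MCA, LCA).  With control-reference means C and subject means
D,

  TCI = Σ (C\_ang − D\_ang) / 4

whose magnitude is graded into five change levels at configurable cut
points (default 1, 2, 3, 4 °C).

**Classification.**  A five-element ROI feature vector (pixel count,
mean, variance, maximum entropy, gray-level index) feeds linear-SVM and
MLP baselines evaluated one-vs-one (10 pairs for 5 classes) with
sensitivity, specificity, precision, accuracy, F-measure and AUC.  A
nine-layer convolutional network (conv 7×7/32 → pool → conv 1×1/64 →
conv 3×3/64 → pool → conv 3×3/32 → pool → conv 3×3/32 → FC) trains from
scratch on augmented patches (original + 3 rotations + 3 flips) with
Adam, learning rate 0.001, minibatch 64, at most 100 epochs.

## Worked example

```sh
python examples/02_fuzzy_segmentation.py
```

```
n_segments  entropy   thresholds
         2  0.79376   [128]
         3  0.75450   [87, 214]
         4  0.72598   [80, 162, 209]

3-segment ROI (hottest segment): 754 pixels, Jaccard vs planted arch band = 0.90
```

A synthetic control thermogram is quantized to 256 gray levels and the
DE optimizer fits 2-4 fuzzy segments over the plantar histogram.  Total
fuzzy entropy is highest for the coarsest split and falls as segments
are added; the 3-segment thresholds (87, 214) separate the cool
periphery, the foot base and the warm arch, and the hottest segment
recovers 90% (Jaccard 0.90) of the arch band the generator planted.
The other scripts in `examples/` demonstrate thermogram synthesis, TCI
grading (`-2.50 °C → level 3`), patch augmentation (14 patches → 98),
CNN training (first-epoch loss 0.6845 ≈ ln 2, accuracy 1.0 by epoch 4)
and the one-vs-one SVM table.

There is also a thin CLI for shell use:

```sh
thermofoot synth --pattern butterfly --seed 3 --out foot.csv
thermofoot segment --in foot.csv --levels 3 --report entropy.json
```

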