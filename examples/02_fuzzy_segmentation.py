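"""Fuzzy-entropy multilevel thresholding with Differential Evolution.

Quantizes a butterfly thermogram to 256 gray levels, optimizes fuzzy
partitions with 2-4 segments, and reports the total fuzzy entropy, the
extracted thresholds and how well the hottest segment recovers the
planted arch band.
"""

import numpy as np

import thermofoot as tf
from thermofoot.fuzzy import segment_thermogram

spec = tf.SyntheticSpec(seed=0)
t = tf.generate_synthetic(spec)
band = tf.arch_band_mask(spec)
img = tf.to_gray(t, 256)
hist = tf.compute_histogram(img, restrict_to=t.mask)

print("n_segments  entropy   thresholds")
for n in (2, 3, 4):
    p = tf.optimize_partition(hist, n, tf.DEConfig(seed=0))
    thr = tf.extract_thresholds(p)
    entropy = tf.total_fuzzy_entropy(hist, p)
    print(f"{n:>10}  {entropy:.5f}   {thr.thresholds.tolist()}")

res = segment_thermogram(t, n_segments=3, cfg=tf.DEConfig(seed=0))
jac = (res.roi_mask & band).sum() / (res.roi_mask | band).sum()
print(f"\n3-segment ROI (hottest segment): {int(res.roi_mask.sum())} pixels, "
      f"Jaccard vs planted arch band = {jac:.2f}")
print("entropy falls as segments are added; the 3-segment split separates")
print("periphery / base / arch, so its top segment is the hot-region ROI")
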