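"""Patch extraction, 7-fold augmentation and the 5-element ROI features.

Cuts grid patches from a thermogram, expands them with the rotation/flip
augmentation, and extracts the feature vector (pixel count, mean,
variance, max entropy, gray-level index) used by the classical
classifiers.
"""

import thermofoot as tf
from thermofoot.fuzzy import segment_thermogram

spec = tf.SyntheticSpec(pattern="hot_region", target_class=4, seed=9)
t = tf.generate_synthetic(spec)
img = tf.to_gray(t, 256)

patches = tf.extract_patches(img, t.mask, patch_size=24, stride=12,
                             min_mask_fraction=0.8, source_id=t.subject_id, label=4)
augmented = tf.augment(patches)
print(f"{len(patches)} grid patches covering the foot; "
      f"augmentation gives {len(augmented)} ({len(patches)} x 7 variants)")
print(f"variant order per patch: {tf.features.AUGMENT_ORDER}")

seg = segment_thermogram(t, n_segments=3, cfg=tf.DEConfig(seed=9))
fv = tf.extract_features(seg, img)
print("\nROI feature vector (hottest segment):")
print(f"  n_pixels     = {fv.n_pixels}")
print(f"  mean_value   = {fv.mean_value:.2f}  (gray level)")
print(f"  variance     = {fv.variance:.2f}")
print(f"  max_entropy  = {fv.max_entropy:.5f}  (total fuzzy entropy at optimum)")
print(f"  index_value  = {fv.index_value:.0f}  (modal ROI gray level)")
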