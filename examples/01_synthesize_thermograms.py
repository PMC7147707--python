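"""Generate synthetic plantar thermograms and inspect their structure.

Builds one control "butterfly" thermogram (warm medial arch, cooler
periphery, cold background) and one diabetic-type "hot region"
thermogram calibrated to thermal-change class 3, then prints the mean
temperatures that make the two patterns differ.
"""

import numpy as np

import thermofoot as tf

control_spec = tf.SyntheticSpec(pattern="butterfly", seed=1)
control = tf.generate_synthetic(control_spec)
band = tf.arch_band_mask(control_spec)

print("control butterfly thermogram")
print(f"  image {control.shape}, foot pixels {int(control.mask.sum())}")
print(f"  background mean {control.temps[~control.mask].mean():.2f} C")
print(f"  foot (outside arch) mean {control.temps[control.mask & ~band].mean():.2f} C")
print(f"  arch band mean {control.temps[band].mean():.2f} C  <- warmest: the butterfly")

dm_spec = tf.SyntheticSpec(pattern="hot_region", target_class=3, seed=2)
dm = tf.generate_synthetic(dm_spec)
reference = tf.synthetic_reference(dm_spec)
amap = tf.partition_angiosomes(dm.mask, side=dm_spec.side)
tci = tf.compute_tci(tf.angiosome_means(dm, amap), reference)

print("\nhot-region thermogram (requested class 3)")
print(f"  foot mean {dm.temps[dm.mask].mean():.2f} C, max {dm.temps.max():.2f} C")
print(f"  TCI vs control reference: {tci:.2f} C -> level {tf.assign_level(tci)}")
print("  (negative TCI: the subject is hotter than the control reference;")
print("   |TCI| between 2 and 3 C falls in change class 3)")
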