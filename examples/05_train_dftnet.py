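"""Build and train the 9-layer patch-classification network.

Constructs the fixed convolutional stack, prints its structure and
parameter count, then trains it on a small separable patch set and shows
the loss/accuracy trajectory.  Runs in about a minute on one CPU.
"""

import numpy as np

import thermofoot as tf
from thermofoot.dftnet import DFTNetSpec, EarlyStop, TrainConfig
from thermofoot.synthetic import separable_patches

spec = DFTNetSpec(input_shape=(64, 64, 3), n_classes=2)
net = tf.build(spec, seed=0)
print("layer structure:")
for i, row in enumerate(net.structure(), 1):
    print(f"  {i}: {row['type']:<10} kernel={row['kernel']} stride={row['stride']} "
          f"filters={row['filters']}")
print(f"total parameters: {net.param_count()}")

X, y = separable_patches(120, size=64, n_classes=2, seed=0)
hist = tf.train(net, X, y, TrainConfig(
    max_epochs=20, batch_size=64, learning_rate=0.001, seed=0,
    early_stop=EarlyStop("train_accuracy", 0.99)))

print("\nepoch  loss     accuracy")
for e, (l, a) in enumerate(zip(hist["train_loss"], hist["train_accuracy"]), 1):
    print(f"{e:>5}  {l:.4f}   {a:.3f}")
print(f"\nfirst-epoch loss starts near ln(2) = {np.log(2):.4f} (uniform prediction);")
print("intensity-separable patches are learned within a few epochs.")
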