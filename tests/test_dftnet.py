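"""Architecture fidelity, shape arithmetic and training contract.

Unit tests run the full nine-layer stack at a reduced 32x32 input so the
whole file stays fast; the 64x64 training regime is exercised by the
acceptance suite.
"""

import numpy as np
import pytest

import thermofoot as tf
from thermofoot.dftnet import DFTNetSpec, EarlyStop, ShapeError, TrainConfig
from thermofoot.synthetic import separable_patches
from thermofoot.thermogram import ValidationError

SMALL = DFTNetSpec(input_shape=(32, 32, 3), n_classes=2)


@pytest.fixture(scope="module")
def small_net():
    return tf.build(SMALL, seed=0)


class TestArchitecture:
    def test_structure_matches_layer_table(self, small_net):
        rows = small_net.structure()
        expected = [
            ("Conv.", (7, 7), (1, 1), 32),
            ("Max-Pool", (3, 3), (2, 2), None),
            ("Conv.", (1, 1), (1, 1), 64),
            ("Conv.", (3, 3), (1, 1), 64),
            ("Max-Pool", (3, 3), (2, 2), None),
            ("Conv.", (3, 3), (1, 1), 32),
            ("Max-Pool", (2, 2), (2, 2), None),
            ("Conv.", (3, 3), (1, 1), 32),
            ("Full Conn.", None, None, 2),
        ]
        got = [(r["type"], r["kernel"], r["stride"], r["filters"]) for r in rows]
        assert got == expected

    def test_parameter_count_matches_closed_form(self):
        net = tf.build(DFTNetSpec(input_shape=(64, 64, 3), n_classes=2), seed=0)
        expected = ((7 * 7 * 3 + 1) * 32 + (1 * 1 * 32 + 1) * 64
                    + (3 * 3 * 64 + 1) * 64 + (3 * 3 * 64 + 1) * 32
                    + (3 * 3 * 32 + 1) * 32 + (7 * 7 * 32 + 1) * 2)
        assert net.param_count() == expected

    def test_pooling_cascade_shapes(self):
        net = tf.build(DFTNetSpec(input_shape=(64, 64, 3), n_classes=3), seed=0)
        spatial = [s[:2] for s in net._shapes]
        assert (31, 31) in spatial and (15, 15) in spatial and (7, 7) in spatial

    def test_too_small_input_names_offending_layer(self):
        with pytest.raises(ShapeError, match="Max-Pool"):
            tf.build(DFTNetSpec(input_shape=(8, 8, 3), n_classes=2), seed=0)

    def test_same_seed_gives_identical_initial_weights(self):
        a = tf.build(SMALL, seed=9)
        b = tf.build(SMALL, seed=9)
        for la, lb in zip(a.layers, b.layers):
            if hasattr(la, "W"):
                np.testing.assert_array_equal(la.W, lb.W)


class TestForward:
    def test_output_is_probability_vector(self, small_net, rng):
        x = rng.random((4, 32, 32, 3), dtype=np.float32)
        p = small_net.forward(x)
        assert p.shape == (4, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all() and (p <= 1).all()

    def test_predict_is_deterministic(self, small_net, rng):
        x = rng.random((3, 32, 32, 3), dtype=np.float32)
        p1, l1 = tf.predict(small_net, x)
        p2, l2 = tf.predict(small_net, x)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(l1, l2)
        assert set(l1) <= {1, 2}

    def test_wrong_input_shape_rejected(self, small_net, rng):
        with pytest.raises(ShapeError):
            small_net.forward(rng.random((2, 16, 16, 3)))


class TestTraining:
    def test_initial_loss_near_log_n_classes(self):
        X, y = separable_patches(40, 32, 2, seed=0)
        net = tf.build(SMALL, seed=0)
        p = net.forward(X)
        loss = -np.mean(np.log(p[np.arange(len(y)), y - 1]))
        assert loss == pytest.approx(np.log(2), rel=0.05)

    def test_zero_learning_rate_leaves_weights_and_loss_flat(self):
        X, y = separable_patches(20, 32, 2, seed=1)
        net = tf.build(SMALL, seed=1)
        w_before = net.layers[0].W.copy()
        hist = tf.train(net, X, y, TrainConfig(max_epochs=2, learning_rate=0.0, seed=0))
        np.testing.assert_array_equal(net.layers[0].W, w_before)
        assert hist["train_loss"][0] == pytest.approx(hist["train_loss"][1], abs=1e-6)

    def test_separable_data_is_learned(self):
        X, y = separable_patches(60, 32, 2, seed=2)
        net = tf.build(SMALL, seed=2)
        hist = tf.train(net, X, y, TrainConfig(
            max_epochs=15, seed=2, early_stop=EarlyStop("train_accuracy", 0.95)))
        assert hist["train_accuracy"][-1] >= 0.95
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_training_is_reproducible_under_fixed_seed(self):
        X, y = separable_patches(24, 32, 2, seed=3)
        h1 = tf.train(tf.build(SMALL, seed=4), X, y, TrainConfig(max_epochs=2, seed=4))
        h2 = tf.train(tf.build(SMALL, seed=4), X, y, TrainConfig(max_epochs=2, seed=4))
        assert h1["train_loss"] == h2["train_loss"]

    def test_empty_and_single_class_datasets_rejected(self, small_net):
        with pytest.raises(ValidationError):
            tf.train(small_net, np.empty((0, 32, 32, 3)), np.empty(0, dtype=int))
        X, _ = separable_patches(8, 32, 2, seed=0)
        with pytest.raises(ValidationError):
            tf.train(small_net, X, np.ones(8, dtype=int))

    def test_out_of_range_labels_rejected(self, small_net):
        X, _ = separable_patches(8, 32, 2, seed=0)
        with pytest.raises(ValidationError):
            tf.train(small_net, X, np.array([1, 2, 3, 1, 2, 3, 1, 2]))
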