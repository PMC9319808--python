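"""Classifier contracts: architecture geometry, augmentation, training
protocol bookkeeping, metrics and gradient access."""

import numpy as np
import pytest

from xbias import cnn, nn


class _StubModel:
    """Minimal stand-in exposing predict_proba for metric tests."""
    dtype = np.float32

    def __init__(self, proba):
        self._p = np.asarray(proba, dtype=float)

    def predict_proba(self, x, batch=64):
        return np.c_[1 - self._p, self._p]


# -- architecture ------------------------------------------------------

def test_table_architecture_sizes_at_256_input():
    """Stem 128x128, stage-2 input 64x64, stage-3 output 32x32."""
    m = cnn.build_model(cnn.ModelSpec(input_size=256), seed=0)
    x = np.zeros((1, 256, 256, 3), dtype=np.float32)
    stem = m.conv1.forward(x)
    assert stem.shape == (1, 128, 128, 32)
    logits = m.forward(x)
    assert m._taps["conv3"].shape == (1, 32, 32, 64)
    assert m._taps["fc16"].shape == (1, 16)
    assert logits.shape == (1, 2)


def test_stride_arithmetic_at_96_input_and_param_count_invariance():
    m96 = cnn.build_model(cnn.ModelSpec(96), seed=0)
    m96.forward(np.zeros((1, 96, 96, 3), dtype=np.float32))
    assert m96._taps["conv3"].shape == (1, 12, 12, 64)
    count = lambda m: sum(p.size for l in m.param_layers()
                          for p in l.params.values())
    m256 = cnn.build_model(cnn.ModelSpec(256), seed=0)
    assert count(m96) == count(m256)  # fully convolutional body


def test_softmax_probabilities_normalized():
    m = cnn.build_model(cnn.ModelSpec(32), seed=1)
    p = m.predict_proba(np.random.default_rng(0).random((5, 32, 32, 3)))
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_indivisible_input_size_rejected():
    with pytest.raises(ValueError):
        cnn.build_model(cnn.ModelSpec(100))


def test_save_load_roundtrip(tmp_path, toy_model):
    path = str(tmp_path / "m.npz")
    toy_model.save(path)
    back = cnn.TileCNN.load(path)
    x = np.random.default_rng(1).random((2, 32, 32, 3)).astype(np.float32)
    assert np.allclose(toy_model.forward(x), back.forward(x), atol=1e-6)


# -- augmentation ------------------------------------------------------

def test_augment_disabled_is_identity(rng):
    img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
    cfg = cnn.AugmentConfig(flip=False, rotate=False, hsv_jitter=False,
                            cutout=False)
    assert np.array_equal(cnn.augment(img, np.random.default_rng(0), cfg), img)


def test_cutout_region_is_exactly_grey127(rng):
    img = (rng.random((32, 32, 3)) * 200).astype(np.uint8)
    cfg = cnn.AugmentConfig(flip=False, rotate=False, cutout=True,
                            cutout_prob=1.0, cutout_frac=(0.5, 0.5))
    out = cnn.augment(img, np.random.default_rng(3), cfg)
    assert (out == 127).all(axis=-1).sum() >= 16 * 16


def test_horizontal_flip_is_an_involution(rng):
    img = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
    assert np.array_equal(img[:, ::-1, :][:, ::-1, :], img)


# -- training protocol -------------------------------------------------

def _toy_data(n=24, size=16, seed=0):
    r = np.random.default_rng(seed)
    x = (r.random((n, size, size, 3)) * 120 + 60).astype(np.uint8)
    y = r.integers(0, 2, n)
    # paint a deterministic cue: white corner square on positives
    x[y == 1, :4, :4, :] = 250
    return x, y


def test_training_learns_a_deterministic_marker_cue():
    x, y = _toy_data(n=48)
    m = cnn.build_model(cnn.ModelSpec(16), seed=2)
    cfg = cnn.TrainConfig(learning_rate=2e-3, max_epochs=60, early_stop=False,
                          seed=0, augment=cnn.AugmentConfig(
                              flip=False, rotate=False, cutout=False))
    cnn.train(m, x, y, x, y, cfg)
    metrics = cnn.evaluate(m, x, y)
    assert metrics.balanced_accuracy == 1.0


def test_early_stopping_patience_counts_epochs_without_improvement():
    x, y = _toy_data(n=8)
    m = cnn.build_model(cnn.ModelSpec(16), seed=3)
    # vanishing learning rate: validation loss never improves after the
    # first epoch, so training stops after exactly patience extra epochs
    cfg = cnn.TrainConfig(learning_rate=1e-12, max_epochs=50, early_stop=True,
                          patience=3, seed=0)
    hist = cnn.train(m, x, y, x, y, cfg)
    assert len(hist) == 4


def test_disabled_early_stopping_runs_every_epoch():
    x, y = _toy_data(n=8)
    m = cnn.build_model(cnn.ModelSpec(16), seed=3)
    cfg = cnn.TrainConfig(learning_rate=1e-12, max_epochs=7, early_stop=False,
                          seed=0)
    assert len(cnn.train(m, x, y, x, y, cfg)) == 7


def test_class_weights_are_inverse_frequency():
    w = cnn.class_weights(np.array([0, 0, 0, 0, 1, 1]))
    assert w[1] / w[0] == pytest.approx(2.0, abs=1e-6)


def test_invalid_train_configs_rejected():
    with pytest.raises(ValueError):
        cnn.TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        cnn.TrainConfig(patience=0)


# -- metrics -----------------------------------------------------------

def test_metrics_from_known_confusion():
    # TP=2, FP=0, FN=1, TN=3
    y = np.array([1, 1, 1, 0, 0, 0])
    proba = np.array([0.9, 0.8, 0.2, 0.1, 0.2, 0.3])
    m = cnn.evaluate(_StubModel(proba), np.zeros((6, 8, 8, 3)), y)
    assert m.confusion == (2, 0, 1, 3)
    assert m.precision == pytest.approx(1.0)
    assert m.recall == pytest.approx(2 / 3, abs=1e-4)
    assert m.balanced_accuracy == pytest.approx(5 / 6, abs=1e-4)


@pytest.mark.parametrize("precision,recall,f1", [
    (0.80, 2 / 3, 0.727),
    (0.75, 1.00, 0.857),
])
def test_f1_matches_reported_precision_recall_pairs(precision, recall, f1):
    assert 2 * precision * recall / (precision + recall) == pytest.approx(
        f1, abs=5e-4)


def test_roc_auc_matches_sklearn_on_random_scores(rng):
    from sklearn.metrics import roc_auc_score
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    s = rng.random(60)
    assert cnn.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-9)


def test_single_class_auc_flagged():
    m = cnn.evaluate(_StubModel([0.9, 0.8]), np.zeros((2, 8, 8, 3)),
                     np.array([1, 1]))
    assert not m.auc_defined and np.isnan(m.auc)


# -- activations and gradients ----------------------------------------

def test_fc16_activation_rows_shape_and_determinism(toy_model, rng):
    x = rng.random((5, 32, 32, 3)).astype(np.float32)
    rows = cnn.activations(toy_model, "fc16", x)
    assert rows.shape == (5, 16)
    dup = cnn.activations(toy_model, "fc16", np.concatenate([x[:1], x[:1]]))
    assert np.array_equal(dup[0], dup[1])


def test_conv_activations_preserve_spatial_layout(toy_model, rng):
    x = rng.random((3, 32, 32, 3)).astype(np.float32)
    maps = cnn.activations(toy_model, "conv3", x)
    assert maps.shape == (3, 4, 4, 64)


def test_unknown_layer_rejected(toy_model):
    with pytest.raises(KeyError):
        cnn.activations(toy_model, "conv9", np.zeros((1, 32, 32, 3)))
    with pytest.raises(KeyError):
        cnn.class_gradient(toy_model, "conv9", 0, np.zeros((1, 32, 32, 3)))


def test_fc16_class_gradient_is_head_weight_column(toy_model, rng):
    x = rng.random((3, 32, 32, 3)).astype(np.float32)
    g = cnn.class_gradient(toy_model, "fc16", 1, x)
    assert np.allclose(g, np.tile(toy_model.out.params["W"][:, 1], (3, 1)),
                       atol=1e-6)
    glo = cnn.class_gradient(toy_model, "fc16", 1, x, target="logodds")
    w = toy_model.out.params["W"]
    assert np.allclose(glo, np.tile(w[:, 1] - w[:, 0], (3, 1)), atol=1e-6)


def test_class_gradient_matches_finite_differences():
    m = cnn.TileCNN(cnn.ModelSpec(16), seed=5, dtype=np.float64)
    rng = np.random.default_rng(6)
    x = rng.random((1, 16, 16, 3))
    g = cnn.class_gradient(m, "conv3", 1, x)[0]
    eps = 1e-6
    m.forward(x)
    base_maps = m._taps["conv3"].copy()
    # perturb conv3 activations through the head alone
    def head(a):
        z = m._seq[-4][0].forward(a)          # global max pool
        z = m._seq[-3][0].forward(z)          # fc16
        z = m._seq[-2][0].forward(z)          # swish
        return m._seq[-1][0].forward(z)[0, 1]  # class-1 logit
    for _ in range(5):
        idx = tuple(rng.integers(0, s) for s in base_maps.shape)
        up = base_maps.copy(); up[idx] += eps
        dn = base_maps.copy(); dn[idx] -= eps
        num = (head(up) - head(dn)) / (2 * eps)
        denom = max(abs(num), abs(g[idx[1:]]), 1e-8)
        assert abs(num - g[idx[1:]]) / denom < 1e-3 or abs(num) < 1e-10


def test_batched_gradients_equal_per_sample_gradients(toy_model, rng):
    x = rng.random((2, 32, 32, 3)).astype(np.float32)
    both = cnn.class_gradient(toy_model, "fc16", 0, x)
    one = cnn.class_gradient(toy_model, "fc16", 0, x[:1])
    two = cnn.class_gradient(toy_model, "fc16", 0, x[1:])
    assert np.allclose(both, np.concatenate([one, two]), atol=1e-5)
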