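"""Tile normalization, augmentation, the two published layer stacks, the
training recipe contracts, and the cascade decision rule."""

import numpy as np
import pytest

from dicascade import cnn
from dicascade.cnn import (ChromosomeTile, Conv2D, Dense, Flatten, MaxPool,
                           ReLU, TrainingConfig, add_noise, augment,
                           build_architecture, cascade_predict, is_dic,
                           mirror, normalize_tile, oversample, pan, predict,
                           softmax, softmax_cross_entropy, train_stage,
                           Network, TrainedModel)


# ------------------------------------------------------------------- tiles

def _content_bbox(tile, background=230 / 255.0):
    off = np.abs(tile - background).max(axis=-1) > 0.05
    rr, cc = np.nonzero(off)
    return rr.max() - rr.min() + 1, cc.max() - cc.min() + 1


def test_normalize_identity_geometry():
    rng = np.random.default_rng(0)
    crop = (rng.random((151, 151, 3)) * 255).astype(np.uint8)
    tile = normalize_tile(crop)
    assert tile.shape == (151, 151, 3)
    assert tile.dtype == np.float32
    assert 0.0 <= tile.min() and tile.max() <= 1.0


def test_normalize_preserves_aspect_ratio():
    crop = np.zeros((302, 151, 3), dtype=np.uint8)   # dark 2:1 content
    tile = normalize_tile(crop)
    h, w = _content_bbox(tile)
    assert h == 151 and abs(w - 76) <= 1

    crop = np.zeros((75, 100, 3), dtype=np.uint8)
    tile = normalize_tile(crop)
    h, w = _content_bbox(tile)
    assert max(h, w) == 151
    assert abs(h / w - 0.75) < 0.02


def test_normalize_rejects_empty():
    with pytest.raises(ValueError):
        normalize_tile(np.zeros((0, 0, 3)))


def test_augment_involutions_and_degenerate_noise():
    rng = np.random.default_rng(1)
    px = rng.random((151, 151, 3)).astype(np.float32)
    assert (mirror(mirror(px, 1), 1) == px).all()
    assert (mirror(mirror(px, 0), 0) == px).all()
    back = pan(pan(px, 5, 5), -5, -5)
    assert (back[5:-5, 5:-5] == px[5:-5, 5:-5]).all()
    assert (add_noise(px, 0.0, rng) == px).all()
    tile = ChromosomeTile(px, label="DIC", source_id="t")
    variants = augment(tile, seed=3)
    assert len(variants) == 4
    assert all(v.label == "DIC" for v in variants)


# ------------------------------------------------------------- architecture

def test_published_layer_stacks():
    a1 = build_architecture(1)
    assert a1.layers[0] == ("conv", 8, 5)
    a2 = build_architecture(2)
    assert a2.layers[0] == ("conv", 16, 5)
    for arch in (a1, a2):
        convs = [l for l in arch.layers if l[0] == "conv"]
        fcs = [l for l in arch.layers if l[0] == "fc"]
        assert len(convs) == 5 and len(fcs) == 3
        assert [f[1] for f in fcs] == [20, 10, 2]
        assert arch.spatial_trace() == [151, 147, 145, 48, 46, 23, 21, 4, 2]
    drops = [l for l in a2.layers if l[0] == "dropout"]
    assert [d[1] for d in drops] == [0.5, 0.3]
    assert not any(l[0] == "dropout" for l in a1.layers)
    with pytest.raises(ValueError):
        build_architecture(3)


def test_forward_pass_ends_in_normalized_two_vector():
    rng = np.random.default_rng(7)
    x = rng.random((2, 151, 151, 3)).astype(np.float32)
    for stage in (1, 2):
        net = build_architecture(stage).build(rng)
        logits = net.forward(x, train=False)
        assert logits.shape == (2, 2)
        p = softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)


def test_backprop_matches_numeric_gradient():
    """Numeric check on a small smooth stack (no ReLU/pool kinks)."""
    rng = np.random.default_rng(1)
    net = Network([Conv2D(2, 3, 3, rng), Flatten(),
                   Dense(8 * 8 * 3, 5, rng), Dense(5, 2, rng)])
    x = rng.random((3, 10, 10, 2)).astype(np.float32)
    cls = np.array([0, 1, 0])
    logits = net.forward(x)
    _, grad = softmax_cross_entropy(logits, cls)
    net.backward(grad)
    eps = 1e-2
    for layer in net.layers:
        for _, w, g in layer.params():
            flat, gflat = w.reshape(-1), g.reshape(-1)
            for i in rng.integers(0, flat.size, size=min(6, flat.size)):
                old = flat[i]
                flat[i] = old + eps
                lp = softmax_cross_entropy(net.forward(x), cls)[0]
                flat[i] = old - eps
                lm = softmax_cross_entropy(net.forward(x), cls)[0]
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[i]) <= 1e-2 + 0.02 * abs(num)


def test_maxpool_stride_equals_window():
    pool = MaxPool(3)
    x = np.arange(2 * 7 * 7 * 1, dtype=np.float32).reshape(2, 7, 7, 1)
    y = pool.forward(x)
    assert y.shape == (2, 2, 2, 1)
    assert y[0, 0, 0, 0] == x[0, :3, :3, 0].max()


# ---------------------------------------------------------------- training

def test_oversampling_duplicates_dic_rows():
    labels = np.array([1, 0, 0, 1, 0])
    idx = np.arange(5)
    stream = oversample(idx, labels, 3)
    assert (labels[stream] == 1).sum() == 3 * 2
    assert (labels[stream] == 0).sum() == 3


def test_training_requires_both_classes():
    tiles = np.zeros((10, 151, 151, 3), dtype=np.uint8)
    labels = np.zeros(10, dtype=int)
    with pytest.raises(ValueError):
        train_stage(build_architecture(1), tiles, labels,
                    TrainingConfig(epochs=1))


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(split=(5, 3, 3))
    with pytest.raises(ValueError):
        TrainingConfig(epochs=0)


def test_training_is_seed_deterministic(tiny_tile_corpus):
    tiles, labels = tiny_tile_corpus
    cfg = TrainingConfig(lr=0.01, epochs=1, batch_size=16,
                         dic_oversample=3, seed=5)
    h1 = train_stage(build_architecture(1), tiles, labels, cfg).training_history
    h2 = train_stage(build_architecture(1), tiles, labels, cfg).training_history
    assert h1[0]["train_loss"] == h2[0]["train_loss"]
    assert h1[0]["val_loss"] == h2[0]["val_loss"]


def test_smoke_training_learns_separable_tiles(tiny_models, tiny_tile_corpus):
    """On a small synthetic corpus the first stage reaches high training
    accuracy within a few epochs."""
    m1, _ = tiny_models
    assert m1.training_history[-1]["train_acc"] > 0.9


# --------------------------------------------------------------- inference

def test_score_and_tie_conventions():
    assert is_dic(np.array([0.0]))[0]
    assert not is_dic(np.array([1.0]))[0]
    assert not is_dic(np.array([0.5]))[0]      # tie -> non-DIC


class _FixedScoreModel:
    """Stub whose softmax non-DIC probability is preset per tile index."""

    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=np.float64)
        self.network = self

    def forward(self, x, train=False, rng=None):
        n = x.shape[0]
        s = self._scores[self._cursor:self._cursor + n]
        self._cursor += n
        logits = np.zeros((n, 2), dtype=np.float32)
        logits[:, 1] = np.log(np.maximum(s, 1e-9)) - \
            np.log(np.maximum(1 - s, 1e-9))
        return logits

    def reset(self):
        self._cursor = 0
        return self


def test_cascade_decision_rule():
    tiles = np.zeros((3, 151, 151, 3), dtype=np.uint8)
    # stage1: [nonDIC, DIC, DIC]; stage2 sees only the two DIC tiles
    m1 = _FixedScoreModel([0.9, 0.1, 0.2]).reset()
    m2 = _FixedScoreModel([0.05, 0.95]).reset()
    final, s1, s2 = cascade_predict(m1, m2, tiles, batch_size=2)
    assert final.tolist() == [False, True, False]
    assert np.isnan(s2[0]) and not np.isnan(s2[1]) and not np.isnan(s2[2])
    # cascade positives are a subset of stage-1 positives
    assert (final <= is_dic(s1)).all()


def test_cascade_positive_subset_with_real_models(tiny_models,
                                                  tiny_tile_corpus):
    m1, m2 = tiny_models
    tiles, _ = tiny_tile_corpus
    final, s1, _ = cascade_predict(m1, m2, tiles[:60], batch_size=32)
    assert (final <= is_dic(s1)).all()


def test_model_save_load_roundtrip(tmp_path, tiny_models, tiny_tile_corpus):
    m1, _ = tiny_models
    tiles, _ = tiny_tile_corpus
    m1.save(tmp_path / "stage1")
    loaded = TrainedModel.load(tmp_path / "stage1")
    a = predict(m1, tiles[:8], 8)
    b = predict(loaded, tiles[:8], 8)
    assert np.allclose(a, b, atol=1e-6)
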