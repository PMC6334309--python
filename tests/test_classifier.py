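"""Classifier: architecture arithmetic, preprocessing, two-stage protocol."""

import numpy as np
import pytest

from nodulegan import nn
from nodulegan.classifier import (
    ClassifierArch,
    FinetuneConfig,
    NoduleClassifier,
    PretrainConfig,
    finetune,
    predict,
    preprocess,
    pretrain,
)
from nodulegan.augment import PatchImage


def toy_images(n_per_class, size=32, seed=0):
    """Linearly separable bright vs dark images on the [-1, 1] scale."""
    rng = np.random.default_rng(seed)
    dark = np.clip(rng.normal(-0.5, 0.1, (n_per_class, size, size)), -1, 1)
    bright = np.clip(rng.normal(0.5, 0.1, (n_per_class, size, size)), -1, 1)
    return dark, bright


def test_paper_architecture_shape_trace():
    trace = ClassifierArch.paper().shape_trace()
    assert trace[0] == (55, 96)  # conv1
    assert trace[1] == (27, 96)  # pool1
    assert trace[-1] == (6, 256)  # pool5 feeding FC (6*6*256 = 9216)


def test_paper_forward_pass_shapes_and_softmax():
    model = NoduleClassifier(ClassifierArch.paper(), seed=0)
    x = np.random.default_rng(0).uniform(-1, 1, (1, 1, 227, 227)).astype(np.float32)
    conv1_out = model.features.layers[0].forward(x)
    assert conv1_out.shape == (1, 96, 55, 55)
    probs = model.forward(x)
    assert probs.shape == (1, 2)
    assert probs.min() >= 0
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_degenerate_architecture_rejected():
    with pytest.raises(ValueError, match="collapses"):
        ClassifierArch(input_size=8, conv=((8, 5, 4, 0), (8, 5, 4, 0)), pool_after=(0, 1)).shape_trace()


def test_preprocess_resize_and_crop():
    arch = ClassifierArch.paper()
    patch = np.random.default_rng(1).uniform(-900, 300, (64, 64))
    out = preprocess(patch, arch)
    assert out.shape == (227, 227)
    assert out.min() >= -1.0 and out.max() <= 1.0


def test_preprocess_constant_patch_maps_linearly():
    arch = ClassifierArch.tiny()
    out = preprocess(np.full((64, 64), -300.0), arch)
    np.testing.assert_allclose(out, 2 * (-300.0 + 1000.0) / 1400.0 - 1.0, atol=1e-6)


def test_preprocess_identity_at_native_resolution():
    arch = ClassifierArch(input_size=256, resize_size=256)
    patch = np.random.default_rng(2).uniform(-1000, 400, (256, 256))
    np.testing.assert_allclose(preprocess(patch, arch), np.clip(2 * (patch + 1000) / 1400 - 1, -1, 1), atol=1e-6)
    with pytest.raises(ValueError, match="square"):
        preprocess(np.zeros((10, 12)), arch)


def test_pretrain_smoke_returns_finite_loss():
    dark, bright = toy_images(16)
    model, losses = pretrain(dark, bright, PretrainConfig(epochs=1, batch_size=8, seed=0), ClassifierArch.tiny())
    assert np.isfinite(losses).all() and len(losses) == 4


def test_pretrain_rejects_empty_class():
    dark, bright = toy_images(4)
    with pytest.raises(ValueError, match="non-empty"):
        pretrain(dark, np.empty((0, 32, 32)), PretrainConfig(epochs=1), ClassifierArch.tiny())


def test_separable_toy_reaches_perfect_training_accuracy():
    dark, bright = toy_images(32)
    model, _ = pretrain(dark, bright, PretrainConfig(epochs=20, lr=0.01, batch_size=16, seed=1), ClassifierArch.tiny())
    p = predict(model, np.concatenate([dark, bright]), assume_unit_scale=True)
    pred = (p >= 0.5).astype(int)
    truth = np.array([0] * 32 + [1] * 32)
    assert (pred == truth).mean() == 1.0
    assert (p[32:] > 0.5).all()  # bright side above threshold
    assert p.min() >= 0.0 and p.max() <= 1.0


def test_minibatch_class_ratio_matches_dataset_over_epoch():
    """Shuffled minibatches partition the epoch, so aggregated per-batch label
    counts equal the dataset's, and per-batch ratios fluctuate around it."""
    seed, batch_size = 3, 16
    y = np.array([0] * 24 + [1] * 40)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    counts = []
    order = rng.permutation(len(y))
    for start in range(0, len(y), batch_size):
        idx = order[start : start + batch_size]
        counts.append(y[idx].mean())
    assert np.isclose(np.mean(counts), 40 / 64)


def test_finetune_replacement_contract():
    dark, bright = toy_images(8)
    pre, _ = pretrain(dark, bright, PretrainConfig(epochs=1, batch_size=8, seed=2), ClassifierArch.tiny())
    patches = [PatchImage(np.full((32, 32), -500.0), "c0", "benign", "axial")] * 4
    tuned = finetune(pre, patches, [0, 0, 1, 1], FinetuneConfig(epochs=0, seed=9))
    # conv weights identical, FC re-initialized
    np.testing.assert_array_equal(
        tuned.features.state_dict()["0.w"], pre.features.state_dict()["0.w"]
    )
    pre_fc = pre.head.state_dict()
    new_fc = tuned.head.state_dict()
    assert any(not np.array_equal(pre_fc[k], new_fc[k]) for k in pre_fc if k.endswith(".w"))


def test_finetune_updates_all_layers():
    dark, bright = toy_images(8)
    pre, _ = pretrain(dark, bright, PretrainConfig(epochs=1, batch_size=8, seed=4), ClassifierArch.tiny())
    rng = np.random.default_rng(0)
    patches = [PatchImage(rng.uniform(-900, 300, (32, 32)), "c", "benign", "axial") for _ in range(8)]
    tuned = finetune(pre, patches, [0, 1] * 4, FinetuneConfig(epochs=2, lr=0.01, batch_size=4, seed=5))
    assert not np.array_equal(tuned.features.state_dict()["0.w"], pre.features.state_dict()["0.w"])


def test_zero_epoch_pretrain_degenerates_to_scratch():
    """Pretrain(epochs=0) + finetune == finetune from the same random init."""
    dark, bright = toy_images(8)
    arch = ClassifierArch.tiny()
    pre, _ = pretrain(dark, bright, PretrainConfig(epochs=0, seed=6), arch)
    scratch = NoduleClassifier(arch, seed=6)
    np.testing.assert_array_equal(pre.features.state_dict()["0.w"], scratch.features.state_dict()["0.w"])
    rng = np.random.default_rng(1)
    patches = [PatchImage(rng.uniform(-900, 300, (32, 32)), "c", "benign", "axial") for _ in range(8)]
    labels = [0, 1] * 4
    cfg = FinetuneConfig(epochs=1, lr=0.01, batch_size=4, seed=7)
    a = finetune(pre, patches, labels, cfg)
    b = finetune(scratch, patches, labels, cfg)
    for k, v in a.features.state_dict().items():
        np.testing.assert_array_equal(v, b.features.state_dict()[k])


def test_predict_deterministic_with_dropout_off():
    dark, bright = toy_images(8)
    model, _ = pretrain(dark, bright, PretrainConfig(epochs=1, batch_size=8, seed=8), ClassifierArch.tiny())
    p1 = predict(model, dark, assume_unit_scale=True)
    p2 = predict(model, dark, assume_unit_scale=True)
    np.testing.assert_array_equal(p1, p2)
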