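import math

import numpy as np
import pytest

from maaseg import nn
from maaseg.cam import (CAMTrainConfig, MAFModel, align_feature,
                        bce_with_logits, fuse, generate_cam, train_cam_stage)
from maaseg.encoder import EncoderConfig
from maaseg.errors import ConfigError, DimensionError
from maaseg.nn import Tensor
from maaseg.synth import SyntheticSpec, generate_tile
from maaseg.tiling import compute_patch_grid, crop, derive_image_labels


def small_patch_set(n=8, size=112):
    """Alternating gland / gland-free patches with their weak labels."""
    images, labels = [], []
    for s in range(n):
        spec = SyntheticSpec(seed=100 + s, width=size, height=size,
                             n_glands=s % 2, radius_range=(25, 40))
        tile = generate_tile(spec)
        lab = derive_image_labels(tile.mask)
        images.append(tile.image)
        labels.append([lab.gland, lab.background])
    return images, np.array(labels, np.float32)


def test_align_identity_and_constant(rng):
    proj = nn.Conv2d(4, 4, 1, rng=rng)
    proj.weight.data[:] = np.eye(4).reshape(4, 4, 1, 1)
    proj.bias.data[:] = 0.0
    x = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
    np.testing.assert_allclose(align_feature(x, (6, 6), proj).data, x.data,
                               atol=1e-6)
    const = Tensor(np.full((1, 4, 2, 2), 3.0, np.float32))
    out = align_feature(const, (8, 8), proj)
    np.testing.assert_allclose(out.data, 3.0, atol=1e-5)


def test_fuse_sum_and_commutativity(rng):
    a, b, c = (Tensor(rng.normal(size=(1, 3, 4, 4))) for _ in range(3))
    s1 = fuse([a, b, c]).data
    s2 = fuse([c, a, b]).data
    np.testing.assert_allclose(s1, s2, atol=1e-12)
    np.testing.assert_allclose(s1, a.data + b.data + c.data, atol=1e-12)
    with pytest.raises(DimensionError):
        fuse([a, Tensor(np.zeros((1, 3, 5, 5)))])


def test_model_fuses_layers_3_5_6_at_layer3_resolution(small_tile):
    model = MAFModel(EncoderConfig.tiny(), seed=0)
    assert model.fuse_layers == (3, 5, 6)
    raster, logits, fused = model(Tensor(np.zeros((1, 3, 112, 112), np.float32)))
    assert raster.shape == (1, 2, 7, 7)       # layer-3 resolution for 112 input
    assert fused.shape[2:] == (7, 7)
    assert logits.shape == (1, 2)


def test_classify_pooling_contracts(rng):
    model = MAFModel(EncoderConfig.tiny(), seed=0)
    model.head.weight.data[:] = 0.0
    model.head.bias.data[:] = 0.0
    _, logits, _ = model(Tensor(rng.normal(size=(1, 3, 112, 112)).astype(np.float32)))
    np.testing.assert_allclose(logits.data, 0.0, atol=1e-7)
    # uniform raster c pools to logit c
    model.head.bias.data[:] = [1.25, -0.5]
    model.head.weight.data[:] = 0.0
    _, logits, _ = model(Tensor(rng.normal(size=(1, 3, 112, 112)).astype(np.float32)))
    np.testing.assert_allclose(logits.data[0], [1.25, -0.5], atol=1e-6)


def test_class_symmetry_of_head(rng):
    """Permuting the head's class channels permutes the logits."""
    model = MAFModel(EncoderConfig.tiny(), seed=0)
    x = Tensor(np.random.default_rng(1).normal(size=(1, 3, 112, 112)).astype(np.float32))
    _, logits, _ = model(x)
    model.head.weight.data = model.head.weight.data[::-1].copy()
    model.head.bias.data = model.head.bias.data[::-1].copy()
    _, swapped, _ = model(x)
    np.testing.assert_allclose(swapped.data[0], logits.data[0][::-1], atol=1e-5)


def test_bce_loss_values_and_gradient():
    z = Tensor(np.array([[0.0, math.log(3)]], np.float32), requires_grad=True)
    y = np.array([[1.0, 0.0]], np.float32)
    loss = bce_with_logits(z, y)
    expected = (math.log(2) + math.log(4)) / 2   # −log σ(0), −log(1−σ(ln3))
    assert float(loss.data) == pytest.approx(expected, rel=1e-6)
    loss.backward()
    # d/dz BCE = (σ(z) − y) / n for the mean over n = 2 elements
    np.testing.assert_allclose(z.grad, [[(0.5 - 1.0) / 2, (0.75 - 0.0) / 2]],
                               atol=1e-6)


def test_train_smoke_and_determinism():
    images, labels = small_patch_set(8)
    cfg = CAMTrainConfig(epochs=1, batch_size=4, seed=0)
    _, log1 = train_cam_stage(images, labels, cfg)
    assert len(log1["loss"]) == 1 and np.isfinite(log1["loss"][0])
    _, log2 = train_cam_stage(images, labels, cfg)
    assert log1["loss"] == log2["loss"]


def test_train_rejects_empty_manifest():
    with pytest.raises(ConfigError):
        train_cam_stage([], np.zeros((0, 2)))


def test_generate_cam_range_and_degenerate(small_tile):
    model = MAFModel(EncoderConfig.tiny(), seed=0)
    cam, fused = generate_cam(small_tile.image, model)
    assert cam.scores.shape == (7, 7, 2)
    assert cam.scores.min() >= 0.0 and cam.scores.max() <= 1.0
    assert fused.shape == (7, 7, 32)
    # a head that can only emit negatives rectifies to a degenerate
    # channel, which must normalise to all zeros
    model.head.weight.data[:] = 0.0
    model.head.bias.data[:] = [-5.0, -5.0]
    cam2, _ = generate_cam(small_tile.image, model)
    assert (cam2.scores == 0).all()


def test_cam_upsampled_to_patch_resolution(small_tile):
    model = MAFModel(EncoderConfig.tiny(), seed=0)
    cam, _ = generate_cam(small_tile.image, model, out_size=(112, 112))
    assert cam.scores.shape == (112, 112, 2)
    assert cam.scores.min() >= 0.0 and cam.scores.max() <= 1.0
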