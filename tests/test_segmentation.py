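import math

import numpy as np
import pytest

from maaseg.errors import ConfigError, UndefinedLossError
from maaseg.nn import Tensor
from maaseg.segmentation import (PSPSegNet, SegConfig, normalized_loss,
                                 oeem_weights, pixel_ce, predict_mask,
                                 train_seg_stage)
from maaseg.synth import SyntheticSpec, generate_tile


def logits_for(values):
    """(K, n) logit columns → (1, K, 1, n) tensor."""
    arr = np.asarray(values, np.float64)
    return Tensor(arr.reshape(1, arr.shape[0], 1, arr.shape[1]))


def test_pixel_ce_worked_values():
    # uniform logits → ln 2; logits (ln3, 0) at label 0 → ln(4/3)
    z = logits_for([[math.log(3), 0.0], [0.0, 0.0]])
    mask = np.zeros((1, 1, 2), np.uint8)
    ce = pixel_ce(z, mask)
    np.testing.assert_allclose(ce.data, [math.log(4 / 3), math.log(2)],
                               rtol=1e-12)


def test_pixel_ce_ignores_255():
    z = logits_for([[1.0, 5.0, -3.0], [0.0, -2.0, 7.0]])
    mask = np.array([[[0, 255, 1]]], np.uint8)
    ce = pixel_ce(z, mask)
    assert ce.data.shape == (2,)
    # flipping the ignored pixel's logits changes nothing
    z2 = logits_for([[1.0, -5.0, -3.0], [0.0, 2.0, 7.0]])
    np.testing.assert_allclose(pixel_ce(z2, mask).data, ce.data, rtol=1e-12)
    with pytest.raises(UndefinedLossError):
        pixel_ce(z, np.full((1, 1, 3), 255, np.uint8))


def test_ignored_pixels_have_zero_gradient():
    z = Tensor(np.zeros((1, 2, 1, 3)), requires_grad=True)
    mask = np.array([[[0, 255, 1]]], np.uint8)
    normalized_loss(z, mask).backward()
    np.testing.assert_allclose(z.grad[0, :, 0, 1], 0.0, atol=1e-15)
    assert np.abs(z.grad[0, :, 0, 0]).sum() > 0


def test_oeem_weights_worked_example():
    w = oeem_weights(np.array([0.0, math.log(2)]))
    np.testing.assert_allclose(w, [4 / 3, 2 / 3], rtol=1e-12)
    # uniform losses → unit weights
    np.testing.assert_allclose(oeem_weights(np.full(7, 1.3)), 1.0, rtol=1e-12)


def test_oeem_weights_unit_mean_property(rng):
    for _ in range(100):
        losses = rng.exponential(1.0, size=rng.integers(1, 200))
        w = oeem_weights(losses)
        assert abs(w.mean() - 1.0) < 1e-6
        assert (w > 0).all()
    # low-loss pixels get weight above 1
    w = oeem_weights(np.array([0.1, 2.0, 3.0]))
    assert w[0] > 1.0 > w[2]


def test_normalized_loss_two_pixel_example():
    """Pixel losses (0, ln 2) with two classes → weights (4/3, 2/3) and
    loss (4/3·0 + 2/3·ln2)/2 = ln2/3."""
    z = logits_for([[0.0, 0.0], [60.0, 0.0]])
    mask = np.array([[[1, 0]]], np.uint8)
    loss = normalized_loss(z, mask)
    assert float(loss.data) == pytest.approx(math.log(2) / 3, rel=1e-6)


def test_single_class_branch_is_plain_ce(rng):
    z = Tensor(rng.normal(size=(1, 2, 4, 4)))
    mask = np.ones((1, 4, 4), np.uint8)
    loss = normalized_loss(z, mask)
    np.testing.assert_allclose(float(loss.data),
                               float(pixel_ce(z, mask).data.mean()),
                               rtol=1e-12)


def test_uniform_weights_reduce_to_mean_ce():
    """When every pixel has the same loss the weights are all 1 and the
    OEEM branch equals plain mean cross-entropy exactly."""
    z = Tensor(np.zeros((1, 2, 3, 3)))
    mask = np.zeros((1, 3, 3), np.uint8)
    mask[0, 0, 0] = 1            # two classes, but all losses equal ln 2
    loss = normalized_loss(z, mask)
    assert float(loss.data) == pytest.approx(math.log(2), rel=1e-12)


def test_psp_forward_shapes_and_determinism(rng):
    cfg = SegConfig(width=16, ppm_dim=4, seed=0)
    net = PSPSegNet(cfg)
    for size in (64, 128):
        x = Tensor(rng.normal(size=(1, 3, size, size)).astype(np.float32))
        assert net(x).shape == (1, 2, size, size)
    net2 = PSPSegNet(SegConfig(width=16, ppm_dim=4, seed=0))
    x = Tensor(np.ones((1, 3, 64, 64), np.float32))
    np.testing.assert_array_equal(net(x).data, net2(x).data)


def seg_fixture(n=6):
    images, masks = [], []
    for s in range(n):
        tile = generate_tile(SyntheticSpec(seed=300 + s, width=112, height=112,
                                           n_glands=1, radius_range=(25, 40)))
        images.append(tile.image)
        masks.append(tile.mask.astype(np.uint8))
    return images, masks


def test_train_seg_smoke_and_reproducible():
    images, masks = seg_fixture(4)
    cfg = SegConfig(width=16, ppm_dim=4, batch_size=2, iterations=5,
                    lr=0.01, seed=0)
    model, log1 = train_seg_stage(images, masks, cfg)
    assert len(log1["loss"]) == 5 and np.isfinite(log1["loss"]).all()
    _, log2 = train_seg_stage(images, masks, cfg)
    assert log1["loss"] == log2["loss"]
    pred = predict_mask(model, images[0])
    assert pred.shape == (112, 112) and set(np.unique(pred)) <= {0, 1}


def test_train_seg_rejects_empty_or_all_ignored():
    with pytest.raises(ConfigError):
        train_seg_stage([], [])
    images, _ = seg_fixture(2)
    all_ignored = [np.full((112, 112), 255, np.uint8)] * 2
    with pytest.raises(ConfigError):
        train_seg_stage(images, all_ignored, SegConfig(iterations=1))
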