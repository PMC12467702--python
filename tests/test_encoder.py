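import numpy as np
import pytest

from maaseg.encoder import (AttentionBlock, EncoderConfig, MixFFN,
                            MiTEncoder, OverlapPatchMerge, pyramid_shape)
from maaseg.errors import ConfigError
from maaseg.nn import Tensor


def ceil_chain(size, strides):
    for s in strides:
        size = -(-size // s)
    return size


@pytest.mark.parametrize("hw,expected", [
    ((112, 112), [28, 14, 7, 4, 2, 1]),
    ((128, 128), [32, 16, 8, 4, 2, 1]),
])
def test_pyramid_spatial_ladder(hw, expected, small_tile):
    enc = MiTEncoder(EncoderConfig.tiny(), seed=0)
    img = np.zeros((hw[0], hw[1], 3), np.uint8)
    pyr = enc.encode(img)
    assert [m.shape[0] for m in pyr.maps] == expected
    assert [m.shape[1] for m in pyr.maps] == expected
    assert [m.shape[2] for m in pyr.maps] == list(EncoderConfig.tiny().channels)
    # shape law equals repeated ceiling division at factors 4,8,...,128
    for i in range(1, 7):
        assert pyr[i].shape[:2] == pyramid_shape(*hw, i)


def test_pyramid_ceiling_on_odd_sizes():
    # 150 → 38, 19, 10, 5, 3, 2 by repeated ceiling division
    assert [pyramid_shape(150, 150, i)[0] for i in range(1, 7)] == \
        [38, 19, 10, 5, 3, 2]


def test_patch_merge_shapes(rng):
    m = OverlapPatchMerge(3, 8, stride=2, kernel=3, rng=rng)
    assert m(Tensor(np.zeros((1, 3, 32, 32), np.float32))).shape == (1, 8, 16, 16)
    assert m(Tensor(np.zeros((1, 3, 7, 7), np.float32))).shape == (1, 8, 4, 4)
    with pytest.raises(ConfigError):
        OverlapPatchMerge(3, 8, stride=3, kernel=5, rng=rng)


def test_attention_rows_sum_to_one(rng):
    blk = AttentionBlock(8, heads=2, reduction=1, rng=rng)
    x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
    w = blk.attention_weights(x)
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-5)
    assert (w >= 0).all()


def test_attention_zero_value_projection_is_identity(rng):
    blk = AttentionBlock(8, heads=2, reduction=1, rng=rng)
    blk.v.weight.data[:] = 0.0
    x = Tensor(rng.normal(size=(2, 8, 5, 5)).astype(np.float32))
    np.testing.assert_allclose(blk(x).data, x.data, atol=1e-6)


def test_attention_permutation_equivariance(rng):
    """With no key/value reduction, permuting spatial positions permutes
    the outputs identically (no positional encoding exists)."""
    blk = AttentionBlock(6, heads=1, reduction=1, rng=rng)
    x = rng.normal(size=(1, 6, 1, 8)).astype(np.float32)  # 1-row grid
    perm = rng.permutation(8)
    out = blk(Tensor(x)).data
    out_perm = blk(Tensor(x[:, :, :, perm])).data
    np.testing.assert_allclose(out[:, :, :, perm], out_perm, atol=1e-5)


def test_mixffn_zero_contraction_is_identity(rng):
    ffn = MixFFN(8, expansion=2, rng=rng)
    ffn.contract.weight.data[:] = 0.0
    x = Tensor(rng.normal(size=(1, 8, 5, 7)).astype(np.float32))
    np.testing.assert_allclose(ffn(x).data, x.data, atol=1e-6)
    ffn2 = MixFFN(8, expansion=2, rng=rng)
    assert ffn2(x).shape == x.shape


def test_mixffn_translation_of_interior(rng):
    """The 3×3 convolution path is translation-equivariant away from
    borders: shifting a localized bump shifts the response."""
    ffn = MixFFN(4, expansion=2, rng=rng)
    base = np.zeros((1, 4, 16, 16), np.float32)
    bump = rng.normal(size=(4, 3, 3)).astype(np.float32)
    a = base.copy()
    a[0, :, 5:8, 5:8] = bump
    b = base.copy()
    b[0, :, 8:11, 8:11] = bump
    ya = ffn(Tensor(a)).data
    yb = ffn(Tensor(b)).data
    np.testing.assert_allclose(ya[0, :, 4:9, 4:9], yb[0, :, 7:12, 7:12],
                               atol=1e-5)


def test_encoder_determinism(small_tile):
    enc1 = MiTEncoder(EncoderConfig.tiny(), seed=3)
    enc2 = MiTEncoder(EncoderConfig.tiny(), seed=3)
    p1 = enc1.encode(small_tile.image)
    p2 = enc2.encode(small_tile.image)
    for a, b in zip(p1.maps, p2.maps):
        np.testing.assert_array_equal(a, b)


def test_no_positional_encoding_parameters():
    """Every parameter belongs to a conv, linear or layernorm; there is
    no standalone positional-embedding table (its shape would have to
    match the token count 784 at layer 1)."""
    enc = MiTEncoder(EncoderConfig.tiny(), seed=0)
    for p in enc.parameters():
        assert 784 not in p.data.shape


def test_config_validation():
    with pytest.raises(ConfigError):
        EncoderConfig(channels=(8, 16, 24)).validate()
    with pytest.raises(ConfigError):
        EncoderConfig(heads=(3, 3, 3, 3, 3, 3)).validate()  # 8 % 3 != 0
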