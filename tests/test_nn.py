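"""Gradient and contract checks for the autodiff core.

Each structured op (conv, resize, pooling, softmax composites) is checked
against central finite differences in float64 on tiny tensors.
"""

import numpy as np
import pytest

from maaseg import nn
from maaseg.nn import Tensor


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = fn()
        x[idx] = orig - eps
        lo = fn()
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def check_op(make_output, x: Tensor, rtol=1e-5, atol=1e-7):
    x.grad = None
    out = make_output()
    # project to a scalar with fixed random weights for a stringent check
    w = np.random.default_rng(0).normal(size=out.data.shape)
    loss = (out * Tensor(w)).sum()
    loss.backward()
    analytic = x.grad.copy()
    numeric = numeric_grad(
        lambda: float((make_output().data * w).sum()), x.data)
    np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)


@pytest.mark.parametrize("op", [
    lambda t: t.relu(), lambda t: t.gelu(), lambda t: t.sigmoid(),
    lambda t: t.softmax(axis=-1), lambda t: t.log_softmax(axis=-1),
    lambda t: (t * t).mean(axis=0), lambda t: t.exp(),
])
def test_elementwise_and_reduction_grads(op, rng):
    x = Tensor(rng.normal(size=(4, 5)), requires_grad=True)
    check_op(lambda: op(x), x)


def test_matmul_and_broadcast_grads(rng):
    a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    b = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
    c = Tensor(rng.normal(size=(2,)), requires_grad=True)
    out = a @ b + c
    w = rng.normal(size=out.data.shape)
    (out * Tensor(w)).sum().backward()
    for t in (a, b, c):
        assert t.grad is not None and t.grad.shape == t.data.shape
    num = numeric_grad(lambda: float(((a.data @ b.data + c.data) * w).sum()),
                       a.data)
    np.testing.assert_allclose(a.grad, num, rtol=1e-6)


@pytest.mark.parametrize("stride,padding,kernel", [(1, 0, 3), (2, 1, 3), (4, 3, 7)])
def test_conv2d_grads(rng, stride, padding, kernel):
    x = Tensor(rng.normal(size=(2, 3, 8, 8)), requires_grad=True)
    w = Tensor(rng.normal(size=(4, 3, kernel, kernel)), requires_grad=True)
    b = Tensor(rng.normal(size=(4,)), requires_grad=True)
    for t in (x, w, b):
        check_op(lambda: nn.conv2d(x, w, b, stride=stride, padding=padding),
                 t, rtol=1e-5, atol=1e-6)


def test_bilinear_resize_grads_and_constants(rng):
    x = Tensor(rng.normal(size=(1, 2, 3, 4)), requires_grad=True)
    check_op(lambda: nn.bilinear_resize(x, (6, 7)), x)
    const = nn.bilinear_resize(Tensor(np.full((1, 1, 3, 3), 2.5)), (7, 5))
    assert np.allclose(const.data, 2.5)


def test_bilinear_matches_skimage():
    """Independent oracle: half-pixel bilinear upsampling as implemented
    by skimage.transform.resize (order=1, no anti-aliasing)."""
    from skimage.transform import resize

    arr = np.array([[0.0, 1.0], [1.0, 0.0]])
    ours = nn.bilinear_resize_np(arr, (4, 4))
    ref = resize(arr, (4, 4), order=1, anti_aliasing=False, mode="edge")
    np.testing.assert_allclose(ours, ref, atol=1e-12)
    # corners preserved
    assert ours[0, 0] == 0.0 and ours[0, 3] == 1.0


def test_adaptive_pool_grads_and_values(rng):
    x = Tensor(rng.normal(size=(1, 2, 7, 5)), requires_grad=True)
    check_op(lambda: nn.adaptive_avg_pool2d(x, (3, 2)), x)
    full = nn.adaptive_avg_pool2d(Tensor(x.data), (1, 1))
    np.testing.assert_allclose(full.data[..., 0, 0], x.data.mean(axis=(2, 3)))


def test_concat_and_take_grads(rng):
    a = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
    b = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    out = nn.concat([a, b], axis=1)
    (out * Tensor(np.ones_like(out.data))).sum().backward()
    assert np.allclose(a.grad, 1.0) and np.allclose(b.grad, 1.0)

    table = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
    idx = np.array([0, 2, 2, 3])
    table.take(idx).sum().backward()
    np.testing.assert_allclose(table.grad.sum(axis=1), [3., 0., 6., 3.])


def test_layernorm_normalizes(rng):
    ln = nn.LayerNorm(6)
    x = Tensor(rng.normal(size=(2, 5, 6)).astype(np.float32))
    y = ln(x)
    np.testing.assert_allclose(y.data.mean(-1), 0.0, atol=1e-5)
    np.testing.assert_allclose(y.data.std(-1), 1.0, atol=1e-2)


def test_sgd_momentum_and_cosine_schedule():
    p = nn.Parameter(np.array([1.0], np.float32))
    opt = nn.SGD([p], lr=0.1, momentum=0.5)
    p.grad = np.array([1.0], np.float32)
    opt.step()                       # v = 1, p = 1 − 0.1
    assert p.data[0] == pytest.approx(0.9)
    p.grad = np.array([1.0], np.float32)
    opt.step()                       # v = 1.5, p = 0.9 − 0.15
    assert p.data[0] == pytest.approx(0.75)
    assert nn.cosine_lr(1.0, 0, 11) == pytest.approx(1.0)
    assert nn.cosine_lr(1.0, 10, 11) == pytest.approx(0.0, abs=1e-12)
    assert nn.cosine_lr(1.0, 5, 11) == pytest.approx(0.5)


def test_state_dict_roundtrip(rng):
    class Tiny(nn.Module):
        def __init__(self):
            self.lin = nn.Linear(3, 2, rng)
            self.norm = nn.LayerNorm(2)

    a, b = Tiny(), Tiny()
    b.lin.weight.data += 1.0
    b.load_state_dict(a.state_dict())
    np.testing.assert_array_equal(a.lin.weight.data, b.lin.weight.data)
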