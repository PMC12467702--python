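import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maaseg.affinity import (AffinityConfig, AffinityMLP, AffinityScores,
                             affinity_loss, build_pair_sets, build_transition,
                             confidence_labels, finalize_pseudo_labels,
                             pair_affinity, par_refine, random_walk,
                             train_affinity)
from maaseg.errors import ConfigError, UndefinedLossError
from maaseg.nn import Tensor


# ---------------------------------------------------------------------------
# confidence labels
# ---------------------------------------------------------------------------

def test_confidence_label_branches():
    scores = np.array([[0.7, 0.2], [0.45, 0.6]])
    lab = confidence_labels(scores)
    assert lab.labels.tolist() == [[1, 0], [255, 1]]
    # boundary values: exactly β_h is foreground, exactly β_l background
    lab2 = confidence_labels(np.array([[0.6, 0.3]]))
    assert lab2.labels.tolist() == [[1, 0]]


def test_confidence_labels_background_competition():
    """With a background channel, the argmax decides: a dominant
    background maps to label 0 even at high score."""
    scores = np.stack([np.array([[0.9, 0.1]]),
                       np.array([[0.2, 0.95]])], axis=-1)
    lab = confidence_labels(scores, background_channel=1)
    assert lab.labels.tolist() == [[1, 0]]


def test_confidence_labels_threshold_validation():
    with pytest.raises(ConfigError):
        confidence_labels(np.zeros((2, 2)), beta_low=0.7, beta_high=0.6)
    with pytest.raises(ConfigError):
        confidence_labels(np.full((2, 2), 1.5))


# ---------------------------------------------------------------------------
# pair sets
# ---------------------------------------------------------------------------

def exhaustive_pairs(lab, r):
    """Brute-force double loop over all unordered in-radius pairs."""
    H, W = lab.shape
    pos, neg = set(), set()
    for i in range(H * W):
        yi, xi = divmod(i, W)
        for j in range(i + 1, H * W):
            yj, xj = divmod(j, W)
            if (yi - yj) ** 2 + (xi - xj) ** 2 > r * r:
                continue
            a, b = lab[yi, xi], lab[yj, xj]
            if a == 255 or b == 255:
                continue
            (pos if a == b else neg).add((i, j))
    return pos, neg


def canonical(pairs):
    return {(min(a, b), max(a, b)) for a, b in map(tuple, pairs)}


def test_center_cross_fixture():
    lab = np.zeros((3, 3), np.uint8)
    lab[1, 1] = 1
    ps = build_pair_sets(lab, r=1)
    assert ps.n_neg == 4 and ps.n_pos == 8


def test_uniform_and_all_uncertain():
    ones = np.ones((5, 5), np.uint8)
    ps = build_pair_sets(ones, r=2)
    assert ps.n_neg == 0 and ps.n_pos == len(exhaustive_pairs(ones, 2)[0])
    unk = np.full((5, 5), 255, np.uint8)
    ps2 = build_pair_sets(unk, r=2)
    assert ps2.n_pos == 0 and ps2.n_neg == 0


@given(h=st.integers(1, 12), w=st.integers(1, 12),
       r=st.sampled_from([1, 2, 3, 8]), seed=st.integers(0, 10 ** 6))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_pair_sets_match_exhaustive_oracle(h, w, r, seed):
    rng = np.random.default_rng(seed)
    lab = rng.choice([0, 1, 255], size=(h, w)).astype(np.uint8)
    ps = build_pair_sets(lab, r)
    pos, neg = exhaustive_pairs(lab, r)
    assert canonical(ps.positives) == pos
    assert canonical(ps.negatives) == neg


# ---------------------------------------------------------------------------
# affinity scoring and loss
# ---------------------------------------------------------------------------

def test_affinity_symmetry_and_zero_head(rng):
    mlp = AffinityMLP(feat_dim=4, seed=0)
    feat = rng.normal(size=(5, 5, 4))
    lab = rng.choice([0, 1, 255], size=(5, 5)).astype(np.uint8)
    desc = mlp.descriptors(feat, lab)
    assert pair_affinity(mlp, desc, 3, 17) == pytest.approx(
        pair_affinity(mlp, desc, 17, 3), abs=1e-6)
    mlp.fc3.weight.data[:] = 0.0
    mlp.fc3.bias.data[:] = 0.0
    scores = mlp.score_pairs(desc, np.array([[0, 1], [2, 9]]))
    np.testing.assert_allclose(scores.data, 0.0, atol=1e-7)


def test_affinity_loss_fixtures():
    mk = lambda v: Tensor(np.array(v, np.float64))
    assert float(affinity_loss(AffinityScores(mk([0.0]), mk([0.0]))).data) \
        == pytest.approx(1.0)
    # sigmoid(ln 3) = 0.75: loss = (1 − 0.75) + 0.25 = 0.5
    both = AffinityScores(positive=mk([math.log(3)]),
                          negative=mk([-math.log(3)]))
    assert float(affinity_loss(both).data) == pytest.approx(0.5)
    # saturated scores drive the loss to 0
    sat = AffinityScores(positive=mk([80.0]), negative=mk([-80.0]))
    assert float(affinity_loss(sat).data) == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(UndefinedLossError):
        affinity_loss(AffinityScores(mk([]), mk([])))


def test_affinity_loss_monotonicity():
    """Raising a positive-pair score lowers the loss; raising a
    negative-pair score raises it."""
    mk = lambda v: Tensor(np.array(v, np.float64))
    base = float(affinity_loss(AffinityScores(mk([0.2, -0.1]), mk([0.4]))).data)
    up_pos = float(affinity_loss(AffinityScores(mk([0.9, -0.1]), mk([0.4]))).data)
    up_neg = float(affinity_loss(AffinityScores(mk([0.2, -0.1]), mk([1.4]))).data)
    assert up_pos < base < up_neg


def test_train_affinity_separates_classes(rng):
    """On separable descriptors the learned affinity ranks same-label
    pairs above different-label pairs."""
    feat = np.zeros((10, 10, 2))
    lab = np.zeros((10, 10), np.uint8)
    lab[:, 5:] = 1
    feat[..., 0] = lab            # feature mirrors the class
    feat[..., 1] = rng.normal(size=(10, 10)) * 0.05
    mlp, log = train_affinity([feat], [lab],
                              AffinityConfig(r=3, iters=600, lr=0.05, seed=0))
    assert log["loss"][-1] < 0.2 < log["loss"][0]
    desc = mlp.descriptors((feat - feat.mean()) / feat.std(), lab)
    same = pair_affinity(mlp, desc, 0, 1)        # two background pixels
    diff = pair_affinity(mlp, desc, 4, 5)        # across the boundary
    assert same > diff


# ---------------------------------------------------------------------------
# PAR
# ---------------------------------------------------------------------------

def test_par_constant_fixed_point():
    img = np.full((9, 9, 3), 0.5)
    scores = np.full((9, 9), 0.7)
    out = par_refine(img, scores, iterations=5)
    np.testing.assert_allclose(out, 0.7, atol=1e-12)


def test_par_range_preserving(rng):
    img = rng.random((12, 12, 3))
    scores = rng.random((12, 12, 2))
    out = par_refine(img, scores, iterations=10)
    for k in range(2):
        assert out[..., k].min() >= scores[..., k].min() - 1e-12
        assert out[..., k].max() <= scores[..., k].max() + 1e-12


def test_par_attenuates_isolated_spike():
    img = np.full((9, 9, 3), 0.5)      # uniform color: kernels ~ spatial only
    scores = np.zeros((9, 9))
    scores[4, 4] = 1.0
    out = par_refine(img, scores, iterations=10, dilations=(1, 2))
    assert out[4, 4] < scores[4, 4]
    assert out.max() < 0.5


def test_par_respects_color_edges():
    """Smoothing leaks much less across a strong RGB boundary."""
    img = np.zeros((10, 10, 3))
    img[:, 5:] = 1.0
    scores = np.zeros((10, 10))
    scores[:, :5] = 1.0
    out = par_refine(img, scores, iterations=10, dilations=(1,))
    assert out[:, :4].mean() > 0.9
    assert out[:, 6:].mean() < 0.1


# ---------------------------------------------------------------------------
# random walk
# ---------------------------------------------------------------------------

def test_transition_row_stochastic(rng):
    pairs = np.array([[0, 1], [1, 2], [2, 3], [0, 3]])
    vals = rng.random(4)
    T = build_transition(pairs, vals, 6, beta=2.0)
    np.testing.assert_allclose(np.asarray(T.sum(axis=1)).ravel(), 1.0,
                               atol=1e-12)
    assert (T.toarray() >= 0).all()


def test_zero_affinity_is_identity_walk(rng):
    pairs = np.array([[0, 1]])
    T = build_transition(pairs, np.array([0.0]), 4, beta=2.0)
    scores = rng.random((2, 2))
    np.testing.assert_allclose(random_walk(scores, T, t=7), scores,
                               atol=1e-12)


def test_two_pixel_walk_converges_to_pair_mean():
    T = build_transition(np.array([[0, 1]]), np.array([1.0]), 2, beta=1.0)
    scores = np.array([[0.0, 1.0]])
    out = random_walk(scores, T, t=60)
    np.testing.assert_allclose(out, 0.5, atol=1e-9)


def test_negative_affinity_rejected():
    with pytest.raises(ConfigError):
        build_transition(np.array([[0, 1]]), np.array([-0.5]), 2)


# ---------------------------------------------------------------------------
# finalisation
# ---------------------------------------------------------------------------

def test_finalize_saturated_maps():
    high = np.full((4, 4), 0.9)
    assert (finalize_pseudo_labels(high) == 1).all()
    low = np.full((4, 4), 0.1)
    assert (finalize_pseudo_labels(low) == 0).all()


def test_finalize_upsamples_to_patch_resolution():
    scores = np.array([[0.9, 0.1], [0.1, 0.9]])
    out = finalize_pseudo_labels(scores, out_size=(8, 8))
    assert out.shape == (8, 8)
    assert set(np.unique(out)) <= {0, 1, 255}
    assert out[0, 0] == 1 and out[0, 7] == 0
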