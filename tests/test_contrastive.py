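"""Fused similarity, pseudo-labels, hard-sample weights, contrastive loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schsc.autodiff import Tensor
from schsc.contrastive import (
    fused_similarity,
    hard_sample_loss,
    high_confidence_set,
    indicator_matrix,
    pseudo_labels,
    weight_matrix,
)

from conftest import random_unit_rows


def infonce_oracle(S, W, m):
    """Scalar double-loop over the 2m anchors: positive is the other view of
    the same cell; denominator runs over the positive plus every embedding of
    every other cell in both views."""
    L = S * W
    total = 0.0
    for r in range(2 * m):
        pos = (r + m) % (2 * m)
        denom = 0.0
        for c in range(2 * m):
            if c == r:
                continue  # self pair excluded
            denom += np.exp(L[r, c])
        total += -np.log(np.exp(L[r, pos]) / denom)
    return total / (2 * m)


def make_views(rng, m, d):
    return tuple(random_unit_rows(rng, m, d) for _ in range(4))


def blobs(rng, K, per=40, d=2, sep=20.0):
    centers = rng.normal(size=(K, d)) * sep
    X = np.concatenate([centers[c] + rng.normal(size=(per, d)) for c in range(K)])
    labels = np.repeat(np.arange(K), per)
    return X, labels


# ---------------------------------------------------------------- fused S


def test_fused_similarity_alpha_extremes():
    rng = np.random.default_rng(0)
    Z1, Z2, E1, E2 = make_views(rng, 5, 4)
    Z = np.concatenate([Z1, Z2])
    E = np.concatenate([E1, E2])
    np.testing.assert_allclose(fused_similarity((Z1, Z2, E1, E2), 1.0), Z @ Z.T)
    np.testing.assert_allclose(fused_similarity((Z1, Z2, E1, E2), 0.0), E @ E.T)
    S = fused_similarity((Z1, Z2, E1, E2), 0.3)
    np.testing.assert_allclose(S, 0.3 * Z @ Z.T + 0.7 * E @ E.T)
    assert np.abs(S).max() <= 1 + 1e-9
    np.testing.assert_allclose(S, S.T, atol=1e-12)


def test_fused_similarity_single_identical_cell_is_all_ones():
    u = np.array([[1.0, 0.0]])
    S = fused_similarity((u, u, u, u), 0.5)
    np.testing.assert_allclose(S, np.ones((2, 2)))


def test_fused_similarity_rejects_bad_alpha():
    rng = np.random.default_rng(1)
    views = make_views(rng, 2, 3)
    with pytest.raises(ValueError):
        fused_similarity(views, 1.5)


# ---------------------------------------------------------------- pseudo-labels


@pytest.mark.parametrize("K", [2, 3, 5])
@pytest.mark.parametrize("method", ["leiden", "louvain"])
def test_blob_recovery(K, method):
    rng = np.random.default_rng(K)
    X, labels = blobs(rng, K)
    pl = pseudo_labels(X, K_target=K, graph_k=10, method=method, seed=0)
    assert pl.exact
    # communities must coincide with the blobs (up to relabeling)
    for c in range(K):
        assert len(np.unique(pl.P[labels == c])) == 1
    assert len(np.unique(pl.P)) == K


def test_single_cluster_target():
    X = np.zeros((10, 2))
    pl = pseudo_labels(X, K_target=1, graph_k=3)
    assert (pl.P == 0).all() and pl.exact


def test_target_too_large_errors():
    with pytest.raises(ValueError):
        pseudo_labels(np.zeros((5, 2)), K_target=5, graph_k=2)


def test_centers_are_member_means():
    rng = np.random.default_rng(9)
    X, _ = blobs(rng, 3)
    pl = pseudo_labels(X, K_target=3, graph_k=10)
    for c in range(3):
        np.testing.assert_allclose(pl.centers[c], X[pl.P == c].mean(axis=0))
    np.testing.assert_allclose(
        pl.dist_to_center, np.linalg.norm(X - pl.centers[pl.P], axis=1)
    )


def test_resolution_hint_short_circuits():
    rng = np.random.default_rng(10)
    X, _ = blobs(rng, 3)
    pl = pseudo_labels(X, K_target=3, graph_k=10)
    pl2 = pseudo_labels(X, K_target=3, graph_k=10, resolution_hint=pl.resolution)
    assert pl2.resolution == pl.resolution
    np.testing.assert_array_equal(pl.P, pl2.P)


# ---------------------------------------------------------------- confidence


def test_tau_one_selects_everyone():
    rng = np.random.default_rng(2)
    X, _ = blobs(rng, 2, per=10)
    pl = pseudo_labels(X, K_target=2, graph_k=5)
    assert len(high_confidence_set(pl, 1.0)) == 20


def test_floor_rule():
    rng = np.random.default_rng(3)
    X, _ = blobs(rng, 2, per=5)
    pl = pseudo_labels(X, K_target=2, graph_k=4)
    assert len(high_confidence_set(pl, 0.9)) == 9


def test_outlier_excluded():
    # 1-D: two tight blobs plus one point far from its own center
    X = np.array([[0.0], [0.1], [0.2], [30.0], [30.1], [33.0]])
    pl = pseudo_labels(X, K_target=2, graph_k=2)
    H = high_confidence_set(pl, 5 / 6)
    dist = pl.dist_to_center
    assert np.argmax(dist) not in H and len(H) == 5


def test_tau_out_of_range():
    rng = np.random.default_rng(4)
    X, _ = blobs(rng, 2, per=5)
    pl = pseudo_labels(X, K_target=2, graph_k=4)
    with pytest.raises(ValueError):
        high_confidence_set(pl, 0.0)


# ---------------------------------------------------------------- indicator


@pytest.mark.parametrize(
    "P,expected",
    [
        ([0, 0, 1], [[1, 1, 0], [1, 1, 0], [0, 0, 1]]),
        ([2, 2, 2], np.ones((3, 3))),
        ([0, 1, 2], np.eye(3)),
    ],
)
def test_indicator_matrix(P, expected):
    np.testing.assert_array_equal(indicator_matrix(np.array(P)), expected)


# ---------------------------------------------------------------- weights


def test_weight_edge_cases_by_hand():
    m = 2
    # construct S whose min-max normalization is known: entries in [0, 1]
    S = np.array(
        [
            [0.0, 1.0, 0.5, 0.25],
            [1.0, 0.0, 0.5, 0.5],
            [0.5, 0.5, 0.0, 1.0],
            [0.25, 0.5, 1.0, 0.0],
        ]
    )
    Q = np.array([[1.0, 1.0], [1.0, 1.0]])  # same pseudo-cluster
    H = np.array([0, 1])
    W = weight_matrix(S, Q, H, beta=2.0)
    # Norm(S) == S here; easiest positive (Norm 1) -> 0; Norm 0.5 -> 0.25
    assert W[0, 1] == 0.0
    assert W[0, 2] == pytest.approx(0.25)
    Q0 = np.zeros((2, 2))
    W0 = weight_matrix(S, Q0, H, beta=2.0)
    assert W0[0, 1] == 1.0  # hardest negative fully up-weighted


def test_weights_one_outside_confidence_set():
    rng = np.random.default_rng(5)
    m = 6
    S = rng.normal(size=(2 * m, 2 * m))
    Q = indicator_matrix(rng.integers(0, 2, m))
    H = np.array([0, 2, 4])
    W = weight_matrix(S, Q, H, beta=3.0)
    in_h = np.isin(np.arange(2 * m) % m, H)
    outside = ~(in_h[:, None] & in_h[None, :])
    assert (W[outside] == 1.0).all()
    assert (W >= 0).all() and (W <= 1).all()


def test_beta_zero_recovers_unit_weights():
    rng = np.random.default_rng(6)
    m = 4
    S = rng.normal(size=(2 * m, 2 * m))
    Q = indicator_matrix(rng.integers(0, 3, m))
    W = weight_matrix(S, Q, np.arange(m), beta=0.0)
    np.testing.assert_array_equal(W, np.ones((2 * m, 2 * m)))


def test_degenerate_similarity_warns_and_uses_half():
    S = np.full((4, 4), 0.7)
    Q = np.ones((2, 2))
    with pytest.warns(UserWarning, match="degenerate"):
        W = weight_matrix(S, Q, np.array([0, 1]), beta=1.0)
    np.testing.assert_allclose(W, 0.5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.floats(0.5, 4.0))
def test_weight_monotonicity_property(seed, beta):
    """Within H x H: W increases with Norm(S) for Q=0 pairs and decreases
    for Q=1 pairs (hard-mining monotonicity)."""
    rng = np.random.default_rng(seed)
    m = 5
    S = rng.normal(size=(2 * m, 2 * m))
    Q = indicator_matrix(rng.integers(0, 2, m))
    W = weight_matrix(S, Q, np.arange(m), beta=beta)
    normS = (S - S.min()) / (S.max() - S.min())
    Qbig = np.tile(Q, (2, 2))
    for qval, sign in [(0.0, 1), (1.0, -1)]:
        sel = Qbig == qval
        n, w = normS[sel], W[sel]
        order = np.argsort(n)
        assert (sign * np.diff(w[order]) >= -1e-12).all()


# ---------------------------------------------------------------- loss


def test_loss_zero_with_single_cell():
    S = np.array([[1.0, 0.3], [0.3, 1.0]])
    assert hard_sample_loss(S, np.ones((2, 2)), 1) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("m", [2, 3, 5])
def test_loss_matches_brute_force_oracle(m):
    rng = np.random.default_rng(m)
    S = rng.normal(size=(2 * m, 2 * m))
    S = (S + S.T) / 2
    W = rng.uniform(0, 1, size=(2 * m, 2 * m))
    W = (W + W.T) / 2
    got = hard_sample_loss(S, W, m)
    assert got == pytest.approx(infonce_oracle(S, W, m), abs=1e-6)


def test_unit_weights_reduce_to_plain_infonce():
    rng = np.random.default_rng(11)
    m = 4
    views = make_views(rng, m, 6)
    S = fused_similarity(views, 0.5)
    ones = np.ones((2 * m, 2 * m))
    assert hard_sample_loss(S, ones, m) == pytest.approx(
        infonce_oracle(S, ones, m), abs=1e-6
    )


def test_loss_invariant_under_cell_permutation():
    rng = np.random.default_rng(12)
    m = 6
    Z1, Z2, E1, E2 = make_views(rng, m, 4)
    perm = rng.permutation(m)
    S = fused_similarity((Z1, Z2, E1, E2), 0.4)
    Sp = fused_similarity((Z1[perm], Z2[perm], E1[perm], E2[perm]), 0.4)
    ones = np.ones((2 * m, 2 * m))
    assert hard_sample_loss(S, ones, m) == pytest.approx(
        hard_sample_loss(Sp, ones, m), abs=1e-10
    )


def test_loss_decreases_when_positive_similarity_rises():
    rng = np.random.default_rng(13)
    m = 3
    S = rng.normal(size=(2 * m, 2 * m))
    S = (S + S.T) / 2
    ones = np.ones((2 * m, 2 * m))
    base = hard_sample_loss(S, ones, m)
    S2 = S.copy()
    S2[0, m], S2[m, 0] = S2[0, m] + 0.1, S2[m, 0] + 0.1
    assert hard_sample_loss(S2, ones, m) < base


def test_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(14)
    m = 3
    S0 = rng.normal(size=(2 * m, 2 * m))
    W = rng.uniform(0.2, 1.0, size=(2 * m, 2 * m))
    S = Tensor(S0, requires_grad=True)
    loss = hard_sample_loss(S, W, m)
    loss.backward()
    eps = 1e-6
    for idx in [(0, 1), (2, 5), (4, 4)]:
        up, dn = S0.copy(), S0.copy()
        up[idx] += eps
        dn[idx] -= eps
        num = (hard_sample_loss(up, W, m) - hard_sample_loss(dn, W, m)) / (2 * eps)
        assert S.grad[idx] == pytest.approx(num, abs=1e-5)
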