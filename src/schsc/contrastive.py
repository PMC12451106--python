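"""Fused similarity, pseudo-labels, hard-sample weighting, contrastive loss.

The fused similarity blends attribute and structure cosine similarities over
the 2m stacked view embeddings:

    S(i^vk, j^vl) = alpha * <Z_i^vk, Z_j^vl> + (1 - alpha) * <E_i^vk, E_j^vl>

Pseudo-labels come from Leiden (or Louvain) on a KNN graph of the fused
embedding, with the resolution binary-searched so the community count hits
the requested K.  The high-confidence set H keeps the fraction tau of cells
closest to their own pseudo-cluster centroid.  Within H x H, pair (i, j) is
reweighted by

    W = |Q_ij - Norm(S)|^beta        (Norm = batch min-max normalization)

so hard positives (same pseudo-cluster, low similarity) and hard negatives
(different pseudo-cluster, high similarity) get weights near 1 while easy
pairs are damped toward 0; pairs outside H x H keep weight 1.  The loss is
an InfoNCE over the weighted logits S*W: each embedding's positive is the
same cell's other view, its negatives are all embeddings of other cells in
both views.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np

from .autodiff import Tensor
from .graph import knn_graph

__all__ = [
    "PseudoLabeling",
    "fused_similarity",
    "pseudo_labels",
    "high_confidence_set",
    "indicator_matrix",
    "weight_matrix",
    "hard_sample_loss",
]


@dataclass
class PseudoLabeling:
    P: np.ndarray  # (m,) cluster ids
    K_target: int
    resolution: float
    centers: np.ndarray  # (K, d) cluster means
    dist_to_center: np.ndarray  # (m,) Euclidean distance to own center
    achieved_K: int = None

    def __post_init__(self):
        if self.achieved_K is None:
            self.achieved_K = len(np.unique(self.P))

    @property
    def exact(self) -> bool:
        return self.achieved_K == self.K_target


def _stack_views(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        from .autodiff import concat

        return concat([Tensor._lift(a), Tensor._lift(b)], axis=0)
    return np.concatenate([a, b], axis=0)


def fused_similarity(views, alpha: float):
    """The 2m x 2m fused similarity S in block layout [[S11,S12],[S21,S22]].

    Accepts a :class:`~schsc.model.ViewEmbeddings` (Tensor path, used in
    training) and returns a Tensor, or plain arrays via a (Z1, Z2, E1, E2)
    tuple, returning an ndarray.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if hasattr(views, "Z_v1"):
        Z = _stack_views(views.Z_v1, views.Z_v2)
        E = _stack_views(views.E_v1, views.E_v2)
    else:
        Z1, Z2, E1, E2 = views
        Z = _stack_views(Z1, Z2)
        E = _stack_views(E1, E2)
    S = alpha * (Z @ Z.T) + (1.0 - alpha) * (E @ E.T)
    return S


def _community_count(g: igraph.Graph, resolution: float, method: str, seed: int):
    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.array(part.membership)
    elif method == "louvain":
        igraph.set_random_number_generator(random.Random(seed))
        labels = np.array(g.community_multilevel(resolution=resolution).membership)
    else:
        raise ValueError(f"unknown community method {method!r}")
    return labels, len(np.unique(labels))


def pseudo_labels(
    Z_fused,
    K_target: int,
    graph_k: int = 15,
    method: str = "leiden",
    seed: int = 0,
    resolution_hint: float | None = None,
    max_iter: int = 50,
) -> PseudoLabeling:
    """Cluster the fused embedding into (as close as possible to) K_target
    communities via resolution binary search on [1e-4, 10].

    ``resolution_hint`` (e.g. the resolution found in the previous epoch) is
    tried first, which usually short-circuits the search during training.  If
    K_target is unreachable within ``max_iter`` halvings the closest count is
    returned (ties toward the smaller count), flagged via ``exact``.
    """
    Z = np.asarray(getattr(Z_fused, "data", Z_fused), dtype=np.float64)
    m = Z.shape[0]
    if K_target < 1:
        raise ValueError("K_target must be >= 1")
    if m <= K_target:
        raise ValueError(f"need more cells ({m}) than target clusters ({K_target})")

    if K_target == 1:
        return _finish(Z, np.zeros(m, dtype=int), 1, 0.0)

    k = min(graph_k, m - 1)
    cg = knn_graph(Z, k)
    src, dst = cg.adjacency_sym.nonzero()
    keep = src < dst
    g = igraph.Graph(n=m, edges=list(zip(src[keep].tolist(), dst[keep].tolist())))

    best = None  # (|count-K|, count, resolution, labels)

    def try_res(res):
        nonlocal best
        labels, count = _community_count(g, res, method, seed)
        cand = (abs(count - K_target), count, res, labels)
        if best is None or cand[:2] < best[:2]:
            best = cand
        return labels, count

    if resolution_hint is not None:
        labels, count = try_res(resolution_hint)
        if count == K_target:
            return _finish(Z, labels, K_target, resolution_hint)

    lo, hi = 1e-4, 10.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        labels, count = try_res(mid)
        if count == K_target:
            return _finish(Z, labels, K_target, mid)
        if count < K_target:
            lo = mid
        else:
            hi = mid
    _, _, res, labels = best
    warnings.warn(
        f"resolution search reached {len(np.unique(labels))} communities "
        f"(target {K_target})"
    )
    return _finish(Z, _relabel(labels), K_target, res)


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _finish(Z, labels, K_target, resolution) -> PseudoLabeling:
    labels = _relabel(labels)
    ks = np.unique(labels)
    centers = np.stack([Z[labels == c].mean(axis=0) for c in ks])
    dist = np.linalg.norm(Z - centers[labels], axis=1)
    return PseudoLabeling(
        P=labels,
        K_target=K_target,
        resolution=float(resolution),
        centers=centers,
        dist_to_center=dist,
    )


def high_confidence_set(pl: PseudoLabeling, tau: float) -> np.ndarray:
    """Indices of the floor(tau*m) cells closest to their own cluster center.

    Selection is global (one cut across all clusters); distance ties break
    toward the lower cell index.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    m = len(pl.P)
    h = int(np.floor(tau * m))
    order = np.argsort(pl.dist_to_center, kind="stable")
    return np.sort(order[:h])


def indicator_matrix(P: np.ndarray) -> np.ndarray:
    """Q_ij = 1 iff P_i == P_j (symmetric, unit diagonal)."""
    P = np.asarray(P)
    return (P[:, None] == P[None, :]).astype(np.float64)


def weight_matrix(S: np.ndarray, Q: np.ndarray, H: np.ndarray, beta: float) -> np.ndarray:
    """Hard-sample weights over the 2m x 2m similarity.

    W = |Q_ij - Norm(S)|^beta when both cells i, j are in H, else 1.  The
    cell behind embedding row r is r mod m (two stacked views); Norm is
    min-max over the whole batch S.  beta=0 gives W == 1 (0^0 := 1), i.e.
    the unweighted loss.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    S = np.asarray(S, dtype=np.float64)
    two_m = S.shape[0]
    m = two_m // 2
    smin, smax = S.min(), S.max()
    if smax - smin < 1e-12:
        warnings.warn("degenerate similarity range; Norm(S) set to 0.5")
        normS = np.full_like(S, 0.5)
    else:
        normS = (S - smin) / (smax - smin)
    in_h = np.zeros(m, dtype=bool)
    in_h[np.asarray(H, dtype=int)] = True
    row_in_h = np.tile(in_h, 2)
    pair_mask = row_in_h[:, None] & row_in_h[None, :]
    Qbig = np.tile(np.asarray(Q, dtype=np.float64), (2, 2))
    W = np.ones_like(S)
    base = np.abs(Qbig - normS)
    W[pair_mask] = base[pair_mask] ** beta  # numpy: 0**0 == 1
    return W


def hard_sample_loss(S, W, m: int):
    """Weighted InfoNCE over the 2m stacked views.

    For anchor r, the positive is the same cell's other view (row (r+m) mod
    2m); the denominator runs over the positive plus all embeddings of other
    cells in both views (self-pair excluded).  Logits are S*W elementwise;
    the result is the mean over all 2m anchors.

    Returns a Tensor when ``S`` is a Tensor (training path, gradients flow
    through S only; W is a constant), otherwise a float.
    """
    if m == 0:
        raise ValueError("m must be >= 1")
    tensor_in = isinstance(S, Tensor)
    St = S if tensor_in else Tensor(np.asarray(S, dtype=np.float64))
    W = np.asarray(getattr(W, "data", W), dtype=np.float64)
    two_m = 2 * m
    if St.shape != (two_m, two_m) or W.shape != (two_m, two_m):
        raise ValueError("S and W must be 2m x 2m")

    logits = St * Tensor(W)
    # positive partner of row r is (r + m) mod 2m
    pos = np.zeros((two_m, two_m))
    idx = np.arange(two_m)
    pos[idx, (idx + m) % two_m] = 1.0
    # denominator: all columns except the self pair (r, r)
    mask = np.ones((two_m, two_m))
    np.fill_diagonal(mask, 0.0)

    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # detached
    expl = (logits - shift).exp() * Tensor(mask)
    lse = expl.sum(axis=1, keepdims=True).log() + shift
    pos_logit = (logits * Tensor(pos)).sum(axis=1, keepdims=True)
    loss = (lse - pos_logit).mean()
    return loss if tensor_in else loss.item()
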