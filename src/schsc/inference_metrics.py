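"""Final cluster assignment and clustering quality metrics.

After training, every cell is forwarded through the attribute encoders to get
its fused embedding; a KNN graph on those embeddings is clustered with
Louvain at a resolution binary-searched to hit the requested number of
clusters.  Agreement with ground truth is scored with clustering accuracy
(optimal label matching via the Hungarian algorithm), normalized mutual
information and the adjusted Rand index; the label-free indices are
compactness (mean distance of cells to their own centroid, lower is tighter)
and separation (mean pairwise distance between centroids, higher is better).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .contrastive import pseudo_labels
from .model import SCHSCModel

__all__ = [
    "ClusteringResult",
    "embed_all",
    "final_clustering",
    "clustering_accuracy",
    "nmi_ari",
    "compactness_separation",
]


@dataclass
class ClusteringResult:
    embeddings: np.ndarray  # (N, d)
    labels: np.ndarray  # (N,) in [0, K)
    K: int
    resolution_used: float


def embed_all(X_filtered, A_sym, model: SCHSCModel, batch_size: int = 512) -> np.ndarray:
    """Fused attribute embedding (Z_v1 + Z_v2)/2 for every cell.

    Forward passes are batched but per-row, so batching cannot change the
    result; cell order is preserved.
    """
    X_filtered = np.asarray(X_filtered, dtype=np.float64)
    A = A_sym.toarray() if hasattr(A_sym, "toarray") else np.asarray(A_sym)
    out = []
    for start in range(0, X_filtered.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        views = model.encode_views(X_filtered[sl], A[sl])
        out.append(views.Z_fused.data)
    return np.concatenate(out, axis=0)


def final_clustering(
    embeddings: np.ndarray,
    k: int,
    K_target: int,
    method: str = "louvain",
    seed: int = 0,
) -> ClusteringResult:
    """Louvain on the KNN graph of the embeddings, resolution-searched to
    K_target (shares the routine used for training pseudo-labels)."""
    pl = pseudo_labels(embeddings, K_target=K_target, graph_k=k, method=method, seed=seed)
    return ClusteringResult(
        embeddings=np.asarray(embeddings),
        labels=pl.P,
        K=pl.achieved_K,
        resolution_used=pl.resolution,
    )


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((len(pu), len(tu)), dtype=np.int64)
    np.add.at(table, (pi, ti), 1)
    return table


def clustering_accuracy(pred, truth) -> float:
    """ACC: matched fraction under the best one-to-one label assignment."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    table = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(-table)
    return table[rows, cols].sum() / len(pred)


def nmi_ari(pred, truth) -> tuple[float, float]:
    """Normalized mutual information (arithmetic normalization) and ARI."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return (
        float(normalized_mutual_info_score(truth, pred, average_method="arithmetic")),
        float(adjusted_rand_score(truth, pred)),
    )


def compactness_separation(embeddings, labels) -> tuple[float, float | None]:
    """Label-free clustering quality.

    Compactness: mean Euclidean distance of cells to their own cluster
    centroid.  Separation: mean pairwise Euclidean distance between
    centroids; undefined (None) for a single cluster.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    centers = np.stack([X[labels == c].mean(axis=0) for c in ks])
    idx = np.searchsorted(ks, labels)
    compact = float(np.linalg.norm(X - centers[idx], axis=1).mean())
    if len(ks) < 2:
        return compact, None
    sep = float(
        np.mean([np.linalg.norm(centers[a] - centers[b]) for a, b in combinations(range(len(ks)), 2)])
    )
    return compact, sep
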