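"""Synthetic scRNA-seq counts with planted cluster structure.

Counts follow the same zero-inflated negative binomial data model the
likelihood assumes: each cluster has a mean profile equal to ``base_mean``
with a disjoint block of marker genes multiplied by ``marker_fold``; each
cell gets a size factor drawn log-uniform on [1/spread, spread]; counts are
drawn NB(mean * size_factor, theta) and then zeroed independently with
probability ``pi`` (technical dropout).  Ground-truth labels and parameters
are returned so recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import CountMatrix, write_counts

__all__ = ["SyntheticSpec", "generate", "fixture_small", "write_dataset"]


@dataclass
class SyntheticSpec:
    K: int = 5
    n_per_cluster: tuple = (100, 100, 100, 100, 100)
    n_genes: int = 300
    n_marker_genes_per_cluster: int = 20
    base_mean: float = 0.5
    marker_fold: float = 8.0
    theta: float = 2.0
    pi: float = 0.2
    library_size_spread: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_cluster) != self.K:
            raise ValueError("n_per_cluster length must equal K")
        if self.K * self.n_marker_genes_per_cluster > self.n_genes:
            raise ValueError("marker blocks exceed the gene panel")
        if not (self.base_mean > 0 and self.theta > 0 and self.marker_fold > 1):
            raise ValueError("base_mean, theta must be > 0 and marker_fold > 1")
        if not 0 <= self.pi < 1:
            raise ValueError("pi must lie in [0, 1)")
        if self.library_size_spread < 1:
            raise ValueError("library_size_spread must be >= 1")

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_per_cluster))


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, np.ndarray, dict]:
    """Draw a count matrix; returns (CountMatrix, labels, true_params)."""
    rng = np.random.default_rng(spec.seed)
    N, G = spec.n_cells, spec.n_genes

    means = np.full((spec.K, G), spec.base_mean)
    nm = spec.n_marker_genes_per_cluster
    for c in range(spec.K):
        means[c, c * nm : (c + 1) * nm] *= spec.marker_fold

    labels = np.repeat(np.arange(spec.K), spec.n_per_cluster)
    log_s = np.log(spec.library_size_spread)
    size_factors = np.exp(rng.uniform(-log_s, log_s, size=N))

    mu = means[labels] * size_factors[:, None]
    # NB via the gamma-Poisson mixture: works for any real theta > 0
    lam = rng.gamma(shape=spec.theta, scale=mu / spec.theta)
    counts = rng.poisson(lam)
    if spec.pi > 0:
        counts[rng.random(size=counts.shape) < spec.pi] = 0

    cm = CountMatrix(
        counts=counts.astype(np.int64),
        cell_ids=[f"cell_{i:05d}" for i in range(N)],
        gene_ids=[f"gene_{j:05d}" for j in range(G)],
        labels=labels,
    )
    truth = {
        "cluster_means": means,
        "size_factors": size_factors,
        "theta": spec.theta,
        "pi": spec.pi,
        "labels": labels,
    }
    return cm, labels, truth


def fixture_small() -> tuple[SyntheticSpec, CountMatrix, np.ndarray, dict]:
    """The preconfigured 5-cluster instance used throughout the tests:
    5 x 100 cells, 300 genes, 20 markers/cluster at 8-fold, theta 2,
    dropout 0.2, seed 0 — sized so full training runs in minutes on one CPU."""
    spec = SyntheticSpec()
    cm, labels, truth = generate(spec)
    return spec, cm, labels, truth


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> None:
    """Write MTX triplet + labels TSV + parameter JSON (CLI `simulate`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm, labels, truth = generate(spec)
    write_counts(cm, out, format="mtx")
    pd.DataFrame({"cell_id": cm.cell_ids, "label": labels}).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
    params = asdict(spec)
    params["n_per_cluster"] = list(spec.n_per_cluster)
    (out / "params.json").write_text(json.dumps(params, indent=2))
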