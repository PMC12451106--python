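"""Count-matrix IO and the preprocessing chain.

Raw counts (cells x genes) are read from 10x-style MTX triplets, CSV or h5ad,
then pushed through the standard single-cell chain: low-count gene/cell
filtering, median-target library-size normalization, log1p, highly variable
gene (HVG) selection and per-gene standardization.  The raw counts of the
retained cells, restricted to the HVG panel, are kept alongside the
standardized matrix because the zero-inflated negative binomial likelihood is
evaluated against raw counts, not normalized values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix, issparse

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "PreprocessedData",
    "read_counts",
    "write_counts",
    "filter_min_counts",
    "normalize_and_log",
    "select_hvg",
    "standardize",
    "preprocess",
]


@dataclass
class CountMatrix:
    """Raw integer counts with cell/gene identifiers.

    Labels, when present, are ground-truth cell types used only for
    evaluation; nothing in the pipeline reads them.
    """

    counts: np.ndarray  # (n_cells, n_genes) non-negative integers
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        n, p = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != p:
            raise ValueError("id lists inconsistent with counts shape")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene_ids")

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class NormalizedMatrix:
    """Standardized expression over the selected HVG panel."""

    values: np.ndarray  # (n_cells, n_hvg)
    hvg_index: np.ndarray  # indices into the original gene list
    per_gene_mean: np.ndarray
    per_gene_sd: np.ndarray
    cell_library_size: np.ndarray


@dataclass
class PreprocessedData:
    """Bundle handed to graph construction and training."""

    X: np.ndarray  # standardized (n_cells, p)
    raw_hvg: np.ndarray  # raw counts restricted to the HVG panel
    library_size: np.ndarray  # per-cell total count (pre-normalization)
    cell_ids: list[str]
    gene_ids: list[str]  # HVG gene ids
    hvg_index: np.ndarray
    per_gene_mean: np.ndarray = field(default=None, repr=False)
    per_gene_sd: np.ndarray = field(default=None, repr=False)
    labels: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]


def _as_int_counts(values: np.ndarray, context: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite count in {context}")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, rtol=0, atol=1e-8):
        raise ValueError(f"non-integer count in {context}")
    return rounded.astype(np.int64)


def read_counts(
    path: str | Path,
    format: str,
    transpose: bool = False,
    layer: str | None = None,
) -> CountMatrix:
    """Read a raw count matrix.

    Parameters
    ----------
    path:
        For ``mtx``, a directory containing ``matrix.mtx``, ``barcodes.tsv``
        and ``features.tsv``; for ``csv``/``h5ad`` the file itself.
    format:
        One of ``{"mtx", "csv", "h5ad"}``.
    transpose:
        Set when an MTX triplet is stored genes x cells (the 10x convention)
        so it is transposed to cells x genes.
    layer:
        For h5ad, the name of the layer holding raw counts; default uses
        ``adata.X``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        counts = _as_int_counts(df.to_numpy(), str(path))
        return CountMatrix(counts, [str(c) for c in df.index], [str(g) for g in df.columns])
    if format == "mtx":
        mat = mmread(path / "matrix.mtx")
        if issparse(mat):
            mat = mat.toarray()
        if transpose:
            mat = mat.T
        barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].astype(str).tolist()
        feats = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0].astype(str).tolist()
        counts = _as_int_counts(mat, str(path))
        if counts.shape != (len(barcodes), len(feats)):
            raise ValueError(
                f"matrix shape {counts.shape} does not match "
                f"{len(barcodes)} barcodes x {len(feats)} features"
            )
        return CountMatrix(counts, barcodes, feats)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.layers[layer] if layer is not None else adata.X
        if issparse(X):
            X = X.toarray()
        counts = _as_int_counts(np.asarray(X), str(path))
        return CountMatrix(
            counts, adata.obs_names.astype(str).tolist(), adata.var_names.astype(str).tolist()
        )
    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, path: str | Path, format: str) -> None:
    """Write a count matrix (inverse of :func:`read_counts`)."""
    path = Path(path)
    if format == "csv":
        pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids).to_csv(path)
        return
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(path / "matrix.mtx", csr_matrix(cm.counts))
        pd.Series(cm.cell_ids).to_csv(path / "barcodes.tsv", index=False, header=False)
        pd.Series(cm.gene_ids).to_csv(path / "features.tsv", index=False, header=False)
        return
    raise ValueError(f"unknown format {format!r}")


def filter_min_counts(cm: CountMatrix, min_counts: int = 1) -> CountMatrix:
    """Drop genes, then cells, whose total count is below ``min_counts``."""
    if min_counts < 0:
        raise ValueError("min_counts must be >= 0")
    gene_keep = cm.counts.sum(axis=0) >= min_counts
    if not gene_keep.any():
        raise ValueError("all genes removed by filtering")
    counts = cm.counts[:, gene_keep]
    cell_keep = counts.sum(axis=1) >= min_counts
    if not cell_keep.any():
        raise ValueError("all cells removed by filtering")
    return CountMatrix(
        counts[cell_keep],
        [c for c, k in zip(cm.cell_ids, cell_keep) if k],
        [g for g, k in zip(cm.gene_ids, gene_keep) if k],
        labels=None if cm.labels is None else np.asarray(cm.labels)[cell_keep],
    )


def normalize_and_log(cm: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Median-target library-size normalization followed by log1p.

    Each cell's counts are scaled so its total equals the median total over
    all cells, then log1p is applied.  Returns the log-normalized matrix and
    the original per-cell totals (library sizes), which the ZINB size factor
    needs later.
    """
    totals = cm.counts.sum(axis=1).astype(np.float64)
    if (totals <= 0).any():
        raise ValueError("cell with zero total count; filter first")
    target = np.median(totals)
    scaled = cm.counts * (target / totals)[:, None]
    return np.log1p(scaled), totals


def select_hvg(log_matrix: np.ndarray, p: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Dispersion-based highly variable gene selection.

    Per-gene mean and dispersion (variance/mean) are computed on the
    back-transformed (``expm1``) log-normalized values; genes are placed in
    ``n_bins`` equal-frequency bins by mean; dispersions are z-scored within
    each bin; the top ``p`` genes by normalized dispersion are returned
    (ties broken toward the lower gene index).  Indices come back sorted
    ascending so downstream column order matches the input.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    n_genes = log_matrix.shape[1]
    if p >= n_genes:
        if p > n_genes:
            warnings.warn(
                f"requested {p} HVGs but only {n_genes} genes available; keeping all"
            )
        return np.arange(n_genes)
    expr = np.expm1(log_matrix)
    mean = expr.mean(axis=0)
    var = expr.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # equal-frequency binning by mean; duplicate quantile edges collapse so
    # genes with identical means always share a bin
    try:
        bins = pd.qcut(mean, q=min(n_bins, n_genes), labels=False, duplicates="drop")
    except ValueError:  # all means identical -> single bin
        bins = np.zeros(n_genes, dtype=int)
    z = np.zeros(n_genes)
    for b in np.unique(bins):
        idx = np.where(bins == b)[0]
        mu, sd = disp[idx].mean(), disp[idx].std()
        z[idx] = (disp[idx] - mu) / sd if sd > 0 else 0.0
    # sort by descending z, ties toward lower index
    order = np.lexsort((np.arange(n_genes), -z))
    return np.sort(order[:p])


def standardize(matrix: np.ndarray, hvg_index: np.ndarray) -> NormalizedMatrix:
    """Center and scale each HVG column to zero mean, unit (population) sd.

    Constant columns are centered to zero and left there rather than dropped,
    so the panel width stays fixed.
    """
    sub = np.asarray(matrix)[:, hvg_index].astype(np.float64)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0)  # population sd (ddof=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    values = (sub - mean) / safe_sd
    return NormalizedMatrix(
        values=values,
        hvg_index=np.asarray(hvg_index),
        per_gene_mean=mean,
        per_gene_sd=safe_sd,
        cell_library_size=None,
    )


def preprocess(cm: CountMatrix, p: int = 2000, min_counts: int = 1) -> PreprocessedData:
    """Run the full chain: filter -> normalize/log1p -> HVG -> standardize."""
    cm = filter_min_counts(cm, min_counts)
    log_matrix, lib = normalize_and_log(cm)
    hvg = select_hvg(log_matrix, p)
    nm = standardize(log_matrix, hvg)
    nm.cell_library_size = lib
    return PreprocessedData(
        X=nm.values,
        raw_hvg=cm.counts[:, hvg],
        library_size=lib,
        cell_ids=cm.cell_ids,
        gene_ids=[cm.gene_ids[i] for i in hvg],
        hvg_index=hvg,
        per_gene_mean=nm.per_gene_mean,
        per_gene_sd=nm.per_gene_sd,
        labels=cm.labels,
    )
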