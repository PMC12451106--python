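"""Training loop: batch sampling, forward passes, loss, optimization.

Each epoch shuffles the cells and walks them in chunks of the batch size, so
every cell is visited exactly once per epoch (sampling without replacement);
an independent-draw mode is available by flag.  Per iteration the batch's
filtered expression rows and (symmetrized) adjacency rows are encoded into
the four views, the fused similarity is formed, pseudo-labels / the
high-confidence set / the indicator matrix are refreshed (once per epoch by
default), the hard-sample contrastive loss and the ZINB reconstruction loss
are combined with the balance coefficient omega, and one Adam step is taken.

Pseudo-labels, the confidence set, the weight matrix and the min-max
normalization statistics are discrete/selection quantities and are treated
as constants: no gradient flows through them.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import contrastive
from .autodiff import Adam
from .graph import CellGraph, knn_graph, laplacian_filter
from .io_preprocess import PreprocessedData
from .model import EncoderConfig, SCHSCModel
from .zinb_loss import OmegaState, combine_losses, zinb_nll

__all__ = ["TrainConfig", "TrainHistory", "BatchSampler", "sample_batch", "train", "TrainingError"]


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    K_target: int
    m: int = 1000  # batch size (clipped to N)
    epochs: int = 200
    lr: float = 1e-3
    alpha: float = 0.5  # attribute/structure fusion weight
    beta: float = 2.0  # hard-sample focusing coefficient
    tau: float = 0.9  # high-confidence fraction
    k: int = 15  # KNN neighbors for the cell graph
    p: int = 2000  # HVG panel width (used upstream in preprocessing)
    seed: int = 0
    omega_mode: str = "dynamic"  # "dynamic" or a fixed float via omega_fixed
    omega_fixed: float = 1.0
    community: str = "leiden"
    pseudo_refresh: str = "epoch"  # or "iteration"
    sampling: str = "partition"  # or "independent"
    embed_dim: int = 32
    hidden_dims: tuple = (512, 256)
    struct_hidden_dims: tuple = (256,)
    early_stop_window: int = 10
    early_stop_tol: float = 1e-4
    # ablation switches: weighting=False forces W == 1; contrastive_weight=0
    # disables the contrastive term entirely (pure ZINB autoencoder)
    weighting: bool = True
    contrastive_weight: float = 1.0


@dataclass
class TrainHistory:
    L_hs: list = field(default_factory=list)
    L_zinb: list = field(default_factory=list)
    omega: list = field(default_factory=list)
    total: list = field(default_factory=list)
    wall_time: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "L_hs": self.L_hs,
                "L_zinb": self.L_zinb,
                "omega": self.omega,
                "total": self.total,
                "wall_time": self.wall_time,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class BatchSampler:
    """Yields batches of distinct cell indices.

    In ``partition`` mode successive calls within an epoch partition the
    dataset: the permutation is reshuffled once exhausted, so an epoch is
    ceil(N/m) iterations with the last batch possibly smaller.  In
    ``independent`` mode every call draws m indices without replacement,
    independently of previous calls.
    """

    def __init__(self, N: int, m: int, seed: int = 0, mode: str = "partition"):
        if m < 1:
            raise ValueError("m must be >= 1")
        self.N = N
        self.m = min(m, N)
        self.mode = mode
        self.rng = np.random.default_rng(seed)
        self._perm = None
        self._pos = 0

    @property
    def iters_per_epoch(self) -> int:
        return int(np.ceil(self.N / self.m))

    def sample(self) -> np.ndarray:
        if self.mode == "independent":
            return self.rng.choice(self.N, size=self.m, replace=False)
        if self._perm is None or self._pos >= self.N:
            self._perm = self.rng.permutation(self.N)
            self._pos = 0
        batch = self._perm[self._pos : self._pos + self.m]
        self._pos += self.m
        return batch


def sample_batch(N: int, m: int, sampler: BatchSampler | None = None, seed: int = 0):
    """Draw one batch of distinct indices (see :class:`BatchSampler`)."""
    if sampler is None:
        sampler = BatchSampler(N, m, seed=seed)
    return sampler.sample()


def train(
    data: PreprocessedData,
    cfg: TrainConfig,
    graph: CellGraph | None = None,
) -> tuple[SCHSCModel, TrainHistory, CellGraph, np.ndarray]:
    """Train the model on a preprocessed bundle.

    Returns ``(model, history, graph, X_filtered)``; the graph and filtered
    matrix are reused for whole-dataset embedding at inference time.
    """
    N, p = data.X.shape
    if graph is None:
        graph = knn_graph(data.X, min(cfg.k, N - 1))
    Xf = laplacian_filter(graph, data.X)
    A_sym = graph.adjacency_sym.toarray()

    model = SCHSCModel(
        EncoderConfig(
            input_dim_attr=p,
            input_dim_struct=N,
            hidden_dims=tuple(cfg.hidden_dims),
            struct_hidden_dims=tuple(cfg.struct_hidden_dims),
            embed_dim=cfg.embed_dim,
            seed=cfg.seed,
        )
    )
    opt = Adam(model.parameters(), lr=cfg.lr)
    omega_state = OmegaState(
        mode="fixed" if cfg.omega_mode != "dynamic" else "dynamic",
        fixed_value=cfg.omega_fixed,
    )
    sampler = BatchSampler(N, cfg.m, seed=cfg.seed, mode=cfg.sampling)
    history = TrainHistory()
    lib_median = np.median(data.library_size)
    res_hint = None

    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        ep_hs, ep_zinb, ep_total = [], [], []
        for it in range(sampler.iters_per_epoch):
            idx = sampler.sample()
            m_batch = len(idx)
            views = model.encode_views(Xf[idx], A_sym[idx])

            if cfg.contrastive_weight != 0.0:
                S = contrastive.fused_similarity(views, cfg.alpha)
                # Q and H are defined on the cells of the current batch, so a
                # new batch always triggers recomputation; "epoch" mode only
                # skips re-clustering when the same cells are re-visited
                # (single-batch epochs, m >= N).
                refresh = (
                    True
                    if cfg.pseudo_refresh == "iteration"
                    else (it == 0 or sampler.iters_per_epoch > 1)
                )
                if cfg.weighting:
                    if refresh:
                        pl = contrastive.pseudo_labels(
                            views.Z_fused.data,
                            K_target=min(cfg.K_target, m_batch - 1),
                            graph_k=min(cfg.k, m_batch - 1),
                            method=cfg.community,
                            seed=cfg.seed,
                            resolution_hint=res_hint,
                        )
                        res_hint = pl.resolution
                        H = contrastive.high_confidence_set(pl, cfg.tau)
                        Q = contrastive.indicator_matrix(pl.P)
                    W = contrastive.weight_matrix(S.data, Q, H, cfg.beta)
                else:
                    W = np.ones((2 * m_batch, 2 * m_batch))
                L_hs = contrastive.hard_sample_loss(S, W, m_batch)
            else:
                from .autodiff import Tensor

                L_hs = Tensor(0.0)

            # size factors relative to the global median so batch composition
            # does not move them
            params = model.zinb_decode(
                views.Z_fused, data.library_size[idx], median=lib_median
            )
            L_zinb = zinb_nll(data.raw_hvg[idx], params)

            if it == 0:
                omega_state.update(float(L_hs.data), float(L_zinb.data))
            total, bd = combine_losses(
                cfg.contrastive_weight * L_hs if cfg.contrastive_weight != 1.0 else L_hs,
                L_zinb,
                omega_state,
            )
            if not np.isfinite(bd.total):
                raise TrainingError(f"non-finite loss at epoch {epoch}, iteration {it}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_hs.append(bd.L_hs)
            ep_zinb.append(bd.L_zinb)
            ep_total.append(bd.total)

        history.L_hs.append(float(np.mean(ep_hs)))
        history.L_zinb.append(float(np.mean(ep_zinb)))
        history.omega.append(float(omega_state.value))
        history.total.append(float(np.mean(ep_total)))
        history.wall_time.append(time.perf_counter() - t0)

        w = cfg.early_stop_window
        if len(history.total) > w:
            prev, cur = history.total[-w - 1], history.total[-1]
            if abs(cur - prev) / max(abs(prev), 1e-12) < cfg.early_stop_tol:
                break

    return model, history, graph, Xf
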