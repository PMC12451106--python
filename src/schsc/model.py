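"""Dual attribute/structure encoders, fused embedding, and ZINB decoder heads.

Two independently initialized attribute encoders map the Laplacian-filtered
expression rows to d-dimensional embeddings Z^v1, Z^v2; two structure encoders
do the same for the cells' adjacency rows (E^v1, E^v2).  Every embedding row
is l2-normalized so that dot products between views are cosine similarities.
The fused embedding Z = (Z^v1 + Z^v2)/2 feeds three single-layer decoder heads
producing the zero-inflated negative binomial parameters per cell and gene:

    Pi    = sigmoid(Z W_pi + b)          dropout probability, in (0, 1)
    Mu    = exp(Z W_mu + b) * s_i        NB mean, scaled by the cell's size factor
    Theta = exp(Z W_theta + b)           NB dispersion

with size factor s_i = library_size_i / median(library_size).  All outputs
are clamped to numeric-safety bounds so the log-gamma terms of the likelihood
stay finite for any finite weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor

__all__ = ["EncoderConfig", "ViewEmbeddings", "ZINBParams", "SCHSCModel"]

_EPS = 1e-6
_BIG = 1e6


@dataclass
class EncoderConfig:
    input_dim_attr: int  # p, HVG panel width
    input_dim_struct: int  # N, adjacency row length
    hidden_dims: tuple = (512, 256)  # attribute encoder widths
    struct_hidden_dims: tuple = (256,)
    embed_dim: int = 32
    activation: str = "elu"
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be non-empty")


@dataclass
class ViewEmbeddings:
    """The four per-batch view embeddings plus their fusion (all m x d)."""

    Z_v1: Tensor
    Z_v2: Tensor
    E_v1: Tensor
    E_v2: Tensor
    Z_fused: Tensor = field(init=False)

    def __post_init__(self):
        self.Z_fused = (self.Z_v1 + self.Z_v2) * 0.5


@dataclass
class ZINBParams:
    Pi: Tensor  # (m, p) in (0, 1)
    Mu: Tensor  # (m, p) > 0, size-factor scaled
    Theta: Tensor  # (m, p) > 0


class _MLP:
    """Fully connected stack with ELU between layers, linear last layer."""

    def __init__(self, dims: list[int], seed: int):
        rng = np.random.default_rng(seed)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(
                Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)), requires_grad=True)
            )
            self.biases.append(
                Tensor(rng.uniform(-bound, bound, size=(fan_out,)), requires_grad=True)
            )

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < last:
                h = h.elu()
        return h

    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases


def _l2_normalize(z: Tensor) -> Tensor:
    norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    return z / norm


class SCHSCModel:
    """The full network: four encoders plus the three ZINB decoder heads.

    The two encoders of a pair are initialized from ``seed`` and ``seed+1``
    (attribute) and ``seed+2``/``seed+3`` (structure) so the views differ at
    initialization; decoder heads use ``seed+4``.
    """

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        d = cfg.embed_dim
        attr_dims = [cfg.input_dim_attr, *cfg.hidden_dims, d]
        struct_dims = [cfg.input_dim_struct, *cfg.struct_hidden_dims, d]
        self.f_z1 = _MLP(attr_dims, cfg.seed)
        self.f_z2 = _MLP(attr_dims, cfg.seed + 1)
        self.f_e1 = _MLP(struct_dims, cfg.seed + 2)
        self.f_e2 = _MLP(struct_dims, cfg.seed + 3)
        # single affine heads from the fused embedding
        self.dec_pi = _MLP([d, cfg.input_dim_attr], cfg.seed + 4)
        self.dec_mu = _MLP([d, cfg.input_dim_attr], cfg.seed + 5)
        self.dec_theta = _MLP([d, cfg.input_dim_attr], cfg.seed + 6)

    # -- forward passes -------------------------------------------------
    def encode_views(self, X_sub, A_sub) -> ViewEmbeddings:
        """Encode a batch: filtered features X_sub (m x p), adjacency rows
        A_sub (m x N).  Rows of every view are l2-normalized."""
        X_sub = X_sub if isinstance(X_sub, Tensor) else Tensor(np.atleast_2d(X_sub))
        A_sub = A_sub if isinstance(A_sub, Tensor) else Tensor(np.atleast_2d(A_sub))
        if X_sub.shape[1] != self.cfg.input_dim_attr:
            raise ValueError("X_sub width does not match input_dim_attr")
        if A_sub.shape[1] != self.cfg.input_dim_struct:
            raise ValueError("A_sub width does not match input_dim_struct")
        if X_sub.shape[0] == 0:
            empty = Tensor(np.zeros((0, self.cfg.embed_dim)))
            return ViewEmbeddings(empty, empty, empty, empty)
        return ViewEmbeddings(
            _l2_normalize(self.f_z1(X_sub)),
            _l2_normalize(self.f_z2(X_sub)),
            _l2_normalize(self.f_e1(A_sub)),
            _l2_normalize(self.f_e2(A_sub)),
        )

    def zinb_decode(self, Z_fused: Tensor, library_size, median: float | None = None) -> ZINBParams:
        """Decode the fused embedding into per-cell-per-gene (Pi, Mu, Theta).

        ``median`` lets the caller fix the size-factor denominator (e.g. the
        whole-dataset median during mini-batch training); by default the
        median of the passed library sizes is used.
        """
        lib = np.asarray(library_size, dtype=np.float64)
        if (lib <= 0).any():
            raise ValueError("library sizes must be positive")
        size_factor = lib / (np.median(lib) if median is None else float(median))
        Pi = self.dec_pi(Z_fused).sigmoid().clip(_EPS, 1.0 - _EPS)
        Mu = (self.dec_mu(Z_fused).exp() * Tensor(size_factor[:, None])).clip(_EPS, _BIG)
        Theta = self.dec_theta(Z_fused).exp().clip(_EPS, _BIG)
        return ZINBParams(Pi=Pi, Mu=Mu, Theta=Theta)

    # -- parameters & checkpoints ---------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for net in (self.f_z1, self.f_z2, self.f_e1, self.f_e2,
                    self.dec_pi, self.dec_mu, self.dec_theta):
            params.extend(net.parameters())
        return params

    def save(self, path: str | Path) -> None:
        """Save all weights + config as a single .npz archive."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SCHSCModel":
        with np.load(path) as npz:
            raw = bytes(npz["config_json"].tobytes()).decode()
            cfg_dict = json.loads(raw)
            cfg_dict["hidden_dims"] = tuple(cfg_dict["hidden_dims"])
            cfg_dict["struct_hidden_dims"] = tuple(cfg_dict["struct_hidden_dims"])
            model = cls(EncoderConfig(**cfg_dict))
            for i, p in enumerate(model.parameters()):
                p.data = npz[f"p{i}"]
        return model
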