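"""Zero-inflated negative binomial likelihood and the combined objective.

The count model for gene j in cell i is a mixture of a point mass at zero
(dropout, weight pi) and a negative binomial:

    NB(x; mu, theta)   = Gamma(x+theta) / (Gamma(x+1) Gamma(theta))
                         * (theta/(theta+mu))^theta * (mu/(theta+mu))^x
    ZINB(x; pi, mu, theta) = pi * delta_0(x) + (1 - pi) * NB(x; mu, theta)

theta is the dispersion (variance = mu + mu^2/theta; theta -> infinity
recovers Poisson).  The reconstruction loss is the summed negative
log-likelihood of the raw counts; the total training objective is

    L = L_hs + omega * L_zinb

where omega balances the two magnitudes.  In dynamic mode omega tracks the
ratio of the (detached) loss values with an exponential smoother,
omega <- lambda*omega + (1-lambda)*L_hs/L_zinb with lambda = 0.9, initialized
at the first epoch's ratio; a fixed omega is also supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .autodiff import Tensor

__all__ = [
    "nb_log_pmf",
    "zinb_log_pmf",
    "zinb_nll",
    "OmegaState",
    "LossBreakdown",
    "combine_losses",
]


def nb_log_pmf(x, mu, theta):
    """log NB(x; mu, theta), vectorized, via log-gamma."""
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    return (
        gammaln(x + theta)
        - gammaln(x + 1.0)
        - gammaln(theta)
        + theta * (np.log(theta) - np.log(theta + mu))
        + x * (np.log(mu) - np.log(theta + mu))
    )


def zinb_log_pmf(x, pi, mu, theta):
    """log ZINB(x; pi, mu, theta); the delta component only acts at x = 0."""
    lognb = nb_log_pmf(x, mu, theta)
    x, pi, lognb = np.broadcast_arrays(
        np.asarray(x, dtype=np.float64), np.asarray(pi, dtype=np.float64), lognb
    )
    # at zero: log(pi + (1-pi) NB(0)) via a stable two-term logsumexp
    a = np.where(pi > 0, np.log(np.maximum(pi, np.finfo(float).tiny)), -np.inf)
    b = np.log1p(-pi) + lognb
    hi = np.maximum(a, b)
    at_zero = hi + np.log(np.exp(a - hi) + np.exp(b - hi))
    return np.where(x == 0, at_zero, np.log1p(-pi) + lognb)


def zinb_nll(x_raw, params):
    """Summed ZINB negative log-likelihood of raw counts.

    ``params`` is a :class:`~schsc.model.ZINBParams`; when its fields are
    Tensors the result is a Tensor through which gradients flow, otherwise a
    float.  The reduction is a sum over cells x genes (the balancing
    coefficient omega absorbs scale).
    """
    x = np.asarray(x_raw, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("negative counts")
    tensor_in = isinstance(params.Pi, Tensor)
    Pi = params.Pi if tensor_in else Tensor(params.Pi)
    Mu = params.Mu if tensor_in else Tensor(params.Mu)
    Theta = params.Theta if tensor_in else Tensor(params.Theta)
    if Pi.shape != x.shape or Mu.shape != x.shape or Theta.shape != x.shape:
        raise ValueError("parameter shapes must match the count matrix")

    xt = Tensor(x)
    log_nb = (
        (xt + Theta).lgamma()
        - Tensor(gammaln(x + 1.0))
        - Theta.lgamma()
        + Theta * (Theta.log() - (Theta + Mu).log())
        + xt * (Mu.log() - (Theta + Mu).log())
    )
    zero_mask = Tensor((x == 0).astype(np.float64))
    one_minus_pi = 1.0 - Pi
    # Pi is clamped away from {0, 1} by the decoder, so direct logs are safe
    at_zero = (Pi + one_minus_pi * log_nb.exp()).log()
    at_pos = one_minus_pi.log() + log_nb
    ll = zero_mask * at_zero + (1.0 - zero_mask) * at_pos
    nll = -ll.sum()
    return nll if tensor_in else nll.item()


@dataclass
class OmegaState:
    """Running balance coefficient between the contrastive and ZINB losses."""

    mode: str = "dynamic"  # "dynamic" or "fixed"
    fixed_value: float = 1.0
    smoothing: float = 0.9
    eps: float = 1e-8
    value: float = None

    def update(self, l_hs: float, l_zinb: float) -> float:
        """Advance one epoch with the detached loss values; returns omega."""
        if self.mode == "fixed":
            self.value = self.fixed_value
            return self.value
        ratio = l_hs / max(l_zinb, self.eps)
        if self.value is None:
            self.value = ratio
        else:
            self.value = self.smoothing * self.value + (1.0 - self.smoothing) * ratio
        return self.value


@dataclass
class LossBreakdown:
    L_hs: float
    L_zinb: float
    omega: float
    total: float


def combine_losses(L_hs, L_zinb, omega_state: OmegaState):
    """Total objective L_hs + omega * L_zinb with the current omega.

    Accepts Tensors (training) or floats (inspection); ``omega_state`` must
    have been updated for the current epoch.  Returns (total, breakdown).
    """
    l_hs_val = float(getattr(L_hs, "data", L_hs))
    l_zinb_val = float(getattr(L_zinb, "data", L_zinb))
    if not (np.isfinite(l_hs_val) and np.isfinite(l_zinb_val)):
        raise FloatingPointError(
            f"non-finite loss: L_hs={l_hs_val}, L_zinb={l_zinb_val}"
        )
    if omega_state.value is None:
        omega_state.update(l_hs_val, l_zinb_val)
    omega = omega_state.value
    total = L_hs + omega * L_zinb
    breakdown = LossBreakdown(
        L_hs=l_hs_val,
        L_zinb=l_zinb_val,
        omega=omega,
        total=float(getattr(total, "data", total)),
    )
    return total, breakdown
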