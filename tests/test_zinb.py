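"""ZINB likelihood closed forms, normalization, limits, and the omega rule."""

import numpy as np
import pytest
from scipy import stats

from schsc.autodiff import Tensor
from schsc.model import ZINBParams
from schsc.zinb_loss import (
    OmegaState,
    combine_losses,
    nb_log_pmf,
    zinb_log_pmf,
    zinb_nll,
)


# ---------------------------------------------------------------- NB


def test_nb_zero_collapses_to_theta_term():
    for mu, theta in [(1.0, 1.0), (3.0, 0.7), (0.2, 5.0)]:
        assert nb_log_pmf(0, mu, theta) == pytest.approx(
            theta * np.log(theta / (theta + mu)), abs=1e-12
        )


def test_nb_closed_form_value():
    assert nb_log_pmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)


def test_nb_matches_scipy_parameterization():
    # scipy nbinom with n=theta, p=theta/(theta+mu)
    x = np.arange(0, 30)
    for mu, theta in [(5.0, 2.0), (1.5, 0.5)]:
        want = stats.nbinom.logpmf(x, theta, theta / (theta + mu))
        np.testing.assert_allclose(nb_log_pmf(x, mu, theta), want, atol=1e-10)


@pytest.mark.parametrize("mu", [0.5, 1.0, 5.0])
@pytest.mark.parametrize("theta", [0.5, 1.0, 2.0, 10.0])
def test_nb_normalizes_to_one(mu, theta):
    x = np.arange(0, 2001)
    total = np.exp(nb_log_pmf(x, mu, theta)).sum()
    assert total == pytest.approx(1.0, abs=1e-8)


def test_nb_poisson_limit():
    x = np.arange(0, 21)
    for mu in [0.5, 2.0, 10.0]:
        got = nb_log_pmf(x, mu, 1e6)
        want = stats.poisson.logpmf(x, mu)
        np.testing.assert_allclose(got, want, atol=1e-3)


# ---------------------------------------------------------------- ZINB


def test_zinb_reduces_to_nb_when_pi_zero():
    x = np.arange(0, 10)
    np.testing.assert_allclose(
        zinb_log_pmf(x, 0.0, 2.0, 1.5), nb_log_pmf(x, 2.0, 1.5), atol=1e-12
    )


def test_zinb_zero_mixture_closed_form():
    # pi + (1-pi) NB(0; 1, 1) = 0.5 + 0.5 * 0.5 = 0.75
    assert zinb_log_pmf(0, 0.5, 1.0, 1.0) == pytest.approx(np.log(0.75), abs=1e-12)


def test_zinb_positive_counts_scale_by_one_minus_pi():
    for pi in [0.1, 0.6, 0.9]:
        assert zinb_log_pmf(3, pi, 2.0, 1.0) == pytest.approx(
            np.log(1 - pi) + nb_log_pmf(3, 2.0, 1.0), abs=1e-12
        )


def test_zinb_normalizes_to_one():
    x = np.arange(0, 2001)
    total = np.exp(zinb_log_pmf(x, 0.3, 4.0, 2.0)).sum()
    assert total == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------- NLL


def params_of(pi, mu, theta, shape):
    full = lambda v: np.full(shape, v, dtype=float)
    return ZINBParams(Pi=full(pi), Mu=full(mu), Theta=full(theta))


def test_nll_all_dropout_explains_zeros():
    x = np.zeros((3, 4))
    nll = zinb_nll(x, params_of(1 - 1e-6, 1.0, 1.0, (3, 4)))
    assert nll == pytest.approx(0.0, abs=1e-4)


def test_nll_single_entry_closed_form():
    nll = zinb_nll(np.array([[0]]), params_of(0.5, 1.0, 1.0, (1, 1)))
    assert nll == pytest.approx(-np.log(0.75), abs=1e-10)


def test_nll_matches_elementwise_oracle():
    rng = np.random.default_rng(0)
    x = rng.poisson(2.0, size=(3, 4)).astype(float)
    pi, mu, theta = rng.uniform(0.05, 0.6, (3, 4)), rng.uniform(0.5, 5, (3, 4)), rng.uniform(0.5, 3, (3, 4))
    want = -sum(
        zinb_log_pmf(x[i, j], pi[i, j], mu[i, j], theta[i, j])
        for i in range(3)
        for j in range(4)
    )
    got = zinb_nll(x, ZINBParams(Pi=pi, Mu=mu, Theta=theta))
    assert got == pytest.approx(want, abs=1e-8)


def test_nll_rejects_negative_counts():
    with pytest.raises(ValueError):
        zinb_nll(np.array([[-1]]), params_of(0.5, 1.0, 1.0, (1, 1)))


def test_nll_minimized_at_empirical_excess_zero_fraction():
    rng = np.random.default_rng(1)
    mu, theta, pi_true = 3.0, 2.0, 0.4
    n = 20000
    x = rng.negative_binomial(theta, theta / (theta + mu), size=n).astype(float)
    x[rng.random(n) < pi_true] = 0
    x = x.reshape(1, -1)
    grid = np.linspace(0.05, 0.8, 76)
    nlls = [zinb_nll(x, params_of(p, mu, theta, x.shape)) for p in grid]
    assert abs(grid[int(np.argmin(nlls))] - pi_true) < 0.05


def test_nll_gradient_points_toward_sample_mean():
    rng = np.random.default_rng(2)
    mu_true = 4.0
    x = rng.negative_binomial(2.0, 2.0 / (2.0 + mu_true), size=(1, 5000)).astype(float)
    lo = zinb_nll(x, params_of(1e-6, 2.0, 2.0, x.shape))
    hi = zinb_nll(x, params_of(1e-6, 3.5, 2.0, x.shape))
    assert hi < lo  # moving mu toward the truth lowers the NLL


def test_nll_tensor_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    x = rng.poisson(2.0, size=(2, 3)).astype(float)
    mu0 = rng.uniform(0.5, 4, (2, 3))
    Mu = Tensor(mu0, requires_grad=True)
    params = ZINBParams(Pi=Tensor(np.full((2, 3), 0.3)), Mu=Mu, Theta=Tensor(np.full((2, 3), 2.0)))
    zinb_nll(x, params).backward()
    eps = 1e-6
    for idx in [(0, 0), (1, 2)]:
        up, dn = mu0.copy(), mu0.copy()
        up[idx] += eps
        dn[idx] -= eps
        f = lambda m: zinb_nll(x, ZINBParams(Pi=np.full((2, 3), 0.3), Mu=m, Theta=np.full((2, 3), 2.0)))
        assert Mu.grad[idx] == pytest.approx((f(up) - f(dn)) / (2 * eps), rel=1e-4)


# ---------------------------------------------------------------- omega


def test_fixed_omega_combination():
    state = OmegaState(mode="fixed", fixed_value=1.0)
    state.update(2.0, 3.0)
    total, bd = combine_losses(2.0, 3.0, state)
    assert total == 5.0 and bd.omega == 1.0
    assert bd.total == pytest.approx(bd.L_hs + bd.omega * bd.L_zinb)


def test_dynamic_omega_initializes_at_ratio():
    state = OmegaState()
    state.update(4.0, 4.0)
    assert state.value == pytest.approx(1.0)


def test_dynamic_omega_matches_hand_recursion():
    state = OmegaState()
    pairs = [(2.0, 8.0), (3.0, 6.0), (1.0, 10.0)]
    expected = None
    for l_hs, l_zinb in pairs:
        got = state.update(l_hs, l_zinb)
        ratio = l_hs / max(l_zinb, 1e-8)
        expected = ratio if expected is None else 0.9 * expected + 0.1 * ratio
        assert got == pytest.approx(expected, abs=1e-12)


def test_non_finite_losses_abort():
    state = OmegaState(mode="fixed")
    with pytest.raises(FloatingPointError):
        combine_losses(np.nan, 1.0, state)
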