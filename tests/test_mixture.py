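import numpy as np
import pytest
from scipy.integrate import quad

from bayescnax.mixture import (ComponentParams, EffectParams,
                               cgh_component_logdensity, complete_data_loglik,
                               expr_component_logdensity)


@pytest.fixture
def params():
    return ComponentParams(sigma2=1.0, kappa_minus=2.0, kappa_plus=3.0,
                           shift_minus=-1.0, shift_plus=1.5)


def test_standard_normal_at_zero(params):
    val = cgh_component_logdensity(0.0, 0, ComponentParams(sigma2=1.0))
    assert np.isclose(np.exp(val), 1.0 / np.sqrt(2 * np.pi))


@pytest.mark.parametrize("state", [-1, 0, 1])
def test_components_integrate_to_one(params, state):
    total, _ = quad(lambda y: np.exp(
        cgh_component_logdensity(y, state, params)), -30, 30)
    assert abs(total - 1.0) < 1e-6


def test_loss_component_mode_at_theoretical_ratio():
    # single-copy-loss theoretical log2 ratio is -1
    p = ComponentParams(shift_minus=-1.0)
    grid = np.linspace(-3, 1, 2001)
    dens = cgh_component_logdensity(grid, -1, p)
    assert abs(grid[np.argmax(dens)] - (-1.0)) < 2e-3


def test_expr_reduces_to_cgh_without_effects(params):
    eff = EffectParams(alpha=np.zeros(3), beta=np.zeros(4))
    z = 0.7
    for state in (-1, 0, 1):
        assert np.isclose(
            expr_component_logdensity(z, state, 1, 2, params, eff),
            cgh_component_logdensity(z, state, params))


def test_translation_invariance(params):
    eff1 = EffectParams(alpha=np.array([0.5]), beta=np.zeros(2))
    eff2 = EffectParams(alpha=np.array([2.5]), beta=np.zeros(2))
    assert np.isclose(
        expr_component_logdensity(1.0, 1, 0, 0, params, eff1),
        expr_component_logdensity(3.0, 1, 0, 0, params, eff2))


def test_density_matches_independent_gaussian_formula(params):
    rng = np.random.default_rng(42)
    beta = rng.normal(size=6)
    eff = EffectParams(alpha=rng.normal(size=5), beta=beta - beta.mean())
    means = {-1: params.shift_minus, 0: 0.0, 1: params.shift_plus}
    varfac = {-1: params.kappa_minus, 0: 1.0, 1: params.kappa_plus}
    for _ in range(100):
        z = rng.normal()
        state = rng.choice([-1, 0, 1])
        g = rng.integers(5)
        t = rng.integers(6)
        m = means[state] + eff.alpha[g] + eff.beta[t]
        var = varfac[state] * params.sigma2
        expected = -0.5 * np.log(2 * np.pi * var) - (z - m) ** 2 / (2 * var)
        got = expr_component_logdensity(z, state, g, t, params, eff)
        assert np.isclose(got, expected, rtol=0, atol=1e-12)


def test_invalid_state_rejected(params):
    with pytest.raises(ValueError):
        cgh_component_logdensity(0.0, 2, params)


def test_complete_loglik_matches_double_loop(params):
    rng = np.random.default_rng(7)
    B, G, T = 4, 2, 6
    Y = rng.normal(size=(B, T))
    Z = rng.normal(size=(G, T))
    e = rng.choice([-1, 0, 1], size=(B, T))
    lam = rng.choice([-1, 0, 1], size=(G, T))
    beta = rng.normal(size=T)
    beta -= beta.mean()
    eff = EffectParams(alpha=rng.normal(size=G), beta=beta)
    pz = ComponentParams(sigma2=0.5, shift_minus=-0.8, shift_plus=0.9)

    expected = 0.0
    for b in range(B):
        for t in range(T):
            expected += cgh_component_logdensity(Y[b, t], e[b, t], params)
    for g in range(G):
        for t in range(T):
            expected += expr_component_logdensity(Z[g, t], lam[g, t], g, t,
                                                  pz, eff)
    got = complete_data_loglik(Y, Z, e, lam, params, pz, eff)
    assert np.isclose(got, expected, atol=1e-9)

    # single cell reduces to the sum of the two point densities
    got1 = complete_data_loglik(Y[:1, :1], Z[:1, :1], e[:1, :1], lam[:1, :1],
                                params, pz,
                                EffectParams(alpha=eff.alpha[:1],
                                             beta=np.zeros(1)))
    exp1 = (cgh_component_logdensity(Y[0, 0], e[0, 0], params)
            + expr_component_logdensity(Z[0, 0], lam[0, 0], 0, 0, pz,
                                        EffectParams(alpha=eff.alpha[:1],
                                                     beta=np.zeros(1))))
    assert np.isclose(got1, exp1)


def test_loglik_decreases_when_inflating_variance_at_means():
    # data exactly at component means: density is proportional to 1/sigma
    eff = EffectParams(alpha=np.zeros(1), beta=np.zeros(1))
    e = np.array([[0]])
    Y = np.array([[0.0]])
    Z = np.array([[0.0]])
    small = ComponentParams(sigma2=0.5)
    big = ComponentParams(sigma2=2.0)
    assert (complete_data_loglik(Y, Z, e, e, small, small, eff)
            > complete_data_loglik(Y, Z, e, e, big, big, eff))


def test_beta_zero_sum_enforced():
    with pytest.raises(ValueError, match="sum to zero"):
        EffectParams(alpha=np.zeros(2), beta=np.array([0.5, 0.2]))
    # a valid zero-sum vector passes
    EffectParams(alpha=np.zeros(2), beta=np.array([0.5, -0.5]))


def test_component_param_validation():
    with pytest.raises(ValueError):
        ComponentParams(sigma2=-1.0)
    with pytest.raises(ValueError):
        ComponentParams(kappa_minus=0.5)
    with pytest.raises(ValueError):
        ComponentParams(shift_minus=0.3)
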