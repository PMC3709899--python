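import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import ndtr
from scipy.stats import invgamma, norm

from bayescnax.gibbs import (GibbsSampler, McmcConfig, ModelArrays, Priors,
                             run_chain)
from bayescnax.latent import markov_logprior, threshold_scores

from conftest import make_sampler, normalized, tiny_arrays


# ---------------------------------------------------------------------------
# exact enumeration of discrete full conditionals against the joint density

@pytest.mark.parametrize("name", ["delta", "gamma", "rho"])
def test_differential_indicator_conditionals_match_enumeration(name):
    s = make_sampler("differential", seed=3)
    vec = getattr(s, name)
    logw = getattr(s, f"{name}_conditional_logweights")()
    for i in range(len(vec)):
        orig = vec[i]
        lj = np.empty(3)
        for j, k in enumerate((-1, 0, 1)):
            vec[i] = k
            lj[j] = s.log_joint()
        vec[i] = orig
        assert np.abs(normalized(lj) - normalized(logw[:, i])).max() < 1e-10


@pytest.mark.parametrize("name", ["zeta", "xi"])
def test_inclusion_indicator_conditionals_match_enumeration(name):
    s = make_sampler("prediction", seed=4)
    vec = getattr(s, name)
    logw = getattr(s, f"{name}_conditional_logweights")()
    for i in range(len(vec)):
        orig = vec[i]
        lj = np.empty(2)
        for j in (0, 1):
            vec[i] = j
            lj[j] = s.log_joint()
        vec[i] = orig
        assert np.abs(normalized(lj) - normalized(logw[:, i])).max() < 1e-10


def test_outcome_conditional_matches_enumeration():
    s = make_sampler("prediction", seed=4)
    logw = s.outcome_logweights()
    for t in np.nonzero(np.isnan(s.da.u))[0]:
        orig = s.u[t]
        lj = np.empty(2)
        for j in (0, 1):
            s.u[t] = float(j)
            lj[j] = s.log_joint()
        s.u[t] = orig
        assert np.abs(normalized(lj) - normalized(logw[:, t])).max() < 1e-10


# ---------------------------------------------------------------------------
# collapsed (indicator, score-row) blocks against a quadrature oracle

def _collapsed_delta_oracle(s, b):
    """P(delta_b = k) with w_b integrated out, by numerical quadrature."""
    x1 = np.nonzero(s.da.x == 1)[0]
    g = s.gene_of[b]
    R = s._coupling()[g]
    n_g = s.n_per_gene[g]
    r = R / n_g
    logw = np.zeros(3)
    c = s.pr.cutpoint
    for j, k in enumerate((-1, 0, 1)):
        lw = np.log(s.pr.p_delta[j])
        for t in x1:
            m = s.mu[b] + s.a_delta * k
            s_other = s.wsum[g, t] - s.w[b, t]
            vres = (s.v[g, t] - s.nu[g]
                    - s.a_gamma * s.gamma[g] * s.da.x[t]
                    - R * s_other / n_g)
            lo, hi = {-1: (-np.inf, -c), 0: (-c, c), 1: (c, np.inf)}[s.e[b, t]]
            f = lambda w: (norm.pdf(w, m, 1.0)
                           * norm.pdf(vres, r * w, 1.0))
            val, _ = quad(f, max(lo, m - 12), min(hi, m + 12))
            lw += np.log(max(val, 1e-300))
        logw[j] = lw
    return normalized(logw)


def test_collapsed_delta_block_matches_quadrature():
    s = make_sampler("differential", seed=9)
    b = 0  # first probe of its gene: conditioning state is restorable
    oracle = _collapsed_delta_oracle(s, b)
    snap = (s.w.copy(), s.wsum.copy(), s.wbar.copy(), s.delta.copy(),
            s.e.copy())
    counts = np.zeros(3)
    n = 4000
    for _ in range(n):
        s.w, s.wsum, s.wbar, s.delta, s.e = (snap[0].copy(), snap[1].copy(),
                                             snap[2].copy(), snap[3].copy(),
                                             snap[4].copy())
        s._collapsed_delta()
        counts[s.delta[b] + 1] += 1
    freq = counts / n
    se = np.sqrt(oracle * (1 - oracle) / n)
    assert np.all(np.abs(freq - oracle) < 5 * se + 0.01)


def test_collapsed_gamma_rho_block_matches_interval_probabilities():
    s = make_sampler("differential", seed=11)
    g = 0
    c = s.pr.cutpoint
    combos = [(gv, rv) for gv in (-1, 0, 1) for rv in (-1, 0, 1)]
    logw = np.zeros(len(combos))
    for j, (gv, rv) in enumerate(combos):
        lw = (np.log(s.pr.p_gamma[gv + 1]) + np.log(s.pr.p_rho[rv + 1]))
        for t in range(s.T):
            mean = (s.nu[g] + s.a_gamma * gv * s.da.x[t]
                    + s.a_rho * rv * s.wbar[g, t])
            lo, hi = {-1: (-np.inf, -c), 0: (-c, c),
                      1: (c, np.inf)}[s.lam[g, t]]
            val, _ = quad(lambda v: norm.pdf(v, mean, 1.0),
                          max(lo, mean - 12), min(hi, mean + 12))
            lw += np.log(max(val, 1e-300))
        logw[j] = lw
    oracle = normalized(logw)
    snap = (s.v.copy(), s.gamma.copy(), s.rho.copy())
    counts = np.zeros(len(combos))
    n = 4000
    lookup = {cmb: i for i, cmb in enumerate(combos)}
    for _ in range(n):
        s.v, s.gamma, s.rho = snap[0].copy(), snap[1].copy(), snap[2].copy()
        s._collapsed_gamma_rho()
        counts[lookup[(int(s.gamma[g]), int(s.rho[g]))]] += 1
    freq = counts / n
    se = np.sqrt(oracle * (1 - oracle) / n)
    assert np.all(np.abs(freq - oracle) < 5 * se + 0.01)


# ---------------------------------------------------------------------------
# latent state / score joint update

def test_state_update_overwhelming_evidence():
    # data exactly at the +1 component mean with tiny variances
    s = make_sampler("differential", seed=5)
    s.sigma2_y = 1e-4
    s.shifts_y = np.array([-1.0, 0.0, 1.0])
    s.da.Y[:] = 1.0
    loglik = s._y_comp_loglik()
    m = s._w_mean()
    plo = ndtr(-s.pr.cutpoint - m)
    phi = ndtr(s.pr.cutpoint - m)
    logint = np.log(np.clip(np.stack([plo, phi - plo, 1 - phi]),
                            1e-300, None))
    probs = np.exp(loglik + logint
                   - (loglik + logint).max(axis=0, keepdims=True))
    probs /= probs.sum(axis=0, keepdims=True)
    assert np.all(probs[2] > 0.99)


def test_state_update_symmetry():
    s = make_sampler("differential", seed=5)
    s.sigma2_y = 1.0
    s.shifts_y = np.array([-1.0, 0.0, 1.0])
    s.da.Y[:] = 0.0
    s.mu[:] = 0.0
    s.delta[:] = 0
    loglik = s._y_comp_loglik()
    m = s._w_mean()
    plo = ndtr(-s.pr.cutpoint - m)
    phi = ndtr(s.pr.cutpoint - m)
    logint = np.log(np.stack([plo, phi - plo, 1 - phi]))
    logw = loglik + logint
    assert np.allclose(logw[0], logw[2])


def test_scores_always_in_state_region():
    for mode in ("differential", "prediction"):
        s = make_sampler(mode, seed=6, warm=0)
        for _ in range(30):
            s.sweep()
            assert np.array_equal(s.e, threshold_scores(s.w, s.pr.cutpoint))
            assert np.array_equal(s.lam,
                                  threshold_scores(s.v, s.pr.cutpoint))


def test_beta_zero_sum_maintained():
    s = make_sampler("differential", seed=7, warm=0)
    for _ in range(25):
        s.sweep()
        assert abs(s.beta.sum()) < 1e-9


def test_degenerate_prior_forces_null_indicator():
    pr = Priors(p_delta=(0.0, 1.0, 0.0))
    s = make_sampler("differential", seed=8, priors=pr)
    for _ in range(10):
        s.sweep()
        assert np.all(s.delta == 0)


def test_wbar_consistent_with_scores():
    s = make_sampler("differential", seed=12, warm=10)
    expected = np.zeros_like(s.wbar)
    np.add.at(expected, s.gene_of, s.w)
    expected /= s.n_per_gene[:, None]
    assert np.allclose(s.wbar, expected, atol=1e-10)


# ---------------------------------------------------------------------------
# conjugate and Metropolis parameter blocks

def test_variance_update_matches_closed_form_posterior():
    s = make_sampler("differential", seed=10)
    resid = s.da.Y - s.shifts_y[s.e + 1]
    ss = np.sum(resid ** 2 / s.cvar_y[s.e + 1])
    shape = s.pr.sigma2_shape + 0.5 * s.B * s.T
    rate = s.pr.sigma2_rate + 0.5 * ss
    draws = np.empty(20000)
    for i in range(draws.size):
        s._update_sigma2_y()
        draws[i] = s.sigma2_y
    ref = invgamma(a=shape, scale=rate)
    # quantile agreement with the closed-form inverse-gamma posterior
    qs = np.array([0.1, 0.25, 0.5, 0.75, 0.9])
    emp = np.quantile(draws, qs)
    assert np.allclose(emp, ref.ppf(qs), rtol=0.05)


def test_eta_metropolis_stays_in_bounds_and_targets_ar_prior():
    # mu generated with eta = 0.8, tau2 = 1: posterior mean close to truth
    rng = np.random.default_rng(0)
    B = 500
    eta_true, tau2 = 0.8, 1.0
    mu = np.zeros(B)
    mu[0] = rng.normal(0, 1)
    sd = np.sqrt(tau2 * (1 - eta_true ** 2))
    for b in range(1, B):
        mu[b] = eta_true * mu[b - 1] + rng.normal(0, sd)
    arr = tiny_arrays()
    arr.Y = np.zeros((4, 6))
    s = GibbsSampler(arr, config=McmcConfig(n_iter=10, burn_in=1, seed=1))
    s.mu = mu
    s.tau2 = tau2
    s.B = B
    s.da.chain_start = np.zeros(B, dtype=bool)
    s.da.chain_start[0] = True
    etas = []
    for i in range(1500):
        s._update_eta()
        assert 0.0 <= s.eta <= s.pr.eta_max
        if i >= 300:
            etas.append(s.eta)
    assert abs(np.mean(etas) - eta_true) < 0.15


def test_eta_acceptance_ratio_equals_dense_covariance_ratio():
    from scipy.stats import multivariate_normal
    from bayescnax.latent import ar1_covariance

    rng = np.random.default_rng(3)
    mu = rng.normal(size=5)
    tau2 = 1.3
    for eta_a, eta_b in [(0.2, 0.7), (0.5, 0.85)]:
        ratio = (markov_logprior(mu, eta_b, tau2)
                 - markov_logprior(mu, eta_a, tau2))
        dense = (multivariate_normal(np.zeros(5),
                                     ar1_covariance(eta_b, tau2, 5)).logpdf(mu)
                 - multivariate_normal(np.zeros(5),
                                       ar1_covariance(eta_a, tau2,
                                                      5)).logpdf(mu))
        assert np.isclose(ratio, dense, atol=1e-8)


def test_mu_conditional_moments_match_conjugate_formula():
    # with every probe its own chain segment the conditional is
    # N((sum of score residuals) / (1/tau2 + T), 1 / (1/tau2 + T))
    s = make_sampler("differential", seed=13)
    s.da.chain_start = np.ones(s.B, dtype=bool)
    s.eta, s.tau2 = 0.6, 0.8
    eff = s._w_effect()
    prec = 1 / s.tau2 + s.T
    lin = np.sum(s.w - eff, axis=1)
    draws = np.empty((20000, s.B))
    for i in range(draws.shape[0]):
        mu_snapshot = s.mu.copy()
        s._update_mu()
        draws[i] = s.mu
        s.mu = mu_snapshot
    mc_se = np.sqrt(1 / prec / draws.shape[0])
    assert np.all(np.abs(draws.mean(axis=0) - lin / prec) < 4 * mc_se)
    assert np.allclose(draws.std(axis=0), 1 / np.sqrt(prec), atol=0.02)


# ---------------------------------------------------------------------------
# chain driver

def test_same_seed_gives_identical_draws():
    arr1, arr2 = tiny_arrays(), tiny_arrays()
    rng = np.random.default_rng(5)
    Y = rng.normal(size=(4, 6))
    Z = rng.normal(size=(2, 6))
    arr1.Y, arr1.Z = Y.copy(), Z.copy()
    arr2.Y, arr2.Z = Y.copy(), Z.copy()
    cfg = McmcConfig(n_iter=60, burn_in=20, thin=2, seed=42)
    d1 = run_chain(arr1, cfg)
    d2 = run_chain(arr2, cfg)
    assert np.array_equal(d1.delta, d2.delta)
    assert np.array_equal(d1.gamma, d2.gamma)
    for k in d1.scalars:
        assert np.array_equal(d1.scalars[k], d2.scalars[k])
    assert d1.n_draws == (60 - 20) // 2


def test_nan_data_aborts_with_block_name():
    arr = tiny_arrays()
    arr.Y[0, 0] = np.nan
    cfg = McmcConfig(n_iter=20, burn_in=5, seed=0, log_every=1)
    with pytest.raises(RuntimeError, match="block"):
        run_chain(arr, cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(n_iter=10, burn_in=10)
    with pytest.raises(ValueError):
        McmcConfig(thin=0)
    with pytest.raises(ValueError):
        McmcConfig(mode="bogus")
    with pytest.raises(ValueError):
        Priors(p_delta=(0.4, 0.2, 0.4))
    with pytest.raises(ValueError):
        Priors(p_zero=0.3)


def test_posterior_probabilities_equal_draw_counting():
    arr = tiny_arrays()
    rng = np.random.default_rng(6)
    arr.Y = rng.normal(size=(4, 6))
    arr.Z = rng.normal(size=(2, 6))
    cfg = McmcConfig(n_iter=80, burn_in=30, seed=1)
    d = run_chain(arr, cfg)
    p = (d.gamma == 1).mean(axis=0)
    brute = np.array([sum(d.gamma[i, g] == 1 for i in range(d.n_draws))
                      / d.n_draws for g in range(2)])
    assert np.allclose(p, brute)
    assert np.all((p >= 0) & (p <= 1))
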