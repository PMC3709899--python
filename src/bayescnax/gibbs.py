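"""Blocked Gibbs sampler for the integrated copy-number / expression model.

All discrete indicators (trinary differential indicators, binary
outcome-inclusion indicators, imputed outcomes, and the latent trinary
states) are drawn by exact finite-support enumeration of their full
conditionals; latent probit scores come from truncated-normal full
conditionals (jointly with their states, so the score always lies in the
region of the drawn state); every Gaussian location and variance block is
conjugate; the chain correlation eta of the probe-baseline autoregression
is the single Metropolis step.  All enumerations are done in log space
with max-subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ndtr, ndtri, expit, logit

from .latent import markov_logprior, threshold_scores

logger = logging.getLogger("bayescnax")

__all__ = ["Priors", "McmcConfig", "ModelArrays", "PosteriorDraws",
           "GibbsSampler", "run_chain"]

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# configuration containers

@dataclass
class Priors:
    """Hyperparameters of all prior distributions (YAML-serializable).

    Trinary indicator priors are (P(-1), P(0), P(+1)) with the mass at 0
    much larger than the tails.  Effect magnitudes a_* share a common
    positive-truncated normal prior.  Variances carry inverse-gamma priors
    parameterized by (shape, rate); kappa tail-inflation factors are fixed.
    """

    cutpoint: float = 1.0
    p_delta: tuple = (0.05, 0.90, 0.05)
    p_gamma: tuple = (0.05, 0.90, 0.05)
    p_rho: tuple = (0.05, 0.90, 0.05)
    a_mean: float = 1.0
    a_sd: float = 1.0
    tau2_shape: float = 3.0
    tau2_rate: float = 2.0
    eta_max: float = 0.9
    eta_step: float = 0.8
    nu_sd: float = 2.0
    alpha_sd: float = 2.0
    beta_sd: float = 1.0
    sigma2_shape: float = 3.0
    sigma2_rate: float = 1.0
    kappa_minus_y: float = 3.0
    kappa_plus_y: float = 3.0
    kappa_minus_z: float = 3.0
    kappa_plus_z: float = 3.0
    shift_mean: float = 1.0     # prior centre magnitude of the +-1 offsets
    shift_sd: float = 0.5
    # prediction mode
    p_zero: float = 0.99
    b_sd: float | None = None   # None -> empirical-Bayes plug-in upstream
    rho_link_sd: float = 1.0
    pi: float | None = None     # None -> observed outcome proportion

    def __post_init__(self):
        for p in (self.p_delta, self.p_gamma, self.p_rho):
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("trinary prior probabilities must sum to 1")
            if p[1] < max(p[0], p[2]):
                raise ValueError("the null mass P(0) must be the largest entry")
        if not 0.5 < self.p_zero < 1.0:
            raise ValueError("p_zero must be in (0.5, 1)")
        if not 0.0 < self.eta_max < 1.0:
            raise ValueError("eta_max must be in (0, 1)")

    def to_dict(self):
        return asdict(self)


@dataclass
class McmcConfig:
    n_iter: int = 4000
    burn_in: int = 2000
    thin: int = 1
    seed: int = 0
    mode: str = "differential"      # or "prediction"
    log_every: int = 100

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.mode not in ("differential", "prediction"):
            raise ValueError("mode must be 'differential' or 'prediction'")


@dataclass
class ModelArrays:
    """Numeric views of a dataset, in the order the sampler uses."""

    Y: np.ndarray               # (B, T) log2 ratios
    Z: np.ndarray               # (G, T) expression
    gene_of: np.ndarray         # (B,) gene index per probe
    chain_start: np.ndarray     # (B,) bool, Markov chain restarts
    x: np.ndarray               # (T,) binary subgroup covariate
    u: np.ndarray               # (T,) outcome, NaN = unobserved
    probe_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    @classmethod
    def from_dataset(cls, data, holdout=None):
        """Build from an io.Dataset; ``holdout`` sample ids get u masked."""
        u = data.covariates["u"].to_numpy(dtype=float).copy()
        if holdout is not None:
            pos = {s: i for i, s in enumerate(data.covariates.index)}
            for s in holdout:
                u[pos[s]] = np.nan
        return cls(
            Y=data.Y.to_numpy(dtype=float),
            Z=data.Z.to_numpy(dtype=float),
            gene_of=data.gene_of,
            chain_start=data.chain_start,
            x=data.covariates["x"].to_numpy(dtype=int),
            u=u,
            probe_ids=list(data.Y.index),
            gene_ids=list(data.Z.index),
            sample_ids=list(data.Y.columns),
        )


@dataclass
class PosteriorDraws:
    """Retained MCMC draws and the derived posterior probabilities."""

    mode: str
    delta: np.ndarray | None = None   # (n, B)
    gamma: np.ndarray | None = None   # (n, G)
    rho: np.ndarray | None = None     # (n, G)
    zeta: np.ndarray | None = None    # (n, B)
    xi: np.ndarray | None = None      # (n, G)
    u: np.ndarray | None = None       # (n, T)
    u_prob: np.ndarray | None = None  # (n, T) exact conditional P(u=1|rest)
    scalars: dict = field(default_factory=dict)
    probe_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    gene_of: np.ndarray | None = None

    @property
    def n_draws(self):
        for arr in (self.delta, self.zeta, self.gamma, self.xi, self.u):
            if arr is not None:
                return arr.shape[0]
        return 0

    def predictive_pcr(self, rao_blackwell: bool = True):
        """Posterior predictive P(pCR = 1) per sample.

        By default averages the exact per-sweep conditional probabilities
        (Rao-Blackwellized, lower Monte-Carlo variance); with
        ``rao_blackwell=False`` it is the plain average of the imputed
        binary draws.
        """
        if self.u is None:
            raise ValueError("no outcome draws in this chain")
        if rao_blackwell and self.u_prob is not None:
            return self.u_prob.mean(axis=0)
        return self.u.mean(axis=0)


# --------------------------------------------------------------------------
# numeric helpers

def gaussian_logpdf(x, mean, var):
    return -0.5 * (_LOG2PI + np.log(var) + (np.asarray(x) - mean) ** 2 / var)


def _invgamma_logpdf(x, shape, rate):
    from scipy.special import gammaln
    return (shape * np.log(rate) - gammaln(shape)
            - (shape + 1) * np.log(x) - rate / x)


def _truncnorm_pos_logpdf(x, mean, sd):
    if x <= 0:
        return -np.inf
    z = gaussian_logpdf(x, mean, sd ** 2)
    return float(z - np.log(ndtr(mean / sd)))


def _truncnorm_sign_logpdf(x, mean, sd, positive):
    if positive:
        return _truncnorm_pos_logpdf(x, mean, sd)
    if x >= 0:
        return -np.inf
    z = gaussian_logpdf(x, mean, sd ** 2)
    return float(z - np.log(ndtr(-mean / sd)))


def _sample_cat3(logw, rng):
    """Vectorized categorical draw over axis 0 of a (3, ...) log-weight array."""
    m = logw.max(axis=0, keepdims=True)
    w = np.exp(logw - m)
    w /= w.sum(axis=0, keepdims=True)
    u = rng.random(size=w.shape[1:])
    c0 = w[0]
    c1 = w[0] + w[1]
    return (u >= c0).astype(np.int8) + (u >= c1).astype(np.int8)


def _trunc_norm(rng, mean, sd, lo, hi):
    """Inverse-CDF truncated normal draw (vectorized, boundary-safe)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    shape = np.broadcast_shapes(np.shape(mean), np.shape(lo))
    u = a + (b - a) * rng.random(size=shape)
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    x = mean + sd * ndtri(u)
    eps = 1e-12
    x = np.where(np.isfinite(lo), np.maximum(x, lo + eps), x)
    x = np.where(np.isfinite(hi), np.minimum(x, hi - eps), x)
    return x


def _sample_invgamma(rng, shape, rate, size=None):
    return rate / rng.gamma(shape, 1.0, size=size)


def _log_probs(p):
    """Log of prior probabilities, tolerating exact zeros (degenerate priors)."""
    return np.log(np.clip(np.asarray(p, dtype=float), 1e-300, None))


# --------------------------------------------------------------------------
# the sampler

class GibbsSampler:
    """Full-conditional Gibbs sampler over the joint model.

    Parameters
    ----------
    arrays : ModelArrays
    priors : Priors
    config : McmcConfig
    include_y, include_z : bool
        Switch a whole platform off (marginal prediction models fit a
        single platform).
    couple : bool
        Cross-platform regression on/off.  In differential mode
        ``couple=False`` pins every interaction indicator rho_g at 0 (the
        "marginal model"); in prediction mode it pins rho_link at 0.
    """

    def __init__(self, arrays: ModelArrays, priors: Priors | None = None,
                 config: McmcConfig | None = None, include_y: bool = True,
                 include_z: bool = True, couple: bool = True):
        if not (include_y or include_z):
            raise ValueError("at least one platform must be included")
        self.da = arrays
        self.pr = priors or Priors()
        self.cfg = config or McmcConfig()
        self.include_y = include_y
        self.include_z = include_z
        self.couple = couple and include_y and include_z
        self.mode = self.cfg.mode

        self.B, self.T = arrays.Y.shape
        self.G = arrays.Z.shape[0]
        if arrays.Z.shape[1] != self.T:
            raise ValueError("Y and Z must share the sample dimension")
        self.gene_of = np.asarray(arrays.gene_of)
        self.n_per_gene = np.bincount(self.gene_of, minlength=self.G).astype(float)
        if np.any(self.n_per_gene == 0):
            raise ValueError("every gene needs at least one probe")
        # probes grouped by within-gene rank: groups touch each gene at most
        # once, so the coupled score update can be vectorized per group
        ranks = np.zeros(self.B, dtype=int)
        seen = {}
        for i, g in enumerate(self.gene_of):
            ranks[i] = seen.get(g, 0)
            seen[g] = ranks[i] + 1
        self.rank_groups = [np.nonzero(ranks == r)[0]
                            for r in range(int(ranks.max()) + 1)]

        self.cvar_y = np.array([self.pr.kappa_minus_y, 1.0, self.pr.kappa_plus_y])
        self.cvar_z = np.array([self.pr.kappa_minus_z, 1.0, self.pr.kappa_plus_z])

        obs = arrays.u[~np.isnan(arrays.u)]
        if self.pr.pi is not None:
            self.pi = float(self.pr.pi)
        elif obs.size:
            self.pi = float(np.clip(obs.mean(), 1e-3, 1 - 1e-3))
        else:
            self.pi = 0.5
        self.b_sd = float(self.pr.b_sd) if self.pr.b_sd is not None else 1.0

        self.rng = np.random.default_rng(self.cfg.seed)
        self.init_from_prior(self.rng)

    # -- initialization ---------------------------------------------------
    def init_from_prior(self, rng):
        pr = self.pr
        B, G, T = self.B, self.G, self.T
        self.sigma2_y = float(_sample_invgamma(rng, pr.sigma2_shape, pr.sigma2_rate))
        self.sigma2_z = float(_sample_invgamma(rng, pr.sigma2_shape, pr.sigma2_rate))
        self.shifts_y = np.array([
            float(_trunc_norm(rng, -pr.shift_mean, pr.shift_sd, -np.inf, 0.0)),
            0.0,
            float(_trunc_norm(rng, pr.shift_mean, pr.shift_sd, 0.0, np.inf)),
        ])
        self.shifts_z = np.array([
            float(_trunc_norm(rng, -pr.shift_mean, pr.shift_sd, -np.inf, 0.0)),
            0.0,
            float(_trunc_norm(rng, pr.shift_mean, pr.shift_sd, 0.0, np.inf)),
        ])
        self.tau2 = float(_sample_invgamma(rng, pr.tau2_shape, pr.tau2_rate))
        self.eta = float(rng.uniform(0.0, pr.eta_max))
        self.mu = self._sample_mu_prior(rng)
        self.nu = rng.normal(0.0, pr.nu_sd, size=G)
        self.alpha = rng.normal(0.0, pr.alpha_sd, size=G)
        beta = rng.normal(0.0, pr.beta_sd, size=T)
        self.beta = beta - beta.mean()

        self.delta = np.zeros(B, dtype=np.int8)
        self.gamma = np.zeros(G, dtype=np.int8)
        self.rho = np.zeros(G, dtype=np.int8)
        self.a_delta = self.a_gamma = self.a_rho = 1.0
        self.zeta = np.zeros(B, dtype=np.int8)
        self.xi = np.zeros(G, dtype=np.int8)
        self.b_zeta = np.zeros(B)
        self.b_xi = np.zeros(G)
        self.rho_link = np.zeros(G)
        self.u = np.where(np.isnan(self.da.u), 0.0, self.da.u)
        self.u_prob = self.u.copy()

        if self.mode == "differential":
            self.delta = (_sample_cat3(_log_probs(pr.p_delta)[:, None]
                                       * np.ones((3, B)), rng) - 1).astype(np.int8)
            self.gamma = (_sample_cat3(_log_probs(pr.p_gamma)[:, None]
                                       * np.ones((3, G)), rng) - 1).astype(np.int8)
            if self.couple:
                self.rho = (_sample_cat3(_log_probs(pr.p_rho)[:, None]
                                         * np.ones((3, G)), rng) - 1).astype(np.int8)
            self.a_delta = float(_trunc_norm(rng, pr.a_mean, pr.a_sd, 0.0, np.inf))
            self.a_gamma = float(_trunc_norm(rng, pr.a_mean, pr.a_sd, 0.0, np.inf))
            self.a_rho = float(_trunc_norm(rng, pr.a_mean, pr.a_sd, 0.0, np.inf))
        else:
            unobs = np.isnan(self.da.u)
            self.u[unobs] = (rng.random(unobs.sum()) < self.pi).astype(float)
            self.zeta = (rng.random(B) < (1.0 - pr.p_zero)).astype(np.int8)
            self.xi = (rng.random(G) < (1.0 - pr.p_zero)).astype(np.int8)
            self.b_zeta = rng.normal(0.0, self.b_sd, size=B)
            self.b_xi = rng.normal(0.0, self.b_sd, size=G)
            if self.couple:
                self.rho_link = rng.normal(0.0, pr.rho_link_sd, size=G)

        # latent scores from their regressions, states by thresholding
        self.w = self._w_mean() + rng.normal(size=(B, T))
        self.e = threshold_scores(self.w, pr.cutpoint)
        self.wsum = np.zeros((G, T))
        np.add.at(self.wsum, self.gene_of, self.w)
        self.wbar = self.wsum / self.n_per_gene[:, None]
        self.v = self._v_mean() + rng.normal(size=(G, T))
        self.lam = threshold_scores(self.v, pr.cutpoint)
        self.n_sweeps = 0

    def _sample_mu_prior(self, rng):
        mu = np.zeros(self.B)
        start = self.da.chain_start
        sd_inner = np.sqrt(self.tau2 * (1.0 - self.eta ** 2))
        sd0 = np.sqrt(self.tau2)
        for b in range(self.B):
            if start[b]:
                mu[b] = rng.normal(0.0, sd0)
            else:
                mu[b] = rng.normal(self.eta * mu[b - 1], sd_inner)
        return mu

    # -- regression means -------------------------------------------------
    def _w_effect(self):
        """Additive effect on the DNA scores beyond the baseline mu."""
        if self.mode == "differential":
            return self.a_delta * self.delta[:, None] * self.da.x[None, :]
        return (self.zeta * self.b_zeta)[:, None] * self.u[None, :]

    def _v_effect(self):
        """Additive effect on the RNA scores beyond nu and the coupling."""
        if self.mode == "differential":
            return self.a_gamma * self.gamma[:, None] * self.da.x[None, :]
        return (self.xi * self.b_xi)[:, None] * self.u[None, :]

    def _coupling(self):
        """Per-gene coefficient multiplying wbar in the RNA score regression."""
        if not self.couple:
            return np.zeros(self.G)
        if self.mode == "differential":
            return self.a_rho * self.rho.astype(float)
        return self.rho_link

    def _w_mean(self):
        return self.mu[:, None] + self._w_effect()

    def _v_mean(self):
        m = self.nu[:, None] + self._v_effect()
        if self.couple:
            m = m + self._coupling()[:, None] * self.wbar
        return m

    # -- observation component log-likelihoods ----------------------------
    def _y_comp_loglik(self):
        var = self.sigma2_y * self.cvar_y
        return np.stack([gaussian_logpdf(self.da.Y, self.shifts_y[k], var[k])
                         for k in range(3)])

    def _z_comp_loglik(self):
        ab = self.alpha[:, None] + self.beta[None, :]
        var = self.sigma2_z * self.cvar_z
        return np.stack([gaussian_logpdf(self.da.Z, ab + self.shifts_z[k], var[k])
                         for k in range(3)])

    # -- latent state/score updates ---------------------------------------
    def _update_scores_y(self):
        c = self.pr.cutpoint
        m_full = self._w_mean()
        loglik = self._y_comp_loglik()
        if self.include_z and self.couple:
            R = self._coupling()
            vres = self.v - self.nu[:, None] - self._v_effect()
        for idx in self.rank_groups:
            g = self.gene_of[idx]
            m = m_full[idx]
            if self.include_z and self.couple:
                n_g = self.n_per_gene[g][:, None]
                r = (R[g][:, None]) / n_g
                s_other = self.wsum[g] - self.w[idx]
                d = vres[g] - R[g][:, None] * s_other / n_g
                prec = 1.0 + r * r
                mstar = (m + r * d) / prec
                sd = 1.0 / np.sqrt(prec)
            else:
                mstar = m
                sd = np.ones_like(m)
            plo = ndtr((-c - mstar) / sd)
            phi = ndtr((c - mstar) / sd)
            logint = np.log(np.clip(
                np.stack([plo, phi - plo, 1.0 - phi]), 1e-300, None))
            k = _sample_cat3(loglik[:, idx, :] + logint, self.rng)
            e_new = (k - 1).astype(np.int8)
            lo = np.where(e_new == -1, -np.inf, np.where(e_new == 0, -c, c))
            hi = np.where(e_new == -1, -c, np.where(e_new == 0, c, np.inf))
            w_new = _trunc_norm(self.rng, mstar, sd, lo, hi)
            self.wsum[g] += w_new - self.w[idx]
            self.w[idx] = w_new
            self.e[idx] = e_new
        self.wbar = self.wsum / self.n_per_gene[:, None]

    def _update_scores_z(self):
        c = self.pr.cutpoint
        m = self._v_mean()
        loglik = self._z_comp_loglik()
        plo = ndtr(-c - m)
        phi = ndtr(c - m)
        logint = np.log(np.clip(np.stack([plo, phi - plo, 1.0 - phi]),
                                1e-300, None))
        k = _sample_cat3(loglik + logint, self.rng)
        lam_new = (k - 1).astype(np.int8)
        lo = np.where(lam_new == -1, -np.inf, np.where(lam_new == 0, -c, c))
        hi = np.where(lam_new == -1, -c, np.where(lam_new == 0, c, np.inf))
        self.v = _trunc_norm(self.rng, m, np.ones_like(m), lo, hi)
        self.lam = lam_new

    # -- trinary indicator updates (differential mode) ---------------------
    def delta_conditional_logweights(self):
        """(3, B) unnormalized log conditional weights of delta_b."""
        resid = self.w - self.mu[:, None]
        x = self.da.x.astype(float)
        sx2 = float(np.sum(x ** 2))
        cross = resid @ x
        logp = np.empty((3, self.B))
        for j, k in enumerate((-1, 0, 1)):
            logp[j] = (_log_probs(self.pr.p_delta)[j]
                       - 0.5 * (self.a_delta * k) ** 2 * sx2
                       + self.a_delta * k * cross)
        return logp

    def _update_delta(self):
        self.delta = (_sample_cat3(self.delta_conditional_logweights(),
                                   self.rng) - 1).astype(np.int8)

    def gamma_conditional_logweights(self):
        base = (self.v - self.nu[:, None]
                - self._coupling()[:, None] * self.wbar)
        x = self.da.x.astype(float)
        sx2 = float(np.sum(x ** 2))
        cross = base @ x
        logp = np.empty((3, self.G))
        for j, k in enumerate((-1, 0, 1)):
            logp[j] = (_log_probs(self.pr.p_gamma)[j]
                       - 0.5 * (self.a_gamma * k) ** 2 * sx2
                       + self.a_gamma * k * cross)
        return logp

    def _update_gamma(self):
        self.gamma = (_sample_cat3(self.gamma_conditional_logweights(),
                                   self.rng) - 1).astype(np.int8)

    def rho_conditional_logweights(self):
        base = (self.v - self.nu[:, None]
                - self.a_gamma * self.gamma[:, None] * self.da.x[None, :])
        sw2 = np.sum(self.wbar ** 2, axis=1)
        cross = np.sum(base * self.wbar, axis=1)
        logp = np.empty((3, self.G))
        for j, k in enumerate((-1, 0, 1)):
            logp[j] = (_log_probs(self.pr.p_rho)[j]
                       - 0.5 * (self.a_rho * k) ** 2 * sw2
                       + self.a_rho * k * cross)
        return logp

    def _update_rho(self):
        if not self.couple:
            return
        self.rho = (_sample_cat3(self.rho_conditional_logweights(),
                                 self.rng) - 1).astype(np.int8)

    # -- collapsed indicator/score block updates -----------------------------
    # Single-site indicator updates conditioned on the scores mix poorly:
    # a large effect can only switch on after the scores have drifted, and
    # vice versa.  These blocks draw the indicator with its score row
    # integrated out over the current state regions (closed form), then
    # redraw the scores -- an exact joint Gibbs block.

    def _region_bounds(self, states):
        c = self.pr.cutpoint
        lo = np.where(states == -1, -np.inf, np.where(states == 0, -c, c))
        hi = np.where(states == -1, -c, np.where(states == 0, c, np.inf))
        return lo, hi

    def _collapsed_delta(self):
        """Joint draw of (delta_b, w_b over x=1 columns), e fixed."""
        x1 = np.nonzero(self.da.x == 1)[0]
        if x1.size == 0:
            self._update_delta()
            return
        coupled = self.include_z and self.couple
        if coupled:
            R = self._coupling()
            vres = self.v - self.nu[:, None] - self._v_effect()
        logpri = _log_probs(self.pr.p_delta)
        for idx in self.rank_groups:
            g = self.gene_of[idx]
            n = len(idx)
            lo, hi = self._region_bounds(self.e[np.ix_(idx, x1)])
            if coupled:
                n_g = self.n_per_gene[g][:, None]
                r = R[g][:, None] / n_g
                s_other = (self.wsum[np.ix_(g, x1)]
                           - self.w[np.ix_(idx, x1)])
                d = vres[np.ix_(g, x1)] - R[g][:, None] * s_other / n_g
            else:
                r = np.zeros((n, 1))
                d = np.zeros((n, x1.size))
            prec = 1.0 + r * r
            sd = 1.0 / np.sqrt(prec)
            logw = np.empty((3, n))
            mstars = np.empty((3, n, x1.size))
            for j, k in enumerate((-1, 0, 1)):
                m = self.mu[idx][:, None] + self.a_delta * k
                mstar = (m + r * d) / prec
                mstars[j] = mstar
                a_ = ndtr((lo - mstar) / sd)
                b_ = ndtr((hi - mstar) / sd)
                lw = (logpri[j]
                      + np.log(np.clip(b_ - a_, 1e-300, None)).sum(axis=1))
                if coupled:
                    lw = lw + gaussian_logpdf(d, r * m, prec).sum(axis=1)
                logw[j] = lw
            knew = _sample_cat3(logw, self.rng)
            self.delta[idx] = (knew - 1).astype(np.int8)
            mstar = mstars[knew, np.arange(n), :]
            w_new = _trunc_norm(self.rng, mstar,
                                np.broadcast_to(sd, mstar.shape), lo, hi)
            self.wsum[np.ix_(g, x1)] += w_new - self.w[np.ix_(idx, x1)]
            self.w[np.ix_(idx, x1)] = w_new
        self.wbar = self.wsum / self.n_per_gene[:, None]

    def _collapsed_gamma_rho(self):
        """Joint draw of (gamma_g, rho_g, v_g row), lambda fixed."""
        combos = [(gv, rv) for gv in (-1, 0, 1)
                  for rv in ((-1, 0, 1) if self.couple else (0,))]
        x = self.da.x[None, :]
        lo, hi = self._region_bounds(self.lam)
        pg = _log_probs(self.pr.p_gamma)
        prho = _log_probs(self.pr.p_rho)
        logw = np.empty((len(combos), self.G))
        means = np.empty((len(combos), self.G, self.T))
        for j, (gv, rv) in enumerate(combos):
            mean = (self.nu[:, None] + self.a_gamma * gv * x
                    + self.a_rho * rv * self.wbar)
            means[j] = mean
            a_ = ndtr(lo - mean)
            b_ = ndtr(hi - mean)
            lw = np.log(np.clip(b_ - a_, 1e-300, None)).sum(axis=1)
            logw[j] = lw + pg[gv + 1] + (prho[rv + 1] if self.couple else 0.0)
        m = logw.max(axis=0, keepdims=True)
        wts = np.exp(logw - m)
        wts /= wts.sum(axis=0, keepdims=True)
        cum = np.cumsum(wts, axis=0)
        pick = (self.rng.random(self.G)[None, :] > cum).sum(axis=0)
        pick = np.minimum(pick, len(combos) - 1)
        combo_arr = np.array(combos, dtype=np.int8)
        self.gamma = combo_arr[pick, 0]
        self.rho = combo_arr[pick, 1]
        mean = means[pick, np.arange(self.G), :]
        self.v = _trunc_norm(self.rng, mean, np.ones_like(mean), lo, hi)

    def _collapsed_zeta(self):
        """Joint draw of (zeta_b, w_b over u=1 columns), e fixed."""
        u1 = np.nonzero(self.u == 1)[0]
        if u1.size == 0:
            self._update_zeta()
            return
        coupled = self.include_z and self.couple
        if coupled:
            R = self._coupling()
            vres = self.v - self.nu[:, None] - self._v_effect()
        logpri = np.array([np.log(self.pr.p_zero),
                           np.log1p(-self.pr.p_zero)])
        for idx in self.rank_groups:
            g = self.gene_of[idx]
            n = len(idx)
            lo, hi = self._region_bounds(self.e[np.ix_(idx, u1)])
            if coupled:
                n_g = self.n_per_gene[g][:, None]
                r = R[g][:, None] / n_g
                s_other = (self.wsum[np.ix_(g, u1)]
                           - self.w[np.ix_(idx, u1)])
                d = vres[np.ix_(g, u1)] - R[g][:, None] * s_other / n_g
            else:
                r = np.zeros((n, 1))
                d = np.zeros((n, u1.size))
            prec = 1.0 + r * r
            sd = 1.0 / np.sqrt(prec)
            logw = np.empty((2, n))
            mstars = np.empty((2, n, u1.size))
            for j in (0, 1):
                m = self.mu[idx][:, None] + j * self.b_zeta[idx][:, None]
                mstar = (m + r * d) / prec
                mstars[j] = mstar
                a_ = ndtr((lo - mstar) / sd)
                b_ = ndtr((hi - mstar) / sd)
                lw = (logpri[j]
                      + np.log(np.clip(b_ - a_, 1e-300, None)).sum(axis=1))
                if coupled:
                    lw = lw + gaussian_logpdf(d, r * m, prec).sum(axis=1)
                logw[j] = lw
            mx = logw.max(axis=0)
            p1 = np.exp(logw[1] - mx)
            p1 /= p1 + np.exp(logw[0] - mx)
            znew = (self.rng.random(n) < p1).astype(int)
            self.zeta[idx] = znew.astype(np.int8)
            mstar = mstars[znew, np.arange(n), :]
            w_new = _trunc_norm(self.rng, mstar,
                                np.broadcast_to(sd, mstar.shape), lo, hi)
            self.wsum[np.ix_(g, u1)] += w_new - self.w[np.ix_(idx, u1)]
            self.w[np.ix_(idx, u1)] = w_new
        self.wbar = self.wsum / self.n_per_gene[:, None]

    def _collapsed_xi(self):
        """Joint draw of (xi_g, v_g over u=1 columns), lambda fixed."""
        u1 = np.nonzero(self.u == 1)[0]
        if u1.size == 0:
            self._update_xi()
            return
        lo, hi = self._region_bounds(self.lam[:, u1])
        base = self.nu[:, None]
        if self.couple:
            base = base + self._coupling()[:, None] * self.wbar[:, u1]
        else:
            base = np.broadcast_to(base, (self.G, u1.size))
        logw = np.empty((2, self.G))
        means = np.empty((2, self.G, u1.size))
        logpri = (np.log(self.pr.p_zero), np.log1p(-self.pr.p_zero))
        for j in (0, 1):
            mean = base + j * self.b_xi[:, None]
            means[j] = mean
            a_ = ndtr(lo - mean)
            b_ = ndtr(hi - mean)
            logw[j] = (logpri[j]
                       + np.log(np.clip(b_ - a_, 1e-300, None)).sum(axis=1))
        mx = logw.max(axis=0)
        p1 = np.exp(logw[1] - mx)
        p1 /= p1 + np.exp(logw[0] - mx)
        xnew = (self.rng.random(self.G) < p1).astype(int)
        self.xi = xnew.astype(np.int8)
        mean = means[xnew, np.arange(self.G), :]
        self.v[:, u1] = _trunc_norm(self.rng, mean, np.ones_like(mean),
                                    lo, hi)

    # -- marginal-likelihood inclusion moves (coefficient integrated out) ----
    # A spike-slab indicator evaluated at a prior-drawn coefficient almost
    # never activates; the conjugate structure lets the coefficient be
    # integrated out against the current scores, so activation is driven by
    # the residual pattern itself.  Alternated with the score-collapsed
    # moves above, both exact.

    def _marginal_inclusion_update(self, resid, indicator, b_vec):
        """Update binary indicators with N(0, b_sd^2) coefficients marginalized.

        ``resid`` is the (n_units, T) score residual excluding the b*u term;
        returns new (indicator, coefficient) arrays.
        """
        u = self.u
        s2 = self.b_sd ** 2
        su2 = float(np.sum(u ** 2))
        ur = resid @ u
        log_odds = (np.log1p(-self.pr.p_zero) - np.log(self.pr.p_zero)
                    + 0.5 * s2 * ur ** 2 / (1.0 + s2 * su2)
                    - 0.5 * np.log1p(s2 * su2))
        p1 = expit(log_odds)
        new_ind = (self.rng.random(len(p1)) < p1).astype(np.int8)
        # coefficient from its conditional given the new indicator
        prec = 1.0 / s2 + su2
        mean = ur / prec
        new_b = np.where(new_ind == 1,
                         self.rng.normal(mean, 1.0 / np.sqrt(prec)),
                         self.rng.normal(0.0, self.b_sd, size=len(p1)))
        return new_ind, new_b

    def _update_zeta_marginal(self):
        resid = self.w - self.mu[:, None]
        self.zeta, self.b_zeta = self._marginal_inclusion_update(
            resid, self.zeta, self.b_zeta)

    def _update_xi_marginal(self):
        resid = self.v - self.nu[:, None]
        if self.couple:
            resid = resid - self._coupling()[:, None] * self.wbar
        self.xi, self.b_xi = self._marginal_inclusion_update(
            resid, self.xi, self.b_xi)

    # -- shared effect magnitudes ------------------------------------------
    def _update_magnitude(self, q, resid, current):
        """Conjugate positive-truncated-normal update for a shared magnitude."""
        pr = self.pr
        prec = 1.0 / pr.a_sd ** 2 + np.sum(q * q)
        lin = pr.a_mean / pr.a_sd ** 2 + np.sum(q * resid)
        return float(_trunc_norm(self.rng, lin / prec, 1.0 / np.sqrt(prec),
                                 0.0, np.inf))

    def _update_a_delta(self):
        q = self.delta[:, None] * self.da.x[None, :]
        resid = self.w - self.mu[:, None]
        self.a_delta = self._update_magnitude(q.astype(float), resid,
                                              self.a_delta)

    def _update_a_gamma(self):
        q = self.gamma[:, None] * self.da.x[None, :]
        resid = (self.v - self.nu[:, None]
                 - self._coupling()[:, None] * self.wbar)
        self.a_gamma = self._update_magnitude(q.astype(float), resid,
                                              self.a_gamma)

    def _update_a_rho(self):
        if not self.couple:
            return
        q = self.rho[:, None] * self.wbar
        resid = (self.v - self.nu[:, None]
                 - self.a_gamma * self.gamma[:, None] * self.da.x[None, :])
        self.a_rho = self._update_magnitude(q, resid, self.a_rho)

    # -- prediction-mode indicator and coefficient updates ------------------
    def zeta_conditional_logweights(self):
        """(2, B) unnormalized log conditional weights of zeta_b."""
        resid = self.w - self.mu[:, None]
        bu = self.b_zeta[:, None] * self.u[None, :]
        logp = np.empty((2, self.B))
        logp[0] = np.log(self.pr.p_zero) - 0.5 * np.sum(resid ** 2, axis=1)
        logp[1] = (np.log1p(-self.pr.p_zero)
                   - 0.5 * np.sum((resid - bu) ** 2, axis=1))
        return logp

    def _update_zeta(self):
        logp = self.zeta_conditional_logweights()
        m = logp.max(axis=0)
        p1 = np.exp(logp[1] - m)
        p1 /= p1 + np.exp(logp[0] - m)
        self.zeta = (self.rng.random(self.B) < p1).astype(np.int8)

    def _update_b_zeta(self):
        active = self.zeta == 1
        prior = self.rng.normal(0.0, self.b_sd, size=self.B)
        if np.any(active):
            resid = self.w[active] - self.mu[active][:, None]
            su2 = float(np.sum(self.u ** 2))
            prec = 1.0 / self.b_sd ** 2 + su2
            lin = resid @ self.u
            draw = self.rng.normal(lin / prec, 1.0 / np.sqrt(prec))
            prior[active] = draw
        self.b_zeta = prior

    def xi_conditional_logweights(self):
        resid = (self.v - self.nu[:, None]
                 - self._coupling()[:, None] * self.wbar)
        bu = self.b_xi[:, None] * self.u[None, :]
        logp = np.empty((2, self.G))
        logp[0] = np.log(self.pr.p_zero) - 0.5 * np.sum(resid ** 2, axis=1)
        logp[1] = (np.log1p(-self.pr.p_zero)
                   - 0.5 * np.sum((resid - bu) ** 2, axis=1))
        return logp

    def _update_xi(self):
        logp = self.xi_conditional_logweights()
        m = logp.max(axis=0)
        p1 = np.exp(logp[1] - m)
        p1 /= p1 + np.exp(logp[0] - m)
        self.xi = (self.rng.random(self.G) < p1).astype(np.int8)

    def _update_b_xi(self):
        active = self.xi == 1
        prior = self.rng.normal(0.0, self.b_sd, size=self.G)
        if np.any(active):
            resid = (self.v[active] - self.nu[active][:, None]
                     - self._coupling()[active][:, None] * self.wbar[active])
            su2 = float(np.sum(self.u ** 2))
            prec = 1.0 / self.b_sd ** 2 + su2
            lin = resid @ self.u
            prior[active] = self.rng.normal(lin / prec, 1.0 / np.sqrt(prec))
        self.b_xi = prior

    def _update_rho_link(self):
        if not self.couple:
            return
        resid = (self.v - self.nu[:, None]
                 - (self.xi * self.b_xi)[:, None] * self.u[None, :])
        sw2 = np.sum(self.wbar ** 2, axis=1)
        prec = 1.0 / self.pr.rho_link_sd ** 2 + sw2
        lin = np.sum(resid * self.wbar, axis=1)
        self.rho_link = self.rng.normal(lin / prec, 1.0 / np.sqrt(prec))

    def outcome_logweights(self):
        """(2, T) unnormalized log conditional weights of every outcome."""
        logp = np.zeros((2, self.T))
        logp[0] += np.log1p(-self.pi)
        logp[1] += np.log(self.pi)
        if self.include_y:
            resid = self.w - self.mu[:, None]
            zb = (self.zeta * self.b_zeta)
            logp[0] += -0.5 * np.sum(resid ** 2, axis=0)
            logp[1] += -0.5 * np.sum((resid - zb[:, None]) ** 2, axis=0)
        if self.include_z:
            base = (self.v - self.nu[:, None]
                    - self._coupling()[:, None] * self.wbar)
            xb = (self.xi * self.b_xi)
            logp[0] += -0.5 * np.sum(base ** 2, axis=0)
            logp[1] += -0.5 * np.sum((base - xb[:, None]) ** 2, axis=0)
        return logp

    def _update_u(self):
        unobs = np.isnan(self.da.u)
        if not np.any(unobs):
            return
        logp = self.outcome_logweights()
        m = logp.max(axis=0)
        p1 = np.exp(logp[1] - m)
        p1 /= p1 + np.exp(logp[0] - m)
        draw = (self.rng.random(self.T) < p1).astype(float)
        self.u = np.where(unobs, draw, self.da.u)
        # Rao-Blackwellized predictive probability of the current sweep
        self.u_prob = np.where(unobs, p1, self.da.u)

    # -- Gaussian blocks ----------------------------------------------------
    def _update_mu(self):
        start = self.da.chain_start
        eta, tau2 = self.eta, self.tau2
        v1 = tau2 * (1.0 - eta ** 2)
        eff = self._w_effect()
        lik_lin = np.sum(self.w - eff, axis=1)
        lik_prec = float(self.T)
        has_next = np.zeros(self.B, dtype=bool)
        has_next[:-1] = ~start[1:]
        idx_all = np.arange(self.B)
        for parity in (0, 1):
            sel = idx_all[idx_all % 2 == parity]
            prior_prec = np.where(start[sel], 1.0 / tau2, 1.0 / v1)
            prev = np.clip(sel - 1, 0, None)
            prior_lin = np.where(start[sel], 0.0,
                                 eta * self.mu[prev] / v1)
            nxt = np.clip(sel + 1, None, self.B - 1)
            next_prec = np.where(has_next[sel], eta ** 2 / v1, 0.0)
            next_lin = np.where(has_next[sel],
                                eta * self.mu[nxt] / v1, 0.0)
            prec = prior_prec + next_prec + lik_prec
            lin = prior_lin + next_lin + lik_lin[sel]
            self.mu[sel] = self.rng.normal(lin / prec, 1.0 / np.sqrt(prec))

    def _update_tau2(self):
        start = self.da.chain_start
        eta = self.eta
        ss = float(np.sum(self.mu[start] ** 2))
        interior = ~start
        if np.any(interior):
            idx = np.nonzero(interior)[0]
            resid = self.mu[idx] - eta * self.mu[idx - 1]
            ss += float(np.sum(resid ** 2)) / (1.0 - eta ** 2)
        shape = self.pr.tau2_shape + 0.5 * self.B
        rate = self.pr.tau2_rate + 0.5 * ss
        self.tau2 = float(_sample_invgamma(self.rng, shape, rate))

    def _update_eta(self):
        pr = self.pr
        breaks = np.nonzero(self.da.chain_start)[0][1:]
        theta = logit(np.clip(self.eta / pr.eta_max, 1e-12, 1 - 1e-12))
        theta_new = theta + pr.eta_step * self.rng.normal()
        eta_new = pr.eta_max * expit(theta_new)
        ll_new = markov_logprior(self.mu, eta_new, self.tau2, breaks)
        ll_old = markov_logprior(self.mu, self.eta, self.tau2, breaks)
        p_new = expit(theta_new)
        p_old = expit(theta)
        log_jac = (np.log(p_new) + np.log1p(-p_new)
                   - np.log(p_old) - np.log1p(-p_old))
        if np.log(self.rng.random()) < ll_new - ll_old + log_jac:
            self.eta = float(eta_new)

    def _update_nu(self):
        resid = self.v - self._v_effect()
        if self.couple:
            resid = resid - self._coupling()[:, None] * self.wbar
        prec = 1.0 / self.pr.nu_sd ** 2 + self.T
        lin = np.sum(resid, axis=1)
        self.nu = self.rng.normal(lin / prec, 1.0 / np.sqrt(prec))

    def _update_alpha(self):
        ivar = 1.0 / (self.cvar_z[self.lam + 1] * self.sigma2_z)
        resid = (self.da.Z - self.beta[None, :] - self.shifts_z[self.lam + 1])
        prec = 1.0 / self.pr.alpha_sd ** 2 + np.sum(ivar, axis=1)
        lin = np.sum(resid * ivar, axis=1)
        self.alpha = self.rng.normal(lin / prec, 1.0 / np.sqrt(prec))

    def _update_beta(self):
        """Exact draw of beta from its zero-sum-constrained full conditional.

        Sample the unconstrained conjugate posterior, then condition the
        Gaussian on 1'beta = 0 (kriging projection); with equal precisions
        this reduces to centring.
        """
        ivar = 1.0 / (self.cvar_z[self.lam + 1] * self.sigma2_z)
        resid = (self.da.Z - self.alpha[:, None] - self.shifts_z[self.lam + 1])
        q = 1.0 / self.pr.beta_sd ** 2 + np.sum(ivar, axis=0)
        lin = np.sum(resid * ivar, axis=0)
        y = self.rng.normal(lin / q, 1.0 / np.sqrt(q))
        qinv = 1.0 / q
        self.beta = y - qinv * (y.sum() / qinv.sum())

    def _update_sigma2_y(self):
        resid = self.da.Y - self.shifts_y[self.e + 1]
        ss = float(np.sum(resid ** 2 / self.cvar_y[self.e + 1]))
        shape = self.pr.sigma2_shape + 0.5 * self.B * self.T
        rate = self.pr.sigma2_rate + 0.5 * ss
        self.sigma2_y = float(_sample_invgamma(self.rng, shape, rate))

    def _update_sigma2_z(self):
        mean = (self.alpha[:, None] + self.beta[None, :]
                + self.shifts_z[self.lam + 1])
        ss = float(np.sum((self.da.Z - mean) ** 2 / self.cvar_z[self.lam + 1]))
        shape = self.pr.sigma2_shape + 0.5 * self.G * self.T
        rate = self.pr.sigma2_rate + 0.5 * ss
        self.sigma2_z = float(_sample_invgamma(self.rng, shape, rate))

    def _update_shift(self, obs, kappa, sigma2, positive):
        pr = self.pr
        pm = pr.shift_mean if positive else -pr.shift_mean
        prec = 1.0 / pr.shift_sd ** 2 + obs.size / (kappa * sigma2)
        lin = pm / pr.shift_sd ** 2 + obs.sum() / (kappa * sigma2)
        lo, hi = (0.0, np.inf) if positive else (-np.inf, 0.0)
        return float(_trunc_norm(self.rng, lin / prec, 1.0 / np.sqrt(prec),
                                 lo, hi))

    def _update_shifts_y(self):
        y = self.da.Y
        self.shifts_y[0] = self._update_shift(
            y[self.e == -1], self.pr.kappa_minus_y, self.sigma2_y, False)
        self.shifts_y[2] = self._update_shift(
            y[self.e == 1], self.pr.kappa_plus_y, self.sigma2_y, True)

    def _update_shifts_z(self):
        centred = self.da.Z - self.alpha[:, None] - self.beta[None, :]
        self.shifts_z[0] = self._update_shift(
            centred[self.lam == -1], self.pr.kappa_minus_z, self.sigma2_z,
            False)
        self.shifts_z[2] = self._update_shift(
            centred[self.lam == 1], self.pr.kappa_plus_z, self.sigma2_z, True)

    # -- sweep, data resampling, joint density -------------------------------
    def sweep(self):
        """One full scan over every full conditional."""
        if self.include_y:
            self._update_scores_y()
        if self.include_z:
            self._update_scores_z()
        if self.mode == "differential":
            if self.include_y:
                self._collapsed_delta()
                self._update_a_delta()
            if self.include_z:
                self._collapsed_gamma_rho()
                self._update_a_gamma()
                self._update_a_rho()
        else:
            if self.include_y:
                self._update_zeta_marginal()
                self._collapsed_zeta()
                self._update_b_zeta()
            if self.include_z:
                self._update_xi_marginal()
                self._collapsed_xi()
                self._update_b_xi()
                self._update_rho_link()
            self._update_u()
        if self.include_y:
            self._update_mu()
            self._update_tau2()
            self._update_eta()
            self._update_sigma2_y()
            self._update_shifts_y()
        if self.include_z:
            self._update_nu()
            self._update_alpha()
            self._update_beta()
            self._update_sigma2_z()
            self._update_shifts_z()
        self.n_sweeps += 1

    def sample_data(self, rng=None):
        """Redraw Y and Z from the sampling model given the current state.

        Used by joint-distribution (Geweke-style) sampler validation.
        """
        rng = rng or self.rng
        sd_y = np.sqrt(self.sigma2_y * self.cvar_y[self.e + 1])
        self.da.Y = self.shifts_y[self.e + 1] + rng.normal(size=(self.B, self.T)) * sd_y
        mean_z = (self.alpha[:, None] + self.beta[None, :]
                  + self.shifts_z[self.lam + 1])
        sd_z = np.sqrt(self.sigma2_z * self.cvar_z[self.lam + 1])
        self.da.Z = mean_z + rng.normal(size=(self.G, self.T)) * sd_z

    def log_joint(self):
        """Log of the full joint density at the current state (oracle aid)."""
        pr = self.pr
        lp = 0.0
        if self.include_y:
            breaks = np.nonzero(self.da.chain_start)[0][1:]
            lp += _invgamma_logpdf(self.tau2, pr.tau2_shape, pr.tau2_rate)
            lp += -np.log(pr.eta_max)       # uniform prior on eta
            lp += markov_logprior(self.mu, self.eta, self.tau2, breaks)
            lp += _invgamma_logpdf(self.sigma2_y, pr.sigma2_shape,
                                   pr.sigma2_rate)
            lp += _truncnorm_sign_logpdf(self.shifts_y[0], -pr.shift_mean,
                                         pr.shift_sd, False)
            lp += _truncnorm_sign_logpdf(self.shifts_y[2], pr.shift_mean,
                                         pr.shift_sd, True)
            if self.mode == "differential":
                lp += float(np.sum(_log_probs(pr.p_delta)[self.delta + 1]))
                lp += _truncnorm_pos_logpdf(self.a_delta, pr.a_mean, pr.a_sd)
            else:
                n1 = int(self.zeta.sum())
                lp += (n1 * np.log1p(-pr.p_zero)
                       + (self.B - n1) * np.log(pr.p_zero))
                lp += float(np.sum(gaussian_logpdf(self.b_zeta, 0.0,
                                                   self.b_sd ** 2)))
            if not np.array_equal(self.e,
                                  threshold_scores(self.w, pr.cutpoint)):
                return -np.inf
            lp += float(np.sum(gaussian_logpdf(self.w, self._w_mean(), 1.0)))
            var = self.sigma2_y * self.cvar_y
            lp += float(np.sum(gaussian_logpdf(
                self.da.Y, self.shifts_y[self.e + 1], var[self.e + 1])))
        if self.include_z:
            lp += float(np.sum(gaussian_logpdf(self.nu, 0.0, pr.nu_sd ** 2)))
            lp += float(np.sum(gaussian_logpdf(self.alpha, 0.0,
                                               pr.alpha_sd ** 2)))
            lp += float(np.sum(gaussian_logpdf(self.beta, 0.0,
                                               pr.beta_sd ** 2)))
            lp += _invgamma_logpdf(self.sigma2_z, pr.sigma2_shape,
                                   pr.sigma2_rate)
            lp += _truncnorm_sign_logpdf(self.shifts_z[0], -pr.shift_mean,
                                         pr.shift_sd, False)
            lp += _truncnorm_sign_logpdf(self.shifts_z[2], pr.shift_mean,
                                         pr.shift_sd, True)
            if self.mode == "differential":
                lp += float(np.sum(_log_probs(pr.p_gamma)[self.gamma + 1]))
                lp += _truncnorm_pos_logpdf(self.a_gamma, pr.a_mean, pr.a_sd)
                if self.couple:
                    lp += float(np.sum(_log_probs(pr.p_rho)[self.rho + 1]))
                    lp += _truncnorm_pos_logpdf(self.a_rho, pr.a_mean, pr.a_sd)
            else:
                n1 = int(self.xi.sum())
                lp += (n1 * np.log1p(-pr.p_zero)
                       + (self.G - n1) * np.log(pr.p_zero))
                lp += float(np.sum(gaussian_logpdf(self.b_xi, 0.0,
                                                   self.b_sd ** 2)))
                if self.couple:
                    lp += float(np.sum(gaussian_logpdf(
                        self.rho_link, 0.0, pr.rho_link_sd ** 2)))
            if not np.array_equal(self.lam,
                                  threshold_scores(self.v, pr.cutpoint)):
                return -np.inf
            lp += float(np.sum(gaussian_logpdf(self.v, self._v_mean(), 1.0)))
            var = self.sigma2_z * self.cvar_z
            mean_z = (self.alpha[:, None] + self.beta[None, :]
                      + self.shifts_z[self.lam + 1])
            lp += float(np.sum(gaussian_logpdf(self.da.Z, mean_z,
                                               var[self.lam + 1])))
        if self.mode == "prediction":
            unobs = np.isnan(self.da.u)
            if np.any(unobs):
                uu = self.u[unobs]
                lp += float(np.sum(uu * np.log(self.pi)
                                   + (1 - uu) * np.log1p(-self.pi)))
        return float(lp)

    def _check_finite(self, iteration):
        checks = {
            "scores_y": self.w, "scores_z": self.v, "baseline_mu": self.mu,
            "effects": self.alpha,
        }
        for name, arr in checks.items():
            if not np.all(np.isfinite(arr)):
                raise RuntimeError(
                    f"non-finite values in block '{name}' at iteration "
                    f"{iteration}")
        for name, val in (("sigma2_y", self.sigma2_y),
                          ("sigma2_z", self.sigma2_z), ("tau2", self.tau2)):
            if not np.isfinite(val) or val <= 0:
                raise RuntimeError(
                    f"invalid variance in block '{name}' at iteration "
                    f"{iteration}")

    # -- main driver --------------------------------------------------------
    def run(self) -> PosteriorDraws:
        cfg = self.cfg
        n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
        diff = self.mode == "differential"
        draws = PosteriorDraws(
            mode=self.mode,
            delta=np.zeros((n_keep, self.B), dtype=np.int8)
            if diff and self.include_y else None,
            gamma=np.zeros((n_keep, self.G), dtype=np.int8)
            if diff and self.include_z else None,
            rho=np.zeros((n_keep, self.G), dtype=np.int8)
            if diff and self.include_z else None,
            zeta=np.zeros((n_keep, self.B), dtype=np.int8)
            if not diff and self.include_y else None,
            xi=np.zeros((n_keep, self.G), dtype=np.int8)
            if not diff and self.include_z else None,
            u=np.zeros((n_keep, self.T), dtype=np.int8) if not diff else None,
            u_prob=np.zeros((n_keep, self.T)) if not diff else None,
            probe_ids=self.da.probe_ids, gene_ids=self.da.gene_ids,
            sample_ids=self.da.sample_ids, gene_of=self.gene_of,
        )
        scalar_names = ["sigma2_y", "sigma2_z", "tau2", "eta",
                        "a_delta", "a_gamma", "a_rho"]
        draws.scalars = {s: np.zeros(n_keep) for s in scalar_names}

        kept = 0
        for it in range(cfg.n_iter):
            self.sweep()
            if (it + 1) % cfg.log_every == 0:
                self._check_finite(it + 1)
                logger.info(
                    "iter %d/%d sigma2_y=%.3f sigma2_z=%.3f eta=%.2f",
                    it + 1, cfg.n_iter, self.sigma2_y, self.sigma2_z,
                    self.eta)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 \
                    and kept < n_keep:
                if draws.delta is not None:
                    draws.delta[kept] = self.delta
                if draws.gamma is not None:
                    draws.gamma[kept] = self.gamma
                if draws.rho is not None:
                    draws.rho[kept] = self.rho
                if draws.zeta is not None:
                    draws.zeta[kept] = self.zeta
                if draws.xi is not None:
                    draws.xi[kept] = self.xi
                if draws.u is not None:
                    draws.u[kept] = self.u.astype(np.int8)
                    draws.u_prob[kept] = self.u_prob
                for s in scalar_names:
                    draws.scalars[s][kept] = getattr(self, s)
                kept += 1
        self._check_finite(cfg.n_iter)
        return draws


def run_chain(arrays: ModelArrays, config: McmcConfig,
              priors: Priors | None = None, **kwargs) -> PosteriorDraws:
    """Run one Gibbs chain and return the retained draws (seed-deterministic)."""
    sampler = GibbsSampler(arrays, priors=priors, config=config, **kwargs)
    return sampler.run()
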