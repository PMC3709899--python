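"""Latent probit-score layer and the Markov prior along the chromosome.

Every trinary state is the thresholding of a latent Gaussian score at
fixed symmetric cutpoints +-c (c = 1 by default, score variance fixed at 1
for identifiability).  The DNA scores w_bt regress on a probe baseline
mu_b plus a differential-CNA term a_delta * delta_b * x_t; the RNA scores
v_gt regress on a gene intercept nu_g, a differential-expression term
a_gamma * gamma_g * x_t and the cross-platform interaction
a_rho * rho_g * wbar_gt, where wbar_gt is the mean DNA score of the
probes of gene g.  The probe baselines mu_b follow a first-order
autoregression along the chromosome whose coefficients eta are partial
correlations between adjacent probes; the chain restarts at every
chromosome boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["threshold_scores", "gene_level_score", "w_prior_mean",
           "v_prior_mean", "markov_logprior"]

_LOG2PI = np.log(2.0 * np.pi)


def threshold_scores(scores, cutpoint: float = 1.0):
    """Map scores to trinary states: -1 below -c, +1 above +c, else 0."""
    if cutpoint <= 0:
        raise ValueError("cutpoint must be positive")
    scores = np.asarray(scores)
    return (scores > cutpoint).astype(np.int8) - (scores < -cutpoint).astype(np.int8)


def gene_level_score(w, gene_of, n_genes: int | None = None):
    """Per-gene mean of the probe scores, for every sample.

    Parameters
    ----------
    w : (B, T) array of probe scores
    gene_of : (B,) integer gene index per probe
    n_genes : number of genes (defaults to max index + 1)

    Returns the (G, T) matrix of gene-level scores wbar_gt.
    """
    w = np.asarray(w, dtype=float)
    gene_of = np.asarray(gene_of)
    if n_genes is None:
        n_genes = int(gene_of.max()) + 1
    counts = np.bincount(gene_of, minlength=n_genes)
    if np.any(counts == 0):
        raise ValueError("every gene must have at least one probe")
    sums = np.zeros((n_genes, w.shape[1]))
    np.add.at(sums, gene_of, w)
    return sums / counts[:, None]


def w_prior_mean(mu, delta, a_delta, x):
    """Regression mean of the DNA scores: mu_b + a_delta * delta_b * x_t."""
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta)
    x = np.asarray(x)
    return mu[:, None] + a_delta * delta[:, None] * x[None, :]


def v_prior_mean(nu, gamma, rho, a_gamma, a_rho, x, wbar):
    """Regression mean of the RNA scores.

    nu_g + a_gamma * gamma_g * x_t + a_rho * rho_g * wbar_gt — the third
    term carries the cross-platform integration; setting rho_g = 0 for all
    genes recovers the marginal (platform-independent) model.
    """
    nu = np.asarray(nu, dtype=float)
    gamma = np.asarray(gamma)
    rho = np.asarray(rho)
    x = np.asarray(x)
    wbar = np.asarray(wbar, dtype=float)
    return (nu[:, None] + a_gamma * gamma[:, None] * x[None, :]
            + a_rho * rho[:, None] * wbar)


def markov_logprior(mu, eta, tau2, chain_breaks=()):
    """Log density of the AR(1) prior on the probe baselines.

    The first probe of each chain segment is N(0, tau2); subsequent probes
    are N(eta_b * mu_{b-1}, tau2 * (1 - eta_b^2)).  With this
    parameterization every marginal variance equals tau2 exactly, so a
    prior bound eta <= eta_max < 1 bounds the marginal variance of the
    baselines by construction.  ``eta`` may be a scalar (adjacent probes
    equally correlated) or a per-edge vector of length B; ``chain_breaks``
    are the indices (besides 0) where a new chromosome starts.
    """
    mu = np.asarray(mu, dtype=float)
    B = len(mu)
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    eta = np.broadcast_to(np.asarray(eta, dtype=float), (B,))
    if np.any((eta < 0) | (eta >= 1)):
        raise ValueError("eta must lie in [0, 1)")
    start = np.zeros(B, dtype=bool)
    start[0] = True
    start[list(chain_breaks)] = True

    ll = 0.0
    # chain starts: N(0, tau2)
    ll += np.sum(-0.5 * (_LOG2PI + np.log(tau2) + mu[start] ** 2 / tau2))
    # interior: N(eta * prev, tau2 (1 - eta^2))
    interior = ~start
    if np.any(interior):
        idx = np.nonzero(interior)[0]
        var = tau2 * (1.0 - eta[idx] ** 2)
        resid = mu[idx] - eta[idx] * mu[idx - 1]
        ll += np.sum(-0.5 * (_LOG2PI + np.log(var) + resid ** 2 / var))
    return float(ll)


def ar1_covariance(eta, tau2, B, chain_breaks=()):
    """Dense covariance implied by the AR(1) prior (oracle/testing aid)."""
    eta = np.broadcast_to(np.asarray(eta, dtype=float), (B,))
    start = np.zeros(B, dtype=bool)
    start[0] = True
    start[list(chain_breaks)] = True
    cov = np.zeros((B, B))
    for i in range(B):
        cov[i, i] = tau2
        for j in range(i + 1, B):
            if start[j]:
                break
            cov[i, j] = cov[j, i] = tau2 * np.prod(eta[i + 1:j + 1])
    return cov
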