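"""Outcome-linked score regressions for predicting pathological response.

In prediction mode the subtype regressions are replaced by sparse
outcome regressions: a binary inclusion indicator per probe (zeta_b) and
per gene (xi_g) switches an outcome effect on the latent scores on or
off, with prior inclusion probability 1 - p_zero kept very small so that
only a handful of units carry the clinical signal.  Patients without an
observed outcome (new patients, or missing pCR) get a Bernoulli(pi)
prior on u_t and their outcome is imputed inside the Gibbs sweep; the
Monte-Carlo average of the imputed draws is the posterior predictive
probability of positive pCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OutcomeVector", "w_pred_mean", "v_pred_mean",
           "outcome_log_weights", "outcome_full_conditional",
           "posterior_predictive_pcr"]


@dataclass
class OutcomeVector:
    """Binary outcome with an observed mask (False = unknown, imputed)."""

    u: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.u.shape != self.observed.shape:
            raise ValueError("u and observed mask must have the same length")
        if not set(np.unique(self.u)) <= {0.0, 1.0}:
            raise ValueError("u entries must be 0 or 1")

    @classmethod
    def from_series(cls, u):
        """Build from a float vector with NaN marking unknown outcomes."""
        u = np.asarray(u, dtype=float)
        observed = ~np.isnan(u)
        filled = np.where(observed, u, 0.0)
        return cls(filled, observed)


def w_pred_mean(mu, zeta, b_zeta, u):
    """DNA score regression mean: mu_b + zeta_b * b_zeta_b * u_t."""
    mu = np.asarray(mu, dtype=float)
    zeta = np.asarray(zeta)
    b_zeta = np.asarray(b_zeta, dtype=float)
    uvec = u.u if isinstance(u, OutcomeVector) else np.asarray(u, dtype=float)
    return mu[:, None] + (zeta * b_zeta)[:, None] * uvec[None, :]


def v_pred_mean(nu, xi, b_xi, rho_link, u, wbar):
    """RNA score regression mean: nu_g + xi_g*b_xi_g*u_t + rho_link_g*wbar_gt."""
    nu = np.asarray(nu, dtype=float)
    xi = np.asarray(xi)
    b_xi = np.asarray(b_xi, dtype=float)
    rho_link = np.asarray(rho_link, dtype=float)
    uvec = u.u if isinstance(u, OutcomeVector) else np.asarray(u, dtype=float)
    wbar = np.asarray(wbar, dtype=float)
    return (nu[:, None] + (xi * b_xi)[:, None] * uvec[None, :]
            + rho_link[:, None] * wbar)


def outcome_log_weights(t, w, v, mu, zeta, b_zeta, nu, xi, b_xi, rho_link,
                        wbar, pi):
    """Unnormalized log weights of u_t = 0 and u_t = 1 given everything else.

    The outcome of sample t enters only the score regressions of column t,
    so the exact full conditional is a two-point distribution proportional
    to pi^u (1-pi)^(1-u) times the joint normal density (unit variances) of
    the w and v columns evaluated under each value of u.
    """
    logw = np.empty(2)
    for u_val in (0, 1):
        lp = u_val * np.log(pi) + (1 - u_val) * np.log1p(-pi)
        if w is not None:
            mean_w = mu + zeta * b_zeta * u_val
            lp += -0.5 * np.sum((w[:, t] - mean_w) ** 2)
        if v is not None:
            mean_v = nu + xi * b_xi * u_val
            if rho_link is not None and wbar is not None:
                mean_v = mean_v + rho_link * wbar[:, t]
            lp += -0.5 * np.sum((v[:, t] - mean_v) ** 2)
        logw[u_val] = lp
    return logw


def outcome_full_conditional(t, outcome: OutcomeVector, w, v, mu, zeta,
                             b_zeta, nu, xi, b_xi, rho_link, wbar, pi):
    """Exact P(u_t = 1 | everything else) for an unobserved outcome."""
    if outcome.observed[t]:
        raise ValueError(f"outcome of sample {t} is observed, not imputable")
    if not (0.0 < pi < 1.0):
        raise ValueError("pi must be in (0, 1)")
    logw = outcome_log_weights(t, w, v, mu, zeta, b_zeta, nu, xi, b_xi,
                               rho_link, wbar, pi)
    m = logw.max()
    p = np.exp(logw - m)
    return float(p[1] / p.sum())


def posterior_predictive_pcr(u_draws, t, observed=None):
    """Monte-Carlo posterior predictive P(pCR = 1) for patient t.

    ``u_draws`` is the (n_draws, T) matrix of retained outcome draws.
    """
    u_draws = np.asarray(u_draws, dtype=float)
    if observed is not None and np.asarray(observed, dtype=bool)[t]:
        raise ValueError(f"sample {t} was observed, not imputed in the chain")
    return float(u_draws[:, t].mean())
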