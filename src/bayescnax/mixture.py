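"""Three-component sampling densities for log2 ratios and expression.

Each observation is modelled, conditional on its trinary latent state,
as a Gaussian: the neutral state sits at the platform centre with the
"normal range" variance sigma^2, while the aberrant states (copy loss/gain,
under/over-expression) are mean-shifted and variance-inflated by a factor
kappa >= 1 (tail over-dispersion relative to normality).  On the
expression side every component mean is additionally offset by a gene
effect alpha_g and a sample effect beta_t (the aCGH side needs no such
effects because a log2 ratio already cancels them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ComponentParams", "EffectParams", "cgh_component_logdensity",
           "expr_component_logdensity", "complete_data_loglik"]

_LOG2PI = np.log(2.0 * np.pi)
BETA_TOL = 1e-10


@dataclass
class ComponentParams:
    """Mixture-component parameters for one platform.

    ``sigma2`` is the neutral-state variance; ``kappa_minus``/``kappa_plus``
    inflate it in the -1/+1 components; ``shift_minus``/``shift_plus`` are
    the aberrant mean offsets (e.g. the theoretical single-copy-loss log2
    ratio is -1).
    """

    sigma2: float = 0.25
    kappa_minus: float = 3.0
    kappa_plus: float = 3.0
    shift_minus: float = -1.0
    shift_plus: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.kappa_minus < 1 or self.kappa_plus < 1:
            raise ValueError("kappa must be >= 1 (tail over-dispersion)")
        if not (self.shift_minus < 0 < self.shift_plus):
            raise ValueError("need shift_minus < 0 < shift_plus")

    @property
    def means(self) -> np.ndarray:
        """Component means indexed by state+1 (order -1, 0, +1)."""
        return np.array([self.shift_minus, 0.0, self.shift_plus])

    @property
    def variances(self) -> np.ndarray:
        return self.sigma2 * np.array([self.kappa_minus, 1.0, self.kappa_plus])


@dataclass
class EffectParams:
    """Gene effects alpha_g and zero-sum sample effects beta_t."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if abs(self.beta.sum()) > BETA_TOL * max(1, len(self.beta)):
            raise ValueError("sample effects beta must sum to zero")


def _check_state(state):
    if not np.all(np.isin(state, (-1, 0, 1))):
        raise ValueError("state must be in {-1, 0, +1}")


def gaussian_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)


def cgh_component_logdensity(y, state, params: ComponentParams):
    """Log density of a log2 ratio given its copy-number state.

    State 0 -> N(0, sigma2); -1 -> N(shift_minus, kappa_minus*sigma2);
    +1 -> N(shift_plus, kappa_plus*sigma2).  Vectorized over ``y``/``state``.
    """
    state = np.asarray(state)
    _check_state(state)
    idx = state + 1
    return gaussian_logpdf(y, params.means[idx], params.variances[idx])


def expr_component_logdensity(z, state, g, t, params: ComponentParams,
                              effects: EffectParams):
    """Log density of an expression value given its state and cell (g, t)."""
    state = np.asarray(state)
    _check_state(state)
    alpha = effects.alpha[g]
    beta = effects.beta[t]
    idx = state + 1
    mean = params.means[idx] + alpha + beta
    return gaussian_logpdf(z, mean, params.variances[idx])


def complete_data_loglik(Y, Z, e, lam, params_y: ComponentParams,
                         params_z: ComponentParams, effects: EffectParams):
    """Complete-data log likelihood of both matrices given all states.

    Sum over probes x samples of the aCGH component log densities plus the
    sum over genes x samples of the expression component log densities.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    e = np.asarray(e)
    lam = np.asarray(lam)
    if Y.shape != e.shape or Z.shape != lam.shape:
        raise ValueError("state matrices must match data shapes")
    if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(Z))):
        raise ValueError("non-finite observations")
    _check_state(e)
    _check_state(lam)

    ll = cgh_component_logdensity(Y, e, params_y).sum()
    idx = lam + 1
    mean = (params_z.means[idx]
            + effects.alpha[:, None] + effects.beta[None, :])
    ll += gaussian_logpdf(Z, mean, params_z.variances[idx]).sum()
    return float(ll)
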