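"""Sampler validation by joint-distribution (Geweke-style) testing.

Two ways of sampling from the joint distribution of (parameters, data)
must agree: the *marginal-conditional* path draws parameters from the
prior and data from the sampling model, independently each time; the
*successive-conditional* path alternates one Gibbs transition on the
parameters with a redraw of the data given the parameters.  If every full
conditional in the Gibbs sweep is correct, both paths have the same
stationary distribution and the moments of any functional agree up to
Monte-Carlo error.
"""

from __future__ import annotations

import numpy as np

__all__ = ["default_functionals", "geweke_test"]


def default_functionals():
    """Scalar functionals of the sampler state exercised by the test."""
    return {
        "sigma2_y": lambda s: s.sigma2_y,
        "sigma2_z": lambda s: s.sigma2_z,
        "tau2": lambda s: s.tau2,
        "eta": lambda s: s.eta,
        "mean_mu": lambda s: float(s.mu.mean()),
        "mean_w": lambda s: float(s.w.mean()),
        "mean_v": lambda s: float(s.v.mean()),
        "mean_alpha": lambda s: float(s.alpha.mean()),
        "a_delta": lambda s: s.a_delta,
        "frac_delta_pos": lambda s: float((s.delta == 1).mean()),
        "frac_gamma_nonzero": lambda s: float((s.gamma != 0).mean()),
        "shift_plus_y": lambda s: s.shifts_y[2],
        "mean_Y": lambda s: float(s.da.Y.mean()),
        "mean_Z": lambda s: float(s.da.Z.mean()),
        "var_Y": lambda s: float(s.da.Y.var()),
    }


def _batch_se(x, n_batches=40):
    """Batch-means standard error of the mean of a correlated series."""
    x = np.asarray(x, dtype=float)
    n = len(x) // n_batches
    if n < 1:
        return np.std(x) / np.sqrt(len(x))
    means = x[:n * n_batches].reshape(n_batches, n).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(n_batches))


def geweke_test(sampler, n_marginal=5000, n_successive=5000, burn=200,
                functionals=None, seed=0):
    """Compare marginal- and successive-conditional moments.

    Parameters
    ----------
    sampler : GibbsSampler
        Will be re-initialized; its data arrays are overwritten.
    n_marginal, n_successive : draws per path.
    burn : successive-conditional transitions discarded up front.
    functionals : dict name -> callable(state) -> float

    Returns a dict name -> dict with the two means, their standard errors
    and the z score, for each functional and its square.
    """
    fns = functionals or default_functionals()
    rng = np.random.default_rng(seed)

    marg = {k: np.empty(n_marginal) for k in fns}
    for i in range(n_marginal):
        sampler.init_from_prior(rng)
        sampler.sample_data(rng)
        for k, f in fns.items():
            marg[k][i] = f(sampler)

    succ = {k: np.empty(n_successive) for k in fns}
    sampler.init_from_prior(rng)
    sampler.sample_data(rng)
    sampler.rng = rng
    for i in range(burn + n_successive):
        sampler.sweep()
        sampler.sample_data(rng)
        if i >= burn:
            for k, f in fns.items():
                succ[k][i - burn] = f(sampler)

    out = {}
    for k in fns:
        for suffix, tm, ts in ((k, marg[k], succ[k]),
                               (k + "^2", marg[k] ** 2, succ[k] ** 2)):
            m1, m2 = tm.mean(), ts.mean()
            se1 = float(np.std(tm, ddof=1) / np.sqrt(len(tm)))
            se2 = _batch_se(ts)
            z = (m1 - m2) / np.sqrt(se1 ** 2 + se2 ** 2 + 1e-30)
            out[suffix] = {"marginal_mean": float(m1),
                           "successive_mean": float(m2),
                           "marginal_se": se1, "successive_se": se2,
                           "z": float(z)}
    return out
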