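"""Synthetic cohorts emulating the two simulation designs and prediction data.

Design 1 plants differential behaviour empirically: observations are
Gaussian around their baselines and a block of signal genes receives mean
shifts (expression and copy-number) in the first subgroup only.  Design 2
samples ancestrally through the full hierarchical model: baseline chain,
trinary indicators, latent probit scores, thresholded states, then
observations from the three-component mixtures.  A third generator builds
prediction cohorts in which a small set of probes/genes carries
outcome-dependent score shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset
from .latent import threshold_scores, gene_level_score

__all__ = ["SimDesign", "simulate_design1", "simulate_design2",
           "simulate_prediction_cohort", "cohort_from_counts"]


def _default_effects():
    return {
        "cna_shift": 1.0,          # data-scale log2-ratio shift (design 1)
        "expression_shift": 2.0,   # data-scale expression shift (design 1)
        "latent_effect": 2.0,      # shared latent effect magnitude (design 2)
        "outcome_effect": 2.0,     # latent outcome effect (prediction cohorts)
    }


@dataclass
class SimDesign:
    """Knobs of one synthetic study."""

    n_genes: int = 1000
    probes_per_gene: int = 2
    n_samples: int = 50
    n_signal_genes: int = 50
    signal_position: str = "tail"   # "head" or "tail"
    effect_sizes: dict = field(default_factory=_default_effects)
    x_split: int = 10               # samples in subgroup 1 (x = 1)
    outcome_linked_genes: int = 0
    pi: float = 0.5                 # outcome prevalence (prediction cohorts)
    seed: int = 0

    def __post_init__(self):
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must be <= n_genes")
        if self.x_split > self.n_samples:
            raise ValueError("x_split must be <= n_samples")
        if self.signal_position not in ("head", "tail"):
            raise ValueError("signal_position must be 'head' or 'tail'")
        eff = _default_effects()
        eff.update(self.effect_sizes)
        self.effect_sizes = eff

    def signal_mask(self):
        mask = np.zeros(self.n_genes, dtype=bool)
        if self.n_signal_genes:
            if self.signal_position == "tail":
                mask[-self.n_signal_genes:] = True
            else:
                mask[:self.n_signal_genes] = True
        return mask


def _skeleton(design: SimDesign):
    G = design.n_genes
    ppg = design.probes_per_gene
    B = G * ppg
    gene_ids = [f"gene{g:05d}" for g in range(G)]
    probe_ids = [f"probe{b:05d}" for b in range(B)]
    gene_of = np.repeat(np.arange(G), ppg)
    info = pd.DataFrame({
        "chromosome": "1",
        "position": 1000 * (np.arange(B) + 1),
        "gene_id": [gene_ids[g] for g in gene_of],
    }, index=pd.Index(probe_ids, name="probe_id"))
    sample_ids = [f"s{t:03d}" for t in range(design.n_samples)]
    x = np.zeros(design.n_samples, dtype=int)
    x[:design.x_split] = 1
    return gene_ids, probe_ids, gene_of, info, sample_ids, x


def _package(design, Y, Z, info, gene_ids, probe_ids, sample_ids, x, u):
    covars = pd.DataFrame({"x": x, "u": u},
                          index=pd.Index(sample_ids, name="sample_id"))
    return Dataset(
        Y=pd.DataFrame(Y, index=pd.Index(probe_ids, name="probe_id"),
                       columns=sample_ids),
        Z=pd.DataFrame(Z, index=pd.Index(gene_ids, name="gene_id"),
                       columns=sample_ids),
        probe_info=info,
        covariates=covars,
    )


def simulate_design1(design: SimDesign):
    """Empirical signal-planting design.

    Gene effects alpha_g ~ N(0, 1) and zero-sum sample effects beta_t drive
    the expression baseline; observations are Gaussian (sd 0.5) around
    baseline 0 (log2 ratios) and alpha_g + beta_t (expression).  Signal
    genes receive an expression mean shift, and their probes a log2-ratio
    mean shift, in the x = 1 subgroup only.

    Returns ``(dataset, truth)`` where ``truth['signal_genes']`` marks the
    differential genes.
    """
    rng = np.random.default_rng(design.seed)
    gene_ids, probe_ids, gene_of, info, sample_ids, x = _skeleton(design)
    G, B, T = design.n_genes, len(probe_ids), design.n_samples
    eff = design.effect_sizes

    alpha = rng.normal(0.0, 1.0, size=G)
    beta = rng.normal(0.0, 1.0, size=T)
    beta -= beta.mean()

    Y = rng.normal(0.0, 0.5, size=(B, T))
    Z = alpha[:, None] + beta[None, :] + rng.normal(0.0, 0.5, size=(G, T))

    signal = design.signal_mask()
    cols = x == 1
    Z[np.ix_(signal, cols)] += eff["expression_shift"]
    Y[np.ix_(signal[gene_of], cols)] += eff["cna_shift"]

    u = np.full(T, np.nan)
    data = _package(design, Y, Z, info, gene_ids, probe_ids, sample_ids, x, u)
    truth = {"signal_genes": signal, "alpha": alpha, "beta": beta}
    return data, truth


def simulate_design2(design: SimDesign, params: dict | None = None):
    """Ancestral sampling through the full hierarchical model.

    Signal genes carry delta_b = +1 on their probes, gamma_g = +1 and
    rho_g = +1, all with a shared latent effect magnitude (default 2);
    everything else follows the model's own generative path: AR(1) baseline
    chain, probit scores with unit variance, thresholding at +-1, then
    mixture observations.

    ``params`` may override: eta, tau2, sigma2_y, sigma2_z, shift
    magnitudes, kappa, cutpoint.  Returns ``(dataset, truth)`` with the
    generating states and scores in ``truth``.
    """
    p = {
        "eta": 0.5, "tau2": 1.0, "sigma2_y": 0.25, "sigma2_z": 0.25,
        "shift_y": 1.0, "shift_z": 1.0, "kappa": 3.0, "cutpoint": 1.0,
    }
    p.update(params or {})
    rng = np.random.default_rng(design.seed)
    gene_ids, probe_ids, gene_of, info, sample_ids, x = _skeleton(design)
    G, B, T = design.n_genes, len(probe_ids), design.n_samples
    a = design.effect_sizes["latent_effect"]

    signal = design.signal_mask()
    delta = np.where(signal[gene_of], 1, 0).astype(np.int8)
    gamma = np.where(signal, 1, 0).astype(np.int8)
    rho = np.where(signal, 1, 0).astype(np.int8)

    # baseline chain (single chromosome here, so no restarts)
    mu = np.zeros(B)
    mu[0] = rng.normal(0.0, np.sqrt(p["tau2"]))
    sd_in = np.sqrt(p["tau2"] * (1.0 - p["eta"] ** 2))
    innov = rng.normal(0.0, sd_in, size=B)
    for b in range(1, B):
        mu[b] = p["eta"] * mu[b - 1] + innov[b]

    w = mu[:, None] + a * delta[:, None] * x[None, :] + rng.normal(size=(B, T))
    e = threshold_scores(w, p["cutpoint"])
    wbar = gene_level_score(w, gene_of, G)
    nu = np.zeros(G)
    v = (nu[:, None] + a * gamma[:, None] * x[None, :]
         + a * rho[:, None] * wbar + rng.normal(size=(G, T)))
    lam = threshold_scores(v, p["cutpoint"])

    shifts_y = np.array([-p["shift_y"], 0.0, p["shift_y"]])
    shifts_z = np.array([-p["shift_z"], 0.0, p["shift_z"]])
    cvar = np.array([p["kappa"], 1.0, p["kappa"]])
    alpha = rng.normal(0.0, 1.0, size=G)
    beta = rng.normal(0.0, 1.0, size=T)
    beta -= beta.mean()

    Y = (shifts_y[e + 1]
         + rng.normal(size=(B, T)) * np.sqrt(p["sigma2_y"] * cvar[e + 1]))
    Z = (alpha[:, None] + beta[None, :] + shifts_z[lam + 1]
         + rng.normal(size=(G, T)) * np.sqrt(p["sigma2_z"] * cvar[lam + 1]))

    u = np.full(T, np.nan)
    data = _package(design, Y, Z, info, gene_ids, probe_ids, sample_ids, x, u)
    truth = {
        "signal_genes": signal, "delta": delta, "gamma": gamma, "rho": rho,
        "mu": mu, "w": w, "v": v, "e": e, "lam": lam, "wbar": wbar,
        "alpha": alpha, "beta": beta, "params": p,
    }
    return data, truth


def simulate_prediction_cohort(design: SimDesign, params: dict | None = None):
    """Cohort with outcomes linked to a small set of probes and genes.

    Outcomes are Bernoulli(pi).  Of the ``outcome_linked_genes`` linked
    genes, half carry the outcome effect on their probes' DNA scores only
    and half on their RNA scores only, so that each platform holds part of
    the signal and integrating them is rewarded.  Returns
    ``(dataset, truth)``; all outcomes are recorded in the covariates (mask
    some as a test set before fitting).
    """
    p = {
        "eta": 0.5, "tau2": 1.0, "sigma2_y": 0.25, "sigma2_z": 0.25,
        "shift_y": 1.0, "shift_z": 1.0, "kappa": 3.0, "cutpoint": 1.0,
    }
    p.update(params or {})
    rng = np.random.default_rng(design.seed)
    gene_ids, probe_ids, gene_of, info, sample_ids, x = _skeleton(design)
    G, B, T = design.n_genes, len(probe_ids), design.n_samples
    b_eff = design.effect_sizes["outcome_effect"]

    u = (rng.random(T) < design.pi).astype(float)

    n_link = design.outcome_linked_genes
    linked = np.zeros(G, dtype=bool)
    cna_linked = np.zeros(G, dtype=bool)
    expr_linked = np.zeros(G, dtype=bool)
    if n_link:
        linked[:n_link] = True
        cna_linked[:(n_link + 1) // 2] = True
        expr_linked[(n_link + 1) // 2:n_link] = True

    zeta = cna_linked[gene_of].astype(np.int8)
    xi = expr_linked.astype(np.int8)

    mu = np.zeros(B)
    mu[0] = rng.normal(0.0, np.sqrt(p["tau2"]))
    sd_in = np.sqrt(p["tau2"] * (1.0 - p["eta"] ** 2))
    for b in range(1, B):
        mu[b] = p["eta"] * mu[b - 1] + rng.normal(0.0, sd_in)

    w = (mu[:, None] + b_eff * zeta[:, None] * u[None, :]
         + rng.normal(size=(B, T)))
    e = threshold_scores(w, p["cutpoint"])
    wbar = gene_level_score(w, gene_of, G)
    v = (b_eff * xi[:, None] * u[None, :] + rng.normal(size=(G, T)))
    lam = threshold_scores(v, p["cutpoint"])

    shifts_y = np.array([-p["shift_y"], 0.0, p["shift_y"]])
    shifts_z = np.array([-p["shift_z"], 0.0, p["shift_z"]])
    cvar = np.array([p["kappa"], 1.0, p["kappa"]])
    alpha = rng.normal(0.0, 1.0, size=G)
    beta = rng.normal(0.0, 1.0, size=T)
    beta -= beta.mean()

    Y = (shifts_y[e + 1]
         + rng.normal(size=(B, T)) * np.sqrt(p["sigma2_y"] * cvar[e + 1]))
    Z = (alpha[:, None] + beta[None, :] + shifts_z[lam + 1]
         + rng.normal(size=(G, T)) * np.sqrt(p["sigma2_z"] * cvar[lam + 1]))

    data = _package(design, Y, Z, info, gene_ids, probe_ids, sample_ids, x, u)
    truth = {
        "linked_genes": linked, "cna_linked": cna_linked,
        "expr_linked": expr_linked, "u": u, "zeta": zeta, "xi": xi,
        "e": e, "lam": lam, "w": w, "v": v,
    }
    return data, truth


def cohort_from_counts(tn_pos, tn_neg, tn_missing, other_pos, other_neg,
                       other_missing):
    """Covariate table with exact cell counts (subgroup x pCR status)."""
    rows = []
    cells = [
        (1, 1.0, tn_pos), (1, 0.0, tn_neg), (1, np.nan, tn_missing),
        (0, 1.0, other_pos), (0, 0.0, other_neg), (0, np.nan, other_missing),
    ]
    i = 0
    for x, u, n in cells:
        for _ in range(n):
            rows.append({"sample_id": f"p{i:03d}", "x": x, "u": u})
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")
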