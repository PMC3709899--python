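"""Model / Results interface over the Gibbs machinery.

Two fitting objects cover the two analyses: differential behaviour of
genes between breast-cancer subtypes (triple negative versus ER+/HER2+),
and prediction of pathological complete response (pCR) for patients whose
outcome is unknown.  Each is constructed from a validated
:class:`~bayescnax.io.Dataset`, and ``fit()`` returns a results object
carrying the retained posterior draws, derived probabilities, gene
selections and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as _io
from .fdr import build_gene_lists, list_event_probabilities, LIST_LABELS
from .gibbs import GibbsSampler, McmcConfig, ModelArrays, Priors
from .roc import smoothed_roc

__all__ = ["DifferentialBehaviourModel", "DifferentialBehaviourResults",
           "PcrPredictionModel", "PcrPredictionResults"]


class DifferentialBehaviourModel:
    """Joint differential-behaviour model of copy number and expression.

    Parameters
    ----------
    data : io.Dataset
    priors : Priors, optional
    couple : bool
        True (default) fits the integrated model; False pins every
        interaction indicator at zero, i.e. the marginal model in which
        the two platforms are analysed independently.
    """

    def __init__(self, data: _io.Dataset, priors: Priors | None = None,
                 couple: bool = True):
        self.data = data
        self.priors = priors or Priors()
        self.couple = couple

    @classmethod
    def from_files(cls, probe_path, expr_path, map_path, covar_path,
                   **kwargs):
        return cls(_io.load_matrices(probe_path, expr_path, map_path,
                                     covar_path), **kwargs)

    def fit(self, n_iter: int = 4000, burn_in: int = 2000, thin: int = 1,
            seed: int = 0, log_every: int = 100):
        config = McmcConfig(n_iter=n_iter, burn_in=burn_in, thin=thin,
                            seed=seed, mode="differential",
                            log_every=log_every)
        arrays = ModelArrays.from_dataset(self.data)
        sampler = GibbsSampler(arrays, priors=self.priors, config=config,
                               couple=self.couple)
        draws = sampler.run()
        return DifferentialBehaviourResults(self, draws)


class DifferentialBehaviourResults:
    """Posterior draws and gene-level inference of the differential model."""

    def __init__(self, model: DifferentialBehaviourModel, draws):
        self.model = model
        self.draws = draws
        self._probs = None

    @property
    def list_probabilities(self) -> pd.DataFrame:
        """Per-gene posterior probabilities of the five list events."""
        if self._probs is None:
            probs = list_event_probabilities(
                self.draws, self.draws.gene_of, len(self.draws.gene_ids))
            self._probs = pd.DataFrame(probs, index=self.draws.gene_ids)
        return self._probs

    def marginal_probabilities(self) -> pd.DataFrame:
        """Marginal per-gene probabilities of the indicator events."""
        g = self.draws.gamma
        r = self.draws.rho
        return pd.DataFrame({
            "P(gamma=+1)": (g == 1).mean(axis=0),
            "P(gamma=-1)": (g == -1).mean(axis=0),
            "P(rho=+1)": (r == 1).mean(axis=0),
            "P(rho=-1)": (r == -1).mean(axis=0),
        }, index=self.draws.gene_ids)

    def select_genes(self, alpha: float = 0.10):
        """Five FDR-controlled gene lists at expected-FDR level alpha."""
        return build_gene_lists(self.draws, alpha, self.draws.gene_of,
                                self.draws.gene_ids)

    def summary(self, alpha: float = 0.10) -> str:
        lines = [
            "Differential behaviour model "
            f"({'integrated' if self.model.couple else 'marginal'})",
            f"genes: {len(self.draws.gene_ids)}   "
            f"probes: {len(self.draws.probe_ids)}   "
            f"samples: {len(self.draws.sample_ids)}   "
            f"retained draws: {self.draws.n_draws}",
            "-" * 64,
            f"{'list':<30}{'selected':>9}{'  expected FDR':>15}",
        ]
        for sel in self.select_genes(alpha):
            lines.append(f"{sel.list_label:<30}{len(sel):>9}"
                         f"{sel.fdr_at_cut:>15.4f}")
        s = self.draws.scalars
        lines.append("-" * 64)
        lines.append(
            "posterior means: "
            f"sigma2_Y={s['sigma2_y'].mean():.3f} "
            f"sigma2_Z={s['sigma2_z'].mean():.3f} "
            f"eta={s['eta'].mean():.3f} "
            f"a_delta={s['a_delta'].mean():.2f} "
            f"a_gamma={s['a_gamma'].mean():.2f} "
            f"a_rho={s['a_rho'].mean():.2f}")
        return "\n".join(lines)


def _empirical_b_sd(data: _io.Dataset, holdout=None) -> float:
    """Empirical-Bayes scale for the outcome-effect priors.

    Scale of the upper tail (doubled 90th percentile, floored at 1) of the
    per-unit two-group mean differences (positive vs negative observed pCR)
    over probes and genes of the training samples.
    """
    covars = data.covariates
    u = covars["u"].copy()
    if holdout is not None:
        u.loc[list(holdout)] = np.nan
    pos = u == 1
    neg = u == 0
    if pos.sum() < 2 or neg.sum() < 2:
        return 1.0
    diffs = []
    for M in (data.Y.to_numpy(), data.Z.to_numpy()):
        diffs.append(M[:, pos.to_numpy()].mean(axis=1)
                     - M[:, neg.to_numpy()].mean(axis=1))
    diffs = np.abs(np.concatenate(diffs))
    # the slab prior should match the scale of *active* effects, so take the
    # upper tail of the per-unit differences rather than the mostly-null bulk
    scale = 2.0 * float(np.quantile(diffs, 0.90))
    return max(scale, 1.0)


class PcrPredictionModel:
    """Sparse outcome-linked model predicting pathological complete response.

    Parameters
    ----------
    data : io.Dataset
        Outcomes ``u`` may be missing (NaN): those patients' outcomes are
        imputed during sampling and their posterior imputation frequency is
        the predictive probability.
    platform : {"integrated", "expression", "cna"}
        "integrated" uses both platforms with the cross-platform score
        regression; the marginal variants use a single platform.
    holdout : iterable of sample ids, optional
        Patients whose recorded outcome is masked before fitting (test set).
    """

    def __init__(self, data: _io.Dataset, platform: str = "integrated",
                 priors: Priors | None = None, holdout=None):
        if platform not in ("integrated", "expression", "cna"):
            raise ValueError("platform must be integrated|expression|cna")
        self.data = data
        self.platform = platform
        self.holdout = list(holdout) if holdout is not None else None
        priors = priors or Priors()
        if priors.b_sd is None:
            # plug in the data-estimated effect scale
            from dataclasses import replace
            priors = replace(priors,
                             b_sd=_empirical_b_sd(data, holdout=self.holdout))
        self.priors = priors

    def fit(self, n_iter: int = 30000, burn_in: int = 2000, thin: int = 5,
            seed: int = 0, log_every: int = 1000):
        config = McmcConfig(n_iter=n_iter, burn_in=burn_in, thin=thin,
                            seed=seed, mode="prediction",
                            log_every=log_every)
        arrays = ModelArrays.from_dataset(self.data, holdout=self.holdout)
        sampler = GibbsSampler(
            arrays, priors=self.priors, config=config,
            include_y=self.platform in ("integrated", "cna"),
            include_z=self.platform in ("integrated", "expression"),
            couple=self.platform == "integrated",
        )
        draws = sampler.run()
        return PcrPredictionResults(self, draws, arrays)


class PcrPredictionResults:
    """Posterior predictive pCR probabilities and their evaluation."""

    def __init__(self, model: PcrPredictionModel, draws, arrays):
        self.model = model
        self.draws = draws
        self._unobserved = np.isnan(arrays.u)

    @property
    def pcr_probabilities(self) -> pd.Series:
        """Predictive P(pCR = 1) for every patient with an unknown outcome."""
        p = self.draws.predictive_pcr()
        ids = np.asarray(self.draws.sample_ids)
        return pd.Series(p[self._unobserved], index=ids[self._unobserved],
                         name="p_pcr")

    def inclusion_probabilities(self):
        """Posterior inclusion probability per probe (zeta) and gene (xi)."""
        out = {}
        if self.draws.zeta is not None:
            out["zeta"] = pd.Series(self.draws.zeta.mean(axis=0),
                                    index=self.draws.probe_ids)
        if self.draws.xi is not None:
            out["xi"] = pd.Series(self.draws.xi.mean(axis=0),
                                  index=self.draws.gene_ids)
        return out

    def roc(self, true_outcomes: pd.Series):
        """Smoothed ROC of the predictive probabilities against known truth."""
        probs = self.pcr_probabilities
        truth = true_outcomes.loc[probs.index].astype(float)
        pos = probs[truth == 1].to_numpy()
        neg = probs[truth == 0].to_numpy()
        return smoothed_roc(pos, neg)

    def summary(self) -> str:
        probs = self.pcr_probabilities
        incl = self.inclusion_probabilities()
        lines = [
            f"pCR prediction model ({self.model.platform})",
            f"patients with predicted outcome: {len(probs)}   "
            f"retained draws: {self.draws.n_draws}",
            "-" * 64,
        ]
        for sid, p in probs.items():
            lines.append(f"  {sid:<16} P(pCR=1) = {p:.3f}")
        for name, series in incl.items():
            top = series.sort_values(ascending=False).head(3)
            lines.append(f"top {name} inclusions: "
                         + ", ".join(f"{i}={v:.2f}" for i, v in top.items()))
        return "\n".join(lines)
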