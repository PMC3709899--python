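"""Kernel-smoothed ROC curve (Lloyd-Yong style) and AUC.

Instead of the empirical step-function ROC, both score distribution
functions (positive and negative outcome groups) are estimated by
Gaussian-kernel smoothing and the ROC is the composition
ROC(t) = 1 - F_pos(F_neg^{-1}(1 - t)).  For the small test cohorts
typical of clinical prediction this is markedly more stable than the
empirical curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = ["RocCurve", "smoothed_cdf", "smoothed_roc", "cdf_bandwidth"]


@dataclass
class RocCurve:
    grid: np.ndarray        # false positive rates
    tpr: np.ndarray         # true positive rates
    auc: float
    bandwidths: tuple       # (positive group, negative group)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.tpr, **kwargs)
        ax.plot([0, 1], [0, 1], ls=":", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax


def cdf_bandwidth(scores) -> float:
    """Reference-rule bandwidth for kernel *distribution-function* smoothing.

    Distribution functions want a smaller bandwidth than densities: the
    optimal rate is n^(-1/3) rather than Silverman's n^(-1/5), which would
    leave visible bias in the resulting ROC.  The scale is the robust
    minimum of the standard deviation and IQR/1.349.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    sd = scores.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(scores, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        return 0.0
    return 1.3 * scale * n ** (-1.0 / 3.0)


def smoothed_cdf(scores, bandwidth: float):
    """Kernel-smoothed distribution function of a score sample.

    Returns a vectorized callable: the average of integrated Gaussian
    kernels centred at each score.  Monotone non-decreasing with limits
    0 and 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 1:
        raise ValueError("need at least one score")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    def cdf(x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - scores) / bandwidth
        return ndtr(z).mean(axis=-1)

    return cdf


def _invert_cdf(cdf, q, lo, hi, tol=1e-8):
    """Monotone bisection inverse of a smooth CDF (vectorized over q)."""
    q = np.asarray(q, dtype=float)
    lo = np.full(q.shape, lo)
    hi = np.full(q.shape, hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        below = cdf(mid) < q
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


def smoothed_roc(pos_scores, neg_scores, n_grid: int = 512) -> RocCurve:
    """Smoothed ROC and AUC from positive- and negative-group scores."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be non-empty")

    h_pos = cdf_bandwidth(pos)
    h_neg = cdf_bandwidth(neg)
    grid = np.linspace(0.0, 1.0, n_grid)
    if h_pos <= 0 and h_neg <= 0:
        warnings.warn("degenerate constant scores in both groups; "
                      "returning the chance diagonal")
        return RocCurve(grid=grid, tpr=grid.copy(), auc=0.5,
                        bandwidths=(0.0, 0.0))
    # a constant group still needs a positive bandwidth to smooth at all
    fallback = 0.1 * max(h_pos, h_neg, 1e-3)
    h_pos = h_pos if h_pos > 0 else fallback
    h_neg = h_neg if h_neg > 0 else fallback

    f_pos = smoothed_cdf(pos, h_pos)
    f_neg = smoothed_cdf(neg, h_neg)

    all_scores = np.concatenate([pos, neg])
    span = 8.0 * max(h_pos, h_neg) + (all_scores.max() - all_scores.min())
    lo = all_scores.min() - span
    hi = all_scores.max() + span

    inner = grid[1:-1]
    thresholds = _invert_cdf(f_neg, 1.0 - inner, lo, hi)
    tpr = np.empty_like(grid)
    tpr[0] = 0.0
    tpr[-1] = 1.0
    tpr[1:-1] = 1.0 - f_pos(thresholds)
    tpr = np.maximum.accumulate(np.clip(tpr, 0.0, 1.0))
    auc = float(np.trapezoid(tpr, grid))
    return RocCurve(grid=grid, tpr=tpr, auc=auc, bandwidths=(h_pos, h_neg))
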