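"""Bayesian false discovery rate control and the five gene lists.

Rejections are ranked by marginal posterior probability of the event of
interest.  Rejecting the top k genes incurs an expected FDR of
(1/k) * sum of (1 - p) over the k largest probabilities, and the
selection rule keeps the largest k whose expected FDR stays at or below
the chosen level alpha (possibly the empty set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneSelection", "expected_fdr", "select_at_fdr",
           "build_gene_lists", "LIST_LABELS"]

LIST_LABELS = (
    "over+amplified-TN",
    "under+deleted-TN",
    "over-given-aberration-TN",
    "under-given-aberration-TN",
    "positive-interaction",
)


@dataclass
class GeneSelection:
    """FDR-controlled rejection set for one list of interesting genes."""

    list_label: str
    gene_ids: list
    posterior_probs: np.ndarray
    fdr_at_cut: float
    alpha: float

    def __post_init__(self):
        self.posterior_probs = np.asarray(self.posterior_probs, dtype=float)
        if len(self.gene_ids) != len(self.posterior_probs):
            raise ValueError("gene_ids and posterior_probs length mismatch")
        if len(self.posterior_probs) > 1 and np.any(
                np.diff(self.posterior_probs) > 1e-12):
            raise ValueError("genes must be sorted by decreasing probability")

    def __len__(self):
        return len(self.gene_ids)


def expected_fdr(post_probs, n_reject: int) -> float:
    """Posterior expected FDR of rejecting the ``n_reject`` top genes."""
    p = np.sort(np.asarray(post_probs, dtype=float))[::-1]
    if not 1 <= n_reject <= len(p):
        raise ValueError("n_reject must be in [1, len(post_probs)]")
    return float(np.mean(1.0 - p[:n_reject]))


def select_at_fdr(post_probs, alpha: float):
    """Indices of the largest top-k set with expected FDR <= alpha.

    Ties at the boundary are kept together: all genes with probability
    equal to the k-th are included iff the bound still holds with all of
    them, so the selection never depends on input order among ties.
    Returns an integer index array (possibly empty).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(post_probs, dtype=float)
    order = np.argsort(-p, kind="stable")
    ps = p[order]
    cum_fdr = np.cumsum(1.0 - ps) / np.arange(1, len(ps) + 1)
    ok = np.nonzero(cum_fdr <= alpha)[0]
    if len(ok) == 0:
        return np.array([], dtype=int)
    k = ok[-1] + 1
    # extend or shrink across a tie at the boundary
    boundary = ps[k - 1]
    tied = np.nonzero(ps == boundary)[0]
    k_full = tied[-1] + 1
    if cum_fdr[k_full - 1] <= alpha:
        k = k_full
    else:
        k = tied[0]  # drop the whole tied block
    return order[:k]


def gene_cna_state_per_draw(delta_draws, gene_of, n_genes):
    """Majority-vote gene-level differential-CNA state per retained draw.

    For each draw and gene, the sign of the sum of the probe indicators
    delta_b over the probes of the gene; a tie (sum 0) counts as not
    aberrant.  Returns an (n_draws, G) int8 matrix in {-1, 0, +1}.
    """
    delta_draws = np.asarray(delta_draws)
    gene_of = np.asarray(gene_of)
    n_draws = delta_draws.shape[0]
    sums = np.zeros((n_draws, n_genes))
    np.add.at(sums.T, gene_of, delta_draws.T.astype(float))
    counts = np.bincount(gene_of, minlength=n_genes).astype(float)
    # strict majority of probes sharing one sign
    pos = np.zeros((n_draws, n_genes))
    neg = np.zeros((n_draws, n_genes))
    np.add.at(pos.T, gene_of, (delta_draws.T == 1).astype(float))
    np.add.at(neg.T, gene_of, (delta_draws.T == -1).astype(float))
    state = np.zeros((n_draws, n_genes), dtype=np.int8)
    state[pos > counts / 2] = 1
    state[neg > counts / 2] = -1
    return state


def list_event_probabilities(draws, gene_of, n_genes):
    """Per-gene posterior probabilities of the five list events.

    Joint lists: differential expression gamma_g = +-1 together with a
    majority of the gene's probes showing delta_b = +-1 in the same draw.
    Conditional lists: gamma_g = +-1 among the draws where the gene shows a
    (majority-vote) CNA differential at all.  Interaction list: rho_g = +1.
    Returns a dict label -> (G,) probability vector.
    """
    gamma = np.asarray(draws.gamma)
    rho = np.asarray(draws.rho)
    cna = gene_cna_state_per_draw(draws.delta, gene_of, n_genes)
    n_draws = gamma.shape[0]

    probs = {}
    probs[LIST_LABELS[0]] = ((gamma == 1) & (cna == 1)).mean(axis=0)
    probs[LIST_LABELS[1]] = ((gamma == -1) & (cna == -1)).mean(axis=0)
    aberrant = cna != 0
    n_ab = aberrant.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond_over = np.where(
            n_ab > 0, ((gamma == 1) & aberrant).sum(axis=0) / n_ab, 0.0)
        cond_under = np.where(
            n_ab > 0, ((gamma == -1) & aberrant).sum(axis=0) / n_ab, 0.0)
    probs[LIST_LABELS[2]] = cond_over
    probs[LIST_LABELS[3]] = cond_under
    probs[LIST_LABELS[4]] = (rho == 1).mean(axis=0)
    return probs


def build_gene_lists(draws, alpha: float, gene_of, gene_ids) -> list:
    """Construct the five FDR-controlled gene lists from posterior draws."""
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)
    probs = list_event_probabilities(draws, gene_of, n_genes)
    selections = []
    for label in LIST_LABELS:
        p = probs[label]
        idx = select_at_fdr(p, alpha)
        idx = idx[np.argsort(-p[idx], kind="stable")]
        fdr = expected_fdr(p, len(idx)) if len(idx) else 0.0
        selections.append(GeneSelection(
            list_label=label,
            gene_ids=[gene_ids[i] for i in idx],
            posterior_probs=p[idx],
            fdr_at_cut=float(fdr),
            alpha=alpha,
        ))
    return selections
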