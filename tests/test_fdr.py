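import numpy as np
import pytest
from scipy.stats import norm

from bayescnax.fdr import (GeneSelection, LIST_LABELS, build_gene_lists,
                           expected_fdr, gene_cna_state_per_draw,
                           list_event_probabilities, select_at_fdr)
from bayescnax.gibbs import PosteriorDraws


def test_expected_fdr_hand_computation():
    assert np.isclose(expected_fdr([0.9, 0.8, 0.6], 2), 0.15)
    assert expected_fdr(np.ones(5), 3) == 0.0
    with pytest.raises(ValueError):
        expected_fdr([0.5, 0.5], 0)


def test_expected_fdr_matches_exhaustive_topk():
    rng = np.random.default_rng(0)
    p = rng.random(12)
    ps = np.sort(p)[::-1]
    for k in range(1, 13):
        brute = np.mean([1 - ps[i] for i in range(k)])
        assert np.isclose(expected_fdr(p, k), brute)


def test_select_at_fdr_examples():
    idx = select_at_fdr(np.array([0.9, 0.8, 0.6]), alpha=0.15)
    assert sorted(idx.tolist()) == [0, 1]
    # alpha below 1 - max probability: nothing can be rejected
    assert len(select_at_fdr(np.array([0.9, 0.8, 0.6]), alpha=0.05)) == 0
    # alpha near 1: everything rejected
    assert len(select_at_fdr(np.array([0.9, 0.8, 0.6]), alpha=0.999)) == 3


def test_select_at_fdr_equals_brute_force_topk():
    rng = np.random.default_rng(1)
    for trial in range(200):
        n = rng.integers(1, 12)
        p = np.round(rng.random(n), 2)   # rounding creates ties
        alpha = float(rng.uniform(0.02, 0.5))
        got = select_at_fdr(p, alpha)
        order = np.argsort(-p, kind="stable")
        ps = p[order]
        best_k = 0
        for k in range(1, n + 1):
            # a valid cut never splits a tied block
            if k < n and ps[k] == ps[k - 1]:
                continue
            if np.mean(1 - ps[:k]) <= alpha:
                best_k = k
        assert len(got) == best_k
        if best_k:
            assert np.all(np.sort(p[got])[::-1] == ps[:best_k])


def test_select_at_fdr_monotone_in_alpha():
    rng = np.random.default_rng(2)
    p = rng.random(40)
    prev = set()
    for alpha in (0.05, 0.1, 0.2, 0.4, 0.8):
        cur = set(select_at_fdr(p, alpha).tolist())
        assert prev <= cur
        prev = cur


def test_boundary_ties_kept_or_dropped_together():
    p = np.array([0.95, 0.9, 0.9, 0.9, 0.2])
    # k=1: efdr 0.05; k=4: (0.05+0.3)/4 = 0.0875 <= 0.09 -> all ties in
    assert len(select_at_fdr(p, 0.0875)) == 4
    # alpha between efdr(1)=0.05 and efdr(4)=0.0875: tied block dropped
    assert len(select_at_fdr(p, 0.07)) == 1


def _draws(delta, gamma, rho):
    return PosteriorDraws(mode="differential", delta=np.asarray(delta),
                          gamma=np.asarray(gamma), rho=np.asarray(rho))


def test_gene_cna_majority_vote():
    # 2 genes x 2 probes; draws x probes
    delta = np.array([[1, 1, 1, -1],     # gene0 majority +1, gene1 tie -> 0
                      [0, 1, -1, -1],    # gene0 tie -> 0, gene1 majority -1
                      [0, 0, 0, 0]])
    state = gene_cna_state_per_draw(delta, np.array([0, 0, 1, 1]), 2)
    assert state.tolist() == [[1, 0], [0, -1], [0, 0]]


def test_list_probabilities_equal_brute_force_counting():
    rng = np.random.default_rng(3)
    n, B, G = 50, 6, 3
    gene_of = np.array([0, 0, 1, 1, 2, 2])
    d = _draws(rng.choice([-1, 0, 1], size=(n, B)),
               rng.choice([-1, 0, 1], size=(n, G)),
               rng.choice([-1, 0, 1], size=(n, G)))
    probs = list_event_probabilities(d, gene_of, G)
    cna = gene_cna_state_per_draw(d.delta, gene_of, G)
    for g in range(G):
        joint_over = np.mean((d.gamma[:, g] == 1) & (cna[:, g] == 1))
        assert np.isclose(probs[LIST_LABELS[0]][g], joint_over)
        ab = cna[:, g] != 0
        cond = (np.sum((d.gamma[:, g] == 1) & ab) / ab.sum()
                if ab.sum() else 0.0)
        assert np.isclose(probs[LIST_LABELS[2]][g], cond)
        assert np.isclose(probs[LIST_LABELS[4]][g],
                          np.mean(d.rho[:, g] == 1))


def test_all_zero_draws_give_empty_lists():
    d = _draws(np.zeros((20, 4), int), np.zeros((20, 2), int),
               np.zeros((20, 2), int))
    sels = build_gene_lists(d, alpha=0.5, gene_of=np.array([0, 0, 1, 1]),
                            gene_ids=["gA", "gB"])
    assert all(len(s) == 0 for s in sels)
    assert [s.list_label for s in sels] == list(LIST_LABELS)


def test_always_on_gene_has_probability_one():
    n = 30
    delta = np.zeros((n, 4), int)
    delta[:, :2] = 1                    # both probes of gene 0 amplified
    gamma = np.zeros((n, 2), int)
    gamma[:, 0] = 1
    d = _draws(delta, gamma, np.zeros((n, 2), int))
    probs = list_event_probabilities(d, np.array([0, 0, 1, 1]), 2)
    assert probs[LIST_LABELS[0]][0] == 1.0
    sels = build_gene_lists(d, alpha=0.1, gene_of=np.array([0, 0, 1, 1]),
                            gene_ids=["gA", "gB"])
    assert sels[0].gene_ids == ["gA"]
    assert sels[0].fdr_at_cut <= 0.1


def test_gene_selection_validates_ordering():
    with pytest.raises(ValueError, match="decreasing"):
        GeneSelection("positive-interaction", ["a", "b"],
                      np.array([0.2, 0.9]), 0.1, 0.2)


def bayes_two_group_sample(rng, n=400, p_null=0.9, effect=2.0):
    """Conjugate two-group model with closed-form posterior probabilities."""
    is_alt = rng.random(n) < (1 - p_null)
    theta = np.where(is_alt, effect, 0.0)
    y = theta + rng.normal(size=n)
    # P(non-null | y) in closed form
    lik_alt = norm.pdf(y, effect, 1.0)
    lik_null = norm.pdf(y, 0.0, 1.0)
    post = (1 - p_null) * lik_alt / ((1 - p_null) * lik_alt
                                     + p_null * lik_null)
    return post, is_alt


def test_fdr_calibrated_under_generating_model():
    """Realized FDP at alpha=0.10 stays near the nominal level on average."""
    rng = np.random.default_rng(7)
    fdps = []
    for _ in range(50):
        post, is_alt = bayes_two_group_sample(rng)
        idx = select_at_fdr(post, alpha=0.10)
        if len(idx):
            fdps.append(np.mean(~is_alt[idx]))
        else:
            fdps.append(0.0)
    assert np.mean(fdps) <= 0.15
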