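"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning code paths: likelihoods are
computed by explicit enumeration over all internal-node state assignments,
with transition probabilities from scipy's matrix exponential.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg


def enumeration_loglik(tree, tip_state_idx, Q, root_mode="flat"):
    """Log-likelihood by brute-force enumeration.

    Sums, over every assignment of states to internal nodes, the product of
    per-branch transition probabilities, accumulated per root state; then
    applies the root weighting (uniform, or proportional to each root
    state's likelihood share).  Feasible only for a handful of tips and
    states.
    """
    S = Q.shape[0]
    P = {}
    for node in range(tree.n_nodes):
        if tree.parent[node] >= 0:
            t = float(tree.brlen[node])
            if t not in P:
                P[t] = scipy.linalg.expm(Q * t)

    internals = [n for n in range(tree.n_nodes) if tree.children[n]]
    root = tree.root
    like_by_root = np.zeros(S)
    for assignment in itertools.product(range(S), repeat=len(internals)):
        state = dict(zip(internals, assignment))
        for i in range(tree.n_tips):
            state[i] = int(tip_state_idx[i])
        prob = 1.0
        for node in range(tree.n_nodes):
            p = tree.parent[node]
            if p < 0:
                continue
            prob *= P[float(tree.brlen[node])][state[p], state[node]]
            if prob == 0.0:
                break
        like_by_root[state[root]] += prob
    total = like_by_root.sum()
    if total <= 0:
        return -np.inf
    if root_mode == "flat":
        like = total / S
    else:  # fitzjohn: weights proportional to each root state's share
        like = float(like_by_root @ like_by_root) / total
    return float(np.log(like)) if like > 0 else -np.inf


def random_instance(rng, max_tips=5, n_min=1, n_max=5):
    """A random small tree + random rates + random consistent tip data."""
    import karyorate as kr
    from karyorate.likelihood import TipObservation

    n_tips = int(rng.integers(2, max_tips + 1))
    tree = kr.simulate_yule_tree(n_tips, 1.0, rng, height_target=1.0)
    params = kr.RateParameters(*rng.uniform(0.0, 3.0, 8))
    space = kr.build_state_space(n_min, n_max)
    data = {}
    for lab in tree.tip_labels:
        n = int(rng.integers(n_min, n_max + 1))
        ctype = kr.MONOCENTRIC if rng.uniform() < 0.5 else kr.HOLOCENTRIC
        data[lab] = TipObservation(lab, n, ctype)
    Q = kr.build_rate_matrix(params, space)
    return tree, data, Q, space
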