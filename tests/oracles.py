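"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Mk oracle sums the
likelihood over exhaustive ancestral-state assignments, and the alignment
oracle is a memoized three-state recursion over the full alignment lattice.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.linalg import expm


def brute_force_mk(tree, tip_states, model):
    """Exhaustive-enumeration likelihood and marginal posteriors.

    Returns ``(log_likelihood, {node label: posterior vector})``; feasible
    for trees with a handful of leaves only.
    """
    q = model.rate_matrix()
    states = model.states
    k = len(states)
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    kernels = {
        id(n): expm(q * float(n.edge.length or 0.0))
        for n in nodes
        if n.parent_node is not None
    }
    total = 0.0
    marginals = {id(n): np.zeros(k) for n in nodes}
    leaf_choices = {}
    for leaf in tree.leaf_node_iter():
        obs = tip_states[leaf.taxon.label]
        leaf_choices[id(leaf)] = list(range(k)) if obs == "?" else [states.index(obs)]
    leaves = [n for n in nodes if n.is_leaf()]
    for leaf_assign in itertools.product(*(leaf_choices[id(l)] for l in leaves)):
        for internal_assign in itertools.product(range(k), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, internal_assign)}
            assign.update({id(l): s for l, s in zip(leaves, leaf_assign)})
            lik = model.root_prior[assign[id(tree.seed_node)]]
            for n in nodes:
                if n.parent_node is not None:
                    lik *= kernels[id(n)][assign[id(n.parent_node)], assign[id(n)]]
            total += lik
            for n in nodes:
                marginals[id(n)][assign[id(n)]] += lik
    posteriors = {}
    for n in nodes:
        label = n.taxon.label if n.is_leaf() else n.label
        posteriors[label] = marginals[id(n)] / total
    return float(np.log(total)), posteriors


def brute_force_align_score(seq_a, seq_b, matrix, gap_open, gap_extend):
    """Optimal global affine-gap alignment score by three-state recursion.

    Gap of length L costs gap_open + (L - 1) * gap_extend. Memoized over the
    (i, j, previous-move) lattice — independent of the aligner under test.
    """

    def sub(x, y):
        return float(matrix[x, y])

    @lru_cache(maxsize=None)
    def best(i, j, prev):
        if i == len(seq_a) and j == len(seq_b):
            return 0.0
        options = []
        if i < len(seq_a) and j < len(seq_b):
            options.append(sub(seq_a[i], seq_b[j]) + best(i + 1, j + 1, "M"))
        if i < len(seq_a):  # gap in seq_b
            cost = gap_extend if prev == "A" else gap_open
            options.append(-cost + best(i + 1, j, "A"))
        if j < len(seq_b):  # gap in seq_a
            cost = gap_extend if prev == "B" else gap_open
            options.append(-cost + best(i, j + 1, "B"))
        return max(options)

    result = best(0, 0, "M")
    best.cache_clear()
    return result
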