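"""Independent brute-force oracle for the diversity partition.

Recomputes every quantity from first principles with explicit Python
loops over branches and groups — no shared code with the package's
vectorized implementation beyond the tree container's topology arrays.
Used to pin expected values on tiny trees.
"""

from __future__ import annotations

import math


def descendant_leaf_labels(tree, i: int) -> set[str]:
    """Leaf labels under node i, by explicit recursive traversal."""
    if not tree.children[i]:
        return {tree.labels[i]}
    out: set[str] = set()
    for c in tree.children[i]:
        out |= descendant_leaf_labels(tree, c)
    return out


def oracle_partition(tree, group_counts: dict[str, dict[str, float]], weights=None):
    """Full gamma/alpha/beta partition by brute-force summation.

    ``group_counts``: group -> {otu_id -> reads}.  Returns a dict with
    h_gamma, h_alpha, h_beta, per-group entropies, per-branch beta
    terms (by node index), t_bar and turnover.
    """
    groups = list(group_counts)
    G = len(groups)
    if weights is None:
        weights = {g: 1.0 / G for g in groups}
    totals = {g: sum(group_counts[g].values()) for g in groups}

    # within-group frequency of observations descending from each node
    a: dict[int, dict[str, float]] = {}
    for i in range(tree.n_nodes):
        leaves = descendant_leaf_labels(tree, i)
        a[i] = {
            g: sum(group_counts[g].get(l, 0.0) for l in leaves) / totals[g]
            for g in groups
        }
    p = {i: sum(weights[g] * a[i][g] for g in groups) for i in a}
    t_bar = sum(tree.lengths[i] * p[i] for i in range(tree.n_nodes))

    def xlogx(v):
        return v * math.log(v) if v > 0 else 0.0

    h_gamma = -sum(
        tree.lengths[i] / t_bar * xlogx(p[i]) for i in range(tree.n_nodes)
    )
    h_group = {}
    for g in groups:
        h_group[g] = -sum(
            tree.lengths[i] / t_bar * xlogx(a[i][g]) for i in range(tree.n_nodes)
        )
    h_alpha = sum(weights[g] * h_group[g] for g in groups)

    branch_beta = {}
    for i in range(tree.n_nodes):
        term = 0.0
        for g in groups:
            p_ig = weights[g] * a[i][g]
            if p_ig > 0:
                term += p_ig * math.log(p_ig / (p[i] * weights[g]))
        branch_beta[i] = tree.lengths[i] / t_bar * term
    h_beta = sum(branch_beta.values())

    h_g = -sum(xlogx(weights[g]) for g in groups)
    return {
        "h_gamma": h_gamma,
        "h_alpha": h_alpha,
        "h_beta": h_beta,
        "h_group": h_group,
        "branch_beta": branch_beta,
        "t_bar": t_bar,
        "turnover": h_beta / h_g if h_g > 0 else float("nan"),
    }
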