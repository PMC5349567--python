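"""Permutation test for phylogenetic mutual information.

The null hypothesis is that an observation's group label carries no
information about its lineage.  It is simulated by randomly re-assigning
group labels to individual reads while keeping each group's read total
fixed — equivalently, splitting each OTU's pooled count across groups by
a multivariate hypergeometric draw.  The statistic H_beta is recomputed
on every permuted dataset with the same estimator (same group weights)
as the observed value, and the one-sided Monte-Carlo p-value uses the
standard +1 correction:

    p = (1 + #{H_beta_perm >= H_beta_obs}) / (1 + n_permutations)

so p is never 0 and is bounded below by 1/(n_permutations + 1).

Permuting reads rather than whole samples treats every sequence as an
exchangeable observation; a coarser sample-label permutation is offered
for sensitivity analysis (``unit="sample"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedQuantityError, ValidationError
from .grouping import Grouping
from .partition import Weighting, compute_branch_frequencies, partition
from .tree import PhyloTree

__all__ = ["PermutationResult", "permute_observation_labels", "permutation_test"]


@dataclass
class PermutationResult:
    observed_beta: float
    p_value: float
    n_permutations: int
    seed: int | None
    unit: str
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]

    def summary(self) -> dict:
        return {
            "observed_H_beta": self.observed_beta,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "unit": self.unit,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_quantiles": self.null_quantiles,
        }


def permute_observation_labels(
    counts: pd.DataFrame,
    grouping: Grouping,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One random re-assignment of group labels to individual reads.

    Returns pooled OTU-by-group counts whose column totals equal the
    original per-group read totals exactly.  Each OTU's pooled count is
    split across groups by sampling labels without replacement from the
    pooled label multiset (a sequential multivariate-hypergeometric
    scheme).
    """
    if grouping.n_groups < 2:
        raise UndefinedQuantityError("label permutation needs at least two groups")
    rng = np.random.default_rng(rng)
    pooled, group_totals = _pooled_counts(counts, grouping)
    remaining = group_totals.copy()
    out = np.zeros((len(pooled), grouping.n_groups), dtype=np.int64)
    for o, n_o in enumerate(pooled):
        if n_o:
            k = rng.multivariate_hypergeometric(remaining, int(n_o))
            out[o] = k
            remaining -= k
    return pd.DataFrame(out, index=counts.index, columns=list(grouping.groups))


def permutation_test(
    tree: PhyloTree,
    counts: pd.DataFrame,
    grouping: Grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    unit: str = "read",
    weighting: Weighting = "equal",
) -> PermutationResult:
    """Test H_beta against the label-permutation null distribution."""
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if grouping.n_groups < 2:
        raise UndefinedQuantityError("permutation test needs at least two groups")
    part = partition(tree, counts, grouping, weighting=weighting)
    observed = part.h_beta
    rng = np.random.default_rng(seed)
    leaf_counts = part.abundance.group_leaf_counts
    if unit == "read":
        null = _null_beta_reads(
            tree, leaf_counts, grouping, n_permutations, rng, weighting
        )
    elif unit == "sample":
        null = _null_beta_samples(
            tree, counts, grouping, n_permutations, rng, weighting
        )
    else:
        raise ValueError(f"unknown permutation unit {unit!r}")
    n_ge = int((null >= observed - 1e-12).sum())
    p = (1 + n_ge) / (1 + n_permutations)
    qs = np.quantile(null, [0.5, 0.9, 0.95, 0.99])
    return PermutationResult(
        observed_beta=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        unit=unit,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_permutations > 1 else 0.0,
        null_quantiles={
            "q50": float(qs[0]),
            "q90": float(qs[1]),
            "q95": float(qs[2]),
            "q99": float(qs[3]),
        },
    )


# ----------------------------------------------------------------------
# internals
# ----------------------------------------------------------------------

def _pooled_counts(counts: pd.DataFrame, grouping: Grouping):
    grouping.require_samples(counts.columns)
    group_totals = np.array(
        [
            counts[[s for s in counts.columns if grouping.sample_to_group[s] == g]]
            .to_numpy()
            .sum()
            for g in grouping.groups
        ],
        dtype=np.int64,
    )
    pooled = counts.sum(axis=1).to_numpy(np.int64)
    return pooled, group_totals


def _beta_from_group_counts(
    tree: PhyloTree, leaf_counts: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """H_beta for a batch of permuted group-level leaf-count matrices.

    ``leaf_counts``: (B, n_leaves, G).  Fully vectorized; used by the
    read-label null, which may evaluate thousands of permutations.
    """
    B, n_leaves, G = leaf_counts.shape
    totals = leaf_counts.sum(axis=1)                       # (B, G)
    freq = leaf_counts / totals[:, None, :]
    A = tree.leaf_matrix()
    flat = freq.transpose(1, 0, 2).reshape(n_leaves, B * G)
    a = (A @ flat).reshape(tree.n_nodes, B, G)             # node frequencies
    p_joint = a * weights
    p = p_joint.sum(axis=2)                                # (n_nodes, B)
    t_bar = tree.lengths @ p                               # (B,)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(p_joint) - np.log(p)[:, :, None] - np.log(weights)
        terms = np.where(p_joint > 0, p_joint * log_ratio, 0.0).sum(axis=2)
    scaled = (tree.lengths[:, None] * terms).sum(axis=0) / t_bar
    return np.clip(scaled, 0.0, None)


def _null_beta_reads(
    tree: PhyloTree,
    leaf_counts: np.ndarray,
    grouping: Grouping,
    n_perm: int,
    rng: np.random.Generator,
    weighting: Weighting,
) -> np.ndarray:
    """Null H_beta values from read-label permutations.

    Reads are expanded to (leaf, label) pairs once; each permutation
    shuffles the label vector and re-pools, exactly reproducing the
    multivariate-hypergeometric split while staying vectorizable.
    """
    n_leaves, G = leaf_counts.shape
    pair_counts = leaf_counts.astype(np.int64).ravel()     # leaf-major (leaf, group)
    read_pair = np.repeat(np.arange(n_leaves * G), pair_counts)
    read_leaf = (read_pair // G).astype(np.int64)
    read_group = (read_pair % G).astype(np.int8)
    N = read_leaf.size
    group_totals = leaf_counts.sum(axis=0)
    if weighting == "equal":
        weights = grouping.weights
    else:
        weights = group_totals / group_totals.sum()
    out = np.empty(n_perm)
    # chunk so the (chunk, N) label matrix stays modest in memory
    chunk = max(1, min(n_perm, int(2e7 // max(N, 1)) or 1))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        labels = np.tile(read_group, (c, 1))
        labels = rng.permuted(labels, axis=1)
        flat = read_leaf[None, :] * G + labels
        flat += (np.arange(c) * (n_leaves * G))[:, None]
        binned = np.bincount(flat.ravel(), minlength=c * n_leaves * G)
        batch = binned.reshape(c, n_leaves, G).astype(float)
        out[done : done + c] = _beta_from_group_counts(tree, batch, weights)
        done += c
    return out


def _null_beta_samples(
    tree: PhyloTree,
    counts: pd.DataFrame,
    grouping: Grouping,
    n_perm: int,
    rng: np.random.Generator,
    weighting: Weighting,
) -> np.ndarray:
    """Null from permuting whole-sample group labels (coarser unit)."""
    samples = list(counts.columns)
    labels = [grouping.sample_to_group[s] for s in samples]
    out = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(labels))
        mapping = {s: labels[perm[k]] for k, s in enumerate(samples)}
        g = Grouping.from_mapping(mapping, grouping.groups, grouping.weights)
        out[b] = partition(tree, counts, g, weighting=weighting).h_beta
    return out
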