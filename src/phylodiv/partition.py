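"""Phylogenetic Shannon entropy and its gamma/alpha/beta partition.

The diversity of a community observed as reads attached to the leaves of
a rooted tree T is measured by the phylogenetic generalization of
Shannon entropy

    Hp = - sum_i (L_i / T_bar) * p_i * ln p_i

where the sum runs over the branches of T, ``L_i`` is the length of
branch i, ``p_i`` the frequency of observations descending from node i,
and ``T_bar = sum_i L_i p_i`` the abundance-weighted mean root-to-tip
depth.  ``exp(Hp)`` is the number of equally abundant, phylogenetically
independent lineages (branches of a star tree) that would produce the
same entropy — the Hill-number "equivalent lineages" unit.

Splitting observations into groups g with weights w_g gives the additive
partition

    H_gamma = H_alpha + H_beta

with H_alpha the w-weighted mean within-group entropy (computed with the
*pooled* T_bar so the identity is exact) and H_beta the phylogenetic
mutual information between an observation's lineage and its group,

    H_beta = sum_i (L_i / T_bar) * sum_g p_ig * ln( p_ig / (p_i w_g) ),

a sum of per-branch nonnegative terms ``Hp_beta_i`` (each is a scaled
Kullback-Leibler divergence) that localize where between-group structure
sits on the tree.  H_beta is bounded by the grouping entropy
H(G) = -sum_g w_g ln w_g; the ratio ``H_beta / H(G)`` is the *turnover*,
which for two equal-weight groups equals the fraction of observations on
lineages not shared between them.

Group weights default to w_g = 1/G (equal weighting), so groups with
very different sequencing depths contribute equally; read-proportional
weights reproduce the unmodified estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .errors import UndefinedQuantityError, ValidationError
from .grouping import Grouping
from .tree import PhyloTree

__all__ = [
    "BranchAbundance",
    "DiversityPartition",
    "compute_branch_frequencies",
    "branch_frequencies_from_profiles",
    "gamma_entropy",
    "alpha_entropy",
    "beta_mutual_information",
    "turnover",
    "partition",
    "partition_from_profiles",
]

Weighting = Literal["equal", "proportional"]


@dataclass
class BranchAbundance:
    """Per-branch joint and marginal observation frequencies.

    Arrays are in tree preorder (index 0 = root).  ``a`` holds the
    within-group frequencies a_ig (reads descending from node i in group
    g over the group total); ``p_joint`` the joint frequencies
    p_ig = w_g * a_ig; ``p`` the marginals p_i; ``t_bar`` the
    abundance-weighted mean depth used to normalize all entropies.
    """

    tree: PhyloTree
    groups: tuple[str, ...]
    weights: np.ndarray          # (G,)
    group_totals: np.ndarray     # (G,) raw pooled read counts
    a: np.ndarray                # (n_nodes, G)
    p_joint: np.ndarray          # (n_nodes, G)
    p: np.ndarray                # (n_nodes,)
    t_bar: float
    group_leaf_counts: np.ndarray | None = None  # (n_leaves, G) raw counts

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class DiversityPartition:
    """Full gamma/alpha/beta decomposition with per-branch contributions."""

    h_gamma: float
    h_alpha: float
    h_beta: float
    d_gamma: float
    d_alpha: float
    d_beta: float
    group_entropies: dict[str, float]
    group_diversities: dict[str, float]
    h_grouping: float
    turnover: float
    branch_beta: np.ndarray      # (n_nodes,) Hp_beta_i per branch
    abundance: BranchAbundance

    def summary(self) -> dict:
        """JSON-ready scalar summary."""
        return {
            "H_gamma": self.h_gamma,
            "H_alpha": self.h_alpha,
            "H_beta": self.h_beta,
            "D_gamma": self.d_gamma,
            "D_alpha": self.d_alpha,
            "D_beta": self.d_beta,
            "per_group_D": self.group_diversities,
            "per_group_H": self.group_entropies,
            "turnover": self.turnover,
            "H_G": self.h_grouping,
            "n_branches": int(self.abundance.tree.n_nodes - 1),
            "T_bar": self.abundance.t_bar,
        }

    def branch_table(self) -> pd.DataFrame:
        """Per-branch table: lengths, frequencies per group, beta
        contribution and its share of H_beta."""
        ba = self.abundance
        tree = ba.tree
        rows = {
            "node_id": [f"L{i}" for i in range(tree.n_nodes)],
            "lineage_label": [tree.labels[i] or "" for i in range(tree.n_nodes)],
            "L_i": tree.lengths,
            "p_i": ba.p,
        }
        df = pd.DataFrame(rows)
        for k, g in enumerate(ba.groups):
            df[f"p_i_{g}"] = ba.p_joint[:, k]
        df["Hp_beta_i"] = self.branch_beta
        df["contribution_fraction"] = (
            self.branch_beta / self.h_beta if self.h_beta > 0 else np.nan
        )
        return df


# ----------------------------------------------------------------------
# branch frequencies
# ----------------------------------------------------------------------

def _group_leaf_counts(
    tree: PhyloTree, counts: pd.DataFrame, grouping: Grouping
) -> np.ndarray:
    """Pool sample columns within each group onto the tree's leaf order.

    OTUs absent from the tree are a hard error (the analysis is
    undefined for them); tree leaves without counts get frequency 0.
    """
    off_tree = sorted(set(counts.index) - set(tree.leaf_ids))
    if off_tree:
        raise ValidationError(f"OTUs not found on the tree: {off_tree}")
    grouping.require_samples(counts.columns)
    aligned = counts.reindex(tree.leaf_ids, fill_value=0)
    out = np.zeros((tree.n_leaves, grouping.n_groups))
    for k, g in enumerate(grouping.groups):
        cols = [s for s in counts.columns if grouping.sample_to_group[s] == g]
        if not cols:
            raise ValidationError(f"group {g!r} has no samples in the count table")
        out[:, k] = aligned[cols].sum(axis=1).to_numpy()
    return out


def compute_branch_frequencies(
    tree: PhyloTree,
    counts: pd.DataFrame,
    grouping: Grouping,
    *,
    weighting: Weighting = "equal",
    equalize_samples: bool = False,
) -> BranchAbundance:
    """Accumulate read counts onto every branch and normalize.

    Reads of all samples in a group are pooled, normalized to
    within-group frequencies a_ig, then combined with group weights:
    w_g = 1/G under ``weighting="equal"`` (each group contributes
    equally, not proportionally to its read depth) or the group's read
    share under ``"proportional"``.  ``equalize_samples`` additionally
    gives each sample equal weight inside its group (frequencies are
    averaged instead of counts pooled).
    """
    leaf_counts = _group_leaf_counts(tree, counts, grouping)
    totals = leaf_counts.sum(axis=0)
    empty = [g for g, t in zip(grouping.groups, totals) if t == 0]
    if empty:
        raise ValidationError(f"groups with zero reads: {empty}")

    if equalize_samples:
        leaf_freq = np.zeros_like(leaf_counts)
        for k, g in enumerate(grouping.groups):
            cols = [s for s in counts.columns if grouping.sample_to_group[s] == g]
            sub = counts.reindex(tree.leaf_ids, fill_value=0)[cols].to_numpy(float)
            leaf_freq[:, k] = (sub / sub.sum(axis=0)).mean(axis=1)
    else:
        leaf_freq = leaf_counts / totals

    if weighting == "equal":
        weights = grouping.weights
    elif weighting == "proportional":
        weights = totals / totals.sum()
    else:  # pragma: no cover
        raise ValueError(f"unknown weighting {weighting!r}")

    ba = branch_frequencies_from_profiles(
        tree, leaf_freq, weights, groups=grouping.groups, group_totals=totals
    )
    ba.group_leaf_counts = leaf_counts
    return ba


def branch_frequencies_from_profiles(
    tree: PhyloTree,
    leaf_freq: np.ndarray,
    weights: np.ndarray,
    *,
    groups: tuple[str, ...] | None = None,
    group_totals: np.ndarray | None = None,
) -> BranchAbundance:
    """Branch abundances from exact per-group leaf frequency vectors.

    Accepts probability vectors directly (columns sum to 1), which is
    how analytic expectations of the synthetic scenarios are computed.
    """
    leaf_freq = np.atleast_2d(np.asarray(leaf_freq, dtype=float))
    if leaf_freq.shape[0] != tree.n_leaves:
        raise ValidationError("one row per tree leaf required")
    G = leaf_freq.shape[1]
    if not np.allclose(leaf_freq.sum(axis=0), 1.0, atol=1e-8):
        raise ValidationError("each group's leaf frequencies must sum to 1")
    weights = np.asarray(weights, dtype=float)
    a = tree.leaf_matrix() @ leaf_freq            # (n_nodes, G)
    p_joint = a * weights
    p = p_joint.sum(axis=1)
    t_bar = float(tree.lengths @ p)
    if t_bar <= 0:
        raise ValidationError("mean depth T_bar is zero (degenerate tree)")
    if groups is None:
        groups = tuple(f"g{k}" for k in range(G))
    if group_totals is None:
        group_totals = np.full(G, np.nan)
    return BranchAbundance(
        tree=tree,
        groups=tuple(groups),
        weights=weights,
        group_totals=np.asarray(group_totals, dtype=float),
        a=a,
        p_joint=p_joint,
        p=p,
        t_bar=t_bar,
    )


# ----------------------------------------------------------------------
# entropies
# ----------------------------------------------------------------------

def gamma_entropy(ba: BranchAbundance) -> tuple[float, float]:
    """Pooled-community phylogenetic entropy H_gamma and D_gamma = exp(H_gamma)."""
    scale = ba.tree.lengths / ba.t_bar
    h = float(-(scale * xlogy(ba.p, ba.p)).sum())
    return h, float(np.exp(h))


def alpha_entropy(ba: BranchAbundance) -> tuple[float, float, dict[str, float]]:
    """Mean within-group entropy H_alpha, D_alpha, and per-group D_g.

    Per-group entropies use the pooled ``t_bar`` so that
    H_gamma = H_alpha + H_beta holds exactly.
    """
    scale = ba.tree.lengths / ba.t_bar
    h_g = -(scale[:, None] * xlogy(ba.a, ba.a)).sum(axis=0)
    h_alpha = float(ba.weights @ h_g)
    per_group = {g: float(np.exp(h)) for g, h in zip(ba.groups, h_g)}
    return h_alpha, float(np.exp(h_alpha)), per_group


def beta_mutual_information(ba: BranchAbundance) -> tuple[float, np.ndarray]:
    """Phylogenetic mutual information H_beta and per-branch terms.

    Each branch's term is (L_i/T_bar) * p_i * KL(p_ig/p_i || w_g), hence
    nonnegative; tiny negative rounding residues are clipped to zero.
    """
    if ba.n_groups < 2:
        raise UndefinedQuantityError("beta diversity undefined for a single group")
    scale = ba.tree.lengths / ba.t_bar
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(ba.p_joint) - np.log(ba.p)[:, None] - np.log(ba.weights)
        terms = np.where(ba.p_joint > 0, ba.p_joint * log_ratio, 0.0)
    per_branch = scale * terms.sum(axis=1)
    if per_branch.min() < -1e-9:
        raise AssertionError("negative per-branch mutual information term")
    per_branch = np.clip(per_branch, 0.0, None)
    return float(per_branch.sum()), per_branch


def turnover(h_beta: float, grouping: Grouping) -> float:
    """H_beta normalized by its ceiling H(G); lies in [0, 1].

    For two equal-weight groups this is the fraction of observations
    that sit on lineages not shared between the groups.
    """
    h_g = grouping.entropy()
    if h_g <= 0:
        raise UndefinedQuantityError("turnover undefined when H(G) = 0 (one group)")
    return float(h_beta) / h_g


# ----------------------------------------------------------------------
# wrappers
# ----------------------------------------------------------------------

def partition(
    tree: PhyloTree,
    counts: pd.DataFrame,
    grouping: Grouping,
    *,
    weighting: Weighting = "equal",
    equalize_samples: bool = False,
) -> DiversityPartition:
    """Full diversity partition of an OTU table over a rooted tree."""
    ba = compute_branch_frequencies(
        tree, counts, grouping, weighting=weighting, equalize_samples=equalize_samples
    )
    return _partition_from_abundance(ba, grouping)


def partition_from_profiles(
    tree: PhyloTree,
    leaf_freq: np.ndarray,
    grouping: Grouping,
) -> DiversityPartition:
    """Partition computed from exact per-group leaf probabilities
    (the infinite-depth expectation of a synthetic scenario)."""
    ba = branch_frequencies_from_profiles(
        tree, leaf_freq, grouping.weights, groups=grouping.groups
    )
    return _partition_from_abundance(ba, grouping)


def _partition_from_abundance(
    ba: BranchAbundance, grouping: Grouping
) -> DiversityPartition:
    h_gamma, d_gamma = gamma_entropy(ba)
    h_alpha, d_alpha, per_group_d = alpha_entropy(ba)
    if ba.n_groups >= 2:
        h_beta, per_branch = beta_mutual_information(ba)
        tv = turnover(h_beta, grouping)
    else:
        h_beta, per_branch, tv = 0.0, np.zeros(ba.tree.n_nodes), float("nan")
    per_group_h = {g: float(np.log(d)) for g, d in per_group_d.items()}
    return DiversityPartition(
        h_gamma=h_gamma,
        h_alpha=h_alpha,
        h_beta=h_beta,
        d_gamma=d_gamma,
        d_alpha=d_alpha,
        d_beta=float(np.exp(h_beta)),
        group_entropies=per_group_h,
        group_diversities=per_group_d,
        h_grouping=grouping.entropy(),
        turnover=tv,
        branch_beta=per_branch,
        abundance=ba,
    )
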