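"""Downstream community analyses on top of the diversity partition.

Covers the abundance filter, candidate-phyla subsetting, pairwise
sample-turnover distances with PCoA ordination, lineage-level reports
(contribution to beta and per-group observation shares), and export of
tree annotations (branch colour gradient by beta contribution, per-leaf
group-count multibars) in the plain-text dataset format understood by
the iTOL tree viewer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .errors import UndefinedQuantityError, ValidationError
from .grouping import Grouping
from .partition import (
    BranchAbundance,
    DiversityPartition,
    partition,
)
from .tree import PhyloTree

__all__ = [
    "DEFAULT_CANDIDATE_PHYLA",
    "filter_min_count",
    "subset_by_taxa",
    "pairwise_turnover",
    "within_group_mean_turnover",
    "between_group_turnover",
    "PCoAResult",
    "pcoa",
    "lineage_contribution",
    "group_lineage_proportions",
    "lineage_report",
    "export_itol_annotations",
]

#: Candidate phyla / candidate-phyla-radiation rank names used as the
#: default taxonomy subset: bacterial lineages known almost only from
#: sequence data ("microbial dark matter"), including the ultra-small
#: bacteria found in groundwater systems.
DEFAULT_CANDIDATE_PHYLA = (
    "Parcubacteria",
    "Microgenomates",
    "Saccharibacteria",
    "Dependentiae",
    "OP3",
    "OP1",
    "BRC1",
    "WS3",
)


# ----------------------------------------------------------------------
# OTU filters
# ----------------------------------------------------------------------

def filter_min_count(counts: pd.DataFrame, threshold: int = 75) -> pd.DataFrame:
    """Discard OTUs whose total read count across all samples is below
    ``threshold`` (default 75; low-count OTUs are likely artefacts of
    amplicon sequencing error)."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    kept = counts[counts.sum(axis=1) >= threshold]
    if kept.empty:
        raise ValidationError(f"no OTU reaches the minimum total count {threshold}")
    return kept


def subset_by_taxa(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    target_taxa: tuple[str, ...] | list[str] = DEFAULT_CANDIDATE_PHYLA,
) -> pd.DataFrame:
    """Retain OTUs whose lineage string mentions any target taxon.

    Matching is a case-insensitive substring test against each
    semicolon-separated rank name of the OTU's lineage.
    """
    if not target_taxa:
        raise ValidationError("target_taxa must be non-empty")
    targets = [t.lower() for t in target_taxa]

    def hit(otu: str) -> bool:
        if otu not in taxonomy.index:
            return False
        ranks = str(taxonomy.loc[otu, "lineage"]).split(";")
        return any(t in rank.strip().lower() for rank in ranks for t in targets)

    keep = [otu for otu in counts.index if hit(otu)]
    if not keep:
        raise ValidationError(
            f"no OTU matches target taxa {list(target_taxa)}"
        )
    return counts.loc[keep]


# ----------------------------------------------------------------------
# turnover distances and ordination
# ----------------------------------------------------------------------

def pairwise_turnover(tree: PhyloTree, counts: pd.DataFrame) -> DistanceMatrix:
    """Symmetric matrix of pairwise phylogenetic turnover between samples.

    Each pair is treated as a two-group partition with equal weights
    (1/2, 1/2), so the distance does not depend on per-sample read
    depth.  Entries lie in [0, 1]; the diagonal is 0.
    """
    samples = list(counts.columns)
    if len(samples) < 2:
        raise ValidationError("need at least two samples")
    zero = [s for s in samples if counts[s].sum() == 0]
    if zero:
        raise ValidationError(f"samples with zero reads: {zero}")
    off_tree = sorted(set(counts.index) - set(tree.leaf_ids))
    if off_tree:
        raise ValidationError(f"OTUs not found on the tree: {off_tree}")
    aligned = counts.reindex(tree.leaf_ids, fill_value=0).to_numpy(float)
    freq = aligned / aligned.sum(axis=0)
    a = tree.leaf_matrix() @ freq                     # (n_nodes, n_samples)
    L = tree.lengths
    n = len(samples)
    D = np.zeros((n, n))
    ln2 = np.log(2.0)
    for s in range(n):
        for t in range(s + 1, n):
            a1, a2 = a[:, s], a[:, t]
            p = 0.5 * (a1 + a2)
            t_bar = L @ p
            with np.errstate(divide="ignore", invalid="ignore"):
                k1 = np.where(a1 > 0, a1 * (np.log(a1) - np.log(p)), 0.0)
                k2 = np.where(a2 > 0, a2 * (np.log(a2) - np.log(p)), 0.0)
            h_beta = (L * 0.5 * (k1 + k2)).sum() / t_bar
            D[s, t] = D[t, s] = min(max(h_beta / ln2, 0.0), 1.0)
    return DistanceMatrix(D, ids=samples)


def within_group_mean_turnover(
    matrix: DistanceMatrix, grouping: Grouping
) -> pd.Series:
    """Mean off-diagonal turnover among samples of the same group.

    Groups with a single sample have no within-group pair; their mean is
    reported as missing (NaN).
    """
    out = {}
    ids = list(matrix.ids)
    for g in grouping.groups:
        members = [s for s in ids if grouping.sample_to_group.get(s) == g]
        if len(members) < 2:
            out[g] = np.nan
            continue
        vals = [
            matrix[s, t] for i, s in enumerate(members) for t in members[i + 1 :]
        ]
        out[g] = float(np.mean(vals))
    return pd.Series(out, name="mean_turnover")


def between_group_turnover(
    tree: PhyloTree, counts: pd.DataFrame, grouping: Grouping
) -> pd.DataFrame:
    """Turnover for every pair of groups (samples pooled within group,
    equal pair weights); mirrors compartment-vs-compartment contrasts."""
    G = grouping.groups
    out = pd.DataFrame(0.0, index=list(G), columns=list(G))
    for i, g1 in enumerate(G):
        for g2 in G[i + 1 :]:
            sub = grouping.subset((g1, g2))
            cols = [s for s in counts.columns if s in sub.sample_to_group]
            part = partition(tree, counts[cols], sub)
            out.loc[g1, g2] = out.loc[g2, g1] = part.turnover
    return out


@dataclass
class PCoAResult:
    """Classical-scaling ordination of a turnover matrix."""

    coordinates: pd.DataFrame        # samples x axes
    explained: np.ndarray            # fraction of positive inertia per axis
    negative_inertia: float          # |sum negative eigenvalues| / sum |eigenvalues|
    eigenvalues: np.ndarray


def pcoa(matrix: DistanceMatrix, n_axes: int = 3) -> PCoAResult:
    """Principal coordinates analysis of a distance matrix.

    Classical metric scaling: square and double-centre the distances,
    eigendecompose, keep the top positive eigenvalues.  Turnover is not
    guaranteed Euclidean-embeddable; negative eigenvalues are dropped
    and their share of the total inertia reported.
    """
    if n_axes < 1:
        raise ValidationError("n_axes must be >= 1")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(matrix, method="eigh")
    # skbio zero-clips negatives; recover the full spectrum for the inertia report
    d = np.asarray(matrix.data, dtype=float)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    eig = np.linalg.eigvalsh(B)[::-1]
    neg = float(np.abs(eig[eig < 0]).sum())
    tot = float(np.abs(eig).sum())
    n_pos = int((eig > 1e-12).sum())
    if n_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); truncating to {n_pos} axes",
            stacklevel=2,
        )
        n_axes = max(n_pos, 1)
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.columns = [f"PC{k + 1}" for k in range(coords.shape[1])]
    coords.index = list(matrix.ids)
    explained = res.proportion_explained.to_numpy()[:n_axes]
    return PCoAResult(
        coordinates=coords,
        explained=explained,
        negative_inertia=neg / tot if tot > 0 else 0.0,
        eigenvalues=eig,
    )


# ----------------------------------------------------------------------
# lineage reports
# ----------------------------------------------------------------------

def lineage_contribution(part: DiversityPartition, lineage_node: str | int) -> float:
    """Share of H_beta explained by a lineage (a node and all its
    descendant branches)."""
    if part.h_beta <= 0:
        raise UndefinedQuantityError("lineage contribution undefined when H_beta = 0")
    tree = part.abundance.tree
    i = tree.find_node(lineage_node) if isinstance(lineage_node, str) else int(lineage_node)
    sl = tree.subtree_slice(i)
    return float(part.branch_beta[sl].sum() / part.h_beta)


def group_lineage_proportions(
    ba: BranchAbundance, lineage_node: str | int
) -> pd.Series:
    """Per-group share of observations descending from a lineage node
    (the a_ig of its subtending branch)."""
    tree = ba.tree
    i = tree.find_node(lineage_node) if isinstance(lineage_node, str) else int(lineage_node)
    return pd.Series(ba.a[i], index=list(ba.groups), name=tree.node_name(i))


def lineage_report(part: DiversityPartition, top: int | None = None) -> pd.DataFrame:
    """All non-root lineages ranked by their contribution to H_beta,
    with per-group observation proportions."""
    ba = part.abundance
    tree = ba.tree
    rows = []
    for i in range(1, tree.n_nodes):
        sl = tree.subtree_slice(i)
        contrib = (
            float(part.branch_beta[sl].sum() / part.h_beta)
            if part.h_beta > 0
            else np.nan
        )
        row = {
            "lineage": tree.node_name(i),
            "is_leaf": bool(tree.is_leaf[i]),
            "n_leaves": int(tree.leaf_matrix()[i].sum()),
            "contribution_fraction": contrib,
        }
        for k, g in enumerate(ba.groups):
            row[f"prop_{g}"] = float(ba.a[i, k])
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        "contribution_fraction", ascending=False, kind="stable"
    )
    return df.head(top) if top else df


# ----------------------------------------------------------------------
# iTOL export
# ----------------------------------------------------------------------

_GRADIENT_LOW = (255, 255, 0)    # yellow: null contribution
_GRADIENT_HIGH = (139, 0, 0)     # dark red: maximal contribution


def _gradient_hex(value: float, vmax: float) -> str:
    f = 0.0 if vmax <= 0 else min(max(value / vmax, 0.0), 1.0)
    rgb = tuple(
        round(lo + f * (hi - lo)) for lo, hi in zip(_GRADIENT_LOW, _GRADIENT_HIGH)
    )
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def export_itol_annotations(
    tree: PhyloTree, part: DiversityPartition
) -> dict[str, str]:
    """Plain-text iTOL dataset files annotating the analysed tree.

    ``branch_gradient``: a TREE_COLORS dataset colouring every branch
    from yellow (no contribution to the between-group mutual
    information) to dark red (the maximal contribution).
    ``group_multibar``: a DATASET_MULTIBAR with each leaf's pooled read
    counts per group.  Node ids use the deterministic lineage names, so
    they resolve against ``tree.to_newick(name_internal=True)``.
    """
    ba = part.abundance
    vmax = float(part.branch_beta.max())
    lines = [
        "TREE_COLORS",
        "SEPARATOR TAB",
        "DATA",
    ]
    for i in range(1, tree.n_nodes):
        lines.append(
            f"{tree.node_name(i)}\tbranch\t{_gradient_hex(part.branch_beta[i], vmax)}\tnormal\t2"
        )
    gradient = "\n".join(lines) + "\n"

    counts = ba.group_leaf_counts
    if counts is None:
        counts = ba.a[tree.leaf_nodes] * np.nan_to_num(ba.group_totals, nan=1.0)
    field_colors = ["#1f78b4", "#33a02c", "#e31a1c", "#ff7f00", "#6a3d9a"]
    colors = [field_colors[k % len(field_colors)] for k in range(ba.n_groups)]
    lines = [
        "DATASET_MULTIBAR",
        "SEPARATOR TAB",
        "DATASET_LABEL\tgroup read counts",
        "COLOR\t#888888",
        "FIELD_LABELS\t" + "\t".join(ba.groups),
        "FIELD_COLORS\t" + "\t".join(colors),
        "DATA",
    ]
    for j, leaf in enumerate(tree.leaf_nodes):
        vals = "\t".join(f"{counts[j, k]:.6g}" for k in range(ba.n_groups))
        lines.append(f"{tree.node_name(int(leaf))}\t{vals}")
    multibar = "\n".join(lines) + "\n"
    return {"branch_gradient": gradient, "group_multibar": multibar}
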