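"""Synthetic communities with planted phylogenetic structure.

Generates rooted trees, per-group leaf abundance profiles with planted
clade shares, and multinomially sampled read-count tables, so the whole
pipeline is testable end to end against known ground truth.

The ``dwtp`` preset emulates a three-compartment drinking-water
treatment plant: groundwater (GW), granular-activated-carbon filters
(CF) and post-chlorination (CHL), with replicate samples per
compartment.  It plants one clade strongly enriched in the treated
compartments (per-group shares 4% / 68% / 58% of GW / CF / CHL reads)
and one clade found almost only in groundwater (58% / 7% / 10%),
mirroring the kind of compartment-specific "dark matter" lineages such
systems harbour; the remaining abundance sits on a shared background
with identical relative composition in every compartment.  Per-group
read totals are deliberately unequal so the equal-group-weighting
estimator is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import DEFAULT_CANDIDATE_PHYLA
from .errors import ValidationError
from .grouping import Grouping
from .tree import PhyloTree

__all__ = [
    "PlantedClade",
    "SyntheticScenario",
    "simulate_tree",
    "build_profiles",
    "sample_reads",
    "generate_dwtp_preset",
    "DwtpDataset",
]


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def simulate_tree(
    n_leaves: int,
    model: str = "star",
    seed: int | np.random.Generator | None = None,
    *,
    birth_rate: float = 1.0,
    prefix: str = "otu",
) -> PhyloTree:
    """Simulate a rooted tree with ``n_leaves`` leaves.

    ``star``: every leaf attached to the root with unit branch length.
    ``yule``: pure-birth process; between the k-th and (k+1)-th
    speciation all k extant lineages grow by an Exp(k * birth_rate)
    waiting time, a uniformly chosen lineage splits, and a final waiting
    time is added after the last birth so no pendant edge has length 0.
    Deterministic for a given seed.
    """
    if n_leaves < 2:
        raise ValidationError("need at least 2 leaves")
    width = max(3, len(str(n_leaves)))
    names = [f"{prefix}{k + 1:0{width}d}" for k in range(n_leaves)]
    if model == "star":
        return PhyloTree.from_newick("(" + ",".join(f"{x}:1" for x in names) + ");")
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("length", "children", "name")

        def __init__(self):
            self.length = 0.0
            self.children: list[_N] = []
            self.name: str | None = None

    root = _N()
    tips = [_N(), _N()]
    root.children = list(tips)
    while True:
        dt = rng.exponential(1.0 / (birth_rate * len(tips)))
        for t in tips:
            t.length += dt
        if len(tips) == n_leaves:
            break
        k = int(rng.integers(len(tips)))
        parent = tips.pop(k)
        kids = [_N(), _N()]
        parent.children = kids
        tips.extend(kids)
    for name, t in zip(names, tips):
        t.name = name

    def nwk(node: _N) -> str:
        if node.children:
            inner = ",".join(nwk(c) for c in node.children)
            s = f"({inner})"
        else:
            s = node.name  # type: ignore[assignment]
        return s if node is root else f"{s}:{node.length:.10g}"

    return PhyloTree.from_newick(nwk(root) + ";")


# ----------------------------------------------------------------------
# scenarios and profiles
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedClade:
    """A named set of leaves with a fixed abundance share per group."""

    label: str
    leaves: tuple[str, ...]
    shares: tuple[float, ...]    # one share per group, in group order


@dataclass(frozen=True)
class SyntheticScenario:
    """A tree plus planted per-group clade shares and sampling design.

    Leaves not claimed by any planted clade form the shared background;
    each group spreads its remaining abundance mass uniformly over them,
    so the background has identical relative composition in every group.
    """

    tree: PhyloTree
    groups: tuple[str, ...]
    clades: tuple[PlantedClade, ...] = ()
    samples_per_group: int = 4
    depth: int = 10_000
    group_depth_factors: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.samples_per_group < 1 or self.depth < 1:
            raise ValidationError("samples_per_group and depth must be >= 1")
        claimed: set[str] = set()
        leaf_set = set(self.tree.leaf_ids)
        for c in self.clades:
            if len(c.shares) != len(self.groups):
                raise ValidationError(f"clade {c.label}: one share per group required")
            if any(s < 0 for s in c.shares):
                raise ValidationError(f"clade {c.label}: negative share")
            bad = set(c.leaves) - leaf_set
            if bad:
                raise ValidationError(f"clade {c.label}: leaves not on tree: {sorted(bad)}")
            if claimed & set(c.leaves):
                raise ValidationError("clades must claim disjoint leaf sets")
            claimed |= set(c.leaves)
        for k, g in enumerate(self.groups):
            total = sum(c.shares[k] for c in self.clades)
            if total > 1 + 1e-12:
                raise ValidationError(f"group {g}: clade shares sum to {total} > 1")
            if total < 1 - 1e-12 and len(claimed) == len(leaf_set):
                raise ValidationError(
                    f"group {g}: shares sum to {total} < 1 but no shared leaf remains"
                )

    @property
    def shared_leaves(self) -> tuple[str, ...]:
        claimed = {l for c in self.clades for l in c.leaves}
        return tuple(l for l in self.tree.leaf_ids if l not in claimed)


def build_profiles(scenario: SyntheticScenario) -> pd.DataFrame:
    """Exact per-group leaf probability vectors (leaves x groups).

    Within a planted clade the clade's share is split equally among its
    leaves; the leftover mass is split equally among shared leaves.
    """
    tree = scenario.tree
    out = pd.DataFrame(
        0.0, index=list(tree.leaf_ids), columns=list(scenario.groups)
    )
    shared = scenario.shared_leaves
    for k, g in enumerate(scenario.groups):
        used = 0.0
        for c in scenario.clades:
            if c.leaves:
                out.loc[list(c.leaves), g] = c.shares[k] / len(c.leaves)
                used += c.shares[k]
        rest = 1.0 - used
        if shared:
            out.loc[list(shared), g] = rest / len(shared)
    return out


def sample_reads(
    profiles: pd.DataFrame,
    samples_per_group: int,
    depth: int,
    seed: int | np.random.Generator | None = None,
    *,
    group_depth_factors: dict[str, float] | None = None,
    overdispersion: float = 0.0,
) -> tuple[pd.DataFrame, Grouping]:
    """Draw multinomial read counts for every replicate sample.

    Each sample of group g draws ``depth`` (times any per-group depth
    factor) reads from g's leaf probability vector.  ``overdispersion``
    > 0 switches to Dirichlet-multinomial sampling with concentration
    1/overdispersion, for stress-testing calibration under extra
    between-sample variance.  Reproducible for a given seed.
    """
    if depth < 1 or samples_per_group < 1:
        raise ValidationError("depth and samples_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    mapping: dict[str, str] = {}
    for g in profiles.columns:
        p = profiles[g].to_numpy(float)
        factor = (group_depth_factors or {}).get(g, 1.0)
        n = max(1, int(round(depth * factor)))
        for r in range(samples_per_group):
            if overdispersion > 0:
                conc = p * (1.0 / overdispersion)
                conc = np.where(conc > 0, conc, 1e-12)
                p_r = rng.dirichlet(conc)
            else:
                p_r = p
            sample = f"{g}_r{r + 1}"
            columns[sample] = rng.multinomial(n, p_r)
            mapping[sample] = g
    counts = pd.DataFrame(columns, index=profiles.index)
    counts.index.name = "otu_id"
    grouping = Grouping.from_mapping(mapping, tuple(profiles.columns))
    return counts, grouping


# ----------------------------------------------------------------------
# drinking-water treatment plant preset
# ----------------------------------------------------------------------

#: Planted per-group shares of the treated-water-enriched clade (GW, CF, CHL).
DWTP_TREATED_SHARES = (0.04, 0.68, 0.58)
#: Planted per-group shares of the groundwater-typical clade (GW, CF, CHL).
DWTP_GROUNDWATER_SHARES = (0.58, 0.07, 0.10)

_DWTP_GROUPS = ("GW", "CF", "CHL")
_N_TREATED, _N_GW, _N_SHARED = 12, 10, 18


@dataclass
class DwtpDataset:
    """A complete synthetic dataset plus its planted ground truth."""

    tree: PhyloTree
    counts: pd.DataFrame
    grouping: Grouping
    taxonomy: pd.DataFrame
    scenario: SyntheticScenario
    truth: dict = field(default_factory=dict)


def _dwtp_tree() -> PhyloTree:
    t = [f"otuT{k + 1:02d}" for k in range(_N_TREATED)]
    g = [f"otuG{k + 1:02d}" for k in range(_N_GW)]
    s = [f"otuS{k + 1:02d}" for k in range(_N_SHARED)]
    nwk = (
        "(({0})L1372:1,({1})L420:1,({2})SHARED:1);".format(
            ",".join(f"{x}:1" for x in t),
            ",".join(f"{x}:1" for x in g),
            ",".join(f"{x}:1" for x in s),
        )
    )
    return PhyloTree.from_newick(nwk)


def _dwtp_taxonomy(tree: PhyloTree, rng: np.random.Generator) -> pd.DataFrame:
    gw_phyla = ("Dependentiae (TM6)", "OP3", "OP1", "BRC1", "WS3")
    rows = []
    for leaf in tree.leaf_ids:
        if leaf.startswith("otuT"):
            lineage = "Bacteria;Parcubacteria (OD1);unclassified"
        elif leaf.startswith("otuG"):
            phylum = gw_phyla[int(leaf[4:]) % len(gw_phyla)]
            lineage = f"Bacteria;{phylum};unclassified"
        else:
            k = int(leaf[4:])
            if k % 3 == 0:
                lineage = "Bacteria;Microgenomates (OP11);unclassified"
            elif k % 3 == 1:
                lineage = "Bacteria;Saccharibacteria (TM7);unclassified"
            else:
                lineage = "Bacteria;Proteobacteria;Gammaproteobacteria"
        conf = float(np.round(0.8 + 0.2 * rng.random(), 3))
        rows.append((leaf, lineage, conf))
    return pd.DataFrame(
        rows, columns=["otu_id", "lineage", "confidence"]
    ).set_index("otu_id")


def generate_dwtp_preset(
    seed: int | None = None,
    *,
    samples_per_group: int = 4,
    depth: int = 10_000,
) -> DwtpDataset:
    """Three-compartment preset with planted enriched/exclusive clades.

    Groups GW, CF, CHL with ``samples_per_group`` replicates each.  Read
    depths are unequal across groups (GW sampled 3x deeper) so the
    equal-weighting estimator has something to correct for.
    """
    rng = np.random.default_rng(seed)
    tree = _dwtp_tree()
    treated = tuple(l for l in tree.leaf_ids if l.startswith("otuT"))
    ground = tuple(l for l in tree.leaf_ids if l.startswith("otuG"))
    scenario = SyntheticScenario(
        tree=tree,
        groups=_DWTP_GROUPS,
        clades=(
            PlantedClade("L1372", treated, DWTP_TREATED_SHARES),
            PlantedClade("L420", ground, DWTP_GROUNDWATER_SHARES),
        ),
        samples_per_group=samples_per_group,
        depth=depth,
    )
    profiles = build_profiles(scenario)
    depth_factors = {"GW": 3.0, "CF": 1.0, "CHL": 1.0}
    counts, grouping = sample_reads(
        profiles,
        samples_per_group,
        depth,
        rng,
        group_depth_factors=depth_factors,
    )
    taxonomy = _dwtp_taxonomy(tree, rng)
    truth = {
        "groups": list(_DWTP_GROUPS),
        "planted_clades": {
            "L1372": {"shares": list(DWTP_TREATED_SHARES), "n_leaves": _N_TREATED},
            "L420": {"shares": list(DWTP_GROUNDWATER_SHARES), "n_leaves": _N_GW},
        },
        "n_shared_leaves": _N_SHARED,
        "samples_per_group": samples_per_group,
        "depth": depth,
        "group_depth_factors": depth_factors,
        "seed": seed,
    }
    return DwtpDataset(tree, counts, grouping, taxonomy, scenario, truth)
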