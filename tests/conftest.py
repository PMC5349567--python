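import numpy as np
import pandas as pd
import pytest

import phylodiv as pv


@pytest.fixture
def star4():
    return pv.parse_tree("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def caterpillar():
    return pv.parse_tree("((A:1,B:1)N:1,C:2);")


@pytest.fixture
def two_leaf():
    return pv.parse_tree("(A:1,B:1);")


def _random_instance(seed: int, max_leaves: int = 24):
    """A random (tree, counts, grouping) problem instance."""
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(4, max_leaves + 1))
    model = "star" if rng.random() < 0.3 else "yule"
    tree = pv.simulate_tree(n_leaves, model, rng)
    n_groups = int(rng.integers(2, 5))
    samples = []
    mapping = {}
    cols = {}
    for g in range(n_groups):
        for r in range(int(rng.integers(1, 3))):
            s = f"g{g}_s{r}"
            mapping[s] = f"g{g}"
            # random sparse counts; ensure the sample is non-empty
            c = rng.integers(0, 50, size=n_leaves)
            if c.sum() == 0:
                c[rng.integers(n_leaves)] = 1
            cols[s] = c
            samples.append(s)
    counts = pd.DataFrame(cols, index=tree.leaf_ids)
    grouping = pv.Grouping.from_mapping(mapping)
    return tree, counts, grouping


@pytest.fixture
def random_instance():
    """Factory fixture: seed -> random (tree, counts, grouping)."""
    return _random_instance


def make_two_group_star(x: float, depth_per_group: int = 1000):
    """Star tree with a planted unshared fraction x between two groups.

    Five group-exclusive leaves per group carry fraction x of each
    group's reads; five shared leaves carry the rest at identical
    frequencies in both groups.
    """
    shared = [f"S{i}" for i in range(5)]
    e1 = [f"E{i}" for i in range(5)]
    e2 = [f"F{i}" for i in range(5)]
    leaves = shared + e1 + e2
    tree = pv.parse_tree("(" + ",".join(f"{l}:1" for l in leaves) + ");")
    excl = round(depth_per_group * x / 5)
    shar = (depth_per_group - 5 * excl) // 5
    assert 5 * (excl + shar) == depth_per_group, "pick x so counts are integral"
    c1 = {l: shar for l in shared} | {l: excl for l in e1}
    c2 = {l: shar for l in shared} | {l: excl for l in e2}
    counts = pd.DataFrame(
        {"s1": [c1.get(l, 0) for l in leaves], "s2": [c2.get(l, 0) for l in leaves]},
        index=leaves,
    )
    grouping = pv.Grouping.from_mapping({"s1": "g1", "s2": "g2"})
    return tree, counts, grouping
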