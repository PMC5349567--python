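import numpy as np
import pandas as pd
import pytest

import phylodiv as pv
from phylodiv.errors import UndefinedQuantityError, ValidationError

from oracles import oracle_partition


@pytest.fixture
def taxonomy():
    rows = [
        ("o1", "Bacteria;Parcubacteria (OD1);unclassified", 0.95),
        ("o2", "Bacteria;Proteobacteria;Gamma", 0.99),
        ("o3", "Bacteria;Saccharibacteria (TM7);x", 0.9),
        ("o4", "Bacteria;Microgenomates (OP11);y", 0.85),
        ("o5", "Bacteria;Firmicutes;Bacilli", 0.97),
    ]
    return pd.DataFrame(rows, columns=["otu_id", "lineage", "confidence"]).set_index("otu_id")


class TestFilterMinCount:
    def test_boundary_at_threshold(self):
        counts = pd.DataFrame({"s1": [40, 40], "s2": [34, 35]}, index=["low", "ok"])
        kept = pv.filter_min_count(counts, 75)
        assert list(kept.index) == ["ok"]  # total 74 removed, 75 retained

    def test_threshold_zero_identity(self):
        counts = pd.DataFrame({"s1": [1, 2, 3]}, index=list("abc"))
        pd.testing.assert_frame_equal(pv.filter_min_count(counts, 0), counts)

    def test_mixed_totals(self):
        counts = pd.DataFrame({"s1": [10, 75, 1000]}, index=list("abc"))
        assert len(pv.filter_min_count(counts, 75)) == 2

    def test_all_removed_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            pv.filter_min_count(counts, 10)


class TestSubsetByTaxa:
    def test_default_candidate_phyla(self, taxonomy):
        counts = pd.DataFrame({"s1": [1, 1, 1, 1, 1]}, index=[f"o{i}" for i in range(1, 6)])
        kept = pv.subset_by_taxa(counts, taxonomy)
        assert list(kept.index) == ["o1", "o3", "o4"]

    def test_explicit_target(self, taxonomy):
        counts = pd.DataFrame({"s1": [1, 1]}, index=["o1", "o2"])
        kept = pv.subset_by_taxa(counts, taxonomy, ["parcubacteria"])
        assert list(kept.index) == ["o1"]

    def test_no_match_rejected(self, taxonomy):
        counts = pd.DataFrame({"s1": [1]}, index=["o2"])
        with pytest.raises(ValidationError, match="no OTU matches"):
            pv.subset_by_taxa(counts, taxonomy, ["Parcubacteria"])

    def test_commutes_with_min_count_filter(self, taxonomy):
        """Both filters are row predicates on the same table, so the
        order does not change the surviving OTU set (totals are always
        taken over all samples of the input table)."""
        counts = pd.DataFrame(
            {"s1": [100, 100, 10, 80, 100]}, index=[f"o{i}" for i in range(1, 6)]
        )
        a = pv.subset_by_taxa(pv.filter_min_count(counts, 75), taxonomy)
        b = pv.filter_min_count(pv.subset_by_taxa(counts, taxonomy), 75)
        pd.testing.assert_frame_equal(a, b)


class TestPairwiseTurnover:
    def test_identical_and_disjoint_pairs(self):
        tree = pv.parse_tree("(A:1,B:1,C:1,D:1);")
        counts = pd.DataFrame(
            {"s1": [5, 5, 0, 0], "s2": [10, 10, 0, 0], "s3": [0, 0, 7, 7]},
            index=list("ABCD"),
        )
        dm = pv.pairwise_turnover(tree, counts)
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)  # same composition
        assert dm["s1", "s3"] == pytest.approx(1.0, abs=1e-12)  # disjoint

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_zero_diagonal_bounds(self, seed, random_instance):
        tree, counts, _ = random_instance(seed)
        dm = pv.pairwise_turnover(tree, counts)
        d = dm.data
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1

    def test_depth_invariance(self, random_instance):
        tree, counts, _ = random_instance(2)
        scaled = counts.copy()
        scaled[scaled.columns[0]] *= 100
        d1 = pv.pairwise_turnover(tree, counts).data
        d2 = pv.pairwise_turnover(tree, scaled).data
        assert np.allclose(d1, d2, atol=1e-12)

    def test_zero_read_sample_rejected(self):
        tree = pv.parse_tree("(A:1,B:1);")
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 0]}, index=["A", "B"])
        with pytest.raises(ValidationError):
            pv.pairwise_turnover(tree, counts)


class TestWithinGroupMeanTurnover:
    def test_identical_replicates_zero(self):
        tree = pv.parse_tree("(A:1,B:1);")
        counts = pd.DataFrame({"s1": [3, 1], "s2": [3, 1], "s3": [1, 3]}, index=["A", "B"])
        g = pv.Grouping.from_mapping({"s1": "a", "s2": "a", "s3": "b"})
        means = pv.within_group_mean_turnover(pv.pairwise_turnover(tree, counts), g)
        assert means["a"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(means["b"])  # singleton group: undefined

    def test_two_samples_mean_is_their_turnover(self):
        tree = pv.parse_tree("(A:1,B:1,C:1);")
        counts = pd.DataFrame({"s1": [8, 2, 0], "s2": [6, 4, 0]}, index=list("ABC"))
        g = pv.Grouping.from_mapping({"s1": "a", "s2": "a"})
        dm = pv.pairwise_turnover(tree, counts)
        means = pv.within_group_mean_turnover(dm, g)
        assert means["a"] == pytest.approx(dm["s1", "s2"])

    def test_overdispersion_raises_within_group_turnover(self):
        """Dirichlet-multinomial replicates are more variable, so the
        within-group mean turnover exceeds the pure-multinomial one."""
        tree = pv.simulate_tree(12, "star")
        profiles = pd.DataFrame(
            {"g1": np.full(12, 1 / 12)}, index=tree.leaf_ids
        )
        tight, _ = pv.sample_reads(profiles, 4, 2000, 0)
        loose, _ = pv.sample_reads(profiles, 4, 2000, 0, overdispersion=0.05)
        g = pv.Grouping.from_mapping({s: "g1" for s in tight.columns})
        m_tight = pv.within_group_mean_turnover(pv.pairwise_turnover(tree, tight), g)
        m_loose = pv.within_group_mean_turnover(pv.pairwise_turnover(tree, loose), g)
        assert m_loose["g1"] > m_tight["g1"]


class TestBetweenGroupTurnover:
    def test_preset_structure(self):
        data = pv.generate_dwtp_preset(5, samples_per_group=2, depth=2000)
        bt = pv.between_group_turnover(data.tree, data.counts, data.grouping)
        assert np.allclose(bt.values, bt.values.T)
        assert np.all(np.diag(bt.values) == 0)
        # CF and CHL share most composition; both differ strongly from GW
        assert bt.loc["CF", "CHL"] < bt.loc["GW", "CF"]
        assert bt.loc["CF", "CHL"] < bt.loc["GW", "CHL"]


class TestPCoA:
    def test_equilateral_triangle(self):
        from skbio.stats.distance import DistanceMatrix

        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = pv.pcoa(dm, n_axes=2)
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.linalg.norm(coords[i] - coords[j])
                assert d == pytest.approx(1.0, abs=1e-9)

    def test_planted_planar_configuration_recovered(self):
        from scipy.spatial.distance import squareform, pdist
        from skbio.stats.distance import DistanceMatrix

        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.9], [-0.5, 0.4]])
        D = squareform(pdist(pts))
        res = pv.pcoa(DistanceMatrix(D, ids=list("abcd")), n_axes=2)
        coords = res.coordinates.to_numpy()
        rec = squareform(pdist(coords))
        assert np.allclose(rec, D, atol=1e-9)
        assert res.negative_inertia == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_samples_coincide(self):
        tree = pv.parse_tree("(A:1,B:1,C:1);")
        counts = pd.DataFrame(
            {"s1": [4, 2, 0], "s2": [4, 2, 0], "s3": [0, 1, 5]}, index=list("ABC")
        )
        res = pv.pcoa(pv.pairwise_turnover(tree, counts), n_axes=2)
        c = res.coordinates
        assert np.allclose(c.loc["s1"], c.loc["s2"], atol=1e-9)

    def test_excess_axes_truncated_with_warning(self):
        from skbio.stats.distance import DistanceMatrix

        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        with pytest.warns(UserWarning, match="truncating"):
            res = pv.pcoa(dm, n_axes=5)
        assert res.coordinates.shape[1] == 2


class TestLineageReports:
    def test_root_contribution_is_one(self):
        data = pv.generate_dwtp_preset(2, samples_per_group=2, depth=1000)
        part = pv.partition(data.tree, data.counts, data.grouping)
        assert pv.lineage_contribution(part, "L0") == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_cover_sums_to_one(self):
        data = pv.generate_dwtp_preset(4, samples_per_group=2, depth=1000)
        part = pv.partition(data.tree, data.counts, data.grouping)
        total = sum(
            pv.lineage_contribution(part, name)
            for name in ("L1372", "L420", "SHARED")
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_private_branch_matches_bruteforce(self):
        tree = pv.parse_tree("((A:1,B:1)PRIV:1,C:1,D:1);")
        counts = pd.DataFrame(
            {"s1": [10, 10, 20, 0], "s2": [0, 0, 20, 20]}, index=list("ABCD")
        )
        g = pv.Grouping.from_mapping({"s1": "g1", "s2": "g2"})
        part = pv.partition(tree, counts, g)
        oracle = oracle_partition(
            tree,
            {"g1": {"A": 10, "B": 10, "C": 20}, "g2": {"C": 20, "D": 20}},
        )
        i = tree.find_node("PRIV")
        sl = tree.subtree_slice(i)
        expected = sum(oracle["branch_beta"][j] for j in range(sl.start, sl.stop))
        got = pv.lineage_contribution(part, "PRIV") * part.h_beta
        assert got == pytest.approx(expected, abs=1e-12)
        assert got > 0

    def test_identical_conditional_frequencies_contribute_zero(self):
        tree = pv.parse_tree("((A:1,B:1)SAME:1,C:1,D:1);")
        counts = pd.DataFrame(
            {"s1": [10, 10, 30, 0], "s2": [5, 5, 0, 15]}, index=list("ABCD")
        )
        g = pv.Grouping.from_mapping({"s1": "g1", "s2": "g2"})
        part = pv.partition(tree, counts, g)
        assert pv.lineage_contribution(part, "SAME") == pytest.approx(0.0, abs=1e-12)

    def test_contribution_undefined_without_beta(self):
        tree = pv.parse_tree("(A:1,B:1);")
        counts = pd.DataFrame({"s1": [1, 1], "s2": [1, 1]}, index=["A", "B"])
        g = pv.Grouping.from_mapping({"s1": "a", "s2": "b"})
        part = pv.partition(tree, counts, g)
        with pytest.raises(UndefinedQuantityError):
            pv.lineage_contribution(part, "L0")

    def test_group_proportions_root_and_absent(self):
        data = pv.generate_dwtp_preset(6, samples_per_group=2, depth=1000)
        part = pv.partition(data.tree, data.counts, data.grouping)
        root = pv.group_lineage_proportions(part.abundance, "L0")
        assert np.allclose(root.to_numpy(), 1.0)
        # a leaf with zero reads in some group gives 0 for that group
        leaf_props = pv.group_lineage_proportions(part.abundance, data.tree.leaf_ids[0])
        assert np.all(leaf_props.to_numpy() >= 0)

    def test_lineage_report_ranks_planted_clade_first(self):
        data = pv.generate_dwtp_preset(7)
        part = pv.partition(data.tree, data.counts, data.grouping)
        rep = pv.lineage_report(part)
        assert rep.iloc[0]["lineage"] == "L1372"


class TestItolExport:
    def test_gradient_endpoints_and_ids(self):
        data = pv.generate_dwtp_preset(8, samples_per_group=2, depth=1000)
        part = pv.partition(data.tree, data.counts, data.grouping)
        ann = pv.export_itol_annotations(data.tree, part)
        grad = ann["branch_gradient"]
        assert grad.startswith("TREE_COLORS")
        lines = [l for l in grad.splitlines() if "\tbranch\t" in l]
        assert len(lines) == data.tree.n_nodes - 1
        # zero-contribution branches are yellow; the max is dark red
        zero_ids = [
            data.tree.node_name(i)
            for i in range(1, data.tree.n_nodes)
            if part.branch_beta[i] == 0
        ]
        imax = int(np.argmax(part.branch_beta))
        by_id = {l.split("\t")[0]: l.split("\t")[2] for l in lines}
        if zero_ids:
            assert by_id[zero_ids[0]] == "#ffff00"
        assert by_id[data.tree.node_name(imax)] == "#8b0000"
        # every annotated id resolves against the tree
        for node_id in by_id:
            data.tree.find_node(node_id)

    def test_multibar_rows_per_leaf(self):
        data = pv.generate_dwtp_preset(9, samples_per_group=2, depth=500)
        part = pv.partition(data.tree, data.counts, data.grouping)
        bar = pv.export_itol_annotations(data.tree, part)["group_multibar"]
        body = bar.split("DATA\n", 1)[1].strip().splitlines()
        assert len(body) == data.tree.n_leaves
        first = body[0].split("\t")
        assert len(first) == 1 + data.grouping.n_groups
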