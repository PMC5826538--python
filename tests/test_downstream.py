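"""Hotspot/control selection, tree post-processing and cluster purity."""

import numpy as np
import pytest

from idscore import (
    Clustering,
    cluster_purity,
    cut_tree,
    hotspot_positions,
    least_gapped_positions,
    make_ultrametric_binary,
    midpoint_root,
    purity_curve,
    tree_from_newick,
    tree_height,
)
from conftest import make_alignment


def depths(tree):
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {l.taxon.label: l.root_distance for l in tree.leaf_node_iter()}


class TestHotspots:
    def test_one_family_suffices_at_small_f(self):
        # F=5: ceil(0.10 * 5) = 1 qualifying family selects the position
        ids = np.zeros((5, 3))
        ids[2, 1] = 0.15
        assert hotspot_positions(ids) == [2]

    def test_all_zero_scores_select_nothing(self):
        assert hotspot_positions(np.zeros((5, 4))) == []

    def test_zero_cut_zero_fraction_selects_everything(self):
        ids = np.random.default_rng(0).random((4, 7))
        assert hotspot_positions(ids, score_cut=0.0, family_fraction=0.0) == list(
            range(1, 8)
        )

    def test_floor_rounding_flag(self):
        ids = np.zeros((5, 2))
        ids[0, 0] = 0.5
        # floor(0.10*5) = 0: every position qualifies
        assert hotspot_positions(ids, rounding="floor") == [1, 2]


class TestLeastGapped:
    def test_fewest_gaps_selected(self):
        aln, _ = make_alignment(
            {"f": ["AC-D", "A--D", "AC-D"]}
        )  # gap counts (0, 1, 3, 0)
        assert least_gapped_positions(aln, 2) == [1, 4]

    def test_k_equals_n_selects_all(self):
        aln, _ = make_alignment({"f": ["ACD", "ACD"]})
        assert least_gapped_positions(aln, 3) == [1, 2, 3]

    def test_ties_break_toward_lower_index(self):
        aln, _ = make_alignment({"f": ["---", "AAA"]})  # gap counts (1, 1, 1)
        assert least_gapped_positions(aln, 2) == [1, 2]

    def test_k_out_of_range_is_an_error(self):
        aln, _ = make_alignment({"f": ["ACD", "ACD"]})
        with pytest.raises(ValueError):
            least_gapped_positions(aln, 4)


class TestTreeOps:
    def test_midpoint_balances_the_longest_path(self):
        t = midpoint_root(tree_from_newick("(A:1,B:3);"))
        assert depths(t) == {"A": 2.0, "B": 2.0}

    def test_midpoint_is_idempotent(self):
        t1 = midpoint_root(tree_from_newick("((A:1,B:1):1,C:2);"))
        t2 = midpoint_root(t1)
        assert depths(t1) == depths(t2)

    def test_star_tree_roots_at_the_center(self):
        t = midpoint_root(tree_from_newick("(A:2,B:2,C:2);"))
        assert depths(t) == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_zero_length_tree_warns_and_returns(self, caplog):
        t = tree_from_newick("(A:0,B:0);")
        with caplog.at_level("WARNING"):
            midpoint_root(t)
        assert "zero-length" in caplog.text

    def test_terminal_branches_extended_to_max_depth(self):
        t = make_ultrametric_binary(tree_from_newick("((A:1,B:4):1,C:2);"))
        assert set(depths(t).values()) == {5.0}

    def test_ultrametric_binary_is_idempotent(self):
        t1 = make_ultrametric_binary(tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        t2 = make_ultrametric_binary(t1)
        assert depths(t1) == depths(t2)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_polytomy_resolution_preserves_depths_and_binarizes(self):
        t = make_ultrametric_binary(tree_from_newick("(A:2,B:5,C:3);"))
        assert set(depths(t).values()) == {5.0}
        for node in t.preorder_internal_node_iter():
            assert len(node.child_nodes()) == 2

    def test_leaf_set_preserved(self):
        t = make_ultrametric_binary(
            midpoint_root(tree_from_newick("((A:1,B:2,C:3):1,(D:2,E:1):2);"))
        )
        assert {l.taxon.label for l in t.leaf_node_iter()} == set("ABCDE")


class TestCutTree:
    @pytest.fixture()
    def quartet(self):
        return make_ultrametric_binary(
            tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        )

    def test_cut_between_root_and_cherries(self, quartet):
        c = cut_tree(quartet, 0.5)
        assert sorted(sorted(x) for x in c.clusters) == [["A", "B"], ["C", "D"]]

    def test_cut_at_zero_is_one_cluster(self, quartet):
        c = cut_tree(quartet, 0.0)
        assert c.k == 1 and c.n == 4

    def test_cut_at_height_is_singletons(self, quartet):
        c = cut_tree(quartet, tree_height(quartet))
        assert c.k == 4

    def test_out_of_range_depth_is_an_error(self, quartet):
        with pytest.raises(ValueError):
            cut_tree(quartet, 99.0)

    def test_cluster_count_nondecreasing_in_depth(self):
        t = make_ultrametric_binary(
            midpoint_root(
                tree_from_newick("((A:1,(B:2,C:1):1):2,((D:1,E:2):1,F:3):1);")
            )
        )
        ks = [cut_tree(t, d).k for d in np.linspace(0, tree_height(t), 20)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))


class TestPurity:
    def test_family_identical_clustering_is_pure(self):
        c = Clustering(clusters=(frozenset({"a1", "a2"}), frozenset({"b1"})))
        assert cluster_purity(c, {"a1": "A", "a2": "A", "b1": "B"}) == 1.0

    def test_mixed_clusters(self):
        c = Clustering(
            clusters=(frozenset({"s1", "s2", "s3"}), frozenset({"s4", "s5", "s6"}))
        )
        fams = {"s1": "a", "s2": "a", "s3": "b", "s4": "b", "s5": "b", "s6": "a"}
        assert cluster_purity(c, fams) == pytest.approx(4 / 6)

    def test_singletons_are_pure(self):
        c = Clustering(clusters=tuple(frozenset({s}) for s in "abcd"))
        assert cluster_purity(c, {s: "f" + s for s in "abcd"}) == 1.0

    def test_unlabeled_leaf_is_an_error(self):
        c = Clustering(clusters=(frozenset({"a", "mystery"}),))
        with pytest.raises(ValueError):
            cluster_purity(c, {"a": "A"})

    def test_purity_nondecreasing_under_refinement(self):
        """Splitting any cluster never lowers purity."""
        rng = np.random.default_rng(17)
        labels = {f"s{i}": f"f{rng.integers(0, 4)}" for i in range(40)}
        members = list(labels)
        for _ in range(20):
            rng.shuffle(members)
            bounds = sorted(rng.choice(range(1, 40), size=3, replace=False))
            parts = np.split(np.array(members), bounds)
            coarse = Clustering(clusters=tuple(frozenset(p) for p in parts))
            # refine: split the largest cluster in two
            big = max(coarse.clusters, key=len)
            items = sorted(big)
            fine_clusters = [c for c in coarse.clusters if c is not big]
            fine_clusters += [frozenset(items[: len(items) // 2]),
                              frozenset(items[len(items) // 2:])]
            fine = Clustering(clusters=tuple(fine_clusters))
            assert cluster_purity(fine, labels) >= cluster_purity(coarse, labels)

    def test_purity_curve_nondecreasing_on_ultrametric_trees(self):
        t = make_ultrametric_binary(
            midpoint_root(
                tree_from_newick(
                    "(((a1:1,a2:1):1,(a3:1,b1:1):2):2,((b2:1,b3:2):1,(c1:1,c2:1):3):1);"
                )
            )
        )
        fams = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B",
                "b3": "B", "c1": "C", "c2": "C"}
        curve = purity_curve(t, fams, n_cuts=30)
        purities = [p for _, p in curve]
        assert all(a <= b + 1e-12 for a, b in zip(purities, purities[1:]))
        assert curve[-1][1] == 1.0
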