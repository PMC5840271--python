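import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import topouptake as tu
from topouptake.topology import tree_from_json, tree_to_json, tree_to_newick

from brute_oracle import brute_force_pairs, brute_local_maxima
from conftest import random_positive_array, small_phantom_function


class TestLocalMaxima:
    def test_isolated_center_voxel(self):
        arr = np.zeros((3, 3, 3))
        arr[1, 1, 1] = 5.0
        maxima = tu.find_local_maxima(arr)
        assert len(maxima) == 1
        assert maxima[0].voxel == (1, 1, 1)
        assert maxima[0].value == 5.0
        assert maxima[0].rank == 1

    def test_smoothed_bump_has_single_maximum(self, phantom_function):
        # a smoothed phantom always has at least its hottest bump as a maximum
        maxima = tu.find_local_maxima(phantom_function)
        assert len(maxima) >= 1
        values = [m.value for m in maxima]
        assert values == sorted(values, reverse=True)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_neighborhood_check(self, seed):
        arr = random_positive_array(seed, shape=(4, 4, 4))
        ours = {(m.voxel, m.value) for m in tu.find_local_maxima(arr)}
        brute = set(brute_local_maxima(arr))
        assert ours == brute

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tu.find_local_maxima(np.zeros((3, 3, 3)))


class TestSuperlevelComponents:
    def test_threshold_above_global_max_is_empty(self, line_array):
        lab = tu.superlevel_components(line_array, threshold=6.0)
        assert not lab.any()

    def test_low_threshold_covers_connected_roi(self, line_array):
        lab = tu.superlevel_components(line_array, threshold=0.5)
        assert np.all(lab[0, 0, :] == 1)  # one component, labeled by the global max

    def test_two_bumps_split_by_threshold(self, line_array):
        # between the bases: values {5} and {4, 3(2 connects later)} separate at 2.5
        lab = tu.superlevel_components(line_array, threshold=2.5)
        assert lab[0, 0, 0] == 1  # component of the value-5 maximum
        assert lab[0, 0, 2] == 2  # component of the value-4 maximum
        assert lab[0, 0, 4] == 3  # component of the value-3 maximum
        assert lab[0, 0, 1] == 0 and lab[0, 0, 3] == 0


class TestMergeTreeSweep:
    def test_line_example_pairs(self, line_tree):
        assert sorted(line_tree.persistence_pairs()) == [(3.0, 2.0), (4.0, 1.0), (5.0, 0.0)]
        assert sorted(line_tree.childhood_pairs()) == [(3.0, 2.0), (4.0, 2.0), (5.0, 1.0)]
        assert sorted(b.birth for b in line_tree.internal) == [1.0, 2.0]

    def test_single_maximum_tree(self):
        arr = np.zeros((3, 3, 3))
        arr[1, 1, 1] = 5.0
        tree = tu.build_merge_tree(arr, terminal_value=0.0)
        assert tree.m == 1
        (leaf,) = tree.leaves
        assert (leaf.birth, leaf.elder_death, leaf.childhood_death) == (5.0, 0.0, 0.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        arr = random_positive_array(seed)
        tree = tu.build_merge_tree(arr, terminal_value=0.0)
        oracle_elder, oracle_child = brute_force_pairs(arr, terminal=0.0)
        assert sorted(tree.persistence_pairs()) == sorted(oracle_elder)
        assert sorted(tree.childhood_pairs()) == sorted(oracle_child)

    @pytest.mark.parametrize("seed", range(5))
    def test_counting_invariants(self, seed):
        f = small_phantom_function(seed)
        tree = tu.build_merge_tree(f)
        m = len(tu.find_local_maxima(f))
        assert tree.m == m == len(tree.leaves)
        assert len(tree.internal) == m - 1
        assert len(tree.branches) == 2 * m - 1

    def test_order_relations_and_elder_rule(self, phantom_function):
        tree = tu.build_merge_tree(phantom_function)
        by_id = {b.id: b for b in tree.branches}
        for leaf in tree.leaves:
            assert leaf.birth > leaf.childhood_death >= leaf.elder_death
            if leaf.parent is not None:
                parent = by_id[leaf.parent]
                non_elder = parent.label_max != leaf.label_max
                assert (leaf.childhood_death == leaf.elder_death) == non_elder
        for internal in tree.internal:
            children = [by_id[c] for c in internal.children]
            assert internal.label_max == min(c.label_max for c in children)
            assert internal.maxima_set == frozenset().union(*(c.maxima_set for c in children))
            assert all(c.childhood_death == internal.birth for c in children)

    def test_global_maximum_persists_to_root(self, phantom_function):
        tree = tu.build_merge_tree(phantom_function, terminal_value=0.0)
        top_leaf = max(tree.leaves, key=lambda b: b.birth)
        assert top_leaf.elder_death == 0.0
        assert top_leaf.label_max == 1

    def test_homogeneity_under_scaling(self):
        arr = random_positive_array(3)
        tree1 = tu.build_merge_tree(arr, terminal_value=0.0)
        tree2 = tu.build_merge_tree(2.5 * arr, terminal_value=0.0)
        p1 = np.array(sorted(tree1.persistence_pairs()))
        p2 = np.array(sorted(tree2.persistence_pairs()))
        assert np.allclose(2.5 * p1, p2, rtol=1e-12)
        c1 = np.array(sorted(tree1.childhood_pairs()))
        c2 = np.array(sorted(tree2.childhood_pairs()))
        assert np.allclose(2.5 * c1, c2, rtol=1e-12)

    def test_disconnected_roi_yields_forest(self):
        arr = np.zeros((1, 1, 5))
        arr[0, 0, 0] = 2.0
        arr[0, 0, 4] = 3.0  # separated by zeros: two components
        tree = tu.build_merge_tree(arr, terminal_value=0.0)
        assert not tree.connected
        assert len(tree.roots) == 2
        for leaf in tree.leaves:
            assert leaf.elder_death == 0.0 and leaf.childhood_death == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.1, max_value=100.0, allow_nan=False),
            min_size=2, max_size=27, unique=True,
        )
    )
    def test_sweep_equals_oracle_for_arbitrary_distinct_values(self, values):
        """The sweep agrees with the brute-force oracle on any generic 3x3x3 input."""
        arr = np.zeros(27)
        arr[: len(values)] = values
        arr = arr.reshape(3, 3, 3)
        tree = tu.build_merge_tree(arr, terminal_value=0.0)
        oracle_elder, oracle_child = brute_force_pairs(arr, terminal=0.0)
        assert sorted(tree.persistence_pairs()) == pytest.approx(sorted(oracle_elder))
        assert sorted(tree.childhood_pairs()) == pytest.approx(sorted(oracle_child))

    def test_terminal_value_must_undercut_minimum(self, line_array):
        with pytest.raises(ValueError):
            tu.build_merge_tree(line_array, terminal_value=1.5)


class TestSerialization:
    def test_json_roundtrip(self, line_tree):
        restored = tree_from_json(tree_to_json(line_tree))
        assert restored.m == line_tree.m
        assert restored.persistence_pairs() == line_tree.persistence_pairs()
        assert restored.childhood_pairs() == line_tree.childhood_pairs()
        assert restored.roots == line_tree.roots

    def test_malformed_json_reports_error(self):
        with pytest.raises(ValueError, match="malformed"):
            tree_from_json("{not json")
        with pytest.raises(ValueError, match="missing field"):
            tree_from_json("{}")

    def test_newick_has_all_branches(self, phantom_function):
        import dendropy

        tree = tu.build_merge_tree(phantom_function)
        nwk = tree_to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        n_edges = sum(1 for e in parsed.preorder_edge_iter() if e.head_node is not None)
        assert len(parsed.leaf_nodes()) == tree.m
        # every branch, including the root edge, carries a length b - d'
        lengths = [e.length for e in parsed.preorder_edge_iter() if e.length is not None]
        assert len(lengths) == 2 * tree.m - 1
        assert all(l >= 0 for l in lengths)
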