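"""Newick handling, Fitch parsimony vs brute force, change mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icmscope import attach_traits, fitch_parsimony, map_changes, read_newick, write_newick
from icmscope.errors import DataError, NewickParseError
from icmscope.phylo import (
    brute_force_min_changes,
    clade_leafset,
    mp_labelings,
    random_trait_tree,
    root_state_set,
)


class TestNewick:
    def test_balanced_quartet_counts(self):
        tree = read_newick("((A,B),(C,D));")
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert sorted(leaves) == ["A", "B", "C", "D"]
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 3  # root + two cherries

    def test_roundtrip_preserves_topology_and_lengths(self):
        text = "((A:1.5,B:2.0):0.5,(C:1.0,D:1.0):0.25);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert write_newick(tree) == write_newick(again)
        lengths = {lf.taxon.label: lf.edge.length for lf in again.leaf_node_iter()}
        assert lengths == {"A": 1.5, "B": 2.0, "C": 1.0, "D": 1.0}

    def test_unbalanced_parentheses_raise(self):
        with pytest.raises(NewickParseError):
            read_newick("((A,B")

    def test_duplicate_leaves_raise(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            read_newick("((A,B),(A,C));")


class TestAttachTraits:
    tree_text = "((A,B),(C,D));"

    def test_full_table(self):
        tt = attach_traits(read_newick(self.tree_text),
                           {"A": "R", "B": "R", "C": "N", "D": "N"})
        assert len(tt.leaf_states) == 4
        assert tt.excluded == []

    def test_exclude_policy_prunes_unstated_leaf(self):
        tt = attach_traits(read_newick(self.tree_text),
                           {"A": "R", "B": "R", "C": "N"},
                           missing_policy="exclude")
        assert tt.excluded == ["D"]
        assert sorted(tt.leaf_labels()) == ["A", "B", "C"]

    def test_missing_leaf_errors_by_default(self):
        with pytest.raises(DataError, match="D"):
            attach_traits(read_newick(self.tree_text),
                          {"A": "R", "B": "R", "C": "N"})

    def test_state_outside_alphabet_names_offender(self):
        with pytest.raises(DataError, match="weird"):
            attach_traits(read_newick(self.tree_text),
                          {"A": "R", "B": "R", "C": "N", "D": "weird"},
                          alphabet=("R", "N"))


class TestFitch:
    def quartet(self):
        return attach_traits(read_newick("((A,B),(C,D));"),
                             {"A": "R", "B": "R", "C": "N", "D": "N"})

    def test_two_state_quartet(self):
        tt = fitch_parsimony(self.quartet())
        assert tt.min_changes == 1
        assert root_state_set(tt) == frozenset({"R", "N"})

    def test_uniform_states_need_no_changes(self):
        tt = attach_traits(read_newick("((A,B),(C,(D,E)));"),
                           dict.fromkeys("ABCDE", "R"))
        fitch_parsimony(tt)
        assert tt.min_changes == 0
        assert all(s == frozenset({"R"}) for s in tt.node_state_sets.values())

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_leaves = int(rng.integers(3, 9))
            n_states = int(rng.integers(2, 4))
            tt = random_trait_tree(rng, n_leaves, n_states)
            fitch_parsimony(tt)
            assert tt.min_changes == brute_force_min_changes(tt)

    def test_min_changes_invariant_under_rerooting(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tt = random_trait_tree(rng, int(rng.integers(4, 9)), 2)
            fitch_parsimony(tt)
            base = tt.min_changes
            tree2 = tt.tree.clone(depth=1)
            edges = [e for e in tree2.preorder_edge_iter()
                     if e.head_node.parent_node is not None]
            e = edges[int(rng.integers(len(edges)))]
            tree2.reroot_at_edge(e, update_bipartitions=False)
            tt2 = attach_traits(tree2, tt.leaf_states, alphabet=tt.alphabet)
            fitch_parsimony(tt2)
            assert tt2.min_changes == base

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_min_changes_bounded_by_minority_count(self, seed):
        rng = np.random.default_rng(seed)
        tt = random_trait_tree(rng, int(rng.integers(3, 10)), 2)
        fitch_parsimony(tt)
        counts = {s: list(tt.leaf_states.values()).count(s) for s in tt.alphabet}
        assert 0 <= tt.min_changes <= len(tt.leaf_states) - max(counts.values())


class TestMapChanges:
    def quartet(self):
        tt = attach_traits(read_newick("((A,B),(C,D));"),
                           {"A": "R", "B": "R", "C": "N", "D": "N"})
        return fitch_parsimony(tt)

    def test_quartet_all_mp_union_and_intersection(self):
        res = map_changes(self.quartet(), "all_mp")
        assert res["n_labelings"] == 2
        assert res["union"] == [("A", "B"), ("C", "D")]
        assert res["intersection"] == []
        for per in res["per_labeling"]:
            assert len(per) == 1  # each MP labeling has exactly one change

    def test_zero_change_tree_has_empty_list(self):
        tt = attach_traits(read_newick("((A,B),(C,D));"), dict.fromkeys("ABCD", "N"))
        fitch_parsimony(tt)
        assert map_changes(tt, "acctran") == []
        assert map_changes(tt, "all_mp")["union"] == []

    @pytest.mark.parametrize("resolution", ["acctran", "deltran"])
    def test_single_labelings_respect_min_changes(self, resolution):
        rng = np.random.default_rng(99)
        for _ in range(25):
            tt = random_trait_tree(rng, int(rng.integers(4, 9)), 3)
            fitch_parsimony(tt)
            changes = map_changes(tt, resolution)
            assert len(changes) == tt.min_changes


class TestCuratedFixture:
    def load(self):
        from importlib import resources

        data = resources.files("icmscope") / "data"
        tree = read_newick((data / "pnsb_tree_curated.nwk").read_text())
        tt = attach_traits(tree, str(data / "pnsb_traits_curated.csv"),
                           alphabet=("nonrestricted", "restricted"),
                           missing_policy="exclude")
        return tt

    def test_outgroup_without_trait_is_pruned(self):
        tt = self.load()
        assert tt.excluded == ["Magnetococcus_marinus"]
        assert len(tt.leaf_labels()) == 14

    def test_nonrestricted_root_with_gains_inside_rhizobiales(self):
        """There is an MP labeling with a nonrestricted ancestor in which every
        gain of restricted localization falls inside the Rhizobiales clade."""
        tt = fitch_parsimony(self.load())
        assert "nonrestricted" in root_state_set(tt)
        rhizobiales = clade_leafset(tt, [
            "Rhodopseudomonas_palustris", "Rhodoplanes_elegans",
            "Rhodobium_orientis", "Rhodoblastus_acidophilus",
        ])
        found = False
        for lab in mp_labelings(tt):
            root_key = tuple(sorted(tt.leaf_labels()))
            if lab[root_key] != "nonrestricted":
                continue
            gains = []
            for node in tt.tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                key = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
                pkey = tuple(sorted(
                    lf.taxon.label for lf in node.parent_node.leaf_iter()))
                if lab[pkey] == "nonrestricted" and lab[key] == "restricted":
                    gains.append(set(key))
            if gains and all(g <= rhizobiales for g in gains):
                found = True
                break
        assert found
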