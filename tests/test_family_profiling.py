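import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import fitch_min_changes
from syntelink.family_profiling import (
    copy_number_matrix,
    fitch_emergence,
    motif_scan,
    select_family_orthogroups,
)
from syntelink.io_formats import GeneLocus


class TestSelectFamilyOrthogroups:
    def test_single_bait(self):
        assert select_family_orthogroups(["a1"], {"a1": "OG7"}) == ["OG7"]

    def test_unmapped_bait_warns_but_returns_rest(self):
        og_map = {"a": "OG1", "b": "OG2", "c": "OG3"}
        with pytest.warns(UserWarning, match="ghost"):
            ogs = select_family_orthogroups(["a", "b", "c", "ghost"], og_map)
        assert ogs == ["OG1", "OG2", "OG3"]

    def test_all_baits_missing_is_error(self):
        with pytest.raises(KeyError, match="x1"):
            select_family_orthogroups(["x1"], {"a": "OG1"})

    def test_one_bait_per_family_a_og_recovers_family(self, clean_dataset):
        ds = clean_dataset
        a_ogs = sorted(
            og for og, fam in ds.family_of_og.items() if fam == "A"
        )
        baits = []
        for og in a_ogs:
            baits.append(
                next(g for g, o in sorted(ds.og_map.items()) if o == og)
            )
        assert select_family_orthogroups(baits, ds.og_map) == a_ogs


def _locus(gene, sp, rank=1):
    return GeneLocus(gene, sp, "chr1", rank * 1000, rank * 1000 + 10, "+",
                     rank=rank)


class TestCopyNumberMatrix:
    def test_single_cell_count(self):
        og_map = {f"g{i}": "OG1" for i in range(3)}
        loci = [_locus(f"g{i}", "spA", i + 1) for i in range(3)]
        mat = copy_number_matrix(og_map, loci, ["OG1"], min_total=1)
        assert mat.loc["spA", "OG1"] == 3

    def test_min_total_display_filter(self):
        og_map = {f"g{i}": "OG1" for i in range(99)}
        loci = [_locus(f"g{i}", "spA", i + 1) for i in range(99)]
        mat = copy_number_matrix(og_map, loci, ["OG1"], min_total=100)
        assert "OG1" not in mat.columns
        mat = copy_number_matrix(og_map, loci, ["OG1"], min_total=99)
        assert mat.loc["spA", "OG1"] == 99

    def test_counts_match_dataset_bookkeeping(self, clean_dataset):
        ds = clean_dataset
        fam_ogs = sorted(ds.family_of_og)
        mat = copy_number_matrix(ds.og_map, ds.loci, fam_ogs, min_total=1)
        for og in fam_ogs:
            total = sum(1 for g, o in ds.og_map.items() if o == og)
            assert mat[og].sum() == total

    def test_totals_invariant_to_species_order(self, clean_dataset):
        ds = clean_dataset
        fam_ogs = sorted(ds.family_of_og)
        fwd = copy_number_matrix(
            ds.og_map, ds.loci, fam_ogs, min_total=1,
            species_order=ds.species,
        )
        rev = copy_number_matrix(
            ds.og_map, ds.loci, fam_ogs, min_total=1,
            species_order=list(reversed(ds.species)),
        )
        assert (fwd.sum() == rev.sum()).all()


BALANCED4 = "((A:1,B:1)N1:1,(C:1,D:1)N2:1)N0;"


class TestFitchEmergence:
    def test_all_present_origin_is_root(self):
        res = fitch_emergence(
            {"A": 1, "B": 1, "C": 1, "D": 1}, BALANCED4
        )
        assert res.origin_node == "N0"
        assert res.n_changes == 0

    def test_clade_presence_origin_is_mrca(self):
        res = fitch_emergence({"A": 1, "B": 1, "C": 0, "D": 0}, BALANCED4)
        assert res.origin_node == "N1"
        assert not res.multiple_origins

    def test_disjoint_gains_flagged(self):
        res = fitch_emergence({"A": 1, "B": 0, "C": 1, "D": 0}, BALANCED4)
        assert res.multiple_origins
        assert res.origin_node == "N0"  # MRCA of present terminals

    def test_root_tie_prefers_absent_by_default(self):
        # one of two sister leaves present: root set is ambiguous
        res = fitch_emergence({"A": 1, "B": 0, "C": 0, "D": 0}, BALANCED4)
        assert res.node_states["N0"] in ("absent", "ambiguous")
        assert res.origin_node == "A"

    def test_unrooted_tree_rejected(self):
        with pytest.raises(ValueError, match="rooted"):
            fitch_emergence({"A": 1}, "(A:1,B:1,C:1);")

    def test_change_count_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(99)
        for _ in range(3):
            children, leaves = _random_tree_structure(16, rng)
            newick = _to_newick(children, "I0") + ";"
            for _ in range(3):
                states = {
                    leaf: int(rng.integers(2)) for leaf in leaves
                }
                if not any(states.values()):
                    states[leaves[0]] = 1
                res = fitch_emergence(states, newick)
                assert res.n_changes == fitch_min_changes(children, states)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**16 - 1))
    def test_cost_bounded_by_present_terminals(self, bits):
        leaves = [f"L{i}" for i in range(16)]
        states = {leaf: (bits >> i) & 1 for i, leaf in enumerate(leaves)}
        if not any(states.values()):
            states["L0"] = 1
        rng = np.random.default_rng(1)
        children, tree_leaves = _random_tree_structure(16, rng)
        mapping = dict(zip(tree_leaves, leaves))
        children = {
            p: tuple(mapping.get(c, c) for c in cs)
            for p, cs in children.items()
        }
        res = fitch_emergence(states, _to_newick(children, "I0") + ";")
        assert res.n_changes <= sum(states.values())


def _random_tree_structure(n_leaves, rng):
    """Random rooted binary tree as internal->children mapping."""
    leaves = [f"L{i}" for i in range(n_leaves)]
    nodes = list(leaves)
    children = {}
    counter = n_leaves - 2
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        label = f"I{counter}"
        counter -= 1
        children[label] = (a, b)
        nodes.append(label)
    return children, leaves


def _to_newick(children, node):
    if node not in children:
        return f"{node}:1"
    a, b = children[node]
    return f"({_to_newick(children, a)},{_to_newick(children, b)}){node}:1"


class TestMotifScan:
    def test_acyltransferase_pentapeptide_found(self):
        res = motif_scan("AAGDSYSAA")
        assert res.classification == "putative_AT"
        assert res.positions["GDSYS"] == [2]

    def test_nothing_found(self):
        assert motif_scan("MKLVVA").classification == "not_found"

    def test_scp_variant(self):
        assert motif_scan("MGDSASKL").classification == "SCP_like"

    def test_at_takes_precedence_with_both_positions_reported(self):
        res = motif_scan("GDSASWWGDSYS")
        assert res.classification == "putative_AT"
        assert res.positions["GDSYS"] == [7]
        assert res.positions["GDSAS"] == [0]

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            motif_scan("MKL8VA")
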