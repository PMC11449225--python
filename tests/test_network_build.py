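import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from conftest import quiet_config
from syntelink.io_formats import GeneLocus, SyntenyPair
from syntelink.network_build import (
    assign_edge_weight,
    build_network,
    collapse_tandems,
    core_components,
    decompose_by_orthogroup,
    merge_evidence,
)
from syntelink.synthetic_data import simulate_dataset


def _locus(gene, rank, og="OG1", sp="spA", chrom="chr1"):
    return GeneLocus(gene, sp, chrom, rank * 1000, rank * 1000 + 10, "+",
                     rank=rank, orthogroup=og)


class TestCollapseTandems:
    def test_adjacent_run_merges(self):
        loci = [_locus(f"g{r}", r) for r in (5, 6, 7)]
        fam = {l.gene_id: "OG1" for l in loci}
        nodes, g2n = collapse_tandems(loci, fam, tandem_max_gap=1)
        assert len(nodes) == 1
        assert len(nodes[0].member_gene_ids) == 3
        assert set(g2n.values()) == {nodes[0].node_id}

    def test_gap_beyond_threshold_splits(self):
        loci = [_locus("g5", 5), _locus("g8", 8)]
        fam = {"g5": "OG1", "g8": "OG1"}
        nodes, _ = collapse_tandems(loci, fam, tandem_max_gap=1)
        assert len(nodes) == 2

    def test_gap_equal_threshold_merges(self):
        loci = [_locus("g5", 5), _locus("g7", 7)]
        fam = {"g5": "OG1", "g7": "OG1"}
        nodes, _ = collapse_tandems(loci, fam, tandem_max_gap=1)
        assert len(nodes) == 1

    def test_unassigned_gene_is_singleton_with_warning(self):
        loci = [_locus("g1", 1), _locus("g2", 2)]
        with pytest.warns(UserWarning, match="family assignment"):
            nodes, _ = collapse_tandems(loci, {"g1": "OG1"})
        assert len(nodes) == 2

    def test_tandem_event_ledger_matches_array_sizes(self):
        import dendropy

        cfg = quiet_config(n_species=4)
        cfg.family_a.tandem_dup_rate = 0.5
        ds = simulate_dataset(cfg)
        fam_loci = [
            l for l in ds.loci if (l.orthogroup or "") in ds.family_of_og
        ]
        fam = {l.gene_id: l.orthogroup for l in fam_loci}
        nodes, _ = collapse_tandems(fam_loci, fam)
        assert any(e["type"] == "tandem_dup" for e in ds.event_log)
        tree = dendropy.Tree.get(data=ds.tree_newick, schema="newick",
                                 suppress_internal_node_taxa=False)
        for leaf in tree.leaf_node_iter():
            sp = leaf.taxon.label
            path = {sp}
            node = leaf.parent_node
            while node is not None:
                if node.taxon is not None:
                    path.add(node.taxon.label)
                elif node.label:
                    path.add(node.label)
                node = node.parent_node
            events = sum(
                1 for e in ds.event_log
                if e["type"] == "tandem_dup" and e["branch"] in path
            )
            extra = sum(
                len(n.member_gene_ids) - 1
                for n in nodes if n.species == sp
            )
            # each tandem duplication on the lineage adds one array member
            assert extra == events, sp

    def test_node_count_bounded_by_gene_count(self, noisy_dataset):
        ds = noisy_dataset
        fam_loci = [
            l for l in ds.loci if (l.orthogroup or "") in ds.family_of_og
        ]
        fam = {l.gene_id: l.orthogroup for l in fam_loci}
        nodes, _ = collapse_tandems(fam_loci, fam)
        assert len(nodes) <= len(fam_loci)


class TestEvidenceAndWeights:
    def test_support_sets(self):
        lists = {
            "OGxD1": [SyntenyPair("a", "b")],
            "OGxD2": [SyntenyPair("b", "a")],
            "MCLxD1": [SyntenyPair("a", "b"), SyntenyPair("c", "d")],
            "MCLxD2": [SyntenyPair("a", "b")],
        }
        merged = merge_evidence(lists)
        assert merged[("a", "b")] == frozenset(lists)
        assert merged[("c", "d")] == frozenset({"MCLxD1"})

    def test_merge_commutative(self):
        lists = {
            "OGxD1": [SyntenyPair("a", "b")],
            "OGxD2": [SyntenyPair("c", "d")],
            "MCLxD1": [],
            "MCLxD2": [],
        }
        rev = dict(reversed(list(lists.items())))
        assert merge_evidence(lists) == merge_evidence(rev)

    @pytest.mark.parametrize(
        "n,expected", [(1, 0.25), (2, 0.5), (3, 0.75), (4, 1.0)]
    )
    def test_weight_steps(self, n, expected):
        support = frozenset(list("wxyz")[:n])
        assert assign_edge_weight(support) == expected

    def test_empty_support_is_no_edge(self):
        with pytest.raises(ValueError, match="never weight 0"):
            assign_edge_weight(frozenset())

    @settings(derandomize=True, max_examples=30)
    @given(st.sets(st.sampled_from(["OGxD1", "OGxD2", "MCLxD1", "MCLxD2"]),
                   min_size=1))
    def test_weights_always_quarter_steps(self, support):
        assert assign_edge_weight(support) in {0.25, 0.5, 0.75, 1.0}


def _two_singletons():
    loci = [_locus("a", 1, sp="spA"), _locus("b", 1, sp="spB")]
    fam = {"a": "OG1", "b": "OG1"}
    return collapse_tandems(loci, fam)


class TestBuildNetwork:
    def test_single_approach_edge(self):
        nodes, g2n = _two_singletons()
        net = build_network(
            nodes, g2n, {("a", "b"): frozenset({"OGxD1"})}
        )
        assert net.edges["a", "b"]["weight"] == 0.25

    def test_strict_mode_requires_both_detectors(self):
        nodes, g2n = _two_singletons()
        net = build_network(
            nodes, g2n, {("a", "b"): frozenset({"OGxD1"})},
            strict_both_detectors=True,
        )
        assert net.number_of_edges() == 0
        net = build_network(
            nodes, g2n, {("a", "b"): frozenset({"OGxD1", "MCLxD2"})},
            strict_both_detectors=True,
        )
        assert net.edges["a", "b"]["weight"] == 0.5

    def test_unknown_gene_skipped_with_warning(self):
        nodes, g2n = _two_singletons()
        with pytest.warns(UserWarning, match="unknown gene"):
            net = build_network(
                nodes, g2n, {("a", "zz"): frozenset({"OGxD1"})}
            )
        assert net.number_of_edges() == 0

    def test_perfect_detectors_recover_truth_with_weight_one(
        self, clean_dataset
    ):
        ds = clean_dataset
        fam_loci = [
            l for l in ds.loci if (l.orthogroup or "") in ds.family_of_og
        ]
        fam = {l.gene_id: l.orthogroup for l in fam_loci}
        nodes, g2n = collapse_tandems(fam_loci, fam)
        net = build_network(
            nodes, g2n, merge_evidence(ds.detector_calls)
        )
        expected = {
            frozenset((g2n[a], g2n[b]))
            for a, b in ds.truth_pairs
            if g2n[a] != g2n[b]
        }
        assert {frozenset(e) for e in net.edges} == expected
        assert all(d["weight"] == 1.0 for _, _, d in net.edges(data=True))

    def test_edge_set_invariant_to_pair_orientation(self):
        nodes, g2n = _two_singletons()
        n1 = build_network(nodes, g2n, {("a", "b"): frozenset({"OGxD1"})})
        n2 = build_network(nodes, g2n, {("b", "a"): frozenset({"OGxD1"})})
        assert set(n1.edges) == set(n2.edges)


class TestComponents:
    def _network(self, sizes):
        g = nx.Graph()
        offset = 0
        for size in sizes:
            members = [f"n{offset + i}" for i in range(size)]
            nx.add_path(g, members)
            for m in members:
                g.add_node(m, orthogroup="OGX")
            offset += size
        return g

    def test_k_largest(self):
        g = self._network([10, 7, 3])
        comps = core_components(g, k=2)
        assert [c.number_of_nodes() for c in comps] == [10, 7]

    def test_tie_break_deterministic(self):
        g = self._network([4, 4, 4])
        comps = core_components(g, k=1)
        assert min(comps[0].nodes) == "n0"

    def test_k_exceeding_component_count_warns(self):
        g = self._network([3])
        with pytest.warns(UserWarning):
            comps = core_components(g, k=6)
        assert len(comps) == 1

    def test_clean_two_family_run_recovers_family_components(
        self, clean_dataset
    ):
        ds = clean_dataset
        fam_loci = [
            l for l in ds.loci if (l.orthogroup or "") in ds.family_of_og
        ]
        fam = {l.gene_id: l.orthogroup for l in fam_loci}
        nodes, g2n = collapse_tandems(fam_loci, fam)
        net = build_network(nodes, g2n, merge_evidence(ds.detector_calls))
        # event-free run: one clique component per orthogroup
        k = len(ds.family_of_og)
        comps = core_components(net, k=k)
        ogs = {
            next(iter(c.nodes(data="orthogroup")))[1] for c in comps
        }
        assert len(ogs) == k

    def test_min_nodes_filter(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        nx.add_path(g, ["c", "d", "e"])
        for n, og in zip("abcde", ["OG1"] * 2 + ["OG2"] * 3):
            g.add_node(n, orthogroup=og)
        comps = decompose_by_orthogroup(g, min_nodes=3)
        assert len(comps) == 1
        assert comps[0].graph["orthogroup"] == "OG2"

    def test_triangle_kept(self):
        g = nx.complete_graph(3)
        g = nx.relabel_nodes(g, str)
        for n in g.nodes:
            g.nodes[n]["orthogroup"] = "OG1"
        assert len(decompose_by_orthogroup(g)) == 1

    def test_decomposition_totals_bounded_by_core(self, noisy_dataset):
        ds = noisy_dataset
        fam_loci = [
            l for l in ds.loci if (l.orthogroup or "") in ds.family_of_og
        ]
        fam = {l.gene_id: l.orthogroup for l in fam_loci}
        nodes, g2n = collapse_tandems(fam_loci, fam)
        net = build_network(nodes, g2n, merge_evidence(ds.detector_calls))
        comps = decompose_by_orthogroup(net)
        assert sum(c.number_of_nodes() for c in comps) <= len(net)
        assert sum(c.number_of_edges() for c in comps) <= net.number_of_edges()
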