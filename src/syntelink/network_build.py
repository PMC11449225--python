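"""Assemble the weighted phylosynteny network.

Tandem arrays (runs of same-family genes with small rank gaps) collapse to
single nodes; collinearity evidence from the four clustering x detector
approach combinations is merged per gene pair and lifted to node level;
edge weights are 0.25 per supporting approach, so a relationship seen by
all four approaches gets weight 1.0 and one seen by a single approach gets
the minimum weight 0.25. A strict mode additionally requires support from
both detectors (i-ADHoRe and MCScanX) before an edge is created.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_formats import GeneLocus, SyntenyPair, canonical_pair

__all__ = [
    "NetworkNode",
    "collapse_tandems",
    "merge_evidence",
    "assign_edge_weight",
    "build_network",
    "core_components",
    "decompose_by_orthogroup",
]


@dataclass(frozen=True)
class NetworkNode:
    """A gene or tandem array of genes: one vertex of the network."""

    node_id: str
    species: str
    chromosome: str
    member_gene_ids: tuple[str, ...]
    orthogroup: str | None
    mcl_group: str | None


def collapse_tandems(
    loci: Sequence[GeneLocus],
    family_map: Mapping[str, str],
    tandem_max_gap: int = 1,
) -> tuple[list[NetworkNode], dict[str, str]]:
    """Merge tandem arrays into single nodes.

    A tandem array is a maximal run of genes on one chromosome that share
    the same ``family_map`` label and whose consecutive rank gaps (number
    of intervening genes) are at most ``tandem_max_gap``. Every other gene
    becomes a singleton node. Genes absent from ``family_map`` stay
    singletons with a warning. Returns the nodes plus a gene→node-id map.

    The node id is the lexicographically smallest member gene id; the
    representative orthogroup/mcl_group is the most common one among
    members (ties broken lexicographically).
    """
    by_chrom: dict[tuple[str, str], list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault((loc.species, loc.chromosome), []).append(loc)

    nodes: list[NetworkNode] = []
    gene_to_node: dict[str, str] = {}
    for (sp, chrom) in sorted(by_chrom):
        genes = sorted(by_chrom[(sp, chrom)], key=lambda g: g.rank)
        run: list[GeneLocus] = []

        def flush() -> None:
            if not run:
                return
            members = tuple(g.gene_id for g in run)
            node_id = min(members)
            og = _majority(g.orthogroup for g in run)
            mcl = _majority(g.mcl_group for g in run)
            nodes.append(
                NetworkNode(node_id, sp, chrom, members, og, mcl)
            )
            for m in members:
                gene_to_node[m] = node_id
            run.clear()

        for loc in genes:
            label = family_map.get(loc.gene_id)
            if label is None:
                warnings.warn(
                    f"gene {loc.gene_id} has no family assignment; "
                    "kept as singleton node"
                )
                flush()
                run.append(loc)
                flush()
                continue
            if run:
                prev = run[-1]
                prev_label = family_map.get(prev.gene_id)
                gap = loc.rank - prev.rank - 1
                if prev_label == label and gap <= tandem_max_gap:
                    run.append(loc)
                    continue
                flush()
            run.append(loc)
        flush()
    return nodes, gene_to_node


def _majority(values: Iterable[str | None]) -> str | None:
    counts = Counter(v for v in values if v is not None)
    if not counts:
        return None
    return min(counts, key=lambda v: (-counts[v], v))


def merge_evidence(
    pair_lists: Mapping[str, Sequence[SyntenyPair]],
) -> dict[tuple[str, str], frozenset[str]]:
    """Union the per-approach pair lists into pair → support set.

    The result is invariant to the ordering of the lists and of the genes
    within a pair.
    """
    support: dict[tuple[str, str], set[str]] = {}
    for approach, pairs in pair_lists.items():
        for p in pairs:
            key = canonical_pair(p.gene_a, p.gene_b)
            support.setdefault(key, set()).add(approach)
    return {k: frozenset(v) for k, v in support.items()}


def assign_edge_weight(support_set: frozenset[str] | set[str]) -> float:
    """Edge weight = 0.25 per supporting approach (0.25 ... 1.0).

    An empty support set is not a weight-0 edge but no edge at all.
    """
    n = len(support_set)
    if n == 0:
        raise ValueError("empty support set: no edge, never weight 0")
    if n > 4:
        raise ValueError("support cannot exceed the four approaches")
    return 0.25 * n


def _has_both_detectors(support: frozenset[str]) -> bool:
    return any(a.endswith("D1") for a in support) and any(
        a.endswith("D2") for a in support
    )


def build_network(
    nodes: Sequence[NetworkNode],
    gene_to_node: Mapping[str, str],
    merged_evidence: Mapping[tuple[str, str], frozenset[str]],
    strict_both_detectors: bool = False,
) -> nx.Graph:
    """Lift gene-level evidence to node level and weight the edges.

    Node-level support is the union of the supports of all member-gene
    pairs (a tandem array is syntenic if any member is). Pairs that fall
    within a single node are discarded (no self-loops). In strict mode an
    edge requires at least one i-ADHoRe-based and one MCScanX-based
    approach in its support.
    """
    g = nx.Graph()
    for node in nodes:
        g.add_node(
            node.node_id,
            species=node.species,
            chromosome=node.chromosome,
            members=node.member_gene_ids,
            orthogroup=node.orthogroup,
            mcl_group=node.mcl_group,
        )
    node_support: dict[tuple[str, str], set[str]] = {}
    for (ga, gb), support in merged_evidence.items():
        na, nb = gene_to_node.get(ga), gene_to_node.get(gb)
        if na is None or nb is None:
            missing = ga if na is None else gb
            warnings.warn(f"pair references unknown gene {missing!r}; skipped")
            continue
        if na == nb:
            continue
        key = canonical_pair(na, nb)
        node_support.setdefault(key, set()).update(support)
    for (na, nb), support in node_support.items():
        if strict_both_detectors and not _has_both_detectors(
            frozenset(support)
        ):
            continue
        g.add_edge(na, nb, weight=assign_edge_weight(support))
    return g


def _component_sort_key(g: nx.Graph, comp: set[str]):
    sub_edges = sum(1 for a, b in g.edges(comp) if a in comp and b in comp)
    return (-len(comp), -sub_edges, min(comp))


def core_components(network: nx.Graph, k: int = 6) -> list[nx.Graph]:
    """The k largest connected components (the core network), largest first.

    Ties on node count break by edge count, then by smallest node id, so
    the selection is reproducible.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    comps = sorted(
        nx.connected_components(network),
        key=lambda c: _component_sort_key(network, c),
    )
    if k > len(comps):
        warnings.warn(
            f"requested {k} components but network has {len(comps)}"
        )
    return [network.subgraph(c).copy() for c in comps[:k]]


def decompose_by_orthogroup(
    core_network: nx.Graph,
    og_of_node: Mapping[str, str] | None = None,
    min_nodes: int = 3,
) -> list[nx.Graph]:
    """Split the core network into per-orthogroup connected components.

    For each orthogroup the induced subgraph over its nodes is taken and
    broken into connected components; components with fewer than
    ``min_nodes`` nodes (default 3) are dropped. Orthogroup labels default
    to the nodes' ``orthogroup`` attribute.
    """
    if og_of_node is None:
        og_of_node = {
            n: d.get("orthogroup") for n, d in core_network.nodes(data=True)
        }
    by_og: dict[str, list[str]] = {}
    for n in core_network.nodes:
        og = og_of_node.get(n)
        if og is not None:
            by_og.setdefault(og, []).append(n)
    out: list[nx.Graph] = []
    for og in sorted(by_og):
        sub = core_network.subgraph(by_og[og])
        for comp in sorted(nx.connected_components(sub), key=min):
            if len(comp) >= min_nodes:
                piece = sub.subgraph(comp).copy()
                piece.graph["orthogroup"] = og
                out.append(piece)
    return out
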