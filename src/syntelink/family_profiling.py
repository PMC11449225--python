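"""Bait-driven family retrieval, copy-number matrices, parsimony emergence
and pentapeptide motif classification.

The workflow mirrors how acyltransferase families are profiled across a
genome panel: biochemically characterized "bait" genes pull their
orthogroups out of the clustering output; per-species copy numbers of
those orthogroups form a heatmap-ready matrix; Fitch parsimony on the
species tree places the origin of each orthogroup; and a pentapeptide
around the catalytic serine separates putative acyltransferases from
plain serine carboxypeptidases.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .io_formats import GeneLocus

__all__ = [
    "EmergenceResult",
    "MotifResult",
    "select_family_orthogroups",
    "copy_number_matrix",
    "fitch_emergence",
    "motif_scan",
]


def select_family_orthogroups(
    bait_gene_ids: Sequence[str], og_map: Mapping[str, str]
) -> list[str]:
    """Union of orthogroups containing at least one bait gene.

    Returns a stably ordered (sorted) list. Baits missing from the map are
    reported with a warning; if none resolve, an error lists them all.
    """
    found: set[str] = set()
    missing: list[str] = []
    for bait in bait_gene_ids:
        og = og_map.get(bait)
        if og is None:
            missing.append(bait)
        else:
            found.add(og)
    if missing and not found:
        raise KeyError(f"no bait gene found in orthogroup map: {missing}")
    if missing:
        warnings.warn(f"bait genes not in orthogroup map: {missing}")
    return sorted(found)


def copy_number_matrix(
    og_map: Mapping[str, str],
    loci: Sequence[GeneLocus],
    family_ogs: Sequence[str],
    min_total: int = 100,
    species_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Species x orthogroup gene-count matrix for the selected family.

    Columns whose total count is below ``min_total`` are dropped — the
    same display filter used for copy-number heatmaps (default 100 genes).
    Rows follow ``species_order`` when supplied (a taxonomy ordering),
    otherwise sorted species names.
    """
    family = set(family_ogs)
    species_of = {loc.gene_id: loc.species for loc in loci}
    counts: dict[tuple[str, str], int] = {}
    for gene, og in og_map.items():
        if og not in family:
            continue
        sp = species_of.get(gene)
        if sp is None:
            continue
        counts[(sp, og)] = counts.get((sp, og), 0) + 1
    if species_order is None:
        species_order = sorted({sp for sp, _ in counts})
    cols = sorted(family)
    mat = pd.DataFrame(0, index=list(species_order), columns=cols, dtype=int)
    for (sp, og), n in counts.items():
        if sp in mat.index:
            mat.loc[sp, og] = n
    keep = [c for c in cols if mat[c].sum() >= min_total]
    return mat[keep]


@dataclass
class EmergenceResult:
    """Fitch reconstruction of an orthogroup's presence/absence history."""

    orthogroup: str
    origin_node: str
    node_states: dict[str, str]  # node label -> present/absent/ambiguous
    n_changes: int
    multiple_origins: bool = False


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
        tree.is_rooted = True
    return tree


def _node_label(node: dendropy.Node, idx: int) -> str:
    if node.is_leaf():
        return node.taxon.label.replace(" ", "_")
    return node.label or f"_internal_{idx}"


def fitch_emergence(
    presence: Mapping[str, int],
    tree: dendropy.Tree | str,
    orthogroup: str = "",
    root_tie: str = "absent",
) -> EmergenceResult:
    """Fitch parsimony presence/absence reconstruction on a rooted tree.

    Bottom-up state sets followed by a top-down resolution; a root tie is
    broken toward ``root_tie`` (default "absent", i.e. the latest,
    most conservative origin). Nodes whose bottom-up set contained both
    states are reported as "ambiguous" alongside their resolved state.
    ``origin_node`` is the rootmost node resolved present on the path from
    the MRCA of present terminals toward the root; when the reconstruction
    implies several independent gains, that MRCA is returned and
    ``multiple_origins`` is set.
    """
    tree = _as_tree(tree)
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        raise ValueError("tree must be rooted (root with at most 2 children)")
    if root_tie not in ("absent", "present"):
        raise ValueError("root_tie must be 'absent' or 'present'")

    labels: dict[int, str] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        labels[id(node)] = _node_label(node, i)

    present_leaves = [
        leaf for leaf in tree.leaf_node_iter()
        if presence.get(labels[id(leaf)], 0)
    ]
    if not present_leaves:
        raise ValueError("at least one terminal must be present")

    sets: dict[int, frozenset[str]] = {}
    n_changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = "present" if presence.get(labels[id(node)], 0) else "absent"
            sets[id(node)] = frozenset([state])
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[id(node)] = inter
            else:
                sets[id(node)] = frozenset.union(*child_sets)
                n_changes += 1

    resolved: dict[int, str] = {}
    node_states: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        s = sets[id(node)]
        if len(s) == 1:
            choice = next(iter(s))
        elif node.parent_node is None:
            choice = root_tie
        else:
            parent = resolved[id(node.parent_node)]
            choice = parent if parent in s else root_tie
        resolved[id(node)] = choice
        node_states[labels[id(node)]] = (
            "ambiguous" if len(s) > 1 else choice
        )

    if len(present_leaves) == 1:
        mrca = present_leaves[0]
    else:
        mrca = tree.mrca(
            taxa=[leaf.taxon for leaf in present_leaves]
        )
    multiple = resolved[id(mrca)] != "present"
    origin = mrca
    if not multiple:
        node = mrca
        while (
            node.parent_node is not None
            and resolved[id(node.parent_node)] == "present"
        ):
            node = node.parent_node
        origin = node
    return EmergenceResult(
        orthogroup=orthogroup,
        origin_node=labels[id(origin)],
        node_states=node_states,
        n_changes=n_changes,
        multiple_origins=multiple,
    )


_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Diagnostic pentapeptide of characterized clade-IA SCPL acyltransferases;
#: the central S is the catalytic serine.
AT_PENTAPEPTIDE = "GDSYS"
#: Default peptidase-form variant; configurable, as the peptidase motif
#: differs from the acyltransferase form by limited sequence variation.
SCP_PENTAPEPTIDE = "GDSAS"


@dataclass
class MotifResult:
    classification: str  # putative_AT / SCP_like / not_found
    positions: dict[str, list[int]] = field(default_factory=dict)


def motif_scan(
    protein_seq: str,
    pentapeptide: str = AT_PENTAPEPTIDE,
    scp_variant: str = SCP_PENTAPEPTIDE,
) -> MotifResult:
    """Classify a protein by catalytic-serine pentapeptide content.

    ``putative_AT`` if the acyltransferase pentapeptide occurs (takes
    precedence), ``SCP_like`` if only the peptidase variant occurs, else
    ``not_found``. All (0-based) match offsets of both motifs are reported.
    """
    seq = protein_seq.strip().upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    positions: dict[str, list[int]] = {}
    for motif in (pentapeptide, scp_variant):
        hits = []
        start = seq.find(motif)
        while start != -1:
            hits.append(start)
            start = seq.find(motif, start + 1)
        if hits:
            positions[motif] = hits
    if pentapeptide in positions:
        cls = "putative_AT"
    elif scp_variant in positions:
        cls = "SCP_like"
    else:
        cls = "not_found"
    return MotifResult(classification=cls, positions=positions)
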