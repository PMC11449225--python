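"""Genome-evolution simulator with ground truth for synteny-network testing.

Genomes are ordered gene lists on a fixed number of chromosomes. Two gene
families with contrasting dynamics ("A", BAHD-like, and "B", SCPL-like)
evolve along a species tree by tandem duplication, dispersed duplication,
gene loss, single-gene relocation (synteny rupture) and whole-genome
duplication followed by fractionation. Background genes are single-copy
orthologues that drift by slow relocation, so the local gene neighbourhood
of any locus decays gradually with phylogenetic distance.

Ancestral collinearity (the truth ledger) is defined operationally: two
same-orthogroup genes in different species are collinear iff the gene
neighbourhoods of width ``synteny_window`` around them share at least
``min_shared_neighbors`` orthologue families. With zero relocation this
reduces to per-ancestral-locus cross-species cliques; with relocation it
produces the graded decay of synteny that real detectors see.

Detector outputs for the four approach combinations (OrthoFinder/MCL x
i-ADHoRe/MCScanX) are emulated by thinning the truth ledger at a
per-approach sensitivity and adding false-positive pairs between
non-collinear genes of the same homology group.

Base pairs are synthesized as ``rank x 1000`` spans; gene order is what
matters downstream.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    APPROACHES,
    GeneLocus,
    SyntenyPair,
    canonical_pair,
    write_collinearity,
    write_gene_positions,
    write_mcl_clusters,
    write_orthogroups,
)

__all__ = [
    "FamilyParams",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "emit_detector_calls",
    "write_dataset",
]


@dataclass
class FamilyParams:
    """Per-family evolutionary rates (all per gene per branch).

    ``rearrangement_rate`` is the probability that a gene is relocated to a
    random genomic position on a branch, breaking its synteny context.
    ``tandem_burst_branch`` optionally multiplies the tandem-duplication
    rate on one internal branch (e.g. a land-transition burst).
    """

    n_orthogroups: int = 4
    root_copies_per_og: int = 1
    #: "staggered" draws each orthogroup's birth branch uniformly from the
    #: internal nodes with enough descendant species, emulating family
    #: expansion at different tree depths; "root" places every orthogroup
    #: in the ancestral genome.
    origin: str = "staggered"
    tandem_dup_rate: float = 0.05
    dispersed_dup_rate: float = 0.02
    loss_rate: float = 0.02
    rearrangement_rate: float = 0.06
    retention_after_wgd: float = 0.5
    tandem_burst_branch: str | None = None
    tandem_burst_multiplier: float = 1.0

    def validate(self) -> None:
        for name in (
            "tandem_dup_rate",
            "dispersed_dup_rate",
            "loss_rate",
            "rearrangement_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.retention_after_wgd <= 1:
            raise ValueError("retention_after_wgd must be in [0, 1]")
        if self.n_orthogroups < 1:
            raise ValueError("n_orthogroups must be >= 1")
        if self.origin not in ("staggered", "root"):
            raise ValueError("origin must be 'staggered' or 'root'")


def _default_sensitivity() -> dict[str, float]:
    return {"OGxD1": 0.9, "OGxD2": 0.85, "MCLxD1": 0.85, "MCLxD2": 0.8}


@dataclass
class SimulationConfig:
    """Full specification of one simulated dataset; the seed fixes all
    randomness (tree shape, root genome, events, detector noise)."""

    seed: int = 0
    n_species: int = 16
    species_tree: str | None = None
    chromosomes_per_species: int = 4
    background_genes_per_chromosome: int = 150
    family_a: FamilyParams = field(
        default_factory=lambda: FamilyParams(
            n_orthogroups=4, rearrangement_rate=0.06, retention_after_wgd=0.2
        )
    )
    family_b: FamilyParams = field(
        default_factory=lambda: FamilyParams(
            n_orthogroups=3, root_copies_per_og=2, rearrangement_rate=0.30,
            retention_after_wgd=0.75
        )
    )
    background_shuffle_rate: float = 0.12
    background_retention_after_wgd: float = 0.5
    wgd_probability: float = 0.08
    wgd_branches: tuple[str, ...] = ()
    synteny_window: int = 10
    min_shared_neighbors: int = 5
    rearrangement_flank: int = 2
    detector_sensitivity: dict[str, float] = field(
        default_factory=_default_sensitivity
    )
    detector_fp_rate: float = 0.002

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.chromosomes_per_species < 1:
            raise ValueError("chromosomes_per_species must be >= 1")
        if self.background_genes_per_chromosome < 1:
            raise ValueError("background_genes_per_chromosome must be >= 1")
        if not 0 <= self.wgd_probability <= 1:
            raise ValueError("wgd_probability must be in [0, 1]")
        if not 0 <= self.detector_fp_rate <= 1:
            raise ValueError("detector_fp_rate must be in [0, 1]")
        for v in self.detector_sensitivity.values():
            if not 0 <= v <= 1:
                raise ValueError("detector sensitivities must be in [0, 1]")
        self.family_a.validate()
        self.family_b.validate()


@dataclass(eq=False)
class _SimGene:
    og: str
    family: str | None  # "A", "B" or None for background
    strand: str


@dataclass
class SyntheticDataset:
    """A simulated dataset plus every ground-truth ledger a test needs."""

    config: SimulationConfig
    species: list[str]
    tree_newick: str
    loci: list[GeneLocus]
    og_map: dict[str, str]
    mcl_map: dict[str, str]
    mcl_clusters: list[list[str]]
    family_of_og: dict[str, str]
    truth_pairs: list[tuple[str, str]]
    windows: dict[str, frozenset[str]]
    detector_calls: dict[str, list[SyntenyPair]]
    event_log: list[dict]

    @property
    def family_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {"A": [], "B": []}
        for loc in self.loci:
            fam = self.family_of_og.get(loc.orthogroup or "")
            if fam:
                out[fam].append(loc.gene_id)
        return out

    def family_of_gene(self, gene_id: str) -> str | None:
        return self.family_of_og.get(self.og_map.get(gene_id, ""))


# ---------------------------------------------------------------------------
# species tree

class _TreeNode:
    __slots__ = ("label", "children")

    def __init__(self, label: str, children: list["_TreeNode"] | None = None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:1"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}){self.label}:1"


def _random_tree(n_species: int, rng: np.random.Generator) -> _TreeNode:
    width = max(2, len(str(n_species)))
    leaves = [_TreeNode(f"S{i + 1:0{width}d}") for i in range(n_species)]
    if n_species == 1:
        root = _TreeNode("N0", [leaves[0]])
        return root
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(_TreeNode("", [a, b]))
    root = nodes[0]
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.children:
            node.label = f"N{counter}"
            counter += 1
            stack.extend(reversed(node.children))
    return root


def _parse_newick(newick: str) -> _TreeNode:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    counter = [0]

    def convert(nd) -> _TreeNode:
        if nd.is_leaf():
            return _TreeNode(nd.taxon.label.replace(" ", "_"))
        label = nd.label or f"N{counter[0]}"
        counter[0] += 1
        return _TreeNode(label, [convert(c) for c in nd.child_nodes()])

    return convert(tree.seed_node)


# ---------------------------------------------------------------------------
# simulation

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the simulation; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.species_tree:
        root = _parse_newick(config.species_tree)
    else:
        root = _random_tree(config.n_species, rng)

    event_log: list[dict] = []
    births = _assign_origins(root, config, rng, event_log)
    genome = _root_genome(config, rng, births.get(root.label, []))
    if "root" in config.wgd_branches:
        genome = _apply_wgd(genome, config, rng)
        event_log.append({"type": "wgd", "branch": "root"})

    leaf_genomes: dict[str, dict[str, list[_SimGene]]] = {}

    def descend(node: _TreeNode, genome: dict[str, list[_SimGene]]) -> None:
        for child in node.children:
            g = _evolve_branch(genome, child.label, config, rng, event_log)
            for og, fam, copies in births.get(child.label, []):
                for _ in range(copies):
                    _insert_gene(g, og, fam, rng)
            if child.children:
                descend(child, g)
            else:
                leaf_genomes[child.label] = g

    if root.children:
        descend(root, genome)
    else:  # degenerate single-species tree without a cherry
        leaf_genomes[root.label] = genome

    species = sorted(leaf_genomes)
    loci, og_map = _materialize(leaf_genomes, config)
    family_of_og = {}
    for fam, params in (("A", config.family_a), ("B", config.family_b)):
        for i in range(params.n_orthogroups):
            family_of_og[f"OG_{fam}{i + 1}"] = fam
    mcl_clusters, mcl_map = _mcl_truth(og_map, family_of_og)
    loci = [
        dataclasses.replace(
            loc,
            orthogroup=og_map[loc.gene_id],
            mcl_group=mcl_map[loc.gene_id],
        )
        for loc in loci
    ]
    truth_pairs, windows = _truth_ledger(loci, family_of_og, config)

    detector_calls: dict[str, list[SyntenyPair]] = {}
    dataset = SyntheticDataset(
        config=config,
        species=species,
        tree_newick=root.newick() + ";",
        loci=loci,
        og_map=og_map,
        mcl_map=mcl_map,
        mcl_clusters=mcl_clusters,
        family_of_og=family_of_og,
        truth_pairs=truth_pairs,
        windows=windows,
        detector_calls=detector_calls,
        event_log=event_log,
    )
    for i, approach in enumerate(APPROACHES):
        sub = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(100 + i,))
        )
        detector_calls[approach] = emit_detector_calls(
            dataset,
            approach,
            config.detector_sensitivity[approach],
            config.detector_fp_rate,
            sub,
        )
    return dataset


def _internal_nodes(root: _TreeNode) -> dict[str, tuple[int, int]]:
    """label -> (leaf count, depth) for internal nodes."""
    info: dict[str, tuple[int, int]] = {}

    def walk(node: _TreeNode, depth: int) -> int:
        if not node.children:
            return 1
        n = sum(walk(c, depth + 1) for c in node.children)
        info[node.label] = (n, depth)
        return n

    walk(root, 0)
    return info


def _assign_origins(
    root: _TreeNode,
    config: SimulationConfig,
    rng: np.random.Generator,
    event_log: list[dict],
    min_leaves: int = 4,
) -> dict[str, list[tuple[str, str, int]]]:
    """Birth branch per orthogroup: node label -> [(og, family, copies)]."""
    info = _internal_nodes(root)
    by_depth: dict[int, list[str]] = {}
    for label, (n, depth) in sorted(info.items()):
        if n >= min_leaves:
            by_depth.setdefault(depth, []).append(label)
    depths = sorted(by_depth)
    births: dict[str, list[tuple[str, str, int]]] = {}
    for fam, params in (("A", config.family_a), ("B", config.family_b)):
        for i in range(params.n_orthogroups):
            og = f"OG_{fam}{i + 1}"
            if params.origin == "root" or not depths:
                label = root.label
            else:
                # uniform over emergence depth, then over nodes at that
                # depth, so old and young orthogroups are equally likely
                d = depths[int(rng.integers(len(depths)))]
                nodes_at = by_depth[d]
                label = nodes_at[int(rng.integers(len(nodes_at)))]
            births.setdefault(label, []).append(
                (og, fam, params.root_copies_per_og)
            )
            event_log.append({"type": "birth", "branch": label, "og": og,
                              "family": fam})
    return births


def _insert_gene(
    genome: dict[str, list[_SimGene]], og: str, fam: str,
    rng: np.random.Generator,
) -> None:
    chroms = sorted(genome)
    chrom = chroms[int(rng.integers(len(chroms)))]
    pos = int(rng.integers(len(genome[chrom]) + 1))
    genome[chrom].insert(
        pos, _SimGene(og, fam, "+" if rng.random() < 0.5 else "-")
    )


def _root_genome(
    config: SimulationConfig,
    rng: np.random.Generator,
    root_births: list[tuple[str, str, int]],
) -> dict[str, list[_SimGene]]:
    genome: dict[str, list[_SimGene]] = {}
    serial = 0
    for c in range(config.chromosomes_per_species):
        genes = []
        for _ in range(config.background_genes_per_chromosome):
            serial += 1
            genes.append(
                _SimGene(
                    f"BG{serial:05d}",
                    None,
                    "+" if rng.random() < 0.5 else "-",
                )
            )
        genome[f"chr{c + 1}"] = genes
    for og, fam, copies in root_births:
        for _ in range(copies):
            _insert_gene(genome, og, fam, rng)
    return genome


def _copy_genome(g: dict[str, list[_SimGene]]) -> dict[str, list[_SimGene]]:
    return {c: list(genes) for c, genes in g.items()}


def _apply_wgd(
    genome: dict[str, list[_SimGene]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, list[_SimGene]]:
    """Duplicate every chromosome, then fractionate each new copy gene-wise."""
    retention = {
        "A": config.family_a.retention_after_wgd,
        "B": config.family_b.retention_after_wgd,
        None: config.background_retention_after_wgd,
    }
    out = _copy_genome(genome)
    for chrom in sorted(genome):
        kept = [
            _SimGene(g.og, g.family, g.strand)
            for g in genome[chrom]
            if rng.random() < retention[g.family]
        ]
        if kept:
            out[chrom + "w"] = kept
    return out


def _evolve_branch(
    parent: dict[str, list[_SimGene]],
    branch_label: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    event_log: list[dict],
) -> dict[str, list[_SimGene]]:
    genome = _copy_genome(parent)
    if branch_label in config.wgd_branches or (
        config.wgd_probability > 0
        and rng.random() < config.wgd_probability
    ):
        genome = _apply_wgd(genome, config, rng)
        event_log.append({"type": "wgd", "branch": branch_label})

    params = {"A": config.family_a, "B": config.family_b}

    # Segmental rearrangements: a breakpoint relocates the family gene
    # together with part of its flanking block, so each event erodes the
    # gene's ancestral neighbourhood only partially; repeated events at the
    # family-specific rate drive the gradual family-specific decay of
    # synteny with divergence.
    carry = max(0, config.rearrangement_flank)
    to_move: list[_SimGene] = []
    for chrom in sorted(genome):
        for gene in genome[chrom]:
            if gene.family is None:
                continue
            if rng.random() < params[gene.family].rearrangement_rate:
                to_move.append(gene)
    for gene in to_move:
        loc = _locate(genome, gene)
        if loc is None:  # already moved inside another segment
            continue
        chrom, idx = loc
        left = int(rng.integers(0, carry + 1))
        right = int(rng.integers(0, carry + 1))
        lo = max(0, idx - left)
        segment = genome[chrom][lo:idx + right + 1]
        del genome[chrom][lo:idx + right + 1]
        chroms = sorted(genome)
        target = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(len(genome[target]) + 1))
        genome[target][pos:pos] = segment
        event_log.append(
            {"type": "rearrangement", "branch": branch_label,
             "family": gene.family, "og": gene.og,
             "segment_size": len(segment)}
        )

    relocated: list[_SimGene] = []
    new_genome: dict[str, list[_SimGene]] = {}
    for chrom in sorted(genome):
        rebuilt: list[_SimGene] = []
        for gene in genome[chrom]:
            if gene.family is None:
                if rng.random() < config.background_shuffle_rate:
                    relocated.append(gene)
                    event_log.append(
                        {"type": "shuffle", "branch": branch_label,
                         "og": gene.og}
                    )
                else:
                    rebuilt.append(gene)
                continue
            p = params[gene.family]
            if rng.random() < p.loss_rate:
                event_log.append(
                    {"type": "loss", "branch": branch_label,
                     "family": gene.family, "og": gene.og}
                )
                continue
            rebuilt.append(gene)
            tandem_rate = p.tandem_dup_rate
            if branch_label == p.tandem_burst_branch:
                tandem_rate *= p.tandem_burst_multiplier
            if rng.random() < tandem_rate:
                rebuilt.append(_SimGene(gene.og, gene.family, gene.strand))
                event_log.append(
                    {"type": "tandem_dup", "branch": branch_label,
                     "family": gene.family, "og": gene.og}
                )
            if rng.random() < p.dispersed_dup_rate:
                relocated.append(_SimGene(gene.og, gene.family, gene.strand))
                event_log.append(
                    {"type": "dispersed_dup", "branch": branch_label,
                     "family": gene.family, "og": gene.og}
                )
        new_genome[chrom] = rebuilt
    chroms = sorted(new_genome)
    for gene in relocated:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(len(new_genome[chrom]) + 1))
        new_genome[chrom].insert(pos, gene)
    return new_genome


def _locate(
    genome: dict[str, list[_SimGene]], gene: _SimGene
) -> tuple[str, int] | None:
    for chrom in sorted(genome):
        for i, g in enumerate(genome[chrom]):
            if g is gene:
                return chrom, i
    return None


def _materialize(
    leaf_genomes: dict[str, dict[str, list[_SimGene]]],
    config: SimulationConfig,
) -> tuple[list[GeneLocus], dict[str, str]]:
    loci: list[GeneLocus] = []
    og_map: dict[str, str] = {}
    for sp in sorted(leaf_genomes):
        for chrom in sorted(leaf_genomes[sp]):
            for i, gene in enumerate(leaf_genomes[sp][chrom]):
                rank = i + 1
                gid = f"{sp}_{chrom}_{rank:04d}"
                start = (rank - 1) * 1000 + 1
                loci.append(
                    GeneLocus(
                        gid, sp, chrom, start, start + 499, gene.strand,
                        rank=rank,
                    )
                )
                og_map[gid] = gene.og
    return loci, og_map


def _mcl_truth(
    og_map: dict[str, str], family_of_og: dict[str, str]
) -> tuple[list[list[str]], dict[str, str]]:
    """MCL ground truth: family-A orthogroups each keep their own group,
    all family-B orthogroups merge into a single coarse group, background
    orthologue families are one group each."""
    genes_by_og: dict[str, list[str]] = {}
    for gene in sorted(og_map):
        genes_by_og.setdefault(og_map[gene], []).append(gene)
    clusters: list[list[str]] = []
    a_ogs = sorted(og for og, f in family_of_og.items() if f == "A")
    for og in a_ogs:
        clusters.append(genes_by_og.get(og, []))
    b_members: list[str] = []
    for og in sorted(og for og, f in family_of_og.items() if f == "B"):
        b_members.extend(genes_by_og.get(og, []))
    clusters.append(b_members)
    for og in sorted(genes_by_og):
        if og not in family_of_og:
            clusters.append(genes_by_og[og])
    mcl_map = {
        gene: f"group_{i}"
        for i, cluster in enumerate(clusters)
        for gene in cluster
    }
    return clusters, mcl_map


def _truth_ledger(
    loci: Sequence[GeneLocus],
    family_of_og: dict[str, str],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], dict[str, frozenset[str]]]:
    by_chrom: dict[tuple[str, str], list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault((loc.species, loc.chromosome), []).append(loc)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.rank)

    windows: dict[str, frozenset[str]] = {}
    fam_genes: dict[str, list[GeneLocus]] = {}
    w = config.synteny_window
    for (sp, chrom), genes in by_chrom.items():
        for i, loc in enumerate(genes):
            og = loc.orthogroup or ""
            if og not in family_of_og:
                continue
            fam_genes.setdefault(og, []).append(loc)
            neigh = genes[max(0, i - w):i] + genes[i + 1:i + 1 + w]
            windows[loc.gene_id] = frozenset(
                g.orthogroup for g in neigh if g.orthogroup != og
            )

    pairs: set[tuple[str, str]] = set()
    k = config.min_shared_neighbors
    for og, members in fam_genes.items():
        members = sorted(members, key=lambda g: g.gene_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if a.species == b.species:
                    continue
                shared = windows[a.gene_id] & windows[b.gene_id]
                if len(shared) >= k:
                    pairs.add(canonical_pair(a.gene_id, b.gene_id))
    return sorted(pairs), windows


# ---------------------------------------------------------------------------
# detector emulation

def emit_detector_calls(
    dataset: SyntheticDataset,
    approach: str,
    sensitivity: float,
    fp_rate: float,
    rng: np.random.Generator,
) -> list[SyntenyPair]:
    """Thin the truth ledger at ``sensitivity`` and add false positives.

    False positives are drawn between non-collinear cross-species genes of
    the same homology group (orthogroup for OG approaches, MCL group for
    MCL approaches) whose neighbourhoods share at least one orthologue —
    borderline calls on partially degraded regions, which is where real
    collinearity detectors err; a pair with no residual context cannot be
    called. Cross-family spurious pairs cannot arise because detectors
    operate within homology matrices. The kept/injected pairs are recorded
    in the dataset event log.
    """
    if not 0 <= sensitivity <= 1:
        raise ValueError("sensitivity must be in [0, 1]")
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    truth = dataset.truth_pairs
    keep = rng.random(len(truth)) < sensitivity if truth else []
    grouping = dataset.og_map if approach.startswith("OG") else dataset.mcl_map
    species_of = {loc.gene_id: loc.species for loc in dataset.loci}

    calls: list[SyntenyPair] = []
    for (a, b), kept in zip(truth, keep):
        if kept:
            block = f"{grouping[a]}|{species_of[a]}|{species_of[b]}"
            calls.append(SyntenyPair(a, b, approach=approach, block_id=block))

    fp_pairs: list[tuple[str, str]] = []
    if fp_rate > 0:
        # borderline pairs only: just below the anchor threshold; a chain
        # detector cannot validate a 1-2 gene remnant
        near_miss = max(1, dataset.config.min_shared_neighbors - 2)
        truth_set = set(truth)
        members: dict[str, list[str]] = {}
        for loc in dataset.loci:
            if dataset.family_of_og.get(loc.orthogroup or "") is None:
                continue
            members.setdefault(grouping[loc.gene_id], []).append(loc.gene_id)
        for group in sorted(members):
            genes = sorted(members[group])
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    a, b = genes[i], genes[j]
                    if species_of[a] == species_of[b]:
                        continue
                    if canonical_pair(a, b) in truth_set:
                        continue
                    shared = (
                        dataset.windows.get(a, frozenset())
                        & dataset.windows.get(b, frozenset())
                    )
                    if len(shared) < near_miss:
                        continue
                    if rng.random() < fp_rate:
                        fp_pairs.append(canonical_pair(a, b))
                        calls.append(
                            SyntenyPair(
                                a, b, approach=approach,
                                block_id=f"fp|{group}",
                            )
                        )
    dataset.event_log.append(
        {
            "type": "detector",
            "approach": approach,
            "n_truth": len(truth),
            "n_truth_kept": int(np.sum(keep)) if len(truth) else 0,
            "false_positives": fp_pairs,
        }
    )
    return calls


# ---------------------------------------------------------------------------
# export

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write every pipeline input format plus the JSON truth ledger.

    Returns a manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["gff3"] = outdir / "genes.gff3"
    with open(paths["gff3"], "w") as fh:
        write_gene_positions(dataset.loci, fh)

    groups: dict[str, dict[str, list[str]]] = {}
    for loc in dataset.loci:
        groups.setdefault(loc.orthogroup, {}).setdefault(
            loc.species, []
        ).append(loc.gene_id)
    paths["orthogroups"] = outdir / "Orthogroups.tsv"
    with open(paths["orthogroups"], "w") as fh:
        write_orthogroups(groups, dataset.species, fh)

    paths["mcl"] = outdir / "clusters.mcl"
    with open(paths["mcl"], "w") as fh:
        write_mcl_clusters(dataset.mcl_clusters, fh)

    dialect_of = {"D1": "iadhore", "D2": "mcscanx"}
    ext_of = {"iadhore": "tsv", "mcscanx": "collinearity"}
    for approach in APPROACHES:
        dialect = dialect_of[approach[-2:]]
        path = outdir / f"{approach}.{ext_of[dialect]}"
        with open(path, "w") as fh:
            write_collinearity(dataset.detector_calls[approach], fh, dialect)
        paths[approach] = path

    paths["tree"] = outdir / "species_tree.nwk"
    paths["tree"].write_text(dataset.tree_newick + "\n")

    paths["truth"] = outdir / "truth_ledger.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "truth_pairs": [list(p) for p in dataset.truth_pairs],
                "family_of_og": dataset.family_of_og,
                "event_log": dataset.event_log,
            },
            fh,
            indent=1,
        )

    paths["config"] = outdir / "sim_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(dataset.config), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
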