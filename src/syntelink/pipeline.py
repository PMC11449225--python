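"""Configured, seeded, resumable end-to-end runs.

A run directory is produced from one YAML/JSON config: simulate (or read)
the inputs, build the weighted network, extract the core components,
decompose cliques, detect communities, profile component topology and
compare the two families' regression coefficients. A manifest records the
package version, the seeds, and input/output hashes per stage; a stage is
skipped on re-run when its outputs exist and its recorded input hashes
are unchanged, so deleting one stage's outputs regenerates only that
stage and everything downstream.

The single top-level seed fans out to per-stage sub-seeds so the
stochastic stages (simulation, clique restarts, bootstrap) are
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clique_decomposition, community_detection, network_build
from . import topology_compare
from .io_formats import (
    APPROACHES,
    read_collinearity,
    read_gene_positions,
    read_mcl_clusters,
    read_network,
    read_orthogroups,
    write_network,
)
from .synthetic_data import (
    FamilyParams,
    SimulationConfig,
    simulate_dataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())
            self.data.setdefault("stages", {})

    def stage_fresh(self, name: str, in_hashes: dict, outputs: list[Path]):
        rec = self.data["stages"].get(name)
        return (
            rec is not None
            and rec.get("inputs") == in_hashes
            and all(p.exists() for p in outputs)
        )

    def record(self, name: str, in_hashes: dict, outputs: list[Path]):
        self.data["stages"][name] = {
            "inputs": in_hashes,
            "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
        }
        self.save()

    def save(self):
        self.data["version"] = __version__
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _sim_config(block: Mapping[str, Any], seed: int) -> SimulationConfig:
    block = dict(block or {})
    for fam_key in ("family_a", "family_b"):
        if fam_key in block:
            block[fam_key] = FamilyParams(**block[fam_key])
    block.setdefault("seed", seed)
    if "wgd_branches" in block:
        block["wgd_branches"] = tuple(block["wgd_branches"])
    return SimulationConfig(**block)


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    outdir: str | Path | None = None,
) -> Path:
    """Execute all stages; returns the run directory.

    The config either contains a ``simulate:`` block (forwarded to
    :class:`SimulationConfig`) or an ``inputs:`` block with paths to a
    GFF3 file, Orthogroups.tsv, MCL clusters, the four per-approach
    collinearity files and a two-column orthogroup→family TSV.
    """
    cfg = _load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "syntelink_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = _Manifest(outdir / "manifest.json")
    manifest.data["seed"] = seed
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    logging.getLogger().addHandler(fh)
    try:
        return _run_stages(cfg, outdir, seed, manifest)
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()


def _run_stage(
    manifest: _Manifest,
    name: str,
    input_paths: list[Path],
    extra_inputs: dict,
    outputs: list[Path],
    fn: Callable[[], None],
) -> None:
    for p in input_paths:
        if not p.exists():
            raise FileNotFoundError(f"stage {name!r}: missing input {p}")
    in_hashes = {str(p): _sha256(p) for p in input_paths}
    in_hashes.update({k: str(v) for k, v in extra_inputs.items()})
    if manifest.stage_fresh(name, in_hashes, outputs):
        logger.info("stage %s: up to date, skipped", name)
        return
    logger.info("stage %s: running", name)
    fn()
    manifest.record(name, in_hashes, outputs)


def _run_stages(
    cfg: dict, outdir: Path, seed: int, manifest: _Manifest
) -> Path:
    data_dir = outdir / "data"
    net_cfg = cfg.get("network", {})
    clique_cfg = cfg.get("cliques", {})
    comm_cfg = cfg.get("communities", {})
    topo_cfg = cfg.get("topology", {})

    # --- stage: simulate (optional) ------------------------------------
    simulate_block = cfg.get("simulate")
    if simulate_block is not None or "inputs" not in cfg:
        sim_config = _sim_config(simulate_block or {}, seed)
        sim_outputs = [
            data_dir / "genes.gff3",
            data_dir / "Orthogroups.tsv",
            data_dir / "clusters.mcl",
            data_dir / "truth_ledger.json",
        ]

        def do_simulate():
            dataset = simulate_dataset(sim_config)
            write_dataset(dataset, data_dir)

        _run_stage(
            manifest, "simulate", [],
            {"config": json.dumps(dataclasses.asdict(sim_config),
                                  sort_keys=True)},
            sim_outputs, do_simulate,
        )
        inputs = {
            "gff": data_dir / "genes.gff3",
            "orthogroups": data_dir / "Orthogroups.tsv",
            "mcl": data_dir / "clusters.mcl",
            "collinearity": {
                "OGxD1": data_dir / "OGxD1.tsv",
                "MCLxD1": data_dir / "MCLxD1.tsv",
                "OGxD2": data_dir / "OGxD2.collinearity",
                "MCLxD2": data_dir / "MCLxD2.collinearity",
            },
            "family_map": data_dir / "truth_ledger.json",
        }
    else:
        raw = cfg["inputs"]
        inputs = {
            "gff": Path(raw["gff"]),
            "orthogroups": Path(raw["orthogroups"]),
            "mcl": Path(raw["mcl"]),
            "collinearity": {
                k: Path(v) for k, v in raw["collinearity"].items()
            },
            "family_map": Path(raw["family_map"]),
        }

    # --- stage: build ---------------------------------------------------
    net_path = outdir / "net.graphml"
    core_path = outdir / "core.graphml"
    build_inputs = [
        inputs["gff"], inputs["orthogroups"], inputs["mcl"],
        *inputs["collinearity"].values(), inputs["family_map"],
    ]

    def do_build():
        loci = read_gene_positions(inputs["gff"])
        og_map = read_orthogroups(inputs["orthogroups"])
        mcl_map = read_mcl_clusters(inputs["mcl"])
        family_of_og = _read_family_map(inputs["family_map"])
        loci = [
            dataclasses.replace(
                loc,
                orthogroup=og_map.get(loc.gene_id),
                mcl_group=mcl_map.get(loc.gene_id),
            )
            for loc in loci
        ]
        family_loci = [
            loc for loc in loci if (loc.orthogroup or "") in family_of_og
        ]
        family_map = {loc.gene_id: loc.orthogroup for loc in family_loci}
        nodes, gene_to_node = network_build.collapse_tandems(
            family_loci, family_map,
            tandem_max_gap=int(net_cfg.get("tandem_max_gap", 1)),
        )
        pair_lists = {}
        for approach, path in inputs["collinearity"].items():
            dialect = "iadhore" if approach.endswith("D1") else "mcscanx"
            pair_lists[approach] = read_collinearity(
                path, dialect, approach=approach
            )
        evidence = network_build.merge_evidence(pair_lists)
        net = network_build.build_network(
            nodes, gene_to_node, evidence,
            strict_both_detectors=bool(
                net_cfg.get("strict_both_detectors", False)
            ),
        )
        write_network(net, net_path)
        core = network_build.core_components(
            net, k=int(net_cfg.get("core_k", 6))
        )
        core_union = nx.union_all(core) if core else nx.Graph()
        write_network(core_union, core_path)

    _run_stage(
        manifest, "build", build_inputs,
        {"config": json.dumps(net_cfg, sort_keys=True)},
        [net_path, core_path], do_build,
    )

    # --- stage: cliques -------------------------------------------------
    cliques_json = outdir / "cliques.json"
    clique_matrix = outdir / "clique_matrix.tsv"

    def do_cliques():
        core = read_network(core_path)
        binar = clique_decomposition.binarize(core)
        decomps = []
        comps = sorted(nx.connected_components(binar), key=lambda c:
                       (-len(c), min(c)))
        for i, comp in enumerate(comps):
            decomps.append(
                clique_decomposition.best_of_restarts(
                    binar.subgraph(comp),
                    n_restarts=int(clique_cfg.get("restarts", 100)),
                    seed=seed * 1000 + i,
                    component_id=f"component{i}",
                )
            )
        species_of = {
            n: d.get("species", "") for n, d in core.nodes(data=True)
        }
        mat = clique_decomposition.clique_species_matrix(
            decomps, species_of,
            min_species=int(clique_cfg.get("min_species", 10)),
            min_members=int(clique_cfg.get("min_members", 10)),
        )
        mat.to_csv(clique_matrix, sep="\t")
        cliques_json.write_text(json.dumps([
            {
                "component_id": d.component_id,
                "restart_index": d.restart_index,
                "n_cliques": d.n_cliques,
                "n_cliques_reported": d.n_cliques_reported,
                "median_membership": d.median_membership,
                "cliques": [sorted(c) for c in d.cliques],
            }
            for d in decomps
        ], indent=1))

    _run_stage(
        manifest, "cliques", [core_path],
        {"config": json.dumps(clique_cfg, sort_keys=True), "seed": seed},
        [cliques_json, clique_matrix], do_cliques,
    )

    # --- stage: communities ----------------------------------------------
    communities_tsv = outdir / "communities.tsv"

    def do_communities():
        core = read_network(core_path)
        rows = []
        methods = comm_cfg.get(
            "methods", list(community_detection.COMMUNITY_METHODS)
        )
        for method in methods:
            res = community_detection.detect_communities(
                core, method, seed=seed
            )
            for node, comm in sorted(res.membership.items()):
                rows.append(
                    {"method": method, "node": node, "community": comm,
                     "modularity": res.modularity}
                )
        pd.DataFrame(rows).to_csv(communities_tsv, sep="\t", index=False)

    _run_stage(
        manifest, "communities", [core_path],
        {"config": json.dumps(comm_cfg, sort_keys=True), "seed": seed},
        [communities_tsv], do_communities,
    )

    # --- stage: topology --------------------------------------------------
    topology_tsv = outdir / "topology.tsv"
    comparison_tsv = outdir / "comparison.tsv"

    def do_topology():
        core = read_network(core_path)
        family_of_og = _read_family_map(inputs["family_map"])
        components = network_build.decompose_by_orthogroup(
            core, min_nodes=int(topo_cfg.get("min_component_nodes", 3))
        )
        records = []
        for comp in components:
            og = comp.graph["orthogroup"]
            records.append(
                topology_compare.component_topology(
                    comp,
                    component_id=f"{og}:{min(comp.nodes)}",
                    family=family_of_og.get(og, ""),
                )
            )
        rows = [
            {"component_id": r.component_id, "family": r.family,
             "n_nodes": r.n_nodes, "n_edges": r.n_edges, **r.parameters}
            for r in records
        ]
        pd.DataFrame(rows).to_csv(topology_tsv, sep="\t", index=False)

        rec_a = [r for r in records if r.family == "A"]
        rec_b = [r for r in records if r.family == "B"]
        if len(rec_a) >= 3 and len(rec_b) >= 3:
            n_boot = topo_cfg.get("n_boot")
            rng_a = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(11,))
            )
            rng_b = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(12,))
            )
            boot_a = topology_compare.bootstrap_coefficients(
                rec_a, n_boot=n_boot, rng=rng_a
            )
            boot_b = topology_compare.bootstrap_coefficients(
                rec_b, n_boot=n_boot, rng=rng_b
            )
            comparisons = topology_compare.compare_coefficients(
                boot_a, boot_b
            )
            pd.DataFrame(
                [dataclasses.asdict(c) for c in comparisons]
            ).to_csv(comparison_tsv, sep="\t", index=False)
        else:
            logger.info(
                "fewer than 3 components in a family; comparison skipped"
            )
            comparison_tsv.write_text(
                "parameter\tcoefficient\tt_statistic\twelch_df\t"
                "p_value\tadj_p_value\tsignificant\n"
            )

    _run_stage(
        manifest, "topology",
        [core_path, inputs["family_map"]],
        {"config": json.dumps(topo_cfg, sort_keys=True), "seed": seed},
        [topology_tsv, comparison_tsv], do_topology,
    )
    manifest.save()
    return outdir


def _read_family_map(path: Path) -> dict[str, str]:
    """Orthogroup→family map from a two-column TSV or a truth-ledger JSON."""
    if path.suffix == ".json":
        return json.loads(path.read_text())["family_of_og"]
    df = pd.read_csv(path, sep="\t", header=None, names=["og", "family"],
                     dtype=str, comment="#")
    return dict(zip(df.og, df.family))
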