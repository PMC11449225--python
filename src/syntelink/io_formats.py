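"""Readers and writers for the external formats the pipeline touches.

Fixed dialects:

* GFF3 gene features (1-based, inclusive coordinates). Because GFF3 has no
  species column, the species may be given as a ``species=`` attribute on each
  feature or as an argument to :func:`read_gene_positions`.
* OrthoFinder ``Orthogroups.tsv``: first column the orthogroup id, one column
  per species holding comma-separated gene ids.
* MCL cluster files: one cluster per line, whitespace-separated gene ids,
  clusters named ``group_<line index>`` (0-based).
* MCScanX ``.collinearity``: ``## Alignment`` block headers followed by
  ``block-idx:  geneA  geneB  score`` anchor lines.
* i-ADHoRe pair table: tab-separated with columns ``gene_x``, ``gene_y``,
  ``multiplicon``.
* Networks: GraphML (via networkx) or a plain ``node_a  node_b  weight`` TSV.

Synteny pairs are stored orientation-free: the two gene ids are kept in
lexicographic order. Strand is parsed and stored on loci but never enters
pair identity.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx
import pandas as pd

__all__ = [
    "GeneLocus",
    "SyntenyPair",
    "APPROACHES",
    "ParseError",
    "canonical_pair",
    "read_gene_positions",
    "write_gene_positions",
    "read_orthogroups",
    "write_orthogroups",
    "read_mcl_clusters",
    "write_mcl_clusters",
    "read_collinearity",
    "write_collinearity",
    "read_network",
    "write_network",
]

#: Clustering-source x detector combinations. D1 = i-ADHoRe, D2 = MCScanX;
#: OG = OrthoFinder orthogroups, MCL = Markov clustering groups.
APPROACHES = ("OGxD1", "OGxD2", "MCLxD1", "MCLxD2")


class ParseError(ValueError):
    """Malformed input; the message names the offending line number."""


@dataclass(frozen=True)
class GeneLocus:
    """One gene's genomic placement plus cluster memberships.

    ``rank`` is the 1-based ordinal position of the gene among the genes of
    its chromosome, sorted by ascending ``start`` (ties broken by gene id);
    all downstream order logic runs on ranks, not base pairs.
    """

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int = 0
    orthogroup: str | None = None
    mcl_group: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class SyntenyPair:
    """An orientation-free collinear gene pair from one detection approach."""

    gene_a: str
    gene_b: str
    approach: str | None = None
    block_id: str = ""

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered gene-id pair (undirected identity)."""
    return (a, b) if a <= b else (b, a)


def _as_lines(stream: TextIO | str | Path) -> Iterable[str]:
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            yield from fh
    else:
        yield from stream


def _parse_attributes(col: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gene_positions(
    stream: TextIO | str | Path,
    species: str | None = None,
    feature_type: str = "gene",
) -> list[GeneLocus]:
    """Parse ``gene`` features from a GFF3 stream into ranked loci.

    Ranks are assigned per chromosome by ascending start coordinate with a
    deterministic tie-break on gene id. A ``species=`` attribute on a feature
    overrides the ``species`` argument.

    Raises
    ------
    ParseError
        On a malformed line (names the line number), a duplicate gene id
        within one species, or a gene with no resolvable species.
    """
    raw: list[GeneLocus] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(_as_lines(stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            fields = line.split()
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: expected 9 GFF3 columns")
        if fields[2] != feature_type:
            continue
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        strand = fields[6]
        if strand not in ("+", "-"):
            raise ParseError(f"line {lineno}: strand must be + or -")
        attrs = _parse_attributes(fields[8])
        gene_id = attrs.get("ID") or attrs.get("Name")
        if gene_id is None:
            raise ParseError(f"line {lineno}: feature has no ID attribute")
        sp = attrs.get("species", species)
        if sp is None:
            raise ParseError(
                f"line {lineno}: no species attribute and no species argument"
            )
        if (sp, gene_id) in seen:
            raise ParseError(f"line {lineno}: duplicate gene id {gene_id!r}")
        seen.add((sp, gene_id))
        try:
            raw.append(
                GeneLocus(gene_id, sp, fields[0], start, end, strand)
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc

    out: list[GeneLocus] = []
    by_chrom: dict[tuple[str, str], list[GeneLocus]] = {}
    for loc in raw:
        by_chrom.setdefault((loc.species, loc.chromosome), []).append(loc)
    for key in sorted(by_chrom):
        genes = sorted(by_chrom[key], key=lambda g: (g.start, g.gene_id))
        for rank, loc in enumerate(genes, start=1):
            out.append(replace(loc, rank=rank))
    return out


def write_gene_positions(loci: Sequence[GeneLocus], stream: TextIO) -> None:
    """Write loci as GFF3 gene features carrying a ``species=`` attribute."""
    stream.write("##gff-version 3\n")
    for loc in loci:
        stream.write(
            f"{loc.chromosome}\tsyntelink\tgene\t{loc.start}\t{loc.end}\t.\t"
            f"{loc.strand}\t.\tID={loc.gene_id};species={loc.species}\n"
        )


def read_orthogroups(stream: TextIO | str | Path) -> dict[str, str]:
    """Read an OrthoFinder ``Orthogroups.tsv`` into a gene→orthogroup map."""
    df = pd.read_csv(_ensure_buffer(stream), sep="\t", dtype=str).fillna("")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        og = row.iloc[0]
        for cell in row.iloc[1:]:
            for gene in str(cell).split(","):
                gene = gene.strip()
                if not gene:
                    continue
                if gene in mapping and mapping[gene] != og:
                    raise ParseError(
                        f"gene {gene!r} assigned to both {mapping[gene]} and {og}"
                    )
                mapping[gene] = og
    return mapping


def write_orthogroups(
    groups: Mapping[str, Mapping[str, Sequence[str]]],
    species_order: Sequence[str],
    stream: TextIO,
) -> None:
    """Write ``{og: {species: [genes]}}`` in the Orthogroups.tsv dialect."""
    stream.write("Orthogroup\t" + "\t".join(species_order) + "\n")
    for og in sorted(groups):
        cells = [", ".join(groups[og].get(sp, [])) for sp in species_order]
        stream.write(og + "\t" + "\t".join(cells) + "\n")


def read_mcl_clusters(stream: TextIO | str | Path) -> dict[str, str]:
    """Read one-cluster-per-line MCL output into a gene→``group_<i>`` map."""
    mapping: dict[str, str] = {}
    for idx, line in enumerate(_as_lines(stream)):
        name = f"group_{idx}"
        for gene in line.split():
            if gene in mapping:
                raise ParseError(
                    f"line {idx + 1}: gene {gene!r} already in {mapping[gene]}"
                )
            mapping[gene] = name
    return mapping


def write_mcl_clusters(
    clusters: Sequence[Sequence[str]], stream: TextIO
) -> None:
    for members in clusters:
        stream.write("\t".join(members) + "\n")


def read_collinearity(
    stream: TextIO | str | Path,
    dialect: str,
    approach: str | None = None,
) -> list[SyntenyPair]:
    """Read collinear gene pairs in the ``mcscanx`` or ``iadhore`` dialect.

    Pairs are canonicalized and deduplicated (first block id wins);
    self-pairs are skipped with a warning. The approach tag is supplied by
    the caller, not read from the file.
    """
    if dialect == "mcscanx":
        return _read_mcscanx(stream, approach)
    if dialect == "iadhore":
        return _read_iadhore(stream, approach)
    raise ValueError(f"unknown collinearity dialect {dialect!r}")


def _read_mcscanx(
    stream: TextIO | str | Path, approach: str | None
) -> list[SyntenyPair]:
    pairs: dict[tuple[str, str], SyntenyPair] = {}
    block = ""
    for lineno, line in enumerate(_as_lines(stream), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("## Alignment"):
            tok = line.split()[2]
            block = tok.rstrip(":")
            continue
        if line.startswith("#"):
            continue
        if ":" not in line:
            raise ParseError(f"line {lineno}: expected 'idx: geneA geneB ...'")
        _, rest = line.split(":", 1)
        toks = rest.split()
        if len(toks) < 2:
            raise ParseError(f"line {lineno}: anchor line needs two gene ids")
        a, b = toks[0], toks[1]
        if a == b:
            warnings.warn(f"line {lineno}: self-pair {a!r} skipped")
            continue
        key = canonical_pair(a, b)
        if key not in pairs:
            pairs[key] = SyntenyPair(a, b, approach=approach, block_id=block)
    return list(pairs.values())


def _read_iadhore(
    stream: TextIO | str | Path, approach: str | None
) -> list[SyntenyPair]:
    df = pd.read_csv(_ensure_buffer(stream), sep="\t", dtype=str)
    needed = {"gene_x", "gene_y", "multiplicon"}
    if not needed.issubset(df.columns):
        raise ParseError(
            f"i-ADHoRe table must have columns {sorted(needed)}, "
            f"got {list(df.columns)}"
        )
    pairs: dict[tuple[str, str], SyntenyPair] = {}
    for row in df.itertuples(index=False):
        a, b = row.gene_x, row.gene_y
        if a == b:
            warnings.warn(f"self-pair {a!r} skipped")
            continue
        key = canonical_pair(a, b)
        if key not in pairs:
            pairs[key] = SyntenyPair(
                a, b, approach=approach, block_id=str(row.multiplicon)
            )
    return list(pairs.values())


def write_collinearity(
    pairs: Sequence[SyntenyPair], stream: TextIO, dialect: str
) -> None:
    """Emit pairs in one of the two detector dialects, grouped by block."""
    if dialect == "mcscanx":
        by_block: dict[str, list[SyntenyPair]] = {}
        for p in pairs:
            by_block.setdefault(p.block_id, []).append(p)
        for block in sorted(by_block):
            members = by_block[block]
            stream.write(
                f"## Alignment {block}: score=100.0 e_value=0 N={len(members)} "
                "plus\n"
            )
            for i, p in enumerate(members):
                stream.write(f"{block}-{i:3d}:\t{p.gene_a}\t{p.gene_b}\t  0\n")
    elif dialect == "iadhore":
        stream.write("gene_x\tgene_y\tmultiplicon\n")
        for p in pairs:
            stream.write(f"{p.gene_a}\t{p.gene_b}\t{p.block_id}\n")
    else:
        raise ValueError(f"unknown collinearity dialect {dialect!r}")


_NODE_ATTRS = ("species", "chromosome", "members", "orthogroup", "mcl_group")


def write_network(
    network: nx.Graph, path: str | Path, format: str = "graphml"
) -> None:
    """Write a weighted synteny network as GraphML or a TSV edge list.

    Node attributes are species, chromosome, comma-joined member gene ids,
    orthogroup and mcl_group; the only edge attribute is ``weight``. The
    TSV format stores edges only (columns node_a, node_b, weight).
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for n, data in network.nodes(data=True):
            attrs = {k: data[k] for k in _NODE_ATTRS if data.get(k) is not None}
            members = attrs.get("members")
            if members is not None and not isinstance(members, str):
                attrs["members"] = ",".join(members)
            g.add_node(n, **attrs)
        for a, b, data in network.edges(data=True):
            g.add_edge(a, b, weight=float(data.get("weight", 1.0)))
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b in sorted(map(tuple, map(sorted, network.edges()))):
                w = network.edges[a, b].get("weight", 1.0)
                fh.write(f"{a}\t{b}\t{w}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read back a network written by :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for n, data in g.nodes(data=True):
            if "members" in data and isinstance(data["members"], str):
                data = dict(data)
                data["members"] = tuple(data["members"].split(","))
            out.add_node(n, **data)
        for a, b, data in g.edges(data=True):
            out.add_edge(a, b, weight=float(data.get("weight", 1.0)))
        return out
    if format == "edge_tsv":
        out = nx.Graph()
        df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
        for row in df.itertuples(index=False):
            out.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        return out
    raise ValueError(f"unknown network format {format!r}")


def _ensure_buffer(stream: TextIO | str | Path):
    if isinstance(stream, (str, Path)):
        return stream
    if isinstance(stream, io.TextIOBase) or hasattr(stream, "read"):
        return stream
    raise TypeError(f"cannot read from {type(stream)!r}")
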