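"""Signed pathway topology: KGML parsing, influence matrices, global network merge.

A pathway is a directed graph whose edges carry a sign ``beta`` in {+1, -1}
(activation-like vs inhibition-like relations).  Pathways merge into a single
global network used for edge scoring; each pathway also yields a normalized
influence matrix ``B`` with ``B[i, j] = beta(j->i) / Nds(j)`` where ``Nds(j)``
counts the outgoing signed edges of gene ``j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree

import numpy as np

from .errors import EmptyPathwayError, KgmlParseError, ValidationError

logger = logging.getLogger(__name__)

#: Relation-subtype -> edge sign.  Subtypes absent from the table are dropped.
DEFAULT_WEIGHT_TABLE: dict[str, int] = {
    "activation": +1,
    "expression": +1,
    "inhibition": -1,
    "repression": -1,
}


@dataclass
class PathwayGraph:
    """One signed, directed pathway graph.

    ``edges`` holds ``(src, dst, beta, subtype)`` tuples with ``beta`` in
    {+1, -1}.  ``psize`` is the gene count and ``nds`` maps each gene with
    outgoing edges to its outgoing-edge count (the normalizer of the
    influence matrix).
    """

    pathway_id: str
    name: str
    nodes: frozenset[str]
    edges: tuple[tuple[str, str, int, str], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for src, dst, beta, subtype in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise ValidationError(
                    f"pathway {self.pathway_id}: edge ({src}, {dst}) has an "
                    "endpoint outside the node set"
                )
            if beta not in (-1, 1):
                raise ValidationError(
                    f"pathway {self.pathway_id}: beta must be +1 or -1, got {beta}"
                )
            key = (src, dst, subtype)
            if key in seen:
                raise ValidationError(
                    f"pathway {self.pathway_id}: duplicate edge {key}"
                )
            seen.add(key)

    @property
    def psize(self) -> int:
        return len(self.nodes)

    @property
    def nds(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for src, _, _, _ in self.edges:
            counts[src] = counts.get(src, 0) + 1
        return counts

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def signed_edge_set(self) -> frozenset[tuple[str, str, int]]:
        return frozenset((s, d, b) for s, d, b, _ in self.edges)


@dataclass
class PathwayCollection:
    """Ordered list of pathways plus the measured gene universe."""

    pathways: tuple[PathwayGraph, ...]
    gene_universe: frozenset[str]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValidationError("pathway ids must be unique")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> PathwayGraph:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def pathway_gene_union(self) -> frozenset[str]:
        genes: set[str] = set()
        for p in self.pathways:
            genes |= p.nodes
        return frozenset(genes)


@dataclass
class GlobalNetwork:
    """Deduplicated union of pathway edges with per-edge provenance."""

    edges: dict[tuple[str, str], tuple[int, str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    n_sign_conflicts: int = 0

    @property
    def edge_pairs(self) -> list[tuple[str, str]]:
        return list(self.edges)

    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for src, dst in self.edges:
            out.add(src)
            out.add(dst)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.edges)


def _strip_prefix(gene_id: str) -> str:
    """Drop a KEGG-style organism prefix like ``mmu:`` from a gene id."""
    _, sep, rest = gene_id.partition(":")
    return rest if sep else gene_id


def parse_kgml(
    path: str | Path,
    weight_table: Mapping[str, int] | None = None,
    strip_prefixes: bool = True,
) -> PathwayGraph:
    """Parse a KGML (KEGG XML) file into a :class:`PathwayGraph`.

    Entries of type ``gene`` become nodes; an entry naming k genes expands to
    k nodes, and a relation between two entries expands to the Cartesian
    product of their gene lists.  Group, compound and map entries are
    ignored.  Relation subtypes are mapped to signs through ``weight_table``
    (default :data:`DEFAULT_WEIGHT_TABLE`); subtypes absent from the table
    are dropped silently (the nodes are kept).
    """
    path = Path(path)
    table = dict(DEFAULT_WEIGHT_TABLE if weight_table is None else weight_table)
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise KgmlParseError(f"malformed KGML in {path.name}: {exc}") from exc
    root = tree.getroot()
    pathway_id = root.get("name", path.stem)
    if strip_prefixes:
        pathway_id = _strip_prefix(pathway_id)
    title = root.get("title", pathway_id)

    entry_genes: dict[str, list[str]] = {}
    nodes: set[str] = set()
    for entry in root.findall("entry"):
        if entry.get("type") != "gene":
            continue
        raw = (entry.get("name") or "").split()
        genes = [_strip_prefix(g) if strip_prefixes else g for g in raw]
        genes = [g for g in genes if g]
        if not genes:
            continue
        entry_genes[entry.get("id", "")] = genes
        nodes.update(genes)
    if not nodes:
        raise EmptyPathwayError(f"{path.name}: no gene entries")

    edges: list[tuple[str, str, int, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for relation in root.findall("relation"):
        src_entry = relation.get("entry1", "")
        dst_entry = relation.get("entry2", "")
        if src_entry not in entry_genes or dst_entry not in entry_genes:
            continue
        for subtype_el in relation.findall("subtype"):
            subtype = subtype_el.get("name", "")
            if subtype not in table:
                continue
            beta = int(table[subtype])
            for src in entry_genes[src_entry]:
                for dst in entry_genes[dst_entry]:
                    key = (src, dst, subtype)
                    if key in seen:
                        continue
                    seen.add(key)
                    edges.append((src, dst, beta, subtype))

    return PathwayGraph(
        pathway_id=pathway_id,
        name=title,
        nodes=frozenset(nodes),
        edges=tuple(edges),
    )


def parse_kgml_directory(
    directory: str | Path,
    weight_table: Mapping[str, int] | None = None,
    gene_universe: Iterable[str] | None = None,
    strip_prefixes: bool = True,
) -> PathwayCollection:
    """Parse every ``*.xml``/``*.kgml`` file in a directory, sorted by name."""
    directory = Path(directory)
    files = sorted(
        f for f in directory.iterdir() if f.suffix.lower() in {".xml", ".kgml"}
    )
    if not files:
        raise KgmlParseError(f"no KGML files found in {directory}")
    pathways = tuple(
        parse_kgml(f, weight_table=weight_table, strip_prefixes=strip_prefixes)
        for f in files
    )
    universe: set[str] = set(gene_universe or ())
    for p in pathways:
        universe |= p.nodes
    return PathwayCollection(pathways=pathways, gene_universe=frozenset(universe))


def build_beta_matrix(
    pathway: PathwayGraph, node_order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Normalized influence matrix ``B`` over the pathway's nodes.

    ``B[i, j] = beta(j -> i) / Nds(j)`` for each edge ``j -> i``, zero
    elsewhere, so every column with outgoing edges has absolute sum 1.
    Returns the matrix together with the node order used for its axes.
    """
    order = list(node_order) if node_order is not None else pathway.sorted_nodes()
    if set(order) != set(pathway.nodes):
        raise ValidationError("node_order must be a permutation of pathway.nodes")
    index = {g: i for i, g in enumerate(order)}
    n = len(order)
    B = np.zeros((n, n), dtype=float)
    nds = pathway.nds
    for src, dst, beta, _ in pathway.edges:
        B[index[dst], index[src]] += beta / nds[src]
    return B, order


def merge_global_network(collection: PathwayCollection) -> GlobalNetwork:
    """Union of all pathway edges, deduplicated on the (src, dst) pair.

    When the same pair carries conflicting signs across pathways, the sign
    of the first-listed pathway wins and a warning is logged; provenance
    keeps every contributing pathway either way.
    """
    if len(collection) == 0:
        raise ValidationError("cannot merge an empty pathway collection")
    net = GlobalNetwork()
    prov: dict[tuple[str, str], list[str]] = {}
    for pathway in collection:
        for src, dst, beta, subtype in pathway.edges:
            pair = (src, dst)
            if pair not in net.edges:
                net.edges[pair] = (beta, subtype)
                prov[pair] = [pathway.pathway_id]
            else:
                if pathway.pathway_id not in prov[pair]:
                    prov[pair].append(pathway.pathway_id)
                kept_beta, _ = net.edges[pair]
                if kept_beta != beta:
                    net.n_sign_conflicts += 1
                    logger.warning(
                        "sign conflict on edge %s->%s: keeping %+d from %s, "
                        "ignoring %+d from %s",
                        src, dst, kept_beta, prov[pair][0], beta,
                        pathway.pathway_id,
                    )
    net.provenance = {pair: tuple(ids) for pair, ids in prov.items()}
    return net


def write_graph_summary_tsv(collection: PathwayCollection, path: str | Path) -> None:
    """One row per pathway: pathway_id, name, pSize, n_edges."""
    lines = ["pathway_id\tname\tpSize\tn_edges"]
    for p in collection:
        lines.append(f"{p.pathway_id}\t{p.name}\t{p.psize}\t{len(p.edges)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list_tsv(net: GlobalNetwork, path: str | Path) -> None:
    """One row per global-network edge: src, dst, beta, subtype, pathways."""
    lines = ["src\tdst\tbeta\tsubtype\tpathways"]
    for (src, dst), (beta, subtype) in sorted(net.edges.items()):
        pathways = ",".join(net.provenance.get((src, dst), ()))
        lines.append(f"{src}\t{dst}\t{beta:+d}\t{subtype}\t{pathways}")
    Path(path).write_text("\n".join(lines) + "\n")
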