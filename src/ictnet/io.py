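"""Readers and writers for the network formats.

Three on-disk representations are supported, all plain text, UTF-8,
tab-delimited, with ``.`` standing for a missing value:

``tsv_pair``
    ``nodes.tsv`` (id, type, label) + ``edges.tsv`` (source, target, type,
    weight, directed, pubmed).  This is the canonical lossless format: a
    write/read round trip reproduces the network exactly (weights are
    serialized with 17 significant digits, i.e. bit-exact for doubles).
``sif``
    ``network.sif`` with ``source<TAB>token<TAB>target`` lines (tokens pp,
    pd, dg, dt, tg, drg; isolated nodes as bare lines), plus sidecar
    attribute tables ``node_attributes.tsv`` and ``edge_attributes.tsv``
    carrying node classes, weights and PubMed provenance, since SIF itself
    has no attribute channel.
``graphml``
    ``network.graphml`` with typed attributes (node_type, label, edge_type,
    weight, directed, pubmed), for Cytoscape interoperability.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import DuplicateEdgeError, FormatError, ReferentialIntegrityError
from .model import (
    DIRECTED_EDGE_TYPES,
    SIF_TOKENS,
    SIF_TOKENS_INV,
    Edge,
    EdgeType,
    HeteroNetwork,
    Node,
    NodeType,
)

FORMATS = ("tsv_pair", "sif", "graphml")

NODE_COLUMNS = ("id", "type", "label")
EDGE_COLUMNS = ("source", "target", "type", "weight", "directed", "pubmed")

MISSING = "."


def _fmt_weight(w: float) -> str:
    return format(w, ".17g")


def _split_row(line: str, n_cols: int, path: str, lineno: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != n_cols:
        raise FormatError(
            f"{path}:{lineno}: expected {n_cols} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def read_node_table(path: str | os.PathLike) -> list[Node]:
    """Parse a node TSV (header ``id  type  label``) into :class:`Node`s."""
    path = os.fspath(path)
    nodes: list[Node] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if tuple(header.rstrip("\n").split("\t")) != NODE_COLUMNS:
            raise FormatError(
                f"{path}:1: expected header {'/'.join(NODE_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            nid, ntype, label = _split_row(line, 3, path, lineno)
            try:
                node_type = NodeType(ntype)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unknown node type {ntype!r}"
                ) from None
            if nid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate node id {nid!r}")
            seen.add(nid)
            nodes.append(Node(nid, node_type, label))
    return nodes


def read_edge_table(
    path: str | os.PathLike, nodes: Iterable[Node] | Mapping[str, Node]
) -> list[Edge]:
    """Parse an edge TSV against a node set.

    Raises a format error (naming the line) on unknown edge types or a
    directedness flag inconsistent with the edge class, a
    referential-integrity error for edges whose endpoints are absent, and a
    duplicate error on repeated (source, target, type) triples.
    """
    path = os.fspath(path)
    if isinstance(nodes, Mapping):
        node_map = dict(nodes)
    else:
        node_map = {n.id: n for n in nodes}
    edges: list[Edge] = []
    seen: set[tuple[str, str, EdgeType]] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if tuple(header.rstrip("\n").split("\t")) != EDGE_COLUMNS:
            raise FormatError(
                f"{path}:1: expected header {'/'.join(EDGE_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            src, tgt, etype, weight, directed, pubmed = _split_row(
                line, 6, path, lineno
            )
            try:
                edge_type = EdgeType(etype)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unknown edge type {etype!r}"
                ) from None
            want_directed = edge_type in DIRECTED_EDGE_TYPES
            if directed.lower() not in ("true", "false"):
                raise FormatError(
                    f"{path}:{lineno}: directed must be true/false, "
                    f"got {directed!r}"
                )
            if (directed.lower() == "true") != want_directed:
                raise FormatError(
                    f"{path}:{lineno}: edge type {etype} must have "
                    f"directed={str(want_directed).lower()}"
                )
            w = 1.0 if weight == MISSING else _parse_float(weight, path, lineno)
            provenance = () if pubmed in (MISSING, "") else tuple(
                pubmed.split(";")
            )
            for nid in (src, tgt):
                if nid not in node_map:
                    raise ReferentialIntegrityError(
                        f"{path}:{lineno}: edge references absent node {nid!r}"
                    )
            edge = Edge(src, tgt, edge_type, w, provenance)
            if edge.key in seen:
                raise DuplicateEdgeError(
                    f"{path}:{lineno}: duplicate edge "
                    f"({src}, {tgt}, {etype})"
                )
            seen.add(edge.key)
            edges.append(edge)
    return edges


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: invalid weight {token!r}"
        ) from None


# ---------------------------------------------------------------------------
# writing

def write_network(
    network: HeteroNetwork, path: str | os.PathLike, fmt: str = "tsv_pair"
) -> Path:
    """Write ``network`` under directory ``path`` in the given format.

    Returns the output directory.  ``tsv_pair`` is lossless; the other two
    formats carry the same information via attribute tables/fields.
    """
    if fmt not in FORMATS:
        raise FormatError(f"unknown format {fmt!r}; choose from {FORMATS}")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv_pair":
        _write_tsv_pair(network, out)
    elif fmt == "sif":
        _write_sif(network, out)
    else:
        _write_graphml(network, out)
    return out


def _write_tsv_pair(network: HeteroNetwork, out: Path) -> None:
    with open(out / "nodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(NODE_COLUMNS) + "\n")
        for node in network.nodes:
            fh.write(f"{node.id}\t{node.node_type.value}\t{node.label}\n")
    with open(out / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in network.edges:
            pubmed = ";".join(e.provenance) if e.provenance else MISSING
            fh.write(
                f"{e.source}\t{e.target}\t{e.edge_type.value}\t"
                f"{_fmt_weight(e.weight)}\t{str(e.directed).lower()}\t"
                f"{pubmed}\n"
            )


def _write_sif(network: HeteroNetwork, out: Path) -> None:
    touched = {e.source for e in network.edges} | {
        e.target for e in network.edges
    }
    with open(out / "network.sif", "w", encoding="utf-8") as fh:
        for e in network.edges:
            fh.write(f"{e.source}\t{SIF_TOKENS[e.edge_type]}\t{e.target}\n")
        for node in network.nodes:  # SIF convention: bare isolated nodes
            if node.id not in touched:
                fh.write(f"{node.id}\n")
    with open(out / "node_attributes.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\tnode_type\tlabel\n")
        for node in network.nodes:
            fh.write(f"{node.id}\t{node.node_type.value}\t{node.label}\n")
    with open(out / "edge_attributes.tsv", "w", encoding="utf-8") as fh:
        fh.write("source\tinteraction\ttarget\tweight\tpubmed\n")
        for e in network.edges:
            pubmed = ";".join(e.provenance) if e.provenance else MISSING
            fh.write(
                f"{e.source}\t{SIF_TOKENS[e.edge_type]}\t{e.target}\t"
                f"{_fmt_weight(e.weight)}\t{pubmed}\n"
            )


def _write_graphml(network: HeteroNetwork, out: Path) -> None:
    g = nx.MultiDiGraph()
    for node in network.nodes:
        g.add_node(node.id, node_type=node.node_type.value, label=node.label)
    for e in network.edges:
        g.add_edge(
            e.source,
            e.target,
            key=e.edge_type.value,
            edge_type=e.edge_type.value,
            weight=_fmt_weight(e.weight),
            directed=e.directed,
            pubmed=";".join(e.provenance),
        )
    nx.write_graphml(g, out / "network.graphml")


# ---------------------------------------------------------------------------
# reading whole networks

def read_network(path: str | os.PathLike, fmt: str = "tsv_pair") -> HeteroNetwork:
    """Read a network previously written by :func:`write_network`."""
    if fmt not in FORMATS:
        raise FormatError(f"unknown format {fmt!r}; choose from {FORMATS}")
    src = Path(path)
    if fmt == "tsv_pair":
        nodes = read_node_table(src / "nodes.tsv")
        edges = read_edge_table(src / "edges.tsv", nodes)
        return HeteroNetwork(nodes, edges)
    if fmt == "sif":
        return _read_sif(src)
    return _read_graphml(src)


def _read_sif(src: Path) -> HeteroNetwork:
    nodes: list[Node] = []
    with open(src / "node_attributes.tsv", encoding="utf-8") as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            nid, ntype, label = _split_row(
                line, 3, str(src / "node_attributes.tsv"), lineno
            )
            nodes.append(Node(nid, NodeType(ntype), label))
    net = HeteroNetwork(nodes)
    with open(src / "edge_attributes.tsv", encoding="utf-8") as fh:
        fh.readline()
        path = str(src / "edge_attributes.tsv")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            s, token, t, weight, pubmed = _split_row(line, 5, path, lineno)
            if token not in SIF_TOKENS_INV:
                raise FormatError(
                    f"{path}:{lineno}: unknown interaction token {token!r}"
                )
            provenance = () if pubmed == MISSING else tuple(pubmed.split(";"))
            net.add_edge(
                Edge(
                    s,
                    t,
                    SIF_TOKENS_INV[token],
                    _parse_float(weight, path, lineno),
                    provenance,
                )
            )
    return net


def _read_graphml(src: Path) -> HeteroNetwork:
    g = nx.read_graphml(src / "network.graphml")
    net = HeteroNetwork()
    for nid, data in sorted(g.nodes(data=True)):
        net.add_node(Node(nid, NodeType(data["node_type"]), data["label"]))
    for s, t, data in g.edges(data=True):
        pubmed = data.get("pubmed", "")
        provenance = tuple(pubmed.split(";")) if pubmed else ()
        net.add_edge(
            Edge(
                s,
                t,
                EdgeType(data["edge_type"]),
                float(data["weight"]),
                provenance,
            )
        )
    return net
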