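"""Typed heterogeneous-network data model.

The central object is :class:`HeteroNetwork`, a multi-partite graph over four
node classes (gene, disease, tissue, drug) joined by six type-constrained edge
classes.  Genes, SNPs and proteins collapse onto a single ``gene`` node class:
SNPs are resolved to genes during assembly and gene products carry the
interaction layers, so the graph stays 4-partite.

Invariants enforced at mutation time:

* node ids are unique; a node's class is immutable;
* every edge endpoint exists, and the endpoint classes match the edge class
  (a ``disease_gene`` edge joins exactly one disease and one gene, ...);
* only ``protein_dna`` (TF -> target) edges are directed;
* edge weights are non-negative (``disease_gene`` weights are -log10 p);
* no duplicate (source, target, edge_type) triples — undirected edges are
  canonicalized with lexicographically ordered endpoints so duplicate
  detection is order-insensitive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import (
    DomainError,
    DuplicateEdgeError,
    LookupMissError,
    ReferentialIntegrityError,
)


class NodeType(str, enum.Enum):
    GENE = "gene"
    DISEASE = "disease"
    TISSUE = "tissue"
    DRUG = "drug"


class EdgeType(str, enum.Enum):
    DISEASE_GENE = "disease_gene"
    PROTEIN_PROTEIN = "protein_protein"
    PROTEIN_DNA = "protein_dna"
    DISEASE_TISSUE = "disease_tissue"
    TISSUE_GENE = "tissue_gene"
    DRUG_GENE = "drug_gene"


#: Node classes each edge class may join; (source, target) order is
#: significant only for directed edge classes.
EDGE_ENDPOINTS: dict[EdgeType, tuple[NodeType, NodeType]] = {
    EdgeType.DISEASE_GENE: (NodeType.DISEASE, NodeType.GENE),
    EdgeType.PROTEIN_PROTEIN: (NodeType.GENE, NodeType.GENE),
    EdgeType.PROTEIN_DNA: (NodeType.GENE, NodeType.GENE),
    EdgeType.DISEASE_TISSUE: (NodeType.DISEASE, NodeType.TISSUE),
    EdgeType.TISSUE_GENE: (NodeType.TISSUE, NodeType.GENE),
    EdgeType.DRUG_GENE: (NodeType.DRUG, NodeType.GENE),
}

DIRECTED_EDGE_TYPES = frozenset({EdgeType.PROTEIN_DNA})

#: Fixed SIF interaction tokens.  SIF has no attribute channel, so the mapping
#: must be deterministic and stable across versions.
SIF_TOKENS: dict[EdgeType, str] = {
    EdgeType.PROTEIN_PROTEIN: "pp",
    EdgeType.PROTEIN_DNA: "pd",
    EdgeType.DISEASE_GENE: "dg",
    EdgeType.DISEASE_TISSUE: "dt",
    EdgeType.TISSUE_GENE: "tg",
    EdgeType.DRUG_GENE: "drg",
}
SIF_TOKENS_INV = {v: k for k, v in SIF_TOKENS.items()}

#: Gene-gene interaction layer (the substrate for neighborhood expansion and
#: random-walk prioritization).
GENE_LAYER_EDGE_TYPES = frozenset(
    {EdgeType.PROTEIN_PROTEIN, EdgeType.PROTEIN_DNA}
)


@dataclass(frozen=True)
class Node:
    """A typed network node; ``label`` defaults to the id."""

    id: str
    node_type: NodeType
    label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DomainError("node id must be a non-empty string")
        object.__setattr__(self, "id", str(self.id))
        if not isinstance(self.node_type, NodeType):
            object.__setattr__(self, "node_type", NodeType(self.node_type))
        object.__setattr__(self, "label", str(self.label) or self.id)


@dataclass(frozen=True)
class Edge:
    """A typed edge.

    Undirected edges are stored with endpoints in lexicographic order so the
    (source, target, edge_type) key is canonical.  ``provenance`` holds PubMed
    id strings (possibly empty).  Direction is a function of the edge class:
    only ``protein_dna`` edges are directed.
    """

    source: str
    target: str
    edge_type: EdgeType
    weight: float = 1.0
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", str(self.source))
        object.__setattr__(self, "target", str(self.target))
        if not isinstance(self.edge_type, EdgeType):
            object.__setattr__(self, "edge_type", EdgeType(self.edge_type))
        if not (self.weight >= 0.0):
            raise DomainError(
                f"edge weight must be >= 0, got {self.weight!r} for "
                f"{self.source}-{self.target}"
            )
        object.__setattr__(self, "weight", float(self.weight))
        object.__setattr__(self, "provenance", tuple(self.provenance))
        if not self.directed and self.source > self.target:
            src, tgt = self.target, self.source
            object.__setattr__(self, "source", src)
            object.__setattr__(self, "target", tgt)

    @property
    def directed(self) -> bool:
        return self.edge_type in DIRECTED_EDGE_TYPES

    @property
    def key(self) -> tuple[str, str, EdgeType]:
        return (self.source, self.target, self.edge_type)


class HeteroNetwork:
    """Multi-partite network of typed nodes and type-constrained edges."""

    def __init__(self, nodes: Iterable[Node] = (), edges: Iterable[Edge] = ()):
        self._nodes: dict[str, Node] = {}
        self._edges: dict[tuple[str, str, EdgeType], Edge] = {}
        for node in nodes:
            self.add_node(node)
        for edge in edges:
            self.add_edge(edge)

    # -- mutation ---------------------------------------------------------

    def add_node(self, node: Node) -> None:
        existing = self._nodes.get(node.id)
        if existing is not None:
            if existing != node:
                raise DomainError(
                    f"node id {node.id!r} already present with different "
                    f"type or label"
                )
            return
        self._nodes[node.id] = node

    def add_edge(self, edge: Edge, *, skip_duplicate: bool = False) -> None:
        if edge.key in self._edges:
            if skip_duplicate:
                return
            raise DuplicateEdgeError(
                f"duplicate edge ({edge.source}, {edge.target}, "
                f"{edge.edge_type.value})"
            )
        self._check_endpoints(edge)
        self._edges[edge.key] = edge

    def _check_endpoints(self, edge: Edge) -> None:
        for nid in (edge.source, edge.target):
            if nid not in self._nodes:
                raise ReferentialIntegrityError(
                    f"edge ({edge.source}, {edge.target}, "
                    f"{edge.edge_type.value}) references absent node {nid!r}"
                )
        want = EDGE_ENDPOINTS[edge.edge_type]
        got = (
            self._nodes[edge.source].node_type,
            self._nodes[edge.target].node_type,
        )
        ok = got == want if edge.directed else sorted(got) == sorted(want)
        if not ok:
            raise ReferentialIntegrityError(
                f"edge type {edge.edge_type.value} cannot join node types "
                f"({got[0].value}, {got[1].value})"
            )
        if edge.source == edge.target and edge.edge_type not in (
            EdgeType.PROTEIN_PROTEIN,
            EdgeType.PROTEIN_DNA,
        ):
            raise ReferentialIntegrityError(
                f"self-edge not allowed for type {edge.edge_type.value}"
            )

    # -- access -----------------------------------------------------------

    @property
    def n(self) -> int:
        """Node count (the n of the O(t n^2) propagation bound)."""
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise LookupMissError(f"unknown node id {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    @property
    def nodes(self) -> list[Node]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    @property
    def node_ids(self) -> list[str]:
        return sorted(self._nodes)

    @property
    def edges(self) -> list[Edge]:
        return [self._edges[k] for k in sorted(self._edges, key=_edge_sort_key)]

    def nodes_of_type(self, node_type: NodeType) -> list[Node]:
        node_type = NodeType(node_type)
        return [n for n in self.nodes if n.node_type == node_type]

    def edges_of_type(self, *edge_types: EdgeType) -> list[Edge]:
        wanted = {EdgeType(t) for t in edge_types}
        return [e for e in self.edges if e.edge_type in wanted]

    def has_edge(self, source: str, target: str, edge_type: EdgeType) -> bool:
        probe = Edge(source, target, EdgeType(edge_type))
        return probe.key in self._edges

    def copy(self) -> "HeteroNetwork":
        out = HeteroNetwork()
        out._nodes = dict(self._nodes)
        out._edges = dict(self._edges)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeteroNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"HeteroNetwork(n={self.n}, edges={self.n_edges})"

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """Re-check every structural invariant; return a list of warnings.

        Raises on any hard violation (dangling endpoint, type mismatch);
        self-interactions on the gene layer are legal but flagged.
        """
        warnings: list[str] = []
        for key, edge in self._edges.items():
            if key != edge.key:
                raise ReferentialIntegrityError(
                    f"edge stored under stale key {key!r}"
                )
            self._check_endpoints(edge)
            if edge.source == edge.target:
                warnings.append(
                    f"self-interaction {edge.source} ({edge.edge_type.value})"
                )
        return warnings


def _edge_sort_key(key: tuple[str, str, EdgeType]) -> tuple[str, str, str]:
    source, target, edge_type = key
    return (source, target, edge_type.value)


def induced_subgraph(
    network: HeteroNetwork, node_ids: Iterable[str]
) -> HeteroNetwork:
    """Subnetwork on ``node_ids`` with every edge whose endpoints both remain.

    Raises :class:`LookupMissError` for ids absent from ``network``.
    """
    keep = set(node_ids)
    for nid in keep:
        if nid not in network:
            raise LookupMissError(f"unknown node id {nid!r}")
    out = HeteroNetwork()
    for node in network.nodes:
        if node.id in keep:
            out.add_node(node)
    for edge in network.edges:
        if edge.source in keep and edge.target in keep:
            out.add_edge(edge)
    return out
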