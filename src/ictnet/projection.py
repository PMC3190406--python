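"""Bipartite similarity projection.

Collapses indirect connections in a bi-partite slice of the network: two
nodes of the projected class (e.g. diseases) are joined when they share at
least one neighbor of the intermediate class (e.g. genes), with edge weight
equal to the number of shared neighbors.  Edge weights on the underlying
bipartite edges are ignored — presence/absence only.  ``normalized_weight``
rescales by the maximum shared count, for color mapping by any renderer.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations

from .errors import DomainError
from .model import EdgeType, HeteroNetwork, NodeType

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityEdge:
    u: str
    v: str
    weight: float  # shared-neighbor count (int-valued) or Jaccard index
    normalized_weight: float

    def __post_init__(self) -> None:
        if self.u >= self.v:
            raise DomainError("similarity edge endpoints must satisfy u < v")


@dataclass(frozen=True)
class SimilarityNetwork:
    node_type: NodeType
    nodes: tuple[str, ...]
    edges: tuple[SimilarityEdge, ...]

    def weight(self, u: str, v: str) -> float:
        """Shared-neighbor weight for a pair (0 when no edge); symmetric."""
        if u > v:
            u, v = v, u
        for e in self.edges:
            if e.u == u and e.v == v:
                return e.weight
        return 0.0


def project(
    network: HeteroNetwork,
    project_type: NodeType,
    via_type: NodeType,
    via_edge_type: EdgeType,
    jaccard: bool = False,
) -> SimilarityNetwork:
    """Project the ``via_edge_type`` bipartite layer onto ``project_type``.

    For every unordered pair (u, v) of projected nodes the weight is the
    number of ``via_type`` neighbors they share through ``via_edge_type``;
    pairs sharing nothing get no edge.  With ``jaccard=True`` the weight is
    the Jaccard index of the two neighbor sets instead.  No self-edges are
    produced and the result is symmetric by construction.
    """
    project_type = NodeType(project_type)
    via_type = NodeType(via_type)
    via_edge_type = EdgeType(via_edge_type)
    if project_type == via_type:
        raise DomainError("projected and intermediate node types must differ")

    neighbors: dict[str, set[str]] = defaultdict(set)
    n_via_edges = 0
    for e in network.edges_of_type(via_edge_type):
        src_t = network.node(e.source).node_type
        tgt_t = network.node(e.target).node_type
        if {src_t, tgt_t} != {project_type, via_type}:
            continue
        proj, via = (
            (e.source, e.target) if src_t == project_type else (e.target, e.source)
        )
        neighbors[proj].add(via)
        n_via_edges += 1
    if n_via_edges == 0:
        logger.warning(
            "no %s edges between %s and %s nodes: empty similarity network",
            via_edge_type.value,
            project_type.value,
            via_type.value,
        )

    shared: dict[tuple[str, str], int] = defaultdict(int)
    for projs in _invert(neighbors).values():
        for u, v in combinations(sorted(projs), 2):
            shared[(u, v)] += 1

    weights: dict[tuple[str, str], float]
    if jaccard:
        weights = {
            pair: count / len(neighbors[pair[0]] | neighbors[pair[1]])
            for pair, count in shared.items()
        }
    else:
        weights = dict(shared)

    max_w = max(weights.values(), default=0.0)
    edges = tuple(
        SimilarityEdge(u, v, w, w / max_w)
        for (u, v), w in sorted(weights.items())
    )
    nodes = tuple(n.id for n in network.nodes_of_type(project_type))
    return SimilarityNetwork(project_type, nodes, edges)


def _invert(neighbors: dict[str, set[str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = defaultdict(set)
    for proj, vias in neighbors.items():
        for via in vias:
            out[via].add(proj)
    return out


def write_similarity(
    simnet: SimilarityNetwork, path: str | os.PathLike
) -> None:
    """Edge TSV: u, v, shared_count, normalized_weight."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write("u\tv\tshared_count\tnormalized_weight\n")
        for e in simnet.edges:
            weight = (
                str(int(e.weight)) if e.weight == int(e.weight) else repr(e.weight)
            )
            fh.write(f"{e.u}\t{e.v}\t{weight}\t{e.normalized_weight:.6g}\n")
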