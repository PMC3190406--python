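import math

import numpy as np
import pytest

from ictnet.model import Edge, EdgeType, HeteroNetwork, Node, NodeType


def make_network(node_specs, edge_specs):
    """node_specs: (id, type); edge_specs: (src, tgt, type[, weight[, pubmed]])."""
    net = HeteroNetwork()
    for nid, ntype in node_specs:
        net.add_node(Node(nid, NodeType(ntype)))
    for spec in edge_specs:
        src, tgt, etype = spec[:3]
        weight = spec[3] if len(spec) > 3 else 1.0
        provenance = tuple(spec[4]) if len(spec) > 4 else ()
        net.add_edge(Edge(src, tgt, EdgeType(etype), weight, provenance))
    return net


def gene_path(n):
    """Path graph G1-G2-...-Gn on gene nodes (protein_protein edges)."""
    genes = [f"G{i}" for i in range(1, n + 1)]
    return make_network(
        [(g, "gene") for g in genes],
        [(genes[i], genes[i + 1], "protein_protein") for i in range(n - 1)],
    )


def random_gene_network(rng, n_nodes, edge_prob):
    """Random undirected PPI network over gene nodes; isolated nodes allowed."""
    genes = [f"G{i:03d}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((genes[i], genes[j], "protein_protein"))
    return make_network([(g, "gene") for g in genes], edges), genes


def chi2_sf_even_df(x, k):
    """Closed-form chi-square upper tail for even df = 2k.

    P(X > x) = exp(-x/2) * sum_{i<k} (x/2)^i / i!  -- an oracle independent
    of the implementation's distribution routines.
    """
    half = x / 2.0
    term = 1.0
    total = 1.0
    for i in range(1, k):
        term *= half / i
        total += term
    return math.exp(-half) * total


def fixed_point_solve(w, p0, r):
    """Dense closed-form fixed point p = r (I - (1-r) W)^-1 p0."""
    w = np.asarray(w.todense() if hasattr(w, "todense") else w, dtype=float)
    n = w.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1.0 - r) * w, np.asarray(p0))


@pytest.fixture
def rng():
    return np.random.default_rng(20110926)
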