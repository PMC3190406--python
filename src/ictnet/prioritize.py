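"""Candidate-gene prioritization by network propagation.

Both prioritizers iterate the same update

    p(t+1) = (1 - r) W p(t) + r p0

where W is a degree-normalized adjacency operator, p0 is the restart/prior
vector and r in [0, 1] is the restart ratio: the probability per time step
that the walker jumps back to its starting distribution.  Small r lets the
walk reach far into the network; at r = 1 the walker is trapped at the
starting nodes and the scores equal p0 exactly.  For r > 0 the iteration is
a contraction (spectral radius of (1-r)W is below 1 in both normalization
modes), so it converges to the unique fixed point
p* = r (I - (1-r)W)^-1 p0.

*Random walk with restarts* runs on the gene-gene interaction layer only,
with p0 uniform over the "associated" genes (those whose disease-gene weight
passes the user threshold); every other gene in the layer is a "candidate"
ranked by its converged score.

*Extended PRINCE* propagates over the entire heterogeneous network (all
edge classes, unweighted, undirected).  Instead of an arbitrary disease
similarity, the prior comes from the GWAS layer itself: the disease-disease
genetic similarity is the shared-gene count normalized by the smaller gene
set, and each gene's prior is the logistic transform L(s) = 1/(1+exp(c s+d))
of its best similarity to the query disease (defaults pin L(0) ~ 1e-4 and
L(1) ~ 0.997, the classic propagation-prior shape).

Per-iteration cost is one sparse matrix-vector product, i.e. linear in the
edge count (quadratic in n for a dense operator).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .errors import DomainError, LookupMissError
from .model import (
    EdgeType,
    GENE_LAYER_EDGE_TYPES,
    HeteroNetwork,
    NodeType,
)
from .projection import project

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("column_stochastic", "symmetric")

#: Logistic prior defaults: L(x) = 1 / (1 + exp(c*x + d)).
LOGISTIC_C = -15.0
LOGISTIC_D = math.log(9999.0)


@dataclass(frozen=True)
class PropagationParams:
    """Restart ratio, convergence control and the normalization mode."""

    r: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    normalization: str = "column_stochastic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0):
            raise DomainError(f"restart ratio must lie in [0, 1], got {self.r}")
        if self.tol <= 0:
            raise DomainError("tolerance must be positive")
        if self.max_iter < 1:
            raise DomainError("max_iter must be >= 1")
        if self.normalization not in NORMALIZATIONS:
            raise DomainError(
                f"normalization must be one of {NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )


@dataclass(frozen=True)
class PropagationResult:
    """Converged scores plus the deterministic candidate ranking."""

    scores: dict[str, float]
    seed_set: frozenset[str]
    candidate_ranking: tuple[tuple[str, float, int], ...]
    iterations_used: int
    converged: bool


# ---------------------------------------------------------------------------
# adjacency and normalization

def adjacency_matrix(
    network: HeteroNetwork,
    edge_types: Iterable[EdgeType] | None = None,
    node_types: Iterable[NodeType] | None = None,
) -> tuple[sparse.csr_matrix, list[str]]:
    """Unweighted, undirected 0/1 adjacency over the selected slice.

    Returns the matrix together with the sorted node-id order indexing it.
    Directed protein-DNA edges are symmetrized; self-interactions put a 1 on
    the diagonal.
    """
    if node_types is None:
        ids = network.node_ids
    else:
        wanted = {NodeType(t) for t in node_types}
        ids = [n.id for n in network.nodes if n.node_type in wanted]
    index = {nid: i for i, nid in enumerate(ids)}
    if edge_types is None:
        edges = network.edges
    else:
        edges = network.edges_of_type(*edge_types)
    rows: list[int] = []
    cols: list[int] = []
    for e in edges:
        if e.source not in index or e.target not in index:
            continue
        i, j = index[e.source], index[e.target]
        rows.append(i)
        cols.append(j)
        if i != j:
            rows.append(j)
            cols.append(i)
    n = len(ids)
    a = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    a.data[:] = 1.0  # collapse any accidental parallel entries
    return a, ids


def normalize_adjacency(
    adjacency: sparse.spmatrix, mode: str = "column_stochastic"
) -> sparse.csr_matrix:
    """Degree-normalize an adjacency matrix.

    ``column_stochastic``: A D^-1 (each nonzero column sums to 1);
    ``symmetric``: D^-1/2 A D^-1/2.  Zero-degree nodes keep zero rows and
    columns; their fixed-point score is exactly r * p0 by the update.
    """
    if mode not in NORMALIZATIONS:
        raise DomainError(
            f"normalization must be one of {NORMALIZATIONS}, got {mode!r}"
        )
    a = sparse.csr_matrix(adjacency, dtype=float)
    if a.shape[0] == 0:
        raise DomainError("cannot normalize an empty graph")
    deg = np.asarray(a.sum(axis=0)).ravel()
    if mode == "column_stochastic":
        inv = np.zeros_like(deg)
        inv[deg > 0] = 1.0 / deg[deg > 0]
        return (a @ sparse.diags(inv)).tocsr()
    inv_sqrt = np.zeros_like(deg)
    inv_sqrt[deg > 0] = deg[deg > 0] ** -0.5
    d = sparse.diags(inv_sqrt)
    return (d @ a @ d).tocsr()


def propagate(
    w: sparse.spmatrix,
    p0: np.ndarray,
    params: PropagationParams,
    on_iteration: Callable[[int, np.ndarray], None] | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Iterate p <- (1-r) W p + r p0 from p0 until the L1 change < tol.

    Returns (scores, iterations used, converged).  Non-convergence within
    ``max_iter`` is reported, not raised.
    """
    r = params.r
    p = np.asarray(p0, dtype=float).copy()
    for t in range(1, params.max_iter + 1):
        p_next = (1.0 - r) * (w @ p) + r * p0
        diff = float(np.abs(p_next - p).sum())
        p = p_next
        if on_iteration is not None:
            on_iteration(t, p)
        if diff < params.tol:
            return p, t, True
    logger.warning(
        "propagation did not converge in %d iterations (last L1 change %g)",
        params.max_iter,
        diff,
    )
    return p, params.max_iter, False


# ---------------------------------------------------------------------------
# ranking

def rank_candidates(
    scores: Mapping[str, float], seed_set: Iterable[str]
) -> tuple[tuple[str, float, int], ...]:
    """Dense 1..m ranking of non-seed nodes, descending score, ties by id."""
    seeds = set(seed_set)
    ordered = sorted(
        ((g, s) for g, s in scores.items() if g not in seeds),
        key=lambda item: (-item[1], item[0]),
    )
    return tuple((g, s, rank) for rank, (g, s) in enumerate(ordered, start=1))


# ---------------------------------------------------------------------------
# random walk with restarts

def rwr(
    network: HeteroNetwork,
    seeds: Iterable[str],
    params: PropagationParams | None = None,
) -> PropagationResult:
    """Random walk with restarts on the gene-gene interaction layer.

    ``seeds`` are the associated genes; the restart vector assigns each seed
    probability 1/|seeds|.  Scores cover every gene in the layer and the
    candidate ranking excludes the seeds.
    """
    if params is None:
        params = PropagationParams()
    seed_set = frozenset(seeds)
    if not seed_set:
        raise DomainError("seed set must be non-empty")
    gene_ids = {n.id for n in network.nodes_of_type(NodeType.GENE)}
    missing = seed_set - gene_ids
    if missing:
        raise LookupMissError(
            f"seed genes absent from the network: {sorted(missing)[:5]}"
        )
    a, ids = adjacency_matrix(
        network, GENE_LAYER_EDGE_TYPES, node_types=(NodeType.GENE,)
    )
    w = normalize_adjacency(a, params.normalization)
    p0 = np.zeros(len(ids))
    for i, nid in enumerate(ids):
        if nid in seed_set:
            p0[i] = 1.0 / len(seed_set)
    p, iters, converged = propagate(w, p0, params)
    scores = {nid: float(p[i]) for i, nid in enumerate(ids)}
    return PropagationResult(
        scores=scores,
        seed_set=seed_set,
        candidate_ranking=rank_candidates(scores, seed_set),
        iterations_used=iters,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# disease genetic similarity (PRINCE prior)

@dataclass(frozen=True)
class DiseaseSimilarity:
    """GWAS-derived disease-disease genetic similarity in [0, 1].

    sim(d1, d2) = |shared genes| / min(|genes(d1)|, |genes(d2)|) over the
    tau-thresholded disease-gene layer; sim(d, d) = 1.
    """

    diseases: tuple[str, ...]
    gene_sets: dict[str, frozenset[str]]
    _shared: dict[tuple[str, str], int]

    def sim(self, d1: str, d2: str) -> float:
        for d in (d1, d2):
            if d not in self.gene_sets:
                raise LookupMissError(f"unknown disease {d!r}")
        if d1 == d2:
            return 1.0
        lo = min(len(self.gene_sets[d1]), len(self.gene_sets[d2]))
        if lo == 0:
            return 0.0
        key = (d1, d2) if d1 < d2 else (d2, d1)
        return self._shared.get(key, 0) / lo


def build_disease_similarity(
    network: HeteroNetwork, tau: float
) -> DiseaseSimilarity:
    """Genetic similarity from the disease-gene layer thresholded at tau."""
    if tau < 0:
        raise DomainError("tau must be >= 0")
    phenotypes = {n.id for n in network.nodes_of_type(NodeType.DISEASE)}
    gene_sets: dict[str, set[str]] = {d: set() for d in phenotypes}
    core = HeteroNetwork()
    for d in phenotypes:
        core.add_node(network.node(d))
    for e in network.edges_of_type(EdgeType.DISEASE_GENE):
        if e.weight < tau:
            continue
        disease, gene = (
            (e.source, e.target) if e.source in phenotypes else (e.target, e.source)
        )
        gene_sets[disease].add(gene)
        if gene not in core:
            core.add_node(network.node(gene))
        core.add_edge(e)
    simnet = project(
        core, NodeType.DISEASE, NodeType.GENE, EdgeType.DISEASE_GENE
    )
    shared = {(e.u, e.v): int(e.weight) for e in simnet.edges}
    return DiseaseSimilarity(
        tuple(sorted(phenotypes)),
        {d: frozenset(g) for d, g in gene_sets.items()},
        shared,
    )


def logistic_prior(
    x: float, c: float = LOGISTIC_C, d: float = LOGISTIC_D
) -> float:
    """L(x) = 1 / (1 + exp(c*x + d)); maps similarity in [0,1] to a prior."""
    return 1.0 / (1.0 + math.exp(c * x + d))


# ---------------------------------------------------------------------------
# extended PRINCE

def prince_extended(
    network: HeteroNetwork,
    query_disease: str | None,
    tau: float,
    params: PropagationParams | None = None,
    c: float = LOGISTIC_C,
    d: float = LOGISTIC_D,
    prior: Mapping[str, float] | None = None,
) -> PropagationResult:
    """Network propagation over the full heterogeneous network.

    The prior of a gene is L of its best genetic similarity between the
    query disease and any disease the gene is associated with at threshold
    tau; the query disease node itself gets prior 1 and all remaining nodes
    0.  Every edge class enters the operator unweighted and undirected.
    Scores are reported for gene nodes only.  ``prior`` overrides the
    GWAS-derived prior with an explicit per-node vector (missing nodes get
    0), in which case ``query_disease`` may be None.
    """
    if params is None:
        params = PropagationParams(normalization="symmetric")
    phenotypes = {n.id for n in network.nodes_of_type(NodeType.DISEASE)}
    seed_set: frozenset[str] = frozenset()
    if prior is None:
        if query_disease is None or query_disease not in phenotypes:
            raise LookupMissError(
                f"query disease {query_disease!r} not in the network"
            )
        similarity = build_disease_similarity(network, tau)
        gene_prior: dict[str, float] = {}
        for e in network.edges_of_type(EdgeType.DISEASE_GENE):
            if e.weight < tau:
                continue
            disease, gene = (
                (e.source, e.target)
                if e.source in phenotypes
                else (e.target, e.source)
            )
            value = logistic_prior(similarity.sim(query_disease, disease), c, d)
            gene_prior[gene] = max(gene_prior.get(gene, 0.0), value)
        prior = dict(gene_prior)
        prior[query_disease] = 1.0
        seed_set = similarity.gene_sets[query_disease]

    a, ids = adjacency_matrix(network)  # all node and edge classes
    p0 = np.array([float(prior.get(nid, 0.0)) for nid in ids])
    if p0.sum() == 0.0:
        logger.warning("prior vector is all zero: scores will be all zero")
    w = normalize_adjacency(a, params.normalization)
    p, iters, converged = propagate(w, p0, params)
    gene_ids = {n.id for n in network.nodes_of_type(NodeType.GENE)}
    scores = {
        nid: float(p[i]) for i, nid in enumerate(ids) if nid in gene_ids
    }
    return PropagationResult(
        scores=scores,
        seed_set=seed_set,
        candidate_ranking=rank_candidates(scores, seed_set),
        iterations_used=iters,
        converged=converged,
    )
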