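"""Five-layer network assembly from raw records.

The basic level of analysis is the disease-gene relationship.  GWAS
phenotype-SNP associations are mapped to their closest gene, per-study
p-values for the same phenotype-SNP pair are combined with Fisher's method,
and the most significant SNP per gene defines the gene-trait edge, weighted
-log10(p).  On top of that core the optional layers attach: protein-protein
interactions, directed TF->target edges derived from high-confidence
transcription-factor binding sites near transcription start sites, and
disease-tissue / tissue-gene / drug-gene relationships.  The gene-gene layer
around the directly associated genes can be widened by a user-chosen number
of degrees of separation (ds).

Conventions: genomic coordinates are 1-based inclusive internally; BED input
(0-based half-open) is converted at the reader boundary.  p-values reported
as 0 are clamped to 1e-300 so -log10 stays finite.  All ties (equidistant
genes, equidistant TSSs) break toward the lexicographically smaller symbol.
"""

from __future__ import annotations

import logging
import math
import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import chi2

from .errors import DomainError, FormatError, UnmappedSNPError
from .model import (
    Edge,
    EdgeType,
    GENE_LAYER_EDGE_TYPES,
    HeteroNetwork,
    Node,
    NodeType,
)

logger = logging.getLogger(__name__)

#: Smallest representable p-value; inputs at or below 0 are clamped here.
P_FLOOR = 1e-300

VALID_LAYERS = frozenset({"ppi", "tfbs", "tissue", "drug"})


# ---------------------------------------------------------------------------
# record types

@dataclass(frozen=True)
class AssociationRecord:
    """One published phenotype-SNP association result."""

    phenotype: str
    snp_id: str
    chrom: str
    pos: int
    pvalue: float
    pubmed: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise DomainError(
                f"p-value must lie in (0, 1], got {self.pvalue!r} "
                f"for {self.snp_id}"
            )
        if self.pos < 1:
            raise DomainError(f"position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene coordinates (1-based, inclusive); TSS follows the strand."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DomainError(
                f"start > end for gene {self.symbol} "
                f"({self.start} > {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise DomainError(f"strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class TFBSRecord:
    """A transcription-factor binding site call (site midpoint + Z-score)."""

    tf_symbol: str
    chrom: str
    pos: int
    zscore: float


@dataclass(frozen=True)
class AssemblyConfig:
    """Knobs of the assembly pipeline.

    ``threshold_tau`` is the -log10(p) significance cutoff on disease-gene
    edges (boundary inclusive: weight >= tau is retained).  ``ds`` widens the
    gene-gene layer by breadth-first neighbors of the directly associated
    genes.  ``z_min`` (strict) and ``promoter_window`` (inclusive, bp from
    the TSS) control TFBS-derived TF->target edges.
    """

    threshold_tau: float
    ds: int = 0
    layers: frozenset = frozenset()
    z_min: float = 4.0
    promoter_window: int = 5000
    keep_isolated_diseases: bool = False

    def __post_init__(self) -> None:
        if self.threshold_tau < 0:
            raise DomainError("threshold tau must be >= 0")
        if self.ds not in (0, 1, 2):
            raise DomainError(f"ds must be 0, 1 or 2, got {self.ds}")
        unknown = set(self.layers) - VALID_LAYERS
        if unknown:
            raise DomainError(f"unknown layers: {sorted(unknown)}")
        object.__setattr__(self, "layers", frozenset(self.layers))


# ---------------------------------------------------------------------------
# SNP -> gene mapping

def gene_distance(pos: int, gene: GeneAnnotation) -> int:
    """0 inside the gene body, else distance to the nearer gene boundary."""
    if gene.start <= pos <= gene.end:
        return 0
    return min(abs(pos - gene.start), abs(pos - gene.end))


def map_snp_to_gene(
    record: AssociationRecord, annotation: Sequence[GeneAnnotation]
) -> str:
    """Closest gene to the SNP on its chromosome (ties: smaller symbol)."""
    candidates = [g for g in annotation if g.chrom == record.chrom]
    if not candidates:
        raise UnmappedSNPError(
            f"no gene annotated on chromosome {record.chrom!r} "
            f"for SNP {record.snp_id}"
        )
    best = min(candidates, key=lambda g: (gene_distance(record.pos, g), g.symbol))
    return best.symbol


# ---------------------------------------------------------------------------
# Fisher's method

def fisher_meta_p(pvalues: Sequence[float]) -> float:
    """Combine per-study p-values with Fisher's method.

    A single p-value is returned unchanged.  For k >= 2 studies the statistic
    X^2 = -2 sum(ln p_i) is referred to a chi-square law with 2k degrees of
    freedom and the upper-tail probability is returned, floored at 1e-300.
    """
    ps = [float(p) for p in pvalues]
    if not ps:
        raise DomainError("need at least one p-value")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise DomainError(f"p-value must lie in (0, 1], got {p!r}")
    if len(ps) == 1:
        return ps[0]
    # sorted summation => exactly permutation-invariant results
    stat = -2.0 * sum(math.log(p) for p in sorted(ps))
    meta = float(chi2.sf(stat, 2 * len(ps)))
    return min(1.0, max(meta, P_FLOOR))


# ---------------------------------------------------------------------------
# disease-gene edges

def build_disease_gene_edges(
    records: Iterable[AssociationRecord],
    annotation: Sequence[GeneAnnotation],
) -> list[Edge]:
    """One weighted edge per (disease, gene) pair.

    Per (phenotype, SNP) pair, p-values reported by different studies are
    combined into a Fisher meta p-value; per (disease, gene), the most
    significant of the gene's SNPs sets the edge weight -log10(p).
    Provenance is the union of all contributing PubMed ids.  Records whose
    chromosome has no annotated gene are skipped with a warning.
    """
    by_snp: dict[tuple[str, str], list[AssociationRecord]] = defaultdict(list)
    skipped = 0
    gene_of: dict[tuple[str, str], str] = {}
    for rec in records:
        key = (rec.phenotype, rec.snp_id)
        if key not in gene_of:
            try:
                gene_of[key] = map_snp_to_gene(rec, annotation)
            except UnmappedSNPError as exc:
                logger.warning("skipping record: %s", exc)
                gene_of[key] = ""
        if gene_of[key]:
            by_snp[key].append(rec)
        else:
            skipped += 1
    if skipped:
        logger.warning("%d unmappable association records skipped", skipped)

    best_p: dict[tuple[str, str], float] = {}
    provenance: dict[tuple[str, str], set[str]] = defaultdict(set)
    for (phenotype, snp), recs in by_snp.items():
        meta = fisher_meta_p([r.pvalue for r in recs])
        pair = (phenotype, gene_of[(phenotype, snp)])
        if pair not in best_p or meta < best_p[pair]:
            best_p[pair] = meta
        provenance[pair].update(r.pubmed for r in recs if r.pubmed)

    edges = []
    for (phenotype, gene), p in sorted(best_p.items()):
        weight = -math.log10(max(p, P_FLOOR))
        edges.append(
            Edge(
                phenotype,
                gene,
                EdgeType.DISEASE_GENE,
                weight,
                tuple(sorted(provenance[(phenotype, gene)])),
            )
        )
    return edges


def filter_by_threshold(edges: Iterable[Edge], tau: float) -> list[Edge]:
    """Keep disease-gene edges with weight >= tau; pass other types through."""
    if tau < 0:
        raise DomainError(f"threshold tau must be >= 0, got {tau}")
    return [
        e
        for e in edges
        if e.edge_type != EdgeType.DISEASE_GENE or e.weight >= tau
    ]


# ---------------------------------------------------------------------------
# TFBS-derived directed edges

def derive_tfbs_edges(
    sites: Iterable[TFBSRecord],
    annotation: Sequence[GeneAnnotation],
    z_min: float = 4.0,
    window: int = 5000,
) -> list[Edge]:
    """Directed TF -> target edges from high-confidence binding sites.

    A site qualifies when its Z-score is strictly above ``z_min`` and it lies
    within ``window`` bp (inclusive) of the nearest transcription start site
    on its chromosome; the TF then regulates that nearest gene.  Duplicate
    (TF, target) pairs collapse to one edge of weight 1.  Self-edges (a TF
    binding its own promoter) are kept and logged.
    """
    tss_by_chrom: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for g in annotation:
        tss_by_chrom[g.chrom].append(g)
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    for site in sites:
        if not (site.zscore > z_min):
            dropped += 1
            continue
        genes = tss_by_chrom.get(site.chrom)
        if not genes:
            dropped += 1
            continue
        nearest = min(genes, key=lambda g: (abs(site.pos - g.tss), g.symbol))
        if abs(site.pos - nearest.tss) <= window:
            if site.tf_symbol == nearest.symbol:
                logger.info(
                    "TFBS self-edge: %s regulates its own promoter",
                    site.tf_symbol,
                )
            pairs.add((site.tf_symbol, nearest.symbol))
        else:
            dropped += 1
    if dropped:
        logger.info("%d TFBS sites failed the Z/window filters", dropped)
    return [
        Edge(tf, target, EdgeType.PROTEIN_DNA, 1.0)
        for tf, target in sorted(pairs)
    ]


# ---------------------------------------------------------------------------
# ds-neighborhood expansion

def expand_neighborhood(
    network: HeteroNetwork,
    ppi_universe: HeteroNetwork | Iterable[Edge],
    ds: int,
) -> HeteroNetwork:
    """Widen the gene-gene layer by ``ds`` degrees of separation.

    ``ds = 0`` adds only universe interactions among genes already present
    (the induced gene layer); ``ds = k`` first adds every gene within graph
    distance <= k of a directly associated gene (distances over the combined
    protein-protein and protein-DNA layer, directions ignored), then all
    universe interactions among the enlarged gene set.
    """
    if ds not in (0, 1, 2):
        raise DomainError(f"ds must be 0, 1 or 2, got {ds}")
    if isinstance(ppi_universe, HeteroNetwork):
        universe_edges = ppi_universe.edges_of_type(*GENE_LAYER_EDGE_TYPES)
    else:
        universe_edges = [
            e for e in ppi_universe if e.edge_type in GENE_LAYER_EDGE_TYPES
        ]

    adjacency: dict[str, set[str]] = defaultdict(set)
    for e in universe_edges:
        adjacency[e.source].add(e.target)
        adjacency[e.target].add(e.source)

    out = network.copy()
    reached = {n.id for n in network.nodes_of_type(NodeType.GENE)}
    frontier = set(reached)
    for _ in range(ds):
        frontier = {
            nbr for g in frontier for nbr in adjacency[g]
        } - reached
        reached |= frontier
    for gene in sorted(reached):
        if gene not in out:
            out.add_node(Node(gene, NodeType.GENE))
    for e in universe_edges:
        if e.source in reached and e.target in reached:
            out.add_edge(e, skip_duplicate=True)
    return out


# ---------------------------------------------------------------------------
# orchestration

def assemble(
    records: Iterable[AssociationRecord],
    annotation: Sequence[GeneAnnotation],
    config: AssemblyConfig,
    sites: Iterable[TFBSRecord] = (),
    aux_layers: HeteroNetwork | None = None,
) -> HeteroNetwork:
    """Run the full pipeline: map, combine, weight, filter, attach, expand.

    ``aux_layers`` supplies the interaction universe: protein-protein edges
    (layer ``ppi``) and the disease-tissue / tissue-gene (layer ``tissue``)
    and drug-gene (layer ``drug``) relationships, each used only if the
    corresponding layer is requested in ``config.layers``.  TF->target edges
    are derived from ``sites`` when layer ``tfbs`` is requested.  Tissue and
    drug edges attach only to diseases/genes present after expansion, so the
    result stays anchored on the retained disease-gene core.
    """
    records = list(records)
    dg_edges = build_disease_gene_edges(records, annotation)
    retained = filter_by_threshold(dg_edges, config.threshold_tau)
    logger.info(
        "disease-gene edges: %d built, %d at tau=%g",
        len(dg_edges),
        len(retained),
        config.threshold_tau,
    )

    phenotypes = {r.phenotype for r in records}
    net = HeteroNetwork()
    if config.keep_isolated_diseases:
        for phenotype in sorted(phenotypes):
            net.add_node(Node(phenotype, NodeType.DISEASE))
    for e in retained:
        disease, gene = (
            (e.source, e.target) if e.source in phenotypes else (e.target, e.source)
        )
        net.add_node(Node(disease, NodeType.DISEASE))
        net.add_node(Node(gene, NodeType.GENE))
        net.add_edge(e)

    universe: list[Edge] = []
    if "ppi" in config.layers and aux_layers is not None:
        universe.extend(aux_layers.edges_of_type(EdgeType.PROTEIN_PROTEIN))
    if "tfbs" in config.layers:
        universe.extend(
            derive_tfbs_edges(
                sites, annotation, config.z_min, config.promoter_window
            )
        )
    net = expand_neighborhood(net, universe, config.ds)

    if aux_layers is not None:
        if "tissue" in config.layers:
            _attach(net, aux_layers, EdgeType.DISEASE_TISSUE, NodeType.DISEASE)
            _attach(net, aux_layers, EdgeType.TISSUE_GENE, NodeType.GENE)
        if "drug" in config.layers:
            _attach(net, aux_layers, EdgeType.DRUG_GENE, NodeType.GENE)
    logger.info("assembled network: %d nodes, %d edges", net.n, net.n_edges)
    return net


def _attach(
    net: HeteroNetwork,
    aux: HeteroNetwork,
    edge_type: EdgeType,
    anchor_type: NodeType,
) -> None:
    """Attach aux edges of one type whose anchor endpoint is already present."""
    for e in aux.edges_of_type(edge_type):
        src_t = aux.node(e.source).node_type
        anchor, other = (
            (e.source, e.target) if src_t == anchor_type else (e.target, e.source)
        )
        if anchor in net:
            if other not in net:
                net.add_node(aux.node(other))
            net.add_edge(e, skip_duplicate=True)


# ---------------------------------------------------------------------------
# readers for the raw-record formats

def read_association_table(path: str | os.PathLike) -> list[AssociationRecord]:
    """Association TSV: snp_id, chrom, pos, phenotype, pvalue, pubmed.

    p-values of exactly 0 are clamped to 1e-300 with a warning; p outside
    [0, 1] is a format error naming the line.
    """
    path = os.fspath(path)
    header = ("snp_id", "chrom", "pos", "phenotype", "pvalue", "pubmed")
    out: list[AssociationRecord] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if tuple(first.rstrip("\n").split("\t")) != header:
            raise FormatError(f"{path}:1: expected header {'/'.join(header)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 fields, got {len(fields)}"
                )
            snp_id, chrom, pos, phenotype, pvalue, pubmed = fields
            try:
                p = float(pvalue)
                position = int(pos)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: invalid pos/pvalue"
                ) from None
            if p == 0.0:
                logger.warning(
                    "%s:%d: p-value 0 clamped to %g", path, lineno, P_FLOOR
                )
                p = P_FLOOR
            if not (0.0 < p <= 1.0):
                raise FormatError(
                    f"{path}:{lineno}: p-value {pvalue} outside (0, 1]"
                )
            out.append(
                AssociationRecord(
                    phenotype,
                    snp_id,
                    chrom,
                    position,
                    p,
                    "" if pubmed == "." else pubmed,
                )
            )
    return out


def read_gene_annotation_bed(path: str | os.PathLike) -> list[GeneAnnotation]:
    """BED6 gene annotation (chrom, start, end, symbol, score-ignored, strand).

    BED's 0-based half-open coordinates convert to the internal 1-based
    inclusive convention (start+1, end).
    """
    path = os.fspath(path)
    out: list[GeneAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected BED6 (6 fields), "
                    f"got {len(fields)}"
                )
            chrom, start, end, symbol, _score, strand = fields[:6]
            try:
                out.append(
                    GeneAnnotation(
                        symbol, chrom, int(start) + 1, int(end), strand
                    )
                )
            except (ValueError, DomainError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def read_tfbs_table(path: str | os.PathLike) -> list[TFBSRecord]:
    """TFBS TSV: tf_symbol, chrom, pos, zscore."""
    path = os.fspath(path)
    header = ("tf_symbol", "chrom", "pos", "zscore")
    out: list[TFBSRecord] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if tuple(first.rstrip("\n").split("\t")) != header:
            raise FormatError(f"{path}:1: expected header {'/'.join(header)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            tf, chrom, pos, z = fields
            try:
                out.append(TFBSRecord(tf, chrom, int(pos), float(z)))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: invalid pos/zscore"
                ) from None
    return out
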