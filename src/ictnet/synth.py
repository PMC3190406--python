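"""Synthetic five-layer fixtures with planted disease modules.

The generator emulates the *edge-level* statistical structure the downstream
methods consume — nothing more.  Each disease gets a planted module of genes:
truly associated genes draw strong GWAS p-values (log-uniform over
[1e-30, 1e-8] by default) while a held-out subset of the module is emitted
only with noise-level p-values (uniform over [1e-6, 0.05]), so a -log10
threshold of 7 cleanly separates signal from noise and the held-out genes
become the recoverable targets for the prioritizers.  Module genes are wired
more densely in the protein-interaction layer (base rate times
``within_module_edge_boost``), which is the topological signal propagation
exploits.  Designated disease pairs share a fixed fraction of their modules
so the similarity projection and the PRINCE prior have known answers.

Not a realistic GWAS simulator: no linkage disequilibrium, genotypes or
effect sizes.  Gene coordinates are laid out on synthetic chromosomes with a
fixed 10 kb start-to-start spacing and 2 kb gene bodies, so every emitted
SNP sits inside its gene and nearest-gene mapping is unambiguous (an
optional flag plants one deliberately equidistant tie SNP).

All randomness flows through one ``numpy`` generator seeded from
``rng_seed``: identical configs give byte-identical files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .assembly import (
    AssemblyConfig,
    AssociationRecord,
    GeneAnnotation,
    TFBSRecord,
    assemble,
)
from .errors import DomainError
from .io import write_network
from .model import Edge, EdgeType, HeteroNetwork, Node, NodeType
from .prioritize import (
    PropagationParams,
    prince_extended,
    rank_candidates,
    rwr,
)

GENE_SPACING = 10_000  # start-to-start, bp
GENE_LENGTH = 2_001  # odd length => even inter-gene gap => exact tie midpoints
N_CHROMS = 4


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and noise parameters of a synthetic fixture."""

    n_genes: int = 300
    n_diseases: int = 6
    n_tissues: int = 8
    n_drugs: int = 10
    module_size: int = 12
    held_out_fraction: float = 0.25
    ppi_model: tuple = ("erdos_renyi", 0.02)
    within_module_edge_boost: float = 20.0
    p_signal: tuple[float, float] = (1e-30, 1e-8)  # log-uniform support
    p_noise: tuple[float, float] = (1e-6, 0.05)  # uniform support
    n_noise_assoc: int = 150
    overlap_fraction: float = 0.2
    duplicate_study_fraction: float = 0.3
    n_tfs: int = 8
    targets_per_tf: int = 5
    plant_tie_snp: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise DomainError(
                f"infeasible config: module_size {self.module_size} exceeds "
                f"n_genes {self.n_genes}"
            )
        if self.n_diseases * self.module_size > self.n_genes * 2:
            raise DomainError(
                "infeasible config: modules cannot be drawn from the gene pool"
            )
        for name in ("n_genes", "n_diseases", "n_tissues", "n_drugs",
                     "n_noise_assoc", "n_tfs"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not (0.0 <= self.held_out_fraction < 1.0):
            raise DomainError("held_out_fraction must lie in [0, 1)")
        if self.ppi_model[0] not in ("erdos_renyi", "scale_free"):
            raise DomainError(f"unknown PPI model {self.ppi_model[0]!r}")
        if self.within_module_edge_boost < 1.0:
            raise DomainError("within_module_edge_boost must be >= 1")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth the generator planted."""

    planted: dict[str, tuple[str, ...]]  # disease -> associated genes
    held_out: dict[str, tuple[str, ...]]  # subset emitted at noise level
    pair_overlap: dict[tuple[str, str], int]  # designated disease pairs


@dataclass(frozen=True)
class Fixture:
    config: FixtureConfig
    truth: FixtureTruth
    associations: tuple[AssociationRecord, ...]
    annotation: tuple[GeneAnnotation, ...]
    tfbs_sites: tuple[TFBSRecord, ...]
    aux_layers: HeteroNetwork  # ppi + tissue + drug universe


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _layout_genes(n: int) -> list[GeneAnnotation]:
    """Non-overlapping genes, 10 kb spacing, alternating strand."""
    per_chrom = math.ceil(n / N_CHROMS)
    out = []
    for i, symbol in enumerate(_gene_symbols(n)):
        chrom = f"c{i // per_chrom + 1}"
        j = i % per_chrom
        start = 1 + j * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        out.append(
            GeneAnnotation(symbol, chrom, start, start + GENE_LENGTH - 1, strand)
        )
    return out


def generate_fixture(config: FixtureConfig) -> Fixture:
    """Build a complete in-memory fixture; deterministic given the seed."""
    rng = np.random.default_rng(config.rng_seed)
    genes = _gene_symbols(config.n_genes)
    annotation = _layout_genes(config.n_genes)
    ann_by_symbol = {g.symbol: g for g in annotation}
    diseases = [f"D{i}" for i in range(1, config.n_diseases + 1)]
    tissues = [f"T{i}" for i in range(1, config.n_tissues + 1)]
    drugs = [f"R{i}" for i in range(1, config.n_drugs + 1)]

    # --- planted modules, overlaps and held-out subsets
    pool = list(rng.permutation(genes))
    n_shared = round(config.overlap_fraction * config.module_size)
    planted: dict[str, list[str]] = {}
    pair_overlap: dict[tuple[str, str], int] = {}
    i = 0
    while i + 1 < len(diseases):
        d1, d2 = diseases[i], diseases[i + 1]
        shared = [pool.pop() for _ in range(n_shared)]
        planted[d1] = shared + [
            pool.pop() for _ in range(config.module_size - n_shared)
        ]
        planted[d2] = shared + [
            pool.pop() for _ in range(config.module_size - n_shared)
        ]
        pair_overlap[(d1, d2)] = n_shared
        i += 2
    if i < len(diseases):  # odd disease count: last module unpaired
        planted[diseases[i]] = [pool.pop() for _ in range(config.module_size)]

    n_held = math.ceil(config.held_out_fraction * config.module_size)
    held_out: dict[str, tuple[str, ...]] = {}
    for d in diseases:
        # hold out non-shared genes only, so overlap truth stays threshold-stable
        eligible = planted[d][n_shared:] if n_shared else planted[d]
        chosen = rng.choice(eligible, size=min(n_held, len(eligible)),
                            replace=False)
        held_out[d] = tuple(sorted(chosen))

    # --- association records
    records: list[AssociationRecord] = []
    rs = 0
    lo_s, hi_s = math.log10(config.p_signal[0]), math.log10(config.p_signal[1])
    for d in diseases:
        for gene in planted[d]:
            rs += 1
            ann = ann_by_symbol[gene]
            pos = int(ann.start + 100 + rng.integers(0, GENE_LENGTH - 200))
            if gene in held_out[d]:
                p = float(rng.uniform(*config.p_noise))
            else:
                p = float(10.0 ** rng.uniform(lo_s, hi_s))
            pubmed = str(int(rng.integers(10_000_000, 99_999_999)))
            records.append(
                AssociationRecord(d, f"rs{rs}", ann.chrom, pos, p, pubmed)
            )
            if (
                gene not in held_out[d]
                and rng.random() < config.duplicate_study_fraction
            ):
                p2 = float(10.0 ** rng.uniform(lo_s, hi_s))
                pubmed2 = str(int(rng.integers(10_000_000, 99_999_999)))
                records.append(
                    AssociationRecord(d, f"rs{rs}", ann.chrom, pos, p2, pubmed2)
                )
    for _ in range(config.n_noise_assoc):
        rs += 1
        d = diseases[int(rng.integers(0, len(diseases)))]
        gene = genes[int(rng.integers(0, len(genes)))]
        ann = ann_by_symbol[gene]
        pos = int(ann.start + 100 + rng.integers(0, GENE_LENGTH - 200))
        p = float(rng.uniform(*config.p_noise))
        pubmed = str(int(rng.integers(10_000_000, 99_999_999)))
        records.append(
            AssociationRecord(d, f"rs{rs}", ann.chrom, pos, p, pubmed)
        )
    if config.plant_tie_snp and config.n_genes >= 2:
        # midpoint between the ends of gene 1 and the start of gene 2 on c1
        g1, g2 = annotation[0], annotation[1]
        rs += 1
        mid = (g1.end + g2.start) // 2  # exactly equidistant (even gap)
        records.append(
            AssociationRecord(
                diseases[0], f"rs{rs}", g1.chrom, mid,
                float(rng.uniform(*config.p_noise)),
                str(int(rng.integers(10_000_000, 99_999_999))),
            )
        )

    # --- PPI layer with boosted within-module density
    module_of: dict[str, set[int]] = {g: set() for g in genes}
    for k, d in enumerate(diseases):
        for g in planted[d]:
            module_of[g].add(k)
    model, param = config.ppi_model
    if model == "erdos_renyi":
        base_rate = float(param)
    else:  # scale_free(m): expected density ~ 2m/n
        base_rate = 2.0 * float(param) / max(config.n_genes, 1)
    boosted = min(1.0, base_rate * config.within_module_edge_boost)

    ppi_pairs: list[tuple[str, str]] = []
    if model == "erdos_renyi":
        draws = rng.random(config.n_genes * (config.n_genes - 1) // 2)
        idx = 0
        for a in range(config.n_genes):
            for b in range(a + 1, config.n_genes):
                within = bool(module_of[genes[a]] & module_of[genes[b]])
                if draws[idx] < (boosted if within else base_rate):
                    ppi_pairs.append((genes[a], genes[b]))
                idx += 1
    else:
        import networkx as nx

        g = nx.barabasi_albert_graph(
            config.n_genes, int(param),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ppi_pairs = [(genes[a], genes[b]) for a, b in g.edges()]
        extra = min(1.0, base_rate * (config.within_module_edge_boost - 1.0))
        have = {tuple(sorted(p)) for p in ppi_pairs}
        for a in range(config.n_genes):
            for b in range(a + 1, config.n_genes):
                if not (module_of[genes[a]] & module_of[genes[b]]):
                    continue
                pair = tuple(sorted((genes[a], genes[b])))
                if pair not in have and rng.random() < extra:
                    ppi_pairs.append(pair)
                    have.add(pair)

    # --- TFBS sites (kept, Z-rejected, window-rejected, and boundary cases)
    tfbs: list[TFBSRecord] = []
    tf_symbols = sorted(
        rng.choice(genes, size=min(config.n_tfs, config.n_genes), replace=False)
    )
    for t, tf in enumerate(tf_symbols):
        targets = rng.choice(genes, size=config.targets_per_tf, replace=False)
        for k, target in enumerate(targets):
            ann = ann_by_symbol[str(target)]
            if t == 0 and k == 0:
                offset = 5000  # exactly on the inclusive window boundary
            else:
                offset = int(rng.integers(-4000, 4001))
            pos = max(1, ann.tss + offset)
            z = float(4.0 + rng.uniform(0.1, 6.0))
            tfbs.append(TFBSRecord(tf, ann.chrom, pos, z))
        decoy = ann_by_symbol[str(targets[0])]
        tfbs.append(  # fails the strict Z filter at exactly 4.0
            TFBSRecord(tf, decoy.chrom, max(1, decoy.tss + 100), 4.0)
        )
        tfbs.append(  # high Z but outside the promoter window
            TFBSRecord(
                tf, decoy.chrom, decoy.tss + 5001 + int(rng.integers(0, 1000)),
                float(4.5 + rng.uniform(0.0, 4.0)),
            )
        )

    # --- tissue and drug layers, anchored on the modules
    aux = HeteroNetwork()
    for g in genes:
        aux.add_node(Node(g, NodeType.GENE))
    for d in diseases:
        aux.add_node(Node(d, NodeType.DISEASE))
    for t in tissues:
        aux.add_node(Node(t, NodeType.TISSUE))
    for r in drugs:
        aux.add_node(Node(r, NodeType.DRUG))
    for a, b in ppi_pairs:
        aux.add_edge(Edge(a, b, EdgeType.PROTEIN_PROTEIN), skip_duplicate=True)
    if tissues:
        for k, d in enumerate(diseases):
            tissue = tissues[k % len(tissues)]
            aux.add_edge(
                Edge(d, tissue, EdgeType.DISEASE_TISSUE), skip_duplicate=True
            )
            expressed = rng.choice(
                planted[d], size=min(5, len(planted[d])), replace=False
            )
            for g in expressed:
                aux.add_edge(
                    Edge(tissue, str(g), EdgeType.TISSUE_GENE),
                    skip_duplicate=True,
                )
        for tissue in tissues:
            for g in rng.choice(genes, size=8, replace=False):
                aux.add_edge(
                    Edge(tissue, str(g), EdgeType.TISSUE_GENE),
                    skip_duplicate=True,
                )
    for k, drug in enumerate(drugs):
        d = diseases[k % len(diseases)]
        n_targets = 1 + int(rng.integers(0, 3))
        targeted = rng.choice(planted[d], size=n_targets, replace=False)
        for g in targeted:
            aux.add_edge(
                Edge(drug, str(g), EdgeType.DRUG_GENE), skip_duplicate=True
            )

    truth = FixtureTruth(
        planted={d: tuple(planted[d]) for d in diseases},
        held_out=held_out,
        pair_overlap=pair_overlap,
    )
    return Fixture(
        config=config,
        truth=truth,
        associations=tuple(records),
        annotation=tuple(annotation),
        tfbs_sites=tuple(tfbs),
        aux_layers=aux,
    )


# ---------------------------------------------------------------------------
# file emission (round-trips through the package readers)

def write_fixture(fixture: Fixture, outdir: str | os.PathLike) -> Path:
    """Write the fixture as the tabular inputs the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "associations.tsv", "w", encoding="utf-8") as fh:
        fh.write("snp_id\tchrom\tpos\tphenotype\tpvalue\tpubmed\n")
        for r in fixture.associations:
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.phenotype}\t"
                f"{r.pvalue:.17g}\t{r.pubmed or '.'}\n"
            )
    with open(out / "genes.bed", "w", encoding="utf-8") as fh:
        for g in fixture.annotation:  # back to 0-based half-open
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\t0\t{g.strand}\n"
            )
    with open(out / "tfbs.tsv", "w", encoding="utf-8") as fh:
        fh.write("tf_symbol\tchrom\tpos\tzscore\n")
        for s in fixture.tfbs_sites:
            fh.write(f"{s.tf_symbol}\t{s.chrom}\t{s.pos}\t{s.zscore:.17g}\n")
    write_network(fixture.aux_layers, out / "layers", "tsv_pair")
    import json

    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "planted": {d: list(v) for d, v in fixture.truth.planted.items()},
                "held_out": {
                    d: list(v) for d, v in fixture.truth.held_out.items()
                },
                "pair_overlap": {
                    f"{a}|{b}": n
                    for (a, b), n in fixture.truth.pair_overlap.items()
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return out


# ---------------------------------------------------------------------------
# recovery experiment

@dataclass(frozen=True)
class RecoverySummary:
    """Held-out rank percentiles: per replicate and pooled."""

    method: str
    per_replicate_median: tuple[float, ...]
    percentiles: tuple[float, ...]

    @property
    def median(self) -> float:
        return float(np.median(self.percentiles))


def recovery_experiment(
    config: FixtureConfig,
    method: str,
    params: PropagationParams | None = None,
    replicates: int = 20,
    tau: float = 7.0,
    ds: int = 1,
    base_seed: int = 1000,
) -> RecoverySummary:
    """Rank-recovery of held-out module genes across fixture replicates.

    Per replicate a fresh fixture is generated (seed ``base_seed + rep``),
    assembled at ``tau`` (which separates planted signal from noise by
    construction) with the PPI layer at the given ``ds``, and each disease's
    held-out genes are scored by the chosen method.  Reported percentiles
    are 100 * rank / #candidates; a held-out gene absent from the assembled
    network scores the worst possible 100.  ``method`` is ``rwr``,
    ``prince``, or ``null`` (candidate order shuffled uniformly — the
    no-information control whose median sits near 50).
    """
    if method not in ("rwr", "prince", "null"):
        raise DomainError(f"unknown method {method!r}")
    layers = {"ppi"} if method != "prince" else {"ppi", "tissue", "drug"}
    per_rep: list[float] = []
    pooled: list[float] = []
    for rep in range(replicates):
        seed = (base_seed + rep) % (2**31 - 1)
        fx = generate_fixture(replace(config, rng_seed=seed))
        acfg = AssemblyConfig(
            threshold_tau=tau, ds=ds, layers=frozenset(layers)
        )
        net = assemble(
            fx.associations, fx.annotation, acfg, aux_layers=fx.aux_layers
        )
        null_rng = np.random.default_rng(seed + 7)
        rep_pcts: list[float] = []
        for disease in fx.truth.held_out:
            if disease not in net or not fx.truth.held_out[disease]:
                continue
            seeds = {
                e.source if e.target == disease else e.target
                for e in net.edges_of_type(EdgeType.DISEASE_GENE)
                if disease in (e.source, e.target) and e.weight >= tau
            }
            if not seeds:
                continue
            if method == "rwr":
                result = rwr(net, seeds, params)
                ranking = result.candidate_ranking
            elif method == "prince":
                result = prince_extended(net, disease, tau, params)
                ranking = result.candidate_ranking
            else:
                gene_ids = [
                    n.id
                    for n in net.nodes_of_type(NodeType.GENE)
                    if n.id not in seeds
                ]
                scores = {
                    g: float(s)
                    for g, s in zip(gene_ids, null_rng.random(len(gene_ids)))
                }
                ranking = rank_candidates(scores, seeds)
            m = len(ranking)
            rank_of = {g: rank for g, _s, rank in ranking}
            for g in fx.truth.held_out[disease]:
                pct = 100.0 * rank_of[g] / m if g in rank_of else 100.0
                rep_pcts.append(pct)
        per_rep.append(float(np.median(rep_pcts)))
        pooled.extend(rep_pcts)
    return RecoverySummary(method, tuple(per_rep), tuple(pooled))
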