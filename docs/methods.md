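# Methods

## Network model

The network is 4-partite: gene, disease, tissue and drug nodes joined by
six type-constrained edge classes (disease_gene, protein_protein,
protein_dna, disease_tissue, tissue_gene, drug_gene). Genes, SNPs and
proteins share one node class: SNPs are resolved to genes during assembly
(the most significant SNP defines the gene–trait edge) and gene products
carry the interaction layers, so SNPs never appear as nodes. Only
protein_dna (TF → target) edges are directed. Undirected edges are stored
with lexicographically ordered endpoints, which makes the
(source, target, type) key canonical and duplicate detection
order-insensitive. Duplicate edges are rejected at read time rather than
merged; all merging of association evidence happens in the assembly stage
where the meta-p-value rule applies, so the merging policy lives in
exactly one place.

Self-interactions are accepted on the gene layer only (a protein can bind
itself; a TF can bind its own promoter) and flagged by the validator.

### Serialization

`tsv_pair` (nodes.tsv + edges.tsv) is the canonical format; weights are
written with 17 significant digits so doubles round-trip bit-exactly.
SIF uses the fixed token map pp, pd, dg, dt, tg, drg — SIF has no
attribute channel, so node classes, weights and PubMed provenance travel
in sidecar attribute tables, which also makes the SIF export losslessly
readable. GraphML carries the same attributes inline. Missing values are
written as `.`.

## Assembly

Pipeline: map SNPs to genes → combine per-study p-values → weight edges →
filter at τ → expand the gene layer by *ds* → attach tissue/drug edges to
the nodes present.

- **SNP→gene mapping** uses the gene *body*: distance 0 inside
  [start, end], otherwise distance to the nearer boundary; the closest
  gene on the SNP's chromosome wins, ties broken toward the smaller
  symbol. Coordinates are 1-based inclusive internally; BED input
  (0-based half-open) is converted at the reader boundary.
- **Fisher combination** applies at the (phenotype, SNP) level across
  studies — the same association reported twice is one piece of evidence
  combined, not two edges. Per (disease, gene), the smallest resulting
  meta p across the gene's SNPs sets the weight −log₁₀(p); provenance is
  the union of contributing PubMed ids. p-values of 0 are clamped to
  1e−300 so the weight stays finite. Summation inside Fisher's statistic
  runs over sorted p-values, making the result exactly
  permutation-invariant.
- **Threshold** τ is inclusive (w ≥ τ, i.e. p ≤ 10⁻τ): "significant at
  10⁻⁴" reads naturally as p ≤ 10⁻⁴. Diseases whose every association
  fails τ are dropped by default; `keep_isolated_diseases` retains them
  as isolated nodes.
- **TFBS derivation** uses the TSS point (not the gene body): a site
  qualifies with Z *strictly* greater than 4.0 and distance to the
  nearest TSS *at most* 5,000 bp — the strict/inclusive split follows the
  usual reading of "> 4.0" versus "within 5,000 bp". Nearest-TSS ties
  break toward the smaller symbol. Self-edges are kept and logged.
- **ds-expansion** treats the union of protein_protein and protein_dna
  edges as one undirected gene–gene layer; ds = 0 adds only interactions
  among genes already present, ds = k adds breadth-first neighbors to
  depth k plus all interactions among the enlarged set. Tissue and drug
  edges are attached after expansion so neighbor genes acquire their
  tissue/drug context too; tissue and drug nodes enter only via an
  already-present anchor, keeping the network rooted in the disease–gene
  core.

## Similarity projection

For two nodes of the projected class the weight is the count of shared
intermediate neighbors (|N(u) ∩ N(v)|); pairs sharing nothing get no
edge. Underlying edge weights are ignored — the projection counts genes,
not evidence strength. A Jaccard variant is available behind a flag,
default off. `normalized_weight` = weight / max(weight) is exported for
color mapping; the rendering itself is out of scope.

## Propagation

Update: p(t+1) = (1−r) W p(t) + r p0, iterated from p0 until the L1
change drops below `tol` (default 1e−6) or `max_iter` (default 1,000).
Defaults: r = 0.5. Two normalizations of the 0/1 adjacency A:
column-stochastic A D⁻¹ (RWR default) and symmetric D^(−1/2) A D^(−1/2)
(PRINCE default) — the conventions of the two source methods. Zero-degree
nodes keep zero rows/columns; their fixed point is exactly r·p0, which is
documented rather than special-cased. At r = 1 the update returns p0
exactly in one iteration (the "trapped walker" limit). Non-convergence
returns a result with `converged=False` and a warning, never an
exception.

RWR seeds are the genes whose disease–gene weight passes τ; p0 is uniform
over seeds. Extended PRINCE builds the operator over *all* nodes and
*all* edge classes, unweighted and undirected (including protein_dna —
direction-aware propagation is deliberately not attempted). Its gene
prior is y(g) = max over linked diseases d of L(sim(query, d)), with
sim(d₁, d₂) = |shared genes| / min(|genes(d₁)|, |genes(d₂)|) computed via
the projection module, and L(x) = 1/(1 + exp(c·x + d)). Defaults
c = −15, d = ln 9999 pin L(0) ≈ 1e−4 and L(1) ≈ 0.997: near-zero leakage
for unrelated diseases, near-full prior for the query's own genes. The
min-normalization is one defensible construction of a genetic-similarity
prior — it keeps sim in [0, 1] as the logistic expects; alternatives
(Jaccard, overlap over union) would change only the prior's scale.
Tissue and drug nodes carry zero prior. The query disease node itself
gets prior 1, letting mass flow through the disease's own hub position.

Rankings sort by descending score with ties broken by ascending node id
(deterministic), ranks dense 1..m, seeds excluded.

Per-iteration cost is one sparse mat-vec — linear in edge count,
O(n²) per step for a dense operator.

## Synthetic fixtures

The generator emulates the edge-level statistical structure the methods
consume; it is *not* a GWAS simulator (no LD, genotypes or effect
sizes). Defaults: 300 genes, 6 diseases, 12-gene modules, 8 tissues, 10
drugs. Genes are laid out on 4 synthetic chromosomes at a fixed 10 kb
start-to-start spacing with 2,001 bp bodies (the odd length makes
inter-gene gaps even, so exactly equidistant tie SNPs exist when
requested); every association SNP sits inside its gene, making mapping
unambiguous. Truly associated genes draw p log-uniform over
[1e−30, 1e−8]; a held-out quarter of each module and 150 spurious
associations draw noise p-values supported on [1e−6, 0.05]. Because the
noise support is capped at 1e−6, τ = 7 retains exactly the non-held-out
planted pairs — filter tests are exact, and the held-out genes are
recoverable only through network position. The PPI layer is
Erdős–Rényi(p = 0.02) with within-module pairs boosted ×20 (capped at 1);
a scale-free alternative is available. Designated disease pairs share
20% of their modules (shared genes are never held out, so overlap truth
is threshold-stable). About 30% of signal associations are emitted twice
as independent "studies" to exercise Fisher combination. All randomness
flows through a single seeded generator: identical configs give
byte-identical files.

What passing recovery tests shows — and does not. With the default
boost, held-out genes are densely wired to their module's seeds, so both
prioritizers place them in the top decile of candidates (median
percentile ≈ 1% in practice, vs ≈ 50% for the shuffled null, degrading
monotonically to ≈ null as the boost → 1). Real disease modules are far
less cleanly separable; these fixtures validate the machinery, not the
biological effect size.

The recovery experiment assembles each replicate at τ = 7, ds = 1 (RWR on
the PPI layer; PRINCE additionally with tissue and drug layers), ranks
per disease, and scores each held-out gene by 100·rank/#candidates; a
held-out gene missing from the assembled network scores 100. Twenty
replicates at ~300 genes keep the full experiment under a minute on one
CPU; the problem size was chosen so that the null's median is stable to
a few percentage points.

## Numerical and design notes

- Convergence tolerance 1e−6 (L1) and max_iter 1,000 are conventional
  for propagation methods; the oracle tests tighten tol to 1e−12 and
  compare against the dense linear solve, agreeing to < 1e−8.
- The adjacency is rebuilt per call rather than cached; networks at this
  scale make the mat-vec, not construction, the dominant cost.
- Assembly accepts the auxiliary layers as one typed network
  (`aux_layers`) rather than separate edge lists, so the fixture's layer
  universe round-trips through the standard readers and endpoint classes
  are known when attaching.
- Known limitations: no liftover between genome builds; tissue-name
  pooling is treated as an input mapping, not an algorithm; no
  significance testing of projection overlaps (hypergeometric tests are
  out of scope); no head-to-head benchmark claim between RWR and PRINCE
  is made — users should try both.
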