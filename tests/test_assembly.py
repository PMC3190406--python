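"""Assembly pipeline: mapping, combination, filtering, TFBS, expansion.

Each operation is checked against a brute-force or closed-form oracle that
is independent of the implementation path.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictnet.assembly import (
    AssemblyConfig,
    AssociationRecord,
    GeneAnnotation,
    TFBSRecord,
    assemble,
    build_disease_gene_edges,
    derive_tfbs_edges,
    expand_neighborhood,
    filter_by_threshold,
    fisher_meta_p,
    gene_distance,
    map_snp_to_gene,
    read_association_table,
    read_gene_annotation_bed,
)
from ictnet.errors import DomainError, UnmappedSNPError
from ictnet.model import Edge, EdgeType, NodeType

from conftest import chi2_sf_even_df, make_network

ANN = [
    GeneAnnotation("GA", "c1", 1_000, 3_000, "+"),
    GeneAnnotation("GB", "c1", 50_000, 52_000, "-"),
    GeneAnnotation("GC", "c2", 10, 500, "+"),
]


def rec(pos, chrom="c1", p=1e-8, phenotype="D1", snp="rs1", pubmed="111"):
    return AssociationRecord(phenotype, snp, chrom, pos, p, pubmed)


class TestSnpMapping:
    def test_position_inside_gene_body_maps_there(self):
        assert map_snp_to_gene(rec(2_000), ANN) == "GA"

    def test_strictly_nearer_gene_wins(self):
        # 10 kb from GA's end, 37 kb from GB's start
        assert map_snp_to_gene(rec(13_000), ANN) == "GA"

    def test_exact_tie_breaks_to_smaller_symbol(self):
        # gap GA.end=3000 .. GB.start=50000; midpoint 26500 is equidistant
        assert gene_distance(26_500, ANN[0]) == gene_distance(26_500, ANN[1])
        assert map_snp_to_gene(rec(26_500), ANN) == "GA"

    def test_no_gene_on_chromosome_raises(self):
        with pytest.raises(UnmappedSNPError):
            map_snp_to_gene(rec(5, chrom="cX"), ANN)

    @given(pos=st.integers(min_value=1, max_value=100_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_minimization(self, pos):
        got = map_snp_to_gene(rec(pos), ANN)
        on_chrom = [g for g in ANN if g.chrom == "c1"]
        best = min(gene_distance(pos, g) for g in on_chrom)
        expect = min(
            g.symbol for g in on_chrom if gene_distance(pos, g) == best
        )
        assert got == expect


class TestFisher:
    def test_single_study_returned_unchanged(self):
        assert fisher_meta_p([0.01]) == 0.01

    def test_all_ones_combine_to_one(self):
        assert fisher_meta_p([1.0, 1.0]) == 1.0

    def test_two_equal_pvalues_match_chi_square_oracle(self):
        # frozen from the closed-form even-df upper tail at X2 = -4 ln 0.05
        got = fisher_meta_p([0.05, 0.05])
        expect = chi2_sf_even_df(-4.0 * math.log(0.05), 2)
        assert got == pytest.approx(0.017478661367769956, abs=1e-12)
        assert got == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], []])
    def test_out_of_domain_pvalues_rejected(self, bad):
        with pytest.raises(DomainError):
            fisher_meta_p(bad)

    @given(
        ps=st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=2,
            max_size=8,
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_oracle_and_is_permutation_invariant(self, ps):
        got = fisher_meta_p(ps)
        expect = chi2_sf_even_df(-2.0 * sum(math.log(p) for p in ps), len(ps))
        assert got == pytest.approx(expect, abs=1e-10)
        assert fisher_meta_p(list(reversed(ps))) == got

    @given(
        ps=st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=5
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_adding_a_null_study_is_deterministic_vs_oracle(self, ps):
        with_null = ps + [1.0]
        expect = chi2_sf_even_df(
            -2.0 * sum(math.log(p) for p in with_null), len(with_null)
        )
        assert fisher_meta_p(with_null) == pytest.approx(expect, abs=1e-10)


class TestDiseaseGeneEdges:
    def test_single_record_weight_is_minus_log10_p(self):
        (edge,) = build_disease_gene_edges([rec(2_000, p=1e-8)], ANN)
        assert edge.weight == pytest.approx(8.0)
        assert edge.provenance == ("111",)

    def test_two_null_studies_give_weight_zero(self):
        records = [
            rec(2_000, p=1.0, pubmed="1"),
            rec(2_000, p=1.0, pubmed="2"),
        ]
        (edge,) = build_disease_gene_edges(records, ANN)
        assert edge.weight == 0.0
        assert edge.provenance == ("1", "2")

    def test_best_snp_in_gene_sets_the_weight(self):
        records = [
            rec(2_000, p=1e-6, snp="rs1", pubmed="1"),
            rec(2_500, p=1e-9, snp="rs2", pubmed="2"),
        ]
        (edge,) = build_disease_gene_edges(records, ANN)
        assert edge.weight == pytest.approx(9.0)
        assert edge.provenance == ("1", "2")

    def test_study_combination_happens_before_best_snp_selection(self):
        # same phenotype-SNP pair in two studies combines via Fisher first
        records = [
            rec(2_000, p=0.05, snp="rs1", pubmed="1"),
            rec(2_000, p=0.05, snp="rs1", pubmed="2"),
        ]
        (edge,) = build_disease_gene_edges(records, ANN)
        assert edge.weight == pytest.approx(
            -math.log10(fisher_meta_p([0.05, 0.05]))
        )

    def test_unmappable_records_skipped_not_fatal(self):
        records = [rec(2_000, p=1e-8), rec(5, chrom="cX", snp="rs9")]
        edges = build_disease_gene_edges(records, ANN)
        assert len(edges) == 1


class TestThresholdFilter:
    def dg(self, w):
        return Edge("D1", "G1", EdgeType.DISEASE_GENE, w)

    def test_boundary_weight_retained_inclusively(self):
        assert filter_by_threshold([self.dg(8.0)], 8.0) == [self.dg(8.0)]

    def test_weight_just_below_threshold_dropped(self):
        assert filter_by_threshold([self.dg(7.999)], 8.0) == []

    def test_tau_zero_retains_everything(self):
        edges = [self.dg(0.0), self.dg(8.0)]
        assert filter_by_threshold(edges, 0.0) == edges

    def test_other_edge_types_pass_through(self):
        ppi = Edge("A", "B", EdgeType.PROTEIN_PROTEIN)
        assert filter_by_threshold([ppi], 99.0) == [ppi]

    def test_negative_tau_rejected(self):
        with pytest.raises(DomainError):
            filter_by_threshold([], -1.0)

    @given(
        weights=st.lists(
            st.floats(min_value=0, max_value=12), min_size=0, max_size=30
        ),
        taus=st.tuples(
            st.floats(min_value=0, max_value=12),
            st.floats(min_value=0, max_value=12),
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_filter_is_monotone_in_tau_and_matches_brute_force(
        self, weights, taus
    ):
        edges = [
            Edge("D", f"G{i}", EdgeType.DISEASE_GENE, w)
            for i, w in enumerate(weights)
        ]
        t1, t2 = sorted(taus)
        at_t1 = {e.key for e in filter_by_threshold(edges, t1)}
        at_t2 = {e.key for e in filter_by_threshold(edges, t2)}
        assert at_t2 <= at_t1
        assert at_t1 == {e.key for e in edges if e.weight >= t1}


class TestTFBSDerivation:
    def site(self, pos, z, tf="GB", chrom="c1"):
        return TFBSRecord(tf, chrom, pos, z)

    def test_zscore_exactly_at_cutoff_excluded(self):
        # GA is '+' so its TSS is start=1000
        assert derive_tfbs_edges([self.site(1_000, 4.0)], ANN) == []

    def test_site_exactly_at_window_boundary_included(self):
        (edge,) = derive_tfbs_edges([self.site(6_000, 5.0)], ANN)
        assert (edge.source, edge.target) == ("GB", "GA")
        assert edge.directed and edge.weight == 1.0

    def test_tf_binding_its_own_promoter_yields_self_edge(self):
        # GB is '-' so its TSS is end=52000
        (edge,) = derive_tfbs_edges([self.site(52_100, 5.0)], ANN)
        assert edge.source == edge.target == "GB"

    def test_duplicate_sites_collapse_to_one_edge(self):
        sites = [self.site(1_100, 5.0), self.site(1_200, 6.0)]
        assert len(derive_tfbs_edges(sites, ANN)) == 1

    @given(
        sites=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=80_000),
                st.floats(min_value=0.0, max_value=10.0),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_site_by_gene_scan(self, sites):
        records = [self.site(pos, z) for pos, z in sites]
        got = {
            (e.source, e.target) for e in derive_tfbs_edges(records, ANN)
        }
        expect = set()
        for s in records:
            if not s.zscore > 4.0:
                continue
            genes = [g for g in ANN if g.chrom == s.chrom]
            best = min(abs(s.pos - g.tss) for g in genes)
            nearest = min(
                g.symbol for g in genes if abs(s.pos - g.tss) == best
            )
            if best <= 5_000:
                expect.add((s.tf_symbol, nearest))
        assert got == expect


class TestNeighborhoodExpansion:
    def universe(self):
        return make_network(
            [(g, "gene") for g in "ABCDE"],
            [("A", "B", "protein_protein"), ("B", "C", "protein_protein"),
             ("C", "D", "protein_protein"), ("D", "E", "protein_protein")],
        )

    def core(self):
        return make_network(
            [("D1", "disease"), ("A", "gene"), ("B", "gene")],
            [("D1", "A", "disease_gene", 8.0), ("D1", "B", "disease_gene", 8.0)],
        )

    def test_ds0_adds_only_edges_among_present_genes(self):
        out = expand_neighborhood(self.core(), self.universe(), 0)
        assert "C" not in out
        assert out.has_edge("A", "B", EdgeType.PROTEIN_PROTEIN)
        assert out.n == 3 and out.n_edges == 3

    def test_ds1_includes_first_neighbors(self):
        out = expand_neighborhood(self.core(), self.universe(), 1)
        assert "C" in out and "D" not in out
        assert out.has_edge("B", "C", EdgeType.PROTEIN_PROTEIN)

    def test_no_associated_genes_leaves_network_unchanged(self):
        lonely = make_network([("D1", "disease")], [])
        out = expand_neighborhood(lonely, self.universe(), 1)
        assert out == lonely

    def test_invalid_ds_rejected(self):
        with pytest.raises(DomainError):
            expand_neighborhood(self.core(), self.universe(), 3)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_equals_depth_limited_bfs(self, data):
        import networkx as nx

        n = data.draw(st.integers(min_value=2, max_value=15))
        p = data.draw(st.floats(min_value=0.05, max_value=0.5))
        seed = data.draw(st.integers(min_value=0, max_value=10_000))
        g = nx.fast_gnp_random_graph(n, p, seed=seed)
        genes = [f"G{i}" for i in range(n)]
        universe = make_network(
            [(x, "gene") for x in genes],
            [(genes[a], genes[b], "protein_protein") for a, b in g.edges()],
        )
        k = data.draw(st.integers(min_value=0, max_value=len(genes) - 1))
        ds = data.draw(st.sampled_from([0, 1, 2]))
        assoc = genes[: k + 1]
        core = make_network(
            [("D", "disease")] + [(x, "gene") for x in assoc],
            [("D", x, "disease_gene", 9.0) for x in assoc],
        )
        out = expand_neighborhood(core, universe, ds)
        reach = set(assoc)
        for s in assoc:
            lengths = nx.single_source_shortest_path_length(
                g, genes.index(s), cutoff=ds
            )
            reach |= {genes[i] for i in lengths}
        got_genes = {x.id for x in out.nodes_of_type(NodeType.GENE)}
        assert got_genes == reach
        expect_edges = {
            tuple(sorted((genes[a], genes[b])))
            for a, b in g.edges()
            if genes[a] in reach and genes[b] in reach
        }
        got_edges = {
            (e.source, e.target)
            for e in out.edges_of_type(EdgeType.PROTEIN_PROTEIN)
        }
        assert got_edges == expect_edges


class TestAssemble:
    def test_minimal_pipeline_one_significant_association(self):
        net = assemble(
            [rec(2_000, p=1e-8)], ANN, AssemblyConfig(threshold_tau=4.0)
        )
        assert net.n == 2 and net.n_edges == 1
        assert net.validate() == []

    def test_overlarge_tau_empties_unless_diseases_kept(self):
        records = [rec(2_000, p=1e-8)]
        empty = assemble(records, ANN, AssemblyConfig(threshold_tau=99.0))
        assert empty.n == 0
        kept = assemble(
            records,
            ANN,
            AssemblyConfig(threshold_tau=99.0, keep_isolated_diseases=True),
        )
        assert kept.node_ids == ["D1"]

    def test_edge_count_monotone_in_tau(self):
        from ictnet.synth import FixtureConfig, generate_fixture

        fx = generate_fixture(FixtureConfig(rng_seed=3))
        nets = {
            tau: assemble(
                fx.associations,
                fx.annotation,
                AssemblyConfig(threshold_tau=tau, layers=frozenset({"ppi"})),
                aux_layers=fx.aux_layers,
            )
            for tau in (4.0, 8.0)
        }
        assert nets[8.0].n_edges <= nets[4.0].n_edges


class TestReaders:
    def test_bed_coordinates_convert_to_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("c1\t999\t3000\tGA\t0\t+\nc1\t49999\t52000\tGB\t0\t-\n")
        got = read_gene_annotation_bed(bed)
        assert got[0] == GeneAnnotation("GA", "c1", 1_000, 3_000, "+")
        assert got[0].tss == 1_000 and got[1].tss == 52_000

    def test_zero_pvalue_clamped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "assoc.tsv"
        p.write_text(
            "snp_id\tchrom\tpos\tphenotype\tpvalue\tpubmed\n"
            "rs1\tc1\t2000\tD1\t0\t111\n"
        )
        with caplog.at_level("WARNING"):
            (got,) = read_association_table(p)
        assert got.pvalue == 1e-300
        assert any("clamped" in r.message for r in caplog.records)
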