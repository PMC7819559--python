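"""2x2 enrichment, expressed-gene rules and GO over-representation."""

import io
import itertools
import math

import numpy as np
import obonet
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from urbmeth.enrichment import (EnrichmentResult, expressed_gene_flag,
                                expression_enrichment, feature_enrichment,
                                go_enrichment, propagate_annotations,
                                sites_with_neighbors)


class TestTwoByTwo:
    def test_equal_proportions_give_odds_ratio_one(self):
        r = EnrichmentResult.from_counts("t", 30, 70, 300, 700)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value > 0.9

    def test_all_focal_in_property_is_infinite_and_flagged(self):
        r = EnrichmentResult.from_counts("t", 50, 0, 800, 200)
        assert math.isinf(r.odds_ratio)
        assert r.degenerate

    def test_empty_focal_rejected(self):
        with pytest.raises(ValueError, match="empty focal"):
            EnrichmentResult.from_counts("t", 0, 0, 10, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(1, 200), st.integers(1, 200),
                     st.integers(1, 200), st.integers(1, 200)))
    def test_swapping_focal_and_background_inverts_odds(self, counts):
        a, b, c, d = counts
        r = EnrichmentResult.from_counts("t", a, b, c, d)
        s = r.swap()
        assert s.odds_ratio == pytest.approx(1.0 / r.odds_ratio)
        assert s.p_value == pytest.approx(r.p_value, rel=1e-9)

    def test_feature_enrichment_builds_table_from_annotations(self):
        dms_ann = pd.DataFrame({"cgi": [True] * 8 + [False] * 2,
                                "nonregulatory": [False] * 10})
        bg_ann = pd.DataFrame({"cgi": [True] * 40 + [False] * 60,
                               "nonregulatory": [False] * 100})
        r = feature_enrichment(dms_ann, bg_ann, "cgi")
        assert (r.a, r.b, r.c, r.d) == (8, 2, 40, 60)
        assert r.odds_ratio == pytest.approx((8 / 2) / (40 / 60))

    def test_regulatory_is_complement_of_nonregulatory(self):
        ann = pd.DataFrame({"nonregulatory": [True, False, False]})
        bg = pd.DataFrame({"nonregulatory": [True] * 5 + [False] * 5})
        r = feature_enrichment(ann, bg, "regulatory")
        assert (r.a, r.b) == (2, 1)
        assert (r.c, r.d) == (5, 5)


class TestExpressedGeneFlag:
    def _counts(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])

    def test_ten_or_more_in_exactly_three_of_twelve_is_expressed(self):
        counts = self._counts([[10, 10, 10] + [0] * 9])
        assert expressed_gene_flag(counts).iloc[0]

    def test_nine_everywhere_is_not_expressed(self):
        counts = self._counts([[9] * 12])
        assert not expressed_gene_flag(counts).iloc[0]

    def test_all_zero_gene_not_expressed(self):
        counts = self._counts([[0] * 12])
        assert not expressed_gene_flag(counts).iloc[0]

    def test_fraction_rule_uses_ceiling(self):
        counts = self._counts([[10, 10] + [0] * 8])  # 2 of 10 < ceil(2.5) = 3
        assert not expressed_gene_flag(counts).iloc[0]


class TestSitesWithNeighbors:
    def test_triple_within_span_qualifies_all_members(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [100, 900, 1900, 9000]})
        mask = sites_with_neighbors(sites)
        assert mask.tolist() == [True, True, True, False]

    def test_pairs_only_never_qualify(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [100, 900, 5000, 5500]})
        assert not sites_with_neighbors(sites).any()

    def test_row_order_is_preserved(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [9000, 100, 1900, 900]})
        mask = sites_with_neighbors(sites)
        assert mask.tolist() == [False, True, True, True]


class TestExpressionEnrichment:
    def _ann(self, genes_list, positions=None):
        n = len(genes_list)
        return pd.DataFrame({
            "chrom": "chr1",
            "pos": positions if positions is not None else np.arange(n) * 100,
            "promoter": [bool(g) for g in genes_list],
            "tss": False, "gene_body": False,
            "genes": [tuple(g) for g in genes_list]})

    def test_counts_linked_expressed_genes(self):
        expressed = pd.Series({"gA": True, "gB": False})
        dms_ann = self._ann([("gA",), ("gB",), ()])
        bg_ann = self._ann([("gA",), ("gA",), ("gB",), ()])
        r = expression_enrichment(dms_ann, bg_ann, expressed)
        assert (r.a, r.b) == (1, 2)
        assert (r.c, r.d) == (2, 2)

    def test_gene_missing_from_counts_treated_unexpressed(self):
        expressed = pd.Series({"gA": True})
        dms_ann = self._ann([("gZ",), ("gA",)])
        r = expression_enrichment(dms_ann, self._ann([("gA",), ()]), expressed)
        assert (r.a, r.b) == (1, 1)

    def test_dmr_restricted_uses_clustered_background(self):
        expressed = pd.Series({"gA": True})
        dms_ann = self._ann([("gA",), (), ("gA",)], positions=[100, 900, 1900])
        bg_ann = self._ann([("gA",), ("gA",), (), ("gA",)],
                           positions=[100, 900, 1900, 50_000])
        r = expression_enrichment(dms_ann, bg_ann, expressed, dmr_restricted=True,
                                  dms_in_dmr=np.array([True, True, True]))
        # isolated background site at 50 kb is excluded from the background
        assert r.c + r.d == 3

    def test_randomised_flags_centre_odds_at_one(self, background_sites, catalog, dataset):
        from urbmeth.annotation import annotate_sites
        rng = np.random.default_rng(0)
        ann = annotate_sites(background_sites.sample(n=800, random_state=1), catalog)
        focal = ann.sample(n=200, random_state=2)
        genes = dataset.genes.gene_id.tolist()
        ors = []
        for _ in range(20):
            flags = pd.Series(rng.random(len(genes)) < 0.5, index=genes)
            r = expression_enrichment(focal, ann, flags)
            if np.isfinite(r.odds_ratio) and r.odds_ratio > 0:
                ors.append(math.log(r.odds_ratio))
        assert abs(np.mean(ors)) < 0.25


TOY_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: mid
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf_a
is_a: GO:0000002

[Term]
id: GO:0000004
name: leaf_b
relationship: part_of GO:0000002
"""


class TestGoEnrichment:
    @pytest.fixture()
    def ontology(self):
        return obonet.read_obo(io.StringIO(TOY_OBO))

    def test_true_path_propagation_covers_is_a_and_part_of(self, ontology):
        gt = pd.DataFrame({"gene_id": ["g1", "g2"], "term": ["GO:0000003", "GO:0000004"]})
        ann = propagate_annotations(gt, ontology)
        assert ann["g1"] == {"GO:0000003", "GO:0000002", "GO:0000001"}
        assert ann["g2"] == {"GO:0000004", "GO:0000002", "GO:0000001"}

    def test_focal_equal_background_gives_p_one(self, ontology):
        genes = [f"g{i}" for i in range(10)]
        gt = pd.DataFrame({"gene_id": genes,
                           "term": ["GO:0000003", "GO:0000004"] * 5})
        out = go_enrichment(genes, genes, gt, ontology)
        assert np.allclose(out.p_value, 1.0)

    def test_toy_hypergeometric_value(self, ontology):
        # N=10, K=5 annotated, n=4 focal all annotated: p = C(5,4)C(5,0)/C(10,4)
        genes = [f"g{i}" for i in range(10)]
        gt = pd.DataFrame({"gene_id": genes[:5], "term": "GO:0000003"})
        out = go_enrichment(genes[:4], genes, gt, ontology)
        row = out[out.term == "GO:0000003"].iloc[0]
        assert (row.k, row.K, row.n, row.N) == (4, 5, 4, 10)
        assert row.p_value == pytest.approx(5 / 210)

    def test_hypergeometric_matches_exhaustive_enumeration(self):
        for N in (6, 9, 12):
            for K in (2, N // 2, N - 1):
                for n in (2, N // 2):
                    for k in range(0, min(K, n) + 1):
                        exact = sum(
                            1 for draw in itertools.combinations(range(N), n)
                            if sum(1 for x in draw if x < K) >= k
                        ) / math.comb(N, n)
                        assert stats.hypergeom.sf(k - 1, N, K, n) == pytest.approx(exact)

    def test_unannotated_genes_count_in_totals_only(self, ontology):
        genes = [f"g{i}" for i in range(8)]
        gt = pd.DataFrame({"gene_id": genes[:4], "term": "GO:0000003"})
        out = go_enrichment(genes[:4], genes, gt, ontology)
        assert (out.N == 8).all() and (out.n == 4).all()

    def test_planted_term_detected(self, ontology):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(60)]
        rows = [(g, "GO:0000004") for g in genes]
        rows += [(g, "GO:0000003") for g in genes[:12]]  # the planted term
        gt = pd.DataFrame(rows, columns=["gene_id", "term"])
        hits = 0
        for _ in range(10):
            focal = list(rng.choice(genes[:12], size=6, replace=False)) + \
                list(rng.choice(genes[12:], size=2, replace=False))
            out = go_enrichment(focal, genes, gt, ontology)
            row = out[out.term == "GO:0000003"]
            hits += bool(len(row)) and bool(row.iloc[0].fdr < 0.05)
        assert hits >= 9

    def test_fdr_at_least_p(self, ontology):
        genes = [f"g{i}" for i in range(20)]
        gt = pd.DataFrame({"gene_id": genes,
                           "term": (["GO:0000003"] * 7 + ["GO:0000004"] * 13)})
        out = go_enrichment(genes[:6], genes, gt, ontology)
        assert (out.fdr >= out.p_value - 1e-12).all()
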