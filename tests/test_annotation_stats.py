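"""Gene/TSS/feature proximity and the chi-squared goodness-of-fit test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from riscall.annotation_stats import (
    GENE_CATEGORIES,
    ProximityReport,
    annotate_features,
    annotate_gene,
    annotate_site,
    annotate_tss,
    chisq_gof,
    gene_category,
    summarize,
)
from riscall.config import PipelineConfig
from riscall.formats_io import GeneModel, GenomicFeature


def gene(name, start, end, strand="+", chrom="chr1"):
    return GeneModel(name, chrom, strand, start, end)


def report(pos, chrom="chr1", strand="+"):
    return ProximityReport(chrom=chrom, strand=strand, position=pos)


class TestAnnotateGene:
    def test_containment(self, cfg):
        r = annotate_gene(report(5000), [gene("g", 4000, 6000)], cfg)
        assert r.in_gene and r.gene_distance == 0 and r.gene_name == "g"

    def test_nearest_within_5kb(self, cfg):
        r = annotate_gene(report(3500), [gene("g", 4000, 6000)], cfg)
        assert not r.in_gene
        assert (r.gene_name, r.gene_distance) == ("g", 500)
        assert r.gene_side == "upstream"

    def test_beyond_5kb_unreported(self, cfg):
        r = annotate_gene(report(3500), [gene("g", 9000, 12000)], cfg)
        assert r.gene_name is None and r.gene_distance is None

    def test_exactly_5kb_reported(self, cfg):
        r = annotate_gene(report(4000), [gene("g", 9000, 12000)], cfg)
        assert (r.gene_name, r.gene_distance) == ("g", 5000)

    def test_containment_tie_smallest_span(self, cfg):
        genes = [gene("big", 1000, 9000), gene("small", 4000, 6000)]
        r = annotate_gene(report(5000), genes, cfg)
        assert r.gene_name == "small"

    def test_downstream_side_of_minus_gene(self, cfg):
        # position left of a '-' gene is past its 3' end -> downstream
        r = annotate_gene(report(3500), [gene("g", 4000, 6000, strand="-")], cfg)
        assert r.gene_side == "downstream"

    def test_matches_bruteforce_nearest_scan(self, cfg, rng):
        genes = []
        for i in range(100):
            s = int(rng.integers(1, 200_000))
            genes.append(gene(f"g{i}", s, s + int(rng.integers(100, 3000)),
                              strand="+-"[i % 2]))
        for _ in range(200):
            pos = int(rng.integers(1, 205_000))
            r = annotate_gene(report(pos), genes, cfg)
            # oracle: exhaustive interval distances
            dists = []
            for g in genes:
                if g.tx_start <= pos <= g.tx_end:
                    d = 0
                elif pos < g.tx_start:
                    d = g.tx_start - pos
                else:
                    d = pos - g.tx_end
                dists.append(d)
            best = min(dists)
            if best == 0:
                assert r.in_gene and r.gene_distance == 0
            elif best <= cfg.gene_max_dist:
                assert r.gene_distance == best
            else:
                assert r.gene_name is None


class TestAnnotateTss:
    def test_at_plus_strand_tss(self):
        r = annotate_tss(report(4000), [gene("g", 4000, 6000)])
        assert (r.tss_gene_name, r.tss_distance) == ("g", 0)

    def test_nearer_tss_of_another_gene_wins(self):
        genes = [gene("host", 1000, 20_000), gene("other", 10_200, 15_000)]
        r = annotate_tss(report(10_000), genes)
        assert r.tss_gene_name == "other"
        assert r.tss_distance == -200  # 200 bp upstream of other's TSS

    def test_minus_strand_upstream_is_negative(self):
        # '-' gene TSS = tx_end; a site 300 bp to its right is upstream
        r = annotate_tss(report(6300), [gene("g", 4000, 6000, strand="-")])
        assert r.tss_distance == -300

    def test_minus_strand_downstream_is_positive(self):
        r = annotate_tss(report(5700), [gene("g", 4000, 6000, strand="-")])
        assert r.tss_distance == 300

    def test_no_genes_on_chromosome(self):
        r = annotate_tss(report(5000), [gene("g", 1, 10, chrom="chr9")])
        assert r.tss_gene_name is None and r.tss_distance is None


class TestAnnotateFeatures:
    FEATS = {"cpg": [GenomicFeature("a", "chr1", 1000, 2000),
                     GenomicFeature("b", "chr1", 5000, 6000)]}

    def test_within(self):
        r = annotate_features(report(1500), self.FEATS)
        assert r.features["cpg"] == (True, "a", 0)

    def test_one_bp_past_end(self):
        r = annotate_features(report(2001), self.FEATS)
        assert r.features["cpg"] == (False, "a", 1)

    def test_equidistant_tie_breaks_on_name(self):
        r = annotate_features(report(3500), self.FEATS)  # 1500 from both
        assert r.features["cpg"] == (False, "a", 1500)

    def test_empty_list(self):
        r = annotate_features(report(3500), {"empty": []})
        assert r.features["empty"] == (False, None, None)


class TestChisqGof:
    def test_exact_fit(self):
        res = chisq_gof([50, 50], [0.5, 0.5])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.dof == 1

    def test_hand_computed_statistic(self):
        res = chisq_gof([10, 90], [0.5, 0.5])
        assert res.statistic == pytest.approx(64.0, abs=1e-12)  # 2 * 40^2/50

    def test_three_category_exact_fit(self):
        res = chisq_gof([30, 20, 50], [0.3, 0.2, 0.5])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.dof == 2

    def test_expected_scaled_to_observed_total(self):
        res = chisq_gof([10, 90], [0.25, 0.75])
        assert sum(res.expected) == pytest.approx(100, abs=1e-9)

    def test_zero_expected_with_observed_errors(self):
        with pytest.raises(ValueError, match="merge"):
            chisq_gof([10, 90], [0.0, 1.0])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(1, 500), min_size=2, max_size=6),
        st.lists(st.integers(1, 50), min_size=6, max_size=6),
    )
    def test_agrees_with_reference_implementation(self, observed, weights):
        """Statistic and p match scipy.stats.chisquare to 1e-9."""
        weights = weights[: len(observed)]
        props = np.array(weights, dtype=float) / sum(weights)
        res = chisq_gof(observed, props)
        expected = np.array(observed).sum() * props
        ref = scipy_stats.chisquare(observed, expected)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestSummarize:
    def make_reports(self, n, n_in_gene, genes, cfg):
        # in-gene sites at 5000 (inside g1), others far away
        reports = []
        for i in range(n):
            pos = 5000 if i < n_in_gene else 50_000
            reports.append(annotate_site("chr1", "+", pos, genes, None, cfg))
        return reports

    def test_pct_in_genes(self, cfg):
        genes = [gene("g1", 4000, 6000)]
        summary, _ = summarize(self.make_reports(100, 70, genes, cfg), None, cfg)
        assert summary.pct_in_genes == 70.0
        assert summary.n_unique == 100

    def test_equal_proportions_give_zero_statistic(self, cfg):
        genes = [gene("g1", 4000, 6000)]
        obs = self.make_reports(40, 10, genes, cfg)
        rand = self.make_reports(80, 20, genes, cfg)  # same 1:3 split
        _, tests = summarize(obs, rand, cfg)
        assert tests and tests[0][1].statistic == pytest.approx(0.0, abs=1e-12)
        assert tests[0][1].p_value == pytest.approx(1.0)

    def test_lentiviral_like_enrichment_detected(self, cfg, rng):
        """80 % in-gene observed vs near-uniform random on a gene-sparse
        genome: the chi-squared test must reject at n = 100."""
        genes = [gene("g1", 10_000, 12_000)]  # 2 kb gene on a 200 kb chrom
        obs = []
        for i in range(100):
            pos = 11_000 if i < 80 else int(rng.integers(30_000, 200_000))
            obs.append(annotate_site("chr1", "+", pos, genes, None, cfg))
        rand = [
            annotate_site("chr1", "+", int(rng.integers(1, 200_000)), genes, None, cfg)
            for _ in range(5000)
        ]
        _, tests = summarize(obs, rand, cfg)
        res = dict(tests)["gene_proximity"]
        assert res.statistic > 0 and res.p_value < 0.05

    def test_categories_partition_observed_set(self, cfg):
        genes = [gene("g1", 4000, 6000)]
        obs = self.make_reports(37, 12, genes, cfg)
        _, tests = summarize(obs, self.make_reports(50, 25, genes, cfg), cfg)
        res = dict(tests)["gene_proximity"]
        assert sum(res.observed) == 37

    def test_no_random_set_yields_summary_without_tests(self, cfg):
        genes = [gene("g1", 4000, 6000)]
        summary, tests = summarize(self.make_reports(10, 5, genes, cfg), None, cfg)
        assert summary.n_unique == 10 and tests == []

    def test_feature_test_two_categories(self, cfg):
        genes = [gene("g1", 4000, 6000)]
        feats = {"cpg": [GenomicFeature("a", "chr1", 4900, 5100)]}
        obs = [annotate_site("chr1", "+", 5000, genes, feats, cfg) for _ in range(8)]
        obs += [annotate_site("chr1", "+", 50_000, genes, feats, cfg) for _ in range(2)]
        rand = [annotate_site("chr1", "+", p, genes, feats, cfg)
                for p in range(1000, 101_000, 1000)]
        summary, tests = summarize(obs, rand, cfg)
        assert summary.feature_within_counts["cpg"] == 8
        res = dict(tests)["feature:cpg"]
        assert res.categories == ("within", "not_within")
        assert sum(res.observed) == 10
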