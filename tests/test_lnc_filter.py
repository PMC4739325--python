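import numpy as np
import pytest

from slinc.genomic_io import GenomicInterval, Transcript
from slinc.lnc_filter import (
    COLLAPSED,
    KEPT,
    REMOVED_CODING,
    REMOVED_DUP,
    REMOVED_SINGLE_EXON,
    REMOVED_SYNTENIC,
    CodingFilterModel,
    FilterConfig,
    find_duplication_clusters,
    remove_coding_overlap,
    run_filter_pipeline,
    select_canonical_isoforms,
)


def _tx(tid, exons, strand="+", chrom="c1"):
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    span = GenomicInterval(chrom, ivs[0].start, ivs[-1].end, strand)
    return Transcript(id=tid, gene_id=tid, interval=span, exons=ivs)


class TestCodingOverlap:
    CODING = [_tx("cod", [(1000, 1500), (2000, 2500)])]

    def test_single_bp_same_strand_removed(self):
        cand = _tx("x", [(500, 1001), (3000, 3200)])
        kept, removed = remove_coding_overlap([cand], self.CODING)
        assert [t.id for t in removed] == ["x"]

    def test_opposite_strand_kept(self):
        cand = _tx("x", [(900, 1600), (3000, 3200)], strand="-")
        kept, removed = remove_coding_overlap([cand], self.CODING)
        assert [t.id for t in kept] == ["x"]

    def test_intronic_only_overlap_kept_in_exon_mode(self):
        cand = _tx("x", [(1600, 1700), (1750, 1900)])  # inside the intron
        kept, removed = remove_coding_overlap([cand], self.CODING, mode="exon")
        assert [t.id for t in kept] == ["x"]

    def test_span_mode_removes_intronic(self):
        cand = _tx("x", [(1600, 1700), (1750, 1900)])
        kept, removed = remove_coding_overlap([cand], self.CODING, mode="span")
        assert [t.id for t in removed] == ["x"]


class TestCanonicalIsoforms:
    def test_longest_exonic_wins(self):
        a = _tx("short", [(0, 500)])
        b = _tx("long", [(100, 600), (700, 1000)])
        canonical, clusters = select_canonical_isoforms([a, b])
        assert [t.id for t in canonical] == ["long"]
        assert sorted(clusters["long"]) == ["long", "short"]

    def test_transitive_clustering(self):
        a = _tx("a", [(0, 300)])
        b = _tx("b", [(200, 600)])
        c = _tx("c", [(500, 900)])
        canonical, clusters = select_canonical_isoforms([a, b, c])
        assert len(canonical) == 1
        assert sorted(clusters[canonical[0].id]) == ["a", "b", "c"]

    def test_disjoint_all_canonical(self):
        txs = [_tx("a", [(0, 300)]), _tx("b", [(1000, 1300)])]
        canonical, _ = select_canonical_isoforms(txs)
        assert sorted(t.id for t in canonical) == ["a", "b"]

    def test_same_position_opposite_strand_not_clustered(self):
        a = _tx("fwd", [(0, 300)])
        b = _tx("rev", [(0, 300)], strand="-")
        canonical, _ = select_canonical_isoforms([a, b])
        assert len(canonical) == 2


class TestThresholdModel:
    def test_all_ones_gives_one(self):
        m = CodingFilterModel.from_scores([1.0] * 20)
        assert m.threshold == 1.0

    def test_empirical_fifth_percentile_order_statistic(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0.3, 1.0, size=100)
        m = CodingFilterModel.from_scores(scores)
        assert m.threshold == sorted(scores)[int(np.floor(0.05 * 99))]

    def test_too_few_positives_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            CodingFilterModel.from_scores([0.9] * 9)


class TestDuplicationClusters:
    def test_planted_family_removed_uniques_kept(self, fx7, filter_result):
        report = filter_result["report"]
        (cluster,) = report.clusters
        assert cluster.members == ("dupA_0", "dupA_1", "dupA_2")
        assert any(hit[1] == "ZFP_toy" for hit in cluster.known_family_hits)
        kept_ids = {t.id for t in filter_result["kept"]}
        assert "lincA_0" in kept_ids

    def test_min_cluster_size_above_family_keeps_it(self, fx7):
        dups = [t for t in fx7.candidates_a if t.id.startswith(("dupA", "lincA"))]
        kept, clusters = find_duplication_clusters(
            dups, fx7.genome_a, fx7.annotations_a(), n_null=50,
            min_cluster_size=4, rng_seed=0,
        )
        assert clusters == []
        assert {t.id for t in kept} == {t.id for t in dups}


class TestPipeline:
    def test_fates_match_fixture_truth(self, fx7, filter_result):
        assert filter_result["report"].fates == fx7.truth.expected_fates()

    def test_fates_partition_input(self, fx7, filter_result):
        report = filter_result["report"]
        assert sum(report.counts.values()) == len(fx7.candidates_a)

    def test_empty_candidates(self, fx7):
        cfg = FilterConfig(
            genome_a=fx7.genome_a, coding_a=fx7.coding_a,
            genome_b=fx7.genome_b, coding_b=fx7.coding_b,
            chains=fx7.chains, enable_syntenic=False,
        )
        kept, report, single = run_filter_pipeline([], cfg)
        assert kept == [] and single == []
        assert all(v == 0 for v in report.counts.values())

    def test_disable_syntenic_stage(self, fx7):
        cfg = FilterConfig(
            genome_a=fx7.genome_a, coding_a=fx7.coding_a,
            genome_b=fx7.genome_b, coding_b=fx7.coding_b,
            chains=fx7.chains, enable_syntenic=False, seed=1,
        )
        kept, report, _ = run_filter_pipeline(fx7.candidates_a, cfg)
        assert report.counts[REMOVED_SYNTENIC] == 0
        assert {t.id for t in kept} >= {"pseudoA_0", "utrfragA_1"}

    def test_idempotent_on_kept_set(self, fx7, filter_result):
        cfg = FilterConfig(
            genome_a=fx7.genome_a, coding_a=fx7.coding_a,
            genome_b=fx7.genome_b, coding_b=fx7.coding_b,
            chains=fx7.chains,
            identity_threshold=filter_result["report"].model.threshold,
            seed=1,
        )
        kept2, report2, _ = run_filter_pipeline(filter_result["kept"], cfg)
        assert {t.id for t in kept2} == {t.id for t in filter_result["kept"]}
        assert all(f == KEPT for f in report2.fates.values())

    def test_expected_fate_constants_cover_truth(self, fx7):
        fates = set(fx7.truth.expected_fates().values())
        assert fates == {
            KEPT, REMOVED_CODING, COLLAPSED, REMOVED_DUP,
            REMOVED_SYNTENIC, REMOVED_SINGLE_EXON,
        }
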