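import numpy as np
import pytest
from scipy.stats import fisher_exact

from helpers import fisher_two_sided_oracle

from slinc.fixtures import plant_promoter_set
from slinc.genomic_io import GenomeSequence, GenomicInterval, Transcript
from slinc.promoters import (
    annotate_promoters,
    call_cpg_islands,
    gc_fraction,
    promoter_interval,
    repeat_enrichment,
    sample_matched_background,
)


def _tx(tid, start, end, strand="+", chrom="c1"):
    iv = GenomicInterval(chrom, start, end, strand)
    return Transcript(id=tid, gene_id=tid, interval=iv, exons=[iv])


class TestPromoterInterval:
    def test_plus_strand(self):
        iv = promoter_interval(_tx("t", 1000, 2000))
        assert (iv.start, iv.end) == (500, 1000)

    def test_minus_strand(self):
        iv = promoter_interval(_tx("t", 500, 1000, strand="-"))
        assert (iv.start, iv.end) == (1000, 1500)

    def test_clipped_at_contig_start(self):
        iv = promoter_interval(_tx("t", 200, 900))
        assert (iv.start, iv.end) == (0, 200)


class TestAnnotate:
    GENOME = GenomeSequence({"c1": "ACGT" * 1000})

    def test_repeat_fraction_full(self):
        prom = GenomicInterval("c1", 100, 200)
        rec, = annotate_promoters(
            [("t", prom)], [], [(GenomicInterval("c1", 0, 400), "L1")], self.GENOME
        )
        assert rec.repeat_fraction == 1.0

    def test_no_cpg_overlap_false(self):
        prom = GenomicInterval("c1", 100, 200)
        rec, = annotate_promoters(
            [("t", prom)], [(GenomicInterval("c1", 300, 400), "CpG")], [], self.GENOME
        )
        assert not rec.has_cpg

    def test_gc_count(self):
        genome = GenomeSequence({"c1": "A" * 60 + "GC" * 20 + "A" * 100})
        prom = GenomicInterval("c1", 0, 100)
        rec, = annotate_promoters([("t", prom)], [], [], genome)
        assert rec.gc_fraction == pytest.approx(0.4)

    def test_overlapping_repeats_union(self):
        prom = GenomicInterval("c1", 100, 200)
        reps = [
            (GenomicInterval("c1", 100, 160), "L1"),
            (GenomicInterval("c1", 140, 180), "L2"),
        ]
        rec, = annotate_promoters([("t", prom)], [], reps, self.GENOME)
        assert rec.repeat_bp == 80


class TestFisherOracle:
    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            table = [
                [int(rng.integers(0, 15)), int(rng.integers(0, 15))],
                [int(rng.integers(0, 15)), int(rng.integers(0, 15))],
            ]
            if sum(table[0]) == 0 or sum(table[1]) == 0:
                continue
            _, p = fisher_exact(table, alternative="two-sided")
            assert p == pytest.approx(fisher_two_sided_oracle(table), abs=1e-12)

    def test_identical_proportions_p_one(self):
        _, p = fisher_exact([[5, 5], [5, 5]])
        assert p == 1.0


class TestBackgroundSampling:
    def _setup(self):
        genome, promoters, repeat_bed, blocked = plant_promoter_set(rng_seed=0)
        records = annotate_promoters(promoters, [], repeat_bed, genome)
        return genome, records, repeat_bed, blocked

    def test_matched_lengths_and_gc(self):
        genome, records, _, blocked = self._setup()
        bg = sample_matched_background(records, genome, blocked, rng_seed=1)
        assert len(bg) == len(records)
        for rec, iv in zip(records, bg):
            assert len(iv) == len(rec.interval)
            assert abs(gc_fraction(genome.fetch(iv)) - rec.gc_fraction) <= 0.02

    def test_background_avoids_blocked_spans(self):
        genome, records, _, blocked = self._setup()
        bg = sample_matched_background(records, genome, blocked, rng_seed=2)
        for iv in bg:
            assert not any(iv.overlaps(b) for b in blocked)

    def test_unmatchable_promoter_errors(self):
        genome = GenomeSequence({"c1": "AT" * 5000})
        rec, = annotate_promoters(
            [("t", GenomicInterval("c1", 100, 200))], [], [], genome
        )
        rec.gc_fraction = 0.9  # unattainable in an AT-only genome
        with pytest.raises(ValueError, match="t"):
            sample_matched_background([rec], genome, [], rng_seed=0, max_tries=50)


class TestEnrichment:
    def test_planted_family_is_the_only_significant_one(self):
        genome, promoters, repeat_bed, blocked = plant_promoter_set(rng_seed=3)
        records = annotate_promoters(promoters, [], repeat_bed, genome)
        bg = sample_matched_background(records, genome, blocked, rng_seed=4)
        results = repeat_enrichment(records, bg, repeat_bed, alpha=0.005)
        significant = {r.family for r in results if r.significant}
        assert significant == {"ERVK_toy"}

    def test_background_vs_background_not_significant(self):
        genome, promoters, repeat_bed, blocked = plant_promoter_set(rng_seed=5)
        records = annotate_promoters(promoters, [], repeat_bed, genome)
        hits = 0
        for seed in range(5):
            bg1 = sample_matched_background(records, genome, blocked, rng_seed=10 + seed)
            bg2 = sample_matched_background(records, genome, blocked, rng_seed=20 + seed)
            fake = annotate_promoters(
                [(f"bg{i}", iv) for i, iv in enumerate(bg1)], [], repeat_bed, genome
            )
            results = repeat_enrichment(fake, bg2, repeat_bed, alpha=0.005)
            hits += sum(r.significant for r in results)
        assert hits == 0


class TestCpgCalling:
    def test_planted_island_found(self):
        rng = np.random.default_rng(0)
        from slinc.fixtures import _cpg_rich, _random_seq

        seq = _random_seq(3000, rng) + _cpg_rich(400, rng) + _random_seq(3000, rng)
        islands = call_cpg_islands(GenomeSequence({"c": seq}))
        assert any(iv.start < 3400 and iv.end > 3000 for iv, _ in islands)
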