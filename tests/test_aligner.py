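import numpy as np
import pytest

from helpers import brute_sw_affine, numpy_sw_affine

from slinc.aligner import (
    IntergenicSampler,
    LocalAlignment,
    ScoringScheme,
    alignment_identity,
    best_local_score,
    empirical_significance,
    local_align,
    sample_intergenic,
)
from slinc.genomic_io import GenomeSequence, GenomicInterval, Transcript, reverse_complement


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScoringScheme:
    def test_reduced_gap_preset(self):
        s = ScoringScheme.lncrna()
        assert (s.gap_open, s.gap_extend) == (25, 40)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(seed_length=4)
        with pytest.raises(ValueError):
            ScoringScheme(match=0)


class TestLocalAlign:
    def test_self_alignment_perfect(self):
        rng = np.random.default_rng(0)
        seq = _rand_seq(rng, 500)
        (aln,) = local_align(seq, seq)
        assert aln.identity == 1.0
        assert aln.score == 500 * 5
        assert all(op == "M" for op, _ in aln.ops)

    def test_reverse_complement_no_seeds(self):
        rng = np.random.default_rng(1)
        seq = _rand_seq(rng, 400)
        assert local_align(seq, reverse_complement(seq)) == []

    def test_too_short_for_seed(self):
        assert local_align("ACGTACG", "ACGTACG") == []

    def test_score_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            core = _rand_seq(rng, 60)
            a = _rand_seq(rng, 100) + core + _rand_seq(rng, 50)
            b = _rand_seq(rng, 30) + core + _rand_seq(rng, 120)
            sa = local_align(a, b)[0].score
            sb = local_align(b, a)[0].score
            assert sa == sb

    def test_ops_rescore_to_reported_score(self):
        rng = np.random.default_rng(3)
        s = ScoringScheme.lncrna()
        base = _rand_seq(rng, 1500)
        mutated = "".join(
            c if rng.random() > 0.05 else "ACGT"[rng.integers(0, 4)] for c in base
        )
        a = _rand_seq(rng, 800) + base + _rand_seq(rng, 400)
        b = _rand_seq(rng, 300) + mutated + _rand_seq(rng, 900)
        for aln in local_align(a, b, s):
            total = 0
            for op, n in aln.ops:
                if op == "M":
                    total += n * s.match
                elif op == "X":
                    total -= n * s.mismatch
                else:
                    total -= s.gap_open + s.gap_extend * n
            assert total == aln.score

    @pytest.mark.parametrize("n_pairs", [60])
    def test_matches_full_dp_oracle(self, n_pairs):
        """Seeded top score equals an independent affine DP on short pairs
        with a planted exact core."""
        rng = np.random.default_rng(11)
        s = ScoringScheme()
        for _ in range(n_pairs):
            core = _rand_seq(rng, int(rng.integers(12, 40)))
            a = _rand_seq(rng, int(rng.integers(20, 140))) + core + _rand_seq(
                rng, int(rng.integers(10, 120))
            )
            b = _rand_seq(rng, int(rng.integers(10, 120))) + core + _rand_seq(
                rng, int(rng.integers(20, 140))
            )
            a, b = a[:300], b[:300]
            expected = numpy_sw_affine(a, b, s.match, s.mismatch, s.gap_open, s.gap_extend)
            got = local_align(a, b, s)
            assert got and got[0].score == expected
            assert best_local_score(a, b, s) == expected

    def test_numpy_oracle_agrees_with_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = _rand_seq(rng, int(rng.integers(15, 60)))
            b = _rand_seq(rng, int(rng.integers(15, 60)))
            core = _rand_seq(rng, 12)
            a = core + a
            b = b + core
            for open_, ext in ((25, 40), (400, 30), (10, 5)):
                assert brute_sw_affine(a, b, 5, 4, open_, ext) == numpy_sw_affine(
                    a, b, 5, 4, open_, ext
                )


class TestIdentity:
    def _aln(self, ops):
        q = sum(n for op, n in ops if op in "MXI")
        t = sum(n for op, n in ops if op in "MXD")
        return LocalAlignment(0, q, 0, t, ops, score=1)

    def test_matches_and_mismatches(self):
        assert alignment_identity(self._aln([("M", 90), ("X", 10)])) == 0.90

    def test_gap_columns_count_in_denominator(self):
        assert alignment_identity(self._aln([("M", 90), ("I", 10)])) == 0.90

    def test_no_matches(self):
        assert alignment_identity(self._aln([("X", 20)])) == 0.0

    def test_all_n_query_never_matches(self):
        seq = "N" * 100
        other = "ACGT" * 25
        assert local_align(seq, other) == []  # N k-mers are not seeds

    def test_score_in_query_range(self):
        s = ScoringScheme()
        aln = self._aln([("M", 10), ("X", 2), ("M", 8)])
        assert aln.score_in_query_range(0, 20, s) == 10 * 5 - 2 * 4 + 8 * 5
        assert aln.score_in_query_range(0, 10, s) == 50


class TestIntergenicSampling:
    def _toy(self):
        genome = GenomeSequence({"c1": "ACGT" * 2500})
        iv = GenomicInterval("c1", 2000, 6000, "+")
        tx = Transcript(id="t", gene_id="t", interval=iv, exons=[iv])
        return genome, [tx]

    def test_fully_covered_genome_errors(self):
        genome = GenomeSequence({"c1": "ACGT" * 100})
        iv = GenomicInterval("c1", 0, 400, "+")
        tx = Transcript(id="t", gene_id="t", interval=iv, exons=[iv])
        with pytest.raises(ValueError):
            sample_intergenic(genome, [tx], 100, rng_seed=0)

    def test_seed_reproducible(self):
        genome, anns = self._toy()
        assert sample_intergenic(genome, anns, 300, rng_seed=5) == sample_intergenic(
            genome, anns, 300, rng_seed=5
        )

    def test_draws_never_overlap_annotations(self):
        genome, anns = self._toy()
        sampler = IntergenicSampler(genome, anns)
        rng = np.random.default_rng(0)
        for _ in range(2000):
            iv = sampler.sample(137, rng)
            assert iv.end <= 2000 or iv.start >= 6000


class TestEmpiricalSignificance:
    def test_alpha_one_keeps_any_alignment(self, fx7):
        rng = np.random.default_rng(0)
        sampler = IntergenicSampler(fx7.genome_a, fx7.annotations_a())
        q = sampler.sample_seq(300, rng)
        t = q[:150] + sampler.sample_seq(150, rng)
        kept, sig = empirical_significance(
            q, t, fx7.genome_a, fx7.annotations_a(), n_null=20, alpha=1.0,
            rng_seed=rng, sampler=sampler,
        )
        assert kept is not None
        assert 0 < sig.empirical_p <= 1

    def test_planted_homolog_kept(self, fx7):
        """A 70%-identity 1 kb homolog beats the intergenic null."""
        rng = np.random.default_rng(1)
        sampler = IntergenicSampler(fx7.genome_a, fx7.annotations_a())
        q = sampler.sample_seq(1000, rng)
        t = "".join(
            c if rng.random() > 0.3 else "ACGT"[rng.integers(0, 4)] for c in q
        )
        kept, sig = empirical_significance(
            q, t, fx7.genome_a, fx7.annotations_a(), n_null=100,
            rng_seed=rng, sampler=sampler,
        )
        assert kept is not None and sig.empirical_p <= 0.05

    def test_add_one_estimator_never_zero(self):
        from slinc.aligner import AlignmentSignificance

        sig = AlignmentSignificance(score=100, null_scores=[0] * 200)
        assert sig.empirical_p == pytest.approx(1 / 201)
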