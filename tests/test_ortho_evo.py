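import math

import numpy as np
import pytest

from slinc.aligner import AlignmentSignificance, ScoringScheme
from slinc.genomic_io import GenomeSequence, GenomicInterval, Transcript
from slinc.ortho_evo import (
    DIVERGENT,
    INTERGENIC,
    MIRNA_HOST,
    SNORNA_HOST,
    EvoMetrics,
    OrthologPair,
    canonical_pair_per_gene,
    classify_lncrna,
    classify_pair,
    evo_metrics,
    exon_identity_profile,
    fit_tti_mixture,
    is_exonic_host,
    reciprocal_orthologs,
    shuffled_transcript_control,
    splice_shuffle_expectation,
)


def _tx(tid, exons, strand="+", chrom="c1", gene=None):
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    span = GenomicInterval(chrom, ivs[0].start, ivs[-1].end, strand)
    return Transcript(id=tid, gene_id=gene or tid, interval=span, exons=ivs)


def _pair(query, target):
    return OrthologPair(
        species_a="A", species_b="B", query=query, target=target,
        significance=AlignmentSignificance(score=1, null_scores=[0]),
        transcript_aligned=True,
    )


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMetricIdentities:
    def test_self_alignment_identity(self, fx7):
        """Aligning each fixture transcript to itself gives TGI=TTI=1,
        SSC=1 (where junctions exist) and IDR=0 (where defined)."""
        for tx in fx7.candidates_a[:8]:
            m = evo_metrics(_pair(tx, tx), fx7.genome_a, fx7.genome_a)
            assert m.tgi == pytest.approx(1.0, abs=1e-9)
            assert m.tti == pytest.approx(1.0, abs=1e-9)
            if tx.n_exons > 1:
                assert m.ssc == pytest.approx(1.0, abs=1e-9)
            if m.idr is not None:
                assert m.idr == pytest.approx(0.0, abs=1e-9)


class TestConstructedMetrics:
    def _genomes(self, seq_a, seq_b):
        return GenomeSequence({"c1": seq_a}), GenomeSequence({"c1": seq_b})

    def test_partially_transcribed_target(self):
        """Target transcribes exon 1 fully but only the last 20 bp of the
        image of exon 2: TTI counts only those bases."""
        rng = np.random.default_rng(0)
        seq = _rand_seq(rng, 400)
        ga, gb = self._genomes(seq, seq)
        tx_a = _tx("a", [(0, 100), (200, 300)])
        tx_b = _tx("b", [(0, 100), (280, 300)])
        m = evo_metrics(_pair(tx_a, tx_b), ga, gb)
        assert m.tgi == pytest.approx(1.0, abs=1e-9)
        assert m.tti == pytest.approx(120 / 200, abs=1e-9)
        assert m.ssc == pytest.approx(1.0, abs=1e-9)  # donor boundary matches
        assert m.idr == pytest.approx(0.0, abs=1e-9)

    def test_mismatches_reduce_identity(self):
        rng = np.random.default_rng(1)
        seq = _rand_seq(rng, 400)
        mutated = list(seq)
        for pos in (10, 11, 12, 13, 14):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        ga, gb = self._genomes(seq, "".join(mutated))
        tx_a = _tx("a", [(0, 100), (200, 300)])
        tx_b = _tx("b", [(0, 100), (200, 300)])
        m = evo_metrics(_pair(tx_a, tx_b), ga, gb)
        assert m.tgi == pytest.approx(195 / 200, abs=1e-9)
        assert m.tti == pytest.approx(195 / 200, abs=1e-9)

    def test_one_of_two_junctions_conserved(self):
        rng = np.random.default_rng(2)
        seq = _rand_seq(rng, 700)
        ga, gb = self._genomes(seq, seq)
        tx_a = _tx("a", [(0, 100), (200, 300), (400, 500)])
        # second junction displaced by 5 bp (> tol 2)
        tx_b = _tx("b", [(0, 100), (200, 305), (405, 500)])
        m = evo_metrics(_pair(tx_a, tx_b), ga, gb)
        assert m.ssc == pytest.approx(0.5, abs=1e-9)

    def test_intronic_indel_rate_hand_value(self):
        rng = np.random.default_rng(3)
        seq = _rand_seq(rng, 450)
        seq_b = seq[:150] + seq[152:]  # 2 bp intronic deletion
        ga, gb = self._genomes(seq, seq_b)
        tx_a = _tx("a", [(0, 100), (250, 350)])
        tx_b = _tx("b", [(0, 100), (248, 348)])
        m = evo_metrics(_pair(tx_a, tx_b), ga, gb)
        assert m.exonic_indel_events == 0 and m.intronic_indel_events == 1
        expected = math.log2((1 / m.exonic_aligned_bp) / (2 / m.intronic_aligned_bp))
        assert m.idr == pytest.approx(expected, abs=1e-9)
        assert m.idr < 0  # indel-constrained exons

    def test_single_exon_has_no_ssc(self):
        rng = np.random.default_rng(4)
        seq = _rand_seq(rng, 300)
        ga, gb = self._genomes(seq, seq)
        tx = _tx("a", [(0, 250)])
        m = evo_metrics(_pair(tx, tx), ga, gb)
        assert m.ssc is None


class TestReciprocal:
    def test_both_directions_kept_one_dropped(self):
        a1, b1 = _tx("a1", [(0, 300)]), _tx("b1", [(0, 300)])
        a2, b2 = _tx("a2", [(500, 800)]), _tx("b2", [(500, 800)])
        ab = [_pair(a1, b1), _pair(a2, b2)]
        ba = [_pair(b1, a1)]
        confirmed = reciprocal_orthologs(ab, ba)
        assert [(p.query.id, p.target.id) for p in confirmed] == [("a1", "b1")]
        assert confirmed[0].reciprocal

    def test_symmetric_under_swapped_inputs(self):
        a1, b1 = _tx("a1", [(0, 300)]), _tx("b1", [(0, 300)])
        ab, ba = [_pair(a1, b1)], [_pair(b1, a1)]
        k1 = {frozenset((p.query.id, p.target.id)) for p in reciprocal_orthologs(ab, ba)}
        k2 = {frozenset((p.query.id, p.target.id)) for p in reciprocal_orthologs(ba, ab)}
        assert k1 == k2


class TestCanonicalPair:
    def _with_metrics(self, tid, gene, ssc_count, tti):
        p = _pair(_tx(tid, [(0, 300)], gene=gene), _tx(tid + "_t", [(0, 300)], gene="gB"))
        p.metrics = EvoMetrics(tgi=1.0, tti=tti, ssc=None, idr=None,
                               conserved_junctions=ssc_count, n_junctions=2)
        return p

    def test_most_conserved_junctions_wins(self):
        pairs = [self._with_metrics("i1", "g", 2, 0.4), self._with_metrics("i2", "g", 1, 0.9)]
        assert [p.query.id for p in canonical_pair_per_gene(pairs)] == ["i1"]

    def test_tti_breaks_ties(self):
        pairs = [self._with_metrics("i1", "g", 1, 0.5), self._with_metrics("i2", "g", 1, 0.7)]
        assert [p.query.id for p in canonical_pair_per_gene(pairs)] == ["i2"]

    def test_single_isoform_is_itself(self):
        pairs = [self._with_metrics("only", "g", 0, 0.3)]
        assert [p.query.id for p in canonical_pair_per_gene(pairs)] == ["only"]


class TestClassification:
    def test_mirna_host(self):
        tx = _tx("t", [(0, 200), (400, 600)])
        mir = [(GenomicInterval("c1", 250, 330), "mir1")]
        assert classify_lncrna(tx, mir, [], []) == MIRNA_HOST
        assert not is_exonic_host(tx, mir[0][0])

    def test_exonic_host_flag(self):
        tx = _tx("t", [(0, 200), (400, 600)])
        mir = GenomicInterval("c1", 50, 130)
        assert is_exonic_host(tx, mir)

    def test_divergent_within_window(self):
        tx = _tx("t", [(1000, 1200), (1400, 1600)], strand="-")
        cod = _tx("c", [(1900, 2200)], strand="+")
        assert classify_lncrna(tx, [], [], [cod]) == DIVERGENT

    def test_intergenic_when_nothing_near(self):
        tx = _tx("t", [(1000, 1200), (1400, 1600)])
        assert classify_lncrna(tx, [], [], []) == INTERGENIC

    def test_pair_class_requires_both_species(self):
        tx_a = _tx("a", [(0, 200), (400, 600)])
        tx_b = _tx("b", [(0, 200), (400, 600)])
        p = _pair(tx_a, tx_b)
        mir_a = [(GenomicInterval("c1", 250, 330), "m")]
        assert classify_pair(p, {"mirna": mir_a}, {"mirna": []}) == INTERGENIC
        assert classify_pair(p, {"mirna": mir_a}, {"mirna": mir_a}) == MIRNA_HOST

    def test_fixture_classes_match_truth(self, fx7, ortho_result):
        truth = {e.id_a: e.expected_class for e in fx7.truth.elements if e.expected_class}
        for p in ortho_result["confirmed"]:
            assert ortho_result["classes"][p.query.id] == truth[p.query.id]


class TestExonProfile:
    def test_divergent_pairs_conserve_first_exon_only(self, ortho_result):
        pairs = [p for p in ortho_result["confirmed"] if p.query.id.startswith("div")]
        prof = exon_identity_profile(pairs, first_n=3)
        assert prof["tti"][0] >= 0.7
        assert prof["tti"][1] <= 0.2 and prof["tti"][2] <= 0.2

    def test_single_pair_profile_is_its_own(self, ortho_result):
        p = next(p for p in ortho_result["confirmed"] if p.query.id == "lincA_0")
        prof = exon_identity_profile([p], first_n=3)
        assert prof["tti"] == pytest.approx(p.metrics.tti_per_exon[:3])


class TestShuffledControl:
    def test_structure_preserved_and_intergenic(self, fx7):
        txs = [t for t in fx7.candidates_a if t.id.startswith("lincA")][:3]
        shuffled = shuffled_transcript_control(
            txs, fx7.genome_a, fx7.coding_a, rng_seed=0
        )
        for orig, shuf in zip(txs, shuffled):
            assert sorted(len(e) for e in shuf.exons) == sorted(len(e) for e in orig.exons)
            for cod in fx7.coding_a:
                assert not shuf.interval.overlaps(cod.interval)

    def test_seed_reproducible(self, fx7):
        txs = [t for t in fx7.candidates_a if t.id.startswith("lincA")][:2]
        s1 = shuffled_transcript_control(txs, fx7.genome_a, fx7.coding_a, rng_seed=3)
        s2 = shuffled_transcript_control(txs, fx7.genome_a, fx7.coding_a, rng_seed=3)
        assert [(t.chrom, t.start, t.strand) for t in s1] == [
            (t.chrom, t.start, t.strand) for t in s2
        ]


class TestSpliceShuffle:
    def test_donors_pinned_to_true_junctions_recover_count(self):
        """When the locus' only GT motifs sit at the true donor sites, every
        shuffle re-places junctions on themselves and the conserved count is
        exact."""
        rng = np.random.default_rng(0)
        body = "".join("ACT"[i] for i in rng.integers(0, 3, 500))  # G-free
        seq = list(body)
        tx_a = _tx("a", [(0, 100), (200, 300), (400, 500)])
        for donor, _ in tx_a.internal_junctions():
            seq[donor] = "G"
            seq[donor + 1] = "T"
        genome = GenomeSequence({"c1": "".join(seq)})
        p = _pair(tx_a, tx_a)
        exp = splice_shuffle_expectation(p, genome, genome, n_shuffles=50, rng_seed=1)
        assert exp == pytest.approx(2.0)

    def test_error_without_motifs(self):
        genome = GenomeSequence({"c1": "ACA" * 200})
        tx = _tx("a", [(0, 100), (200, 300)])
        with pytest.raises(ValueError, match="GT"):
            splice_shuffle_expectation(_pair(tx, tx), genome, genome, rng_seed=0)

    def test_sparse_motifs_give_low_expectation(self, fx7, ortho_result):
        p = next(p for p in ortho_result["confirmed"] if p.query.id == "lincA_0")
        exp = splice_shuffle_expectation(
            p, fx7.genome_a, fx7.genome_b, n_shuffles=100, rng_seed=2
        )
        assert 0 <= exp < p.query.n_exons - 1
        assert exp < 0.5  # random GT placement rarely lands on a junction


class TestMixture:
    def test_loglik_monotone(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.66, 0.07, 250), rng.normal(0.16, 0.12, 250)])
        fit = fit_tti_mixture(x, rng_seed=1)
        diffs = np.diff(fit.loglik_trajectory)
        assert (diffs >= -1e-8).all()

    def test_all_equal_degenerate_error(self):
        with pytest.raises(ValueError, match="degenerate|observations"):
            fit_tti_mixture([0.5] * 50, rng_seed=0)

    def test_single_component_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.05, 300)
        fit = fit_tti_mixture(x, rng_seed=2)
        dominated = fit.weights.max() >= 0.9
        close_means = abs(fit.means[0] - fit.means[1]) < 0.05
        assert dominated or close_means

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="10"):
            fit_tti_mixture([0.1, 0.9], rng_seed=0)
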