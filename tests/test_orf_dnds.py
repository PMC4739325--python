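import math

import numpy as np
import pytest

from helpers import ng_counts_oracle

from slinc.aligner import ScoringScheme, local_align
from slinc.fixtures import neutral_codon_pair
from slinc.orf_dnds import (
    DnDsNullTable,
    OrfHit,
    build_dnds_null,
    enumerate_aligned_orfs,
    nei_gojobori_dnds,
    orf_significance,
)

# Hand-workable codon alignments with their pathway counts (N, S, Nd, Sd);
# verified against the enumeration oracle below.
TOY_ALIGNMENTS = [
    # one synonymous (AAA->AAG) + one nonsynonymous (TTT->TAT) change
    ("ATGAAACCGTTTGGC", "ATGAAGCCGTATGGC", (37 / 3, 8 / 3, 1.0, 1.0)),
    # one two-substitution codon (TTT->CTC): both orderings average to 1N+1S
    ("ATGAAACCGTTTGGC", "ATGAAACCGCTCGGC", (12.0, 3.0, 1.0, 1.0)),
    # identical sequences
    ("AAATTTGGG", "AAATTTGGG", (22 / 3, 5 / 3, 0.0, 0.0)),
    # single codon, synonymous third-position change
    ("AAA", "AAG", (8 / 3, 1 / 3, 0.0, 1.0)),
    # five third-position transitions, all synonymous
    ("TGTCGTACTATTCAC", "TGCCGGACCATCCAT", (11.5, 3.5, 0.0, 5.0)),
]


class TestNeiGojobori:
    @pytest.mark.parametrize("sa,sb,expected", TOY_ALIGNMENTS)
    def test_hand_worked_counts(self, sa, sb, expected):
        r = nei_gojobori_dnds((sa, sb))
        n, s, nd, sd = expected
        assert r.n_sites == pytest.approx(n, abs=1e-9)
        assert r.s_sites == pytest.approx(s, abs=1e-9)
        assert r.nd == pytest.approx(nd, abs=1e-9)
        assert r.sd == pytest.approx(sd, abs=1e-9)

    @pytest.mark.parametrize("sa,sb,expected", TOY_ALIGNMENTS)
    def test_counts_equal_enumeration_oracle(self, sa, sb, expected):
        n, s, nd, sd = ng_counts_oracle(sa, sb)
        r = nei_gojobori_dnds((sa, sb))
        assert (r.n_sites, r.s_sites, r.nd, r.sd) == pytest.approx((n, s, nd, sd))

    def test_oracle_agreement_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sa, sb = neutral_codon_pair(30, 0.1, 1.0, rng)
            n, s, nd, sd = ng_counts_oracle(sa, sb)
            r = nei_gojobori_dnds((sa, sb))
            assert (r.n_sites, r.s_sites, r.nd, r.sd) == pytest.approx((n, s, nd, sd))

    def test_site_conservation_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            sa, sb = neutral_codon_pair(25, 0.2, 1.0, rng)
            r = nei_gojobori_dnds((sa, sb))
            assert r.n_sites + r.s_sites == pytest.approx(3 * 25)

    def test_identical_orfs_ratio_zero(self):
        r = nei_gojobori_dnds(("AAATTTGGG", "AAATTTGGG"))
        assert r.ratio == 0.0

    def test_single_synonymous_change_ratio_zero(self):
        r = nei_gojobori_dnds(("AAA", "AAG"))
        assert r.dn == 0.0 and r.ratio == 0.0

    def test_ds_zero_dn_positive_is_inf(self):
        r = nei_gojobori_dnds(("AAA", "GAA"))  # K->E nonsynonymous
        assert math.isinf(r.ratio)

    def test_internal_stop_errors(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori_dnds(("TAAAAA", "TAAAAA"))

    def test_neutral_simulation_median_near_one(self):
        rng = np.random.default_rng(2)
        ratios = []
        for _ in range(300):
            sa, sb = neutral_codon_pair(300, 0.05, 1.0, rng)
            ratios.append(nei_gojobori_dnds((sa, sb)).ratio)
        med = float(np.median([r for r in ratios if not math.isinf(r)]))
        assert abs(med - 1.0) < 0.15


class TestOrfEnumeration:
    def _aln(self, sa, sb, scoring=None):
        alns = local_align(sa, sb, scoring or ScoringScheme())
        assert alns
        return alns[0]

    def test_identical_orf_reported(self):
        pad = "CCCCCCCCCCCCCCCC"
        orf = "ATG" + "AAA" * 10 + "TAA"
        seq = pad + orf + pad
        hits = enumerate_aligned_orfs(self._aln(seq, seq), seq, seq, min_len=33)
        assert any(h.length_nt == 36 for h in hits)

    def test_frameshift_indel_disqualifies(self):
        pad = "CCCCCCCCCCCCCCCC"
        orf = "ATG" + "AAA" * 10 + "TAA"
        seq_a = pad + orf + pad
        mid = len(pad) + 18
        seq_b = seq_a[:mid] + "G" + seq_a[mid:]  # 1 bp insertion mid-ORF
        s = ScoringScheme.lncrna(seed_length=8)
        hits = []
        for aln in local_align(seq_a, seq_b, s):
            hits += enumerate_aligned_orfs(aln, seq_a, seq_b, min_len=33)
        assert hits == []

    def test_short_orf_not_reported(self):
        pad = "C" * 20
        orf = "ATG" + "AAA" + "TAA"  # 9 nt
        seq = pad + orf + pad
        hits = enumerate_aligned_orfs(self._aln(seq, seq), seq, seq, min_len=33)
        assert all(h.length_nt >= 33 for h in hits)
        assert not any(h.length_nt == 9 for h in hits)


class TestNullTable:
    def test_binning_and_usability(self):
        pairs = [(300, r) for r in np.linspace(0, 2, 150)] + [(500, 0.5)] * 5
        table = DnDsNullTable.from_ratios(pairs)
        assert table.usable(300) and table.usable(302)
        assert not table.usable(500)

    def test_p_value_add_one(self):
        table = DnDsNullTable.from_ratios([(300, r) for r in np.linspace(0.5, 2, 100)])
        assert table.p_value(300, 0.0) == pytest.approx(1 / 101)
        assert table.p_value(300, 3.0) == pytest.approx(1.0)

    def test_build_from_fixture_deterministic(self, fx7):
        kw = dict(
            scoring=ScoringScheme.lncrna(),
            n_regions=150, min_per_bin=5, rng_seed=3,
        )
        t1 = build_dnds_null(fx7.genome_a, fx7.genome_b, fx7.chains,
                             fx7.annotations_a(), **kw)
        t2 = build_dnds_null(fx7.genome_a, fx7.genome_b, fx7.chains,
                             fx7.annotations_a(), **kw)
        assert {k: list(v) for k, v in t1.bins.items()} == {
            k: list(v) for k, v in t2.bins.items()
        }
        kw["rng_seed"] = 4
        t3 = build_dnds_null(fx7.genome_a, fx7.genome_b, fx7.chains,
                             fx7.annotations_a(), **kw)
        assert {k: list(v) for k, v in t3.bins.items()} != {
            k: list(v) for k, v in t1.bins.items()
        }

    def test_lengths_fall_in_their_bins(self, fx7):
        table = build_dnds_null(
            fx7.genome_a, fx7.genome_b, fx7.chains, fx7.annotations_a(),
            scoring=ScoringScheme.lncrna(), n_regions=200, rng_seed=5,
        )
        for idx in table.bins:
            assert idx == int(idx)


def _hit(length, ratio, tid="t"):
    return OrfHit(
        transcript_id=tid, q_start=0, t_start=0, length_nt=length,
        codons_a="", codons_b="",
        dnds=type("D", (), {"ratio": ratio, "dn": 0.0, "ds": 0.0})(),
    )


class TestOrfSignificance:
    def _table(self):
        return DnDsNullTable.from_ratios([(300, r) for r in np.linspace(0.5, 2, 100)])

    def test_low_ratio_small_p(self):
        hits = orf_significance([_hit(300, 0.0)], self._table())
        assert hits[0].p_empirical == pytest.approx(1 / 101)
        assert hits[0].flagged_coding

    def test_long_orf_fallback_flags_below_one(self):
        hits = orf_significance([_hit(1200, 0.4)], self._table())
        assert hits[0].used_fallback and hits[0].flagged_coding

    def test_long_orf_fallback_not_flagged_above_one(self):
        hits = orf_significance([_hit(1200, 1.3)], self._table())
        assert hits[0].used_fallback and not hits[0].flagged_coding

    def test_bh_correction_monotone(self):
        hits = [_hit(300, r, tid=f"t{i}") for i, r in enumerate((0.0, 0.6, 1.9))]
        orf_significance(hits, self._table())
        ordered = sorted(hits, key=lambda h: h.p_empirical)
        qs = [h.q_value for h in ordered]
        assert qs == sorted(qs)


class TestSelectionSimulations:
    def test_purifying_flagged_neutral_not(self):
        """Purifying ORFs (omega 0.1) flag at >=80% against a same-length
        neutral null; neutral ORFs stay <=10% after BH."""
        rng = np.random.default_rng(7)
        n_codons, sub = 100, 0.05
        null_ratios = [
            (3 * n_codons, nei_gojobori_dnds(neutral_codon_pair(n_codons, sub, 1.0, rng)).ratio)
            for _ in range(300)
        ]
        table = DnDsNullTable.from_ratios(null_ratios)
        purifying = [
            _hit(3 * n_codons, nei_gojobori_dnds(neutral_codon_pair(n_codons, sub, 0.1, rng)).ratio, f"p{i}")
            for i in range(60)
        ]
        neutral = [
            _hit(3 * n_codons, nei_gojobori_dnds(neutral_codon_pair(n_codons, sub, 1.0, rng)).ratio, f"n{i}")
            for i in range(60)
        ]
        orf_significance(purifying, table)
        orf_significance(neutral, table)
        assert np.mean([h.flagged_coding for h in purifying]) >= 0.8
        assert np.mean([h.flagged_coding for h in neutral]) <= 0.1

    def test_omega_zero_never_nonsynonymous(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            sa, sb = neutral_codon_pair(50, 0.2, 0.0, rng)
            assert nei_gojobori_dnds((sa, sb)).nd == 0.0
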