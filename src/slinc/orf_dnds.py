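"""Hidden-ORF detection in lncRNA alignments: aligned ORF enumeration,
Nei-Gojobori dN/dS, and length-binned empirical significance.

A transcript pair hiding a conserved protein shows an ORF present in both
species with depressed nonsynonymous substitution (dN/dS << 1). Because the
dN/dS estimate is strongly length-dependent, observed ratios are compared to
ratios of ORFs found the same way in aligned random intergenic regions,
binned by ORF length (5 nt bins, usable from 100 null ORFs); long ORFs with
no usable bin fall back to the dN/dS < 1 rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import false_discovery_control

from .aligner import IntergenicSampler, LocalAlignment, ScoringScheme, as_rng, local_align
from .genomic_io import ChainSet, GenomeSequence
from .synteny import lift_interval

__all__ = [
    "DnDsResult",
    "OrfHit",
    "DnDsNullTable",
    "nei_gojobori_dnds",
    "enumerate_aligned_orfs",
    "build_dnds_null",
    "orf_significance",
]

MIN_ORF_NT = 33  # ATG + >=9 codons + stop

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_NTS = "ACGT"


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '*' for stop."""
    if codon in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table[codon]


_AA = {a + b + c: translate_codon(a + b + c) for a in _NTS for b in _NTS for c in _NTS}
STOPS = set(_TABLE.stop_codons)


@dataclass
class DnDsResult:
    n_sites: float  # expected nonsynonymous sites (N)
    s_sites: float  # expected synonymous sites (S)
    nd: float  # observed nonsynonymous differences
    sd: float  # observed synonymous differences
    dn: float
    ds: float
    ratio: float  # dN/dS; 0 when no substitutions, +inf when dS == 0 < dN


def _codon_sites(codon: str) -> Tuple[float, float]:
    """(nonsyn_sites, syn_sites) of one codon; changes to stop codons count
    as nonsynonymous."""
    aa = _AA[codon]
    n = 0.0
    for pos in range(3):
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _AA[alt] != aa:
                n += 1 / 3
    return n, 3.0 - n


_SITES_CACHE = {c: _codon_sites(c) for c in _AA}
_PATH_CACHE: Dict[Tuple[str, str], Tuple[float, float]] = {}


def _codon_path_counts(c1: str, c2: str) -> Tuple[float, float]:
    """(Nd, Sd) between two codons: equal-weight average over all substitution
    orderings (pathway counting)."""
    key = (c1, c2)
    if key in _PATH_CACHE:
        return _PATH_CACHE[key]
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        result = (0.0, 0.0)
    else:
        nd_tot = sd_tot = 0.0
        n_paths = 0
        for order in permutations(diff):
            cur = c1
            nd = sd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _AA[nxt] == _AA[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            nd_tot += nd
            sd_tot += sd
            n_paths += 1
        result = (nd_tot / n_paths, sd_tot / n_paths)
    _PATH_CACHE[key] = result
    return result


def _jukes_cantor(p: float) -> float:
    if p <= 0:
        return 0.0
    x = 1 - 4 * p / 3
    if x <= 0:
        return math.inf
    return -0.75 * math.log(x)


def nei_gojobori_dnds(
    codon_aln: Union[Tuple[str, str], Sequence[Tuple[str, str]]]
) -> DnDsResult:
    """Nei-Gojobori (pathway-counting) dN/dS with Jukes-Cantor correction.

    codon_aln is either a pair of gap-free, in-frame nucleotide strings of
    equal length (multiple of 3) or a sequence of codon pairs. Internal stop
    codons are an error; the ORF enumeration never emits them.
    """
    if (
        len(codon_aln) == 2
        and isinstance(codon_aln[0], str)
        and isinstance(codon_aln[1], str)
        and len(codon_aln[0]) == len(codon_aln[1])
        and len(codon_aln[0]) % 3 == 0
        and len(codon_aln[0]) >= 3
    ):
        sa, sb = codon_aln
        if len(sa) != len(sb) or len(sa) % 3:
            raise ValueError("codon alignment must be equal length, multiple of 3")
        pairs = [(sa[i : i + 3], sb[i : i + 3]) for i in range(0, len(sa), 3)]
    else:
        pairs = [tuple(p) for p in codon_aln]
    n_sites = s_sites = nd = sd = 0.0
    for ca, cb in pairs:
        if ca in STOPS or cb in STOPS:
            raise ValueError(f"internal stop codon in alignment: {ca}/{cb}")
        na, sa_ = _SITES_CACHE[ca]
        nb, sb_ = _SITES_CACHE[cb]
        n_sites += (na + nb) / 2
        s_sites += (sa_ + sb_) / 2
        d_n, d_s = _codon_path_counts(ca, cb)
        nd += d_n
        sd += d_s
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    dn = _jukes_cantor(pn)
    ds = _jukes_cantor(ps)
    if nd == 0 and sd == 0:
        ratio = 0.0  # maximally conserved; calibrated by the same-way null
    elif ds == 0:
        ratio = math.inf  # never coding-flagged
    elif math.isinf(ds):
        ratio = 0.0 if not math.isinf(dn) else 1.0
    else:
        ratio = dn / ds
    return DnDsResult(n_sites, s_sites, nd, sd, dn, ds, ratio)


@dataclass
class OrfHit:
    """An ORF aligned, in frame and gap-free, in both species."""

    transcript_id: str
    q_start: int  # nt offset of ATG in the query sequence given to enumerate
    t_start: int
    length_nt: int  # stop codon included
    codons_a: str
    codons_b: str
    dnds: DnDsResult
    p_empirical: float = math.nan
    q_value: float = math.nan
    flagged_coding: bool = False
    used_fallback: bool = False

    @property
    def ratio(self) -> float:
        return self.dnds.ratio


def _gapfree_blocks(aln: LocalAlignment) -> List[Tuple[int, int, int]]:
    """Maximal runs of match/mismatch columns as (q_start, t_start, length)."""
    blocks = []
    q, t = aln.q_start, aln.t_start
    cur: Optional[List[int]] = None
    for op, n in aln.ops:
        if op in "MX":
            if cur is None:
                cur = [q, t, n]
            else:
                cur[2] += n
            q += n
            t += n
        else:
            if cur is not None:
                blocks.append(tuple(cur))
                cur = None
            if op == "I":
                q += n
            else:
                t += n
    if cur is not None:
        blocks.append(tuple(cur))
    return blocks


def enumerate_aligned_orfs(
    aln: LocalAlignment,
    seq_a: str,
    seq_b: str,
    min_len: int = MIN_ORF_NT,
    transcript_id: str = "",
) -> List[OrfHit]:
    """ATG..stop spans >= min_len nt present in the aligned region of both
    species, in frame in both, with no indel inside (the strict frameshift
    rule: any gap disqualifies, so ORFs live within gap-free blocks)."""
    hits: List[OrfHit] = []
    for q0, t0, length in _gapfree_blocks(aln):
        sa = seq_a[q0 : q0 + length]
        sb = seq_b[t0 : t0 + length]
        for frame in range(3):
            i = frame
            while i + 3 <= length:
                if sa[i : i + 3] == "ATG" and sb[i : i + 3] == "ATG":
                    j = i + 3
                    ended = False
                    while j + 3 <= length:
                        stop_a = sa[j : j + 3] in STOPS
                        stop_b = sb[j : j + 3] in STOPS
                        if stop_a or stop_b:
                            if stop_a and stop_b:
                                orf_len = j + 3 - i
                                if orf_len >= min_len:
                                    body_a = sa[i:j]
                                    body_b = sb[i:j]
                                    hits.append(
                                        OrfHit(
                                            transcript_id=transcript_id,
                                            q_start=q0 + i,
                                            t_start=t0 + i,
                                            length_nt=orf_len,
                                            codons_a=body_a,
                                            codons_b=body_b,
                                            dnds=nei_gojobori_dnds((body_a, body_b)),
                                        )
                                    )
                            ended = True
                            break
                        j += 3
                    del ended
                i += 3
    hits.sort(key=lambda h: (h.q_start, -h.length_nt))
    return hits


@dataclass
class DnDsNullTable:
    """Null dN/dS ratios from identically-processed random intergenic
    alignments, binned by ORF length (bin_width nt)."""

    bin_width: int = 5
    min_per_bin: int = 100
    n_regions: int = 0
    bins: Dict[int, np.ndarray] = field(default_factory=dict)

    def bin_index(self, length_nt: int) -> int:
        return length_nt // self.bin_width

    def usable(self, length_nt: int) -> bool:
        b = self.bins.get(self.bin_index(length_nt))
        return b is not None and b.size >= self.min_per_bin

    def p_value(self, length_nt: int, ratio: float) -> float:
        """One-sided low-ratio empirical P (lower ratio = more coding-like),
        add-one estimator."""
        b = self.bins[self.bin_index(length_nt)]
        le = int(np.searchsorted(b, ratio, side="right"))
        return (1 + le) / (b.size + 1)

    @classmethod
    def from_ratios(
        cls, lengths_ratios: Sequence[Tuple[int, float]], bin_width: int = 5,
        min_per_bin: int = 100, n_regions: int = 0,
    ) -> "DnDsNullTable":
        acc: Dict[int, List[float]] = {}
        table = cls(bin_width=bin_width, min_per_bin=min_per_bin, n_regions=n_regions)
        for length, ratio in lengths_ratios:
            acc.setdefault(length // bin_width, []).append(ratio)
        table.bins = {k: np.sort(np.array(v)) for k, v in acc.items()}
        return table


def build_dnds_null(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    chains: ChainSet,
    annotations: Sequence,
    scoring: ScoringScheme = ScoringScheme(),
    n_regions: int = 50_000,
    bin_width: int = 5,
    region_length: int = 500,
    min_len: int = MIN_ORF_NT,
    min_per_bin: int = 100,
    rng_seed=None,
) -> DnDsNullTable:
    """Align random intergenic regions to their syntenic counterparts, run the
    same ORF enumeration, and bin the resulting dN/dS ratios by ORF length."""
    rng = as_rng(rng_seed)
    sampler = IntergenicSampler(genome_a, annotations)
    pairs: List[Tuple[int, float]] = []
    for _ in range(n_regions):
        iv = sampler.sample(region_length, rng)
        lifted = lift_interval(chains, iv, min_match=0.1)
        span = lifted.span
        if span is None:
            continue
        qseq = genome_a.fetch(iv)
        tseq = genome_b.fetch(span)
        for aln in local_align(qseq, tseq, scoring):
            for hit in enumerate_aligned_orfs(aln, qseq, tseq, min_len=min_len):
                pairs.append((hit.length_nt, hit.ratio))
    return DnDsNullTable.from_ratios(
        pairs, bin_width=bin_width, min_per_bin=min_per_bin, n_regions=n_regions
    )


def orf_significance(
    hits: List[OrfHit], null: DnDsNullTable, alpha: float = 0.05
) -> List[OrfHit]:
    """Assign empirical P (one-sided, low ratio) per length bin, correct by
    Benjamini-Hochberg across hits, and flag q <= alpha. Hits in unusable
    (too-long) bins use the dN/dS < 1 fallback."""
    binned = [h for h in hits if null.usable(h.length_nt)]
    for h in hits:
        if null.usable(h.length_nt):
            h.p_empirical = null.p_value(h.length_nt, h.ratio)
            h.used_fallback = False
        else:
            h.p_empirical = math.nan
            h.used_fallback = True
            h.flagged_coding = h.ratio < 1.0
            h.q_value = math.nan
    if binned:
        qs = false_discovery_control([h.p_empirical for h in binned], method="bh")
        for h, q in zip(binned, qs):
            h.q_value = float(q)
            h.flagged_coding = h.q_value <= alpha
    return hits
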