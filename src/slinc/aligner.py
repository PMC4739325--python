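"""Seed-and-extend local pairwise DNA alignment with affine gaps, plus
empirical alignment significance against shuffled-intergenic nulls.

The aligner finds exact-match k-mer seeds, groups them into diagonal bands,
and runs gapped affine extension by dynamic programming: full Smith-Waterman
for short sequences (exact), banded DP around each seed group otherwise.
Identity counts matches over all aligned columns including gap columns, and
N never matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _dp
from .genomic_io import GenomeSequence, GenomicInterval, Transcript

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "AlignmentSignificance",
    "local_align",
    "best_local_score",
    "alignment_identity",
    "IntergenicSampler",
    "sample_intergenic",
    "empirical_significance",
    "as_rng",
]


def as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring. Penalties are positive magnitudes; a gap of length
    L costs gap_open + gap_extend * L."""

    match: int = 5
    mismatch: int = 4
    gap_open: int = 400
    gap_extend: int = 30
    seed_length: int = 12

    def __post_init__(self):
        if self.match <= 0 or self.mismatch <= 0:
            raise ValueError("match reward and mismatch penalty must be positive")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.seed_length < 8:
            raise ValueError("seed length must be >= 8")

    @classmethod
    def lncrna(cls, **kw) -> "ScoringScheme":
        """Reduced gap-open scheme for lncRNA loci, which tolerate many small
        insertions (open=25, extend=40)."""
        kw.setdefault("gap_open", 25)
        kw.setdefault("gap_extend", 40)
        return cls(**kw)


_OP_CHARS = "MXID"  # match, mismatch, insertion-in-query, deletion-from-query


def _runs_from_codes(codes: np.ndarray) -> List[Tuple[str, int]]:
    runs: List[Tuple[str, int]] = []
    for c in codes:
        ch = _OP_CHARS[c]
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return runs


@dataclass
class LocalAlignment:
    """Gapped local alignment between query and target sequence slices.

    Coordinates are 0-based offsets into the sequences given to local_align;
    optional genomic anchors record what those sequences were.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    ops: List[Tuple[str, int]]
    score: int
    query: Optional[GenomicInterval] = None
    target: Optional[GenomicInterval] = None

    def __post_init__(self):
        q = sum(n for op, n in self.ops if op in "MXI")
        t = sum(n for op, n in self.ops if op in "MXD")
        if q != self.q_end - self.q_start or t != self.t_end - self.t_start:
            raise ValueError("ops inconsistent with alignment spans")

    @property
    def n_matches(self) -> int:
        return sum(n for op, n in self.ops if op == "M")

    @property
    def n_columns(self) -> int:
        return sum(n for _, n in self.ops)

    @property
    def identity(self) -> float:
        """Matches over all aligned columns, gap columns included."""
        cols = self.n_columns
        return self.n_matches / cols if cols else 0.0

    def columns(self):
        """Yield (op, q_pos, t_pos) per column; gap columns report the
        position of the consumed side and the next position on the other."""
        q, t = self.q_start, self.t_start
        for op, n in self.ops:
            for _ in range(n):
                yield op, q, t
                if op in "MXI":
                    q += 1
                if op in "MXD":
                    t += 1

    def colinear_segments(self) -> List[Tuple[int, int, int]]:
        """Gap-free stretches as (q_start, q_end, t_start): within a segment,
        query position q maps to t_start + (q - q_start)."""
        out = []
        q, t = self.q_start, self.t_start
        for op, n in self.ops:
            if op in "MX":
                if out and out[-1][1] == q and out[-1][2] + (out[-1][1] - out[-1][0]) == t:
                    out[-1] = (out[-1][0], q + n, out[-1][2])
                else:
                    out.append((q, q + n, t))
                q += n
                t += n
            elif op == "I":
                q += n
            else:
                t += n
        return out

    def map_query_to_target(self, q_pos: int) -> Optional[int]:
        """Target position aligned to query position (match/mismatch columns
        only); None if q_pos falls in a gap or outside the alignment."""
        q, t = self.q_start, self.t_start
        for op, n in self.ops:
            if op in "MX":
                if q <= q_pos < q + n:
                    return t + (q_pos - q)
                q += n
                t += n
            elif op == "I":
                if q <= q_pos < q + n:
                    return None
                q += n
            else:
                t += n
        return None

    def score_in_query_range(self, q_lo: int, q_hi: int, scoring: ScoringScheme) -> int:
        """Score contribution of columns whose query coordinate lies in
        [q_lo, q_hi); D-gap runs are attributed to the current query position.
        Gap runs crossing the boundary are charged one open inside."""
        total = 0
        q = self.q_start
        for op, n in self.ops:
            if op == "M":
                inside = max(0, min(q + n, q_hi) - max(q, q_lo))
                total += inside * scoring.match
                q += n
            elif op == "X":
                inside = max(0, min(q + n, q_hi) - max(q, q_lo))
                total -= inside * scoring.mismatch
                q += n
            elif op == "I":
                inside = max(0, min(q + n, q_hi) - max(q, q_lo))
                if inside:
                    total -= scoring.gap_open + scoring.gap_extend * inside
                q += n
            else:  # D: consumes target at current q
                if q_lo <= q < q_hi:
                    total -= scoring.gap_open + scoring.gap_extend * n
        return total

    def overlaps_alignment(self, other: "LocalAlignment") -> bool:
        q = self.q_start < other.q_end and other.q_start < self.q_end
        t = self.t_start < other.t_end and other.t_start < self.t_end
        return q or t


def alignment_identity(aln: LocalAlignment) -> float:
    return aln.identity


# ---------------------------------------------------------------------------
# seeding


def _kmer_values(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(values, positions) of valid (N-free) k-mers, base-4 packed."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n - k + 1, dtype=np.int64)
    c = codes.astype(np.int64)
    for i in range(k):
        vals = vals * 4 + np.minimum(c[i : n - k + 1 + i], 3)
    bad = (codes == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    ok = (cs[k:] - cs[:-k]) == 0
    pos = np.nonzero(ok)[0]
    return vals[pos], pos


def _seed_hits(a: np.ndarray, b: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """All exact k-mer matches as parallel arrays (ia, jb)."""
    va, pa = _kmer_values(a, k)
    vb, pb = _kmer_values(b, k)
    if va.size == 0 or vb.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order_b = np.argsort(vb, kind="stable")
    vb_sorted = vb[order_b]
    lo = np.searchsorted(vb_sorted, va, side="left")
    hi = np.searchsorted(vb_sorted, va, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ia = np.repeat(pa, counts)
    idx = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
    jb = pb[order_b[idx]]
    return ia, jb


def _seed_groups(
    ia: np.ndarray, jb: np.ndarray, k: int, band: int, max_i_gap: int = 5000
) -> List[Tuple[int, int, int, int, int, int]]:
    """Group seed hits into diagonal envelopes.

    Returns tuples (i_min, i_max, j_min, j_max, d_min, d_max) with i_max/j_max
    inclusive of the seed length.
    """
    diag = ia - jb
    order = np.lexsort((ia, diag))
    d_s, i_s, j_s = diag[order], ia[order], jb[order]
    groups = []
    start = 0
    for t in range(1, d_s.size + 1):
        if t == d_s.size or d_s[t] - d_s[t - 1] > band:
            sub = np.argsort(i_s[start:t], kind="stable") + start
            s2 = 0
            i_sub = i_s[sub]
            for u in range(1, sub.size + 1):
                if u == sub.size or i_sub[u] - i_sub[u - 1] > max_i_gap:
                    sel = sub[s2:u]
                    groups.append(
                        (
                            int(i_s[sel].min()),
                            int(i_s[sel].max() + k),
                            int(j_s[sel].min()),
                            int(j_s[sel].max() + k),
                            int(d_s[sel].min()),
                            int(d_s[sel].max()),
                        )
                    )
                    s2 = u
            start = t
    return groups


_FULL_DP_LIMIT = 1000
_MARGIN = 400
_CELL_CAP = 60_000_000


def _traceback_to_alignment(res, q_off: int, t_off: int, scoring) -> Optional[LocalAlignment]:
    score, i0, i1, j0, j1, op_codes = res
    if score <= 0 or op_codes.size == 0:
        return None
    return LocalAlignment(
        q_start=q_off + int(i0),
        q_end=q_off + int(i1),
        t_start=t_off + int(j0),
        t_end=t_off + int(j1),
        ops=_runs_from_codes(op_codes),
        score=int(score),
    )


def local_align(
    seq_a: str,
    seq_b: str,
    scoring: ScoringScheme = ScoringScheme(),
    band: int = 64,
) -> List[LocalAlignment]:
    """Seed-and-extend local alignments of seq_a (query) vs seq_b (target).

    Returns non-overlapping alignments sorted by decreasing score; empty when
    no exact k-mer seed is shared. Deterministic for fixed inputs.
    """
    k = scoring.seed_length
    if len(seq_a) < k or len(seq_b) < k:
        return []
    a = _dp.encode(seq_a)
    b = _dp.encode(seq_b)
    ia, jb = _seed_hits(a, b, k)
    if ia.size == 0:
        return []
    args = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    if len(seq_a) <= _FULL_DP_LIMIT and len(seq_b) <= _FULL_DP_LIMIT:
        aln = _traceback_to_alignment(_dp.sw_traceback(a, b, *args), 0, 0, scoring)
        return [aln] if aln else []
    cands: List[LocalAlignment] = []
    for i0, i1, j0, j1, dmin, dmax in _seed_groups(ia, jb, k, band):
        ai0 = max(0, i0 - _MARGIN)
        ai1 = min(len(seq_a), i1 + _MARGIN)
        aj0 = max(0, j0 - _MARGIN)
        aj1 = min(len(seq_b), j1 + _MARGIN)
        W = (dmax - dmin) + 2 * band + 1
        step = max(1, int(_CELL_CAP // max(W, 1)))
        r = ai0
        while r < ai1:
            r1 = min(ai1, r + step)
            sub_a = a[r:r1]
            sub_b = b[aj0:aj1]
            # group diagonals are query-minus-target; the banded kernel bounds
            # target-minus-query in slice coordinates
            dlo = -dmax - band + r - aj0
            dhi = -dmin + band + r - aj0
            res = _dp.swb_traceback(
                sub_a, sub_b, np.int64(dlo), np.int64(dhi), *args
            )
            aln = _traceback_to_alignment(res, r, aj0, scoring)
            if aln:
                cands.append(aln)
            r = r1
    cands.sort(key=lambda x: (-x.score, x.q_start, x.t_start))
    kept: List[LocalAlignment] = []
    for c in cands:
        if not any(c.overlaps_alignment(kc) for kc in kept):
            kept.append(c)
    return kept


def best_local_score(
    seq_a: str, seq_b: str, scoring: ScoringScheme = ScoringScheme(), band: int = 64
) -> int:
    """Top local alignment score (0 when no seed is shared); cheaper than
    local_align as no traceback is materialized."""
    k = scoring.seed_length
    if len(seq_a) < k or len(seq_b) < k:
        return 0
    a = _dp.encode(seq_a)
    b = _dp.encode(seq_b)
    ia, jb = _seed_hits(a, b, k)
    if ia.size == 0:
        return 0
    args = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    if len(seq_a) <= _FULL_DP_LIMIT and len(seq_b) <= _FULL_DP_LIMIT:
        return int(_dp.sw_score(a, b, *args))
    best = 0
    for i0, i1, j0, j1, dmin, dmax in _seed_groups(ia, jb, k, band):
        ai0 = max(0, i0 - _MARGIN)
        ai1 = min(len(seq_a), i1 + _MARGIN)
        aj0 = max(0, j0 - _MARGIN)
        aj1 = min(len(seq_b), j1 + _MARGIN)
        dlo = -dmax - band + ai0 - aj0
        dhi = -dmin + band + ai0 - aj0
        s = _dp.swb_score(
            a[ai0:ai1], b[aj0:aj1], np.int64(dlo), np.int64(dhi), *args
        )
        best = max(best, int(s))
    return best


# ---------------------------------------------------------------------------
# intergenic sampling and empirical significance


class IntergenicSampler:
    """Uniform draws of fixed-length windows not overlapping any annotated
    transcript span."""

    def __init__(self, genome: GenomeSequence, annotations: Sequence):
        self.genome = genome
        spans: dict = {name: [] for name in genome.contigs}
        for ann in annotations:
            iv = ann.interval if isinstance(ann, Transcript) else ann
            if iv.chrom in spans:
                spans[iv.chrom].append((iv.start, iv.end))
        self.segments: List[Tuple[str, int, int]] = []
        for name, ivs in spans.items():
            ivs.sort()
            pos = 0
            clen = genome.contig_length(name)
            for s, e in ivs:
                if s > pos:
                    self.segments.append((name, pos, s))
                pos = max(pos, e)
            if pos < clen:
                self.segments.append((name, pos, clen))
        self.segments.sort()

    def sample(self, length: int, rng: np.random.Generator) -> GenomicInterval:
        counts = np.array(
            [max(0, (e - s) - length + 1) for _, s, e in self.segments],
            dtype=np.int64,
        )
        total = int(counts.sum())
        if total <= 0:
            raise ValueError(f"no intergenic window of length {length} available")
        r = int(rng.integers(total))
        cum = np.cumsum(counts)
        idx = int(np.searchsorted(cum, r, side="right"))
        offset = r - (int(cum[idx - 1]) if idx else 0)
        name, s, _ = self.segments[idx]
        return GenomicInterval(name, s + offset, s + offset + length)

    def sample_seq(self, length: int, rng: np.random.Generator) -> str:
        return self.genome.fetch(self.sample(length, rng))


def sample_intergenic(
    genome: GenomeSequence,
    annotations: Sequence,
    length: int,
    rng_seed: Union[int, np.random.Generator, None] = None,
) -> str:
    """One uniform intergenic draw of the given length; reproducible under seed."""
    return IntergenicSampler(genome, annotations).sample_seq(length, as_rng(rng_seed))


@dataclass
class AlignmentSignificance:
    """Empirical significance of an alignment score versus intergenic nulls;
    the add-one estimator keeps P strictly positive."""

    score: int
    null_scores: List[int] = field(repr=False, default_factory=list)

    @property
    def n_null(self) -> int:
        return len(self.null_scores)

    @property
    def empirical_p(self) -> float:
        ge = sum(1 for s in self.null_scores if s >= self.score)
        return (1 + ge) / (self.n_null + 1)


def empirical_significance(
    query: str,
    target: str,
    genome_for_null: GenomeSequence,
    annotations: Sequence,
    scoring: ScoringScheme = ScoringScheme(),
    n_null: int = 200,
    alpha: float = 0.05,
    rng_seed: Union[int, np.random.Generator, None] = None,
    sampler: Optional[IntergenicSampler] = None,
) -> Tuple[Optional[LocalAlignment], AlignmentSignificance]:
    """Align query to target and keep the best alignment iff it scores higher
    than (1 - alpha) of n_null length-matched intergenic draws."""
    rng = as_rng(rng_seed)
    if sampler is None:
        sampler = IntergenicSampler(genome_for_null, annotations)
    alns = local_align(query, target, scoring)
    best = alns[0] if alns else None
    obs = best.score if best else 0
    nulls = [
        best_local_score(query, sampler.sample_seq(len(target), rng), scoring)
        for _ in range(n_null)
    ]
    sig = AlignmentSignificance(score=obs, null_scores=nulls)
    kept = best if (best is not None and sig.empirical_p <= alpha) else None
    return kept, sig
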