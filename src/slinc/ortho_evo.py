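"""Orthologous lncRNA discovery across two genomes and transcript-evolution
metrics.

A query lncRNA is lifted to the comparing genome, the padded syntenic loci
are aligned with a reduced gap-open scheme (lncRNAs tolerate many small
insertions), and the alignment is kept only when the transcript-overlapping
score beats 95% of alignments of the transcript to random intergenic draws.
Confirmed pairs are scored with four metrics:

* TGI (transcript-genome identity): fraction of the query's exonic bases
  aligning identically to the syntenic locus, transcribed there or not.
* TTI (transcript-transcript identity): fraction of the query's exonic bases
  aligning identically inside exons of BOTH transcripts.
* SSC (splice-site conservation): fraction of internal junctions whose
  aligned image falls within a small tolerance of a target junction.
* IDR (indel rate): log2 ratio of indel-event rates in exonic vs intronic
  aligned sequence; negative values mean indel-constrained exons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy.special import logsumexp

from .aligner import (
    AlignmentSignificance,
    IntergenicSampler,
    LocalAlignment,
    ScoringScheme,
    as_rng,
    best_local_score,
    local_align,
)
from .genomic_io import ChainSet, GenomeSequence, GenomicInterval, Transcript
from .synteny import lift_transcript, syntenic_window

__all__ = [
    "EvoMetrics",
    "OrthologPair",
    "LncClass",
    "MixtureFit",
    "find_candidate_ortholog",
    "reciprocal_orthologs",
    "canonical_pair_per_gene",
    "evo_metrics",
    "exon_identity_profile",
    "classify_lncrna",
    "classify_pair",
    "shuffled_transcript_control",
    "splice_shuffle_expectation",
    "fit_tti_mixture",
]

MIRNA_HOST = "MIRNA_HOST"
SNORNA_HOST = "SNORNA_HOST"
DIVERGENT = "DIVERGENT"
INTERGENIC = "INTERGENIC"
LncClass = str

MIN_COMPARTMENT_BP = 100  # IDR undefined below this many aligned bp


@dataclass
class EvoMetrics:
    tgi: float
    tti: float
    ssc: Optional[float]  # None when the query has no internal junction
    idr: Optional[float]  # None when either compartment has <100 aligned bp
    exonic_aligned_bp: int = 0
    intronic_aligned_bp: int = 0
    exonic_indel_events: int = 0
    intronic_indel_events: int = 0
    conserved_junctions: int = 0
    n_junctions: int = 0
    tgi_per_exon: List[float] = field(default_factory=list)
    tti_per_exon: List[float] = field(default_factory=list)


@dataclass
class OrthologPair:
    species_a: str
    species_b: str
    query: Transcript
    target: Optional[Transcript]
    significance: AlignmentSignificance
    transcript_aligned: bool
    syntolog: bool = False
    reciprocal: bool = False
    metrics: Optional[EvoMetrics] = None

    @property
    def key(self):
        return (
            (self.species_a, self.query.id),
            (self.species_b, self.target.id if self.target else None),
        )


# ---------------------------------------------------------------------------
# ortholog search


def find_candidate_ortholog(
    tx: Transcript,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    target_txs: Sequence[Transcript],
    chains: ChainSet,
    scoring_lnc: Optional[ScoringScheme] = None,
    pad: int = 150_000,
    n_null: int = 200,
    alpha: float = 0.05,
    min_match: float = 0.1,
    rng_seed=None,
    sampler_b: Optional[IntergenicSampler] = None,
    annotations_b: Sequence = (),
    species: Tuple[str, str] = ("A", "B"),
) -> Optional[OrthologPair]:
    """Search the padded syntenic window of tx for an orthologous transcript.

    The observed statistic is the best window-alignment score restricted to
    the transcript's span; the null realigns the transcript locus against
    n_null length-matched intergenic draws. Windows whose flanks align
    significantly while the transcript does not are reported as syntologs
    (target=None, transcript_aligned=False).
    """
    if scoring_lnc is None:
        scoring_lnc = ScoringScheme.lncrna()
    rng = as_rng(rng_seed)
    lift = lift_transcript(chains, tx, min_match=min_match)
    if not lift.mapped:
        return None
    window = syntenic_window(chains, tx, genome_b, pad=pad, min_match=min_match)
    clen = genome_a.contig_length(tx.chrom)
    qiv = tx.interval.padded(pad, contig_length=clen)
    qseq = genome_a.fetch(qiv)
    tseq = genome_b.fetch(window)
    alns = local_align(qseq, tseq, scoring_lnc)
    tx_lo = tx.start - qiv.start
    tx_hi = tx.end - qiv.start
    obs = 0
    for aln in alns:
        if aln.q_start < tx_hi and aln.q_end > tx_lo:
            obs = max(obs, aln.score_in_query_range(tx_lo, tx_hi, scoring_lnc))
    if sampler_b is None:
        sampler_b = IntergenicSampler(genome_b, annotations_b)
    tx_seq = genome_a.fetch(tx.interval)
    nulls = [
        best_local_score(tx_seq, sampler_b.sample_seq(len(tx.interval), rng), scoring_lnc)
        for _ in range(n_null)
    ]
    sig = AlignmentSignificance(score=obs, null_scores=nulls)
    if obs > 0 and sig.empirical_p <= alpha:
        # project the query's exonic bp through the alignment columns and
        # vote for the target transcript receiving the most mapped exonic bp
        in_window = [
            c for c in target_txs
            if c.chrom == window.chrom and c.interval.overlaps(window)
        ]
        votes: Dict[str, int] = {c.id: 0 for c in in_window}
        for aln in alns:
            if aln.q_end <= tx_lo or aln.q_start >= tx_hi:
                continue
            for q0, q1, t0 in aln.colinear_segments():
                for exon in tx.exons:
                    lo = max(q0, exon.start - qiv.start)
                    hi = min(q1, exon.end - qiv.start)
                    if hi <= lo:
                        continue
                    tg0 = window.start + t0 + (lo - q0)
                    tg1 = tg0 + (hi - lo)
                    seg = GenomicInterval(window.chrom, tg0, tg1)
                    for cand in in_window:
                        votes[cand.id] += sum(seg.overlap_bp(e) for e in cand.exons)
        target = None
        if votes:
            best_id, best_olap = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if best_olap > 0:
                target = next(c for c in in_window if c.id == best_id)
        return OrthologPair(
            species_a=species[0],
            species_b=species[1],
            query=tx,
            target=target,
            significance=sig,
            transcript_aligned=True,
            syntolog=target is None,
        )
    # transcript not significant: flank-only alignment => syntolog
    flank_best = max((a.score for a in alns), default=0)
    flank_sig = AlignmentSignificance(score=flank_best, null_scores=nulls)
    if flank_best > 0 and flank_sig.empirical_p <= alpha:
        return OrthologPair(
            species_a=species[0],
            species_b=species[1],
            query=tx,
            target=None,
            significance=sig,
            transcript_aligned=False,
            syntolog=True,
        )
    return None


def reciprocal_orthologs(
    pairs_ab: Sequence[OrthologPair], pairs_ba: Sequence[OrthologPair]
) -> List[OrthologPair]:
    """Keep pairs with a matched transcript confirmed in both search
    directions; symmetric in its arguments."""
    keys_ba = {
        (p.target.id, p.query.id) for p in pairs_ba if p.target is not None
    }
    keys_ab = {
        (p.target.id, p.query.id) for p in pairs_ab if p.target is not None
    }
    del keys_ab
    out = []
    for p in pairs_ab:
        if p.target is not None and (p.query.id, p.target.id) in keys_ba:
            p.reciprocal = True
            out.append(p)
    return sorted(out, key=lambda p: (p.query.id, p.target.id))


def canonical_pair_per_gene(pairs: Sequence[OrthologPair]) -> List[OrthologPair]:
    """One canonical ortholog pair per gene pair: the isoform pair with the
    most conserved splice sites, then highest TTI, then smallest id."""
    by_gene: Dict[Tuple[str, str], List[OrthologPair]] = {}
    for p in pairs:
        if p.target is None or p.metrics is None:
            continue
        by_gene.setdefault((p.query.gene_id, p.target.gene_id), []).append(p)
    out = []
    for _, group in sorted(by_gene.items()):
        group.sort(
            key=lambda p: (
                -p.metrics.conserved_junctions,
                -p.metrics.tti,
                p.query.id,
            )
        )
        out.append(group[0])
    return out


# ---------------------------------------------------------------------------
# metrics


def _exon_index_array(tx: Transcript, locus: GenomicInterval) -> np.ndarray:
    """Per-locus-position exon ordinal in 5'->3' transcript order; -1 outside
    exons."""
    arr = np.full(len(locus), -1, dtype=np.int32)
    ordered = tx.exons_5to3()
    for idx, exon in enumerate(ordered):
        arr[exon.start - locus.start : exon.end - locus.start] = idx
    return arr


def _locus_alignments(
    tx_a: Transcript,
    tx_b: Transcript,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    scoring: ScoringScheme,
) -> List[LocalAlignment]:
    qseq = genome_a.fetch(tx_a.interval)
    tseq = genome_b.fetch(tx_b.interval)
    return local_align(qseq, tseq, scoring)


def _junction_conserved(
    alns: Sequence[LocalAlignment],
    junction: Tuple[int, int],
    tx_b: Transcript,
    la: GenomicInterval,
    lb: GenomicInterval,
    tol: int,
) -> bool:
    donor_end, acceptor_start = junction
    b_junctions = tx_b.internal_junctions()
    for aln in alns:
        t_img = aln.map_query_to_target(donor_end - 1 - la.start)
        if t_img is not None:
            boundary = t_img + 1 + lb.start
            if any(abs(boundary - be) <= tol for be, _ in b_junctions):
                return True
        t_img = aln.map_query_to_target(acceptor_start - la.start)
        if t_img is not None:
            boundary = t_img + lb.start
            if any(abs(boundary - bs) <= tol for _, bs in b_junctions):
                return True
    return False


def evo_metrics(
    pair: OrthologPair,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    scoring: Optional[ScoringScheme] = None,
    ssc_tol: int = 2,
) -> EvoMetrics:
    """Compute TGI/TTI/SSC/IDR for a confirmed pair by aligning the two
    transcript loci. Denominator of TGI and TTI is the query's exonic length
    (species-of-origin perspective)."""
    if pair.target is None:
        raise ValueError("metrics need a target transcript")
    if scoring is None:
        scoring = ScoringScheme.lncrna()
    tx_a, tx_b = pair.query, pair.target
    la, lb = tx_a.interval, tx_b.interval
    alns = _locus_alignments(tx_a, tx_b, genome_a, genome_b, scoring)
    a_exon = _exon_index_array(tx_a, la)
    b_exon = _exon_index_array(tx_b, lb)
    n_a_exons = tx_a.n_exons
    exon_sizes = [len(e) for e in tx_a.exons_5to3()]
    ident_exon = np.zeros(n_a_exons, dtype=np.int64)
    ident_both = np.zeros(n_a_exons, dtype=np.int64)
    exonic_aligned = intronic_aligned = 0
    exonic_events = intronic_events = 0
    for aln in alns:
        q, t = aln.q_start, aln.t_start
        for op, n in aln.ops:
            if op in "MX":
                for off in range(n):
                    k = a_exon[q + off]
                    if k >= 0:
                        exonic_aligned += 1
                        if op == "M":
                            ident_exon[k] += 1
                            if b_exon[t + off] >= 0:
                                ident_both[k] += 1
                    else:
                        intronic_aligned += 1
                q += n
                t += n
            else:
                k = a_exon[min(q, len(a_exon) - 1)]
                if k >= 0:
                    exonic_events += 1
                else:
                    intronic_events += 1
                if op == "I":
                    q += n
                else:
                    t += n
    exonic_len = tx_a.exonic_length
    tgi = float(ident_exon.sum()) / exonic_len
    tti = float(ident_both.sum()) / exonic_len
    junctions = tx_a.internal_junctions()
    if junctions:
        conserved = sum(
            _junction_conserved(alns, j, tx_b, la, lb, ssc_tol) for j in junctions
        )
        ssc = conserved / len(junctions)
    else:
        conserved = 0
        ssc = None
    if exonic_aligned < MIN_COMPARTMENT_BP or intronic_aligned < MIN_COMPARTMENT_BP:
        idr = None
    elif exonic_events == 0 and intronic_events == 0:
        idr = 0.0
    else:
        idr = math.log2(
            ((exonic_events + 1) / exonic_aligned)
            / ((intronic_events + 1) / intronic_aligned)
        )
    m = EvoMetrics(
        tgi=min(1.0, tgi),
        tti=min(1.0, tti),
        ssc=ssc,
        idr=idr,
        exonic_aligned_bp=exonic_aligned,
        intronic_aligned_bp=intronic_aligned,
        exonic_indel_events=exonic_events,
        intronic_indel_events=intronic_events,
        conserved_junctions=int(conserved),
        n_junctions=len(junctions),
        tgi_per_exon=[ident_exon[i] / exon_sizes[i] for i in range(n_a_exons)],
        tti_per_exon=[ident_both[i] / exon_sizes[i] for i in range(n_a_exons)],
    )
    pair.metrics = m
    return m


def exon_identity_profile(
    pairs: Sequence[OrthologPair], first_n: int = 3
) -> Dict[str, List[float]]:
    """Median per-exon TGI and TTI across pairs (exons in 5'->3' order);
    pairs with fewer exons contribute only to the indices they have."""
    if not pairs:
        raise ValueError("no pairs")
    tgi_cols: List[List[float]] = [[] for _ in range(first_n)]
    tti_cols: List[List[float]] = [[] for _ in range(first_n)]
    for p in pairs:
        if p.metrics is None:
            continue
        for i in range(min(first_n, len(p.metrics.tgi_per_exon))):
            tgi_cols[i].append(p.metrics.tgi_per_exon[i])
            tti_cols[i].append(p.metrics.tti_per_exon[i])
    return {
        "tgi": [float(np.median(c)) if c else math.nan for c in tgi_cols],
        "tti": [float(np.median(c)) if c else math.nan for c in tti_cols],
    }


# ---------------------------------------------------------------------------
# classification


def classify_lncrna(
    tx: Transcript,
    mirna_bed: Sequence,
    snorna_bed: Sequence,
    coding_txs: Sequence[Transcript],
    window: int = 500,
) -> LncClass:
    """Host calls require the small RNA fully inside the transcript span;
    divergent calls require an opposite-strand coding TSS within `window` bp
    of the lncRNA TSS; everything else is intergenic."""
    span = tx.interval
    for iv, _ in mirna_bed:
        if span.contains(iv):
            return MIRNA_HOST
    for iv, _ in snorna_bed:
        if span.contains(iv):
            return SNORNA_HOST
    for c in coding_txs:
        if c.chrom == tx.chrom and c.strand != tx.strand and c.strand in "+-" and tx.strand in "+-":
            if abs(c.tss - tx.tss) <= window:
                return DIVERGENT
    return INTERGENIC


def is_exonic_host(tx: Transcript, small_rna: GenomicInterval) -> bool:
    """True when the hosted small RNA lies inside an exon (sequence-level
    conservation pattern) rather than an intron."""
    return any(e.contains(small_rna) for e in tx.exons)


def classify_pair(
    pair: OrthologPair,
    annots_a: Dict[str, Sequence],
    annots_b: Dict[str, Sequence],
    window: int = 500,
) -> LncClass:
    """A pair is a host/divergent class only when both species' transcripts
    are annotated as such; all other orthologs are intergenic."""
    if pair.target is None:
        return classify_lncrna(
            pair.query,
            annots_a.get("mirna", ()),
            annots_a.get("snorna", ()),
            annots_a.get("coding", ()),
            window,
        )
    ca = classify_lncrna(
        pair.query, annots_a.get("mirna", ()), annots_a.get("snorna", ()),
        annots_a.get("coding", ()), window,
    )
    cb = classify_lncrna(
        pair.target, annots_b.get("mirna", ()), annots_b.get("snorna", ()),
        annots_b.get("coding", ()), window,
    )
    if ca == cb and ca in (MIRNA_HOST, SNORNA_HOST, DIVERGENT):
        return ca
    return INTERGENIC


# ---------------------------------------------------------------------------
# shuffle controls


def shuffled_transcript_control(
    txs: Sequence[Transcript],
    genome: GenomeSequence,
    annotations: Sequence,
    rng_seed=None,
    max_tries: int = 1000,
) -> List[Transcript]:
    """Relocate each transcript to a uniform intergenic start on a random
    strand, preserving its exon/intron structure."""
    rng = as_rng(rng_seed)
    trees: Dict[str, IntervalTree] = {name: IntervalTree() for name in genome.contigs}
    for ann in annotations:
        iv = ann.interval if isinstance(ann, Transcript) else ann
        trees[iv.chrom].addi(iv.start, iv.end)
    contigs = sorted(genome.contigs)
    lengths = np.array([genome.contig_length(c) for c in contigs], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    for tx in txs:
        span = tx.span_length
        placed = None
        for _ in range(max_tries):
            chrom = contigs[int(rng.choice(len(contigs), p=probs))]
            clen = genome.contig_length(chrom)
            if clen <= span:
                continue
            start = int(rng.integers(0, clen - span))
            if trees[chrom].overlap(start, start + span):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            placed = (chrom, start, strand)
            break
        if placed is None:
            raise ValueError(f"could not place shuffled copy of {tx.id}")
        chrom, start, strand = placed
        exons = [
            GenomicInterval(chrom, start + (e.start - tx.start), start + (e.end - tx.start), strand)
            for e in tx.exons
        ]
        iv = GenomicInterval(chrom, start, start + span, strand)
        out.append(
            Transcript(
                id=tx.id + "_shuf", gene_id=tx.gene_id + "_shuf",
                interval=iv, exons=exons, biotype=tx.biotype,
            )
        )
    return out


def splice_shuffle_expectation(
    pair: OrthologPair,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    n_shuffles: int = 200,
    rng_seed=None,
    scoring: Optional[ScoringScheme] = None,
    ssc_tol: int = 2,
) -> float:
    """Expected conserved-junction count when the query's donor sites are
    re-placed uniformly on GT dinucleotide positions within its locus."""
    if pair.target is None:
        raise ValueError("needs a paired transcript")
    tx_a, tx_b = pair.query, pair.target
    if tx_a.n_exons < 2:
        raise ValueError("query has no internal junction")
    if scoring is None:
        scoring = ScoringScheme.lncrna()
    rng = as_rng(rng_seed)
    la, lb = tx_a.interval, tx_b.interval
    seq = genome_a.fetch(la)
    donors = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "GT"]
    if not donors:
        raise ValueError("locus has no GT donor motif")
    alns = _locus_alignments(tx_a, tx_b, genome_a, genome_b, scoring)
    b_ends = [be for be, _ in tx_b.internal_junctions()]
    n_junc = tx_a.n_exons - 1
    total = 0
    for _ in range(n_shuffles):
        picks = rng.choice(len(donors), size=n_junc, replace=len(donors) < n_junc)
        for p in np.atleast_1d(picks):
            pos = donors[int(p)]  # locus-local intron start
            conserved = False
            for aln in alns:
                t_img = aln.map_query_to_target(pos - 1)
                if t_img is not None:
                    boundary = t_img + 1 + lb.start
                    if any(abs(boundary - be) <= ssc_tol for be in b_ends):
                        conserved = True
                        break
            total += conserved
    return total / n_shuffles


# ---------------------------------------------------------------------------
# two-Gaussian mixture on TTI


@dataclass
class MixtureFit:
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    loglik_trajectory: List[float]
    n_iter: int
    posteriors: np.ndarray
    assignments: np.ndarray  # component index by posterior > 0.5


def _em_once(x, k, tol, max_iter, rng):
    n = x.size
    means = np.sort(rng.choice(x, size=k, replace=False) + rng.normal(0, 1e-3, k))
    sds = np.full(k, max(x.std(), 1e-3))
    weights = np.full(k, 1.0 / k)
    traj: List[float] = []
    prev = -np.inf
    for it in range(1, max_iter + 1):
        log_pdf = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :])
            - 0.5 * math.log(2 * math.pi)
            + np.log(weights[None, :])
        )
        ll = float(logsumexp(log_pdf, axis=1).sum())
        traj.append(ll)
        resp = np.exp(log_pdf - logsumexp(log_pdf, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < 1e-8):
            return None
        sds = np.sqrt(var)
        if ll - prev < tol and it > 1:
            break
        prev = ll
    post = np.exp(log_pdf - logsumexp(log_pdf, axis=1, keepdims=True))
    return MixtureFit(
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=traj[-1],
        loglik_trajectory=traj,
        n_iter=len(traj),
        posteriors=post,
        assignments=(post.argmax(axis=1)).astype(int),
    )


def fit_tti_mixture(
    ttis: Sequence[float],
    k: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 10,
    rng_seed=None,
) -> MixtureFit:
    """EM for a k-component univariate Gaussian mixture; best of n_starts by
    log-likelihood; assignment by posterior > 0.5 (argmax for k=2). Restarts
    on degenerate variance; errors when every start degenerates."""
    x = np.asarray(ttis, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 observations")
    rng = as_rng(rng_seed)
    best: Optional[MixtureFit] = None
    for _ in range(n_starts):
        fit = _em_once(x, k, tol, max_iter, rng)
        if fit is not None and (best is None or fit.log_likelihood > best.log_likelihood):
            best = fit
    if best is None:
        raise ValueError("all EM starts hit degenerate variance")
    return best
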