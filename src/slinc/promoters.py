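"""Promoter extraction and conservation-correlate statistics: CpG-island and
repeat content of 500 bp upstream windows, and repeat-family enrichment versus
size- and GC-matched random intergenic background (Fisher's exact test,
Bonferroni-corrected at P < 0.005).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact

from .aligner import IntergenicSampler, as_rng
from .genomic_io import GenomeSequence, GenomicInterval, Transcript

__all__ = [
    "PromoterRecord",
    "EnrichmentResult",
    "promoter_interval",
    "annotate_promoters",
    "sample_matched_background",
    "repeat_enrichment",
    "gc_fraction",
    "call_cpg_islands",
]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def promoter_interval(tx: Transcript, flank: int = 500) -> Optional[GenomicInterval]:
    """Strand-aware upstream window: [TSS-flank, TSS) on + strand,
    [TSS, TSS+flank) on - strand (TSS = interval end), clipped to the contig
    start; None when the clipped window is empty."""
    if tx.strand == "-":
        return GenomicInterval(tx.chrom, tx.end, tx.end + flank, "-")
    start = max(0, tx.start - flank)
    if start >= tx.start:
        return None
    return GenomicInterval(tx.chrom, start, tx.start, "+")


@dataclass
class PromoterRecord:
    transcript_id: str
    interval: GenomicInterval
    gc_fraction: float
    has_cpg: bool
    repeat_bp: int
    repeat_fraction: float
    repeat_families: Tuple[str, ...] = ()


def _clip_to_contig(iv: GenomicInterval, genome: GenomeSequence) -> GenomicInterval:
    clen = genome.contig_length(iv.chrom)
    return GenomicInterval(iv.chrom, max(0, iv.start), min(clen, iv.end), iv.strand)


def annotate_promoters(
    promoters: Sequence[Tuple[str, GenomicInterval]],
    cpg_bed: Sequence,
    repeat_bed: Sequence,
    genome: GenomeSequence,
) -> List[PromoterRecord]:
    """promoters: (transcript id, interval) pairs. has_cpg is any-bp overlap
    with a CpG-island interval; repeat_bp is the union of repeat overlaps."""
    out = []
    for tid, iv in promoters:
        iv = _clip_to_contig(iv, genome)
        seq = genome.fetch(iv)
        has_cpg = any(iv.overlap_bp(c) > 0 for c, _ in cpg_bed)
        covered: List[Tuple[int, int]] = []
        fams = set()
        for riv, fam in repeat_bed:
            bp = iv.overlap_bp(riv)
            if bp > 0:
                covered.append((max(iv.start, riv.start), min(iv.end, riv.end)))
                fams.add(fam)
        covered.sort()
        repeat_bp = 0
        pos = iv.start
        for s, e in covered:
            s = max(s, pos)
            if e > s:
                repeat_bp += e - s
                pos = e
        out.append(
            PromoterRecord(
                transcript_id=tid,
                interval=iv,
                gc_fraction=gc_fraction(seq),
                has_cpg=has_cpg,
                repeat_bp=repeat_bp,
                repeat_fraction=repeat_bp / len(iv),
                repeat_families=tuple(sorted(fams)),
            )
        )
    return out


def sample_matched_background(
    promoters: Sequence[PromoterRecord],
    genome: GenomeSequence,
    annotations: Sequence,
    gc_tol: float = 0.02,
    n_per: int = 1,
    max_tries: int = 1000,
    rng_seed=None,
    on_unmatched: str = "error",
) -> List[GenomicInterval]:
    """For each promoter, n_per random intergenic intervals of equal length
    with GC content within gc_tol; seeded and reproducible.

    on_unmatched='skip' drops promoters for which no match exists (e.g.
    CpG-island promoters in a genome with no GC-rich intergenic space)
    instead of raising."""
    rng = as_rng(rng_seed)
    sampler = IntergenicSampler(genome, annotations)
    out = []
    for rec in promoters:
        for _ in range(n_per):
            found = None
            for _try in range(max_tries):
                iv = sampler.sample(len(rec.interval), rng)
                if abs(gc_fraction(genome.fetch(iv)) - rec.gc_fraction) <= gc_tol:
                    found = iv
                    break
            if found is None:
                if on_unmatched == "skip":
                    continue
                raise ValueError(
                    f"no GC-matched intergenic window for promoter of "
                    f"{rec.transcript_id} (GC {rec.gc_fraction:.3f})"
                )
            out.append(found)
    return out


@dataclass
class EnrichmentResult:
    family: str
    promoters_with: int
    promoters_without: int
    background_with: int
    background_without: int
    odds_ratio: float
    p: float
    p_corrected: float
    significant: bool


def repeat_enrichment(
    promoters: Sequence[PromoterRecord],
    background: Sequence[GenomicInterval],
    repeat_bed: Sequence,
    alpha: float = 0.005,
    correction: str = "bonferroni",
) -> List[EnrichmentResult]:
    """Per repeat family, two-sided Fisher's exact test on presence/absence in
    promoters vs background; corrected for the number of families tested."""
    families = sorted({fam for _, fam in repeat_bed})
    fam_ivs: Dict[str, List[GenomicInterval]] = {f: [] for f in families}
    for riv, fam in repeat_bed:
        fam_ivs[fam].append(riv)

    def has(iv: GenomicInterval, fam: str) -> bool:
        return any(iv.overlap_bp(r) > 0 for r in fam_ivs[fam])

    raw = []
    for fam in families:
        pw = sum(1 for rec in promoters if has(rec.interval, fam))
        bw = sum(1 for iv in background if has(iv, fam))
        if pw == 0 and bw == 0:
            continue  # family absent from both sets
        table = [[pw, len(promoters) - pw], [bw, len(background) - bw]]
        odds, p = fisher_exact(table, alternative="two-sided")
        raw.append((fam, pw, bw, float(odds), float(p)))
    n_tested = len(raw)
    out = []
    if correction == "bonferroni":
        corrected = [min(1.0, p * n_tested) for *_, p in raw]
    elif correction == "bh":
        from scipy.stats import false_discovery_control

        corrected = list(false_discovery_control([p for *_, p in raw], method="bh"))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    for (fam, pw, bw, odds, p), pc in zip(raw, corrected):
        out.append(
            EnrichmentResult(
                family=fam,
                promoters_with=pw,
                promoters_without=len(promoters) - pw,
                background_with=bw,
                background_without=len(background) - bw,
                odds_ratio=odds,
                p=p,
                p_corrected=float(pc),
                significant=pc < alpha,
            )
        )
    return out


def call_cpg_islands(
    genome: GenomeSequence,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    step: int = 50,
) -> List[Tuple[GenomicInterval, str]]:
    """De-novo CpG-island helper for synthetic genomes, using the classic
    thresholds (length >= 200, GC >= 0.5, observed/expected CpG >= 0.6).
    Sliding windows passing all thresholds are merged."""
    out = []
    for name, seq in genome.contigs.items():
        hits = []
        for s in range(0, max(1, len(seq) - min_length + 1), step):
            w = seq[s : s + min_length]
            if len(w) < min_length:
                break
            g, c = w.count("G"), w.count("C")
            gc = (g + c) / len(w)
            cpg = w.count("CG")
            exp = g * c / len(w) if g and c else 0
            if gc >= min_gc and exp > 0 and cpg / exp >= min_obs_exp:
                hits.append((s, s + min_length))
        hits.sort()
        merged: List[List[int]] = []
        for s, e in hits:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            out.append((GenomicInterval(name, s, e), "CpG"))
    return out
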