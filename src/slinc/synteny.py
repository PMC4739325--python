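"""Interval and transcript lifting through genome alignment chains, and
padded syntenic window construction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .genomic_io import Chain, ChainSet, GenomeSequence, GenomicInterval, Transcript

__all__ = ["LiftResult", "lift_interval", "lift_transcript", "syntenic_window"]

# Relaxed preset for distant species pairs (e.g. fish vs mammal):
DISTANT_MIN_MATCH = 0.01
DISTANT_PAD = 500_000


@dataclass
class LiftResult:
    source: GenomicInterval
    mapped: List[GenomicInterval] = field(default_factory=list)
    mapped_fraction: float = 0.0
    chain_id: Optional[str] = None

    @property
    def span(self) -> Optional[GenomicInterval]:
        if not self.mapped:
            return None
        chrom = self.mapped[0].chrom
        return GenomicInterval(
            chrom,
            min(m.start for m in self.mapped),
            max(m.end for m in self.mapped),
            self.mapped[0].strand,
        )


def _merge(ivs: List[GenomicInterval]) -> List[GenomicInterval]:
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda v: (v.chrom, v.start))
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.chrom == last.chrom and iv.start <= last.end:
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            out.append(iv)
    return out


def _lift_through_chain(chain: Chain, iv: GenomicInterval) -> List[GenomicInterval]:
    """Map the source-bp of iv inside this chain's aligned blocks, block by
    block, onto the destination genome."""
    if chain.t_name != iv.chrom:
        return []
    out = []
    t = chain.t_start
    q = chain.q_start
    strand = iv.strand
    for size, dt, dq in chain.blocks:
        lo = max(t, iv.start)
        hi = min(t + size, iv.end)
        if hi > lo:
            q_lo = q + (lo - t)
            q_hi = q + (hi - t)
            if chain.q_strand == "-":
                start = chain.q_size - q_hi
                end = chain.q_size - q_lo
                s = {"+": "-", "-": "+", ".": "."}[strand]
                out.append(GenomicInterval(chain.q_name, start, end, s))
            else:
                out.append(GenomicInterval(chain.q_name, q_lo, q_hi, strand))
        t += size + dt
        q += size + dq
        if t >= iv.end:
            break
    return out


def lift_interval(
    chains: ChainSet,
    iv: GenomicInterval,
    min_match: float = 0.1,
    multiple: bool = False,
) -> LiftResult:
    """liftOver contract: map iv through each chain; a mapping is emitted iff
    the fraction of source bp inside aligned blocks is >= min_match. With
    multiple=False only the best-covering chain is kept (ties broken by chain
    score, then chain id)."""
    results = []
    for chain in chains.for_source_chrom(iv.chrom):
        mapped = _merge(_lift_through_chain(chain, iv))
        covered = sum(len(m) for m in mapped)
        frac = covered / len(iv)
        if mapped and frac >= min_match:
            results.append((frac, chain.score, chain.chain_id, mapped))
    if not results:
        return LiftResult(source=iv)
    results.sort(key=lambda r: (-r[0], -r[1], r[2]))
    if multiple:
        mapped = _merge([m for r in results for m in r[3]])
        return LiftResult(iv, mapped, results[0][0], results[0][2])
    frac, _, cid, mapped = results[0]
    return LiftResult(iv, mapped, frac, cid)


def lift_transcript(
    chains: ChainSet, tx: Transcript, min_match: float = 0.1
) -> LiftResult:
    """Lift the exonic footprint: exons are lifted independently through the
    best chain for the transcript span, then unioned on the destination; the
    mapped fraction is computed over exonic bp."""
    total_exonic = tx.exonic_length
    cands = []
    for chain in chains.for_source_chrom(tx.chrom):
        mapped = []
        covered = 0
        for exon in tx.exons:
            m = _merge(_lift_through_chain(chain, exon))
            covered += sum(len(x) for x in m)
            mapped.extend(m)
        frac = covered / total_exonic
        mapped = _merge(mapped)
        if mapped and frac >= min_match:
            cands.append((frac, chain.score, chain.chain_id, mapped))
    if not cands:
        return LiftResult(source=tx.interval)
    cands.sort(key=lambda r: (-r[0], -r[1], r[2]))
    frac, _, cid, mapped = cands[0]
    return LiftResult(tx.interval, mapped, frac, cid)


def syntenic_window(
    chains: ChainSet,
    tx: Transcript,
    genome_dest: GenomeSequence,
    pad: int = 150_000,
    min_match: float = 0.1,
) -> Optional[GenomicInterval]:
    """Destination-genome span of the lifted exonic footprint, extended by pad
    on both sides and clipped to contig bounds; None when unmappable."""
    lift = lift_transcript(chains, tx, min_match=min_match)
    span = lift.span
    if span is None:
        return None
    return span.padded(pad, contig_length=genome_dest.contig_length(span.chrom))
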