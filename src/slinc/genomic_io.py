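"""Genomic coordinate model and parsers for the flat-file formats the pipeline touches.

All coordinates are 0-based half-open (BED-native). GTF input (1-based,
closed) is converted on ingest and round-trips losslessly through BED12.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GenomeSequence",
    "Chain",
    "ChainSet",
    "read_fasta",
    "write_fasta",
    "read_bed12",
    "write_bed12",
    "read_bed6",
    "write_bed6",
    "read_gtf",
    "read_chain",
    "write_chain",
]

_DNA_OK = set("ACGTN")


def _clean_seq(raw: str) -> str:
    s = raw.upper().replace("U", "T")
    if set(s) <= _DNA_OK:
        return s
    return "".join(c if c in _DNA_OK else "N" for c in s)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named contig."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty contig name")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def padded(self, pad: int, contig_length: Optional[int] = None) -> "GenomicInterval":
        start = max(0, self.start - pad)
        end = self.end + pad
        if contig_length is not None:
            end = min(end, contig_length)
        return replace(self, start=start, end=end)


@dataclass(frozen=True)
class Transcript:
    """Stranded multi-exon gene model (BED12 semantics)."""

    id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple
    biotype: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise ValueError(f"{self.id}: transcript needs >=1 exon")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(f"{self.id}: exon chrom/strand mismatch")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.id}: exons overlap or unsorted")
            prev_end = ex.end
        if self.exons[0].start != self.interval.start or self.exons[-1].end != self.interval.end:
            raise ValueError(f"{self.id}: exons do not span transcript interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def exonic_length(self) -> int:
        """Transcript 'length' throughout the package = sum of exon sizes."""
        return sum(len(e) for e in self.exons)

    @property
    def span_length(self) -> int:
        return len(self.interval)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (half-open convention: the
        position of the first transcribed base)."""
        return self.start if self.strand != "-" else self.end - 1

    def introns(self) -> list:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return out

    def internal_junctions(self) -> list:
        """Genomic coordinates of internal splice junctions as (donor_like,
        acceptor_like) = (exon end, next exon start), in genomic order."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]

    def exons_5to3(self) -> tuple:
        """Exons in transcript (5' -> 3') order."""
        return self.exons if self.strand != "-" else tuple(reversed(self.exons))


class GenomeSequence:
    """Uppercase DNA over {A,C,G,T,N}, one string per contig."""

    def __init__(self, contigs: dict):
        if not contigs:
            raise ValueError("genome has no contigs")
        for name, seq in contigs.items():
            if not name:
                raise ValueError("empty contig name")
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
        self.contigs = dict(contigs)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def contig_length(self, name: str) -> int:
        return len(self.contigs[name])

    def fetch(self, iv: GenomicInterval) -> str:
        """Plus-strand sequence of the interval."""
        seq = self.contigs[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"{iv} outside contig (len {len(seq)})")
        return seq[iv.start : iv.end]

    def fetch_oriented(self, iv: GenomicInterval) -> str:
        s = self.fetch(iv)
        return reverse_complement(s) if iv.strand == "-" else s

    def spliced(self, tx: Transcript) -> str:
        """Exonic sequence of the transcript, 5'->3'."""
        s = "".join(self.fetch(e) for e in tx.exons)
        return reverse_complement(s) if tx.strand == "-" else s

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def _as_handle(stream: Union[str, TextIO]) -> TextIO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def read_fasta(stream: Union[str, TextIO]) -> GenomeSequence:
    """Read FASTA into a GenomeSequence; case-folds, maps U->T, others->N."""
    contigs: dict = {}
    for rec in SeqIO.parse(_as_handle(stream), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig header: {rec.id!r}")
        contigs[rec.id] = _clean_seq(str(rec.seq))
    if not contigs:
        raise ValueError("empty FASTA input")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, handle: TextIO, width: int = 80) -> None:
    for name in genome.contigs:
        handle.write(f">{name}\n")
        seq = genome.contigs[name]
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED12 / BED6


def read_bed12(stream: Union[str, TextIO]) -> list:
    txs = []
    for lineno, line in enumerate(_as_handle(stream), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 12:
            raise ValueError(f"line {lineno}: expected 12 BED columns, got {len(f)}")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",") if x != ""]
        starts = [int(x) for x in f[11].rstrip(",").split(",") if x != ""]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValueError(f"line {lineno}: blockCount mismatch")
        exons = []
        for bs, sz in zip(starts, sizes):
            es, ee = start + bs, start + bs + sz
            if es < start or ee > end:
                raise ValueError(f"line {lineno}: block outside chromStart/chromEnd")
            exons.append(GenomicInterval(chrom, es, ee, strand))
        iv = GenomicInterval(chrom, start, end, strand)
        txs.append(Transcript(id=name, gene_id=name, interval=iv, exons=exons))
    return txs


def write_bed12(transcripts: Iterable[Transcript], handle: TextIO) -> None:
    """Deterministic BED12 output ordered by (chrom, start, id)."""
    for tx in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id)):
        sizes = ",".join(str(len(e)) for e in tx.exons) + ","
        starts = ",".join(str(e.start - tx.start) for e in tx.exons) + ","
        handle.write(
            "\t".join(
                [
                    tx.chrom,
                    str(tx.start),
                    str(tx.end),
                    tx.id,
                    "0",
                    tx.strand,
                    str(tx.start),
                    str(tx.end),
                    "0",
                    str(tx.n_exons),
                    sizes,
                    starts,
                ]
            )
            + "\n"
        )


def read_bed6(stream: Union[str, TextIO]) -> list:
    """Annotation track: list of (GenomicInterval, name). Name (col 4) carries
    e.g. the repeat family."""
    out = []
    for lineno, line in enumerate(_as_handle(stream), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 3:
            raise ValueError(f"line {lineno}: expected >=3 BED columns")
        name = f[3] if len(f) > 3 else "."
        strand = f[5] if len(f) > 5 else "."
        out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand), name))
    return out


def write_bed6(records: Iterable, handle: TextIO) -> None:
    for iv, name in sorted(records, key=lambda r: (r[0].chrom, r[0].start, r[1])):
        handle.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
        )


# ---------------------------------------------------------------------------
# GTF (read-only; exon features grouped by transcript_id)


def _gtf_attrs(col: str) -> dict:
    out = {}
    for part in col.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(stream: Union[str, TextIO]) -> list:
    """Minimal GTF ingest: exon features only, 1-based closed converted to
    0-based half-open."""
    by_tx: dict = {}
    for lineno, line in enumerate(_as_handle(stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"line {lineno}: expected 9 GTF columns")
        if f[2] != "exon":
            continue
        attrs = _gtf_attrs(f[8])
        tid = attrs.get("transcript_id")
        if tid is None:
            raise ValueError(f"line {lineno}: exon without transcript_id")
        gid = attrs.get("gene_id", tid)
        iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
        by_tx.setdefault(tid, (gid, []))[1].append(iv)
    txs = []
    for tid, (gid, exons) in by_tx.items():
        exons = sorted(exons, key=lambda e: e.start)
        iv = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        txs.append(Transcript(id=tid, gene_id=gid, interval=iv, exons=exons))
    return sorted(txs, key=lambda t: (t.chrom, t.start, t.id))


# ---------------------------------------------------------------------------
# UCSC chain


@dataclass
class Chain:
    """One UCSC chain. `t` is the source genome of a lift, `q` the destination.

    blocks: list of (aligned_size, dt, dq); dt/dq are gaps after the block on
    the t/q side. The last block has dt == dq == 0.
    """

    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list = field(default_factory=list)

    def validate(self) -> None:
        tsum = sum(b[0] + b[1] for b in self.blocks)
        qsum = sum(b[0] + b[2] for b in self.blocks)
        if tsum != self.t_end - self.t_start or qsum != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: block arithmetic does not match spans"
            )
        for size, dt, dq in self.blocks:
            if size < 1 or dt < 0 or dq < 0:
                raise ValueError(f"chain {self.chain_id}: bad block ({size},{dt},{dq})")
        if self.blocks and (self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0):
            raise ValueError(f"chain {self.chain_id}: last block must end the chain")


class ChainSet:
    def __init__(self, chains: list):
        self.chains = list(chains)
        self._by_t: dict = {}
        for c in self.chains:
            self._by_t.setdefault(c.t_name, []).append(c)

    def for_source_chrom(self, chrom: str) -> list:
        return self._by_t.get(chrom, [])

    def inverted(self) -> "ChainSet":
        """Swap source and destination roles (only +/+ chains supported,
        which is all the fixture generator emits)."""
        out = []
        for c in self.chains:
            if c.t_strand != "+" or c.q_strand != "+":
                raise ValueError("cannot invert strand-flipping chain")
            out.append(
                Chain(
                    score=c.score,
                    t_name=c.q_name,
                    t_size=c.q_size,
                    t_strand="+",
                    t_start=c.q_start,
                    t_end=c.q_end,
                    q_name=c.t_name,
                    q_size=c.t_size,
                    q_strand="+",
                    q_start=c.t_start,
                    q_end=c.t_end,
                    chain_id=c.chain_id,
                    blocks=[(s, dq, dt) for (s, dt, dq) in c.blocks],
                )
            )
        return ChainSet(out)


def read_chain(stream: Union[str, TextIO]) -> ChainSet:
    chains = []
    cur: Optional[Chain] = None
    for line in _as_handle(stream):
        line = line.strip()
        if not line:
            cur = None
            continue
        if line.startswith("chain"):
            f = line.split()
            cur = Chain(
                score=int(f[1]),
                t_name=f[2],
                t_size=int(f[3]),
                t_strand=f[4],
                t_start=int(f[5]),
                t_end=int(f[6]),
                q_name=f[7],
                q_size=int(f[8]),
                q_strand=f[9],
                q_start=int(f[10]),
                q_end=int(f[11]),
                chain_id=f[12] if len(f) > 12 else str(len(chains) + 1),
            )
            chains.append(cur)
        else:
            if cur is None:
                raise ValueError("chain block line outside a chain")
            f = line.split()
            if len(f) == 1:
                cur.blocks.append((int(f[0]), 0, 0))
            else:
                cur.blocks.append((int(f[0]), int(f[1]), int(f[2])))
    for c in chains:
        c.validate()
    return ChainSet(chains)


def write_chain(chainset: ChainSet, handle: TextIO) -> None:
    for c in chainset.chains:
        handle.write(
            f"chain {c.score} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} "
            f"{c.t_end} {c.q_name} {c.q_size} {c.q_strand} {c.q_start} "
            f"{c.q_end} {c.chain_id}\n"
        )
        for size, dt, dq in c.blocks[:-1]:
            handle.write(f"{size} {dt} {dq}\n")
        if c.blocks:
            handle.write(f"{c.blocks[-1][0]}\n")
        handle.write("\n")
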