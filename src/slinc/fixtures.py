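"""Synthetic two-genome fixtures with planted elements and exact truth tables.

Genome B is derived from genome A segment by segment: background spacers
diverge neutrally (substitutions plus short indels), planted elements carry
their own divergence regimes, and alignment chains are emitted from the
generative event log, so liftover in tests is exact by construction. The
planted content mirrors what the pipeline must separate in real data: coding
genes with overlapping candidate fragments, conserved and exon-1-only
(divergent-class) lncRNA pairs, miRNA/snoRNA hosts, a lineage-specific
duplicated family matching a known ZFP-like panel, a processed pseudogene, a
3'-UTR fragment, species-specific and unliftable lncRNAs, and a single-exon
artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .aligner import as_rng
from .genomic_io import (
    Chain,
    ChainSet,
    GenomeSequence,
    GenomicInterval,
    Transcript,
)
from . import lnc_filter as lf
from . import ortho_evo as oe

__all__ = [
    "FixtureConfig",
    "PlantedElement",
    "FixtureTruth",
    "GenomePairFixture",
    "mutate_sequence",
    "plant_genome_pair",
    "neutral_codon_pair",
    "plant_promoter_set",
]

_BASES = "ACGT"


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _encode(seq: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(_BASES)}
    return np.array([lut[c] for c in seq], dtype=np.int8)


@dataclass
class MutationResult:
    seq: str
    # (a_len, b_len, aligned) runs; aligned runs have a_len == b_len
    segments: List[Tuple[int, int, bool]]
    events: List[Tuple[int, str, int]]  # (a_pos, 'ins'|'del', length)
    n_substitutions: int


def mutate_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng_seed=None,
    mean_indel_len: float = 2.0,
) -> MutationResult:
    """Per-base independent substitutions plus Poisson-along-the-sequence
    indel events with geometric lengths. The event log makes the expected
    identity and the alignment chain exactly computable."""
    rng = as_rng(rng_seed)
    n = len(seq)
    codes = _encode(seq)
    mask = rng.random(n) < sub_rate
    n_subs = int(mask.sum())
    shift = rng.integers(1, 4, size=n_subs)
    mut = codes.copy()
    mut[mask] = (mut[mask] + shift) % 4
    sub_seq = _decode(mut)
    if indel_rate <= 0:
        return MutationResult(sub_seq, [(n, n, True)] if n else [], [], n_subs)
    event_pos = np.nonzero(rng.random(n) < indel_rate)[0]
    parts: List[str] = []
    segments: List[Tuple[int, int, bool]] = []
    events: List[Tuple[int, str, int]] = []
    pos = 0
    for p in event_pos:
        p = int(p)
        if p < pos:
            continue  # swallowed by a previous deletion
        is_ins = rng.random() < 0.5
        length = int(rng.geometric(1.0 / mean_indel_len))
        if p > pos:
            parts.append(sub_seq[pos:p])
            segments.append((p - pos, p - pos, True))
        if is_ins:
            ins = _random_seq(length, rng)
            parts.append(ins)
            segments.append((0, length, False))
            events.append((p, "ins", length))
            pos = p
        else:
            length = min(length, n - p)
            segments.append((length, 0, False))
            events.append((p, "del", length))
            pos = p + length
    if pos < n:
        parts.append(sub_seq[pos:])
        segments.append((n - pos, n - pos, True))
    return MutationResult("".join(parts), segments, events, n_subs)


# ---------------------------------------------------------------------------
# codon-pair simulator for dN/dS calibration

from .orf_dnds import STOPS, _AA  # noqa: E402  (shared codon table)


def neutral_codon_pair(
    n_codons: int, sub_rate: float, omega: float, rng_seed=None
) -> Tuple[str, str]:
    """A gap-free codon alignment: sequence B evolves from A with per-site
    substitutions accepted with probability 1 when synonymous and `omega`
    when nonsynonymous; stop-creating changes are rejected."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = as_rng(rng_seed)
    codons = []
    while len(codons) < n_codons:
        c = _random_seq(3, rng)
        if c not in STOPS:
            codons.append(c)
    seq_a = "".join(codons)
    b = list(seq_a)
    for i in range(len(b)):
        if rng.random() >= sub_rate:
            continue
        cstart = 3 * (i // 3)
        old_codon = "".join(b[cstart : cstart + 3])
        new_base = _BASES[(("ACGT".index(b[i])) + int(rng.integers(1, 4))) % 4]
        new_codon = old_codon[: i - cstart] + new_base + old_codon[i - cstart + 1 :]
        if new_codon in STOPS:
            continue
        if _AA[new_codon] == _AA[old_codon] or rng.random() < omega:
            b[i] = new_base
    return seq_a, "".join(b)


# ---------------------------------------------------------------------------
# fixture configuration and truth


@dataclass
class FixtureConfig:
    seed: int = 7
    species: Tuple[str, str] = ("spA", "spB")
    n_coding: int = 12
    n_conserved_linc: int = 5
    n_divergent: int = 2
    n_mirna_host: int = 1
    n_snorna_host: int = 1
    dup_copies: int = 3
    n_species_specific: int = 2
    n_unliftable: int = 1
    n_single_exon: int = 1
    spacer_min: int = 6000
    spacer_max: int = 12000
    genome_sub: float = 0.03
    genome_indel: float = 3e-4
    coding_sub: float = 0.02
    lnc_exon_sub: float = 0.10
    lnc_intron_sub: float = 0.15
    lnc_intron_indel: float = 0.003
    divergent_exon1_sub: float = 0.08
    dup_sub: float = 0.06
    pseudogene_sub: float = 0.01
    utr_sub: float = 0.005
    indel_mean_len: float = 2.0

    def __post_init__(self):
        for r in (self.genome_sub, self.genome_indel, self.coding_sub, self.lnc_exon_sub):
            if not (0 <= r < 1):
                raise ValueError("rates must be in [0, 1)")


@dataclass
class PlantedElement:
    kind: str
    id_a: Optional[str] = None
    id_b: Optional[str] = None
    expected_fate: Optional[str] = None
    expected_ortholog: Optional[str] = None  # target id, "syntolog", or None
    expected_class: Optional[str] = None
    expected_lca: Optional[str] = None
    expected_identity: Optional[float] = None


@dataclass
class FixtureTruth:
    elements: List[PlantedElement] = field(default_factory=list)

    def by_id(self) -> Dict[str, PlantedElement]:
        out = {}
        for el in self.elements:
            if el.id_a:
                if el.id_a in out:
                    raise ValueError(f"duplicate planted id {el.id_a}")
                out[el.id_a] = el
        return out

    def expected_fates(self) -> Dict[str, str]:
        return {
            el.id_a: el.expected_fate
            for el in self.elements
            if el.id_a and el.expected_fate
        }

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.elements], indent=1, sort_keys=True)


@dataclass
class GenomePairFixture:
    config: FixtureConfig
    genome_a: GenomeSequence
    genome_b: GenomeSequence
    chains: ChainSet  # A -> B
    candidates_a: List[Transcript]
    lnc_b: List[Transcript]
    coding_a: List[Transcript]
    coding_b: List[Transcript]
    mirna_a: List = field(default_factory=list)
    mirna_b: List = field(default_factory=list)
    snorna_a: List = field(default_factory=list)
    snorna_b: List = field(default_factory=list)
    repeats_a: List = field(default_factory=list)
    cpg_a: List = field(default_factory=list)
    known_panels: Dict[str, str] = field(default_factory=dict)
    truth: FixtureTruth = field(default_factory=FixtureTruth)
    tree_newick: str = "(spA,spB)anc;"

    def annotations_a(self) -> List[Transcript]:
        return list(self.coding_a) + list(self.candidates_a)

    def annotations_b(self) -> List[Transcript]:
        return list(self.coding_b) + list(self.lnc_b)

    def recommended_run_config(self) -> Dict:
        """Pipeline parameters matched to the fixture's genome scale: the
        syntenic-window pad spans several flanking elements (the same role
        150 kb plays on mammalian genomes)."""
        return {
            "pad": 20_000,
            "n_null": 200,
            "alpha": 0.05,
            "min_cluster_size": 2,
            "cap": 250,
            "min_orf": 33,
            "min_match": 0.1,
            "ssc_tol": 2,
            "flank": 500,
            "enrichment_alpha": 0.005,
        }


class _ContigBuilder:
    def __init__(self, chrom: str):
        self.chrom = chrom
        self._a: List[str] = []
        self._b: List[str] = []
        self.apos = 0
        self.bpos = 0
        self.segments: List[Tuple[int, int, bool]] = []

    def add(self, a_seq: str, b_seq: str, segments) -> Tuple[int, int]:
        at, bt = self.apos, self.bpos
        self._a.append(a_seq)
        self._b.append(b_seq)
        self.apos += len(a_seq)
        self.bpos += len(b_seq)
        self.segments.extend(segments)
        return at, bt

    def add_mutated(self, seq: str, sub: float, indel: float, rng) -> Tuple[int, int]:
        m = mutate_sequence(seq, sub, indel, rng)
        return self.add(seq, m.seq, m.segments)

    def add_replaced(self, seq: str, rng) -> Tuple[int, int]:
        """Syntenic position retained (chain block) but sequence fully
        turned over in B -- a species-specific locus."""
        return self.add(seq, _random_seq(len(seq), rng), [(len(seq), len(seq), True)])

    def add_a_only(self, seq: str) -> Tuple[int, int]:
        """Present in A, deleted in B (chain gap)."""
        return self.add(seq, "", [(len(seq), 0, False)])

    def finish(self) -> Tuple[str, str]:
        return "".join(self._a), "".join(self._b)

    def chain(self, chrom_b: str, chain_id: str) -> Chain:
        a = b = 0
        blocks: List[Tuple[int, int, int]] = []
        t0 = q0 = None
        t_last = q_last = None
        cur = dt = dq = 0
        for al, bl, aligned in self.segments:
            if aligned and al > 0:
                if t0 is None:
                    t0, q0 = a, b
                if cur and (dt or dq):
                    blocks.append((cur, dt, dq))
                    cur = 0
                    dt = dq = 0
                cur += al
                t_last, q_last = a + al, b + bl
            elif t0 is not None:
                dt += al
                dq += bl
            a += al
            b += bl
        if cur:
            blocks.append((cur, 0, 0))
        chain = Chain(
            score=sum(s for s, _, _ in blocks),
            t_name=self.chrom,
            t_size=self.apos,
            t_strand="+",
            t_start=t0 or 0,
            t_end=t_last or 0,
            q_name=chrom_b,
            q_size=self.bpos,
            q_strand="+",
            q_start=q0 or 0,
            q_end=q_last or 0,
            chain_id=chain_id,
        )
        chain.blocks = blocks
        chain.validate()
        return chain


def _make_transcript(
    tid: str,
    chrom: str,
    start: int,
    strand: str,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
    biotype: Optional[str] = None,
    gene_id: Optional[str] = None,
) -> Transcript:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    iv = GenomicInterval(chrom, start, exons[-1].end, strand)
    return Transcript(id=tid, gene_id=gene_id or tid, interval=iv, exons=exons, biotype=biotype)


def _coding_sequence(exon_lens: Sequence[int], rng) -> List[str]:
    """Exon sequences forming an ATG...stop mRNA with no internal stop."""
    total = sum(exon_lens)
    if total % 3:
        raise ValueError("coding exon lengths must sum to a multiple of 3")
    codons = ["ATG"]
    while len(codons) < total // 3 - 1:
        c = _random_seq(3, rng)
        if c not in STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    mrna = "".join(codons)
    out, pos = [], 0
    for el in exon_lens:
        out.append(mrna[pos : pos + el])
        pos += el
    return out


def _cpg_rich(n: int, rng) -> str:
    out = []
    while len(out) < n:
        if rng.random() < 0.25:
            out.extend("CG")
        else:
            out.append(_BASES[int(rng.choice([0, 1, 2, 3], p=[0.15, 0.35, 0.35, 0.15]))])
    return "".join(out[:n])


def plant_genome_pair(config: FixtureConfig) -> GenomePairFixture:
    """Build the paired toy genomes, chains, annotation tracks, and truth."""
    rng = as_rng(config.seed)
    fx = GenomePairFixture(
        config=config,
        genome_a=None,  # filled at the end
        genome_b=None,
        chains=None,
        candidates_a=[],
        lnc_b=[],
        coding_a=[],
        coding_b=[],
    )
    sp_a, sp_b = config.species
    fx.tree_newick = f"({sp_a},{sp_b})anc;"
    extra_chains: List[Chain] = []
    b_gene_info: Dict[str, Dict] = {}  # per coding gene: B exon seqs/coords

    def spacer(builder):
        n = int(rng.integers(config.spacer_min, config.spacer_max))
        builder.add_mutated(_random_seq(n, rng), config.genome_sub, config.genome_indel, rng)

    def plant_repeat(builder, family: str):
        n = int(rng.integers(250, 400))
        a0, _ = builder.add_mutated(_random_seq(n, rng), config.genome_sub, 0, rng)
        fx.repeats_a.append((GenomicInterval(builder.chrom, a0, a0 + n), family))

    def plant_coding(builder, i: int, with_utr: bool = False):
        strand = "-" if i % 2 and i > 1 else "+"
        exon_lens = [300, 450, 360]
        intron_lens = [400, 650]
        exon_seqs = _coding_sequence(exon_lens, rng)
        if strand == "-":
            # keep genomic layout; sequence content does not matter for the
            # filter logic, only annotations do
            pass
        gene_a0 = None
        b_exons = []
        b_offsets = []
        for k, es in enumerate(exon_seqs):
            a0, b0 = builder.add_mutated(es, config.coding_sub, 0, rng)
            if gene_a0 is None:
                gene_a0, gene_b0 = a0, b0
            b_offsets.append(b0)
            b_exons.append((b0, len(es)))
            if k < len(intron_lens):
                builder.add_mutated(_random_seq(intron_lens[k], rng), config.coding_sub, 0, rng)
        utr_len = 0
        if with_utr:
            utr = _random_seq(600, rng)
            utr_a0, utr_b0 = builder.add_mutated(utr, config.utr_sub, 0, rng)
            utr_len = 600
        tx_a = _make_transcript(
            f"codA_{i}", builder.chrom, gene_a0, strand, exon_lens, intron_lens, "coding"
        )
        if with_utr:
            b_exon_lens = exon_lens[:-1] + [exon_lens[-1] + utr_len]
        else:
            b_exon_lens = exon_lens
        tx_b = _make_transcript(
            f"codB_{i}", builder.chrom.replace("A", "B"), gene_b0, strand,
            b_exon_lens, intron_lens, "coding",
        )
        fx.coding_a.append(tx_a)
        fx.coding_b.append(tx_b)
        b_gene_info[f"cod_{i}"] = {
            "tx_b": tx_b,
            "b_exon_coords": [(o, o + l) for (o, l) in b_exons],
            "intron_lens": intron_lens,
        }
        # overlapping candidate fragment (a step-1 positive)
        frag = _make_transcript(
            f"cand_olap_{i}",
            builder.chrom,
            tx_a.exons[1].start,
            strand,
            [len(tx_a.exons[1]), len(tx_a.exons[2])],
            [intron_lens[1]],
            "candidate",
        )
        fx.candidates_a.append(frag)
        fx.truth.elements.append(
            PlantedElement(kind="coding_overlap_fragment", id_a=frag.id,
                           expected_fate=lf.REMOVED_CODING)
        )
        if with_utr:
            # candidate covering the UTR only annotated in species B
            utr_frag = _make_transcript(
                f"utrfragA_{i}", builder.chrom, utr_a0, strand, [250, 300], [50],
                "candidate",
            )
            fx.candidates_a.append(utr_frag)
            fx.truth.elements.append(
                PlantedElement(kind="utr_fragment", id_a=utr_frag.id,
                               expected_fate=lf.REMOVED_SYNTENIC)
            )
            del utr_b0
        return tx_a

    def plant_lnc_pair(
        builder, tid_a: str, tid_b: str, exon_lens, intron_lens,
        exon_subs=None, strand: str = "+", replace_exons: Optional[set] = None,
        with_cpg: bool = False, small_rna: Optional[str] = None,
    ):
        """A lncRNA with homologous structure in both genomes. Exons whose
        genomic index is in replace_exons are turned over to unrelated
        sequence in B (the exon-1-only conservation pattern of
        divergent-class lncRNAs); introns flanked by replaced exons are
        replaced too."""
        replace_exons = replace_exons or set()
        if with_cpg:
            cpg = _cpg_rich(400, rng)
            a0, _ = builder.add_mutated(cpg, 0.02, 0, rng)
            fx.cpg_a.append((GenomicInterval(builder.chrom, a0, a0 + 400), "CpG"))
        a_start = b_start = None
        small_rna_ivs = None
        b_exon_offsets = []
        for k, el in enumerate(exon_lens):
            seq = _random_seq(el, rng)
            if k in replace_exons:
                a0, b0 = builder.add_replaced(seq, rng)
            else:
                sub = (exon_subs or {}).get(k, config.lnc_exon_sub)
                a0, b0 = builder.add_mutated(seq, sub, 0, rng)
            b_exon_offsets.append(b0)
            if a_start is None:
                a_start, b_start = a0, b0
            if k < len(intron_lens):
                iseq = _random_seq(intron_lens[k], rng)
                if k in replace_exons and (k + 1) in replace_exons:
                    builder.add_replaced(iseq, rng)
                elif small_rna is not None and k == 0:
                    # keep the hosting intron indel-free so the small RNA has
                    # identical offsets in both species
                    ia, ib = builder.add_mutated(iseq, config.lnc_intron_sub, 0, rng)
                    off = intron_lens[k] // 3
                    small_rna_ivs = (
                        GenomicInterval(builder.chrom, ia + off, ia + off + 80),
                        GenomicInterval(builder.chrom.replace("A", "B"), ib + off, ib + off + 80),
                    )
                else:
                    builder.add_mutated(
                        iseq, config.lnc_intron_sub, config.lnc_intron_indel, rng
                    )
        tx_a = _make_transcript(tid_a, builder.chrom, a_start, strand, exon_lens, intron_lens, "candidate")
        # B exon coordinates come from the builder cursor: intron indels
        # shift downstream exons, so the A intron lengths cannot be reused
        chrom_b = builder.chrom.replace("A", "B")
        b_exons = [
            GenomicInterval(chrom_b, b0, b0 + el, strand)
            for b0, el in zip(b_exon_offsets, exon_lens)
        ]
        tx_b = Transcript(
            id=tid_b,
            gene_id=tid_b,
            interval=GenomicInterval(chrom_b, b_exons[0].start, b_exons[-1].end, strand),
            exons=b_exons,
            biotype="lncRNA",
        )
        fx.candidates_a.append(tx_a)
        fx.lnc_b.append(tx_b)
        if small_rna == "mirna":
            fx.mirna_a.append((small_rna_ivs[0], f"mir_{tid_a}"))
            fx.mirna_b.append((small_rna_ivs[1], f"mir_{tid_b}"))
        elif small_rna == "snorna":
            fx.snorna_a.append((small_rna_ivs[0], f"sno_{tid_a}"))
            fx.snorna_b.append((small_rna_ivs[1], f"sno_{tid_b}"))
        return tx_a, tx_b

    # NB: the B-transcript exon offsets above rely on exon/intron pieces being
    # planted without indels whenever a B annotation is needed at the same
    # relative position; intron pieces of plain conserved lincRNAs do carry
    # indels, so their B exon offsets are taken from the builder cursor, which
    # tracks them exactly.

    # --- panel-derived duplicated family
    panel_seq = _random_seq(1100, rng)
    fx.known_panels["ZFP_toy"] = panel_seq

    def plant_dup_copy(builder, i: int):
        m = mutate_sequence(panel_seq, config.dup_sub, 0, rng)
        e1, e2 = m.seq[:600], m.seq[600:]
        a0, _ = builder.add_replaced(e1, rng)
        builder.add_mutated(_random_seq(450, rng), config.genome_sub, 0, rng)
        builder.add_replaced(e2, rng)
        tx = _make_transcript(f"dupA_{i}", builder.chrom, a0, "+", [600, 500], [450], "candidate")
        fx.candidates_a.append(tx)
        fx.truth.elements.append(
            PlantedElement(kind="duplication_copy", id_a=tx.id, expected_fate=lf.REMOVED_DUP)
        )

    def plant_species_specific(builder, i: int):
        plant_repeat(builder, "ERVK_toy")
        builder.add_mutated(_random_seq(80, rng), config.genome_sub, 0, rng)
        seq1, intron, seq2 = _random_seq(450, rng), _random_seq(500, rng), _random_seq(400, rng)
        a0, _ = builder.add_replaced(seq1, rng)
        builder.add_replaced(intron, rng)
        builder.add_replaced(seq2, rng)
        tx = _make_transcript(f"ssA_{i}", builder.chrom, a0, "+", [450, 400], [500], "candidate")
        fx.candidates_a.append(tx)
        fx.truth.elements.append(
            PlantedElement(
                kind="species_specific", id_a=tx.id, expected_fate=lf.KEPT,
                expected_ortholog="syntolog", expected_class=oe.INTERGENIC,
                expected_lca=sp_a,
            )
        )

    def plant_unliftable(builder, i: int):
        seq = _random_seq(1200, rng)
        a0, _ = builder.add_a_only(seq)
        tx = _make_transcript(f"unliftA_{i}", builder.chrom, a0, "+", [400, 350], [450], "candidate")
        fx.candidates_a.append(tx)
        fx.truth.elements.append(
            PlantedElement(
                kind="unliftable", id_a=tx.id, expected_fate=lf.KEPT,
                expected_ortholog=None, expected_class=oe.INTERGENIC,
                expected_lca=sp_a,
            )
        )

    def plant_pseudogene(builder, parent_key: str, i: int):
        info = b_gene_info[parent_key]
        tx_b: Transcript = info["tx_b"]
        # retrieve the B mRNA text lazily at the end; store a placeholder now
        pseudo_pending.append((builder, builder.apos, parent_key, i))
        # reserve space: the pseudogene sequence is exactly the B exonic length
        total = sum(e - s for s, e in info["b_exon_coords"])
        builder.add_a_only("N" * total)  # patched with real sequence below

    pseudo_pending: List[Tuple] = []

    def plant_divergent(builder, i: int):
        # '-' strand lncRNA whose first (rightmost, promoter-proximal) exon is
        # conserved while its distal exons turned over in B; a '+' strand
        # coding gene starts 200 bp to the right, sharing the promoter region
        lnc_a, lnc_b = plant_lnc_pair(
            builder, f"divA_{i}", f"divB_{i}",
            exon_lens=[350, 300, 400], intron_lens=[450, 500],
            strand="-",
            exon_subs={2: config.divergent_exon1_sub},
            replace_exons={0, 1},
        )
        builder.add_mutated(_random_seq(200, rng), config.genome_sub, 0, rng)
        exon_lens = [300, 300]
        exon_seqs = _coding_sequence(exon_lens, rng)
        g_a0 = g_b0 = None
        for k, es in enumerate(exon_seqs):
            a0, b0 = builder.add_mutated(es, config.coding_sub, 0, rng)
            if g_a0 is None:
                g_a0, g_b0 = a0, b0
            if k == 0:
                builder.add_mutated(_random_seq(400, rng), config.coding_sub, 0, rng)
        cod_a = _make_transcript(f"divcodA_{i}", builder.chrom, g_a0, "+", exon_lens, [400], "coding")
        cod_b = _make_transcript(
            f"divcodB_{i}", builder.chrom.replace("A", "B"), g_b0, "+", exon_lens, [400], "coding"
        )
        fx.coding_a.append(cod_a)
        fx.coding_b.append(cod_b)
        fx.truth.elements.append(
            PlantedElement(
                kind="divergent_linc", id_a=lnc_a.id, id_b=lnc_b.id,
                expected_fate=lf.KEPT, expected_ortholog=lnc_b.id,
                expected_class=oe.DIVERGENT, expected_lca="anc",
            )
        )

    def plant_conserved(builder, i: int, with_isoform: bool = False):
        lnc_a, lnc_b = plant_lnc_pair(
            builder, f"lincA_{i}", f"lincB_{i}",
            exon_lens=[400, 500, 300], intron_lens=[500, 700],
            strand="+", with_cpg=True,
        )
        fx.truth.elements.append(
            PlantedElement(
                kind="conserved_linc", id_a=lnc_a.id, id_b=lnc_b.id,
                expected_fate=lf.KEPT, expected_ortholog=lnc_b.id,
                expected_class=oe.INTERGENIC, expected_lca="anc",
                expected_identity=round(1 - config.lnc_exon_sub * 0.75, 3),
            )
        )
        if with_isoform:
            iso = _make_transcript(
                f"lincA_{i}_iso", builder.chrom, lnc_a.exons[1].start, "+",
                [len(lnc_a.exons[1]), len(lnc_a.exons[2])], [700], "candidate",
                gene_id=lnc_a.id,
            )
            fx.candidates_a.append(iso)
            fx.truth.elements.append(
                PlantedElement(kind="isoform", id_a=iso.id, expected_fate=lf.COLLAPSED)
            )

    def plant_host(builder, i: int, which: str):
        tid = "mirhost" if which == "mirna" else "snohost"
        lnc_a, lnc_b = plant_lnc_pair(
            builder, f"{tid}A_{i}", f"{tid}B_{i}",
            exon_lens=[350, 400], intron_lens=[600],
            strand="+", small_rna=which,
        )
        fx.truth.elements.append(
            PlantedElement(
                kind=f"{which}_host", id_a=lnc_a.id, id_b=lnc_b.id,
                expected_fate=lf.KEPT, expected_ortholog=lnc_b.id,
                expected_class=oe.MIRNA_HOST if which == "mirna" else oe.SNORNA_HOST,
                expected_lca="anc",
            )
        )

    def plant_single_exon(builder, i: int):
        seq = _random_seq(500, rng)
        a0, _ = builder.add_replaced(seq, rng)
        tx = _make_transcript(f"seA_{i}", builder.chrom, a0, "+", [500], [], "candidate")
        fx.candidates_a.append(tx)
        fx.truth.elements.append(
            PlantedElement(kind="single_exon", id_a=tx.id, expected_fate=lf.REMOVED_SINGLE_EXON)
        )

    # ---- layout -----------------------------------------------------------
    b1 = _ContigBuilder("chrA1")
    b2 = _ContigBuilder("chrA2")
    half_coding = config.n_coding // 2
    plan1 = []
    plan1.append(("coding", 0, {}))
    plan1.append(("pseudogene", 0, {"parent": "cod_0"}))
    plan1.append(("coding", 1, {"with_utr": True}))
    for i in range(2, half_coding):
        plan1.append(("coding", i, {}))
    for i in range((config.n_conserved_linc + 1) // 2):
        plan1.append(("conserved", i, {"with_isoform": i == 0}))
    plan1.append(("divergent", 0, {}))
    if config.n_mirna_host:
        plan1.append(("host", 0, {"which": "mirna"}))
    for i in range((config.dup_copies + 1) // 2):
        plan1.append(("dup", i, {}))
    if config.n_species_specific:
        plan1.append(("species_specific", 0, {}))
    plan1.append(("repeat", 0, {"family": "LINE_toy"}))
    plan1.append(("repeat", 1, {"family": "SINE_toy"}))

    plan2 = []
    for i in range(half_coding, config.n_coding):
        plan2.append(("coding", i, {}))
    for i in range((config.n_conserved_linc + 1) // 2, config.n_conserved_linc):
        plan2.append(("conserved", i, {}))
    if config.n_divergent > 1:
        plan2.append(("divergent", 1, {}))
    if config.n_snorna_host:
        plan2.append(("host", 0, {"which": "snorna"}))
    for i in range((config.dup_copies + 1) // 2, config.dup_copies):
        plan2.append(("dup", i, {}))
    for i in range(1, config.n_species_specific):
        plan2.append(("species_specific", i, {}))
    for i in range(config.n_unliftable):
        plan2.append(("unliftable", i, {}))
    for i in range(config.n_single_exon):
        plan2.append(("single_exon", i, {}))
    plan2.append(("repeat", 2, {"family": "LINE_toy"}))

    dispatch = {
        "coding": lambda b, i, kw: plant_coding(b, i, **kw),
        "pseudogene": lambda b, i, kw: plant_pseudogene(b, kw["parent"], i),
        "conserved": lambda b, i, kw: plant_conserved(b, i, **kw),
        "divergent": lambda b, i, kw: plant_divergent(b, i),
        "host": lambda b, i, kw: plant_host(b, i, kw["which"]),
        "dup": lambda b, i, kw: plant_dup_copy(b, i),
        "species_specific": lambda b, i, kw: plant_species_specific(b, i),
        "unliftable": lambda b, i, kw: plant_unliftable(b, i),
        "single_exon": lambda b, i, kw: plant_single_exon(b, i),
        "repeat": lambda b, i, kw: plant_repeat(b, kw["family"]),
    }
    for builder, plan in ((b1, plan1), (b2, plan2)):
        spacer(builder)
        for kind, i, kw in plan:
            dispatch[kind](builder, i, kw)
            spacer(builder)

    a1, bb1 = b1.finish()
    a2, bb2 = b2.finish()

    # ---- patch pseudogenes with real sequence and emit their chains -------
    genome_a_parts = {"chrA1": list(a1), "chrA2": list(a2)}
    genome_b_seqs = {"chrB1": bb1, "chrB2": bb2}
    for builder, a_off, parent_key, i in pseudo_pending:
        info = b_gene_info[parent_key]
        chrom_b = info["tx_b"].chrom
        b_seq = genome_b_seqs[chrom_b]
        exon_seqs = [b_seq[s:e] for s, e in info["b_exon_coords"]]
        mrna = "".join(exon_seqs)
        m = mutate_sequence(mrna, config.pseudogene_sub, 0, rng)
        chars = genome_a_parts[builder.chrom]
        chars[a_off : a_off + len(mrna)] = list(m.seq)
        tx = _make_transcript(
            f"pseudoA_{i}", builder.chrom, a_off, info["tx_b"].strand,
            [len(exon_seqs[0]), len(mrna) - len(exon_seqs[0])], [0], "candidate",
        )
        fx.candidates_a.append(tx)
        fx.truth.elements.append(
            PlantedElement(kind="processed_pseudogene", id_a=tx.id,
                           expected_fate=lf.REMOVED_SYNTENIC)
        )
        blocks = []
        coords = info["b_exon_coords"]
        for k, (s, e) in enumerate(coords):
            if k < len(coords) - 1:
                gap_q = coords[k + 1][0] - e
                blocks.append((e - s, 0, gap_q))
            else:
                blocks.append((e - s, 0, 0))
        ch = Chain(
            score=len(mrna),
            t_name=builder.chrom,
            t_size=len(chars),
            t_strand="+",
            t_start=a_off,
            t_end=a_off + len(mrna),
            q_name=chrom_b,
            q_size=len(b_seq),
            q_strand="+",
            q_start=coords[0][0],
            q_end=coords[-1][1],
            chain_id=f"pseudo_{i}",
        )
        ch.blocks = blocks
        ch.validate()
        extra_chains.append(ch)

    fx.genome_a = GenomeSequence(
        {name: "".join(chars) for name, chars in genome_a_parts.items()}
    )
    fx.genome_b = GenomeSequence(genome_b_seqs)
    fx.chains = ChainSet(
        [b1.chain("chrB1", "c1"), b2.chain("chrB2", "c2")] + extra_chains
    )
    return fx


def write_fixture(fx: GenomePairFixture, out_dir) -> None:
    """Serialize a fixture to plain-text files (the layout RunConfig
    .from_fixture_dir expects)."""
    from pathlib import Path

    from .genomic_io import write_bed6, write_bed12, write_chain, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genomeA.fa", "w") as fh:
        write_fasta(fx.genome_a, fh)
    with open(out / "genomeB.fa", "w") as fh:
        write_fasta(fx.genome_b, fh)
    with open(out / "chains.chain", "w") as fh:
        write_chain(fx.chains, fh)
    for name, txs in (
        ("candidates_a", fx.candidates_a),
        ("lnc_b", fx.lnc_b),
        ("coding_a", fx.coding_a),
        ("coding_b", fx.coding_b),
    ):
        with open(out / f"{name}.bed", "w") as fh:
            write_bed12(txs, fh)
    for name, recs in (
        ("mirna_a", fx.mirna_a),
        ("mirna_b", fx.mirna_b),
        ("snorna_a", fx.snorna_a),
        ("snorna_b", fx.snorna_b),
        ("repeats_a", fx.repeats_a),
        ("cpg_a", fx.cpg_a),
    ):
        with open(out / f"{name}.bed", "w") as fh:
            write_bed6(recs, fh)
    with open(out / "panels.fa", "w") as fh:
        for name in sorted(fx.known_panels):
            fh.write(f">{name}\n{fx.known_panels[name]}\n")
    (out / "tree.nwk").write_text(fx.tree_newick + "\n")
    (out / "truth.json").write_text(fx.truth.to_json() + "\n")
    rows = ["\t".join(["kind", "id_a", "id_b", "fate", "ortholog", "class", "lca"])]
    for e in fx.truth.elements:
        rows.append(
            "\t".join(
                str(x) if x is not None else "NA"
                for x in (e.kind, e.id_a, e.id_b, e.expected_fate,
                          e.expected_ortholog, e.expected_class, e.expected_lca)
            )
        )
    (out / "truth.tsv").write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# dedicated promoter-enrichment fixture


def plant_promoter_set(
    rng_seed=None,
    n_promoters: int = 40,
    frac_with_repeat: float = 0.3,
    promoter_length: int = 500,
    genome_length: int = 400_000,
    background_density: float = 0.08,
):
    """A single-contig genome with `n_promoters` promoter intervals, a planted
    ERVK-like family present in frac_with_repeat of them (and nowhere else),
    and two neutral families (LINE/SINE) scattered uniformly so they appear at
    matched rates in promoters and background.

    Returns (genome, promoters, repeat_bed, blocked) where promoters is a list
    of (id, interval) pairs and blocked the spans excluded from background
    sampling.
    """
    rng = as_rng(rng_seed)
    seq = list(_random_seq(genome_length, rng))
    chrom = "chrP"
    spacing = genome_length // (n_promoters + 2)
    promoters = []
    repeat_bed = []
    n_with = int(round(n_promoters * frac_with_repeat))
    ervk = _random_seq(200, rng)
    for i in range(n_promoters):
        start = spacing * (i + 1) + int(rng.integers(0, spacing // 4))
        iv = GenomicInterval(chrom, start, start + promoter_length, "+")
        promoters.append((f"prom_{i}", iv))
        if i < n_with:
            off = int(rng.integers(0, promoter_length - 200))
            seq[start + off : start + off + 200] = list(ervk)
            repeat_bed.append(
                (GenomicInterval(chrom, start + off, start + off + 200), "ERVK_toy")
            )
    for fam, count in (("LINE_toy", 60), ("SINE_toy", 60)):
        for _ in range(count):
            s = int(rng.integers(0, genome_length - 150))
            repeat_bed.append((GenomicInterval(chrom, s, s + 150), fam))
    genome = GenomeSequence({chrom: "".join(seq)})
    blocked = [iv for _, iv in promoters]
    return genome, promoters, repeat_bed, blocked
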