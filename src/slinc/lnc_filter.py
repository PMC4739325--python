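"""The stringent three-step filter that turns candidate transcripts into a
high-confidence lncRNA set:

1. remove candidates with any same-strand exonic overlap of an annotated
   (or mapped) coding gene;
2. collapse exon-overlapping candidates to one canonical isoform, then remove
   duplication clusters -- groups of putative lncRNAs sharing significant
   mutual homology (lineage-specific gene-family expansions such as zinc
   fingers or olfactory genes), with homology judged against each
   transcript's own shuffled-intergenic score null;
3. remove candidates that align to a syntenic coding gene in the comparing
   species better than a threshold learned from the step-1 positives (this
   catches pseudogenes and UTR/intronic fragments even when the alignment is
   entirely non-exonic in the coding gene).

Single-exon candidates are quarantined to a side list; only conserved ones
are worth keeping, which the orthology stage decides.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from intervaltree import IntervalTree

from .aligner import (
    IntergenicSampler,
    ScoringScheme,
    as_rng,
    best_local_score,
    local_align,
)
from .genomic_io import ChainSet, GenomeSequence, Transcript, reverse_complement
from .synteny import lift_transcript

__all__ = [
    "DuplicationCluster",
    "CodingFilterModel",
    "FilterReport",
    "FilterConfig",
    "remove_coding_overlap",
    "select_canonical_isoforms",
    "find_duplication_clusters",
    "learn_coding_identity_threshold",
    "filter_syntenic_coding",
    "run_filter_pipeline",
]

KEPT = "kept"
REMOVED_CODING = "removed_coding_overlap"
COLLAPSED = "collapsed_isoform"
REMOVED_DUP = "removed_duplication"
REMOVED_SYNTENIC = "removed_syntenic_coding"
REMOVED_SINGLE_EXON = "removed_single_exon"
FATES = (KEPT, REMOVED_CODING, COLLAPSED, REMOVED_DUP, REMOVED_SYNTENIC, REMOVED_SINGLE_EXON)


@dataclass
class DuplicationCluster:
    members: Tuple[str, ...]
    known_family_hits: List[Tuple[str, str]] = field(default_factory=list)


@dataclass
class CodingFilterModel:
    """Exonic-identity scores of known coding transcripts aligned to their
    syntenic coding genes; the removal threshold is the empirical 5th
    percentile (P = 0.05 for a true coding alignment to fall below it)."""

    positive_scores: List[float]
    threshold: float
    n_positive: int

    @classmethod
    def from_scores(cls, scores: Sequence[float]) -> "CodingFilterModel":
        scores = sorted(float(s) for s in scores)
        if len(scores) < 10:
            raise ValueError(
                f"only {len(scores)} positive alignments; supply an explicit "
                "identity threshold instead"
            )
        thr = float(np.quantile(scores, 0.05, method="lower"))
        return cls(positive_scores=scores, threshold=thr, n_positive=len(scores))


@dataclass
class FilterReport:
    fates: Dict[str, str]
    clusters: List[DuplicationCluster] = field(default_factory=list)
    model: Optional[CodingFilterModel] = None
    isoform_clusters: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def counts(self) -> Counter:
        c = Counter(self.fates.values())
        for f in FATES:
            c.setdefault(f, 0)
        return c


def _exon_tree(txs: Sequence[Transcript], stranded: bool = True) -> Dict:
    trees: Dict = {}
    for tx in txs:
        for e in tx.exons:
            key = (e.chrom, e.strand if stranded else ".")
            trees.setdefault(key, IntervalTree()).addi(e.start, e.end, tx.id)
    return trees


def remove_coding_overlap(
    candidates: Sequence[Transcript],
    coding: Sequence[Transcript],
    mode: str = "exon",
) -> Tuple[List[Transcript], List[Transcript]]:
    """Remove candidates overlapping coding genes on the same strand in any
    amount. mode='exon' requires exon-exon overlap (keeps intronic antisense
    lncRNAs); mode='span' uses whole gene spans."""
    if mode == "exon":
        trees = _exon_tree(coding)
    elif mode == "span":
        trees = {}
        for tx in coding:
            key = (tx.chrom, tx.strand)
            trees.setdefault(key, IntervalTree()).addi(tx.start, tx.end, tx.id)
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    kept, removed = [], []
    for tx in candidates:
        hit = any(
            trees.get((tx.chrom, tx.strand), IntervalTree()).overlap(e.start, e.end)
            for e in tx.exons
        )
        (removed if hit else kept).append(tx)
    return kept, removed


def select_canonical_isoforms(
    transcripts: Sequence[Transcript],
) -> Tuple[List[Transcript], Dict[str, List[str]]]:
    """Cluster transcripts by any same-strand exonic overlap (transitively)
    and keep one canonical isoform per cluster: greatest exonic length, ties
    by genomic span then id."""
    by_id = {tx.id: tx for tx in transcripts}
    g = nx.Graph()
    g.add_nodes_from(by_id)
    trees = _exon_tree(transcripts)
    for tx in transcripts:
        for e in tx.exons:
            for hit in trees.get((tx.chrom, tx.strand), IntervalTree()).overlap(
                e.start, e.end
            ):
                if hit.data != tx.id:
                    g.add_edge(tx.id, hit.data)
    canonical, cluster_map = [], {}
    for comp in nx.connected_components(g):
        members = sorted(comp)
        # longest exonic length, then longest span, then smallest id
        ranked = sorted(
            members,
            key=lambda i: (-by_id[i].exonic_length, -by_id[i].span_length, i),
        )
        best = ranked[0]
        canonical.append(by_id[best])
        cluster_map[best] = members
    canonical.sort(key=lambda t: (t.chrom, t.start, t.id))
    return canonical, cluster_map


def find_duplication_clusters(
    candidates: Sequence[Transcript],
    genome: GenomeSequence,
    annotations: Sequence,
    scoring: ScoringScheme = ScoringScheme(),
    n_null: int = 200,
    alpha: float = 0.05,
    min_cluster_size: int = 2,
    known_panels: Optional[Dict[str, str]] = None,
    rng_seed=None,
    sampler: Optional[IntergenicSampler] = None,
    min_score: int = 200,
) -> Tuple[List[Transcript], List[DuplicationCluster]]:
    """All-vs-all alignment of candidate exonic sequences; pairs significant
    against BOTH transcripts' shuffled-intergenic nulls are merged
    transitively, and clusters of >= min_cluster_size are removed. Members
    are also checked against the known gene-family panels (ZFP/olfactory) and
    hits reported on the cluster.

    min_score plays the role of the delegated aligner's minimum reportable
    HSP score: a bare shared seed between unrelated transcripts is not an
    alignment worth testing, and without this floor transitive merging would
    chain unrelated transcripts at the per-pair false-positive rate."""
    rng = as_rng(rng_seed)
    if sampler is None:
        sampler = IntergenicSampler(genome, annotations)
    seqs = {tx.id: genome.spliced(tx) for tx in candidates}
    ids = sorted(seqs)
    # per-transcript null score distribution (length-matched draws)
    null_scores: Dict[str, List[int]] = {}
    for tid in ids:
        null_scores[tid] = sorted(
            best_local_score(seqs[tid], sampler.sample_seq(len(seqs[tid]), rng), scoring)
            for _ in range(n_null)
        )

    def p_vs_null(tid: str, score: int) -> float:
        nulls = null_scores[tid]
        ge = len(nulls) - int(np.searchsorted(nulls, score, side="left"))
        return (1 + ge) / (len(nulls) + 1)

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, ta in enumerate(ids):
        for tb in ids[i + 1 :]:
            s = best_local_score(seqs[ta], seqs[tb], scoring)
            if s < min_score:
                continue
            if p_vs_null(ta, s) <= alpha and p_vs_null(tb, s) <= alpha:
                g.add_edge(ta, tb)
    clusters: List[DuplicationCluster] = []
    removed_ids = set()
    for comp in nx.connected_components(g):
        if len(comp) >= min_cluster_size and len(comp) >= 2:
            members = tuple(sorted(comp))
            hits = []
            if known_panels:
                for member in members:
                    for panel_gene, pseq in sorted(known_panels.items()):
                        s = best_local_score(seqs[member], pseq, scoring)
                        if s >= min_score and p_vs_null(member, s) <= alpha:
                            hits.append((member, panel_gene))
            clusters.append(DuplicationCluster(members=members, known_family_hits=hits))
            removed_ids |= set(members)
    kept = [tx for tx in candidates if tx.id not in removed_ids]
    clusters.sort(key=lambda c: c.members)
    return kept, clusters


def _best_syntenic_coding_identity(
    tx: Transcript,
    other_coding: Sequence[Transcript],
    chains: ChainSet,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    scoring: ScoringScheme,
    slack: int = 2000,
    min_match: float = 0.1,
) -> Optional[float]:
    """Identity of the candidate's spliced sequence against the full pre-mRNA
    span (UTRs and introns included) of coding genes at its syntenic locus;
    None when the transcript does not lift."""
    lift = lift_transcript(chains, tx, min_match=min_match)
    span = lift.span
    if span is None:
        return None
    region = span.padded(slack, contig_length=genome_b.contig_length(span.chrom))
    qseq = genome_a.spliced(tx)
    best = 0.0
    for c in other_coding:
        if c.chrom != region.chrom or not c.interval.overlaps(region):
            continue
        tseq = genome_b.fetch(c.interval)
        # the spliced query is 5'->3'; try both orientations of the gene span
        for t in (tseq, reverse_complement(tseq)):
            alns = local_align(qseq, t, scoring)
            if alns:
                best = max(best, alns[0].identity)
    return best


def learn_coding_identity_threshold(
    removed_coding_overlaps: Sequence[Transcript],
    other_species_coding: Sequence[Transcript],
    chains: ChainSet,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    scoring: ScoringScheme = ScoringScheme(),
    cap: int = 250,
    rng_seed=None,
) -> CodingFilterModel:
    """Learn the syntenic-coding identity threshold from transcripts known to
    overlap coding genes (the step-1 removals): align each to its syntenic
    coding gene and take the 5th percentile of the identities. At most `cap`
    positives are used (random subset when more are available)."""
    rng = as_rng(rng_seed)
    positives = sorted(removed_coding_overlaps, key=lambda t: t.id)
    if len(positives) > cap:
        idx = rng.choice(len(positives), size=cap, replace=False)
        positives = [positives[i] for i in sorted(idx)]
    scores = []
    for tx in positives:
        ident = _best_syntenic_coding_identity(
            tx, other_species_coding, chains, genome_a, genome_b, scoring
        )
        if ident is not None and ident > 0:
            scores.append(ident)
    return CodingFilterModel.from_scores(scores)


def filter_syntenic_coding(
    candidates: Sequence[Transcript],
    model: CodingFilterModel,
    other_species_coding: Sequence[Transcript],
    chains: ChainSet,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    scoring: ScoringScheme = ScoringScheme(),
) -> Tuple[List[Transcript], List[Transcript]]:
    """Remove candidates whose best alignment identity to any syntenic coding
    transcript exceeds the learned threshold -- even when the alignment falls
    entirely in UTR or intronic regions of the coding gene."""
    kept, removed = [], []
    for tx in candidates:
        ident = _best_syntenic_coding_identity(
            tx, other_species_coding, chains, genome_a, genome_b, scoring
        )
        if ident is not None and ident > model.threshold:
            removed.append(tx)
        else:
            kept.append(tx)
    return kept, removed


@dataclass
class FilterConfig:
    genome_a: GenomeSequence
    coding_a: Sequence[Transcript]  # annotated + mapped-coding, merged
    genome_b: Optional[GenomeSequence] = None
    coding_b: Optional[Sequence[Transcript]] = None
    chains: Optional[ChainSet] = None
    scoring: ScoringScheme = ScoringScheme()
    n_null: int = 200
    alpha: float = 0.05
    min_cluster_size: int = 2
    cap: int = 250
    dup_min_score: int = 200
    overlap_mode: str = "exon"
    enable_syntenic: bool = True
    identity_threshold: Optional[float] = None
    known_panels: Optional[Dict[str, str]] = None
    seed: int = 1


def run_filter_pipeline(
    candidates: Sequence[Transcript], config: FilterConfig
) -> Tuple[List[Transcript], FilterReport, List[Transcript]]:
    """Compose the filter stages in order. Returns (kept lncRNAs, report,
    quarantined single-exon candidates). Fates partition the input."""
    fates: Dict[str, str] = {}
    report = FilterReport(fates=fates)
    rng = as_rng(config.seed)

    multi = []
    single_exon = []
    for tx in candidates:
        if tx.n_exons < 2:
            fates[tx.id] = REMOVED_SINGLE_EXON
            single_exon.append(tx)
        else:
            multi.append(tx)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # annotate the failing stage
            raise RuntimeError(f"filter stage {name!r} failed: {exc}") from exc

    kept, removed_coding = stage(
        "coding_overlap", remove_coding_overlap, multi, config.coding_a,
        config.overlap_mode,
    )
    for tx in removed_coding:
        fates[tx.id] = REMOVED_CODING

    canonical, cluster_map = stage("canonical_isoforms", select_canonical_isoforms, kept)
    report.isoform_clusters = cluster_map
    canonical_ids = {t.id for t in canonical}
    for tx in kept:
        if tx.id not in canonical_ids:
            fates[tx.id] = COLLAPSED

    null_annotations = list(config.coding_a) + list(candidates)
    kept2, clusters = stage(
        "duplication_clusters",
        find_duplication_clusters,
        canonical,
        config.genome_a,
        null_annotations,
        config.scoring,
        config.n_null,
        config.alpha,
        config.min_cluster_size,
        config.known_panels,
        rng,
        min_score=config.dup_min_score,
    )
    report.clusters = clusters
    kept2_ids = {t.id for t in kept2}
    for tx in canonical:
        if tx.id not in kept2_ids:
            fates[tx.id] = REMOVED_DUP

    if config.enable_syntenic:
        if config.identity_threshold is not None:
            model = CodingFilterModel(
                positive_scores=[], threshold=config.identity_threshold, n_positive=0
            )
        else:
            model = stage(
                "learn_threshold",
                learn_coding_identity_threshold,
                removed_coding,
                config.coding_b or [],
                config.chains,
                config.genome_a,
                config.genome_b,
                config.scoring,
                config.cap,
                rng,
            )
        report.model = model
        kept3, removed_syntenic = stage(
            "syntenic_coding",
            filter_syntenic_coding,
            kept2,
            model,
            config.coding_b or [],
            config.chains,
            config.genome_a,
            config.genome_b,
            config.scoring,
        )
        for tx in removed_syntenic:
            fates[tx.id] = REMOVED_SYNTENIC
    else:
        kept3 = kept2
    for tx in kept3:
        fates[tx.id] = KEPT
    assert len(fates) == len(candidates), "fates must partition the input"
    return kept3, report, single_exon
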