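"""End-to-end orchestration: filter -> orf -> ortho -> phylo -> promoter,
with a JSON run manifest and byte-deterministic outputs under a fixed seed."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .aligner import IntergenicSampler, ScoringScheme, as_rng
from .genomic_io import (
    read_bed6,
    read_bed12,
    read_chain,
    read_fasta,
    write_bed12,
)
from .lnc_filter import FilterConfig, run_filter_pipeline
from .orf_dnds import build_dnds_null, enumerate_aligned_orfs, orf_significance
from .ortho_evo import (
    canonical_pair_per_gene,
    classify_pair,
    evo_metrics,
    find_candidate_ortholog,
    fit_tti_mixture,
    reciprocal_orthologs,
)
from .phylo_lca import SpeciesTree, fitch_lca, link_ortholog_groups
from .promoters import (
    annotate_promoters,
    promoter_interval,
    repeat_enrichment,
    sample_matched_background,
)
from .aligner import local_align

__all__ = ["RunConfig", "run_all"]

STAGES = ("filter", "orf", "ortho", "phylo", "promoter")


@dataclass
class RunConfig:
    """All paths and stage parameters of a full run. Parameters default to
    the pipeline's standard values (null size 200, alpha 0.05, positive cap
    250, min ORF 33 nt, window pad 150 kb, reduced lncRNA gap (25,40),
    liftover min-match 0.1, junction tolerance 2 bp, promoter flank 500 bp,
    enrichment alpha 0.005)."""

    genome_a: str
    genome_b: str
    candidates_a: str
    chains: str
    out_dir: str
    lnc_b: Optional[str] = None
    coding_a: Optional[str] = None
    coding_b: Optional[str] = None
    tree: Optional[str] = None
    mirna_a: Optional[str] = None
    mirna_b: Optional[str] = None
    snorna_a: Optional[str] = None
    snorna_b: Optional[str] = None
    repeats_a: Optional[str] = None
    cpg_a: Optional[str] = None
    species: tuple = ("spA", "spB")
    pad: int = 150_000
    n_null: int = 200
    alpha: float = 0.05
    min_cluster_size: int = 2
    cap: int = 250
    dup_min_score: int = 200
    min_orf: int = 33
    n_null_regions: int = 2000
    min_match: float = 0.1
    ssc_tol: int = 2
    flank: int = 500
    enrichment_alpha: float = 0.005
    gap_open: int = 25
    gap_extend: int = 40
    seed: int = 1
    skip: tuple = ()

    @classmethod
    def from_fixture_dir(cls, fixture_dir: str, out_dir: str, **overrides) -> "RunConfig":
        d = Path(fixture_dir)
        kw = dict(
            genome_a=str(d / "genomeA.fa"),
            genome_b=str(d / "genomeB.fa"),
            candidates_a=str(d / "candidates_a.bed"),
            chains=str(d / "chains.chain"),
            lnc_b=str(d / "lnc_b.bed"),
            coding_a=str(d / "coding_a.bed"),
            coding_b=str(d / "coding_b.bed"),
            tree=str(d / "tree.nwk"),
            mirna_a=str(d / "mirna_a.bed"),
            mirna_b=str(d / "mirna_b.bed"),
            snorna_a=str(d / "snorna_a.bed"),
            snorna_b=str(d / "snorna_b.bed"),
            repeats_a=str(d / "repeats_a.bed"),
            cpg_a=str(d / "cpg_a.bed"),
            out_dir=out_dir,
        )
        kw.update(overrides)
        return cls(**kw)

    def validate(self) -> None:
        required = ["genome_a", "genome_b", "candidates_a", "chains"]
        for name in required:
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"config: missing required input {name}={p!r}")
        for name in ("lnc_b", "coding_a", "coding_b", "tree", "mirna_a", "mirna_b",
                     "snorna_a", "snorna_b", "repeats_a", "cpg_a"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config: input {name}={p!r} does not exist")
        for stage in self.skip:
            if stage not in STAGES:
                raise ValueError(f"config: unknown stage to skip {stage!r}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _read_optional_bed6(path: Optional[str]) -> list:
    if path is None:
        return []
    with open(path) as fh:
        return read_bed6(fh)


def _read_optional_bed12(path: Optional[str]) -> list:
    if path is None:
        return []
    with open(path) as fh:
        return read_bed12(fh)


def run_all(config: RunConfig) -> Path:
    """Run all stages in order, writing versioned TSV/BED outputs plus a JSON
    manifest. Identical config and seed produce byte-identical outputs. A
    stage failure aborts with the stage name; earlier outputs are retained."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = as_rng(config.seed)
    manifest: Dict = {
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("out_dir",) and not isinstance(v, (list,))
        },
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    for name in ("genome_a", "genome_b", "candidates_a", "chains", "lnc_b",
                 "coding_a", "coding_b", "tree", "mirna_a", "mirna_b",
                 "snorna_a", "snorna_b", "repeats_a", "cpg_a"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = _sha256(p)

    with open(config.genome_a) as fh:
        genome_a = read_fasta(fh)
    with open(config.genome_b) as fh:
        genome_b = read_fasta(fh)
    candidates = _read_optional_bed12(config.candidates_a)
    lnc_b = _read_optional_bed12(config.lnc_b)
    coding_a = _read_optional_bed12(config.coding_a)
    coding_b = _read_optional_bed12(config.coding_b)
    with open(config.chains) as fh:
        chains = read_chain(fh)
    mirna_a = _read_optional_bed6(config.mirna_a)
    mirna_b = _read_optional_bed6(config.mirna_b)
    snorna_a = _read_optional_bed6(config.snorna_a)
    snorna_b = _read_optional_bed6(config.snorna_b)
    repeats_a = _read_optional_bed6(config.repeats_a)
    cpg_a = _read_optional_bed6(config.cpg_a)

    scoring_default = ScoringScheme()
    scoring_lnc = ScoringScheme(gap_open=config.gap_open, gap_extend=config.gap_extend)

    def emit(name: str):
        manifest["outputs"].append(name)

    def run_stage(name, fn):
        if name in config.skip:
            manifest["stages"][name] = "skipped"
            return None
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = f"failed: {exc}"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = "done"
        return result

    state: Dict = {}

    # ---- filter ----------------------------------------------------------
    def stage_filter():
        fcfg = FilterConfig(
            genome_a=genome_a, coding_a=coding_a, genome_b=genome_b,
            coding_b=coding_b, chains=chains, scoring=scoring_default,
            n_null=config.n_null, alpha=config.alpha,
            min_cluster_size=config.min_cluster_size, cap=config.cap,
            dup_min_score=config.dup_min_score,
            seed=int(rng.integers(2**31)),
        )
        kept, report, single = run_filter_pipeline(candidates, fcfg)
        with open(out / "lncrnas.bed", "w") as fh:
            write_bed12(kept, fh)
        emit("lncrnas.bed")
        rows = sorted(report.fates.items())
        _write_tsv(out / "filter_fates.tsv", ["transcript_id", "fate"], rows)
        emit("filter_fates.tsv")
        counts = report.counts
        _write_tsv(
            out / "filter_report.tsv", ["fate", "count"],
            sorted(counts.items()),
        )
        emit("filter_report.tsv")
        state["kept"] = kept
        state["report"] = report
        state["single_exon"] = single
        return kept

    run_stage("filter", stage_filter)
    kept = state.get("kept", candidates)

    # ---- ortho -----------------------------------------------------------
    def stage_ortho():
        sampler_b = IntergenicSampler(genome_b, list(coding_b) + list(lnc_b))
        sampler_a = IntergenicSampler(genome_a, list(coding_a) + list(candidates))
        inv = chains.inverted()
        pairs_ab, pairs_ba = [], []
        for tx in sorted(kept, key=lambda t: t.id):
            p = find_candidate_ortholog(
                tx, genome_a, genome_b, lnc_b, chains, scoring_lnc,
                pad=config.pad, n_null=config.n_null, alpha=config.alpha,
                min_match=config.min_match, rng_seed=rng, sampler_b=sampler_b,
                species=config.species,
            )
            if p:
                pairs_ab.append(p)
        for tx in sorted(lnc_b, key=lambda t: t.id):
            p = find_candidate_ortholog(
                tx, genome_b, genome_a, kept, inv, scoring_lnc,
                pad=config.pad, n_null=config.n_null, alpha=config.alpha,
                min_match=config.min_match, rng_seed=rng, sampler_b=sampler_a,
                species=(config.species[1], config.species[0]),
            )
            if p:
                pairs_ba.append(p)
        confirmed = reciprocal_orthologs(pairs_ab, pairs_ba)
        annots_a = {"mirna": mirna_a, "snorna": snorna_a, "coding": coding_a}
        annots_b = {"mirna": mirna_b, "snorna": snorna_b, "coding": coding_b}
        rows = []
        for p in confirmed:
            m = evo_metrics(p, genome_a, genome_b, scoring_lnc, ssc_tol=config.ssc_tol)
            cls = classify_pair(p, annots_a, annots_b)
            p.lnc_class = cls
            rows.append(
                [p.query.id, p.target.id, cls, p.significance.empirical_p,
                 m.tgi, m.tti, m.ssc, m.idr, m.conserved_junctions,
                 m.n_junctions, m.exonic_indel_events, m.intronic_indel_events]
            )
        canonical = canonical_pair_per_gene(confirmed)
        syntologs = [p for p in pairs_ab if p.target is None]
        _write_tsv(
            out / "orthologs.tsv",
            ["query", "target", "class", "p", "tgi", "tti", "ssc", "idr",
             "conserved_junctions", "n_junctions", "exonic_indels", "intronic_indels"],
            sorted(rows),
        )
        emit("orthologs.tsv")
        _write_tsv(
            out / "syntologs.tsv", ["query", "transcript_aligned"],
            sorted([p.query.id, int(p.transcript_aligned)] for p in syntologs),
        )
        emit("syntologs.tsv")
        with open(out / "orthologs_a.bed", "w") as fh:
            write_bed12([p.query for p in confirmed], fh)
        emit("orthologs_a.bed")
        state["pairs"] = confirmed
        state["canonical_pairs"] = canonical
        state["syntologs"] = syntologs
        ttis = [p.metrics.tti for p in canonical if p.metrics]
        if len(ttis) >= 10:
            fit = fit_tti_mixture(ttis, rng_seed=rng)
            order = np.argsort(fit.means)
            _write_tsv(
                out / "tti_mixture.tsv",
                ["component", "weight", "mean", "sd"],
                [
                    [i, fit.weights[j], fit.means[j], fit.sds[j]]
                    for i, j in enumerate(order)
                ],
            )
            emit("tti_mixture.tsv")
        return confirmed

    run_stage("ortho", stage_ortho)
    pairs = state.get("pairs", [])

    # ---- orf -------------------------------------------------------------
    def stage_orf():
        null = build_dnds_null(
            genome_a, genome_b, chains, list(coding_a) + list(candidates),
            scoring_lnc, n_regions=config.n_null_regions,
            min_len=config.min_orf, rng_seed=rng,
        )
        hits = []
        for p in pairs:
            sa = genome_a.spliced(p.query)
            sb = genome_b.spliced(p.target)
            for aln in local_align(sa, sb, scoring_lnc):
                hits.extend(
                    enumerate_aligned_orfs(
                        aln, sa, sb, min_len=config.min_orf, transcript_id=p.query.id
                    )
                )
        orf_significance(hits, null, alpha=config.alpha)
        _write_tsv(
            out / "orf_hits.tsv",
            ["transcript_id", "q_start", "length_nt", "dn", "ds", "ratio",
             "p", "q", "fallback", "flagged_coding"],
            sorted(
                [h.transcript_id, h.q_start, h.length_nt, h.dnds.dn, h.dnds.ds,
                 h.ratio, h.p_empirical, h.q_value, int(h.used_fallback),
                 int(h.flagged_coding)]
                for h in hits
            ),
        )
        emit("orf_hits.tsv")
        state["orf_hits"] = hits
        return hits

    run_stage("orf", stage_orf)

    # ---- phylo -----------------------------------------------------------
    def stage_phylo():
        if config.tree is None:
            tree = SpeciesTree(f"({config.species[0]},{config.species[1]})anc;")
        else:
            tree = SpeciesTree(Path(config.tree).read_text())
        sp_a, sp_b = config.species
        links = [((sp_a, p.query.id), (sp_b, p.target.id)) for p in pairs]
        groups = link_ortholog_groups(links)
        grouped_a = {m[1] for g in groups for m in g if m[0] == sp_a}
        for tx in kept:
            if tx.id not in grouped_a:
                groups.append(frozenset({(sp_a, tx.id)}))
        rows = []
        for gi, g in enumerate(sorted(groups, key=lambda g: sorted(map(str, g)))):
            profile = {leaf: False for leaf in tree.leaf_names()}
            for sp, _ in g:
                profile[sp] = True
            res = fitch_lca(tree, profile)
            members = ";".join(f"{sp}:{tid}" for sp, tid in sorted(g))
            rows.append([gi, members, res.node, int(res.tie_broken)])
        _write_tsv(
            out / "ortholog_groups.tsv",
            ["group", "members", "lca", "tie_broken"], rows,
        )
        emit("ortholog_groups.tsv")
        return rows

    run_stage("phylo", stage_phylo)

    # ---- promoter --------------------------------------------------------
    def stage_promoter():
        proms = []
        for tx in sorted(kept, key=lambda t: t.id):
            iv = promoter_interval(tx, flank=config.flank)
            if iv is not None and iv.end <= genome_a.contig_length(iv.chrom):
                proms.append((tx.id, iv))
        records = annotate_promoters(proms, cpg_a, repeats_a, genome_a)
        _write_tsv(
            out / "promoters.tsv",
            ["transcript_id", "chrom", "start", "end", "gc", "has_cpg",
             "repeat_bp", "repeat_fraction"],
            [
                [r.transcript_id, r.interval.chrom, r.interval.start,
                 r.interval.end, r.gc_fraction, int(r.has_cpg), r.repeat_bp,
                 r.repeat_fraction]
                for r in records
            ],
        )
        emit("promoters.tsv")
        if records and repeats_a:
            blocked = list(coding_a) + list(candidates)
            background = sample_matched_background(
                records, genome_a, blocked, rng_seed=rng, on_unmatched="skip"
            )
            enr = repeat_enrichment(
                records, background, repeats_a, alpha=config.enrichment_alpha
            )
            _write_tsv(
                out / "repeat_enrichment.tsv",
                ["family", "prom_with", "prom_without", "bg_with", "bg_without",
                 "odds_ratio", "p", "p_corrected", "significant"],
                [
                    [e.family, e.promoters_with, e.promoters_without,
                     e.background_with, e.background_without, e.odds_ratio,
                     e.p, e.p_corrected, int(e.significant)]
                    for e in enr
                ],
            )
            emit("repeat_enrichment.tsv")
        return records

    run_stage("promoter", stage_promoter)

    manifest["outputs"] = sorted(set(manifest["outputs"]))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
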