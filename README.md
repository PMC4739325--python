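# slinc

Stringent lncRNA identification and evolutionary analysis for two-genome
comparisons.

Transcriptome reconstruction yields thousands of putative long non-coding
RNAs (lncRNAs), heavily contaminated by UTR fragments, pseudogenes, and
poorly annotated members of species-specific coding-gene family expansions
(zinc fingers, olfactory genes) — while coding-potential scores based on
evolutionary signatures wrongly discard *bona fide* conserved lncRNAs such
as the well-known nuclear regulators. `slinc` is for comparative genomicists
and annotation builders who need (1) a high-confidence lncRNA set derived
without coding-potential models, and (2) evolutionary evidence to
prioritize those lncRNAs for experiments.

## What it computes

**Filter** (three steps): remove candidates with any same-strand exonic
overlap of coding genes; collapse isoforms and remove *duplication
clusters* — groups of candidates sharing significant mutual homology
versus each transcript's shuffled-intergenic score null (empirical
P ≤ 0.05, 200 shuffles); remove candidates aligning to a *syntenic coding
gene* in a second species above an identity threshold learned from known
coding-overlapping transcripts (5th percentile of their syntenic-coding
identities), catching pseudogenes and UTR fragments even when the homology
is intronic or untranslated.

**Orthologs**: each lncRNA locus is lifted through genome alignment chains
(liftover contract, minMatch 0.1), padded ±150 kb, and aligned with a
reduced gap-open scheme (open 25, extend 40) suited to the many small
indels lncRNAs tolerate; alignments are kept only when they beat 95 % of
alignments to random intergenic sequence, and pairs must be confirmed
reciprocally. Loci whose flanks align while the transcript no longer does
are reported as *syntologs*.

**Evolution metrics** per pair, with the query's exonic length as
denominator:

* TGI (transcript–genome identity) — fraction of exonic bp aligning
  identically to the syntenic locus;
* TTI (transcript–transcript identity) — fraction aligning identically
  inside exons of both species' transcripts;
* SSC (splice-site conservation) — fraction of internal junctions whose
  aligned image falls within ±2 bp of a partner junction;
* IDR (indel rate) — log₂ ratio of exonic vs intronic indel-event rates
  (negative = indel-constrained exons).

Plus: hidden-ORF flagging by Nei–Gojobori dN/dS with length-binned
empirical P-values from intergenic null ORFs; lncRNA classes (miRNA host,
snoRNA host, divergent, intergenic); ortholog-group linking with
most-recent-ancestor parsimony assignment on a species tree; two-Gaussian
EM on the TTI distribution; and promoter CpG/repeat statistics with
Fisher-exact repeat-family enrichment against GC-matched intergenic
background.

## Worked example

Generate the built-in two-genome fixture (planted coding genes, conserved
and divergent lncRNAs, a duplicated family, a pseudogene, species-specific
loci — with exact chains and a truth table) and run the full pipeline:

```bash
slinc fixtures make --seed 7 --out fx/
slinc run --fixture-dir fx/ --out out/ --pad 20000 --seed 1
```

`out/filter_report.tsv` counts each transcript's fate:

```
fate    count
collapsed_isoform       1
kept    12
removed_coding_overlap  12
removed_duplication     3
removed_single_exon     1
removed_syntenic_coding 2
```

i.e. of 31 candidates, 12 survive: the 12 coding-gene fragments fall at
step 1, the three-copy ZFP-like family at step 2, and the pseudogene plus
the UTR fragment at step 3. `out/orthologs.tsv` holds the reciprocal pairs
and their metrics (excerpt):

```
query      target     class      p          tgi      tti      ssc  idr
divA_0     divB_0     DIVERGENT  0.00497512 0.353333 0.353333 0.5  -0.68096
lincA_0    lincB_0    INTERGENIC 0.00497512 0.918333 0.918333 1    -2.5934
mirhostA_0 mirhostB_0 MIRNA_HOST 0.00497512 0.890667 0.890667 1    0
```

The conserved lincRNA aligns at ~92 % of its exonic bases (TGI), all of it
inside both transcripts (TTI), with both splice junctions conserved and
strongly indel-constrained exons (IDR −2.6); the divergent-class lncRNA
keeps only its promoter-proximal exon (TTI 0.35). `out/ortholog_groups.tsv` assigns
each pair's last common ancestor (`anc` for both-species presence, the
species leaf for species-specific lncRNAs), and `out/syntologs.tsv` lists
loci that are syntenic but no longer alignable. Identical config and seed
reproduce every output byte-for-byte (see `out/manifest.json` for
parameters and input checksums).

The same stages are available as library functions
(`slinc.lnc_filter.run_filter_pipeline`, `slinc.ortho_evo.*`,
`slinc.orf_dnds.*`, `slinc.phylo_lca.*`, `slinc.promoters.*`) for scripted
use.

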