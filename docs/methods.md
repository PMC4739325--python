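# Methods

`slinc` identifies high-confidence long non-coding RNAs (lncRNAs) from a
candidate transcript set, discovers their orthologs in a second genome
through sensitive syntenic alignment, and scores how their sequence and
transcript structure evolve. This note describes the models and procedures,
the parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not demonstrate.

## The filtering model

Candidate transcripts from transcriptome reconstruction are contaminated by
coding-gene fragments, UTR extensions, pseudogenes, and members of
lineage-specific gene-family expansions (zinc-finger, olfactory). The filter
removes these in three steps, learning its main threshold from the data
rather than from a coding-potential model — which deliberately avoids
penalizing *bona fide* lncRNAs for being evolutionarily conserved.

1. **Coding overlap.** Any candidate whose exons overlap an annotated (or
   mapped) coding gene's exons on the same strand, in any amount, is
   removed. Exon–exon overlap is the default (`mode="exon"`), so intronic
   antisense lncRNAs survive; a stricter whole-span mode is available.
   Overlapping survivors are then collapsed to one canonical isoform per
   exon-overlap cluster (greatest exonic length; ties by genomic span, then
   identifier).

2. **Duplication clusters.** Every candidate is aligned to every other
   candidate. A pair is called homologous when its score exceeds the
   1−α quantile of *both* transcripts' null distributions, each built from
   200 alignments of the transcript to length-matched random intergenic
   draws (add-one empirical P, α = 0.05). Significant pairs are merged
   transitively; clusters of ≥ `min_cluster_size` (default 2) members are
   removed and additionally screened against known ZFP/olfactory panels,
   with hits reported as annotations rather than used as a removal
   criterion. A minimum reportable alignment score (`min_score`, default
   200 ≈ 40 perfectly matching bp) plays the role of the delegated
   aligner's HSP threshold: without it, a single shared seed k-mer between
   unrelated transcripts creates an "alignment" whose significance test
   fires at the nominal per-pair rate, and transitive merging amplifies
   those false positives into giant spurious clusters.

3. **Syntenic coding genes.** Transcripts known to overlap coding genes
   (the step-1 removals, capped at 250 random positives) are lifted to the
   comparing genome and aligned to their syntenic coding genes; the 5th
   percentile of the resulting identities (lower empirical order statistic)
   becomes the removal threshold, an empirical P = 0.05 for a true coding
   alignment. Each remaining candidate is then aligned against the *full
   pre-mRNA span* (UTRs and introns included) of any coding gene at its
   syntenic locus and removed if its identity exceeds the threshold — this
   is what catches processed pseudogenes and 3′-UTR fragments whose
   homology is entirely non-exonic in the annotation. The threshold is on
   alignment identity rather than raw score so it transfers across scoring
   schemes. Fewer than 10 usable positives is an error instructing the user
   to supply a threshold explicitly.

Single-exon candidates are quarantined before step 1: reconstruction
artifacts are overwhelmingly single-exon, so only single-exon transcripts
rescued later by cross-species conservation are worth reporting.

## Alignment

The aligner is seed-and-extend local alignment with affine gaps
(gap of length L costs `gap_open + gap_extend·L`). Exact-match k-mers
(default k = 12) are grouped into diagonal envelopes; each envelope is
extended by banded affine dynamic programming (band 64 columns around the
seed diagonals); sequences up to 1 kb with at least one shared seed get the
full exact Smith–Waterman matrix instead. Identity is matches over all
aligned columns including gap columns, and `N` never matches anything.
Two scoring schemes are used: a default (match +5, mismatch −4, gap
open 400, extend 30) for duplication and coding-homology detection, and a
reduced gap-open scheme (open 25, extend 40) for lncRNA loci, which tolerate
many small insertions.

Alignment significance is always empirical: a score is compared to the
scores of the same query aligned against n = 200 length-matched draws from
intergenic sequence (everything outside annotated transcript spans), with
the add-one estimator `P = (1 + #{null ≥ obs}) / (n + 1)` so P is never
zero. Under the defaults, "significant" means scoring above 95 % of random
intergenic sequence. Calibration: when the query is itself an intergenic
draw the pass rate at α = 0.05 is 0.05 ± 0.02 over 500 trials; the test
suite measures this on 700 bp draws with k = 8, conditions under which
random draws essentially always share seeds and the integer score
distribution is fine-grained enough for the rank test (shorter draws
produce heavy score ties, which the add-one estimator counts against the
query, deflating the rate below its nominal level — a property of the
statistic at small scales, not of the method).

## Orthology and evolution metrics

A query lncRNA is lifted through alignment chains (the liftover contract:
block-by-block mapping, emitted when ≥ `min_match` = 0.1 of exonic bp map;
best-covering chain wins, ties by chain score then id). The lifted footprint
padded by 150 kb on both sides defines the syntenic window — the padding
exists to include easily-alignable flanking genes that anchor the
alignment. Query and window are aligned with the reduced gap-open scheme.
The observed statistic is the best alignment score restricted to the
transcript's own span; the null realigns the transcript locus against 200
intergenic draws. Three outcomes:

* transcript alignment significant and a non-coding transcript lies under
  its image → an ortholog candidate (the target receiving the most mapped
  exonic bp, by projecting the query's exons through the alignment
  columns);
* transcript alignment significant with no transcript there → an alignable
  but untranscribed locus;
* only the flanks align → a *syntolog* report (the locus is syntenic but the
  sequence has diverged past alignability).

Pairs confirmed in both reciprocal directions are kept. For genes with
several isoform pairs, the canonical pair maximizes (conserved splice
sites, then transcript–transcript identity).

Metrics, all computed from the alignment of the two transcript loci with
the query's exonic length as denominator (the species-of-origin
perspective):

* **TGI** — identical aligned bp falling in query exons / query exonic
  length: sequence conservation regardless of transcription in the other
  species.
* **TTI** — identical aligned bp falling in exons of *both* transcripts /
  query exonic length: conservation of the transcribed product.
* **SSC** — fraction of the query's internal junctions whose aligned image
  lies within ±2 bp (configurable) of a target junction boundary; donor and
  acceptor boundaries are both accepted, a junction is counted once.
  Undefined for single-exon transcripts.
* **IDR** — log₂ of the exonic vs intronic indel-event rate, an indel event
  being a maximal gap run, attributed to the compartment of its query-side
  position: `log2[ ((e_ex+1)/bp_ex) / ((e_in+1)/bp_in) ]` with +1
  pseudocounts; exactly 0 when no indel was seen in either compartment
  (required for the self-alignment identity to hold), and undefined when
  either compartment has < 100 aligned bp. Negative values mean
  indel-constrained exons.

Classes: a pair is a miRNA/snoRNA host (small RNA fully inside the span; an
"exonic host" sub-flag marks small RNAs inside exons) or divergent
(opposite-strand coding TSS within 500 bp of the lncRNA TSS) only when both
species' transcripts qualify; everything else is intergenic. Two shuffle
controls quantify what syntenic co-occurrence alone produces: relocating
transcripts to random intergenic positions (structure preserved), and
re-placing splice donors uniformly on GT motifs within the locus to get the
expected conserved-junction count by chance.

The TTI distribution of canonical intergenic pairs is modeled as a
two-component univariate Gaussian mixture fitted by EM (best of 10 random
starts, tolerance 1e-6, restart on variance < 1e-8, assignment by posterior
> 0.5), separating sequence-constrained lncRNAs from those conserved only
in transcription.

## Hidden coding potential

For each confirmed pair, the spliced sequences are aligned and every
ATG…stop span present, in frame, and stop-coincident in both species is
reported if ≥ 33 nt including the stop (satisfying both the ">30 bp" and
"≥10 aa" readings; `--min-orf` adjusts it). Any gap inside the ORF
disqualifies it (the strict frameshift rule); a mode tolerating 3n gaps is
off by default. dN/dS uses Nei–Gojobori pathway counting (equal path
weights, changes to stop codons counted nonsynonymous) with Jukes–Cantor
correction. Degenerate cases: no substitutions → ratio 0 (maximally
conserved — the identically-processed null absorbs this); dS = 0 < dN →
+∞ (never flagged).

Because the ratio's distribution depends strongly on ORF length, observed
ratios get one-sided (low-ratio) empirical P-values against ORFs harvested
the same way from alignments of random intergenic regions with their
syntenic counterparts, in 5 nt length bins usable from 100 null ORFs;
Benjamini–Hochberg correction across hits; flagged at q ≤ 0.05. Long ORFs
without a usable bin fall back to the dN/dS < 1 rule. Calibration targets:
neutral simulated codon pairs (ω = 1) give median dN/dS within 1 ± 0.15;
purifying pairs (ω = 0.1, 300 nt) flag at ≥ 80 % while neutral pairs stay
≤ 10 % after correction.

## Ancestral assignment

Pairwise orthologs are linked greedily into groups (pairs {A,B} and {B,C}
yield {A,B,C}). Each group's presence/absence profile over the species-tree
leaves is explained by a single gain plus losses — orthology already
implies homology, so independent origins are not entertained. Candidate
origins are the set-LCA of present leaves and its ancestors; origin cost is
one gain (none for the root, which has no incoming edge) plus one loss per
maximal absent subtree below. Among minimum-cost origins the most recent is
chosen, giving conservative conservation estimates: mouse+rat presence with
primate absence is assigned to the rodent root (tie with root-origin +
primate loss, broken toward recency). Multifurcations are supported.

## Promoters

Promoters are the 500 bp upstream of the TSS, strand-aware and clipped at
contig bounds. Each is annotated with GC fraction, CpG-island overlap
(any-bp against a provided island track; a Gardiner–Garden-style caller
with the classic thresholds — length ≥ 200, GC ≥ 0.5, obs/exp CpG ≥ 0.6 —
is included for synthetic genomes), and repeat content (union bp). Repeat
families are tested for enrichment against random intergenic backgrounds
matched in size and GC (±0.02) with a two-sided Fisher exact test,
Bonferroni-corrected over families tested (BH by flag), significant at
corrected P < 0.005. Promoters for which no GC-matched background exists
(CpG-island promoters in a uniform-GC synthetic genome) can be skipped
rather than fatal.

## Synthetic fixtures

`plant_genome_pair` builds two toy genomes (~2 × 300 kb, spacers 6–12 kb)
where genome B derives from A segment by segment: neutral spacers
(substitution 0.03, indels 3·10⁻⁴), coding genes (0.02, no indels in the
annotated pieces), conserved lncRNAs (exons 0.10, introns 0.15 with
indels), divergent-class lncRNAs (promoter-proximal exon at 0.08, distal
exons fully turned over), hosts with planted small RNAs, a three-copy
ZFP-panel-derived family, a processed pseudogene (its own chain onto the
parent's exons, mirroring how genome chains follow pseudogene homology), a
3′-UTR annotated only in species B with an overlapping A candidate,
species-specific loci (sequence turned over under an intact chain), an
unliftable locus (chain gap), and a single-exon artifact. Chains are
emitted from the generative event log, never re-aligned, so liftover in
tests is exact. The genome scale and the fixture's recommended window pad
(20 kb, spanning several flanking elements — the role 150 kb plays on
mammalian genomes) keep the full golden run under a minute on one CPU.

What the fixture does *not* emulate: realistic repeat landscapes and GC
heterogeneity, transcription levels and tissue specificity, assembly errors
beyond the planted artifact classes, >2 genomes, and strand-flipping or
rearranged chains. Passing the golden run therefore shows the machinery
separates the planted contamination classes under the stated divergence
regimes; it does not certify sensitivity/specificity on real mammalian
annotation sets. A separate promoter fixture plants an ERVK-like family in
30 % of 40 promoters (and two neutral families uniformly) for the
enrichment statistics, since the main fixture has too few species-specific
promoters for Fisher significance at corrected P < 0.005.

## Numerical and reproducibility choices

All randomness flows from explicit seeds (`numpy` Generators); the pipeline
threads one seed through all stages and produces byte-identical outputs for
identical config+seed (the JSON manifest records parameters and input
checksums, no timestamps). Deterministic tie-breaks everywhere: canonical
isoforms by (exonic length, span, id); chains by (coverage, score, id);
ortholog targets by (mapped exonic bp, id). Alignment kernels are
numba-compiled; the banded extension caps its matrix at ~60 M cells per
chunk and splits longer regions. Problem sizes in the test suite (fixture
scale, 200 oracle pairs, 500 calibration trials, 1000 neutral replicates,
~2000 null regions in pipeline runs) are chosen so the whole suite runs in
a few minutes on one CPU while keeping every statistical check at a scale
where its expected behavior is unambiguous.

Known limitations: no translated (protein-space) alignment, no multiple
alignment or >2-species joint orthology, chains are consumed but never
constructed from raw genomes, dN/dS is count-based (no ML/codeml model),
expression-based filtering and ribosome-profiling evidence are out of
scope, and the stage order runs the ORF scan after the ortholog search
because it consumes the pairwise lncRNA alignments.
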