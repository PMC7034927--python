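# Methods

## The analysis model

Nuclear fractionation yields two sequencing libraries per replicate: the
chromatin pellet extract (CPE) and the soluble nuclear extract (SNE).
`chefind` treats the transcript × sample matrix of raw counts as the primary
observable and models each transcript's counts as negative binomial with
variance μ + φμ². The scientific questions it answers are (i) which
transcripts are chromatin-enriched, (ii) where they sit relative to coding
genes, and (iii) how the chromatin-enriched set behaves with respect to
neighboring gene expression, chromatin marks, and structural motif content.

### Coordinates and overlap

All internal coordinates are 0-based half-open; GTF I/O converts from/to
the 1-based inclusive dialect and BED is read natively. Overlap between two
features requires at least one shared base and is evaluated on transcript
*spans*, not exon unions: the classification rules in the source analyses
are span-level, and exon-level overlap is exposed as an option
(`exon_level=True`) for sensitivity analysis. Positional classification
tests a transcript against all coding genes and applies the first matching
rule: same-strand overlap → sense-overlap; opposite-strand-only overlap →
antisense; otherwise intergenic. These three classes partition any
transcript set.

Flanking-gene search is by genomic coordinate order around the transcript's
span with gap distance measured span-to-span; ties break toward the
smaller-coordinate gene, which makes the operation deterministic and
orientation-free. By default flanks must lie on the same strand as the
intergenic transcript (relaxable via `same_strand=False`).

### Noise filter

A transcript is "expressed" when its CPM is ≥ 1 in at least
⌈min_fraction · n_samples⌉ samples (defaults 1.0 CPM and one half).
Library sizes default to column sums of the supplied matrix, which keeps
the filter self-contained and reproducible; externally determined mapped-read
totals can be passed instead. The count over samples pools both fractions;
per-dataset (per cell type) invocation is the intended usage when multiple
cell types are analyzed. No pseudocount enters the filter; a configurable
prior (default 0.5) applies only to log-scale summaries. On the synthetic
study this filter leaves an approximately log-normal expression
distribution, checked with an in-house dip-style unimodality test
(convex-minorant/concave-majorant deviations over candidate modes,
Monte-Carlo calibrated against uniform null samples).

### Enrichment test

The CPE-vs-SNE test is an exact negative-binomial two-group test in the
style of classic count-based differential analysis: counts are scaled to
the mean library size, replicate sums per group are modelled as NB (the sum
of n iid NB(μ, φ) variables is NB(nμ, φ/n)), and the two-sided p-value
conditions on the total, summing the probabilities of all splits no more
likely than the one observed. Per-transcript dispersions come from a
bias-corrected method-of-moments estimate, (s² − μ̂)/(μ̂² − s²/n) per group
(the correction removes the E[μ̂²] = μ² + var/n inflation of the
denominator), averaged over groups, floored at 1e-6, and shrunk with weight
0.7 toward a robust global center (5 %-winsorized mean of the per-transcript
estimates). The strong default moderation is deliberate: with five
replicates per group the raw moment estimate has ~70 % coefficient of
variation, and under-estimated dispersions translate directly into false
positives. With these defaults the global-null p < 0.05 fraction sits at
the nominal level (0.05–0.07 across simulation seeds).

Normalization is per-sample library-size scaling only. Trimmed-mean
normalization is intentionally not applied: the two fractions differ
globally *by design*, and trimming toward equal bulk would absorb genuine
chromatin enrichment. The interface accepts externally computed p-values
(`pvalues=`) so any differential engine can be swapped in behind the same
call surface.

Calls use BH-adjusted FDR < 0.05 with no minimum fold-change; "not
differentially expressed" is simple non-significance, not an equivalence
test. The log2 fold-change adds a 0.5 pseudocount to each group mean for
reporting only — it never enters the test. Swapping the CPE/SNE labels
negates every log2FC and exchanges cheRNA↔sneRNA calls exactly.

### Neighbor-gene correlation

Expression vectors for correlation are log2(FPKM + 1) over all CPE and SNE
samples (the choice of unit is configurable; FPKM removes the length
confound between short lncRNAs and long mRNAs). Each intergenic transcript
is paired with whichever of its two flanks has the larger |Pearson r|;
ties (exactly equal magnitudes) go downstream for determinism. The relative
density uses a Gaussian KDE with Silverman bandwidth on a 201-point grid
over [−1, 1]; the control pairs the same transcripts with uniformly random
coding genes (without replacement when possible, seeded, size-matched), and
the ratio floors the control density at 1e-6, flagging floored grid points.
Fractions beyond the significance cutoff (default ±0.8) are inclusive at
the boundary. Calibration: two independent random pairings of a ~1000-pair
population stay within [0.8, 1.25] of each other on |PCC| ≤ 0.5, where the
null distribution has support.

### Metagene profiles

TSS profiles average the signal-vs-input ratio, (ChIP + pc)/(input + pc)
with pc = 1 RPM (bounded ratios on sparse input), over ±1 kb windows
centered at the TSS in 50-bp bins, oriented 5′→3′ (reversed on the −
strand). Body profiles scale each transcript body to 100 equal-width bins
(exact segment means via cumulative sums) plus 1-kb flanks in ten 100-bp
bins. Averaging is across transcripts of per-transcript binned means, so
long transcripts do not dominate. Windows that leave the chromosome, and
bodies shorter than the bin count, are dropped and counted. Mirroring the
genome (reversing tracks and coordinates with strands flipped) leaves every
profile unchanged, and profiles are linear in the track.

High/low grouping for a mark declares a transcript "high" when its span
extended by a proximity margin (default 1000 bp, reported in output
metadata — "near" has no canonical definition) intersects at least one
peak. Group comparisons use the two-sided Wilcoxon rank-sum test with the
tier mapping NS (p > 0.05), `*` (p < 0.01), `**` (p < 1e-10), `****`
(p < 2.2e-16). The scheme names no symbol for 0.01 ≤ p ≤ 0.05 (nor `***`);
that gap is reported as the NS-adjacent tier `ns*`.

### Motif enrichment and co-enrichment

Structural family motifs are short relative to assembled transcripts, so a
transcript is annotated to a family only when a motif interval lies
entirely within its span on the same strand (boundaries inclusive;
unstranded motifs match either strand). The RR-score of a target set t
against family r within noncoding universe T is
(|t∩r|/|t|) / (|T∩r|/|T|), counting transcripts rather than motif
instances; RR > 1 is overrepresentation, and RR(T, r, T) = 1 identically.
Family-to-super-family grouping is a user-supplied two-column mapping.
Fisher co-enrichment builds the 2×2 table over a declared universe and
reports the conditional-MLE odds ratio with the two-sided exact p
(probability-ordering convention); the enrichment flag requires OR > 2 and
p < 0.05. Externally computed calls (e.g. triplex-formation predictions)
enter simply as id lists.

### Evaluation metrics

ROC evaluation ranks transcripts by signed −log10(FDR) (sign of log2FC; the
ranking statistic is a flag) against a proxy gold standard — the
intersection of all compared methods' calls. Ids without a score rank below
every scored id and are counted. AUC is the trapezoid area and equals the
normalized Mann–Whitney U statistic. PPV on canonical loci is the fraction
predicted with the expected class, unpredicted loci counting as wrong. R1
is the fraction of a cell type's identifications found in no other cell
type, after a greedy coordinate-based deduplication (reciprocal ≥ 50 % span
overlap, same chromosome and strand) that unifies slightly different
assembled coordinates across cell types. qPCR abundances are
A = 2^(−ΔCq) with ΔCq = Cq − Cq_spike.

## The synthetic study

The generator's defaults are the study conditions for all calibration
results. Geometry: four 1-Mb chromosomes; 160 coding genes (2–8 kb, 1–3
exons, random strand) alternating with 8–16 kb gaps; 100 intergenic
lncRNAs (0.5–3 kb) and 700 noise fragments (0.2–0.8 kb) placed in gaps
with a 1.5-kb margin from genes; 40 antisense lncRNAs strictly inside a
host gene on the opposite strand. Counts: baseline means log-normal
(median 200, σ_log = 0.8) for the 300 expressed transcripts, 0.05 for
noise; NB dispersion 0.1; five replicates per fraction with log-normal
library factors (σ = 0.1); planted |log2FC| = 2 between fractions for
cheRNA/sneRNA-truth transcripts (40/40/20 % che/sne/independent among
lncRNAs, 15/15/70 % among coding genes). Each che/sne intergenic lncRNA
shares a latent log-normal factor (weight 0.8) with its nearest same-strand
flanking gene — positively for cheRNA, negatively for sneRNA — inducing the
planted neighbor correlation; each gene serves at most one lncRNA. Tracks:
smoothed gamma noise around 1 for input; the ChIP track adds two Gaussian
bumps (amplitude 4, σ = 150 bp) at ±400 bp around the TSS of a designated
half of the intergenic lncRNAs, leaving the TSS itself at input level, so
the profile rises on the peak-bearing flanks (±200–600 bp) and dips ≥ 20 %
at the TSS. Peak calls span ±2σ around each summit, and the emitted truth
resolves the high/low group for *every* transcript against the placed
peaks. Motifs: six families at 8 % background containment, with one family
planted at 35 % among cheRNA-truth noncoding transcripts. All randomness
derives from the single mandatory seed; equal seeds give byte-identical
files.

The calibration simulations used by the tests and the acceptance script are
counts-only: 200 cheRNA + 200 sneRNA at |log2FC| = 2 with 600 null
transcripts (dispersion 0.1, 5+5 replicates) for sensitivity/FDR; 1000 null
transcripts for p-value calibration; and a 200-pair correlation mixture
with 25 % of pairs at bivariate correlation 0.95 over 30 samples. These
problem sizes keep the full test suite and the acceptance script in the
tens of seconds on a single CPU while leaving the statistics stable across
seeds.

What the generator does *not* emulate: positional biases of read coverage,
exon-level quantification ambiguity, batch effects between replicates,
multiple cell types, overlapping or nested coding genes, and realistic
genome-wide peak densities. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the declared
model, not performance on real sequencing data — real CPE/SNE libraries
bring assembly noise and normalization artifacts outside this model.

## Numerical choices and degenerate inputs

- Dispersion floor 1e-6 (covers constant-count and Poisson-like rows).
- The exact test returns p = 1 for an all-zero total; all-zero rows raise,
  directing to the prefilter.
- KDE control density floored at 1e-6; floored grid points are flagged
  rather than silently capped.
- PCC requires ≥ 3 observations and nonzero variance in both vectors;
  zero-variance flanks are simply not candidates for pairing.
- The boundary PCC = ±0.8 counts as beyond the cutoff; a motif exactly
  coextensive with a transcript counts as contained; a transcript with CPM
  exactly at threshold counts as expressed. All boundary decisions are
  inclusive.
- `flanking_genes` ties break toward the smaller coordinate; `pair_neighbor_gene`
  ties break downstream.
- Fisher tables with an empty margin return p = 1 via the exact convention.

## Known limitations

- The enrichment test treats the shrunken dispersion as known; with two
  replicates per group the moderation dominates and per-transcript
  dispersion differences are mostly ignored.
- Span-level (not exon-level) overlap can over-call sense-overlap for
  transcripts inside long introns; the exon-level option exists but is
  untuned.
- The dip-style unimodality statistic is Monte-Carlo calibrated rather than
  exact; it is used as an internal sanity check, not an inference tool.
- R1 deduplication is greedy first-match; pathological chains of partially
  overlapping assemblies could merge transitively.
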