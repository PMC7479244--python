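# Methods

This note documents the models, conventions and numerical choices behind
`rrbsdiff`, and what the synthetic cohort does and does not establish about
real data.

## Data model and conventions

The central object is the `CountMatrix`: per-CpG, per-sample pairs of
(methylated reads, total reads).  A cell with zero total reads is *missing*,
never 0% methylation.  Internally all coordinates are 0-based with half-open
intervals; the on-disk coverage dialect (chrom, 1-based start, end = start,
methylation %, count-methylated, count-unmethylated) and GTF are converted at
the I/O boundary, BED tracks are read/written natively 0-based.  The emitted
percentage column is always ignored on input and recomputed from counts.

**Strand handling.**  A CpG dyad yields a forward-strand record at position
*p* and a reverse-strand record at *p + 1*.  The default `merged` mode sums
the two into the forward key before filtering, because the analysis unit is
the CpG (not the cytosine) and merged counts make per-CpG coverage
interpretable.  The dialect carries no strand column, so pairing is greedy
left-to-right (a record at *p + 1* joins a not-yet-paired record at *p*);
a dyad covered only on the reverse strand therefore keeps its reverse key.
This is rare at ~25× coverage (both strands empty with probability ~2⁻ⁿ) and
`forward_only` mode is available.  Whether the coverage filter should precede
or follow merging is genuinely open; the pipeline merges first, so "≥ 10
reads" refers to the dyad.

**Thresholds.**  "At least 10 reads" and "at least 4 bulls" are inclusive
(≥).  Methylation classes: hypo < 20, intermediate ∈ [20, 80] with both
boundaries closed, hyper > 80.  A DMC requires adjusted p *strictly* below
0.1 ("weaker than") and |difference| ≥ 10 points (inclusive); the DMR gap
rule (≤ 100 bp between successive DMC positions) is inclusive at 100.
Differences are oriented group1 − group2 with group1 the HM-like group, so
positive means hypermethylated under the high plane of nutrition; every
output header states this.

## Differential test

Counts are modelled beta-binomially: for group *g*, bull *j* at site *i*,
`Var(x/n) = p(1−p)(φ + (1−φ)/n)`.  The test is a deliberately simplified
re-implementation of the dispersion-shrinkage Wald approach standard for
two-group bisulfite designs (no smoothing, no covariates in the mean model);
it is not bit-compatible with any reference tool, and the test suite instead
verifies its statistical behaviour (type-I error, sensitivity/FDR against
planted truth, oracle equalities for the FDR machinery).

* **Dispersion.**  Per site, a method-of-moments estimate solves
  `var(p̂) = p(1−p)(φ + (1−φ)·mean(1/n))` within each group; groups combine by
  degrees of freedom.  The raw estimate is noisy at 7–9 replicates (about half
  the estimates fall below zero under low true dispersion), so it is shrunk:
  `φ_shrunk = (w·max(φ_raw, 0) + w₀·φ̄(level)) / (w + w₀)` with *w* the
  per-site df and `w₀ = 8`.  The prior `φ̄(level)` is the arithmetic mean of
  the *unfloored* raw estimates within quantile bins of pooled methylation
  level (4 bins) — averaging before flooring keeps the prior unbiased, and
  the binning captures the strong dependence of overdispersion on methylation
  level in a bimodal methylome (a logit-scale individual effect contributes
  variance ∝ (p(1−p))², so intermediate sites are far more dispersed than
  extreme ones).  A single global prior either inflates FDR at intermediate
  sites or wastes power at extreme ones; the 4-bin/weight-8 default was
  calibrated on simulations (type-I ≈ 0.05, FDR ≤ 0.09, sensitivity ≥ 0.6
  across seeds at study scale).  Estimates are clipped to [1e-6, 0.999].
* **Wald statistic.**  Coverage-weighted group proportions; the variance is
  evaluated at the *pooled* proportion (null variance), which stabilises the
  statistic when a group sits at 0 or 1; two-sided normal tail.  Degenerate
  sites (pooled proportion 0 or 1) report p = 1.
* **FDR adjustment.**  A native, simplified independent-hypothesis-weighting
  scheme: the covariate (per-site mean methylation across both groups —
  chosen where "the average methylation per group" is ambiguous) is cut into
  10 quantile bins (bins under 200 hypotheses merged); each bin's weight is
  proportional to `1 − π̂₀` (Storey at λ = 0.5, clipped to [0.05, 1]); weights
  are normalised to mean 1 over all hypotheses; BH runs on `p/w`; zero weight
  maps to adjusted p = 1.  With one bin this is exactly BH (verified
  element-wise to 1e-12 against an independent implementation).  The
  reference IHW's cross-validated weight optimisation is intentionally out of
  scope.
* **Paired ages.**  The 15-vs-16-month comparison restricts to bulls sampled
  at both ages but uses the same two-group test; pairing informs reporting
  only.  Because the same bulls appear in both groups with correlated values,
  the test is conservative there — acceptable since that comparison is a
  negative control (the planted age effect is zero by default).

## Permutation tests

QC metrics are compared across cohorts with a k-sample Monte-Carlo
permutation test (default statistic: variance of group means; 100,000 draws;
the statistic choice is logged in the output).  The pyrosequencing per-CpG
comparison uses a two-group test stratified by age: labels are permuted
*within* age strata, preserving per-stratum group counts, which keeps the
level when age carries a main effect unevenly split between diet groups (the
unstratified test demonstrably over-rejects in that setting).  All p-values
use the add-one estimator `(1 + #{T* ≥ T}) / (B + 1)`; two-sample two-sided
p-values double the smaller tail, capped at 1.  Everything is seeded and
reproducible.

## Annotation conventions

Windows: TSS ± 100 bp; promoter −2000..−100 bp of the TSS (half-open against
the TSS window); TTS ± 100 bp; upstream/downstream 10-kb flanks; all
strand-aware and clipped at chromosome ends.  One gene-feature label per
query by fixed precedence TSS > TTS > 5'UTR > 3'UTR > exon > intron >
promoter > upstream_10kb > downstream_10kb > intergenic, any-base overlap
across all genes.  The precedence order is a declared convention of this
package (gene-body features outrank promoter/upstream so intron/exon
proportions stay interpretable); no authoritative order exists for
multi-gene overlaps.  CpG context: shores are within 2,000 bp of an island,
shelves within 2,000 bp of a shore; the three classes are made disjoint
(island ≻ shore ≻ shelf) before the ≥ 75%-of-query-length overlap rule;
single sites reduce to point membership.  Repeats associate at any overlap
extent.  Genes associate with a query within 10 kb of the gene span
(inclusive boundary).  Enrichment against the CpG10 background flags
categories whose query/background ratio exceeds 1.25 or falls below 0.75.
All three assignment paths are verified against an independent per-base
painting oracle on a 1-Mb toy genome at every CpG.

## Pyrosequencing consolidation

Each CpG is assayed in duplicate; duplicates more than 5 points apart are
inconsistent and would be re-run.  For ≥ 3 replicates the kept set is the
largest subset with pairwise range ≤ 5 points, ties broken toward earlier
replicates, and the value is the mean of the kept subset; samples with no
consistent pair are missing.  This pooling rule is a declared convention —
the QC rule the original assay software applies to triplicates is not
public.  Concordance per DMR is Spearman's rank correlation (midranks for
ties; ≥ 5 paired samples required; constant vectors report missing) between
per-sample pyro means and the RRBS mean over the DMCs composing the DMR.

## The synthetic cohort

The generator emulates the global structure of post-pubertal bull sperm RRBS
data and provides planted ground truth; its defaults are the study
conditions, not tuning knobs:

* **Genome** — 2 × 2.5 Mb chromosomes at 50% GC with background CpG depletion
  (half the background CG dinucleotides mutated, giving observed/expected CpG
  ≈ 0.5–0.65), 200 CpG-rich islands, 150 genes with exons/UTRs on both
  strands, and repeat tracks (LINE/SINE/LTR/satellite/simple) at realistic
  aggregate fractions.  MspI digest at C^CGG; both fragment ends must be cut
  sites; size selection 40–290 bp of genomic fragment (adapters excluded):
  ~40k CpGs land on retained fragments.
* **Methylation** — a three-component beta mixture at proportions
  0.471/0.458/0.071 with sharply bimodal components (Beta(60, 1.5),
  Beta(1.5, 60), Beta(5, 5)): the mixture is calibrated so that the
  *observed* CpG10 class split at ~25× coverage reproduces the
  ≈ 47% / 7% / 46% hyper/intermediate/hypo structure and ~50% mean
  methylation — flatter components leak extreme sites into the intermediate
  band through sampling noise.
* **Cohort** — 9 HM15, 7 MM15 and 9 MM16 samples; the MM bulls sampled at 15
  months are a subset of those sampled at 16, and both ages share the same
  underlying truth (an optional parameter can plant age effects; the default
  is zero, mirroring an essentially empty age contrast).
* **Diet effect** — 1% of CpGs shifted by exactly 15 points in the HM group,
  70% upward.  When the shift would leave [0, 1] the group-2 level moves
  instead so the planted difference stays exactly 15 points (flagged in the
  truth table).  30% of planted sites are laid in blocks of 3–5 consecutive
  CpGs within 100-bp gaps so region-level (DMR) signal exists at desk scale,
  mirroring the observation that a minority of DMCs cluster into DMRs.
* **Noise** — coverage per dyad is negative binomial (mean 25, size 8), split
  binomially across strands; a bull-level logit-normal effect (sd 0.6) is
  shared between the two ages of the same bull, plus beta-binomial dispersion
  φ = 0.02 per site×sample; unconverted-cytosine errors occur at rate 0.006
  (conversion 99.4%), and the spike-in control is binomial at the conversion
  rate.  The jitter sd is calibrated qualitatively so that inter-individual
  variability dominates the diet effect: paired same-bull samples are mutual
  nearest neighbours in correlation distance while the 2-cluster cut is
  uninformative about diet (adjusted Rand index ≈ 0).  No published value
  exists for this variance; it is the one deliberately qualitative default.

**What passing tests do and do not show.**  The simulation shares the real
data's marginal structure (bimodality, coverage, conversion, variance
hierarchy) but not its biology: no sequence-driven methylation, no
imprinting, no mapping ambiguity or PCR duplicates (read trimming and
alignment are upstream of this pipeline's scope), no LD-like spatial
correlation beyond the planted blocks, and independent noise across sites.
Calibration and power results therefore validate the *statistical machinery*
at the study's design (sample sizes, coverage, effect sizes), not biological
conclusions about any real cohort.

## Scale and reproducibility choices

Simulations in the test-suite run at two scales: a ~40× reduced genome for
unit tests and the full ~5-Mb/25-sample configuration for calibration,
recovery and fidelity checks (~20–40k CpGs — enough for stable empirical
rates while keeping the whole suite under a minute of simulation time).
Monte-Carlo sizes follow the check: 100,000 permutations for production
p-values, 600–1,000 for repeated-level estimates where only the rejection
*rate* matters.  All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical configurations give byte-identical
emitted files.  The CLI accepts `--threads` for interface compatibility but
runs single-process — every hot path is vectorised.

## Known limitations

* The greedy strand-merge heuristic mis-keys dyads covered only on the
  reverse strand (no strand column in the dialect).
* The Wald normal tail is mildly liberal at 7–9 replicates; empirical type-I
  error sits near 0.050 under the simulator but is not guaranteed for real
  data with heavier-tailed individual effects.
* The IHW scheme is the binned-weights core, not the cross-validated
  optimiser; with sparse signal its weights are nearly uniform.
* Enrichment reports are descriptive (ratio flags), with no significance
  testing on category proportions; downstream gene-set enrichment is the job
  of external tools, for which the package only prepares query and
  background gene lists.
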