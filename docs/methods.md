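# Methods

## Data model

The core container (`AllelicMatrix`) holds estimated read counts for F
features × S samples × 2 alleles, plus B bootstrap replicate count arrays of
the same shape produced by the upstream quantifier.  Allele 1 is the
maternal/reference haplotype, allele 2 the paternal/alternate; all reported
effects (statistics, log2 fold changes) are signed so that positive means
allele 2 higher.  Features can be transcripts, TSS groups, or genes; the
three levels share every downstream operation.

The package assumes phased genotypes and multiple samples of the *same*
diploid genotype (replicates of an F1 cross, time points of one donor's
cell line).  It does not construct diploid references or run quantification;
it consumes quantifier output (quant.sf-dialect tables, one row per allelic
transcript, plus one plain-text matrix per bootstrap replicate).

## TSS grouping

A transcript's TSS is its 5' end (minimum exon start on `+`, maximum exon
end on `-`; 1-based GTF coordinates).  Fuzzy grouping chains the distinct
TSS positions of one gene and strand by single linkage: sorted neighbours at
most `window` bp apart join one group.  `window=0` gives exact-position
groups; the default fuzzy window is 50 bp.  Single linkage was chosen over
a diameter bound because it is order-invariant and matches the intuitive
reading of "TSS within w bp of each other"; a diameter-bounded variant
would split long chains and is noted as an alternative.  Groups never span
genes or strands.  Group ids are `<gene>-<k>` with k numbered along the
genome by each group's minimum TSS; gene-level maps use the bare gene id.

## Aggregation and filters

Aggregation sums point estimates and *every bootstrap replicate* over group
members, per sample and allele, so group-level uncertainty is the
uncertainty of the summed counts (sums conserve totals exactly).  The
pipeline order is: aggregate → drop uninformative features → minimum-count
filter.

* *Uninformative filter*: when no read distinguishes the two alleles, the
  quantifier splits the total equally, so the estimated allelic fold change
  is identically 1; features with exactly equal allelic point estimates in
  every sample (tolerance 1e-8 for text round-trips) are removed.
* *Minimum-count filter*: keep features with count ≥ 10 in at least 3 of
  the 2S allele-sample columns.  Counting allele-sample columns (rather
  than per-sample totals) is the more permissive reading; the per-sample
  total mode is available via `per_sample_total=True`.

No library-size scaling is applied at any point: the tests compare the two
alleles within a sample, where sequencing depth cancels.  (Aggregating
transcripts by the *sign of their estimated fold change* is deliberately
not offered: selecting groups on the same data that is then tested is a
form of double dipping and loses error control.)

## Testing

All three tests share one recipe: a nonparametric per-feature statistic is
computed on every bootstrap replicate and averaged, then calibrated against
a permutation null in which one shared label permutation per draw is
applied to all features (preserving cross-feature correlation in the null,
in the spirit of permutation-pooled FDR methods).

Because ranks of |d| are invariant under allele swaps, and standardized
LFCs are invariant under covariate/group permutations, the permuted
statistic is an inner product of a precomputed bootstrap-averaged matrix
with the permuted label vector.  The permutation null is therefore exact
with respect to the bootstrap averaging, at O(F·S) per permutation.

* Global AI: signed-rank statistic W = Σ sign(d)·rank(|d|), zeros excluded,
  midranks for ties; null = random sign-flip vectors ε ∈ {±1}^S.
* Dynamic AI: Pearson (default) or Spearman correlation between
  pseudocounted LFCs and the covariate; constant LFC within a replicate
  contributes correlation 0; null = covariate permutations.
* Differential AI: centered Mann-Whitney rank sum of the group whose label
  sorts second (so exchanging labels negates the statistic); null = label
  permutations.

P-values are (1 + #{|null| ≥ |obs|}) / (1 + #null) over the pooled null of
n_perm × F values — strictly positive and super-uniform under the null.
With the default n_perm = 100 the attainable p resolution is roughly
1/(100·F), ample for q < 0.01 at thousands of features; n_perm trades
resolution for time.  π₀ is estimated by Storey's smoother (cubic fit of
π₀(λ) on λ = 0.05…0.95, evaluated at 0.95, clipped to [1/N, 1]) and
q-values are π₀ × Benjamini-Hochberg, monotonized.  The reported log2fc is
the mean pseudocounted LFC over samples and replicates, with the same
pseudocount c = 5 used by the dynamic statistic.

The statistic is the raw (unnormalized) rank sum; any monotone rescaling
would give identical permutation p-values, so the simplest form is kept.

### Beta-binomial comparator

As the uncertainty-blind baseline, an intercept-only beta-binomial GLM is
fit per feature to the rounded point estimates (allele-2 successes of
pair totals across samples) by maximum likelihood over (logit mean,
log precision), with a Wald test of zero allelic log odds and BH
correction.  When the precision parameter runs to its upper bound (no
overdispersion), the full Hessian is singular and the conditional SE of
the mean is used.  Non-converged features are flagged with NA.

## The simulator

The generator reproduces a two-allele benchmark at the count level; it
emulates the *statistical* structure of a quantified diploid RNA-seq
experiment, not its sequences.

Study conditions (defaults): 14,821 genes with 1,000 AI genes split 500
concordant / 500 discordant; 10 samples; NB dispersion size = 100
(variance μ + μ²/100); 30 bootstrap replicates; allelic ambiguity ρ = 0.2.
The desk profile (`SimDesign.desk()`) keeps every rate and effect size and
scales the problem to 2,000 genes (250/250 AI) with a 2M-read library so a
full benchmark runs in seconds; the full-scale profile uses a 50M library.

* **Gene models.**  AI-eligible genes have 3–6 isoforms, at least two
  isoforms sharing a TSS, and at least two distinct TSS; background genes
  have 1–6 isoforms with arbitrary TSS structure.  Transcript lengths are
  log-uniform on [500, 5000] bp; distinct TSS within a gene are spaced
  200 bp apart (so exact and 50-bp fuzzy grouping coincide on synthetic
  annotation, keeping truth groups unambiguous).  A single-exon GTF is
  emitted for the annotation path.
* **Abundances.**  Maternal abundance is constant per transcript across
  samples, log-uniform on [1, 100] (a typical two-decade expression range;
  the original design states only "a constant value").  Concordant genes:
  paternal = maternal × 1.25 or × 0.75, at random per gene ("25% down" is
  read as ×0.75, the symmetric percent change, rather than ÷1.25).
  Discordant genes: one TSS group is chosen at random; its n isoforms get
  paternal fold 1 + 1/(2n); the remaining isoforms share the unique common
  down-factor restoring exact gene-level allelic balance (choices that
  would require a negative factor are resampled).
* **Counts.**  Expected counts μ ∝ abundance × length, normalized so each
  sample's total equals the library size; observed counts are NB(μ,
  size) independently per transcript-allele-sample.
* **Quantification emulation.**  Each transcript pair's reads are
  allelically ambiguous with probability ρ.  The emulated estimator
  apportions the pooled ambiguous reads m at the ratio q of the
  unambiguous evidence (unbiased; exactly equal-split only when no read
  distinguishes the alleles, reproducing the artifact the uninformative
  filter removes).  Bootstrap replicates are a parametric bootstrap of the
  estimator's two error sources — reassignment of the ambiguous pool,
  x ~ Bin(m, q), and re-estimation of the ratio from the unambiguous reads,
  q\* = Bin(U, q)/U — giving replicate = point + (m·q\* − x), clipped to
  [0, pair total].  To first order the replicate variance equals the
  estimator's true error variance ρ/(1−ρ)·p(1−p)·t (verified by direct
  simulation), so normal-approximation intervals built from the replicates
  are close to nominal coverage *by construction* — emulating the key
  empirical property of real quantifier bootstraps.  Alleles are resampled
  jointly per transcript pair and replicate totals equal observed totals,
  per transcript and per sample.  Two alternative modes exist for study:
  `em_apportion=False` (blind 50/50 split — biased toward balance, its
  intervals under-cover at high expression) and `resample_totals=True`
  (multinomial resampling of all transcript totals per sample — wider than
  the estimator's error, intervals over-cover).

What the generator does **not** emulate: sequence content, mappability or
GC bias, transcript-level (as opposed to allele-level) multi-mapping,
positional bias, or annotation errors.  Passing benchmarks here shows the
statistics behave correctly under NB counts with allele-ambiguity
uncertainty; it does not certify behavior under quantifier model
misspecification on real reads.

## Evaluation harness

Calls at gene or TSS level are propagated to member transcripts (a
transcript is positive iff its group is called at the q cutoff), so methods
at different resolutions are compared on a common transcript-level footing.
FDR = FP/max(1, FP+TP); TPR is reported overall and stratified by
concordant/discordant AI.  The evaluation universe defaults to all
simulated transcripts and can be restricted (e.g. to features surviving the
minimum-count filter, the natural reading of "expressed isoforms").

Interval coverage follows the normal-approximation recipe: per
feature/sample/allele, the 95% interval is bootstrap mean ± 1.959964 ×
bootstrap SD (ddof = 1, the standard sample SD) over the first B replicates;
a cell is covered iff the true simulated count (the NB realization, which is
what the estimator could at best recover) lies inside.  Rates are averaged
within samples and summarized as mean ± SD across samples, within
expression tertiles computed on true counts pooled over samples (ties
broken by rank).

Two cautions, quantified during design:

* With B iid replicates, the estimated SD fluctuates (≈ chi distribution),
  which *systematically depresses* coverage at small B; for this recipe the
  expected increment from B=30 to B=50 is ≈0.5 percentage points at 95%
  base coverage, shrinking as base coverage rises.  Increments below ~0.5pp
  per cell should therefore only be expected when intervals mildly
  over-cover.
* At desk scale each level × tertile cell carries an additional ±0.1–0.15pp
  Monte-Carlo noise, so per-cell increments scatter around the systematic
  value.

## Numerical and degenerate-input choices

* Signed-rank: zero differences are excluded (classical treatment); an
  all-zero difference vector gives statistic 0.  Fewer than 2 samples is an
  error.
* Dynamic test: requires ≥ 3 distinct covariate values; a constant LFC
  within one replicate contributes correlation 0 rather than NaN.
* Differential test: both groups need ≥ 2 samples.
* Filters: exact-equality tolerance 1e-8; quant tables are written with 17
  significant digits and read with round-trip float parsing, so write→read
  is the identity on counts.
* All randomness flows from explicit seeds (`TestConfig.seed`, the
  simulator seed); results are bit-reproducible.
* Tertile binning with < 3 features yields empty bins reported as NaN.

## Known limitations

* The permutation tests need several samples to have any resolution
  (2^S sign-flip configurations for the global test); S ≥ 6–10 is sensible.
* Storey's π₀ on strongly discrete p-value distributions (tiny F × n_perm)
  can be unstable; the estimate is clipped but n_perm should be raised for
  small feature sets.
* TSS grouping reveals shared-promoter regulation; isoform-specific AI
  driven by splicing or NMD is diluted by any TSS/gene aggregation and is
  better served by splice-event-level grouping, which this package does not
  implement.
* The beta-binomial comparator uses point estimates only — that is its
  purpose — and its error control degrades exactly where inferential
  uncertainty is high.
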