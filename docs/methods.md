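# Methods

## Transcript-size reference

Every diagnostic is anchored to a table assigning one length in base pairs
to each gene. Annotation sources list multiple transcript variants per
gene, so lengths are collapsed: mRNA (and unclassified) genes take the
length of transcript **variant 1** — quantification pipelines that report a
single value per gene id effectively measure the dominant variant, and
averaging across variants would blur the size axis — while lncRNA genes,
whose variant annotation is less mature, take the **arithmetic mean** of
their listed lengths, rounded half-up to an integer (lengths are base
pairs). A gene with no rank-1 record under the variant-one rule raises an
error rather than guessing; a gene annotated with conflicting biotypes is
likewise an error. GTF input computes transcript length as the sum of exon
widths; because GTF carries no variant numbering, ranks are assigned by
order of first appearance within the gene, which matches the convention of
listing the reference variant first but should be checked against the
source annotation.

Lengths are profiled on a fixed grid of 200 equal bins in log₁₀ bp over
[0, log₁₀ 360000], a bin width of log₁₀(360000)/200 ≈ 0.028. Bins are
half-open [left, right) with the last bin closed; lengths above the grid
clamp to the last bin with a logged warning (the reference inventory tops
out at ~348 kb, but user annotations may not). The grid upper bound is kept
at exactly log₁₀(360000) rather than a rounded 5.556 so that the printed
0.028 increment is the rounding of the true width, not the definition.

## Filtering and normalization cascade

The cascade runs in a fixed, logged order:

1. **Raw-count screen** — genes with mean raw count < 3 are dropped before
   any length normalization; below that depth a TPM value is mostly noise.
2. **TPM conversion** — TPM(g, j) = 10⁶ · (c(g,j)/L(g)) / Σₕ (c(h,j)/L(h));
   columns sum to 10⁶ by construction.
3. **Detection floor** — TPM cells < 0.1 are designated 0 (not removed);
   zeros are excluded later from log-space fits rather than offset-shifted,
   matching the > 0.1 inclusion rule used for per-sample regressions.
4. **Mean-TPM omission** — genes whose post-floor mean TPM is < 0.1 are
   omitted.
5. **Common-total scaling** — for cross-cohort comparison each column is
   rescaled to sum to 200,000 counts; with 8,721 genes the per-gene grand
   mean is then exactly 200000/8721 ≈ 22.93 TPM, a useful bench check.

The cascade is idempotent: re-running it on its own output removes nothing.
Duplicate gene ids are collapsed by summation before the cascade, which
conserves per-sample totals (the alternative — keeping the first or the
largest row — discards signal silently). Median-of-ratios size factors
(factor = per-sample median of gene ratios to the gene's across-sample
geometric mean, computed over genes positive in all samples; even counts
take the midpoint of the central ratios) are exposed as a separate step
rather than fused into the TPM conversion, since source matrices may arrive
already normalized; factors are defined only up to the geometric-mean
normalization, so only factor *ratios* are meaningful.

## Regression diagnostics

Both dataset-level fits are ordinary least squares in log₁₀–log₁₀ space:
log₁₀(mean TPM) on log₁₀(L), and log₁₀(CV) on log₁₀(L). The log response
scale is the only one consistent with intercepts of magnitude ~3 alongside
slopes of magnitude ~1 over a length range of 200–30,000 bp. CV uses the
sample (n−1) standard deviation; means and SDs include floored zeros, and
genes with zero mean (or zero CV, for the CV fit) are excluded with the
exclusion count reported. Slope standard errors are the classical OLS
estimator; transcripts are equally weighted. Per-sample fits regress
per-cell TPM (not per-gene means) over cells above the detection floor,
so each sample's slope/intercept is an independent observation for the
cross-cohort ANOVA. All slope diagnostics are invariant to rescaling every
sample by a common factor, and a constant multiplicative shift in TPM moves
only the intercept.

## Cross-cohort inference

Per-sample slopes (and intercepts) are compared across cohorts with a
one-way fixed-effects ANOVA and the Student–Newman–Keuls stepwise range
procedure. SNK orders the group means and tests the widest span first; a
pair spanning r ordered means uses q = (m₍hi₎ − m₍lo₎)/√(MSW/ñ) against the
studentized-range quantile at (1 − α, r, df within), where ñ is the
harmonic mean of the two group sizes — the Tukey–Kramer-style adaptation
for unbalanced designs such as 9/12/35 samples, for which no exact SNK rule
exists. A span retained as homogeneous protects every enclosed pair, which
enforces the procedure's stepwise consistency; with two groups the test
reduces exactly to the pooled-variance t-test (q = t√2).

The studentized-range CDF is computed as
P(Q ≤ q) = ∫₀^∞ f(s) · R_k(qs) ds, where s = χ_df/√df with its closed-form
density f, and R_k(r) = k ∫ φ(z)[Φ(z) − Φ(z − r)]^{k−1} dz is the CDF of
the range of k standard normals. The inner integral uses a fixed 256-node
Gauss–Legendre rule on |z| ≤ 9 (tail mass < 10⁻¹⁸), vectorized; the outer
integral uses adaptive quadrature; quantiles invert the CDF by bisection to
1e-8. Accuracy is validated two ways in the test suite: against
`scipy.stats.studentized_range` (agreement ~1e-9) and against a
200,000-draw Monte-Carlo simulation of the defining ratio. Infinite df
collapses to the plain normal-range CDF.

## Synthetic cohorts

The generator emulates the matrix-level structure the diagnostics assume,
with every parameter recorded as ground truth:

- **Lengths** — a per-biotype log₁₀-normal mixture: mRNA (mean 3.4, sd
  0.35 in log₁₀ bp, i.e. a ~2.5 kb mode) and lncRNA (mean log₁₀ 550 ≈
  2.74, sd 0.25), mixed at a 25.5% lncRNA fraction (the proportion of
  lncRNAs in a 19,608 mRNA + 6,725 lncRNA reference inventory), clipped to
  the reference extremes [180, 43816] bp.
- **Abundances** — log₁₀-normal (mean 1.5, sd 0.6), emulating a
  common-core panel of transcripts detectable in every cohort; such panels
  are dominated by moderately-to-well-expressed genes, so the 0.1-TPM floor
  rarely binds. Wider abundance spreads (sd ≈ 1) add the weak tail seen in
  full detected inventories and are used in tests that exercise
  detection loss.
- **Size bias** — expected TPM ∝ abundance · (L/1000)^β · π(L). The 1 kb
  reference point makes intercepts interpretable. π is a logistic
  capture-efficiency curve in log₁₀ L rising around `dropout_mid_bp`
  (default 800 bp, steepness 4): a graded, multiplicative capture loss,
  which keeps expectations analytic; a per-cell Bernoulli dropout mode is
  available behind a config flag. Setting the midpoint below the minimum
  length (e.g. 1 bp) disables dropout.
- **Noise** — observed log₁₀ TPM adds normal noise with
  sd = σ₀ + γ·(log₁₀ L − mean log₁₀ L) (defaults σ₀ = 0.15, γ = 0);
  positive γ produces the rising CV–size profile of a size-biased cohort.
- Columns are rescaled to 10⁶ before the detection floor is applied,
  mirroring the pipeline's unit convention. One named generator
  (`numpy.random.default_rng`, PCG64) seeded per cohort makes every
  artifact byte-reproducible.

What the generator does **not** emulate: read-level sampling, alignment
and multimapping artifacts, library amplification chemistry, globin/rRNA
carryover, GC effects, and correlated gene–gene structure. Passing
recovery tests therefore demonstrate that the estimators are correct for
the assumed data-generating mechanism, not that real cohorts satisfy it.

Calibration notes, verified in the test and acceptance suites: with
dropout off and γ = 0 the expression–size slope estimator recovers
β ∈ {−1, −0.6, 0} with mean bias within 2 Monte-Carlo standard errors over
20 seeds at 10,000 genes × 12 samples; with dropout on at its defaults the
fitted slope is shallower than β (the logistic's short-end tilt is
positive), which is the intended signature — extraction dropout and
power-law bias are distinct mechanisms with distinct fingerprints.
Moderate dropout *increases* the count of weakly expressed (< 1 TPM)
short transcripts (well-expressed genes migrate into the weak band) while
strictly decreasing the count of *detected* short transcripts; only the
latter is a monotone signature of dropout.

## Numerical and degenerate-input choices

- Half-open bins, ties at an edge go to the higher bin; the grid maximum
  belongs to the (closed) last bin.
- lncRNA averaged lengths round half-up; a gene with several rank-1
  records keeps the first in input order (logged).
- ANOVA with zero within-group variance reports F = 0, p = 1 when the
  between-group variance is also zero, else F = ∞, p = 0.
- Regressions require ≥ 3 usable points; per-transcript statistics require
  ≥ 2 samples; per-sample fits with < 3 usable cells are flagged and
  excluded rather than fatal.
- Matrices carry an explicit unit tag (`raw_counts` or `tpm`); operations
  that need a specific unit raise rather than silently converting. A
  TPM-only input skips the raw-count screen (there is nothing to screen)
  and runs the floor and omission steps.
- Exit codes: 0 success, 2 validation error, 3 data error; all thresholds
  are echoed into each bundle's report for provenance.

## Problem sizes

Simulation-backed checks run at 10,000 genes × 12 samples with 20
replicate seeds (the scale at which Monte-Carlo error is small enough to
resolve slope biases of ~0.01), and distributional oracles use 200,000
draws; the full test suite and the acceptance script each complete in well
under a minute on one core.

## Known limitations

- The variant-one rule depends on the annotation's variant numbering; for
  GTF input the rank-by-first-appearance heuristic may not match the
  curated numbering of other sources.
- SNK on heavily unbalanced designs uses the harmonic-mean adaptation; its
  familywise error under partial nulls is not exactly α (a known property
  of SNK itself, which the test suite checks only under the complete
  null).
- The diagnostics *measure* size bias; they do not correct it, and no
  batch-correction is attempted or implied.
- Recovery fractions require a reference size list covering the queried
  range; an empty reference range is an error, not a zero.
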