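# rnasizebias

Transcript-size extraction-bias diagnostics for whole-blood bulk RNA-seq.

## The problem

RNA extraction protocols differ widely in how completely they recover RNA
from whole blood, and incomplete extraction preferentially loses short to
midsized transcripts (including most lncRNAs, whose size distribution peaks
near 550 bp). Because TPM normalization divides counts by transcript length,
a sequencing run over uniformly recovered RNA should show **no systematic
relationship between a transcript's TPM and its length**. When extraction is
size-biased, that relationship tilts — and so does the relationship between
measurement variability and length. These tilts propagate into downstream
analyses as "batch effects" that no amount of post-hoc normalization
removes, because the transcripts were never captured in the first place.

This package scores gene × sample expression matrices for exactly this
failure mode. It is aimed at anyone comparing or pooling bulk RNA-seq
cohorts that were extracted with different protocols (PAXgene, Tempus,
phenol-based, column-based, ...).

## The diagnostics

For a matrix of TPM values over genes with known transcript lengths
*L<sub>g</sub>* (bp):

- **Expression–size slope** — the OLS slope of log₁₀(mean TPM) on
  log₁₀(L). Slope ≈ 0 is the proportional-recovery ideal; negative slopes
  indicate relative signal loss tied to transcript size.
- **CV–size slope** — the OLS slope of log₁₀(CV) on log₁₀(L), where CV is
  the per-gene coefficient of variation (sd/mean, n−1 denominator) across
  samples. A flat profile means experimental error is independent of
  transcript size.
- **Per-sample slopes/intercepts** — the same fit per sample column over
  cells with TPM > 0.1, compared across cohorts with one-way ANOVA and the
  Student–Newman–Keuls (SNK) stepwise range test. The studentized-range
  distribution behind SNK is computed by numerical integration and checked
  against an independent Monte-Carlo oracle.
- **Size-resolved inventories** — 200-bin log₁₀ size histograms,
  weak-expression (TPM < 1) profiles, recovery fractions against a
  reference size list, and the common core of transcripts detected in all
  cohorts.

Inputs pass through a fixed, documented cascade: duplicate gene ids are
collapsed by summation; genes with mean raw count < 3 are dropped; counts
are converted to TPM (columns sum to 10⁶); TPM cells < 0.1 are designated
0; genes with post-floor mean TPM < 0.1 are omitted; matrices are rescaled
to a common total of 200,000 counts before cross-cohort comparison.
Median-of-ratios (DESeq-style) size factors are available as a separate
normalization step.

A synthetic-cohort generator produces matrices with known injected bias —
a power-law length exponent β on expected TPM, logistic short-transcript
capture dropout, and size-dependent noise — so every estimator can be
validated against ground truth.

## Worked example

Simulate a size-biased (β = −0.65) and an unbiased (β = 0) cohort, run the
QC cascade on each, and compare:

```sh
cat > biased.yaml <<EOF
n_genes: 5000
n_samples: 12
bias_beta: -0.65
dropout_mid_bp: 1
seed: 7
EOF
rnasizebias simulate --config biased.yaml --out sim_biased
rnasizebias qc --matrix sim_biased/matrix.tsv --sizes sim_biased/size_table.tsv \
    --unit tpm --label biased --out qc
# ... same for an unbiased config (bias_beta: 0.0, seed: 8) ...
rnasizebias compare --bundle qc/biased --bundle qc/unbiased --out comparison.json
```

which prints:

```
biased: n=5000 slope=-0.6508 cv_slope=-0.0042 mean_cv=0.341
unbiased: n=5000 slope=+0.0078 cv_slope=-0.0070 mean_cv=0.341
common core: 5000 transcripts
slope ANOVA: F=135965.13 df=(1, 22) p=3.34e-43
slope SNK subsets: biased; unbiased
```

Reading the numbers: the biased cohort's expression–size slope (−0.6508)
recovers the injected β = −0.65 — TPM falls about 4.5-fold per decade of
transcript length — while the unbiased cohort sits at ≈ 0, the value
expected when counts are proportional to transcript size. The ANOVA and SNK
on the 12 per-sample slopes per cohort place the two cohorts in separate
homogeneous subsets: the size-bias difference is far larger than
within-cohort sample variation. Full per-dataset details (slope standard
errors, r², CV fits, filter report, weak-expression totals) are in each
bundle's `regression_summary.json`.

The same `qc`/`compare` workflow applies to real matrices: point
`--matrix` at a gene × sample TSV/CSV of raw counts (`--unit raw_counts`,
the default, enables the full filter cascade including TPM conversion) and
`--sizes` at a transcript-size TSV, which can be built from a GTF or from
per-variant size lists with `rnasizebias.reference_sizes` (variant-one rule
for mRNA, averaging for lncRNA).

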