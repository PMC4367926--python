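# Methods

This note documents the statistical procedure `germcourse` implements,
the modeling assumptions behind its synthetic-data generator, the
defaults and numerical conventions, and what the validation suite does
and does not establish about real array data.

## Experimental design assumed

A common-reference two-channel time course: every array hybridizes one
sample (Cy3) against the same reference (Cy5), where the reference is a
pooled RNA mixture from **all** time points. The pooled reference makes
the expected log-ratio of a temporally constant gene zero at every time
point, and makes log-ratios comparable across arrays up to array-level
location/scale distortion. The default design has 13 time points —
dormant spores (t1), heat-activated spores (t2; 10 min at 50 °C used to
synchronize germination), then every 30 min up to 5.5 h (t3..t13) —
with 4 replicate arrays per time point (the experiment this emulates
used at least three biological and technical replicates). Inputs are
per-gene signals; probe-to-gene collapsing is assumed to have happened
upstream and is not attempted.

## Normalization

* `Log2Ratio = log2(Cy3/Cy5)`, masked where either channel is missing
  or non-positive.
* Equalization maps each array by
  `x ↦ (x − median_a)/MAD_a · MAD* + median*`. MAD is the **raw**
  median absolute deviation — no 1.4826 normal-consistency factor,
  which would cancel in the equalization anyway. The targets are the
  median of the per-array medians and of the per-array MADs: robust,
  symmetric, and exactly idempotent. An array with zero MAD cannot be
  scale-equalized and is a hard error (such degenerate inputs arise
  only in noise-free simulations; see the pipeline toggles below).
* Tail trimming masks, per array, values strictly below the `tail`
  quantile or strictly above the `1 − tail` quantile of that array's
  unmasked values (default `tail = 0.02` per tail — the plain reading
  of trimming "the 0.02 quantile of the least and the most intensive"
  values; 2%-of-total was the alternative reading). Quantiles use
  linear interpolation between order statistics (numpy's default), so
  results are bit-reproducible. Masking is one-shot: quantiles are
  computed once on the input, not recomputed after masking. Cells are
  masked, never whole genes — a gene trimmed on one array still
  contributes its other arrays.
* Normalized log-ratios are exponentiated base-2 back to the ratio
  scale ("Normalized Ratios").

## Replicate outlier rejection

Per gene and time point, the surviving replicate Normalized Ratios are
screened: fewer than 3 values are left untouched, 3–9 values go to
Dixon's Q-test, 10 or more to Peirce's criterion. The boundary case
n = 10 is assigned to the large-sample method (configurable via
`dixon_max`; the Q-test table extends to 10). The tests are applied to
Normalized Ratios — the quantity whose mean defines the expression
level — rather than to log-ratios; this is a documented choice, not a
unique reading.

* **Dixon's Q**: classical single-outlier r10 form. `Q = gap/range`
  for whichever extreme shows the larger gap to its neighbour; reject
  iff Q exceeds the two-tailed critical value (Rorabacher 1991 table;
  default confidence 0.95, the conventional choice). At most one value
  is rejected; a zero range rejects nothing.
* **Peirce's criterion** (Gould's algorithm, m = 1 unknown): for
  k = 1, 2, ... suspects, the squared maximum allowable deviation ratio
  x² is solved by fixed-point iteration between
  `R = exp((x²−1)/2)·erfc(x/√2)` and
  `x² = 1 + (n−1−k)/k·(1 − λ²)`, `λ^(n−k) = Q^n/R^k`
  (tolerance 1e-10, max 100 iterations; non-convergence is an error
  with diagnostics). All values with `|x_i − mean| > x·s` are rejected,
  with s the n−1 sample standard deviation; k grows while at least k
  points are rejected. Rejection is capped so at least two replicates
  always survive. The test suite checks the iteration against an
  independent bracketed root-finding oracle on a fixed battery of
  sequences.

## Highly expressed filter

The overall expression level of a gene is the median of all its
unmasked sample-channel signals across every replicate and time point.
The keep threshold is the first quartile of those per-gene levels
(same interpolation convention as above); genes at or above it are
kept. A below-threshold profile is *rescued* when its maximum
per-time-point median sample signal (its peak) both reaches the
threshold and stands at least `rescue_ratio` (default 4) times above
the gene's own overall level. The rescue rule is a deterministic
stand-in for what was originally a manual inspection for "significant
peaks"; `rescue_ratio` is a free parameter with no counterpart in the
original procedure. The filter operates on raw sample-channel signals,
before normalization.

## Differential expression

Expression level = mean of the replicate Normalized Ratios at a time
point (missing if no replicate survives). The differential profile is
the sequence of 12 consecutive-interval ratios. Significance comes from
a two-sided two-sample t-test on the replicate Normalized Ratios of the
two time points — pooled-variance Student's by default ("standard
t-test for equality of means"), Welch optional. Sides with fewer than
two replicates give a masked p-value. Degenerate zero-variance pairs
take the limit values: p = 1 when the means are equal, p = 0 otherwise
(this is what makes noise-free simulations behave exactly). A call is
*enhanced* iff p < 0.05 and ratio > 2, *diminished* iff p < 0.05 and
ratio < 1/2, all strict — a ratio of exactly 2 is not a call. No
multiple-testing correction is applied by default, matching the
original raw-p procedure; Benjamini–Hochberg is opt-in (`bh=True`).
Tests run only on genes passing the highly expressed filter.

## Pathway and regulator summaries

Calls are joined to a user-supplied frozen KEGG snapshot (TSV of
gene → pathway → functional group; a gene may be in several pathways, a
pathway in exactly one group). A pathway is *activated* at an interval
when **more than** `pathway_gene_threshold = 3` of its genes are
enhanced there (strict, per the ">3 genes" convention); deactivation is
analogous on diminished counts. Group summaries report
`100 × changed genes in group / total genes in group` per interval, and
groups whose whole-course changed-gene count is below
`group_min_changed = 3` are flagged excluded. The two thresholds look
inconsistent (">3" vs "fewer than 3") but are kept as separate literal
parameters rather than harmonized. Sigma-factor tables keep only
factors with at least one call, ordered by earliest enhanced interval,
ties broken by descending fold at that interval. Unmapped called genes
are tallied separately, never dropped silently.

## Synthetic data generator

`generate_experiment(SimulationConfig)` emulates the design:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes on the array |
| `design` | 13 × 4 | study design, 4 replicates per time point |
| `baseline_log_mean` | 10.0 | log2 true abundance center (signal units ≈ 1000, the scale at which the real quartile cutoffs sat) |
| `baseline_log_sd` | 1.5 | between-gene abundance spread (log2) |
| `noise_log_sd` | 0.3 | replicate multiplicative noise (log2), per channel, independent |
| `array_shift_sd` | 0.2 | per-array additive shift of the log-ratio |
| `array_scale_range` | (0.8, 1.25) | per-array multiplicative scale of the log-ratio |
| `planted_effects` | () | (gene, interval, fold) step changes |
| `outlier_fraction` | 0.0 | fraction of cells hit by ±`outlier_magnitude_log2` (4.0) on the log2 sample signal |
| `dormant_pool_decay` | 4.0 | fold by which the dormant pool exceeds the baseline at t1 |
| `dormant_pool_fraction` | 0.0 | fraction of genes carrying that pool |

Sample channel = true abundance × log-normal noise; reference channel
per gene = the time-average of its true abundance × its own independent
noise (the pooled-mixture construction, which centers unchanged genes
at log-ratio 0). Array distortion is applied to the log-ratio, so
normalization has something real to remove. A planted effect
multiplies the gene's abundance at every time point after its interval
— a step change whose true consecutive ratio equals the planted fold at
exactly one interval. The dormant pool is a deterministic elevated
t1 level decaying at the first interval, mimicking stored spore mRNA
degraded on rehydration. True calls are derived from the true abundance
profile with the same strict >2-fold rule the caller uses, so ground
truth and calling rule cannot drift apart. All randomness flows from
one `numpy` generator seeded by `seed`; identical seeds give
bit-identical output.

What the generator does **not** model: intensity-dependent dye bias
(the vendor-side LOWESS step is upstream and out of scope), spatial
array artifacts, probe-level effects, or autocorrelated biological
drift. Passing tests therefore certify the arithmetic and decision
rules of the pipeline under the stated noise model, not robustness to
every artifact of real hybridizations.

## Validation choices and problem sizes

* **Type-I calibration**: a null simulation (5,000 genes, 13 × 4
  design, noise 0.3, no planted structure, no array distortion —
  the `generate_null_experiment` harness) is normalized and tested;
  the fraction of gene-interval tests with p < 0.05 is compared with
  the nominal level within ±3 binomial standard errors of ~60,000
  tests. The fold filter must strictly reduce the called fraction.
* **Noise-free identity**: with zero noise and distortions, pipeline
  calls must equal ground truth exactly. Equalization and trimming are
  disabled for that configuration (`center_scale=False`, `tail=0`):
  a distortion-free, noise-free array has zero MAD (equalization is
  undefined) and any trimming would mask the planted signal itself,
  so the degenerate-but-exact configuration is the meaningful one.
* **Noisy recovery benchmark**: 1,200 genes, 4-fold step activations on
  30% of genes (about the per-direction change prevalence seen in
  germinating spores), timed mostly at the dormancy-exit and
  growth-burst intervals, on a homogeneous baseline so planted effects
  are the only systematic structure — the benchmark measures the
  calling machinery, not the abundance filter, whose interplay with
  heterogeneous baselines is exercised by its own tests. The
  corrupt-cell rate is 4% (±, i.e. 2% per tail), the tail mass the
  0.02-per-tail trim is designed to absorb. The bar is sensitivity
  ≥ 0.9 and false-discovery proportion ≤ 0.1 against ground truth.
* Problem sizes (1,200–5,000 genes) keep the full suite in seconds
  while leaving every rate estimate with comfortable Monte-Carlo
  resolution.

## Known limitations

* Tail trimming interacts with strong real signal: a gene whose
  log-ratio is extreme *because it genuinely changed* can lose cells at
  its extreme arrays when few other genes change. With realistic
  numbers of changing genes the per-array tail is shared and the effect
  is small, but on sparse-signal data trimming can cost sensitivity —
  inherent to the procedure, not an implementation artifact.
* The first-quartile filter removes 25% of genes by construction;
  changes planted on low-abundance genes are lost unless the peak
  rescue fires. This mirrors the original procedure's scope (only
  "highly expressed" profiles are analyzed).
* Dixon's Q rejects at most one replicate per set; two coincident
  outliers in a small replicate set can mask each other (the classical
  limitation of the single-outlier form).
* P-values are raw by default; interval tests share time points and are
  not independent across the profile.
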