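# Methods

`sccalink` implements a two-block multivariate association pipeline: a
behavioral/questionnaire block is related to a regional cortical-thickness
block by sparse canonical correlation analysis (sCCA), with permutation
inference, a resampling reliability battery and covariate-adjusted post hoc
reporting. This note documents the models, the defaults and the places where
the design was genuinely open.

## Task scoring

Raw data are likelihood ratings in [0, 100], one per participant x character
x event, with four characters (student, elderly, businessperson, alcoholic)
and 32 events (16 desirable, 16 undesirable).

**Cleaning.** Ratings equal to 1, 50 or 99 after rounding are treated as
anchor/default responses (50 is the scale default and indistinguishable from
non-responding). The three flag values are pooled into a single
per-participant flag proportion, computed over answered trials; participants
whose proportion exceeds the sample mean + 3 SD (sample SD, n-1 denominator)
are excluded. Unanswered trials are then dropped. Pooling (rather than three
separate 3-SD rules) was chosen because the exclusion is one procedure
targeting one behavior — leaning on salient scale points. The rule is
applied in a single pass; re-running the cleaner on already-cleaned data is
a supported no-op in practice, but the 3-SD rule is not mathematically
idempotent for adversarial inputs (removing an extreme responder shrinks
the SD, which in principle can expose a new extreme). Iterated exclusion was
deliberately not implemented.

**Eight measures per participant.** `desirable_avg` and `undesirable_avg`
are raw-scale means over all desirable resp. undesirable trials, pooled
across characters. Per-character optimism biases are computed on
z-standardized ratings — all of a participant's answered ratings, both
valences and all four characters, standardized together with the sample SD —
as mean(z desirable) - mean(z undesirable) for that character.
`warmth_bias` = (student + elderly) - (businessperson + alcoholic) biases;
`bias_magnitude` = student + elderly + businessperson - alcoholic biases
(the alcoholic bias is typically negative, so it enters inverted). The raw
averages enter the non-imaging block on the raw scale by default; since all
block columns are z-scored before sCCA, this choice only matters if the
preparation step is customized.

## Sparse CCA

Both blocks are prepared by (optional) residualization on covariates via
OLS, then column-wise z-scoring (mean 0, SD 1, sample SD). Blocks must share
participant order; missing values are rejected.

**Algorithm.** Successive sparse rank-one factors of the cross-product
matrix `C12 = X1'X2/(n-1)` under `||u||_2 <= 1`, `||v||_2 <= 1`,
`||u||_1 <= c1`, `||v||_1 <= c2` (penalized matrix decomposition).
Alternating updates `u ∝ S(W1 C12 v, δ1)`, `v ∝ S(W2 C12' u, δ2)`, where
`S` is soft-thresholding and each threshold is the exact level at which the
normalized vector's L1 norm meets its bound (solved in closed form per
support segment rather than by bisection — the two agree to ~1e-11; the
closed form is used because resampling procedures perform thousands of
refits). After each mode, `C12` is deflated by `d_k u_k v_k'`,
`d_k = u_k' C12 v_k`.

**Within-block covariance shrinkage.** `W_j = ((1-g) C_jj + g I)^{-1}` per
block. At the default `g = 1` the working within-block covariance is the
identity — the standard penalized-matrix-decomposition assumption, and the
appropriate regime when variables rival or outnumber participants (24 and
62 variables at n = 47; the unshrunk thickness covariance is singular
there). At `g = 0` on full-rank blocks the loose-penalty limit of the same
iteration is exactly classical CCA (the generalized-eigenvalue solution),
which is how the implementation is validated against an independent oracle.
Intermediate values interpolate.

**Conventions and numerics.** Initialization is the leading right singular
vector of the working matrix (deterministic; the seed argument exists only
for degenerate ties). Convergence: maximum absolute weight change < `tol`
(default 1e-6), `max_iter` = 500, with a warning (never an exception) on
non-convergence. Sign convention: the canonical correlation is made
non-negative by flipping `v` alone if needed, then `(u, v)` are flipped
jointly so the largest-|weight| entry of `u` is positive. Reported
`canonical_correlation` is always the Pearson correlation of the two
variates, not `d`.

**Variance explained** of mode k is `d_k^2 / Σ_j d_j^2` over the computed
modes — shares of the captured (deflated) cross-covariance, summing to 1.
This reproduces the qualitative behavior that later modes carry less and
supports a "first m of K modes carry > 99%" truncation decision. It is a
definition over computed modes, not a share of total data variance.

**Penalty selection.** No principled default exists for `(c1, c2)`; when not
supplied, a small grid of L1 fractions (`c = 1 + f (sqrt(p) - 1)`,
f in {0.2, 0.4, 0.6, 0.8}) is scored by mean held-out first-variate
correlation over 5 random half-splits, and the best pair is used. Fixed
penalties can be given in the config and are recommended for confirmatory
runs.

## Permutation inference

The null of no cross-block association is simulated by shuffling the rows of
block 2 relative to block 1 — participant relabeling, which preserves both
within-block covariances. The full model (same penalties, same number of
tested modes, default 7 of the 10 fitted) is refitted per permutation;
mode-k observed statistics are compared to mode-k permuted ones, with
add-one p-values `(1 + #{null >= obs})/(1 + B)` (minimum attainable p is
`1/(B+1)`). Default B = 10 000; alpha = 0.05 per mode. Penalties are held
fixed across permutations: the test addresses the association, not the
tuning. A maxT variant (comparing each observed mode against the null of the
per-permutation maximum) provides family-wise control as an option, since
the per-mode convention applies no multiplicity correction. Permutation
refits run through a batched implementation of the same iteration (stacked
cross-product matrices, active-set convergence), which is exercised against
the scalar path in the tests.

## Reliability battery

Canonical modes permute and change sign freely across refits, so every
resampled model is first matched to the full-sample model by maximal
absolute cosine between concatenated weight vectors `[u; v]` (optimal
assignment), then sign-aligned.

* **Leave-one-out:** refit without each participant; influence = full-sample
  r minus drop-one r per mode; flag participants whose influence is more
  than 3 SD from the mean influence of any mode.
* **Split-half:** default 10 000 resamples (scaled down in the test suite,
  documented per test); random disjoint halves, the training half getting
  the extra participant when n is odd; each half standardized on its own
  statistics; training weights applied to the held-out half; out-of-sample
  variate correlation recorded per matched mode. Degenerate halves (constant
  column) are redrawn and counted.
* **RR-score:** for a mode on held-out data, the loading vector (correlation
  of every variable with its own block's variate, both blocks concatenated)
  is correlated with the full-sample loading vector. Its mean/SD across
  resamples summarize loading stability. The exact formula behind the
  published score is not public; this operationalization — correlation of
  variable-to-variate correlation profiles — is this package's
  reconstruction and its main interpretive choice. Sign invariance under a
  joint flip of a mode's weights is guaranteed by aligning to reference
  weights before computing loadings.
* **Overfitting index:** mean(training r - test r) per mode. The
  sample-size check subsamples participants at a grid of n, averages the
  mode-1 index over repeats, and labels the curve "marginal" when the index
  at the largest n is below a configurable threshold (default 0.15).

## Post hoc reporting

Partial correlations between selected measures and all 62 regions control
for height, weight, BMI, age and sex: both sides are residualized on the
covariates plus an intercept (least-squares pseudoinverse, so the exact
collinearity of BMI with height and weight degrades nothing beyond a
warning) and the residuals correlated; p-values come from the t distribution
with n - 2 - q degrees of freedom; the reporting threshold is uncorrected
p < 0.001. A side fully explained by the covariates is reported as zero
partial correlation. Weight tables list variables with |weight| > 0.2 in
descending magnitude ("more than 0.2" is read as absolute value, since
negative contributors are conventionally reported in such lists); the full
table is always written alongside.

## Synthetic data

The generator emulates the target study's shape: n = 47 participants, a
24-variable non-imaging block (the 8 task measures plus 16 questionnaire
scale scores: BIS/BAS, COS optimism/pessimism, LOT-R optimism/pessimism,
ERQ suppression/reappraisal, PANAS positive/negative, RSES, and five BFI
dimensions), 62 DKT-atlas thickness regions on a 1.5-4.5 mm scale, and a
covariate table (age ~ N(23.1, 4.0) years, ~40% male, sex-dependent height
and weight, derived BMI).

**Cross-block structure.** Gaussian latent factors: per planted mode,
`z'_k = ρ_f z_k + sqrt(1-ρ_f²) ε`, block 1 = Σ strength·z_k·u_k' + noise,
block 2 likewise with `z'` and `v_k`; `u_k, v_k` are sparse unit-L2 loadings
(default supports: 5 of 24 and 8 of 62). Default per-block noise SD is 0.3
(variables on a support carry ~92% factor variance). By default the
inter-factor correlation is calibrated as
`ρ_f = latent_correlation / (α1 α2)` with attenuation
`α_j = strength/sqrt(strength² + noise_j²)`, so the requested
`latent_correlation` is the *population canonical correlation* between the
blocks; requests beyond the attenuation ceiling raise an error. Calibration
is exact for non-overlapping supports and a good approximation otherwise.
The default spec plants a single mode with canonical correlation 0.7.

**Task responses.** Rating = character/valence mean + participant intercept
(SD 8) + trial noise (SD 10), clipped to [0, 100]; default character means
(desirable, undesirable): student (62, 38), elderly (61, 39), businessperson
(55, 47), alcoholic (44, 54), reproducing the canonical ordering of group
biases (student ≈ elderly > businessperson > 0 > alcoholic). ~1% of trials
are unanswered; a configurable fraction of participants answers 50
throughout, to exercise the cleaning rule. When the full study is generated
(`generate_study`), each participant's desirable-undesirable gap is scaled
by `1 + 0.25·z_1`, coupling the task-derived measures to the first planted
factor so the end-to-end pipeline (scoring included) sees a real
association; the questionnaire file carries the planted block-1 loadings on
its 16 columns exactly.

**What the generator does not emulate:** realistic within-block covariance
(questionnaire scales and neighboring cortical regions correlate strongly in
real data; here off-support correlations are zero), spatial structure of the
thickness map, non-Gaussian rating distributions beyond clipping, and item-
level questionnaire noise. Passing tests therefore demonstrate correctness
of the statistical machinery under the generative model it assumes, not
robustness to real-data violations of that model.

## Problem sizes used in the checks

The verification suite runs the scoring oracle at 100 participants,
classical-CCA equivalence on 50 instances (n = 60, p = 4/5), planted-mode
recovery on 100 replicates at n = 500 (penalties 1.45/1.75 against supports
of 3 and 4), permutation calibration over 500 null datasets at the study
shape with B = 199, reliability ordering at n = 200 with three batches of
100 resamples, and a full study-shape pipeline run with B = 199 and 200
split-half resamples. Mode-truncation concentration (first 7 of 10 modes
> 99%) is demonstrated at n = 1500, where planted structure dominates the
resampling noise floor. These sizes are the package's own verification
choices; the pipeline defaults (B = 10 000, 10 000 resamples) match a
confirmatory analysis.

## Known limitations

* With an active L1 penalty the fit is only piecewise-smooth in the data, so
  leave-one-out influences on duplicated participants are small but not
  machine-zero.
* The PMD regime (`cov_shrinkage = 1`) maximizes cross-block covariance, not
  correlation; its weight vectors are attenuated relative to
  correlation-optimal directions when within-block correlation structure is
  strong. The `cov_shrinkage` dial exposes the trade-off.
* Deflation does not enforce orthogonality of successive variates;
  empirical variance shares can fluctuate mode to mode.
* The RR-score and the sample-size check are reconstructions of verbally
  described procedures (flagged above).
* At the target study's size (n = 47) the permutation test's power to detect
  a single planted mode with population canonical correlation 0.7 is
  marginal and penalty-dependent (roughly 20-60% for mode 1 across
  reasonable L1 bounds in our simulations). Near-threshold p-values at this
  sample size are expected behavior, not a defect; the reliability battery
  carries most of the evidential weight there.
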