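# sccalink

Sparse canonical correlation analysis (sCCA) pipeline linking a block of
behavioral measures — social-optimism-bias scores derived from a likelihood-
rating task plus questionnaire scales — to a block of regional cortical-
thickness values, with permutation inference, a split-half/leave-one-out
reliability battery and covariate-adjusted post hoc reporting.

## Who this is for

Researchers relating two participant-aligned data blocks (e.g. behavior vs.
brain structure) when variables rival or outnumber participants, so that
classical CCA overfits and variable selection is needed. The package covers
the full workflow: cleaning and scoring raw task responses, preparing blocks,
fitting sparse canonical modes, testing them by permutation, screening their
reliability, and reporting covariate-adjusted follow-up correlations. A
synthetic-study generator with planted cross-block modes makes every step
testable against known truth.

## The model

Given standardized blocks `X1` (n x p1) and `X2` (n x p2), each mode k
solves

```
max  u' (X1'X2/(n-1)) v    s.t.  ||u||2 <= 1, ||v||2 <= 1,
u,v                              ||u||1 <= c1, ||v||1 <= c2
```

by alternating soft-thresholded power iterations (penalized matrix
decomposition), with rank-one deflation between modes. The L1 bounds drive
some weights to exactly zero. Each mode yields a pair of participant-level
variates `(X1 u_k, X2 v_k)`; their Pearson correlation is the mode's
canonical correlation. Significance comes from refitting under participant-
relabeling permutations (add-one p-values); reliability from out-of-sample
weight transfer across random half-splits, the redundancy-reliability
(RR) score of loading stability, and leave-one-out influence. A
`cov_shrinkage` parameter interpolates between the identity within-block
covariance of pure PMD (default, suited to p ~ n) and classical CCA
(shrinkage 0, used to validate against a generalized-eigenvalue oracle).
Details, defaults and design choices: [docs/methods.md](docs/methods.md).

The eight task measures per participant: raw-scale mean likelihoods for
desirable and undesirable events; four per-character optimism biases
(mean desirable minus mean undesirable on within-participant z-scored
ratings) for the student, elderly, businessperson and alcoholic characters;
their warmth contrast `(student + elderly) - (businessperson + alcoholic)`;
and the overall bias magnitude `student + elderly + businessperson -
alcoholic`.

## Worked example

```python
import numpy as np
from sccalink import (SyntheticSpec, generate_study, prepare_block,
                      fit_scca, permutation_test, split_half,
                      variance_explained)
from sccalink.scca import FitConfig

study = generate_study(SyntheticSpec(seed=42))   # n=47, 24 x 62 variables
b1raw, b2raw = study["nonimaging"], study["thickness"]
block1 = prepare_block(b1raw.matrix, b1raw.variable_names,
                       b1raw.participant_ids)
block2 = prepare_block(b2raw.matrix, b2raw.variable_names,
                       b2raw.participant_ids)

model = fit_scca(block1, block2, c1=2.5, c2=4.0, n_modes=10)
shares = variance_explained(model)
print("mode-1 r:", round(model.modes[0].canonical_correlation, 3))
print("variance share of first 7 modes:", round(shares[:7].sum(), 3))

results = permutation_test(block1, block2, FitConfig(c1=2.5, c2=4.0),
                           n_perm=999, n_modes_tested=7, seed=0)
print("mode-1 p:", results[0].p_value,
      "| significant modes:", [r.mode_index for r in results if r.significant])

report = split_half(block1, block2, FitConfig(c1=2.5, c2=4.0, n_modes=7),
                    n_resamples=500, seed=0)
print("mode-1 out-of-sample r:", round(np.nanmean(report.splithalf_r[:, 0]), 3))
print("mode-1 RR-score:", round(report.rr_mean[0], 3),
      "+/-", round(report.rr_sd[0], 3))
```

prints

```
mode-1 r: 0.78
variance share of first 7 modes: 0.814
mode-1 p: 0.396 | significant modes: [7]
mode-1 out-of-sample r: 0.382
mode-1 RR-score: 0.822 +/- 0.062
```

The generator planted one sparse cross-block mode with population canonical
correlation 0.7, and the output shows what n = 47 actually buys. The
in-sample mode-1 correlation (0.78) is inflated above the population value,
yet the permutation test does not reject for it — at this sample size a true
r = 0.7 mode is only marginally detectable, and single-seed runs routinely
miss (the one mode the per-mode test does flag here, mode 7, is the kind of
isolated late-mode hit that the `maxT` family-wise option exists to screen
out). What does separate signal from noise at this n is the reliability
battery: the out-of-sample transfer correlation (0.38, far from the ~0 a
null mode gives) and the high, tight RR-score (0.82 ± 0.06) indicate the
mode-1 weights describe structure that survives resampling. This is the
intended reading order — reliability first, in-sample r never.

## Command line

```
sccalink simulate --seed 1 --out data/           # synthetic study inputs
sccalink scores --task data/task_responses.csv --out out/
sccalink run --config config.yaml                # all stages + manifest.json
```

Stages can also be run individually (`fit`, `permute`, `reliability`,
`posthoc`); every stage is seeded from the pipeline seed and the manifest
records config, seeds and input hashes, so reruns are bit-reproducible.

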