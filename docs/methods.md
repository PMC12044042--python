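# Methods

## Overview

`amyenc` implements a systems-identification pipeline for amygdala
function at desk scale.  The scientific object is a *voxel-wise encoding
model*: a linear mapping from a stimulus feature time series (standing in
for deep-network layer activations to a movie) to the BOLD response of
every voxel in a region of interest.  Around that core the package
implements the full analysis arc: hemodynamic convolution, regularized
estimation by partial least squares, cross-validated evaluation with
group inference, validation of model responses against affective-image
ratings, in-silico control of the models by evolutionary activation
maximization of synthesized stimuli, and selectivity analyses of the
synthesized stimuli.

Because the original data (naturalistic-movie fMRI, a pretrained
convolutional feature extractor, a pretrained deep image generator,
licensed affective image sets) cannot ship with a package, a first-class
synthetic-data module generates every input with the statistical
structure the analyses assume.  All claims verified by the test suite are
therefore claims about the *methods*, demonstrated on data whose ground
truth is known — not reproductions of empirical effect sizes.

## Forward model

A session is simulated as

    Y = (X * h) W + E,      E_tv ~ N(0, sigma^2) i.i.d.

where `X` is the T x F feature series, `h` the canonical double-gamma
hemodynamic response function (difference of two gamma densities; peak
delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio 1/6,
sampled at the repetition time and normalized to unit peak), `*` causal
column-wise convolution truncated to T rows, and `W` the F x V
ground-truth weight matrix.  The double-gamma defaults are the widely
used canonical parameterization; region- or subject-specific HRF
estimation is deliberately out of scope.

Ground-truth weights are built from per-region base patterns.  An
orthonormal frame supplies one shared direction and one region-specific
direction per region; a `distinctness` dial in [0, 1] interpolates
between all regions sharing one base (0) and mutually orthonormal bases
(1).  Each voxel adds Gaussian jitter of expected *norm* `jitter_sd`
(default 0.1) relative to the unit-norm base; in a cohort, each subject
first perturbs the population bases by a vector of expected norm
`subject_sd` (default 0.15).  Norm-relative scaling keeps the
signal-to-structure ratio independent of the feature dimension.  Regions
therefore have consistent tuning across subjects — the premise that makes
leave-one-subject-out generalization a meaningful test.

The noise model is i.i.d. Gaussian per voxel and time point.  BOLD
temporal autocorrelation, drift, and spatially shared noise are
deliberately not modeled.  One consequence worth knowing: with i.i.d.
voxel noise, a model trained on the *region-average* time series benefits
from noise averaging and evaluates better than the mean of voxel-wise
performance — the opposite direction from what is typically observed in
real data, where shared noise survives averaging.  The package reports
the comparison (`average_response_model`) but the synthetic world cannot
adjudicate its real-data direction, and no test asserts one.

## SIMPLS estimation

Encoding models are fit with SIMPLS partial least squares (the algorithm
behind MATLAB's `plsregress`, which this family of analyses is usually
run with): successive weight vectors are taken from the dominant singular
direction of the deflated cross-product matrix `S = X0' Y0`, with scores
re-orthogonalized against earlier scores for numerical stability.  Both
blocks are mean-centered, not variance-scaled (scaling is available as an
option).  The dominant direction is extracted from the symmetric
eigenproblem of `S S'`, which is robust where a thin SVD of a nearly
deflated `S` can fail to converge.  A requested component count beyond
`min(T - 1, F)` or beyond the effective rank of the predictor block is
clamped with a warning rather than raised, because real voxel blocks can
be rank-deficient.  At full rank, SIMPLS predictions equal ordinary least
squares; the test suite verifies this to 1e-8 and cross-checks univariate
predictions against an independent NIPALS implementation.

The default is 20 latent dimensions — a regularization choice for
prediction.  The *parameter-recovery* study instead sets the component
count equal to the predictor dimension, because coefficient
identifiability requires the fit to span the full predictor space; with a
rank-limited fit the estimated coefficient matrix can only contain the
projection of the truth onto the retained subspace, whatever the
algorithm.

PLS-DA codes class labels as one-hot indicators (columns ordered by
sorted label), fits the same SIMPLS regression, and classifies by argmax
of predicted indicators, ties broken toward the earlier class —
a deterministic rule for a case the analysis rarely meets.

## Evaluation and inference

Generalization is estimated by k-fold cross-validation (default five
folds) with a seeded *random* partition of time points.  Random
partitioning follows the procedure being modeled; with autocorrelated
noise, temporally contiguous folds would be stricter — irrelevant here
because the generator produces temporally white noise, but worth
remembering for real data.  Per-voxel Pearson correlations between
concatenated held-out predictions and observations are Fisher-transformed
(`atanh`, clipped away from |r| = 1) for group inference.  Voxels with
zero observed variance contribute r = 0 with a logged flag instead of
being dropped, keeping map geometry stable.

Group inference is the two-stage summary-statistics approach throughout:
per-subject estimates, then one-sample t tests across subjects, with
Cohen's d = mean/SD of the subject estimates.  Voxel maps are corrected
by Benjamini–Hochberg FDR at q < 0.05; voxels missing in some subjects
are analyzed case-complete with logged counts.  Subregion performance
(subjects x LB, CM, SF, AStr) is analyzed with a one-way
repeated-measures ANOVA (subject as blocking factor; the sums-of-squares
decomposition is computed directly so degenerate all-equal inputs return
F = 0 rather than 0/0, and is verified against `statsmodels.AnovaRM` in
the tests) plus three planned contrasts — LB vs rest, CM vs {SF, AStr},
SF vs AStr — with weights scaled to unit sum of absolute values so
estimates are comparable across contrasts.

## Affective-image validation

Synthetic affective images are mixtures of a constant RGB field (channel
values uniform in [0.3, 0.7]) and two achromatic sinusoidal gratings, one
at radial frequency 3 (low band) and one at radial frequency 30 (high
band), amplitudes uniform in [0, 0.12] so no pixel clips.  This family
was chosen because its low-level covariates are known analytically.
Normative valence and arousal ratings are linear in the standardized
low-level features plus an independent latent affect factor per rating
dimension (defaults: valence = 1.0·affect + 0.4·power_low + 0.2·median_r;
arousal = 1.0·affect + 0.3·power_high; rating noise SD 0.5), then
standardized to mean 0 / SD 1.  The latent factor gives the validation
regressions a clean signal path, the feature terms a confounded one.

Low-level covariates follow fixed conventions, all configurable: images
are resized to a 128 x 128 working grid before the Fourier transform so
band radii are comparable across inputs; luminance is the
(0.299, 0.587, 0.114) RGB weighting; the DC term is removed by mean
subtraction; band power is the *sum* of |FFT|^2 / N^2 over bins with
centered-spectrum radius < 6 (low, excluding DC) or > 24 (high); channel
medians use the midpoint convention.  With this normalization total power
equals the pixel-count-normalized energy of the mean-subtracted luminance
(Parseval), which the tests verify to 1e-8.

The 8-predictor design (valence, arousal, their interaction, three
channel medians, two band powers) is standardized within each image set;
the interaction is formed from the standardized ratings and then itself
standardized.  Per-subject responses are regressed by OLS with intercept;
a rank-deficient design raises an error naming the collinear columns.
The piecewise valence analysis subsets images by the printed rules —
negative z < 0, neutral |z| < 1, positive z > 1 — which *overlap*; the
implementation follows the rules verbatim rather than guessing a disjoint
intent.

In the recovery study the generating group-level coefficients are
±0.25 on valence, arousal and interaction with between-subject SD 0.25
(|d| = 1, a large effect) and 0 on the five covariates, within-subject
image noise SD 0.5, 20 subjects, 400 images, 50 repetitions.

## Activation maximization

The synthesis loop closes through a fixed generator/extractor pair: the
generator is a seeded random linear decoder from a latent code (default
d_z = 12) to pixel space followed by a logistic squash into [0, 1] (the
zero code renders mid-gray); the extractor projects mean-centered pixels
through a seeded random matrix and tanh to F features.  Session features
for encoding-model fitting are extractor responses to random generator
frames, so the feature geometry seen in fitting is exactly the geometry
the optimizer can reach.

A synthesis target is the mean coefficient column of an encoding model
over a chosen voxel set (whole region by default; single-voxel and
voxel-subset targets are supported), so the objective
`dot(extract(generate(z)), target)` equals the mean centered predicted
activation of those voxels.  Optimization is a (mu/mu_w, lambda)
evolution strategy with log-rank recombination weights and cumulative
step-size adaptation — default lambda 28, mu = lambda/2, initial step
size 1, 100 generations; the batteries use lambda 16 / 30 generations,
which the benchmark shows is ample for this landscape.  The best-so-far
code and objective are tracked, making the reported trace non-decreasing
by construction; on a concave quadratic in 8 dimensions the optimizer
reaches the known optimum within 0.1 in 20/20 seeded runs.

Non-convergence ("the optimization stalled on an identical image") is
operationalized by a two-criterion filter: a run is excluded if its
objective gain over initialization is below `min_gain` (1e-6) or its
final image is within `image_tol` (0.005 mean absolute pixel difference)
of its initialization image.  Both readings of "identical" are thereby
covered; excluded runs never enter downstream analyses.

## Selectivity analyses

Every retained stimulus is re-extracted and scored by every encoding
model, one column per (subject, region), the cell being the mean
predicted activation over the model's voxels.  Classification features
are these cross-response vectors (the figure-caption reading of the
procedure being modeled); the targeted region is decoded by PLS-DA with
seven latent dimensions, generalization estimated by
leave-one-subject-out folds over the *synthesizing* subject.  Confusion
matrices are row-normalized; accuracy is mean ± SE over folds.

Confusion clustering is agglomerative: starting from singleton clusters,
every cluster pair is tested for discriminability — held-out predictions
restricted to the pair, rescored by the larger of each cluster's member
class scores, two-way accuracy tested against 0.5 with a one-sided
binomial test at alpha = 0.05 Bonferroni-corrected over the current
number of pairs.  While any pair fails, the least-discriminable pair
(largest p) is merged and all pairs retested.  The binomial-vs-0.5 choice
and its correction are this package's documented operationalization; the
procedure being modeled does not specify them.

The random-voxel-set null reassigns each amygdala voxel to one of four
sets — independently per subject, so set identity carries no
cross-subject information, which is exactly the null being simulated —
averages each subject's coefficients within each set to form targets,
synthesizes stimuli, and classifies the targeted set with the same LOSO
procedure.  The null iterations replicate the battery's synthesis
configuration (same seeds per target, same ES budget) so the null
accuracy distribution has the same sampling structure as the anatomical
statistic; the reported interval is the empirical 2.5/97.5 percentile
band.  With orthogonal ground-truth subregions (distinctness 1) the
anatomical four-way accuracy exceeds the null band; with a shared base
(distinctness 0) the anatomical partition is exchangeable with a random
one and its accuracy is a draw from the null distribution.

The on/off-target regression is run per evaluated subject: the subject's
region-average responses across all stimuli are regressed on an
on/off-target indicator, a synthesis-subject indicator block, and the
five standardized low-level stimulus covariates (zero-variance covariates
are dropped with a log message); the on-target coefficients are tested
against zero across subjects.

## Study conditions and problem sizes

Desk-scale defaults, chosen so the full suite runs in minutes while every
statistical property remains measurable:

| quantity | desk scale | study-scale analogue |
|---|---|---|
| feature dimension F | 48–64 | 4,096 (layer fc7) |
| amygdala voxels | 32 (LB 10, CM 8, SF 8, AStr 6) | 247–252 (subregions 29–178) |
| control regions | VC 16, IT 12 | VC ~3,064, IT ~850 |
| time points T | 240–300 | full-movie session |
| subjects | 4–6 | 20 |
| PLS components | 20 (F for recovery) | 20 |
| stimuli per target | 3 seeds | 4–5 retained (8–9 for IT) |
| null iterations | 40 | 1,000 |

Real-scale values (e.g. `REAL_REGION_SIZES`, F = 4,096) are accepted
everywhere via arguments; nothing in the code is desk-scale-bound.

## Known limitations

- The noise model is temporally and spatially white; CV estimates on real
  autocorrelated data would be optimistic under random folds, and the
  voxel-wise vs region-average comparison reverses direction (see above).
- The generator/extractor pair is linear-plus-squash; it exercises the
  optimization and selectivity machinery but has none of the semantic
  structure of a deep generator, so synthesized "images" are textures.
- Empirical effect sizes from the modeled study (subregion betas,
  classification accuracies of 71.7% / 70.42%) are properties of the real
  data and pretrained networks and are out of reach by design; the
  acceptance machinery checks method properties, not those numbers.
- The clustering procedure's multiplicity correction uses the current
  pair count at each round; with many classes and few held-out samples
  the binomial test is conservative.
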