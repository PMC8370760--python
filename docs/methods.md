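# Methods

This note documents the models implemented in `mvreact`, the generative
assumptions of its synthetic test bed, the numerical choices, and what
the passing test suite does and does not establish.

## Single-trial amplitude estimation

Retrieval trials are 16 samples on a 2-s grid starting 2 s before the
cue.  The canonical HRF is the double-gamma difference
`g(t; 6, 1) - g(t; 16, 1)/6` (response delay 6 s, undershoot delay 16 s,
unit dispersions, undershoot ratio 1/6), peak-normalized to 1.  Task
regressors are impulse trains at 10/s spanning the task period inclusive
of both endpoints (6-s imagery: 61 impulses; 3-s probe: 31), convolved
with the HRF and sampled on the trial grid.  Each trial's window is
regressed on [intercept, recall, probe]; the recall beta feeds all
downstream analyses.  The intercept is included because windowed data
have an arbitrary baseline; this is a package choice where the procedure
could be read either way.

Encoding runs use least-squares-sum: per trial, a GLM with the target
trial's regressor, the summed regressor of all other trials, and an
intercept.  For non-overlapping trials LSS equals an independent
per-trial OLS on the trial's own window (tested); for overlapping trials
with heterogeneous amplitudes the shared "others" coefficient leaves a
small structural bias that vanishes as amplitudes homogenize — the
usual LSS bias/variance trade, characterized in the tests rather than
assumed away.

Synthetic trial series are generated directly on the 2-s grid; no
volume-level resampling is simulated.

## Feature preparation

Convolutional feature maps are block-averaged to 3x3 with near-equal
integer blocks chosen by edge rounding (224 rows split 75/74/75), then
log-transformed.  The transform is `log(1 + x)` rather than `log x`
because rectified units emit exact zeros; the offset is configurable.
Pooling-before-log is the default order (configurable) — the choice is
immaterial for monotone decoding but stated for reproducibility.  Fully
connected layers (14-16) bypass pooling.  A `log_transformed` flag
makes double application an error.

## Encoding models

Per vertex and layer: `v = h' f + eps`, `h >= 0`.  Features are the
(<=100) columns with the largest strictly positive Pearson correlation
with the vertex signal, recomputed inside each cross-validation fold on
training rows only.  The non-negative lasso objective
`0.5 ||v - F h||^2 + lambda sum(h)` is minimized by cyclic coordinate
descent with the non-negative soft-threshold update; convergence when
the largest per-sweep weight change falls below 1e-6 (relative to the
weight scale), with two safeguards for rank-deficient designs: an
objective-stall exit (any point on a flat optimal face is returned) and
a one-step jump to the boundary when the iterates drift along an exact
null direction of F.  Correctness is pinned to an active-set QP
enumeration oracle on small instances.

Feature columns are centered on training rows always — a centered
target is otherwise unreachable under the non-negativity constraint —
and scaled to unit variance by default so the penalty is comparable
across features (configurable off; predictions are un-standardized).
Lambda is selected per vertex from 5 geometrically spaced values on
[1e-4, 1] by held-out SSE, ties to the smaller value.  Cross-validation
is 3-fold over images, so no image's encoding trials ever train the
models that predict its pattern; movie-viewing samples join every
fold's training rows.

## Rank decoding

Observed recall patterns are Pearson-correlated across vertices with
each candidate image's predicted pattern; the target's descending rank
among N candidates, subtracted from the mean rank (N+1)/2, is the
adjusted rank (0 = chance, +/-(N-1)/2 extremes; +/-44.5 at N=90).  Ties
take the mean of tied positions, which keeps the chance expectation at
exactly 0; zero-variance patterns get correlation 0 with a warning
rather than an exception, so a subject-level run never aborts.
Image-specific scores use each image's four encoding betas averaged
into a template.  Per-layer scores are averaged within level groups;
left/right ROIs are averaged, and the five hippocampal sections grouped
into aHC (two most anterior) and pHC (two most posterior), middle
excluded.

## Residualization

Within-subject analyses replace each measure by OLS residuals (with
intercept) on its shared components: hippocampal level-specific targets
regress on the 3 same-ROI other levels plus all 4 opposite-ROI levels;
hippocampal image-specific targets on the opposite ROI's score;
cortical level-specific targets on the 3 same-ROI other levels.
Residualizing regressions are fitted per subject — the analyses they
feed are within-subject, and pooling would leak between-subject
variance into the residuals — with a pooled flag for sensitivity
checks.  Collinear covariates are dropped with a warning.

## Mixed-model inference

The within-subject models are binomial GLMMs of trial accuracy with
crossed random intercepts for subject and image pair.  Fixed effects:
the reactivation measures (z-scored within subject so coefficients are
per reactivation SD), their interactions with standardized subject mean
lure accuracy, probe type as control; the calcarine variant adds the
calcarine low-level measure, its 8 two-way interactions with the
hippocampal measures, 9 lure-accuracy two-ways, and 8 three-ways.
Fitting is by Laplace approximation: penalized IRLS over the joint
(fixed, random) coefficients inside, Nelder-Mead over the two
log-variances outside.  The fit is validated two ways: forcing the
variances to zero reproduces a plain logistic regression to 1e-4, and
on a crossed design with genuine variance components the fixed effects
and variances match lme4's `glmer` to ~0.02.  When both variance
components collapse (< 1e-4) the model falls back to fixed-effects
logistic regression with a warning; suspected separation (|beta| > 15)
triggers a lightly ridged refit.

Uncertainty is bootstrap-based (B = 1000 default; the tests and the
demo use B = 200).  The within-subject scheme is parametric: binary
responses are simulated from the fitted model (fixed effects plus fresh
random-intercept draws at the estimated variances) and the coefficients
refitted per draw.  Refits hold the variance components at their point
estimates — a conditional parametric bootstrap — because re-profiling
the Laplace likelihood per draw costs ~30x more and the quantities
consumed downstream are the coefficient draws.  The between-subject
scheme resamples subjects with replacement.  One-tailed p-values are
tail counts with a 1/B floor; two-tailed doubles the smaller tail; CIs
are 5th/95th percentiles (90%).  FDR is Benjamini-Hochberg within the
declared family, with prioritized terms (low-level features by
convention) passed through unadjusted.  Lure accuracy enters the models
standardized (raw-proportion anchors are reported alongside); a raw
option exists.

The between-subject model regresses subject mean lure accuracy on the
8 subject-mean reactivation values computed over correct trials only
(trials without a response are scored incorrect and never dropped,
here and everywhere).

## The synthetic generator

`SimConfig` defaults encode the study-scale conditions: 25 subjects, 90
images in 45 lure pairs, 3 encoding runs of 30 images x 4 repetitions
(120 trials per run, 360 total), 16 layers, five hippocampal sections
per hemisphere plus calcarine and a precentral distractor ROI, 3775
movie surrogate samples.  One deliberate simplification: the 90 encoded
images themselves form the 45 lure pairs (a lure probe is the cued
image's encoded pair partner), which keeps the decoder's candidate set
at 90 and gives the image-pair random effect 45 levels without
simulating 90 never-analyzed lure feature tensors.

Schedules come from rejection sampling over a token construction (one
adjacent double plus singles per image; restart cap 10,000), verified
against an independent scan oracle.  "Only one immediate repetition" is
read as *exactly* one; an `at_most` mode covers the other reading.

Layer features are rectified correlated Gaussians: pair members share a
latent with weight sqrt(rho), shifted by +1.5 before rectification so
truncation is mild and the realized within-pair correlation stays near
the target; rho rises from 0.55 (low) to 0.90 (semantic), making lures
"share the gist" most strongly at the semantic levels.  Vertex
sensitivities are sparse non-negative (Exp(1) magnitudes on ~10% of
features); calcarine weights are biased toward low-level layers and the
distractor ROI is weakly tuned everywhere.

Retrieval patterns mix, per feature level, the cued image's noise-free
template (weight: the trial's fidelity phi in [0,1]) with a random
two-image mixture of other templates (weight: 1 - phi), plus Gaussian
noise scaled to `noise_sd` times the SD of the *image-discriminating*
part of the templates (the shared mean profile carries no identity
information, so scaling noise to it would misstate the effective SNR).
The distractor mixture is what lets incorrect trials produce negative
adjusted ranks.  Hippocampal fidelity for detail levels follows the
anterior-to-posterior gradient (default 0.15 to 0.75 over five
sections); the semantic level follows the reversed gradient; calcarine
is strongest for low-level features; subject lure skill shifts
posterior/calcarine detail fidelity (slope 0.08).

Behavior: balanced old/lure probes within subject;
`P(correct) = logistic(b0 + sum b_k x_k + u_subject + u_pair)` where
the x_k are ':'-joined products of z-scored aggregated fidelities, the
latent lure skill, and probe type.  The defaults plant a positive
pHC-low x lure-skill interaction (0.30) and produce ~83% overall
accuracy; 1% of trials are non-responses, scored incorrect.

Two named variants fix the simulation-study conditions.
`recovery_config` is the strong-planted-effects setting for end-to-end
recovery (trial-level fidelity SD 0.30 on a lower-baseline gradient so
the rank measure has dynamic range rather than saturating at ceiling; a
stronger skill main effect 0.8 so observed lure accuracy is a reliable
skill proxy; interaction 1.2; 40 vertices per ROI).  `null_config`
removes every fidelity term from the behavior model while keeping real
between-subject accuracy differences, and is sized smaller (15
subjects, 16 vertices) because null calibration needs many replicates.

### What the generator does not emulate

Spatial autocorrelation and anatomical geometry within ROIs; scanner
drift, motion and physiological noise; eye movements; any actual
network's feature statistics (the rectified-Gaussian features have the
right support, sparsity and pair correlation, not the semantics of a
real trained network);
volume-space preprocessing.  Passing tests therefore establish that the
*pipeline* is correct and can recover known couplings at realistic
sizes and SNR — not that any particular real dataset would yield those
couplings.

## Problem sizes used by the tests and analysis scripts

Oracle and unit tests run at desk scale (tens of rows).  The end-to-end
recovery study runs 20 replicates of `recovery_config` (25 subjects x
90 trials, B=200) and the null study 40 replicates of `null_config`;
the weight-recovery check uses n=240 samples, 120 features, 10-sparse
truth, noise 0.1 x signal SD.  The demonstration pipeline in
`analysis/` uses 4 subjects, 30 images, 8 vertices per ROI and fits
encoding models for six ROIs; these sizes were chosen so the whole
chain, including ~50k coordinate-descent fits, runs in minutes on one
core, and they are stated here because every empirical number in the
analysis outputs depends on them.  The recovery and null studies use
generative-weight predicted patterns (exactly what perfectly fitted
encoding models would produce) so that each replicate exercises
decode -> aggregate -> residualize -> GLMM -> bootstrap without
refitting tens of thousands of lassos per replicate; encoding-model
fitting itself is validated by its own oracle, recovery and
fold-bookkeeping tests and by the demonstration pipeline.

## Known limitations

The Laplace approximation can understate variance components for very
sparse binary data (the standard caveat); the conditional bootstrap
ignores variance-component uncertainty; coordinate descent on heavily
collinear selections returns one point of a flat optimal face; the
generator's fidelity-to-rank coupling (~0.2-0.3 within subject at
default SNR) dilutes generative effect sizes roughly threefold, so
recovered coefficients are smaller than planted ones — sign and
inference calibration, not magnitude equality, are the tested
contracts.
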