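# Methods

This note documents the models implemented in `convstate`, the synthetic
cohort they are validated against, the defaults and why, and the numerical
choices a user should know about.

## The convergence statistic

Trial-level activation patterns are points in an N-dimensional voxel
space.  The prototypical state of an ROI is a centroid estimated with a
leave-one-run-out scheme: for each scanner run *r*, trials from all other
runs define the centroid, and each trial of run *r* is scored by its
correlation distance d = 1 − Pearson r from that centroid.  Shorter
distances mean higher typicality (greater convergence).  Holding out the
scored run keeps the centroid independent of the scored trials and
removes within-run temporal-correlation confounds.

Two centroid estimators are exposed:

- **`kmeans_mean`** (default): the mean of row-standardized patterns.
  Under correlation geometry this is the k = 1 k-means solution in closed
  form, so no stochastic initialization is involved and the statistic is
  deterministic.  Rows are standardized before averaging so that trials
  with large overall amplitude do not dominate the correlation-geometry
  mean; this choice is configurable in spirit (the medoid needs no
  standardization decision) and is documented because a mean over raw
  patterns differs when amplitudes vary.
- **`medoid`**: the training pattern minimizing summed correlation
  distance to all training patterns — the literal "point with the
  shortest distance to all other points".  Mean and medoid coincide for
  tight unimodal clouds and diverge for structured sets (two antipodal
  clusters: the medoid sits inside one cluster, the mean near-cancels);
  the test suite pins this divergence case.

Distances are z-scored within subject for visualization and outlier
flagging (default threshold 3 within-subject SDs, configurable); the
linking models use the **raw** distances, and a refit excluding flagged
trials is part of the test suite (estimates move < 10%).

## Trial-level GLM (least-squares-all)

Each (trial, interval) event is a separate regressor: a boxcar convolved
with the canonical double-gamma HRF (response gamma peaking at 6 s,
undershoot gamma at 16 s, unit dispersions, undershoot ratio 1/6, 32 s
kernel, peak-normalized), built on a grid of TR/16 s and sampled at
volume times.  Per voxel, ordinary least squares gives betas;
t = beta / SE with pooled residual variance and dof = timepoints − rank;
z = sign(t) · Φ⁻¹(1 − p/2) with the two-sided Student-t p evaluated in
log space (`ndtri_exp`), so |t| in the hundreds still maps to finite z.
The question regressor spans the anticipation epoch (question onset to
answer onset) by default, configurable to stimulus-only or impulse.
Nuisance regressors are accepted as an arbitrary matrix; a constant (and
optional linear drift) is always appended; models are fit per run and
trial estimates concatenated.  Rank deficiency is reported with the
names of the dependent columns (pivoted QR), never silently absorbed.

## Linking models

- **Condition and modulator effects on typicality**: linear mixed models
  with subject random intercepts (statsmodels MixedLM, ML estimation so
  nested fits support likelihood-ratio tests; optimizer falls back
  lbfgs → bfgs → powell before raising).  Condition is coded 1 = high
  curiosity, so negative estimates mean "more typical when curious".
- **Subsequent-memory model**: mixed-effects logistic regression of
  trial-level recall on all ROI measures jointly, subject random
  intercepts.  No installed Python library provides a maximum-likelihood
  logistic GLMM with a true log-likelihood, so `convstate.glmm` implements
  one: the random effect is integrated out per subject with Gauss–Hermite
  quadrature *adapted* at the posterior mode (Newton inner loop, curvature
  scaling, 11 nodes; 7×7 tensor nodes for the optional independent random
  slope).  Fits agree with R's `lme4::glmer` (nAGQ = 9) to ~1e-3 on
  coefficients, SEs, and log-likelihood; that cross-check is a unit test.
  Wald p-values use the numerical Hessian of the marginal log-likelihood.
- **Random-slope policy**: a random slope for the focal predictor is
  attempted and retained when a likelihood-ratio test prefers it at
  p < 0.05 (χ² = 2Δll against the nominal χ² tail; no boundary-mixture
  correction, which makes the selection mildly conservative).
- **Mediation**: nonparametric bootstrap over subjects (resampling
  subjects with replacement ≡ integer-weighted refits, vectorized IRLS
  across bootstrap draws).  The mediator model is OLS
  (mediator ~ treatment), the outcome model is logistic
  (outcome ~ treatment + mediator); indirect = a·b on the log-odds scale,
  total = direct + indirect (exact for the linear mediator, an
  approximation for the binary outcome), pME = indirect/total with
  percentile CIs.  Default 5,000 draws, fully seeded.  This is a
  transparent, reproducible alternative to quasi-Bayesian mediation
  engines; with a near-zero total effect pME is flagged unstable.  Note
  the outcome model inside the bootstrap is marginal (clustering is
  handled by the subject-level resampling, not by a random intercept), so
  its coefficients are population-averaged and slightly attenuated
  relative to the conditional GLMM scale.
- **Behavioral contrast**: per-subject recall rates per condition, paired
  two-tailed t, Cohen's d = mean difference / SD of differences.
- **Between-subject correlation**: Pearson r with Fisher-z 95% CI.

## Permutation-null voxelwise map

Per subject, typicality and every voxel's activation are residualized on
the covariate (VTA signal), correlated, and each voxel's observed r has
the 95th percentile of its permutation null subtracted.  The null
permutes the raw typicality vector's trial order within subject (500
draws by default, shared across voxels — vectorized and
variance-reducing) and applies the identical residualization, so the
null matches the statistic; after subtraction only correlations
exceeding their own null quantile remain positive.  The group test is a
per-voxel one-sample t across subjects, **one-sided for positive
coupling**: a null voxel's adjusted r is negative in expectation by
construction, so a two-sided test would flag every null voxel as
reliably negative.  Family-wise error is controlled by Bonferroni over
the tested voxels (default) or a max-statistic sign-flip permutation
test; both are exact at desk scale and need no smoothness estimation.
Degenerate voxels (zero variance) are excluded and logged.

## The synthetic cohort

Defaults encode the emulated design: 23 subjects × 6 runs × (12 high +
12 low curiosity) trials, question 4 s, anticipation delay ∈ {9, 13} s,
answer 1 s, inter-trial interval ~ U(1, 20) s (the active-baseline
period), TR 2 s.  Catch trials and action-contingency are not simulated.

Planted structure, per trial:

- latent modulator m = subject mean (sd 0.3) + N(0, 1) — the VTA-like
  scalar; realized in the VTA ROI as a uniform activation offset, so the
  ROI mean recovers m with noise sd `pattern_noise_sd`/√V ≈ 0.05.
- latent eccentricity
  e = max(0, 0.5 + subject offset (sd 0.02) − 0.02·[high] − 0.06·m
  + 0.15·N(0, 1)).
- recall ~ Bernoulli(logit⁻¹(intercept_cond + subject intercept (sd 0.7)
  − 0.6·e + 0.15·m)), intercepts calibrated so the marginal recall rates
  at zero slopes are 0.63 (high) and 0.40 (low).

Pattern geometry: per subject and ROI a fixed Gaussian prototype **p**;
each trial's pattern is **p** + c(e)·**u** + noise, with **u** a
trial-unique zero-mean unit direction orthogonal to the centered
prototype and c(e) = ‖p̃‖·√((1−e)⁻² − 1), so that the noise-free
correlation distance from the prototype **equals** e.  With the default
voxel noise (sd 0.5, 300 hippocampal voxels) the measured distance is
≈ 0.07 + 0.89·e with ≈ 0.016 trialwise jitter — a mild, quantified
attenuation all recovery tests account for.  Only the hippocampus
carries the trial latent; the control ROIs (PHC, PRC) receive
independent null eccentricity draws, mirroring the regional specificity
the analysis is meant to detect and keeping multi-ROI models
well-conditioned.  A flat 2,000-voxel "grid" stands in for the whole
brain volume; its first 50 voxels add 0.5 × the standardized
eccentricity, planting a coupled region for the map stage.

Default magnitudes are calibration choices, not empirical claims: the
condition shift (−0.02 distance units) and modulator slope (−0.06) sit
at the scale of the reported fitted effects; the trialwise eccentricity
noise (sd 0.15) is set so the planted memory slope is identifiable at
the study's size (with much smaller trial variance the −0.6 log-odds
slope is statistically invisible at n = 3,312, which no analysis could
fix).  Subject-level heterogeneity (memory intercept sd 0.7, subject
modulator mean sd 0.3) makes the random-intercept machinery load-bearing
and produces between-subject VTA/typicality coupling of roughly −0.7.

BOLD mode multiplies each trial's HRF-convolved regressors by its
pattern values (question interval) or the prototype (answer interval)
and adds white noise; run length covers the last event + 20 s.  Because
generation and fitting share the design construction, the LSA betas
reproduce the planted amplitudes exactly at zero noise — the
cross-mode consistency test (pattern-level ≡ BOLD-level at
`bold_noise_sd: 0`) rests on this.

What the generator does **not** emulate: autocorrelated/physiological
noise, scanner drift, spatial smoothness, motion, regional specificity
beyond the planted ROI, nonlinear BOLD summation, or condition effects
on univariate VTA amplitude.  Passing tests therefore certify the
statistical machinery under the stated generative assumptions, not
performance on real scanner data.

## Validation design and problem sizes

The test suite validates every stage against an independent route:
brute-force reimplementation of the leave-one-run-out statistic (1e-12),
exhaustive medoid search, noiseless-BOLD beta recovery (1e-6 relative),
quadrature-based t→z (1e-10), lme4 for the GLMM, closed-form partial
correlation for residualization, and hand arithmetic for the t-tests.
Replicate-based checks use 50 cohorts for parameter recovery (sign and
±50% magnitude of each planted effect), 200 null cohorts for type-I
calibration at α = 0.05, 20 cohorts for coupled-region recovery, 100
replicates for mediation interval coverage, and 200 for the behavioral
contrast; mediation calibration loops use 199–999 bootstrap draws (the
default for a single analysis is 5,000).  The complete-mediation
demonstration uses a strengthened mediated path (a = −0.2, b = −1.5)
because pME is a ratio whose denominator contains an estimated null
direct effect; at the default effect sizes a single cohort cannot pin
pME near 1, only its replicate median can.

One calibration caveat is intrinsic rather than implementational: under
the complete null (both mediation paths zero) the percentile bootstrap
of the product a·b rejects at well below the nominal 5% — the classic
singular-null behavior of product-of-coefficients tests.  Where
calibration is theoretically attainable (a-path-only null) the measured
coverage is 95%.

## Determinism

Every stochastic stage derives its generator from the top-level seed and
its stage name via a stable hash, so adding a stage never perturbs the
others; rerunning the pipeline with the same config yields byte-identical
output files (manifests record SHA-256 checksums and carry no
timestamps).  The convergence statistic itself is fully deterministic.

## Known limitations

- Real-data mode consumes preprocessed, spatially normalized NIfTI; no
  preprocessing (realignment, smoothing, physiological regression,
  high-pass filtering) is provided.
- The GLMM supports one optional random slope, assumed independent of
  the random intercept; correlated random effects are out of scope.
- Mediation's additive total-effect decomposition is approximate on the
  log-odds scale (non-collapsibility); pME should be read accordingly.
- Bonferroni FWE is conservative under strong spatial correlation; the
  max-statistic option is preferable for smooth volumetric data.
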