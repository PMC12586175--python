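# Methods

This note documents the models, estimators and numerical choices behind
`pfcdev`, what the synthetic cohort does and does not emulate, and the
design decisions taken where the analysis was genuinely open.

## Task and data model

Trials follow the oculomotor delayed-response (ODR) structure: 1.0 s of
pre-cue fixation (the *baseline* epoch), a 0.5-s cue at one of eight
locations on a 10°-eccentricity circle (45° spacing), a 1.5-s delay, then
fixation offset and a saccade within 0.6 s to a 6°-radius window around the
cued location. The distractor variant uses four cue locations (90°
spacing) and interposes a 0.5-s distractor 1.25 s after the cue, with the
fixation point extinguished 4.5 s into the trial. Spike windows are
half-open `[start, end)` everywhere so adjacent epochs never double-count a
boundary spike.

All developmental time is *mid-adolescence-relative age*: chronological age
(months) minus the subject's age at distal tibial epiphyseal closure.
Aligning on this skeletal landmark rather than chronological age removes
between-subject pubertal-timing variance before any trajectory is fitted.

## Behavioral metrics

The dispersion index is interpreted as the area of the one-standard-
deviation *covariance ellipse* per target, DI_t = π·√det(Σ̂_t) with the
unbiased (n−1) sample covariance, averaged unweighted over targets with at
least 4 correct trials. The circular alternative π·(mean radial s.d.)² is
available behind `circular=True`; for isotropic scatter the two coincide
(area π·σ²), which is the closed form the calibration tests use. Only
correct trials contribute endpoints. RT = saccade onset − fixation offset,
flagged anticipatory at ≤ 80 ms and late beyond the response window.
Percent correct excludes trials aborted before the end of the delay from
the denominator.

## Firing metrics

CV_ISI pools within-trial baseline ISIs across trials (intervals never span
trials — inter-trial gaps are not ISIs) and uses the sample (n−1) standard
deviation; at least 3 ISIs are required. CV_rate is the across-trial CV of
the per-trial baseline rate. The Fano factor is the slope of the
across-trial count-variance vs. mean-count regression over stimulus
conditions (≥ 3 conditions with ≥ 4 trials), constrained through the origin
because the theoretical intercept is zero; a with-intercept option is kept
for sensitivity checks. Session-level rates use the log-normal (geometric
mean) average over neurons with a 0.1-Hz floor so silent neurons do not
zero the average; variability metrics use plain means.

## Selectivity and intrinsic timescale

Tuning fits the non-periodic Gaussian f(loc) = β₁+β₂·exp(−½((loc−β₃)/β₄)²)
after re-centering the circle on the empirical peak and unwrapping to
(−180°, 180°] — the convention that makes a non-periodic model well posed
on circular data. Initialization is deterministic (min rate, range, 0°,
45°) with β₄ ∈ [5°, 180°]. Downstream filters may drop fits with R² < 0.5
or baseline ≤ 0.5 Hz.

ωPEV uses the one-way ANOVA decomposition with the ω² bias correction, so
an unselective neuron averages ≈ 0 (the statistic may be negative). Spike
counts are the input unit; ω² is scale-invariant so counts vs. rates is
immaterial. The permutation test shuffles condition labels within neuron
and uses the add-one convention p = (1+k)/(1+n_perm).

The intrinsic timescale comes from 50-ms binned counts over the 1-s
baseline: the across-trial covariance between every bin pair is averaged
per lag, normalized by the total count variance, and fitted with
A·exp(−lag/τ)+B over lags ≥ 1 bin (lag 0 holds the Poisson point variance
and is excluded), unweighted least squares. Exclusions are machine-readable:
`low_rate` (< 1 spike/s), `empty_bin` (a bin silent across all trials),
`slow_timescale` (τ > 0.5 s), `fit_failure`.

## Population geometry

Effective dimensionality is the participation ratio N_eff = (Σλ)²/Σλ²,
which discounts small noise eigenvalues. Temporal dimensionality uses each
neuron's 8-condition × ten 50-ms cue-bin mean-rate matrix, columns
centered, eigenvalues of the covariance over condition rows. Full-space
dimensionality pools neurons across subjects into 20 even
relative-age intervals; per bootstrap replicate (500 per interval) 30
neurons are resampled with replacement and N_eff computed from the
(8 conditions × 14 delay bins) × 30 matrix with per-neuron centering. The
14 bins are 200-ms windows stepped by 100 ms across the 1.5-s delay
(starts 0.0–1.3 s). Intervals with fewer than 30 neurons are skipped, not
merged, to avoid resampling inflation.

Subspace rotation uses the distractor task: per neuron an 8-vector of
condition means (4 cue locations × cue/distractor epoch), per-neuron
z-scoring, projection of the 8 points onto the first three PCs, one
total-least-squares plane per epoch (normal = smallest-eigenvalue direction
of the centered points — the closed form of the iterative
distance-minimization it replaces, to which it agrees within 1e-4 rad in
tests), and φ = acute angle between the normals. The 3-PC projection is
refit within each bootstrap replicate so replicates are self-contained.
Degenerate (collinear) replicates are discarded and counted.

## Trajectory model

The smoother is a penalized cubic B-spline (P-spline: 10 basis functions on
equally spaced knots, second-order difference penalty) plus per-subject
random intercepts and slopes as ridge-penalized effects — the same
smoothness class as a thin-plate regression spline for one covariate, which
it deliberately approximates. Because B-spline columns sum to one, the
spline block is reparameterized onto the orthogonal complement of the
constant coefficient direction; with the explicit intercept the penalty
null space is exactly {constant, linear} (dimension 2). All smoothing
parameters minimize the profiled REML criterion
(n−2)·log(P) + log|XᵀWX+S| − log|S|₊ with P the penalized residual sum of
squares, via Nelder–Mead over log-λ. Gaussian outcomes use the identity
link; proportion outcomes use penalized IRLS with a logit link and a free
dispersion from Pearson residuals (quasi-binomial behavior).

Inference simulates 10,000 draws from the Gaussian coefficient posterior
N(β̂, σ̂²(XᵀWX+S)⁻¹). The fitted-curve and derivative bands use the max-|t|
quantile across the prediction grid (200 points), giving simultaneous 95%
coverage; the derivative is a central finite difference with step =
grid spacing/10. Significant-change intervals are the grid runs where the
simultaneous derivative band excludes zero; *monotonic* intervals
additionally require a single derivative sign. Peak-velocity age is the
argmax of |derivative|; extremum age the argmax of the fitted mean. The
smooth test is an approximate Wald F on the spline block (pseudo-inverse of
its posterior covariance); across measures, Benjamini–Hochberg FDR is
applied to the smooth p-values. A calibration experiment (500
constant-truth cohorts) keeps the derivative-significance family-wise false
positive rate at ≈ 0.04–0.07, within the nominal 5% band.

Boundary behavior: spline derivative estimates wiggle in the outermost few
percent of the age range (a known edge effect); landmark ages near the
boundary should be read accordingly.

## Trajectory comparison

Fitted curves are evaluated at 100 evenly spaced ages over their
overlapping range and z-scored. Pearson r measures shape similarity; the
RMSE is computed after shifting each curve to start at zero and taking
absolute values so positively and negatively correlated pairs are
comparable. Significance uses single-step maxT: per permutation the sample
order of X and Y is shuffled independently in every pair of the family and
the maximum |r| retained; each pair's p compares its observed |r| to that
familywise distribution (two-sided, add-one). Because smooth curves are
strongly autocorrelated, independently permuting samples is
*anti-conservative* for inference about underlying processes — the p-value
tests exchangeability of curve samples, not of the data behind them. A
block-permutation mode (configurable block length) is provided for more
honest inference; the default matches the literal sample-permutation
scheme.

## Synthetic cohort

The generator's defaults emulate a cohort of 8 subjects tracked every 3
months across 12 sessions (chronological 40–73 months), mid-adolescence
ages spread 53–63 months, 30 neurons and 64 trials per session, with 4
subjects also performing the distractor task. Planted curves are logistic
in relative age: baseline rate 4→8 Hz, ISI CV 1.25→0.95, Fano 1.8→1.2,
endpoint s.d. 2.2°→1.55° (DI ≈ 15→7.5 deg²), mean RT 0.25→0.19 s, percent
correct 72→85%, latent dimensionality 2→6, cue/distractor angle 10°→45°,
with transition midpoints near −10 months — values chosen once as
realistic magnitudes for adolescent prefrontal development and held fixed.

Mechanisms: spikes are time-rescaled gamma-renewal trains (shape 1/CV², a
five-mean-interval warm-up approximating equilibrium) so ISI CV is directly
planted; a per-trial lognormal gain with variance log(1+(F−CV²)/μ) lifts
count Fano above CV²; baseline rates carry an AR(1)/OU modulation with the
planted 0.15-s timescale (depth 0.5; recovery tests use 0.7 for adequate
signal-to-noise at 500 trials); delay activity adds latent patterns drawn
once as an orthonormal basis over (condition × 100-ms bin) space, scaled to
unit per-bin rate variance (pattern scale 4 Hz) so the planted
dimensionality survives trial-sampling noise; distractor-task epoch means
come from a 3-D construction with isotropic total covariance embedded
through unit-norm stacked-rotation columns, which makes the planted plane
angle survive the z-score + 3-PC pipeline exactly in the noiseless case
(when the neuron count is a multiple of 3). Endpoints are isotropic
bivariate Gaussian around the target (anisotropy is not modeled but
configurable via the dispersion curve); RTs truncated lognormal; aborted
trials 8%.

What the generator does *not* emulate: real spike-sorting noise, neuron
non-stationarity within sessions, correlated noise between simultaneously
recorded neurons, error-trial dynamics, eye-trace kinematics (saccade
onsets/endpoints are emitted directly), or imaging physics — auxiliary
longitudinal measures (a white-matter FA-like sigmoid, an inverted-U
volume-like curve) are generic planted curves. Passing recovery tests
therefore demonstrates estimator correctness under the stated generative
assumptions, not robustness to every property of recorded data.

All randomness flows from one global seed through named substreams
(CRC32-keyed `SeedSequence` spawn keys), so cohorts, bootstraps and
permutation tests are bit-reproducible independently of execution order.

## Pseudo-population trajectory fits

Bootstrap N_eff and rotation values are strongly dependent within a
maturation interval (replicates share neurons). Fitting their trajectories
with observation-level independence assumed makes tiny interval-level
jitter spuriously significant; the pipeline therefore includes an
interval-level random intercept for these two measures, which absorbs the
shared-neuron dependence while the smooth captures the age trend.

## Problem sizes

Default analysis sizes: 500 bootstrap replicates per interval (20 intervals
for full-space dimensionality → 10,000 values; 15 for rotation → 7,500),
1,000 permutations, 200-point prediction grid, 100-point comparison grid,
10,000 posterior draws. The test suite and acceptance script run reduced
replicate counts in places (e.g., 200-run null calibrations, 3,000
posterior draws inside simulation loops), chosen as the package's own
balance between statistical resolution and runtime on a single CPU.
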