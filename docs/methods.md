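# Methods

## The behavioral model

`arcpipe` models repeated approach-avoidance decisions in the
aversion-reward conflict (ARC) task: on each trial a participant chooses
between a safe option (a guaranteed $0.01, no aversive stimulation) and a
risky option paying $0.05–$0.95 with a 10%, 50% or 90% chance of aversive
stimulation. Per trial *i* and participant *j*:

    theta_ij = logistic(beta0_j + beta1_j * I[risk=50%] + beta2_j * I[risk=90%]
                        + beta3_j * reward_z_ij)
    y_ij ~ Bernoulli(theta_ij)
    d_ij = 0.25 − (0.5 − theta_ij)^2
    mu_ij = alpha0_j + alpha1_j * d_ij
    z_ij ~ Gamma(k_j, rate = k_j / mu_ij)

The 10% risk level is the reference absorbed by the intercept; reward is
standardized to mean 0, SD 1 over the pooled design (population-SD
convention, so the fixed design is exactly unit-variance; a `ddof` argument
exposes the sample-SD alternative). The conflict statistic *d* is the
distance to the decision boundary: an inverted parabola in theta, maximal
(0.25) at theta = 0.5 and zero for certain choices. Because *d* drives the
gamma RT mean, response times inform the choice coefficients; the fit is
joint.

Participant-level parameters are partially pooled: each is normal around a
group-level mean. Three variants are implemented — the hierarchical model,
a shared-parameter ("non-hierarchical") model with a single coefficient set
for all participants, and a hierarchical variant adding 50%-risk × reward
and 90%-risk × reward interactions.

**Assumptions.** Trials are conditionally independent given parameters; RTs
are untruncated gamma (the likelihood ignores the 3.5 s response cutoff even
though the simulator can censor at it — with the default parameters the
censored mass is negligible); missing responses (choice and RT always
missing together) contribute nothing to the likelihood; participants with
more than 20% missing trials are excluded before fitting.

### Priors

Not every hyperparameter is fixed by convention, so weakly-informative
defaults are used (all overridable through `PriorSpec`):

| parameter | prior | rationale |
|---|---|---|
| group choice means beta·G | Student-t(eta = 5, 0, 2.5) | robust logistic regression |
| group choice SDs | half-normal(2.5) | weakly informative, logit scale |
| alpha0_G (baseline RT) | Normal(1 s, 1 s) | second-scale responses |
| alpha1_G (conflict-RT slope) | Normal(0, 1) | sign left to the data |
| RT group SDs | half-normal(0.5 s) | modest heterogeneity |
| k_j (gamma shape) | Gamma(2, rate 0.1) | mean 20, i.e. RT CV ≈ 0.22 |

### Sampling

The posterior is sampled with an in-package static-trajectory Hamiltonian
Monte Carlo sampler with analytic gradients (the data-likelihood inner loop
is numba-compiled). Design choices that matter:

- **Centered parameterization.** Each participant contributes ~108 trials,
  so participant-level parameters are strongly identified; in this
  strong-data regime the centered form mixes far better than the
  non-centered form (which induces a strong group-mean/offset
  anticorrelation). This was confirmed empirically: effective sample sizes
  for the group means rose by an order of magnitude after switching.
- **Initialization.** A shared-parameter MAP is found by L-BFGS, broadcast
  to all participants, and refined with the group SDs held fixed (the
  unrestricted joint mode of a hierarchy is degenerate — SDs collapse to
  zero). All chains start at this point with small jitter, so the short
  warmup adapts the metric rather than searching for the typical set.
- **Adaptation.** Dual-averaging step-size adaptation (target acceptance
  0.8) with staged diagonal mass-matrix re-estimation at 25/50/75% of
  warmup; the final quarter of warmup adapts the step size only. After each
  metric update the step size restarts from half its current value — the
  new metric can make the previous step too ambitious.
- **Trajectories.** Leapfrog counts are jittered uniformly in
  [L/2, L] (default L = 14) to avoid resonances. Energy errors above 1000
  count as divergences; a configurable divergence-rate ceiling turns
  persistent divergence into a hard error.
- **Defaults** mirror the study fit: 4 chains × 2000 steps, 1000 burn-in,
  thinning 4 (1000 retained draws). Tests use the reduced 4 × 1000 /
  500-burn-in / no-thinning setting.

Convergence is summarized by split-chain Gelman–Rubin R̂ (computed
in-package for every free parameter; values above 1.1 raise a warning) and
bulk effective sample size (delegated to ArviZ).

### Derived quantities

- **Modal estimates.** Per-participant point estimates are univariate
  posterior modes: a Gaussian KDE (Silverman bandwidth) maximized on a
  512-point grid; a posterior-mean alternative is exposed for sensitivity.
  Per-trial conflict is obtained by pushing the trial features through these
  modal coefficients.
- **WAIC** is reported on the deviance scale, −2(lppd − p_waic), with
  p_waic the summed posterior variance of pointwise log likelihood. One
  trial contributes one pointwise term combining its Bernoulli and gamma
  log densities — the joint model's natural observation unit.
- **HDI** is the narrowest contiguous interval containing ⌈mass·n⌉ sorted
  draws; ties between equally narrow intervals break toward the lowest
  lower bound.
- **Posterior predictive RMSE** compares each participant's observed
  risky-choice rate with the posterior-mean theta averaged over their
  trials, root-mean-squared across participants.

### A scaling ambiguity

The printed equations give max(d) = 0.25, but the reported conflict-RT
slope (0.456 s "at maximal conflict") reads most naturally on a d ∈ [0, 1]
scale. The package follows the equations (d ∈ [0, 0.25]) everywhere; the
simulator's default slope is 1.824 s per unit d so that the implied RT
increase at maximal conflict is 0.456 s, and a `conflict_scale="unit"`
option rescales d to [0, 1] for sensitivity analyses.

## The synthetic-data generators

The behavioral generator draws participants from exactly the hierarchy the
model assumes — normal participant effects around group means, Bernoulli
choices, gamma RTs — at the study's conditions: 108 trials per participant,
three counterbalanced risk levels, rewards uniform on the $0.05–$0.95 cent
grid within risk level, a fixed seeded trial order shared by all simulated
participants, and a 3.5 s response window whose violations mark both choice
and RT missing. Group means default to the printed estimates
(beta = (1.0, −1.922, −4.180, 10.652); the intercept is not printed and was
set to 1.0 to reproduce the reported approach bias). Between-participant
SDs (1.5, 1.0, 1.2, 2.5 on the logit scale; 0.2 s and 0.4 s for the RT
parameters) are not printed either; they were chosen once to reproduce the
reported spread of risky-choice rates (roughly 0.16–0.93 across
participants). Gamma shapes are per-participant log-normal around 20
(SD 0.3 log units).

Because generator and model share the same family, recovery tests validate
the inference machinery, not the model's adequacy for real data. What they
cannot show: robustness to RT distributions that are not gamma, to
participant effects that are not normal, to informative missingness (real
missingness concentrates on slow, high-conflict trials), or to violations
of trial independence (fatigue, learning).

The BOLD generator builds voxel time series as baseline + X·beta + noise,
with AR(1) noise (coefficient 0.2) plus white noise by default and known
per-voxel effect amplitudes. The dissociation scenario places two disjoint
27-voxel blocks in a 12³ grid: "deliberation" voxels respond with
unit-amplitude boxcars lasting each trial's RT; "conflict" voxels respond
with the same durations but amplitudes 1 + 4·(d − d̄). RTs rise linearly
with d (slope 1.824 s, noise SD 0.15 s), so time-on-task and conflict are
confounded by construction — which is precisely what the variable-epoch
analysis must untangle. No fMRI physics beyond this linear model is
emulated.

## The fMRI pipeline

**Epochs and regressors.** The deliberation phase is modeled by boxcars:
duration = response time in variable mode, duration = 3.5 s in fixed mode.
A parametric-modulation copy is amplitude-scaled by d (or risk or
standardized reward in control analyses), zeroed on missing-response trials
(in variable mode the missing trial's boxcar falls back to the 3.5 s
window), and mean-centered across non-missing trials before convolution so
the control regressor absorbs the mean response (a config flag disables
centering). The stimulus function is sampled on a grid 16× finer than the
TR with exact fractional-bin areas, convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, unit dispersions, 6:1 ratio,
32 s support, normalized to unit peak), and read out at scan times.

**Nuisance.** A DCT-II high-pass basis with floor(2·T·0.01 Hz) orthonormal
columns; six motion regressors demeaned, linearly detrended and
Gram–Schmidt-orthogonalized in column order; framewise displacement
FD_t = Σ|Δtrans| + 50 mm·Σ|Δrot| with scrubbing of frames above 0.9 mm and
the first four acquisitions. Scrubbed frames become per-scan spike
regressors rather than deleted rows, preserving the time axis for the drift
basis (the equivalence to row deletion is exact for the task-effect
estimates when spikes are included in the model).

**First level.** Ordinary least squares per voxel; rank deficiency is a
hard error naming the collinear columns. Effect sizes become percent
signal change via psc = 100 · beta · peak(unit-amplitude convolved
regressor) / baseline-mean — a fixed convention consistent with the
unit-peak HRF.

**Second level.** Weighted least squares of subject PSC maps on an
intercept plus nuisance covariates (e.g. a scanner indicator), F-testing the
intercept. Weights default to unit (OLS as the WLS special case) because no
weighting scheme is dictated by convention; inverse-variance weights can be
supplied.

**Inference.** Freedman–Lane permutation: the nuisance-only model is
fitted, its residuals resampled, the nuisance fit added back, and the full
model re-estimated. For the intercept (one-sample) contrast the resampling
action is **sign-flipping** of residuals — row permutation leaves a
one-sample statistic invariant and cannot generate a null; sign-flipping is
the standard exchangeability choice for symmetric errors (as in FSL
randomise / PALM). Row permutation is available for covariate contrasts.
Every observed and permuted map is TFCE-enhanced (H = 2, E = 0.5,
step = 0.1, 6-connectivity by default, negative values enhanced separately
on the sign-flipped map), the per-permutation maximum is stored, and
voxelwise FWE-corrected p-values use the add-one estimator
p = (1 + #{maxima ≥ observed}) / (1 + n_perms). Surviving voxels are
cluster-labeled and components under 20 voxels discarded. The TFCE kernel
sorts voxels by height and visits only the suprathreshold prefix per
threshold level, so null maps cost ~1 ms at 12³; it is verified against a
brute-force threshold-sum oracle to 1e-8.

## Problem sizes in the test suite

The acceptance suite runs the full-size behavioral study (28 participants ×
108 trials) over 20 simulate-and-refit replicates with the reduced 4 × 1000
sampler setting; FWE calibration uses 200 null replicates of 28 subjects ×
12³ voxels × 500 permutations; the epoch dissociation uses 10 subjects ×
36 trials × 12³ voxels × 250 permutations. These sizes make the whole suite
a desk-scale computation while keeping every statistical claim testable at
its stated threshold.

## Known limitations

- RT censoring at the response window is simulated but not modeled in the
  likelihood; at realistic parameters the discrepancy is negligible, but a
  truncated-gamma likelihood would be the principled extension.
- The group-level F contrast tests the intercept only; contrasts on
  covariates are permuted by row permutation but have no dedicated API.
- Volumetric analysis only: no surface-based statistics, no atlas-driven
  mask construction, no spatial preprocessing (realignment, normalization,
  smoothing) — masks and preprocessed series are taken as given.
- First-level temporal autocorrelation is not prewhitened; group inference
  relies on permutation across subjects, which is insensitive to
  within-subject autocorrelation misspecification.
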