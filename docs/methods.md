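# Methods

## Task environment

The environment is a restless bandit with 8 options, 4 available per run
(default availability {0–3, 4–7, 0–3, 4–7} across the 4 runs, so each option
appears in exactly two runs — the property the cross-run decoding split
relies on). One available option pays reward with probability 0.7 or 0.9;
the other three pay with probability 0.2. Regime lengths are drawn as
round(Normal(20, 5)), truncated below at 1 trial; at each regime boundary
the high option moves uniformly to one of the other three available options
and its payout rate is re-drawn uniformly from {0.7, 0.9}. Regime changes
are independent of the agent's behaviour. Sessions are 4 runs x 200 trials.
Trial indices, run ids and option ids are 0-based. An ITI jitter column
(uniform 0–4 s) is stored for fixture realism but unused by the
trial-indexed analyses.

Agent policies: `random`, `greedy` (argmax of prior beliefs), `replay`
(fixed choice sequence), and the default `softmax`, whose choice
probabilities are proportional to exp(β·p(H_i)) over the four available
options with a higher inverse temperature (β = 12 vs 4) on trials following
a rewarded choice of the believed-best option. That crude sharpening is
enough to produce human-like alternation between exploration and
exploitation: across seeds the simulated sessions give roughly two-thirds to
three-quarters exploit trials, core-exploit shares near a quarter, softmax
prediction accuracies around 90–95% (exploit) and 45–50% (explore) against
25% chance, and entropy–EV(chosen) correlations near −0.94.

## Ideal observer

The observer holds a joint posterior over hypotheses h ∈ {1..4} (which
available option is the high one) and payout rates p on the grid
0.30:0.01:1.00 (71 values; the grid's lower bound keeps the high rate above
the known low rate of 0.2). The payout matrix is

    M[h, L, p] = p    if h == L
                 0.2  otherwise

for chosen option L. After outcome O_t ∈ {0, 1} each cell is multiplied by
M (if rewarded) or 1−M (if not) and renormalised. Between trials the prior
is a leaky mixture,

    prior_{t+1} = (1 − s) · posterior_t + s · uniform,

with switch probability s = 1/20 — the true mean switch hazard of the
environment — and the uniform taken over the full 284-cell (h, p) grid.
Runs are processed independently from a uniform belief (the leak before a
run's first trial is a no-op on the uniform prior and is skipped).

Reported per trial, from the posterior *after* that trial's outcome (the
model state at feedback): option marginals p(H_i) = Σ_p mass(i, p), their
entropy −Σ p(H_i)·log p(H_i) in nats by default (base 2 by configuration),
expected values EV(i) = Σ_{h,p} mass(h,p)·M[h,i,p], and relative
uncertainty. Relative uncertainty is implemented as 1 − max_i p(H_i) — a
deliberate design choice among the family of "uncertainty of the favoured
state" measures; it is configurable, and on simulated sessions it correlates
with entropy at r ≈ 0.9+, so conclusions drawn from either measure agree.
The prior marginals entering each trial are also reported, because choice
policies act on them (a choice cannot depend on the outcome it precedes).

Correctness is established against an independent literal-loop oracle (pure
Python nested loops over grid cells) to 1e-10 on random sequences, and
normalisation drift is bounded at 1e-12 over full 800-trial sessions.

## Behavioural segmentation

An exploit block starts on the first trial where the agent selects the true
high option *and* is rewarded, and ends on the last trial before the choice
switches; within a block all choices are identical by construction. If the
environment switches away mid-block, trials remain exploit until the choice
switches (the end rule is purely choice-based). Core-exploit trials lie at
distance ≥ k (default 5) from both the preceding and following choice
switch, inclusively, with run boundaries counting as switches; an
inter-switch gap of length L therefore contributes max(0, L − 2k + 1) core
trials. On simulated sessions this yields core-exploit shares near 25% of
all trials.

Softmax policies are fitted per phase by maximum likelihood over β ∈
[0, 100] (bounded scalar optimisation); fits at the bound are flagged
non-identified (perfectly greedy data); phases with fewer than 5 trials are
skipped with a flag. Prediction accuracy uses the fitted policy's modal
choice, ties broken toward the lowest option id. The switch analysis fits,
per subject, a logistic regression of "next trial initiates exploration" on
entropy (or relative uncertainty) over exploit trials with reward omission,
falling back to a ridge-penalised fit under separation, excluding subjects
with no omission trials or constant outcomes; subject slopes are tested
against zero with a one-sample t-test.

## Synthetic neural and pupil data

All generators are deterministic given (config, seed) and emit data at
trial resolution — each trial's pattern stands in for a per-trial beta map;
HRF convolution and scanner timing are out of scope.

**State-coding regions.** Eight fixed prototypes are drawn once per region
from a standard normal (orthogonalisation optional; overlap is the realistic
default). Trial t's pattern is g·Σ_i w_i·proto_i + N(0, σ²), with w the
posterior option marginals of the run's four available options. Defaults
g = 1, σ = 1, 120 voxels (200 in the headline recovery).

**Action-coding regions.** Pattern = g·proto_chosen +
bleed·g·proto_neighbour + noise, neighbour = (chosen + 1) mod 8; weights
never depend on beliefs, so these regions decode well but carry no entropy
signal.

**Latent pulses and the planted coupling.** On unrewarded trials a latent
neuromodulatory pulse z_t = u_t·max(ΔENT_t, 0) fires, with a private
lognormal gain u_t (σ = 0.5, median 1) so the pulse carries variance beyond
the entropy change itself — without that private gain the coupling would be
inestimable with entropy change partialled out. Two states integrate the
pulses, both resetting at choice switches and run starts:

- pupil baseline elevation: level_t = baseline_mean + a·Σ z (a = 50 a.u.
  per unit pulse), so the baseline change from trial t to t+1 is exactly
  a·z_t — a sustained post-omission elevation;
- representation flattening: F_t accumulates c·z_t (c = 0.6, capped at
  0.95), and the state-region mixture weights become (1−F)·w + F·0.25.

Matching *persistent* states on both sides is what makes the planted
coupling specific: on rewarded trials no pulse arrives and both states
simply carry over, so pupil change and representation-strength change share
no pulse information there; and the shared increment occurs at one lag only.
(A transient one-trial elevation instead produces a spurious
rewarded-trial coupling through the previous trial's pulse — the elevation
decays exactly when the representation recovers.) The flattening rate 0.6
was set from the generator's own statistics: core-exploit omission pulses
average ≈ 0.7, so rates ≳ 1 pin F at its cap on most core trials and cap
saturation decouples the planted chain, while 0.6 keeps F in range. These
values are the package's configured planted effect size and are the
defaults, so a default cohort carries the full planted structure; set
`extra_flattening_c = 0` for uncoupled cohorts.

**Pupil traces.** Each trial occupies a fixed 2 s segment at its baseline
level, with feedback 50 ms before segment end; Gaussian measurement noise
(σ = 5 a.u. on a 1000 a.u. baseline) is added, and blinks are Poisson gaps
(0.05/s, 100 ms) of missing samples. The default sample rate is 100 Hz for
test speed; 1000 Hz mirrors eyetracker hardware and makes the 20 ms baseline
window exactly 20 samples.

**Univariate signals.** signal_t = b·ΔENT_t + N(0, σ²), with ΔENT the
within-run backward difference.

What the generators do *not* emulate: physiological noise spectra, drift,
motion, spatial autocorrelation, HRF temporal blurring, luminance effects on
pupil size, or any mismatch between the participant's learning model and the
ideal observer. Passing recovery tests therefore demonstrates that the
analysis chain detects the planted structure at realistic SNR — not that
real recordings contain it.

## Representation-strength pipeline

Runs are split into two pairs such that each pair covers all eight options
(with the default availability, {runs 0,2} vs {runs 1,3} or equivalent);
training on one pair and testing on the other, then swapping, scores every
trial exactly once. Dimensionality reduction keeps the top 20 eigenvectors
of the voxel–voxel covariance computed across *all* trials (training and
test together — a label-agnostic choice, guarded by the shuffle bias check
below); trial loadings are least-squares projections. Training sets are
class-balanced by deterministic cycling of each class's trials up to the
largest class count, so no resampling randomness enters. The classifier is
an 8-way multinomial logistic regression (scikit-learn, lbfgs) with weak L2
regularisation (C = 1 in standard parameterisation) for convergence on
oversampled data; chance accuracy is 1/8.

Representation strength converts the decoder's probabilities to

    RS_t = ln[ (p_c/(1−p_c)) / (p̄_u/(1−p̄_u)) ],

where p_c is the chosen option's probability and p̄_u the *mean* probability
of available-but-unchosen options (sum available behind a flag; the mean is
the default aggregation choice). Probabilities are clipped to
[1e-6, 1−1e-6] before the odds. Uniform probabilities give RS = 0; at
p_c = 0.5 with the rest spread equally, RS = ln 13.

Controls: `residualize_voxelwise` replaces each voxel's trial series by its
OLS residual against nuisance regressors (option value, reward history)
before decoding; `searchlight_map` runs the full
reduce→balance→train→classify→RS→regress recipe in a sphere (default radius
7 voxels; desk-scale tests use 6³ volumes at radius 2) around every in-mask
voxel; `shuffle_bias_check` permutes voxel identities within every trial and
reruns the entire pipeline (PCA included) to build a null distribution of
the target statistic — centred on zero with symmetric tails when the
pipeline is unbiased.

## Regression suite and group inference

Recipes GLM1–GLM8 assemble named trial-wise design matrices: phase
indicators, entropy, reward, next-trial switching, phase transitions, the
exploited option's belief, entropy and pupil changes, and caller-supplied
series (regional signal, global mean). When runs are concatenated the bias
expands to one indicator per run. Delta conventions: the change-coupling
recipe (GLM6) uses forward differences Δx(t→t+1) = x_{t+1} − x_t — the
outcome-evoked change from the current trial to the next — for the
dependent ΔRS and the Δpupil predictor; the entropy-change regressors of
GLM7/GLM8 use the backward difference arriving at trial t. Differences are
never taken across run boundaries.

Within-subject fits are OLS with classical standard errors; group inference
is a one-sample t-test on per-subject betas (the summary-statistics
approach; a mixed-effects group stage is deliberately out of scope). The
change-coupling analysis regresses ΔRS on Δpupil + ΔENT + intercept per
subject on core-exploit trials with valid baselines, separately for
rewarded and unrewarded trials (subjects with < 10 usable trials in a split
are excluded), tests each split's betas and their paired difference, and
re-runs at lag ±1 for temporal specificity. The median split compares mean
ΔRS above vs below the subject's median Δpupil on unrewarded core-exploit
trials; median-valued trials go to the lower half.

Cluster-mass correction forms clusters on the group t map at a one-tailed
voxelwise threshold (p = 0.001) per direction, scores each cluster by its
summed |t|, and compares against the maximum cluster mass over random
subject sign-flips (≥ 8 subjects required). On pure-noise 12³ volumes with
19 subjects the measured family-wise error rate is ≈ 0.05.

Power: `sample_size_t(d, alpha, tails, power)` searches the smallest
per-group n at which an independent two-sample t-test (equal groups)
reaches the target power, with power computed exactly from the noncentral t
distribution. The two-sample family is used because it uniquely reproduces
the benchmark values 17 (d = 0.89), 6 (d = 1.58) and 5 (d = 1.77) at
α = 0.05 one-tailed and 80% power; note that d = 0.94 under the same
settings gives 15. The routine is cross-checked against statsmodels'
`TTestIndPower` in the tests.

## Problem sizes in the test suite

The suite favours scales at which every recovery is decisive within a short
run: the headline double dissociation uses 19 subjects x 800 trials x
200-voxel regions at five master seeds; the coupling recovery one 19-subject
cohort with lag and median-split controls plus 500 null cohorts for type-I
calibration (run on directly simulated null series, since the test's
calibration does not depend on the decoder); the bias guard 200 voxel-shuffle
permutations on a 60-voxel, 400-trial region; the FWE calibration 200
null cohorts x 100 sign-flip permutations on 12³ volumes. Searchlight tests
use 6³ volumes at radius 2.

## Known limitations

- The observer's leak is uniform; structured transition functions
  (similarity-weighted, volatility-adaptive) are not modelled.
- s is fixed at 1/20 and never fitted to behaviour.
- Synthetic patterns are trial-resolution and spatially white; searchlight
  results on them say nothing about spatial smoothness effects.
- Group inference is the summary-statistics t-test; between-subject variance
  heterogeneity is not modelled.
- The CLI pipeline handles synthetic cohorts only; adapters for external
  eye-tracker or imaging formats are out of scope.
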