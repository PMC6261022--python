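# Methods

`ostfmri` estimates individualized optimal stopping times (OSTs) for a
task-fMRI acquisition: the volume at which a subject's trial-type
activation estimates have stabilized enough that further scanning adds
little. The pipeline has four stages — behavioral simulation, volume-wise
GLM, exponential-decay convergence modeling, and classification-based
validation — plus a synthetic data generator that stands in for scanner
data throughout.

## Stop-signal paradigm and race-model behavior

The task is a performance-adjusted stop-signal task (SST): 300 go/stop
trials (75 stops), a fixed 2,000 ms inter-trial interval, three 20 s rest
blocks, and a short instruction block, acquired at TR = 2 s over 502
volumes. The stop-signal delay (SSD) starts at 250 ms and moves in a
one-up/one-down staircase: +50 ms after a successful inhibition, −50 ms
after a failed one (floored at 0 ms). This staircase targets ~50% stop
success regardless of the subject's speed.

Stop-trial placement is uniform over trial slots with no two consecutive
stop trials; because the per-trial timing beyond the ITI is not fully
determined by those protocol parameters, a per-trial stimulus window (default 1 s, so 3 s per
trial with the ITI) plus end-of-run padding fills the 502-volume scan,
both exposed in the configuration.

Behavior comes from an independent horse-race model: go finishing times
are ex-Gaussian (defaults mu = 450 ms, sigma = 80 ms, tau = 60 ms — a
standard choice RT distribution with a heavy tail), the stop process has
fixed latency SSRT (default 250 ms), and the stop wins iff
SSD + SSRT < go finish. Go omissions occur at rate 0.02. Under these
defaults the simulated stop-success rate averages 50% (the acceptance
script recomputes this), confirming the staircase does its job on a
synthetic performer.

Trial types follow the SST-GLM convention: SS/FS for stop trials by
outcome, and GG/GfSS/GfFS for go trials by the immediately preceding
task trial. The first trial and go trials after instruction or rest
default to GG (the neutral class). The SSD series is deterministic given
the outcome sequence, and the package asserts that round-trip.

## Synthetic IC timecourses

Each subject is a (502 volumes × 22 components) matrix emulating
independent-component timecourses of preprocessed fMRI in percent signal
change. Per trial, the evoked amplitude of component c for trial type L
is

    a = amp_mean[L, c] + state[L, c],

an impulse at trial onset convolved with the canonical double-gamma HRF
(response gamma shape 6, undershoot shape 16, ratio 1/6, peak normalized
to 1, evaluated in continuous time so design regressors and simulated
signal use the identical kernel). Added to this are a motor response at
every button press, low-frequency cosine drift (random coefficients on
the same 1/128 Hz DCT basis the GLM uses, so the noiseless model is
exactly identifiable), and stationary AR(1) observation noise
(marginal SD 1.0, lag-1 correlation 0.3).

`state` is the trial-by-trial amplitude deviation: an AR(1) process over
trials (one state per trial type × component) with per-trial coefficient
`amp_rho` (default 0.97) and marginal SD `amp_sd`. This "engagement
state" models slow attentional drift in responsiveness and is the dial
that controls convergence speed: a subject whose evoked amplitudes
wander presents the incremental GLM with a moving target, so the beta
trajectory keeps drifting and its convergence statistic decays slowly.
Two properties of this choice matter:

- With independent jitter (`amp_rho = 0`) the amplitude variance scales
  the convergence statistic multiplicatively but leaves its *decay rate*
  unchanged (a log-linear fit is invariant to scale), so iid jitter
  cannot create fast vs. slow convergers. Serial correlation is what
  converts amplitude variance into convergence speed. Measured on the
  defaults: median 1-half-life ~88 volumes at amp_sd 0.2 vs ~99 volumes
  at amp_sd 3.0, monotone in between.
- Inflating one trial type's amplitude variance does *not* selectively
  slow that type's own convergence: the slowly varying unmodeled
  residual of one type projects almost equally onto all trial-type
  coefficients, because the regressors share the HRF shape and are
  temporally interleaved. Convergence speed is therefore effectively a
  global property of the fit in this generator. Within-subject
  trial-type OST contrasts — which real task-fMRI data can exhibit —
  are not reproduced by this mechanism; group/arm-level contrasts
  are. Tests only assert the latter.

Head motion is a per-parameter Gaussian random walk (steps 0.01 mm;
rotations carried in radians) with occasional persistent translation
jumps of 0.6–1.5 mm at probability `spike_prob` (default 0.02) per
volume. Framewise displacement (FD) is the Power-style sum of absolute
backward differences with rotations converted to arc length on a 50 mm
sphere; baseline FD sits well below the 0.5 censoring threshold, so the
censored fraction matches the spike rate.

Cohorts default to 40 CD / 27 control subjects (30 and 14 males —
a realistic, deliberately unbalanced clinical composition). CD subjects receive an amplitude offset
(default 0.5 PSC) on the stop-related cells (SS and FS × first 8
components); all subjects get between-subject amplitude jitter
(SD 0.15) and a log-normal per-subject `amp_sd`
(median 0.6, log-SD 0.4) so convergence rates spread across the cohort.
Site effects and scanner differences are not modeled. What passing tests
on this cohort show is that the *pipeline* recovers planted group
structure and convergence differences — not that such structure exists
in any particular real population.

## Volume-wise GLM

The design contains six HRF-convolved trial-type regressors
(instruction, GG, GfSS, GfFS, SS, FS), an HRF-convolved motor regressor
at every button press, 24 motion regressors (raw, raw², backward
difference, difference², first difference row zeroed), an intercept, and
cosine drift columns up to 1/128 Hz. Volumes with FD > 0.5 are censored
by row deletion, identically at every step. Fitting starts at the 50th
volume (a 49-volume burn-in) or later if some trial-type or the motor
regressor has no support yet; a subject in which some regressor never
gains support is excluded with a sentinel rather than fit. For
t = t_start..T the model is refit on volumes 1..t and the six trial-type
beta vectors are saved, yielding the beta trajectory β_t.

Estimation is ordinary least squares (minimum-norm via SVD). AFNI-style
pipelines estimate this GLM by REML with ARMA(1,1) noise; OLS is used here
because the convergence statistic is estimator-agnostic, OLS is exactly
checkable against a normal-equations oracle, and an AR(1) prewhitening
flag exists for sensitivity checks. No bit-compatibility with AFNI is
claimed.

Numerics: with ~47 regressors, fits at early t (~50 rows) are genuinely
rank-deficient or severely ill-conditioned — short-window cosine columns
are nearly collinear and squared-rotation columns are tiny. Such volumes
are solved minimum-norm and flagged per volume. Two engines exist: the
default naive per-t `lstsq`, and a QR row-append recursion (square-root
recursive least squares) that updates the triangular factor per volume.
They agree to < 1e-8 wherever the per-t design is numerically full rank;
at flagged volumes the minimum-norm answer is numerically delicate and
small discrepancies between any two algorithms are expected.

## Convergence model and stopping times

Convergence of the trajectory is tracked by the sum of absolute
differences (SoAD) over components, per trial type:
SoAD(t) = Σ_c |β_t(c) − β_{t−1}(c)|. The SoAD series is modeled as a
single exponential decay N(t) = N0·e^(−λt), fit by regressing ln SoAD on
the volume index. Non-positive SoAD values cannot be log-transformed and
are excluded (count reported) rather than floored, which would inject an
arbitrary constant into the slope.

The line fit is iteratively reweighted least squares with Tukey bisquare
weights: tuning constant 4.685, scale = MAD/0.6745 computed on
leverage-adjusted residuals r/√(1−h), iterated to a relative coefficient
change below 1e-8 or 50 iterations — the documented defaults of the
standard robust line-fitting routine, implemented in-package because
neither scipy nor statsmodels applies the leverage adjustment. An OLS
toggle supports sensitivity comparisons.

λ = −slope; t½ = ln 2 / λ. λ ≤ 0 (a non-decaying subject) is a
first-class outcome: the fit is flagged invalid and the stopping time
falls back to the last acquired volume — mirroring real subjects whose
responses never stabilize. The OST at k half-lives (k = 1..4, removing
50/75/87.5/93.75% of the initial SoAD) is

    stop_volume = t_start + round(k · t½),

rounded half-up, clipped at T (last volume's betas substitute when the
estimate exceeds the acquisition). The decay clock anchors at the first
fitted volume because no SoAD exists before it; counting from volume 0
is available behind a flag and recorded in outputs. A subject's overall
OST at fixed k is the maximum across the four task trial types.

## Validation

Features are the four task trial types' betas (GfSS, GfFS, SS, FS × 22
components = 88 dimensions) read out at a stopping volume; the condition
(trial type × k) determines each subject's stop volume via that
subject's OST for that type, and the full-task condition reads out the
final volume. Classification is CD vs Con with a linear soft-margin SVM
(cost 1, no feature scaling by default; implemented via a precomputed
linear Gram matrix, which is mathematically identical to the linear
kernel and much faster under resampling) in balanced leave-one-out
cross-validation: for each left-out subject the CD group is subsampled
to the control size (54 training subjects for a CD test, 52 for a Con
test), 1000 independent draws by default; the fraction of draws
predicting the true label is the subject's fractional score, the
headline accuracy is the mean fractional score (majority-vote accuracy
also reported). Fractional scores keep the signed-rank test well defined
on 67 continuous values.

Accuracy vs chance uses the one-sided one-sample Wilcoxon signed-rank
test against 0.5; condition-vs-full-task comparisons use the paired
one-sided signed-rank with Bonferroni correction over a family of 16
(4 trial types × 4 half-lives), configurable. Signed-rank and rank-sum
tests use exact distributions for n ≤ 25 without ties and the normal
approximation with continuity correction otherwise; both are
cross-checked against exact enumeration in the tests. An optional step
regresses participant sex out of every feature dimension before
classification.

Behavioral validation correlates, across subjects, the mean reaction
time of a trial type inside the truncated window (trials with onset
before stop_volume × TR) with the full-task mean RT. Subjects whose
truncated window spans the whole acquisition are excluded (their
correlation is trivially perfect); successful-stop trials have no RT by
definition and are rejected with a dedicated error.

## Reproducibility and problem sizes

Every stage is a pure function of (config, seed); per-stage and
per-subject streams are derived by hashing "seed:stage:index" (31-bit),
so adding a subject never perturbs the others. All outputs are plain
TSV/CSV/JSON written with 17-significant-digit floats; rerunning a
configuration reproduces the files byte for byte.

The test suite exercises most components on a shortened protocol (80
trials / 20 stops / 160 volumes) and reserves the full 502-volume,
67-subject cohort for the acceptance checks; the cross-validation checks
use 100 resampled training sets per fold (scaled down from the 1000 the
method specifies at full scale). The acceptance script's quantity —
the staircase's stop-success percentage — uses 20 full-length simulated
runs.

## Known limitations

- The generator's engagement-state mechanism produces between-subject
  convergence differences but not within-subject trial-type differences
  (see above); real data presumably contain type-specific
  nonstationarities this model lacks.
- OLS (optionally AR(1)-prewhitened) rather than REML/ARMA(1,1); early
  ill-conditioned volumes are minimum-norm and flagged.
- Censoring is row deletion; zero-weighting inside the solver is not
  implemented.
- No site/scanner covariates, no voxel-space synthesis, no spatial ICA;
  component timecourses are generated directly.
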