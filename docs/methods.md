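# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Task model

A session is four continuous blocks of twenty trials with two cues. Per
block the CS+ appears 12 times and is reinforced on 4 of them (a 33%
rate on CS+ presentations); the CS- appears 8 times and is never
reinforced. Cue roles alternate between blocks. Stimuli last 4 s with a
12-s inter-stimulus interval; reversal instructions occupy a 10-s epoch
after trials 20, 40, and 60, inserted into the timeline for both groups
(the uninstructed group sees a fixation period of the same length, so
one timeline serves both).

Sequences are drawn by rejection sampling over within-block shuffles
with a bounded retry budget (10,000 attempts per block): shuffle the
roles, reject on the cue-run constraint (no cue more than twice in a
row, counted across block boundaries — "condition" is read as cue
identity, not US status), then place the US trials on CS+ positions
that are mutually non-adjacent, non-adjacent to the previous block's
last shock, and late enough that each cue has appeared at least twice
after the instruction. Generation is deterministic in `(config, seed)`;
seeds 1 and 2 define the two canonical trial orders that cohorts
alternate over, mirroring a two-order design. The abstract-level "30%"
and methods-level "33%" reinforcement figures conflict; the generator
implements the explicit per-block counts (4 of 12).

Reversal windows pair each instruction's post-instruction,
pre-reinforcement trials with the equally many unreinforced trials of
the same cue immediately before the instruction. Pre-window trials are
restricted to unreinforced presentations because reinforced trials
carry US-evoked responses rather than CS responses.

## Learning models

Expected value (EV) of the presented cue updates by the delta rule with
constant learning rate α; the unpresented cue's EV carries forward. The
instructed variant mixes the two cues' EVs with weight ρ immediately
after the pre-instruction trial's update: ρ = 0 is a no-op (the model
nests the feedback-driven variant), ρ = 1 exchanges the values. The
mixing conserves the EV sum for any ρ and keeps EVs in [0, 1] for valid
parameters. Initial values are 0.5/0.5 for the feedback variant and
0.75/0.25 by original role for the instructed variant (instructed
subjects are told the initial contingencies); both are overridable,
which the nesting tests rely on. EV is attributed to cue onset and the
prediction error δ = r − V to cue offset, matching their placement in
the fMRI design.

## Observation model and fitting

SCR on unreinforced CS trials is assumed linear in EV with a
per-subject intercept and slope. The across-subjects fit treats (α, ρ)
as fixed effects for the group: for each candidate parameter vector,
each subject's EV timecourse is built on their trial order, the subject
is fit by OLS, and the summed squared error over the concatenated
predictions is minimized. Within-subject fits use the same objective
with one subject. US trials do not enter the regression (their scores
reflect the US response and serve normalization); this is the
`analyze="unreinforced"` default.

Minimization is Nelder-Mead with dispersed restarts (default 10; the
restart seed makes them reproducible). Two parameterizations are
provided:

* **Unbounded (default for across-subjects fits).** The simplex moves
  in natural parameter space, restricted only to a broad feasibility
  box (α ∈ [−0.5, 1.5], ρ ∈ [−1, 2], infinite SSE outside). A bounded
  estimator folds all sampling error at a boundary to one side, so at a
  true ρ = 0 its mean is biased upward by roughly the sampling SD
  (~0.06 under the default recovery conditions); the unbounded estimate
  is centered on the truth. Point estimates are reported as found, and
  clipped copies are kept in `params_` for simulation use.
* **Logistic-bounded (default for within-subject fits).**
  Single-subject SSE surfaces are flat and occasionally globally
  minimized at uninterpretable values (α > 1, ρ < 0), which inflates
  the spread of individual estimates; constraining both parameters to
  (0, 1) through a logistic transform regularizes the ensemble of
  individual fits, whose summary statistics then live on the
  interpretable scale.

Goodness of fit is reported both as raw SSE and as the Gaussian
deviance −2·logLik = N·log(2π·SSE/N) + N with the residual variance at
its maximum-likelihood value; the deviance convention is a package
choice, so SSE is always reported alongside it. A noiseless exact fit
(SSE ≈ 0) flags the deviance as degenerate instead of reporting −∞.
Subjects with constant SCR are excluded with a warning. Optimizer
tolerances (`xatol` 1e-6 on parameters, `fatol` 1e-12 on SSE) keep
noiseless self-fits within 1e-3 of the generating values. Group
differences in ρ use a pooled-variance two-sample t-test on the
within-subject estimates (df = n₁ + n₂ − 2).

## SCR scoring

Waveforms (200 Hz) pass a 25-Hz low-pass windowed-sinc FIR (order 64,
Hamming) and a 10-sample Gaussian smoothing kernel, both applied
forward-backward so the pipeline is exactly zero-phase (the even-length
kernel cannot be zero-phase in one pass). A trial's score is the
base-to-peak amplitude of the first response whose onset — a local
minimum followed by a rise of at least 0.01 µS/s sustained for 0.25 s —
falls 0.5–4.5 s after cue onset (after the US, for reinforced trials);
deflections under 0.02 µS count as non-responses. The onset/peak rule
is an explicit algorithmic stand-in for human scorers and is
configurable. Scores are square-root transformed and divided by the
subject's mean transformed US response (division, not subtraction, so
normalized responses read as fractions of the US response); a subject
with no positive US response cannot be normalized and raises. A
*learner* shows strictly greater mean normalized SCR to unreinforced
CS+ than CS- trials in the second half of block 1; ties classify as
non-learners.

## Synthetic cohorts

Per trial, amplitude = max(0, intercept + slope·EV + habituation·n +
ε), with ε ~ N(0, noise_sd²); US trials add a truncated-normal
US-evoked amplitude. Subject intercepts and slopes are Gaussian across
the cohort, and a mixture fraction of non-learners has near-zero slope.
Defaults (slope 0.5 ± 0.15 µS per unit EV, intercept 0.2 ± 0.08 µS,
habituation −0.0015 µS/trial, noise 0.25 µS, US amplitude 0.8 ± 0.2 µS,
35% non-learners) put normalized differential effects and learner
fractions in the range such cohorts show empirically; no noise
magnitudes are published for this paradigm, so these are configuration,
not claims. The optional waveform renderer places a unit-peak canonical
impulse ((1 − e^(−t/0.75))·e^(−t/2), truncated at 1% of peak) at a
uniform 0.5–4.5-s latency per response.

The generator emulates exactly the structure the analysis assumes —
linearity in EV, Gaussian noise, linear habituation. It does not
emulate scanner or movement artifacts, non-responders with intact US
responses, latency-dependent amplitude changes, or SCR superposition at
short ISIs. Passing recovery tests therefore show the estimators are
correct and well-calibrated *under the assumed observation model*, not
that real SCR obeys it.

## Two-level behavioral analysis

Unreinforced trials are effect-coded ±½ for Stimulus (original CS+ vs
CS-) and Reversal (original vs reversed contingencies); the interaction
column is ±½ for current CS+ vs current CS- (the sign of the product,
rescaled so its beta equals the mean differential response). Reversal
boundaries follow the instructions in the instructed group and the
first shock on the previous CS- in the uninstructed group. Time is the
standardized trial index. Stage one fits each subject by OLS (columns
with zero variance in a subset are flagged and return NaN for that
effect); stage two regresses each beta on a centered group code, so the
intercept tests the within-subject effect controlling for group and the
slope tests the group difference (one-sample t-tests when only one
group is present). On balanced noiseless data the two-stage estimates
equal pooled OLS exactly; a random-intercept MixedLM (statsmodels) is
wired in as an independent cross-check, not as the implementation.

The instructed-reversal contrast codes the differential response by the
*new* contingencies in both the pre- and post-instruction windows and
averages (post − pre) over the three reversals per subject, followed by
a one-sample t-test (df = n − 1). Under full reversal (ρ = 1) this
equals twice the differential EV scale; under ρ = 0 the pre and post
differentials cancel.

## fMRI design construction

Cue epochs are 4-s boxcars at onset (sticks available), cue offsets are
sticks, EV modulates the onset event, shock (0/1) and PE modulate the
offset event, and instructions contribute a 10-s boxcar. Modulators are
mean-centered before convolution by default. Columns are built at 16
bins per TR (TR = 2 s), convolved with a double-gamma HRF (modes at 6 s
and 16 s, amplitude ratio 6, unit peak normalized on a fixed 1-ms
reference grid so kernels at different resolutions share one scale),
and downsampled to the TR grid. Orthogonalization is off by default —
two EV regressors keep their shared variance symmetrically, as needed
when contrasting instructed against feedback-driven EV — and when on,
each modulator is residualized against all earlier columns in declared
order. The collinearity report computes pairwise correlations and VIFs
on the TR-resolution columns but evaluates rank on the raw per-trial
modulator values, where δ = r − V makes EV, shock, and PE from one
trace exactly dependent; convolution onto different event supports can
mask that dependence.

## Problem sizes in the test suite

Monte-Carlo suites use: parameter recovery — 100 replicate cohorts per
ρ* ∈ {0, 0.5, 1} at α* = 0.06, n = 20 subjects, noise at half the mean
EV slope, habituation and the non-learner mixture disabled (the
recovery question concerns the estimator under the assumed model);
group discrimination — 100 replicates of 20-vs-20 cohorts at ρ* = 0.9
vs 0; two-level calibration — 200 injected-effect and 500 null
cohorts. Within-subject Monte-Carlo fits use 5 optimizer restarts
(the objective is a smooth 2-parameter surface; restart count is an
exposed option defaulting to 10).

## Known limitations

* The hybrid associability model is out of scope (its equations are not
  published); only EV-based variants are implemented.
* The deviance convention is one of several possible; comparisons
  across packages should use SSE.
* Single-subject ρ estimates are weakly identified at low α and low
  SNR; within-subject means inherit a centering bias toward 0.5 under
  the bounded search when the data carry little signal. Group-level ρ
  estimates for feedback-driven cohorts are likewise noisy under the
  full observational model (sqrt normalization, habituation, learner
  selection): single cohort draws can land well above zero even when
  the generating process never uses instructions.
* The scoring rule is an explicit algorithm, not a reproduction of any
  particular human scorer; round-trip accuracy is demonstrated only on
  synthetic waveforms with the canonical impulse shape.
* No imaging data are fitted anywhere; the design module stops at the
  design matrix and its diagnostics.
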