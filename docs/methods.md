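# Methods

`recalib` simulates and analyzes a three-block visual–vestibular cue-conflict
recalibration experiment.  This note documents the generative model, the
analysis procedures, the numerical choices, and what the synthetic data can
and cannot establish.

## Paradigm and generative model

**Trial schedule.** A session has three blocks.  *Pre*: single-cue
(vestibular-only or visual-only) 2AFC heading discrimination over ten signed
log-spaced headings (±1°, ±2°, ±4°, ±8°, ±16°), `reps_pre` (default 10)
repetitions per (cue, heading), randomly interleaved.  *Recalibration*: only
combined-cue trials, with the vestibular and visual headings offset to
opposite sides of the nominal heading by Δ/2 each.  |Δ| ramps from 2° to 10°
in 2° steps (8 trials per increment by default, headings cycled in shuffled
order), then holds at 10° for an additional 12 trials; no choice is
collected and fixation alone is rewarded.  The sign of Δ (Δ⁺: vestibular
offset rightward, visual leftward) is fixed within a session.  *Post*:
single-cue probe trials (10 repetitions per cue × heading) randomly
interleaved with combined trials at the maximum Δ (4 per heading) that
maintain the recalibrated state.

**Rewards.** Pre-block: 95% reward probability for correct choices, none for
errors.  Post-block single-cue trials are rewarded that way only when the
implied other-cue heading (offset by the full Δ) lies on the same side of
straight ahead; otherwise reward is stochastic (70%, choice-independent), so
feedback cannot undo the recalibration being measured.  Combined post trials
use the same rule with their two actual cue headings.  Rewards do not feed
back into the generative observer (no within-block learning is modeled).

**Stimulus kinematics.** Velocity follows a Gaussian bell over 1 s with
13 cm displacement and 0.41 m/s peak.  The temporal SD is implied:
σ_t = 0.13/(0.41·√(2π)) ≈ 0.126 s, giving a biphasic acceleration with peak
≈ 1.97 m/s² (≈ 2 m/s²).

**Behavior.** Choices are drawn from a lapse-contaminated cumulative
Gaussian per cue and block: P(right|h) = λ/2 + (1−λ)·Φ((h−μ)/σ).
Recalibration is a *step*: μ changes between the pre and post blocks (the
analyses only ever compare pre vs post; within-block dynamics are out of
scope).  Combined-cue trials use a weighted-average observer
(h_eff = w·h_vest + (1−w)·h_vis, default w = 0.6 reflecting the vestibular
dominance of the measured shifts).  This combined observer is a stand-in —
the analyses never consume combined-trial choices — and is flagged as such.

**Batch conditions.** When simulating many sessions, the Δ⁺ generative mean
shifts are +1.5° (vestibular) and −0.9° (visual), mirrored under Δ⁻,
echoing the measured population means (≈1.1–1.8° vestibular, ≈0.7–1.1°
visual, vestibular larger).  A shared per-session recalibration strength
(mean 1, SD 0.8) scales both cues' shifts, with residual per-cue SDs of
0.6°/0.5°.  The shared strength is what couples the two cues across
sessions — it reproduces both the ≈2° across-session dispersion of
vestibular shifts and the strong correlations between neuronal and
perceptual shifts; with independent per-cue variability those correlations
would be much weaker than observed.  Session-wise pre-block biases are
N(0, 0.8°); thresholds default to σ = 4° (vestibular) and 3° (visual);
lapse 0.02.

**Neurons.** The bin rate is
`baseline + [slope_cue·(h_cue − tuning_shift) + choice_gain·C]·m(t)`,
C ∈ {−1, +1} (0 without a choice), clipped at zero, with Poisson counts in
100 ms bins on a grid from −1.0 to +1.3 s (all analysis windows align to
bin edges; a rounded zero-truncated Gaussian noise model exists for
analytic cross-checks).  `m(t)` is the normalized stimulus velocity, or its
leaky integral (τ = 0.5 s, unit peak) for sustained responses that persist
past stimulus offset.  The default tuning slope is 2 spikes/s/deg at
baseline 20 spikes/s — the steep-tuning-around-straight-ahead regime that
the screening criteria deliberately select for (neurometric threshold
≈ 5–10°, comparable to behavior).  Tuning shifts, like PSEs, step between
pre and post; recalibration-block trials already carry the post values.

**Area profiles.**
* *MSTd-like*: each cue's tuning shift tracks that cue's perceptual shift
  (+0.4° jitter); slopes ~1.5/2.0 spikes/s/deg (vestibular/visual),
  velocity-locked, modest constant choice gain (2 spikes/s).
* *PIVC-like*: vestibular tuning tracks the vestibular perceptual shift;
  visual slopes are N(0, 0.01 spikes/s/deg) — below what the tuning screen
  can detect at session trial counts.
* *VIP-like*: *both* cues' tuning shifts track the *vestibular* perceptual
  shift (so visual tuning moves contrary to visual perception), choice gain
  halves after recalibration (6 → 3 spikes/s), sustained temporal mode.

## Analyses

**Psychometrics.** Binomial ML fit of the lapse-contaminated cumulative
Gaussian, with λ either free on [0, 0.1] or pinned at 0 (both treatments
are available because the original toolbox settings are not knowable;
shifts must compare matching treatments).  Five deterministic (μ, σ)
restarts; ties broken by likelihood then smaller σ.  PSE shift =
μ_post − μ_pre; a positive value (rightward curve shift) is a leftward
perceptual shift.  Only single-cue trials enter per-cue fits.

**Firing rates.** FR = counts/duration over the stimulus window (0–1 s);
baseline = mean FR over the 1 s before onset, per block.  Tuning =
OLS regression of baseline-subtracted FR on heading over the narrow ±16°
range; "tuned" means slope p < 0.05; preferred side = slope sign (fixed
from the *pre* block and reused for post, preventing sign flips from
corrupting shifts).  Raw (unsubtracted) FRs feed the neurometrics — the
z-scoring supplies its own reference; both choices are exposed as options.

**Reference-anchored neurometrics.** Per cue, FRs of *both* blocks are
z-scored with the pre-block pooled-across-headings mean and SD (pooling is
what makes "z = 0 is the pre-recalibration mean" well defined).  Per
heading, a criterion sweeps the z-range in 100 equal steps and the ROC
point (I(0 > c), P(z > c)) is recorded; the trapezoid area is the ideal
observer's probability of calling that heading's responses larger than the
reference.  The reference value 0 is always included in the criterion set
and the path carries both one-sided limit points there, which makes the
area independent of the grid resolution at the only abscissa transition and
exactly equal to the exceedance count (ties at the reference split evenly).
AUC maps to P(rightward) directly for right-preferring neurons, mirrored
otherwise; a cumulative Gaussian weighted by trials-per-heading gives the
neurometric PSE.  Neuronal shift = post − pre PSE, same sign convention as
behavior.

**Curve fitting.** Neurometric curves are fit by a batched, damped
Gauss–Newton least-squares iteration over (μ, log σ) with probit-regression
initialization, vectorized across bootstrap resamples and neurons (checked
against `scipy.optimize.curve_fit` in the tests).  Fits escaping |μ| > 90°
or σ outside [0.05°, 150°] are flagged unreliable.  Estimates carry a small
common positive offset from Poisson skew/discreteness (≈ +0.6° at baseline
20 spikes/s); it is identical in both blocks and cancels in shifts.

**Screening.** A (neuron, cue) enters group analyses iff (1) tuned pre *or*
post and (2) the bootstrap SD of the neurometric PSE is < 10° in *both*
blocks.  The bootstrap (default B = 1000; B = 100 in the validation
experiments, where the SD estimate only has to clear a 10° threshold)
resamples trials with replacement within heading; refits that fail the
reliability envelope are dropped, and if more than 20% drop the SD is +∞.

**Sliding windows.** 200 ms windows stepped by 100 ms, centers 0.1–1.2 s
(12 windows, ending before the choice saccade); reference stats are
recomputed per window from the pre block; the preferred side stays fixed
from the full-window pre-block tuning.

**Choice analysis.** Pearson partial correlations of stimulus-window FR
with heading given choice (R_h) and with choice given heading (R_c), choice
coded −1/+1, p-values from the t transform with n−3 df; raw FRs by default
(config switch for baseline-subtracted).  Pre/post comparisons use paired
two-sided t-tests on the *squared* partials (unique variance explained).
Choice-conditioned tuning curves mask cells with fewer than 3 trials; the
overall curve is exactly the count-weighted mean of the conditioned cells.

**Group statistics.** Sign-flip pooling maps shifts onto a
conflict-reducing-positive axis (vestibular flipped in Δ⁻, visual in Δ⁺).
Neuronal vs perceptual correlations use raw signed shifts of screened
records, both Δ signs in one cloud.  The pooled OLS regression is compared
with a by-monkey random-intercept-and-slope mixed model; ML likelihoods
feed AIC/BIC (REML likelihoods are not comparable across these models; the
REML fixed effect is reported alongside), and the LMM is "preferred" only
if it wins on both.  Singular random-slope fits fall back to random
intercepts, flagged.  All t-tests are two-sided at α = 0.05 unless a
one-sided decrease is the stated hypothesis.

## Validation experiments and problem sizes

`recalib.evaluation` re-derives every stage's behavior from scratch:
ROC-vs-count-oracle agreement (1000 random z sets, n ∈ [5, 200]);
psychometric recovery (200 sessions, 10 headings × 20 reps, μ bias and a
+1.5° step); neurometric recovery (±3° injected shifts, 100 neurons per
sign, 10 reps/heading); the behavioral sign pattern (50 sessions per Δ
sign); area correlation signatures (40 sessions × 2 neurons per area,
mixed Δ); choice-signal reduction (100 replicates of 50 one-neuron
sessions); screen calibration (1000 flat-Poisson neurons); and the
within-stimulus time course (25 sessions per temporal mode, windows with
fewer than 10 converged fits reported as r = 0).  These sizes give stable
statistics for each check while keeping a full run to a few minutes.

## What passing does and does not show

The generator realizes exactly the statistical structure the analyses
assume: linear tuning around straight ahead, block-stationary rates,
Poisson counts, lapse-symmetric observers, step recalibration.  Passing
therefore demonstrates that the pipeline measures what it claims to measure
(no sign errors, correct anchoring, calibrated screens, adequate power at
session-scale trial counts) — not that the biological claims hold; real
recordings add non-Poisson variability, nonstationarity, correlated noise
across simultaneously recorded neurons, eye-movement artifacts and
non-linear tuning, none of which are emulated.  An adapter for externally
recorded session data (same tabular schema) is deliberately deferred.

## Known limitations

* The combined-cue observer is plumbing, not a fitted integration model.
* Neurometric PSEs inherit a small Poisson-skew offset (cancels in shifts).
* The LMM comparison can be optimizer-sensitive for few monkeys; three
  optimizers are tried before falling back to random intercepts.
* Degenerate inputs (zero reference SD, one-sided choices, < 3 distinct
  headings) are flagged or refused rather than silently fit.
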