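# Methods

## The observer model

The package models single-trial choices in steering-wheel contrast
tasks as a three-way multinomial logit. Each side's contrast is mapped
through the saturating contrast-response function
`f(c) = c^n / (c50^n + c^n)` (semi-saturation `c50` in (0, 1],
exponent `n > 0`, `f(0) = 0`, `f(c50) = 1/2`), and the two decision
variables `z_L = b_L + s_L f(c_L)` and `z_R = b_R + s_R f(c_R)` are the
log odds of choosing left or right versus withholding (no-go). The
no-go category is the reference: its log-odds are fixed at zero, so
`p_L = e^{z_L}/D`, `p_R = e^{z_R}/D`, `p_0 = 1/D` with
`D = 1 + e^{z_L} + e^{z_R}`. Probabilities are computed with max-shift
normalization and are stable for |z| well beyond 700.

Model assumptions worth stating explicitly: choices are conditionally
independent across trials given the stimulus; there are no lapse/guess
floors (the logit is implemented exactly as written above); no history
terms (win-stay, choice kernels) enter the decision variables; and the
two sides contribute separably. Contrast is stored as a fraction in
[0, 1] everywhere; percent appears only at I/O (`--percent`), and
signed contrast (negative = left) is purely a display axis.

For forced-choice (2AFC) data, conditioning on a go response gives
`P(right | go) = logistic(z_R − z_L)`. Strict 2AFC datasets are fit in
this binary reduction; since only the bias difference is identifiable
there, it is stored in `b_right` with `b_left = 0`.

## Fitting

Maximum likelihood with a two-level scheme:

- **Inner (convex):** at fixed `(c50, n)` the likelihood is a
  multinomial logistic regression in `(b_L, b_R, s_L, s_R)` (or three
  parameters under the `equal_sensitivity` constraint `s_L = s_R`, or
  the binary 2AFC reduction). It is solved with L-BFGS-B using analytic
  gradients on per-condition sufficient statistics (choice counts per
  stimulus condition), which makes the cost independent of trial count.
  Parameters are boxed at |b|, |s| ≤ 30; hitting the box signals
  separation and sets `converged=False`.
- **Outer (non-convex):** `(c50, n)` is searched on a 12 × 12
  log-spaced grid (`c50 ∈ [0.02, 1]`, `n ∈ [0.3, 8]`) and the best grid
  point is refined with Nelder-Mead on log-parameters under the same
  bounds. The grid+refine choice is deliberate: the profiled likelihood
  in `(c50, n)` is smooth but non-convex, and at this problem size the
  full sweep costs well under a second.

Sensitivities are deliberately unconstrained in sign: cortical
inactivation can drive an effective sensitivity to or below zero, and
a positivity constraint would bias the inferred effect sizes.
Error-triggered repeat trials (flagged in the trial table) are excluded
before any fitting or curve estimation. Data with all choices in one
category are non-identifiable and returned as a flagged boundary
result rather than an exception.

`fit_shared_nonlinearity` fits several trial-table groups (e.g.
control and laser trials) with a single `(c50, n)` optimized on the
pooled likelihood and per-group linear parameters. This is the
prerequisite for comparing decision variables across conditions: the
inactivation effect is `Δz_side = z_side(0.5; control) −
z_side(0.5; laser)`, reported per session, with a paired one-sided
t test (contralateral > ipsilateral) across sessions and exact
Wilcoxon rank-sum tests between regions (exact null for ≤ 10 sessions
per group, counting ties without correction; normal approximation with
tie correction above that). Degenerate paired differences (zero
variance) map to p = 0, 0.5, or 1 by the sign of the common gap.

Cross-validation is stratified by stimulus condition (default k = 10,
seeded; unstratified folds with a warning when a condition has fewer
trials than folds, which also covers leave-one-out). Two held-out
metrics are reported: argmax choice-prediction accuracy — the fraction
of held-out trials whose observed choice has the highest predicted
probability, with ties broken in the fixed order left / no-go / right —
and the mean probability assigned to the observed choices. Argmax
accuracy is the primary metric; the assigned-probability mean is the
smoother alternative.

## Psychometrics

Proportion curves use exact Clopper-Pearson 95% intervals
(two-sided). The 2AFC psychometric function is a cumulative Gaussian
with two lapse parameters, `p_R(x) = λ_L + (1 − λ_L − λ_R)
Φ((x − μ)/σ)` on signed contrast, fit by bounded ML from a small
multi-start (lapses in [0, 0.3]); bound-hitting fits are flagged.
The learning curve is a centered sliding-window binomial estimate of
p(correct) on easy trials (contrast ≥ 0.40), default window 200 easy
trials, truncated at the edges; it equals the plain window mean
wherever the window is complete. A transparent windowed estimator was
chosen over a state-space smoother so that every plotted point is an
exact binomial summary of identifiable trials; the window size is a
parameter. The criterion-crossing rule requires both the point
estimate above the criterion level and the CI lower bound above
chance (0.5). Correctness on zero-contrast forced-choice trials is
undefined and such trials are never "easy"; in unforced-choice data a
zero-contrast no-go counts as correct.

## Signal operators

- **Wheel turns.** Velocity is wheel position differenced and smoothed
  with a 50-ms boxcar (`wheel_velocity`). Detection is a Schmitt
  trigger on |velocity|: onset when it rises above the high threshold,
  offset at the first later sample below the low threshold; the band
  between the thresholds is the hysteresis that suppresses
  re-triggering on ripple. Default thresholds are 5× and 2× the
  trace's robust noise scale (1.4826 × MAD), re-estimated per trace.
  Events still open at the end of a trace are dropped.
- **ΔF/F.** Baseline `F0` is the minimum of the 1-s boxcar-smoothed
  fluorescence over a 20-s sliding window (centered by default; a
  causal trailing window is available by flag). The output is a causal
  exponentially weighted filter (τ = 0.2 s) of the fractional change
  `(F − F0)/F`. Dividing by `F` rather than `F0` is unusual but
  intentional — it is the form implemented here as primary — and a
  `/F0` variant sits behind `divide_by_baseline=True`. Both forms are
  invariant to rescaling the raw trace. The smoothing constant for the
  baseline (1 s) is a package default, configurable.
- **Event-triggered averages** drop events whose window leaves the
  trace (counted), report mean and SEM per lag, and flag the
  single-event case (SEM undefined). Per-neuron responses are min-max
  normalized to [0, 1] per row (constant rows excluded with a warning)
  and sorted by descending amplitude at a chosen lag. The response
  amplitude used for contrast-response analysis is the mean ΔF/F in a
  small window 1 s after stimulus onset (window parameters exposed).
- **Neural contrast fits** use `p + q f(c)` with the same `f` as the
  observer model: `(p, q)` is a weighted linear least-squares
  subproblem at fixed `(c50, n)`, searched on the same grid with
  Nelder-Mead refinement. Flat data (negligible `q`) leave `(c50, n)`
  unidentifiable and are flagged.

## The simulator

The simulator is the package's source of study data; all tests and the
acceptance script run on it. Defaults define the simulated conditions:

- Detection contrast set {0, 0.06, 0.12, 0.25, 0.50} per side (the
  zero-zero condition only in unforced-choice variants); recovery and
  cross-validation studies use the 11-condition set
  {0, 0.06, 0.12, 0.25, 0.5, 1.0}. Discrimination pedestals
  {0, 0.10, 0.25} with the same difference set; sides are randomized
  and the pedestal is always `min(c_L, c_R)`.
- Reward rule: the higher-contrast side is correct; equal nonzero
  contrasts reward either go response with probability 0.5; no-go is
  rewarded only at zero contrast; no-go is invalid in 2AFC.
- Laser trials are scheduled independently of the stimulus with
  probability 0.30 per trial in inactivation sessions (one printed
  source says ≈1/3, another ≈30%; 0.30 is the default and the knob is
  exposed). Inactivation is injected as bias/sensitivity decrements on
  laser trials, so the true Δz at any contrast is available in closed
  form. The recovery study uses a base observer with control
  `z_R(0.5) = 3.0` and laser `z_R(0.5) = 0.1` — the scale of the
  example inactivation sessions this analysis targets; 7 sessions of
  400 trials at 30% laser probability.
- Learning trajectories grow sensitivity as
  `s(t) = s_final (1 − e^{−t/rate})` with fixed biases.
- Response times are lognormal with a contrast-dependent median
  (higher contrast, faster); they only exercise the response-window
  and no-go bookkeeping, and make no claim about chronometry.
- Wheel fixtures place one smooth (Hann) velocity pulse per go trial;
  ground-truth events are the Schmitt crossings of the noise-free
  kinematics at 0.5×/0.2× amplitude. Calcium fixtures are
  double-exponential transients (rise 0.1 s, decay 0.5 s) on a slowly
  drifting baseline.

What the simulator does **not** emulate: sequential dependencies
beyond the repeat-after-error rule, lapses and disengagement,
session-to-session drift, biomechanics of the wheel, eye movements, or
spatial spread of the laser. Passing recovery tests therefore shows
the estimators are correct and well calibrated under the model's own
assumptions — not that real mice satisfy those assumptions.

## Numerical choices and limitations

- Likelihoods are computed from per-condition counts with
  log-sum-exp; the brute-force per-trial likelihood is kept as a test
  oracle only.
- The MLE-dominance property (fitted likelihood ≥ generating-parameter
  likelihood) is asserted in tests up to 1e-6 to absorb optimizer
  tolerance.
- Grid bounds clip `c50` at 0.02 from below; data truly demanding
  smaller semi-saturation hit the edge and should be treated with
  suspicion anyway at these contrast sets.
- Per-session Δz estimates at 400 trials are noisy (SD ≈ 0.8 for the
  simulated conditions above); means across ≥ 7 sessions are
  approximately unbiased. Cross-region tests inherit the small-sample
  behavior of the exact rank-sum null.
- The problem sizes used by the test suite and acceptance script
  (e.g. 20 repeats for recovery studies, 10,000-trial sessions,
  50,000 trials for the chance-level check) were chosen to make
  sampling error small relative to the tolerances asserted, while
  keeping the whole suite comfortably runnable on a laptop.
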