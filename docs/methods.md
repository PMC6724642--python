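# Methods

## Model

Time is discrete with one step per second; there is no sub-step integration.
Absolute steps are 1-based: steps 1–20 are pre-stimulus, steps 21–100 are
stimulus-on (constant unit amplitude). All unit states start at 0, so every
pre-stimulus series is exactly zero.

The dynamical primitive is the leaky integrator

    linear:     x(n+1) = w1·x(n) + w0·u(n)
    squashing:  x(n+1) = tanh(w1·x(n) + w0·u(n))

For the linear unit the step response has the closed form
`x(n) = w0·U·(1 − w1^n)/(1 − w1)` (w1 ≠ 1); with `w0 = 1 − w1` the asymptote
equals the input amplitude and the rise time grows as w1 approaches 1. The
pure accumulator `w1 = 1` grows as `n·w0·U` and is reported by a separate
function rather than silently mishandled.

The full network has, per stimulus channel (tone, flash), a squashing Go
unit and a squashing No-Go unit, a linear sum operator
`s = w_go·g + w_nogo·q`, and a shared fixed linear final integrator
`x(n+1) = 0.9·x(n) + 0.1·(s_tone + s_flash)` whose state is the model's
response. Update order within a step is fixed: unit next-states from current
states, then sums from the *new* unit values, then the integrator from the
new sums. This ordering is what makes the cutoff-crossing steps (below)
well-defined and reproducible.

With the packaged reference weight set the fitted channels behave as
opponent processes: the Go unit saturates within one or two stimulus steps
(its recurrent weight is far above 1, so tanh latches near 1), while the
No-Go unit declines slowly toward a negative equilibrium. Their weighted sum
is a transient pulse whose peak time encodes the trained interval; the tone
sum's late equilibrium is slightly negative, reproducing the below-baseline
late responding seen on tone trials.

## Saliency (compound trials)

On compound trials only, each channel's raw sum passes through a
piecewise-linear saturation — slope equal to the channel's saturation
constant, clipped to ± that constant (the constant acts as both slope and
clip level, which is how the saturation equations read as printed) — and
through an AND-gated cutoff: transmission is zeroed when the *other*
channel's post-saturation sum exceeds a presence threshold ε and the
channel's *own* No-Go activation lies below its cutoff threshold. The gate
input uses the other channel's pre-cutoff sum, so a channel keeps gating its
partner even after being cut off itself. Once both gates trip, the final
integrator discharges geometrically with ratio 0.9 per step.

Numerical choices:

* **Cutoff tolerance.** The published cutoff thresholds carry four decimals,
  and the auditory threshold (−0.8632) is itself the rounded value of the
  tone No-Go activation at its crossing step (−0.86315245…). Threshold
  comparisons therefore use an absolute tolerance of 1e-4 (the rounding
  scale of the printed parameters). With it, the tone gate trips at absolute
  step 27 and the flash gate at step 54, matching the published crossing
  times; any tolerance in [5e-5, 1e-2] gives the same conclusions, and `<`
  versus `≤` does not matter at this scale.
* **ε = 0.01** ("a value close to zero"; the original value is unstated).
  The test suite checks that every conclusion is unchanged for
  ε ∈ {0.001, 0.01, 0.05}.
* **Latching** is available but is provably redundant with the reference
  weights (the No-Go trajectories are monotone after crossing); the latched
  and unlatched simulations are asserted identical.
* Negative sums are propagated as computed; saturation is odd and monotone.

Without saliency the whole stimulus-to-output map is linear in the channel
sums, so the compound response equals the sum of the single-stimulus
responses exactly (superposition); with saliency the compound peak falls
strictly between the tone-only and flash-only peaks (temporal averaging).

## Fitting

Trainable weights minimize the mean squared error between the final
integrator's output and a 100-bin target curve, over all bins including the
pre-stimulus segment. Fitting is staged: the tone stage trains the six
tone-channel weights with the flash input at zero; the flash stage trains
the six flash-channel weights with the tone weights frozen bit-identically;
the final integrator (0.1, 0.9) never trains.

Gradients are exact. `bptt_gradient` differentiates the loss by reverse
accumulation through the unrolled 100-step computation; the optimizer's
Jacobian of per-step residuals is assembled from forward-propagated state
sensitivities of the same unrolled graph (the two agree to machine
precision, and both match central finite differences — asserted in tests).
A finite-difference Jacobian fallback exists behind a config flag. Saliency
is excluded from gradient-based training because its switches are
discontinuous; the saliency constants are instead tuned by exhaustive grid
search on the compound-trial MSE, ties broken in first-in-grid order.

The optimizer is a damped least-squares (Levenberg–Marquardt) loop: solve
`(JᵀJ + λ·diag(JᵀJ)) δ = −Jᵀr`, accept the step only if the loss decreases
(λ/10 on acceptance, λ×10 on rejection, λ₀ = 1e-3), stop on a relative loss
reduction below 1e-12, a vanishing gradient, a stall at maximal damping, or
3000 iterations. The loss trace records accepted steps only and is
non-increasing by construction. Initialization draws input weights uniformly
in [−0.5, 0.5] and recurrent weights in [0.5, 1.5] — fitted solutions have
recurrent weights ≥ 1, and tanh saturation kills gradients far from that
regime — and then sets the two sum weights by exact linear least squares
(the output is linear in them given the unit trajectories). With this
scheme, a model-generated tone target is recovered to MSE < 1e-6 from 9 of
the 10 initialization seeds 0–9; weight *values* are not identifiable (the
loss surface is multimodal and the saturated Go unit is insensitive to the
magnitude of its recurrent weight), so recovery is judged at the
output-curve level only.

## Behavioral analysis

Curves are normalized to their maximum ("proportion of maximal response
rate"). The peak function fitted to the 80 stimulus bins is the dual
asymmetric sigmoid

    f(t) = y0 + A · σ((t − c + w/2)/s1) · [1 − σ((t − c − w/2)/s2)]

with independent rise/fall scales s1, s2 and a baseline offset y0 (the
original analysis names this family without defining it; the offset absorbs
residual baseline responding and the round-trip tests pin the behavior).
Fitting uses bounded non-linear least squares from several starting points —
the surface is multimodal for broad, plateau-like curves — keeping the best
sum of squares. A fit with R² < 0.5, or whose peak is pinned to the window
edge, is flagged invalid ("no clear peak function") and its rat is excluded
listwise, mirroring the one excluded animal in the reference table.

Peak time is the argmax of the fitted function on a 0.01-s grid; width-50 is
the span between the half-of-peak crossings on either side of the peak
(linearly interpolated; the right edge clamps at 80 s when the function
never falls below half). PT/W-50 and CV = W-50/PT are exact reciprocals per
rat. The omnibus test is a one-way repeated-measures ANOVA computed from the
standard two-way (subject × condition) sums-of-squares decomposition,
F = MS_condition / MS_(condition×subject), df = (k−1, (k−1)(n−1)); it is
invariant to per-subject constants. Post-hoc comparisons are
Bonferroni-corrected paired t-tests; only the induced ordering of condition
means (and, for peak times, all-pairs significance) is treated as a robust
conclusion — on the per-rat CVs the corrected pairwise tests leave only the
flash–compound contrast significant, although the ordering
compound > tone > flash is clear.

## Synthetic data

`make_curve` builds a deterministic 100-bin curve: flat baseline over bins
1–20, then a dual-asymmetric-sigmoid bump whose center and plateau width are
calibrated by fixed-point iteration on a dense grid so that the *full* curve
(baseline included — the same observable the analysis measures) has its
argmax at the requested peak time and its half-of-peak span equal to the
requested width-50. The rise/fall slope ratio is the spec's asymmetry,
steepened automatically when the requested combination would push the left
half-crossing before stimulus onset (early-peaked wide curves rise sharply,
as real peak data do). An optional late undershoot takes tone-like curves
below baseline; rates are clipped at zero. The binned maximum equals the
requested amplitude exactly.

Trial noise is per-bin Poisson on press counts (presses are events;
overdispersion is not modeled). Between-rat variation perturbs each rat's
peak time and width with clipped normal draws. Cohort defaults mirror the
published 15-rat dataset: per-type means (tone 4.7/9.1 s, flash 26.1/40.6 s,
compound 16.2/35.9 s), between-rat SDs equal to that table's per-rat
spreads, peak rates 1.10/1.28/1.23 presses/s, baseline 0.15 presses/s, and
64 trials per rat per type. Because the published per-rat spread already
contains measurement noise, stacking Poisson noise on top of it slightly
overstates total variability; with 64 trials the peak-time estimator's
single-curve SD is ≈0.5 s (tone) to ≈1.6 s (compound), so cohort-mean
recovery to ±0.5 s is comfortable for tone and tight for compound.

What passing synthetic tests do **not** show about real data: the generator
draws smooth unimodal curves from the same family the analysis fits (no
model mismatch), uses independent Poisson counts (no burst/sequential
structure in responding), and has no session, learning-curve, or
reinforcement-schedule structure. It validates the pipeline's arithmetic and
power, not the behavioral model itself.

## Problem sizes and determinism

All simulations use the 100-step protocol. The acceptance script's
quantities are deterministic; every stochastic path (weight initialization,
trial sampling, cohort draws) takes an explicit integer seed and is
bit-reproducible given it. The self-consistency training check runs 10 seeds
(~15 s); the end-to-end cohort check uses one 15-rat, 64-trial cohort
(seconds).

## Known limitations

* Stochastic trial-by-trial response generation and reinforcement-driven
  learning of the weights are out of scope; the model's output is a
  deterministic rate-like curve.
* Two recurrent units per channel and two modalities only.
* Refitting does not reproduce the reference weight *values* (multimodal
  loss; saturated units), only their output curve.
* The printed reference parameters are 4-decimal roundings, hence the 1e-4
  cutoff-comparison tolerance above; one printed table average (the tone
  PT/W-50 ratio) is inconsistent with its own per-rat entries and is not
  used by any check.
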