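# Methods

This note documents the models, numerical choices, and open design
decisions behind `myograsp`, and what its synthetic-data tests do and do
not demonstrate.

## Synthetic sEMG model

Surface EMG during a sustained contraction is well approximated, for
classifier-development purposes, by band-limited noise whose amplitude
tracks neuromuscular drive. The generator produces, per channel,

```
x(t) = g(label(t)) ⊛ h_rise · n_band(t) + n_base(t) + a_pl sin(2π f_pl t + φ)
```

where `n_band` is unit-variance Gaussian noise shaped by a 4th-order
Butterworth band-pass (default 20–450 Hz), the gesture gate
`g(label(t))` (mV) is smoothed by a first-order lag `h_rise` with a
50 ms time constant (real neuromuscular drive has no step
discontinuities), `n_base` is white sensor noise (default SD 0.02 mV),
and the optional powerline term defaults to 0.05 mV at 50 Hz. Samples
are clipped at ±6 mV, the saturation of the modelled acquisition chain,
which also enforces the documented 0–6 mV signal envelope.

Default activation gains are 1.5/0.4 mV (channel 1/2) for *grasp* and
0.4/1.5 mV for *open*, emulating two distinct muscles of which each
responds preferentially to one movement; *rest* drives nothing. These
defaults are deliberately high-SNR: they model a clean, well-placed
electrode pair.

A subject session (`make_subject_dataset`) alternates grasp and open
bouts (default 10 repetitions of 5 s holds, 2 s rest between bouts),
mirroring a standard acquisition protocol. All randomness flows from one
integer seed; identical parameters are bit-reproducible.

**What passing tests show — and do not.** The generator's statistics
are stand-ins: amplitude and band match the stated acquisition envelope,
but the distributional shape is not calibrated to recorded traces. High
recognition accuracy on these signals demonstrates the pipeline's
correctness (features separate when the underlying drives separate),
not expected field performance. Electrode shift, cross-talk, fatigue,
motion artifact and day-to-day variability are not modelled.

## Signal conditioning

Defaults: 4th-order Butterworth band-pass 20–450 Hz plus an IIR notch at
50 Hz (Q = 30), both applied forward–backward (zero phase) so per-sample
gesture labels stay aligned; software gain 1.0 keeps units in mV
(amplification is a hardware concern). The cutoffs are the standard
surface-EMG choices consistent with content in 0–500 Hz at 1000 Hz
sampling; no published filter chain was available to copy, so all
parameters are configurable (including a 60 Hz notch).
`filter_response` reports the chain's magnitude response as applied,
i.e. the squared single-pass response.

## Windowing and features

250 ms windows stepped by 100 ms give `floor((N − W)/S) + 1` left-aligned
frames; a frame's label is the per-sample majority, ties resolved toward
the earlier-starting gesture (transitions are otherwise ambiguous). Both
durations must convert to whole sample counts at the recording's rate.

Feature definitions per channel over a window of N samples x_n:

- iEMG = Σ|x_n|·dt with dt = 1/f_s (discretized rectified integral)
- RMS = √(Σx_n²/N)
- MAV = Σ|x_n|/N (hence iEMG = MAV · N · dt identically)
- ZC: count of consecutive pairs with x_n·x_{n−1} < 0 and
  |x_n − x_{n−1}| ≥ threshold (default 0.01 mV). A literal
  printed-formula variant that counts *non*-crossing pairs
  (sgn(x_n·x_{n−1}) = 1) circulates in the literature; it contradicts
  the feature's name and standard practice and is exposed only behind
  `printed_rule=True` for auditability.
- VAR = Σ(x_i − x̄)²/(n − 1) (unbiased sample variance)
- MIN: the raw minimum sample of the window. Definitions using |min| or
  a rectified envelope exist; the raw minimum is the literal reading and
  is easily swapped.

The default recognition set is {VAR, RMS, MIN}; columns are ordered
channel-major, feature-minor (`ch1_VAR, ch1_RMS, ch1_MIN, ch2_VAR, …`).

## Fisher discriminant

Scatter matrices use the count-weighted between-class form
S_b = Σ nᵢ(uᵢ−u)(uᵢ−u)ᵀ and the per-sample within-class sum, so the
total scatter decomposes exactly as S_t = S_b + S_w; the grand mean is
taken over all m training samples. No further per-class normalization is
applied — the nᵢ weights in S_b and the implicit per-sample weighting in
S_w already account for unequal class sizes.

Numerical choices:

- **Ridge**: S_w can be singular with few windows or correlated
  features; the generalized eigenproblem is solved against
  S_w + εI with ε = 1e−6 · trace(S_w)/d (floor 1e−12) — deterministic
  and scale-aware.
- **Canonicalization**: eigenvectors are unit-norm with the first
  nonzero component positive, making serialized models reproducible.
- **Components**: min(c − 1, d) directions are kept by default (one for
  the two-gesture task); configurable for c > 2.
- **Decision rule**: nearest projected class mean, equivalent to the
  midpoint threshold for two balanced classes; distance ties break
  toward the earlier class in sorted label order. Class order is sorted
  lexicographically so that refitting permuted data yields an identical
  model.

The scikit-learn discriminant serves as a cross-check oracle in the test
suite only; the fitted path is entirely this module.

## Evaluation protocol

Per subject: 128 balanced windows (64 per gesture), split 64/64 with
stratification (class counts preserved to ±1), seeded and reproducible.
Accuracy = 100 · trace/total on the confusion matrix. Baselines use
scikit-learn: Gaussian NB (variance floor 1e−9 of the largest feature
variance), k-NN with k = 5 (Euclidean), CART with Gini impurity and
depth 4 — k, depth and floor are conventional defaults, exposed in
config. An SVM is not built in; the comparison harness accepts pluggable
classifiers so one can be added externally. Wall-clock comparisons are
hardware-dependent and are never asserted.

## Grasp controller

One controller tick corresponds to one analysis frame (100 ms). Defaults:
10 mm stroke, 1 mm/tick position rate, 1.0 A current limit, linear
contact model (current = stiffness × compression past contact). A grasp
command advances the motor (position loop) until either the stroke ends
or sensed current reaches the limit, at which point the position is
clamped to the exact limit-current compression and the mode latches to
*holding* (current loop) — so simulated current never exceeds the limit.
An open command retracts to zero and returns to *idle*; rest leaves the
motor in place.

Decision smoothing is a majority vote over the last m = 3 frames
(rejects single-frame flickers at 200 ms added latency; three-way ties
fall back to the raw decision). Because the two-class model never saw
rest data, a confidence gate converts low-margin classifications to
rest: a command is issued only when the projected sample's margin
(distance to second-nearest projected mean minus distance to nearest)
is at least 0.5 × the inter-mean distance. Silent muscles project near
the midpoint between the projected class means, where this margin
collapses to zero, so rest activity does not actuate the hand. Whether
sensed current should also participate in intent recognition is left
out: the simulator implements current only as a grasp-termination
signal.

## Linkage kinematics

The finger's two vector loops (r4 + r6 = r3 + r5 and
r1 + r2 + r7 = r3 + r5 + r8, with rigid offsets θ4a = θ4 + δ,
θ5a = θ5 + β) are written in x/y components under the convention
x rightward, y upward, angles counter-clockwise from +x — published
component forms of these equations contain internal sign/function
inconsistencies, so the components here are re-derived from the vector
loops and validated by residual tests on constructed poses. With θ2
fixed to the frame and one angle driven (default θ1, the proximal
phalanx), the remaining four angles are solved by Newton iteration with
the analytic Jacobian (residual norm < 1e−12, cap 100 iterations, step
damping to stay on the guess's assembly branch; a condition number
above 1e12 raises a dead-point error). Trajectory sweeps use
continuation — each solution seeds the next guess — guaranteeing branch
consistency, and stop with a partial trajectory and diagnostic at the
first unassemblable point. θ6 is reserved for the passive distal
coupling and does not enter the closure.

The true link dimensions of the modelled hand are not published. The
packaged **reference geometry is illustrative, not measured**: it is
built by forward placement (choose plausible lengths and a nominal pose;
loop A then fixes r6, θ5 and loop B fixes r8, θ7 exactly), which
guarantees assemblability at the nominal pose, and its default sweep
spans an 84.5° proximal excursion — the stated joint limit of the design
it emulates, treated as a configuration constant rather than a
recomputable output. The actuator's 10 mm stroke maps to the driven
angle through a configurable relation (linear by default, with a
slider-crank arcsine option).

An independent grid-search oracle cross-checks the Newton solver in the
tests: for fixed θ1 the four equations reduce to one scalar equation in
θ3 (two-link closed form for θ4, θ5; loop B's length mismatch as the
residual), solved by dense grid plus bisection.

## Problem sizes

Default test and acceptance runs use: 200 random Gaussian problems for
the closed-form check, 20 problems × 1000 directions for
Rayleigh-quotient maximality, 10 synthetic subjects × 128 windows for
the recognition protocol, 100 randomized controller sessions, and
101-point stroke sweeps — sizes at which every check completes in
seconds while keeping the Monte-Carlo assertions stable across seeds.

## Known limitations

- The generator's gesture separability is by construction; it cannot
  falsify feature choices the way recorded data could.
- The controller is kinematic/quasi-static: no motor electrical
  dynamics, PWM, spring compliance, or contact mechanics.
- The kinematics module covers the four linked fingers' planar
  mechanism; the thumb's passive rotation is out of scope.
- Only single random splits are provided (a repeated-split utility can
  be built on `split_dataset` seeds); no significance testing between
  classifiers.
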