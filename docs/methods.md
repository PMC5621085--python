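# Methods

`lmradapt` implements a phase-dependent locomotion-mode-recognition (LMR)
pipeline for powered lower-limb prostheses, together with three unsupervised
adaptation strategies that keep it reliable when the input signals drift.
Because no public dataset exists for this setting, the package ships a
seeded synthetic gait-signal generator and runs the full system on it.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic evaluation does and does not show.

## 1. Recognition pipeline

**Inputs.** Seven surface-EMG channels (thigh muscles) and six load-cell
force/moment channels, synchronously sampled at 1000 Hz, with per-sample
gait-phase labels (five phases per cycle, phase 1 = foot contact) and
locomotion-mode labels for five modes: level walking (W), ramp ascent and
descent (RA, RD), stair ascent and descent (SA, SD).

**Windowing.** A sliding analysis window of 160 ms with a 20 ms increment
(50 ms in the online configuration, trading decision rate for compute).
A window's phase and true mode are attributed from its final sample — the
causal decision point. For a trial of `T` samples the window count is
`floor((T - L) / Δ) + 1`.

**Features.** Within each window the EMG is band-passed with a 20–420 Hz
8th-order Butterworth filter (forward filtering of the window's own samples;
the short start-up transient is accepted and identical for every window).
Four classical time-domain features are computed per EMG channel:

- MAV — mean absolute value;
- WL — waveform length, `Σ|x_{i+1} − x_i|`;
- SSC — slope-sign changes: interior samples that are a local extremum with
  at least one neighbouring step above a dead-zone `ε`;
- ZC — zero crossings where both neighbouring magnitudes exceed `ε`.

The dead-zone defaults to 1% of each channel's training-set standard
deviation — a conventional noise guard for threshold-free counts; the
counts use strict inequalities throughout. Mechanical channels contribute
the window maximum, minimum, mean and population standard deviation
(divisor `n`) of the raw samples. The fused vector is ordered EMG-first
(channel-major, MAV/WL/SSC/ZC) then mechanical (max/min/mean/std):
4×7 + 4×6 = 52 dimensions.

**Classifier bank.** One multiclass classifier per gait phase. Each is a
one-against-all (OAA) set of five binary RBF-kernel support-vector
classifiers over standardized features (per-phase mean/scale; zero-variance
columns pass through with scale 1). Hyperparameters (C, γ) are selected per
phase by stratified 3-fold cross-validated OAA accuracy over a log-spaced
grid (C ∈ {2⁻³, 2², 2⁷}, γ ∈ {2⁻⁹, 2⁻⁵, 2⁻¹}); ties keep the first grid
point in scan order. Each binary margin is mapped to a probability with a
Platt sigmoid `1/(1 + exp(A f + B))` fitted by maximum likelihood with
Platt's smoothed targets on *cross-validated* margins (3 folds), avoiding
optimistic calibration; the five OAA probabilities are renormalized to a
5-class posterior `p_k(n)`. Decision confidence is the Shannon entropy
`E(n) = −Σ_k p_k ln p_k` (nats; maximum ln 5 ≈ 1.609), computed on the
pre-vote posterior. A trailing majority vote over the last 5 decisions of
the trial (window shrinks at the trial start; ties go to the most recent
raw label) smooths the output stream. Kernels are precomputed per phase —
one pairwise squared-distance matrix re-exponentiated per γ — which keeps
grid search and repeated retraining cheap.

## 2. Adaptation strategies

All three strategies are unsupervised (they never see a testing label),
retrain only after a full trial, reuse the initially searched
hyperparameters, pseudo-label with pre-vote raw labels, and route every
augmented window to the classifier of its own gait phase. The augmented set
is unbounded by default (an optional FIFO cap is available).

- **EBA** (entropy-based): select exactly the windows with `E(n) < τ`,
  τ = 0.6 nats (strict inequality; the boundary value is excluded).
- **LIFT**: a window is selected iff exactly one OAA binary claims it
  (calibrated binary probability > 0.5); the claiming mode is its label.
- **TSVM** (transductive): for each binary problem, iteratively fit the
  hyperplane, move up to m = 5 points per side whose signed distance lies
  strictly inside the margin (0 < d < 1, "closest to 1" = largest below 1)
  into the labeled set with their predicted side, and refit, until every
  testing window is assigned (remaining points take the hyperplane's sign;
  an iteration cap is flagged if hit). The multiclass label is the argmax
  of the calibrated posteriors under the updated binaries; the bank carried
  to the next trial is then refit on base ∪ newly-labeled data so that its
  calibrators stay consistent.

With an empty augmented set, retraining is skipped: refitting identical
data with the same seed reproduces the same bank, so the skip is exact.

## 3. Synthetic gait-signal generator

**EMG model.** Channel c during (mode m, phase p) is
`env[m,p,c] · g · s_c · carrier + σ₀ · b · noise`, where the carrier is
unit-variance Gaussian noise band-limited to 20–400 Hz (4th-order
Butterworth prototype), `g` is a per-stride lognormal gain
(σ = 0.32) capturing stride-to-stride variability, `s_c` is the drift
amplitude scale, σ₀ = 0.08 is the baseline noise floor, and `b` its drift
multiplier. Envelope tables share a per-(phase, channel) base modulated by
mode-specific lognormal deviations (σ = 0.30), smoothed over 60 ms, and
crossfaded over 150 ms at mode transitions — motor patterns change over a
step, not at a sample; a hard switch would create windows whose content
belongs mostly to the old mode but whose label is the new one, an artifact
real recordings do not have.

**Mechanical model.** Per (mode, channel) two-harmonic profiles
`a₀ + gain·(a₁ sin(2πt* + φ₁) + a₂ sin(4πt* + φ₂))` over cycle fraction
t*, with per-stride lognormal gain (σ = 0.32), measurement noise
(σ = 0.18) and the drift offset. Mode deviations of the profile parameters
use σ = 0.11.

**Operating point.** The separation/noise parameters above were calibrated
once so that, with no drift, the trained bank scores ≈ 93–95% static-state
accuracy (mean over seeds) — the regime a practical LMR system occupies —
rather than at ceiling, where adaptation would have nothing to do.

**Drift.** `DriftState` holds per-EMG-channel amplitude scales, a baseline
-noise multiplier, a fractional lowering of the 400 Hz corner (fatigue
analog) and additive mechanical offsets. The *gradual* schedule is a
multiplicative random walk: each channel has a fixed seeded direction and
steps by `exp(±rate·(1 + 0.3 jitter))` per trial, with baseline growth
`exp(0.6·rate)`, spectral lowering `0.25·rate` and mechanical-offset creep
`1.0·rate` per trial. The default rate 0.035/trial was calibrated to
reproduce the qualitative pattern of interest: a static classifier falling
from the low-to-mid 90s to the mid 80s (or lower) over ten trials. Both
the EMG and the load-cell channels drift — gait-pattern re-learning changes
kinetics as well as muscle activity; with EMG-only drift the mechanical
features act as stable anchors and baseline errors at transitions become
structural rather than drift-driven. The *abrupt* schedule applies one step
(per-channel lognormal EMG scale factors σ = 0.45, baseline ×1.6, spectral
+0.08, small mechanical offsets) at a configured trial index, modelling a
socket don/doff plus a temperature change.

**Protocol geometry.** Each trial runs the task sequence
W→SA→W→SD→W→RA→W→RD→W (eight transitions) with 3 strides per mode and
0.8 s cycles (phases of 100/300/100/150/150 ms, ±10% seeded jitter), i.e.
≈ 21.6 s per trial. Mode changes occur at phase-1 onsets (foot contact),
so transitional periods are well defined.

## 4. Evaluation

**Transitional period**: from the phase-1 onset at/before a transition
event to the end of single stance (phase 2) in the following gait cycle —
one full cycle plus two stance phases under the synthetic phase convention.
Windows whose final sample falls inside any period are transitional; all
others are static. **Static accuracy** is the percentage of static windows
whose voted label matches the true mode (pre-vote accuracy is also emitted
for diagnostics). A **missed transition** is a period whose last in-period
voted decision is not the new mode; with ten trials the denominator is 80.
The **instability proxy** counts maximal runs (≥ one vote window) of wrong
voted labels during stance in the descent modes (RD/SD), where
misclassified prosthesis behaviour is most destabilizing; it is a synthetic
stand-in for user-reported instability events, not a human measure.

**Part 1 (gradual drift).** One session: 3 training repetitions, 10
gradually drifting testing trials. The static baseline and each strategy
classify the *same* trials; reports carry per-trial accuracy, missed
transitions, instability proxies and augmentation counts.

**Part 2 (abrupt shift, online).** Twenty testing trials at the 50 ms
online increment, alternating adaptive (EBA) and non-adaptive arms, with
the abrupt step between the fifth and sixth trial of each arm and a mild
session-long gradual drift (rate 0.015/trial) underneath — after a don/doff
the signals keep evolving, which is what makes a static classifier decay
rather than plateau. The non-adaptive arm never retrains; the adaptive arm
retrains only from its own trials.

## 5. Problem sizes, determinism, limitations

The shipped test-suite and acceptance-script runs use desk-scale sizes
chosen to keep a full run on one CPU short: the stationary-safety check
uses 4 testing trials per session, the drift and abrupt-shift checks use
the full 10-trial (per-arm) protocols at the default trial length, and
repeatability checks use 2-trial sessions; stochastic properties aggregate
10 seeded sessions (3 in the acceptance script).

Every random draw descends from named integer seeds via
`numpy.random.SeedSequence`; sessions, training, calibration folds and
retraining are bit-reproducible, and the CLI `all` command writes
byte-identical summaries across runs with the same seed.

What the synthetic evaluation shows: the implemented selection rules,
transduction, retraining loop and metrics behave exactly as specified, and
the adaptive strategies track both gradual and abrupt distribution shifts
that degrade a static classifier, without harming stationary sessions.
What it does not show: performance on real neuromuscular signals. The
generator's EMG is amplitude-modulated band-limited noise — it has no
motor-unit structure, no within-phase temporal dynamics, no fatigue-related
spectral compression beyond a corner shift, and no human adaptation in the
loop; mechanical profiles are smooth harmonics rather than measured
kinetics. Transition dynamics are a 150 ms crossfade, so transitional
windows are simpler than real terrain changes. Absolute accuracies and
missed-transition counts therefore characterize the simulator's operating
point, not any human subject; only the qualitative contrasts
(drift degradation, adaptive recovery, strategy rankings) are meaningful.

Known limitations: the unbounded augmented set grows linearly in session
length (the FIFO cap exists but is off by default, matching the studied
procedure); TSVM is an order of magnitude more expensive than EBA/LIFT and
its missed-transition behaviour is the weakest of the three, consistent
with its different adaptation mechanism; and phase labels are read from the
recording's ground truth (a prosthesis controller would supply them
online) — phase estimation from signals is out of scope.
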