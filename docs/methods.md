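# Methods

This note documents the models, numerical choices, and limitations behind
`reloop`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## sEMG conditioning and features

Two channels (wrist flexor, wrist extensor) in millivolts at 1000 Hz. The
offline chain is a 20–150 Hz Butterworth band-pass followed by a 50 Hz IIR
notch, then 5 s windows with 5 s steps and per-window RMS; the session
feature is the across-window mean RMS.

Choices the processing description leaves open, fixed here:

* **Order and phase.** Butterworth order 4 (`scipy.signal.butter`,
  second-order sections), applied forward–backward (`sosfiltfilt`) because
  the analysis is offline; zero phase preserves burst timing against the
  intent labels. The effective amplitude response is the squared magnitude;
  mid-band (100 Hz) gain remains within 0.5% of unity.
* **Notch.** Second-order IIR (`iirnotch`) at 50 Hz with Q = 30 (≈ 1.7 Hz
  −3 dB width), giving > 50 dB rejection at the line frequency after the
  forward–backward pass.
* **Edge handling.** Both filters use odd-reflection padding of 3 s rather
  than scipy's short default. The slowest transient in the chain is the
  notch (time constant ≈ 0.19 s); 3 s of padding lets any initial-condition
  transient decay below 1e-6 before the data proper, which is what allows an
  independent direct difference-equation implementation with zero initial
  state to reproduce the production output to better than 1e-6 relative per
  analysis window (the signal-chain oracle test).
* **Windowing.** Trailing partial windows are dropped, never zero-padded, so
  every RMS covers a full 5 s. Window count is floor((T − w)/s) + 1.
* **Validation.** Loaders and constructors reject NaN/Inf samples rather
  than imputing; RMS on filtered signals is the default (computing RMS on
  raw signals is possible by skipping `preprocess`).

## Threshold control

Calibration sets, per muscle, `thr_on = rest + k·(active − rest)` from the
mean RMS of rest and sustained-contraction recordings, with k = 0.4 by
default (configurable; in the clinic this gain is adjusted per user). If the
active RMS does not exceed rest, calibration fails loudly rather than
producing an unusable threshold.

The online decoder uses 0.2 s RMS windows advanced every 0.05 s — far
shorter than the 5 s feature windows, because a playable game needs
sub-second latency. Hysteresis (off-threshold = 0.8 × on-threshold) removes
boundary chatter; a noiseless ramp through threshold yields exactly one
command transition. Co-activation of both muscles decodes as NEUTRAL, the
safest reading of an ambiguous command. Both the window length and the
hysteresis ratio are configurable (`DecoderConfig`, `ThresholdPair`).

## Game simulator

The runner has 3 lanes (configurable), a 0.05 s tick, 10-minute trials, and
independent Poisson spawn processes for coins (0.5 /s) and obstacles
(0.2 /s) drawn once per trial from the seeded generator; a coin is worth 10
points. None of these constants are prescribed by the training protocol the
simulator reproduces — they are declared defaults, chosen to give a
command every few seconds without saturating the player. The protocol-level
facts are fixed: trials last 600 s, 4 trials per day with 300 s rests, and
the learning phase is 10 LEFT + 10 RIGHT + 10 further RIGHT reaches.

Deaths increment a counter and never end the trial (deaths per trial is the
recorded outcome); there is no invulnerability window. The state update is a
pure function of (state, command, config), so a trial replays bit-identically
from (seed, config, command log). Internally the simulator tracks spawned
and missed coins, giving the conservation invariant
`collected + missed = spawned` checked in the tests. An omniscient planner
(`plan_optimal_commands`, dynamic programming over tick × lane) provides the
"perfect player" used to validate the simulator against an independent
reachability oracle. Rendering is deliberately out of scope.

## IMU kinematics

Recordings are 125 Hz six-axis streams (accelerometer ±2 g, gyroscope
±2000 deg/s) from shoulder and elbow sensors, low-passed at 5 Hz
(zero-phase order-4 Butterworth). Out-of-range samples are rejected at
construction; ROM violations are flagged, never clipped.

* **Smoothness.** Jerk is the central-difference derivative of acceleration
  (one-sided at endpoints), in g/s. Curvature is computed on the graph
  (t [s], a [g]) as κ = |a''|/(1 + a'²)^{3/2} with both axes unscaled; the
  unit mixing is acknowledged — this is the curvature of the plotted
  acceleration curve, not a physical invariant — and a scaling hook exists.
  Both operators are second-order accurate on the interior (halving dt cuts
  the max error ≈ 4×, verified on analytic signals).
* **Orientation.** A complementary filter (blend 0.98): pitch and roll
  integrate the gyro and are pulled toward the accelerometer gravity
  direction; yaw is gyro-only (no magnetometer). Euler convention is
  intrinsic Z-Y-X, output in degrees, unwrapped before ROM so a sweep past
  180° is not aliased. A Kalman filter would be the heavier alternative; the
  complementary filter is sufficient for slow reaching movements where
  linear acceleration is small against gravity.
* **ROM.** max − min per axis / per Euler angle; plausibility bounds are
  shoulder 200° and elbow 180°, so e.g. a 350° shoulder sweep is flagged
  invalid (sensor artifact or mounting slip) but reported unmodified.

## Assessment scoring

Clinical fit uses inclusive bounds: length difference ≤ 1 cm, mass ≤ 0.5 kg,
socket traction displacement ≤ 2 cm with no skin discoloration. Completion
times are summarised per task or per difficulty (the ten ADL tasks split
6 simple / 4 complex by default; the split is configuration). The sample
standard deviation is reported as 0 with an explicit n=1 flag for single
trials. Yardstick reference times are configuration inputs — the national
standard's values are licensed content and are never hard-coded. The
Box-and-Block summary is blocks per 60 s per trial plus the mean.

Questionnaires: the 11-item task/prosthesis questionnaire and the 6-item
user questionnaire are 5-point Likert; the IMI is 7-point with five
subscales (interest/fun, cognitive ability, tension/stress, cognitive
choice, value/utility; four items each by default, remappable); NASA-TLX is
scored as unweighted raw subscale values (the RTLX convention) on a 0–20
item scale — pairwise weighting is not implemented because the protocol it
models did not report using it. Reverse-scored items are configurable and
none are reversed by default. Out-of-range or incomplete responses are
input errors.

## Pre/post comparison

Reductions are reported as positive percentages of the pre value,
(pre − post)/pre × 100, matching clinical phrasing; signed values are kept
in the machine-readable report. The Wilcoxon signed-rank test drops zero
differences (Wilcoxon's convention; Pratt's method available), assigns
average ranks to ties, and uses the exact null distribution for n ≤ 25 —
implemented as a subset-sum convolution over doubled ranks, equivalent to
enumerating all 2ⁿ sign patterns, exact in integer arithmetic even with
tied (half-integer) ranks. Above n = 25 a normal approximation with tie
correction and 0.5 continuity correction is used. Two-sided p is
2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1. Significance is α = 0.05 and no
multiple-testing correction is applied by default (a Holm flag exists in
spirit via per-call alpha; corrections were not part of the modelled
analysis). Association slopes are ordinary least squares.

`build_report` aligns subjects × tasks across sessions and fails with the
explicit offender list on mismatch; its output is deterministic and
independent of input row order.

## Synthetic data: what it does and does not emulate

* **sEMG.** Band-limited Gaussian carrier (white noise through the 20–150 Hz
  band-pass, normalised so a burst of amplitude A has RMS A/√2),
  amplitude-modulated by the intent envelope with 100 ms raised-cosine
  rise/fall (chosen to exercise the decoder's hysteresis), plus white noise
  at the configured SNR (20 dB default) and a 0.05 mV 50 Hz power-line
  component so the notch matters. Default burst amplitudes are 0.45 mV
  (flexor) and 0.40 mV (extensor). This is a feature-level surrogate:
  amplitude statistics and spectra are right for RMS/threshold pipelines,
  but there are no motor-unit action potentials, no spectral compression
  with fatigue, and no electrode-shift nonstationarity — so passing tests
  demonstrate pipeline correctness, not robustness to those real-world
  effects.
* **IMU.** Minimum-jerk Euler-angle trajectories between waypoints,
  differentiated analytically; body rates follow the exact Z-Y-X kinematic
  relation and the accelerometer reads the gravity direction plus noise
  (0.02 g, 0.5 deg/s defaults). Linear acceleration of the limb is
  neglected — valid for slow reaches, and the reason the complementary
  filter tracks within 2° RMS at default noise. An optional slow roll drift
  emulates compensatory trunk lean.
* **Sessions.** Baseline completion times: placing 150 s, submitting 90 s,
  ADL 12 s (simple) / 20 s (complex) — a pre-training ADL group mean of
  15.2 s, typical of trans-radial prosthesis users — and 16 blocks/60 s for
  the BBT. Between-subject ability is lognormal (sd 0.2), trial-to-trial
  noise lognormal (CV 0.10 by default), BBT noise 1 block sd. Programmed
  effects enter multiplicatively for CT and sEMG gain, additively for BBT.
  With `include_signals=True` the RMS features are *measured* by running
  30 s synthetic hold recordings through the full pipeline (pre and post
  drawn with independent carriers, so the recovered gain carries realistic
  measurement error ≈ 1%/√(BT) per recording); with `include_signals=False`
  the features are drawn from the model's expected values, the cheap mode
  used for the 200-replicate null simulation, which concerns completion-time
  statistics only.

All generators draw from named sub-streams (`stream_rng`) of one root seed,
so datasets are byte-reproducible and modules can be regenerated
independently.

## Problem sizes in the checks

The acceptance script and end-to-end tests use: a 30 s two-tone signal for
the chain oracle; 16 s labelled streams for decoder agreement; 100 random
15 s game trials for conservation; 20 session seeds × 6 subjects for
effect recovery (per-seed CT within ±3 points, seed-mean RMS gain within
±1 point — the per-recording RMS measurement error makes the seed mean the
meaningful recovery estimate); and 200 replicates × 20 subjects for the
null type-I rate. These sizes were chosen as the smallest that make the
statistical assertions stable across seeds.

## Known limitations

* The game's level structure and scoring constants are declared defaults,
  not reconstructions of any particular production game.
* Curvature and jerk are per-axis quantities; no magnitude-combined or
  dimensionless smoothness index (e.g. SPARC, normalised jerk) is provided.
* The questionnaire item texts are placeholders; only structure and scoring
  are modelled.
* Muscle-strength grading and association of strength ranks with outcomes
  beyond a least-squares slope are out of scope.
* No real-time acquisition, VR rendering, or prosthesis firmware interfaces.
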