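# Methods

This note records the model, the numerical choices and the known limits of
`imukin` in enough detail to re-derive or challenge any of them.

## Frames and conventions

* **Anatomical frame**: X vertical pointing *along* gravity (down), Y
  anteroposterior (front), Z mediolateral (right). All joint angles are
  reported in this frame; the calibration pose (upright, arms at sides,
  palms inward) defines 0° for every channel.
* **Accelerometer sign**: a resting device reads the +1 g reaction opposing
  gravity, `(-9.81, 0, 0) m/s²`. The simulator and the calibration share
  this convention.
* **Quaternions** are Hamilton, scalar-first `(w, x, y, z)`, unit norm,
  canonicalised to `w ≥ 0` (ties resolved by the first non-zero component),
  which fixes the double cover everywhere.
* **Euler angles** are intrinsic Tait-Bryan sequences; the default `ZYX`
  (yaw-pitch-roll) matches the column labels of optical-capture exports.
  All six Tait-Bryan orders are supported; the order is a reader/config
  parameter because the file dialects label axes but not a sequence.
* **Degrees at every public boundary, radians internally.** Angles are
  wrapped into `(-180, 180]`.
* **Earth magnetic field**: magnitude 48 µT, dip 35° (mid-latitude
  values), direction north = anatomical Y. Both are configurable; only the
  gravity/field *non-collinearity* matters to the math.

## Sensor-to-segment calibration

Mount rotations are `R_i = Rx(δ_odd)·Ry′(δ_even)` (intrinsic). The arm
sensor defaults to δ₁ = 270°, all other deltas to 0°; they are pure
configuration describing how the hardware is strapped on.

From `n` static samples the mount-corrected means `ā, b̄` give the TRIAD
basis `v₁ = â`, `v₂ = v̂₁×b̄`, `v₃ = v₁×v₂`, assembled column-wise into a
proper rotation `B`. Degeneracy thresholds: ‖ā‖ ≤ 1e-6 (no gravity) and
‖v₁×b̄‖ ≤ 1e-6 (field parallel to gravity) abort calibration with a
specific error — both are far outside any physical dip-angle
configuration.

The forearm is the reference segment (`M₂ = I` exactly). The arm's
correction is the **basis-transport rotation `M₁ = B₂ B₁ᵀ`**: for any
residual donning misalignment `D` (so the arm's corrected statics are
`D`-rotated), `B₁ = D B₂` and `M₁ = B₂ B₁ᵀ = Dᵀ` — the correction inverts
the misalignment exactly, and `M₁ R₁` maps the measured static vectors
back onto the anatomical gravity and field directions. This order of the
product is forced by that recovery property under the package's
column-vector/premultiplication convention; the same construction written
with row vectors reverses the product. The identity `B₂ B₁ᵀ = B₁⁻¹ B₂`
holds whenever `B₂ = I`, which is why the degenerate examples do not
discriminate between the two orders.

`M·R` applied to the *mean* acceleration lands, by construction, exactly on
the reference sensor's estimate of vertical; with noise, that estimate
itself carries an angular error that shrinks as `1/√n` (asserted
Monte-Carlo in the tests).

## Orientation fusion

The estimator is a 6-state quaternion error-state Kalman filter per sensor:
attitude error (anatomical frame) plus gyro bias (sensor frame).

* **Prediction**: exact exponential-map propagation with the trapezoidal
  average of consecutive gyro samples (`q ← q ⊗ Exp(½(ω_{k-1}+ω_k)·dt)`),
  second-order accurate; left-endpoint integration leaves an
  `O(θ̈ dt²/2)` mid-stroke error of over a degree at protocol speeds.
  `F = [[I, -R dt], [0, I]]`; process noise from the gyro angular
  random-walk density (default 0.2 °/s/√Hz) and a bias random walk
  (default 0.01 °/s per √s). Implementer defaults, not hardware data.
* **Observation**: the TRIAD attitude from each accel/mag pair, against the
  reference vector pair stored in the calibration (the forearm's corrected
  static means), so the filter's zero attitude coincides with the
  calibration pose. Innovation is the rotation-vector of
  `R_obs R̂ᵀ` with `H = [I 0]`. Base observation sigma 2° per axis,
  scaled by the accel/mag trust weights; the axis along gravity is
  magnetometer-determined, the two horizontal axes accelerometer-determined.
* **Dynamic gating**: a sample is *dynamic* when `|‖a‖ − g| > 10 % g` or
  the smoothed angular acceleration exceeds 30 °/s² or the de-biased rate
  exceeds 10 °/s. Dynamic samples have their accelerometer axes inflated
  by ×10³ in sigma — effectively removed from the update, which suppresses
  both attitude corruption and gyro-bias wind-up. The norm test alone is
  insufficient: linear acceleration perpendicular to gravity changes ‖a‖
  only quadratically, and tangential pollution peaks exactly where the rate
  crosses zero (movement onsets and turn-arounds), which is why the
  angular-acceleration term exists. The angular acceleration is estimated
  by central differences with a 5-sample moving average; the filter runs on
  recorded streams, so non-causality is acceptable and is the package's
  choice.
* **Initialisation**: attitude from the first sample's TRIAD; P₀ = (5°)²
  on attitude, (1 °/s)² on bias. Timestamps must be uniform within 10 %
  jitter. The filter is deterministic given stream and parameters.

Any estimator with the same contract (bounded error under constant gyro
bias, exactness under zero noise, time-shift invariance) would be an
acceptable substitute; the invariants, not the internals, are the
interface.

## Angle extraction

`R_rel = R(q_arm)ᵀ R(q_fore)` expresses the forearm in the arm frame
(relative mode is the default; a global/forearm-only mode would only differ
if the arm moved, which the protocol excludes). Extractors (1-based
indices):

* flexion-extension `δ = atan2(r₂₁, r₁₁)` — exact inverse of the elemental
  Z-rotation layout; positive flexion from the calibration pose.
* pronation-supination, upright: `Φ = atan2(r₃₂, r₂₂)` — exact inverse of
  the elemental X-rotation layout; positive pronation (palm down).
* pronation-supination, elbow flexed 90°: `Φ = atan2(r₁₃, r₃₃)`. This pair
  of entries equals `(sin Φ, cos Φ)` both for a pure Y-rotation and for
  `Ry(Φ)·Rz(90°)` — the physical posture where pronation rides on a held
  90° flexion — so one formula covers both readings of "about the Y axis".

`angle_series` defaults to an `auto` pose mode that switches the Φ
extractor to the flexed-90 formula when |δ| ≥ 45°. During pure flexion both
formulas read 0, so the switch is seamless; the threshold sits halfway
between the two postures. The per-sample rotation left after removing
`Rz(δ)` and the assigned Φ rotation is reported as an off-axis residual
diagnostic rather than discarded, because axial-rotation channels are the
ones most corrupted by off-axis interference in practice. Channels are
unwrapped with a 180° jump threshold (`numpy.unwrap`, period 360°).

Repetitions are counted by a Schmitt trigger: thresholds at the channel
midpoint ±15 % of the observed range, one repetition per low-to-high
transition, ranges under 5° counting as no movement. The initial state is
"high" only above the high threshold, so a series starting near the
midline still counts its first excursion.

## Synthetic sessions

The simulator executes a protocol of phases on a two-link geometry (arm
28 cm, forearm 25 cm, sensors at 2/3 of each segment from the proximal
joint — the lower third). The arm segment stays fixed; the forearm rotates
about the assigned anatomical axis (`Rz(δ)`; pronation `Ry(Φ)·Rz(90°)`
flexed, `Rz(δ)·Rx(Φ)` upright). Signals:

* gyro: body rate from exact finite rotation increments (central
  differences of the orientation trajectory), expressed in the mounted
  sensor frame;
* accel: specific force `p̈ − g` at the sensor position (central second
  difference of position), rotated into the sensor frame — so the
  accelerometer is *not* gravity-only during movement and the fusion gate
  is genuinely exercised;
* mag: the earth field in the sensor frame.

Velocity profiles: raised-cosine per repetition (smooth, bounded jerk)
by default, trapezoidal as an alternative; pronation-supination phases
oscillate sinusoidally `mid + amp·sin` so each repetition pronates first
and returns through supination, starting from the thumb-up 0° posture.

The default protocol is three blocks of five repetitions — flexion 0→90°,
flexion 0→145°, pronation-supination ±80° with the elbow flexed — at a
2.8 s period, preceded by 2 s of static calibration pose and a 1 s smooth
flexion transition before the pronation block: 45.0 s at 60 Hz, the
duration and rate of a typical validation session. The 145° and 80° maxima
are conventional physiologic values; real maxima are subject-dependent.

Noise model (seeded, reproducible bit-for-bit): white Gaussian noise of
0.05 m/s² (accel), 0.2 °/s (gyro), 0.5 µT (mag) per axis, plus a constant
gyro bias of magnitude 0.5 °/s (direction (1,1,1)/√3, identical on both
sensors — the bias is a calibration-residual stand-in, not a per-device
model). Sampling rates 30/60/120 Hz.

What the simulator deliberately does **not** model: soft-tissue artifact,
wrist/hand interference during pronation, magnetic disturbance,
donning-position drift, inter-system clock skew. Passing the synthetic
round trip therefore demonstrates the correctness of the mathematics and
the noise robustness of the filter — not the field accuracy of a physical
capture, whose errors against an optical reference are dominated by
exactly those unmodelled effects.

## Validation operators

Two series are compared by resampling both (linear interpolation, after
unwrapping) onto the grid of the slower one, estimating the inter-system
lag by maximising the normalised cross-correlation within ±2 s (flat
series get lag 0 with a degeneracy flag), and reporting per channel the
RMSE `√(Σ(aᵢ−bᵢ)²/N)`, the mean signed difference (bias), and the
range-of-motion difference. Lag resolution is one sample period; the
residual RMSE of a one-sample mis-lag is bounded by the signal slope times
dt.

## Problem sizes and tolerances

The test suite and the acceptance script run the full pipeline at its
natural size — 45 s sessions at 60 Hz (2700 samples per sensor) and a 60 s
bias-drift scenario at 60 Hz — plus 1000-rotation conversion sweeps;
numerical tolerances are 1e-9 for algebraic identities, 1e-6 for
conversion round trips and noiseless calibration recovery, 0.5° RMSE for
the noiseless end-to-end round trip (dominated by the `O(θ̈ dt²)` floor of
integrating sampled rates) and 2.0° under the default noise model.

## Known limitations

* One degree of freedom per channel: no carrying angle, no shoulder or
  wrist model, exactly two sensors.
* The flexed-90 pronation extractor assumes the flexion is held near 90°
  during axial rotation; large simultaneous flexion *and* pronation
  excursions land in the off-axis residual instead.
* Magnetometer disturbances are neither simulated nor rejected; the mag
  observation is always trusted at its configured weight.
* The gating thresholds (10 % g, 10 °/s, 30 °/s², 5-sample smoothing) are
  implementer defaults tuned for protocol-speed movements at 30–120 Hz,
  exposed on `FusionParams`.
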