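# Methods

`gaitmyo` estimates knee-extensor muscle activity (%MVC of the rectus
femoris and lateral gastrocnemius) per gait cycle from two inertial
measurement units — ankle/shank and knee — without skin-contact sensors at
use time.  Surface EMG is needed only once, to build training targets.  The
chain has three parts: per-cycle kinematics from the ankle IMU, %MVC targets
from sEMG, and a feed-forward network mapping one to the other.  This note
records the models, the tunable parameters, and the design decisions.

## 1. Kinematic chain

### Gait events

Events are detected on the sagittal-plane shank angular velocity (gyro
channel `gait.sagittal_axis`, default z): mid-swing (MS) is a positive peak
above `events.min_swing_peak` (default 80 deg/s); toe-off (TO) is the most
prominent negative minimum preceding MS and heel strike (HS) the first
prominent minimum following it (`dip_prominence`, default 30 deg/s); flat
foot (FF) is the start of the first interval after HS where |ω| stays below
`flat_threshold` (10 deg/s) for `flat_hold` (50 ms).  This is the standard
shank-gyro peak grammar; the thresholds were chosen once against the
simulator's waveform and are configuration, not constants.  A gait cycle is
HS → next HS; stance = HS→TO, swing = TO→next HS.  The first detectable
swing of a recording precedes the first detectable heel strike, so its
stride is reported with `cycle_index = -1` and no stance time.

### Attitude: adaptive-R quaternion EKF

A direct 4-state quaternion EKF propagates attitude with the gyroscope
(exact quaternion exponential per step, renormalized; process noise from
`ekf.gyro_noise_var`, default 1 (deg/s)², mapped through the kinematic
Jacobian) and corrects tilt with the accelerometer's gravity direction.
The measurement covariance adapts to the motion state through the windowed
statistic

σ_k² = (1/(N+1)) Σ_{i=k−N..k} (‖a_i‖ − 1)²,  a in G,

with `ekf.window_N` = 40 samples (100 ms at 400 Hz) and the same σ_k² on
all three diagonal entries of R — the norm statistic carries no axis
information, so an axis-resolved variant would be invented structure.  When
the sensor is quasi-static ‖a‖ ≈ 1 G, σ² → 0 and the accelerometer is
trusted (the gain is computed through a pseudo-inverse, since gravity
constrains only two rotational degrees of freedom and R may be exactly
zero); under dynamic motion σ² grows by orders of magnitude and the update
effectively vanishes.  Yaw is unobservable from gravity and rides on the
gyro alone; the initial attitude is taken from the first accelerometer
sample with yaw = 0.  Heading drift is harmless downstream because distance
uses the horizontal speed, not its direction.

### ZUPT velocity and stride length

Local acceleration is rotated to the global frame with the EKF quaternion,
gravity is subtracted, and units leave G only here (× 9.80665 m/s²).
Horizontal velocity accumulates a·dt inside "live" intervals and is pinned
to zero elsewhere, restarting from zero at each live-interval start — the
zero-velocity update that cancels integrator drift once per stride.  Two
interval conventions are implemented (`zupt.zero_interval`):

* `stance-only` (default): zero from flat foot to toe-off, live across the
  whole swing.
* `as-printed`: zero from heel strike to the *next mid-swing*.  For a
  symmetric swing whose velocity peaks at mid-swing this suppresses the
  first half of every swing and recovers only about half of each stride
  (the package's tests demonstrate this), which is why it is not the
  default; it is kept selectable because some instrument conventions state
  the interval this way.

Walking distance is X(t) = Σ‖v‖dt — a staircase for normal gait — and
stride i is the increment of X between consecutive heel strikes (the first
stride is X at the first heel strike).  Strides of `stride.min_length_m`
(default 0.30 m) *or less* are discarded as missteps; stride numbering
advances only for retained strides.  Per-cycle features are the swing-phase
peaks of ‖a‖ (G) and ‖ω‖ (deg/s) over the closed [TO, HS] range, the peak
horizontal speed, stride length, and stance/swing durations.

## 2. EMG targets

Raw sEMG (1000 Hz) is band-passed 20–450 Hz (4th-order zero-phase
recursive filter — the recordings are processed offline, so zero-phase is
preferable to causal; the band reproduces the analog front-end so simulated
raw EMG receives the same shaping).  The envelope is a centered sliding RMS
with a 100 ms total window, normalized by the number of samples actually in
the window (edges truncate; a literal 1/(2·t_window) time normalizer would
make the value unit-dependent).  Rectification is implicit in the squaring.
The maximum-voluntary-contraction (MVC) reference is the peak RMS of a ≥1 s
maximum-effort trial processed by the identical filter+RMS chain; %MVC =
100·RMS/reference, so the MVC trial itself peaks at exactly 100.  Note the
max-of-RMS reference is biased upward by ~15–20% of the estimator's
standard error structure (maximum of ~50 effectively independent 100-ms
windows over a 5 s trial); this cancels in cross-condition comparisons
because every value is scaled by the same reference.  Per-cycle targets are
the mean and maximum %MVC over each HS→HS interval, with the cycles removed
by the misstep filter removed here too so feature and target rows stay
paired.

Body covariates: BMI = weight/height² (kg/m²) and the lower-limb ratio =
calf length / lower-limb length (dimensionless).

## 3. Activity model

One single-output network per target (4 targets: average/peak × two
muscles), so the reported accuracies stay independent.  Inputs are the
eight per-cycle features (the six kinematic features plus the two body
covariates; a configuration flag of the feature list allows the strict
4-kinematic+2-body variant).  Features and target are z-scored with
statistics of the fitting data only; predictions are returned on the %MVC
scale.

Architecture and training: 7 hidden layers × 12 rectified-linear units,
linear output; Adam (lr 1e-3) on a log-cosh loss (smooth L2 core, L1
tails — robust to occasionally mis-segmented cycles); mini-batches of 32;
up to 1000 epochs with early stopping (patience 50) on a 10% held-out slice
of the training data, restoring the best weights; 8:2 train/validation
split by seeded uniform sampling.  All randomness flows from one seed, so a
fixed seed reproduces weights bit-for-bit on a fixed numpy version;
cross-version reproducibility is promised only at tolerance level.

Regularization: during training 20% of the *connections between nodes* are
randomly masked (inverted scaling, one mask per mini-batch; inference uses
the full network).  Connection-level masking was chosen over classic
unit-level dropout deliberately: in layers only 12 units wide, deleting
whole units removes most of the network's capacity (empirically capping
validation R² near 0.6 on the package's recovery benchmark), while deleting
20% of each unit's incoming weights regularizes without crippling the fit
(R² ≈ 0.85–0.90 on the same benchmark).  Unit dropout remains available as
`dropout_kind="unit"`.

The accuracy metric is the coefficient of determination.  Two variants are
implemented: `standard` (denominator Σ(obs − mean(obs))², the default) and
`as-printed` (denominator computed from the *estimates*' spread — almost
certainly a typographical variant in circulation, kept selectable; both
agree at a perfect fit).  A constant reference series makes R² undefined
and raises rather than returning a number.

`grid_search` exhaustively scores a hyperparameter grid, each point trained
3 times (distinct derived seeds and splits) and scored by mean validation
R²; `evaluate_repeated` re-splits/re-trains 20 times and reports mean, std
and the train-validation gap per target.

## 4. The simulator and what it does (not) show

The synthetic module generates the study conditions end-to-end: by default
10 strides of 1.2 m at a 2 Hz stride frequency (within the regular 1–4 Hz
walking band), stance fraction 0.6, 1 s of quiet standing on each side, a
5° mounting tilt, accelerometer noise 0.02 G and gyroscope noise 1 deg/s,
IMU at 400 Hz and EMG at 1000 Hz.

* Ankle trajectory: exactly stationary through stance; swing displacement
  follows a minimum-jerk quintic (velocity and acceleration vanish at both
  swing boundaries), plus a small quartic foot-clearance lift (4 cm).
* Shank angular velocity: balanced Gaussian bumps — positive mid-swing
  peak, negative toe-off/heel-strike dips — integrated to the attitude
  history.  The rotation is placed about the sensor/global z-axis so that
  the sagittal waveform appears on the detector's default gyro channel
  while the mounting tilt (about x) exercises gravity observability.  This
  is a geometric simplification, not an anatomical hinge model.
* IMU signals come from the exact inverse sensor model (rotate gravity plus
  the trajectory's second derivative into the sensor frame; body rates from
  the discrete quaternion log), so forward-integrating them reproduces the
  trajectory to discretization error.
* EMG is activation-envelope-modulated broadband noise (20–450 Hz band,
  unit variance), with phase-locked envelopes: rectus femoris bursts at
  weight acceptance and early swing (peak ~0.26 of MVC — level walking uses
  this muscle far below maximum effort), gastrocnemius ramps to push-off
  (peak ~0.5).  MVC trials ramp to a plateau at exactly 1.
* The feature-level generator draws per-cycle features from a 14-subject
  population (BMI 21.5 ± 3.4 kg/m², lower-limb ratio 0.43 ± 0.04, cadence
  ~N(1.9, 0.25) Hz) and builds the four %MVC targets as smooth mildly
  nonlinear functions of the features plus Gaussian noise with SD 5% of
  each target's range.

What passing tests show: the algorithms recover what they are defined to
recover — events, strides, attitude, envelopes, a learnable smooth
feature→activity map — under realistic sampling, noise and timing.  What
they do not show: performance on real gait (soft-tissue artifact,
anatomical hinge axes, turning, pathological patterns, electrode and
cross-talk effects, inter-subject variability beyond the modeled
covariates are all absent), so simulator accuracies are upper bounds, not
forecasts of clinical accuracy.

## 5. Numerical choices and degenerate inputs

* Quaternions are (w, x, y, z), sensor→global; sign fixed to w ≥ 0.
* EKF covariance is symmetrized each step; the update inverts the
  innovation covariance by Hermitian pseudo-inverse so σ² = 0 is exact, not
  special-cased.
* Zero-norm accelerometer samples skip the update (degenerate measurement).
* CSV round-trips are bit-exact: `%.17g` on write, `float_precision=
  "round_trip"` on read; a declared sampling rate disagreeing with the
  median sample interval by >1% is an error, never a silent resample.
* Event times are timestamps (s); sample lookup is nearest-neighbour.
* Problem sizes in the test-suite and acceptance script (10-stride walks,
  2000-cycle feature tables, 10–20 evaluation repeats) were chosen as the
  smallest sizes at which the statistics of interest stabilize.

## 6. Known limitations

* Single-statistic adaptive R lags the motion state by the window length
  (100 ms): early stance inherits swing variance (conservative) and early
  swing briefly inherits stance confidence (slightly optimistic).
* No magnetometer fusion and no gyro-bias state: heading is unobserved and
  long recordings would drift in yaw; stride length is insensitive to this
  by construction.
* The knee IMU is carried through I/O and simulation but contributes no
  features; the feature set is ankle-based.
* Per-cycle %MVC uses the per-sample envelope aggregated per cycle
  (filter → RMS → normalize → aggregate); recomputing one RMS per cycle
  would be a different, coarser estimator.
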