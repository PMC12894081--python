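# Methods

## Problem and model

A motorised mobility scooter (MMS) driver scans the environment by
turning the head shortly before executing a steering manoeuvre. Given a
head-yaw angle series `x_h(t)` and a steering-angle series `x_s(t)`,
the package quantifies this anticipation as the lag of the peak of the
windowed Pearson cross-correlation

    R_hs(ℓ) = corr( x_h[i+ℓ], x_s[i] )  over the maximal overlap,

for integer-sample lags ℓ within ±`max_lag_s`. The head series is
shifted *forward* by ℓ before correlating, so a head trace that
anticipates steering by `d` seconds peaks at ℓ = −d: **negative lag =
head leads steering**. The peak is the maximum of the *signed* r, not
|r|; under the sign convention below, coordinated turning produces
positive correlation, and anticorrelated peaks are not behavioural
coordination.

A rolling variant slides a window of `window_s` seconds in steps of
`step_s` seconds and computes a correlogram per epoch; the epoch count
is `floor((duration − window_s)/step_s) + 1` with duration counted as
`n_samples / rate` (so 1000 samples at 10 Hz is 100 s and yields 81
epochs at 20 s / 1 s). Per-course results across participants or trials
are summarised as mean ± sample SD (n−1 denominator), reported at two
decimals (r² at three), and |r| is banded verbally (≤0.30 very weak,
0.31–0.50 weak, 0.51–0.70 moderate, 0.71–0.90 strong, 0.91–1.00 very
strong, applied to |r| rounded to two decimals so the band edges are
exhaustive).

### Numerical choices

* **Window geometry.** Defaults: `window_s = 20`, `step_s = 1`,
  `max_lag_s = 5`; the window must exceed twice the lag range so every
  lag retains a meaningful overlap. Five seconds comfortably exceeds the
  ~1 s lags of interest while staying well under the window length.
* **Undefined correlations.** A window with zero variance in either
  signal has no defined correlation; it is flagged NaN, never coerced
  to 0. Averaging across trials excludes undefined cells pairwise and
  reports the contributing count; the sample SD needs ≥2 values.
* **Tie-break.** Equal maxima break toward the smallest |lag|, then
  toward the negative lag (head-leads reading preferred).
* **Sub-sample lags.** Parabolic interpolation through the peak and its
  two neighbours refines the lag below the sample interval. It is off
  in integer-sample tests and on in the CLI summary (`refine_peak`),
  since reported lags such as −0.45 s are finer than a plausible frame
  interval.
* **No detrending or tapering** inside windows: the statistic is applied
  to the raw angle values as defined.
* **Normality gate.** A Shapiro–Wilk test (α = 0.05, 3 ≤ n ≤ 5000) is
  logged before analysis; failure warns but does not block, since the
  correlation is used descriptively. Strongly periodic simulated angles
  routinely fail it — that is expected and visible in the demo.

## Synthetic drives

The generator defines the study conditions the tests run under.

* **Courses.** Quarter turn (90° arc, radius 2 m, between straights),
  left curve (90° arc, radius 4 m), slalom (obstacle interval 2.4 m,
  path width 1.2 m), up/down slope (±5% grade over 6 m each way), and a
  full circuit concatenating them with 3 m connectors. Gate geometry is
  the standard slalom test layout; radii and grades are package
  defaults, configurable, as no canonical values exist.
* **Vehicle.** Kinematic bicycle model, wheelbase 0.8 m (typical
  four-wheel MMS), constant speed ≤ 4 km/h (the scooter's speed cap;
  simulation default 1 m/s), sampling at 10 Hz (configurable; chosen
  because observed lags are multiples of 0.05–0.1 s). Steering tracks
  path curvature as δ = atan(L·κ) through a first-order actuator lag
  (τ = 0.3 s); the slalom is a sinusoidal weave of lateral amplitude
  width/2 and spatial period 2·interval, so the steering period is
  2·interval/speed. Throttle is a constant-speed hold. Sign convention:
  steering and head yaw are both positive leftward.
* **Head–steering coupling.** Pure delayed copy:
  `x_h(t) = gain · x_s(t + lead) + drift + ε`, ε white Gaussian (deg),
  drift an integrated random walk of intensity `drift_sd` deg/√s,
  default 0. Defaults: lead 0.6 s (middle of the observed 0.4–1.0 s
  regime), gain 1.5 (head excursions visibly exceed steering; exact
  ratio unknown), noise 2°. Fractional-sample leads are realised by
  linear interpolation and logged.
* **IMU synthesis.** Units of g; the body unit senses gravity tilted by
  the terrain grade, the lever unit additionally tilts by the steering
  angle on a configurable axis (default pitch; the physical
  axis-to-channel mapping on a given scooter is a configuration fact,
  not hard-coded). Road vibration (`vibration_sd`, m/s² per axis) is
  added identically to both units — common mode — and optional
  independent sensor noise only to the lever unit.
* **Landmark rendering.** A fixed synthetic canonical 68-point face
  (jaw, brows, nose, eyes, lips; non-coplanar, millimetres) is projected
  through a pinhole camera (default fx = fy = 600 px, 640×480, principal
  point at centre) with isotropic Gaussian pixel noise. A per-user
  reconstructed face model is out of scope; using a fixed model shifts
  absolute pose accuracy but not the comparative yaw dynamics the lag
  analysis consumes.

What the generator does **not** emulate: path-planning or
obstacle-avoidance variability, dynamic (inertial) vehicle response,
rider biomechanics, lighting/occlusion effects on landmarks, or
non-stationary coupling within a trial (except where tests construct it
explicitly). Passing tests therefore demonstrate correctness of the
measurement chain under its stated assumptions, not performance on real
recordings.

## IMU fusion

Quasi-static tilt from acceleration only:
pitch = atan2(aₓ, √(a_y² + a_z²)), roll = atan2(a_y, √(aₓ² + a_z²)) —
scale-invariant, valid when dynamic acceleration is small relative to
gravity, which holds at ≤4 km/h. No gyro fusion or Kalman filtering is
attempted; dynamic acceleration is treated as noise, with an optional
moving-average smoother. Differential compensation subtracts the
body-unit inclination from the lever-unit angle after aligning both
series (linear interpolation onto the common grid at the higher rate);
it is exact for common-mode tilt and linear in each argument.
Specific-force norms outside [0.5, 1.5] g are logged, not fatal.

## Head pose

`solve_pnp` estimates the head→camera rigid transform from ≥6
2D–3D correspondences: DLT on normalised image coordinates (sign fixed
by positive projective depths, rotation projected onto SO(3) by SVD)
initialises a Levenberg–Marquardt refinement of the pixel reprojection
residuals over a rotation-vector + translation parameterisation
(numeric central-difference Jacobian, multiplicative damping, accepted
steps never increase the error). Termination: accepted-step norm below
1e-10, a vanishing gradient, or 100 iterations; ten consecutive rejected
steps while the step is still large raises a divergence error. The
final RMS reprojection error is attached to the returned pose.

Euler convention: intrinsic yaw–pitch–roll about the camera-frame
vertical (y), lateral (x) and optical (z) axes, in that order. Putting
yaw first lets it span the full (−180°, 180°] range required of a
horizontal head rotation, with pitch the ±90°-bounded middle angle;
|pitch| > 85° triggers a gimbal-proximity warning. Yaw series are
unwrapped across the ±180° seam. Frames whose pose cannot be solved are
dropped and filled by linear interpolation in yaw, with a log entry.

## Design decisions taken where the design was open

* The lag search uses the signed maximum, not |r| (see above).
* The correlogram's "duration" convention counts whole samples
  (n/rate), making the documented epoch-count formula exact.
* The PnP cross-check in the test suite is an independent scipy
  trust-region least-squares solver started from a generic pose, kept
  deliberately separate from the production DLT+LM path.
* The slalom r SD summary cell recomputable from the three published
  per-participant means is ≈0.03; the printed 0.27 appears to be a
  misprint and is not used as a reference value.
* Machine-readable CSVs use ASCII hyphen-minus; only the human-readable
  report cells use the typographic minus (−) and ± signs.

## Problem sizes

The simulation studies run at 10 Hz: lag recovery uses a 100 m slalom
trial (≈101 s) with entry and exit straights — the straights break the
slalom's ~4.8 s periodicity so the correlogram peak is unambiguous
within the ±5 s search range — over 240 seeded runs spanning lead times
0.4–1.0 s, gains 0.5–2 and noise up to 25% of the steering SD. PnP
accuracy uses 100 random noiseless poses within ±60° yaw plus 50 noisy
frames at 1 px landmark noise. These sizes make the full suite and the
acceptance script complete in seconds while leaving the Monte-Carlo
margins (recovery rate, median errors) stable across seeds.

## Known limitations

* The delayed-copy coupling is a mechanism model, not a cognitive one;
  real head–steering coordination varies with task phase and load.
* Quasi-static tilt ignores centripetal acceleration during turns; at
  higher speeds a gyro-aided estimate would be needed.
* The fixed canonical face biases absolute yaw for faces far from the
  canonical geometry; comparative (lag) analyses are insensitive to a
  smooth monotone miscalibration but not to frame-rate jitter, which is
  not modelled.
* Near-periodic courses alias the correlogram at multiples of the
  course period; keep `max_lag_s` below the manoeuvre period or include
  aperiodic course sections, as the shipped courses do.
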