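# Methods

## Signal model and units

All detectors operate on a `SensorFrame`: synchronized channels on a uniform
time grid at sampling rate `fs` (100 Hz by default; everything is configured
in seconds and converted with `round(duration · fs)`, so the same thresholds
work on 25 Hz logs).  Acceleration is stored in m/s² and normalized to g
(9.81 m/s²) as the per-sample vector magnitude `sqrt(ax² + ay² + az²)/9.81`.
The device is modeled in a front-trouser-pocket mount with the z axis
anti-parallel to gravity when standing (a configurable axis remap covers
other mounts).  Non-uniform timestamps are rejected at ingest rather than
silently resampled, because the detectors index windows as `j + n·fs`; an
explicit linear-resampling utility is provided for off-rate logs.  A
pluggable pre-filter hook (default: identity) is the seam for device-specific
calibration.

## Barometric altimetry

`H(P) = 44330·(1 − (P/P0)^(1/5.225))` with `P0 = 1013.25 hPa` by default.
The exponent denominator is configurable (5.255 reproduces the common
international-standard-atmosphere constant; 5.225 is the package default and
is what the worked pressure-pair example reproduces to 0.23 m).  Altitude is
smoothed with a one-state Kalman filter:

    K  = p / (p + r)
    x' = x + K (z − x)
    p' = (1 − K) p + |x − x'| · q

The `|x − x'|·q` term is a deliberate, nonstandard signal-dependent process
noise rather than a textbook predict step: on a flat signal `p` collapses and
the filter smooths hard; on a ramp the state change keeps re-inflating `p` so
the filter tracks with a sub-second time constant.  Defaults `r = 1 m²`,
`q = 0.01`, `p_init = 1 m²`, seeded with the first raw altitude; the update
is written in incremental form so a constant signal is preserved bit-exactly.

## Orientation

Tilt `theta = arccos(az/|a|)` (degrees) is computed from the raw
accelerometer by default; a config switch derives it from the filtered
gravity direction instead.  Pitch and roll come from a hand-rolled Madgwick
gradient-descent filter (gain `beta = 0.1`, warm-started from the first
sample's accelerometer tilt): the IMU variant corrects gyro integration with
the gravity objective `R(q)ᵀe_z − a`; with a magnetometer the MARG variant
adds the flux objective against a reference direction re-projected into the
horizontal/vertical plane each step.  Euler extraction uses

    Y = atan2(2q2q3 − 2q1q4, 2q1² + 2q2² − 1)
    P = −asin(2q2q4 + 2q1q3)
    R = atan2(2q3q4 − 2q1q2, 2q1² + 2q4² − 1)

which equals the aerospace Z-Y-X angles of the conjugate quaternion.  The
posture decision uses only `theta > 25°`, `|P| > 30°`, `|R| > 30°`, so the
sign convention is immaterial to detection; magnitudes are compared because
opposite fall directions produce opposite signs.  Near the pitch singularity
the asin argument is clamped with a logged warning.  With `beta = 0` the
filter reduces exactly to open-loop gyroscope integration (a test oracle).

## Fall cascade timing and tie-breaks

Trigger: first sample with magnitude strictly above `Uth = 1.8 g`.  Rest
check: samples `[j+3 s, j+5 s]`, closed endpoints, strictly inside
`(0.75, 1.25) g`.  Posture checks at `j+5 s` and `j+5.5 s` -- after the body
has settled.  Design choices where the cascade's description leaves room:

* further super-threshold samples inside an open candidate's 5.5 s
  evaluation window fold into that candidate (no nested candidates);
* a confirmed fall suppresses new triggers for a 6 s refractory period
  (duplicate-alert protection; the duration is a package default);
* a candidate whose window runs past the end of the trace is logged and
  treated as a non-fall;
* thresholds are strict inequalities at the boundary.

The ablation variants remove exactly one feature at a time (recheck, theta,
pitch/roll), so the full cascade's detections are always a subset of each
variant's -- the property the ablation tests assert.

## LOPP detection

Quiescence: maximal runs with every sample strictly inside `(0.8, 1.2) g`
lasting at least 4 s (closed window endpoints).  Within a run the window
start slides sample by sample; each window is classified by the filtered
altitude change `ΔH = h[j+4 s] − h[j]` against the symmetric band ±0.5 m
(one configured magnitude; the band is symmetric because ascending and
descending elevators are physically symmetric cases).  Consecutive
same-class windows coalesce into one event stamped at the onset of
quiescence.  Fall events take precedence: any quiescence-scan event whose
window span intersects a fall's refractory span is dropped (the dispatcher
branches on the impact threshold first).  Without a barometer channel the
detector still alerts but flags events `degraded`, since elevator travel can
no longer be excluded.

Quiet standing is a genuine ambiguity of this scheme: it satisfies the
quiescence band with flat altitude and is indistinguishable, on these
sensors, from incapacitation.  The package documents and scores this
explicitly -- standing trials are scored on the fall detector only -- rather
than hiding the gap with an undocumented heuristic.

## CO alerting

The ppm channel is smoothed with the same scalar Kalman filter; the alert
threshold is 33 ppm (inclusive), with 35 ppm retained in the configuration as
the OSHA hazardous-environment reference.  A 2 s debounce is applied in both
directions, and alert/safe events alternate by construction.  Events are
stamped at the start of the debounced run, so detection latency is the
smoothing lag only.  Raw-sensor calibration (e.g. electrochemical resistance
to ppm) is out of scope; input is assumed already in ppm.

## Synthetic scenarios

The generator scripts each activity class phenomenologically -- what the
thresholds actually see -- rather than simulating body dynamics:

* **falls** (four directions): 3 s quiet stance, 0.3 g free-fall dip
  (0.3 s), triangular impact spike to 3 g, damped ripple under 2 s, then
  rest at 1 g; the attitude slerps from upright to a toppled orientation
  whose printed-convention pitch/roll are 35-50° with direction-dependent
  signs (tilt 53-60°).
* **fall_recovery** (test fixture, not in the default suite): as above, but
  the attitude returns upright before the posture checks, followed by a
  stand-up burst and walking; ground truth is benign.
* **crawl_then_fall / stuck_narrow_path**: crawling or walking, then a
  sustained in-band plateau with flat altitude; truth is one LOPP event at
  the quiescence onset.
* **elevator_up/down**: walk in, 7 s quiescent ride with a ±3 m linear
  altitude ramp, walk out; truth is a moving event and *no* alert.  The
  walk-in/out segments bracket the ride so no flat-altitude quiescent window
  exists.
* **ambulation**: label-specific gait envelopes around 1 g -- walking
  0.6-1.5 g, jogging 0.5-1.7 g, crawling 0.65-1.35 g (all below `Uth`;
  all violate the quiescence band every stride), running to 2.3 g and
  jumping to 3.2 g (above `Uth`, but never followed by post-fall rest).
* **co_exposure**: walking plus a CO channel ramping from the 7 ppm clean-air
  baseline to a 42 ppm plateau over 3 s; truth is stamped where the noise-free
  profile crosses 33 ppm.

Gyroscope rates are finite differences of the scripted quaternion path and
the magnetometer sees a fixed earth flux (60° dip) in the device frame, so
the orientation filter receives mutually consistent inputs.  Default noise:
0.02 g per accelerometer axis, 0.02 hPa pressure (≈0.19 m of raw altitude
noise, far inside the ±0.5 m band after filtering), 0.01 rad/s gyro,
0.005 flux units, 0.3 ppm CO -- levels a decent consumer IMU/barometer
reaches indoors.  All randomness flows from one seed per trace; suite trace
seeds derive from `(suite seed, class index, repetition)`, so truth structure
is seed-invariant while noise realizations differ.

What passing on this suite shows -- and does not.  The generator reproduces
the *decision-relevant geometry* of each class (band violations, spike
heights, ramp slopes, posture excursions) with margins a clean recording
would have.  It does not model soft-tissue impact dynamics, gait variability
across wearers, barometric weather drift, or sensor dropouts, so perfect
scores here demonstrate the correctness and self-consistency of the decision
logic at the stated thresholds, not field-grade performance on real
firefighter recordings.

## Evaluation

One trace = one trial (the way class-level detection tables count actions).
A trial with a truth alert is a TP if a matching-kind event lies within the
2 s tolerance, else FN; a trial without is an FP if any scored alert fired,
else TN.  Scored kinds are fall+LOPP for most classes, fall-only for
standing (above), and the CO alert for exposure trials.  Metrics are kept as
exact rationals and reported as percentages rounded to two decimals; a zero
denominator reports as undefined (`None`), never as 0.

## Problem sizes

The default suite is 20 traces per class across 17 classes (340 traces of
12 s at 100 Hz); it generates and scores in well under a minute on one core.
Property tests cross-check the streaming detectors against naive brute-force
scans on randomized traces up to 30 s.

## Known limitations

* The LOPP/standing ambiguity described above is inherent to the sensor set.
* The Kalman filter's signal-dependent process noise has no optimality
  guarantee; it is used because its smooth-flat / track-ramp behaviour is
  what the altitude disambiguation needs.
* The IMU-only Madgwick variant leaves yaw unobservable; pitch/roll are
  still defined, which is all the posture decision needs.
* Trial-level scoring does not penalize duplicate events of the correct kind
  inside one positive trial.
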