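# Methods

## Fall detection model

The detector operates on uniformly sampled tri-axial acceleration in G
(default 200 Hz, waist placement: x sagittal, y vertical, z frontal). All
features are computed on raw samples; no low-pass filter is applied, since
the thresholds below were calibrated against unfiltered peaks. Users with
noisier sensors should filter upstream and revalidate thresholds.

Two per-sample features drive the decision: the sum vector magnitude
`SVM_xyz` and its horizontal-plane restriction `SVM_xz`. The reference
velocity integrates `(SVM_xyz − 1 G)·g` between the horizontal trigger K
and the rest onset L with the trapezoidal rule at the native sample
spacing (second-order accurate, deterministic). The integrand is not
clamped at zero: sub-1 G free-fall segments legitimately reduce the
velocity estimate, and the signed value is what the threshold compares
against. The G→m/s² constant defaults to standard gravity (9.80665) and
is configurable.

### Thresholds and windows

| parameter | default | meaning |
|---|---|---|
| `th_high_xyz` | 6.0 G | max SVM of fast daily activities; above ⇒ critical |
| `th_low_xyz` | 3.5 G | max SVM of normal-speed activities; above ⇒ normal |
| `th_xz` | 2.0 G | horizontal-impact trigger for the velocity phase |
| `th_v` | 1.7 m/s | reference-velocity criterion for critical falls |
| `rest_window_s` | 0.3 s | duration the body must stay static to define L |
| `search_window_s` | 2.0 s | how far after K the rest onset may begin |
| `rest_epsilon_g` | 0.2 G | "static" means \|SVM_xyz − 1\| ≤ ε throughout |
| `refractory_s` | 2.0 s | one alarm per physical impact |
| `cancel_hold_s` / `cancel_timeout_s` | 2 s / 30 s | button-press protocol |

The four physical thresholds are the published calibration for waist-worn
sensors. The remaining parameters fill gaps the source description leaves
open and are deliberate design choices: "static" is defined by the ε-band
above because rest after a real fall still carries breathing and tremor
jitter; ε = 0.2 G comfortably exceeds the simulator's 0.05 G jitter while
staying far below the 2 G trigger. The refractory period suppresses the
multiple threshold crossings one physical impact produces. The cancel
durations balance accidental holds against usability.

### Phase precedence and candidate evaluation

The three phases are evaluated over a 2 s window opened at the first
sample where any trigger condition holds, with precedence critical-by-peak
(phase 1) → critical-by-velocity (phase 3) → normal (phase 2). Two
consequences motivate this order: a hard impact whose SVM crosses 3.5 G a
few samples before reaching 6 G must not be downgraded to a normal alarm
by its leading edge, and a slow slump that never reaches 3.5 G must still
be able to escalate through the velocity criterion. Phase 3 runs
independently of phase 2's threshold (a 3.2 G slump can be critical).
K is the first sample in the window with `SVM_xz > th_xz`; L is the first
qualifying rest onset strictly after K and beginning within the search
window; if no rest onset exists (continuous motion, or trace end), phase 3
does not fire — the lying-on-ground premise fails. Traces shorter than
the window are evaluated with the window truncated; this is not an error.

## Radio model and positioning

Received power follows the log-distance path-loss law
`P(d) = PL(d0) − 10·n·log10(d/d0) + X_σ` with exponent n = 2 (free
space), d0 = 1 m, and zero-mean Gaussian shadowing X_σ in dB. The
reference power defaults to −40 dBm at 1 m, a typical figure for 2.4 GHz
low-power radios; its absolute value is immaterial because the RSSI map
is calibrated relative to it. The radio chip's dBm→RSSI map is linear
with unpublished constants, so the package fits the unique line sending
the noise-free power at 0.5 m to RSSI 144 and at 7 m to RSSI 60 — the
distance semantics of the class boundaries — making simulated classes
meaningful at any power level. Values are rounded and clamped to 0–255.

The four RSSI classes (25 °C calibration) and their affine transform
parameters:

| class | RSSI range | A | ratio | B |
|---|---|---|---|---|
| I | 144–255 | 176 | 0.05 | 144 |
| II | 112–143 | 112 | 0.3 | 112 |
| III | 61–111 | 60 | 0.6 | 60 |
| IV | 0–60 | 0 | 1 | 0 |

The printed ranges meet at 60; this package assigns 60 to Class IV. Both
parameterizations give the identical weighted value 60.0 there, so the
choice only fixes the partition (verified exhaustively over all 256
inputs, together with strict monotonicity of the full transform). Tables
for other temperature/humidity contexts can be supplied as JSON; only the
25 °C values ship.

Positioning uses normalized inverse-square weights over the p = 4 nearest
reference nodes in (weighted-)RSSI space. The inverse-square form
realizes "nearest node gets the largest weight" and is the standard
choice in reference-tag localization; the weight function is pluggable.
Zero distances receive the entire weight mass, split equally among all
zero-distance nodes (the limit of inverse-square weighting); ties at the
p-th smallest distance break by ascending node id. The estimate is a
convex combination of the selected node coordinates and therefore always
lies in their bounding box.

## Synthetic data

**Accelerometer traces.** Falls are built as pre-activity segment +
optional linear free-fall dip + half-sine impact spike (optionally with a
plateau at the peak, modelling sustained deceleration) + rest near 1 G,
with seeded Gaussian jitter of 0.05 G per axis. The designed SVM profile
is exact before jitter: the dominant horizontal axis carries
`f · SVM` (f is the per-direction horizontal fraction, 0.65 front/back
and 0.7 lateral by default) and the vertical axis the remainder. The
defaults — 5 G impact peak, 0.6 G dip over 0.25 s, 1 s rest, 0.12 s
pulse — sit in the mid-range of published waist-impact magnitudes.
The 28 valid (pre-activity, direction) combinations mirror the trial
taxonomy; the single lie-then-turn variant is mapped to a left-lateral
roll (the sensor is worn on the left waist). Every trace carries
ground-truth labels (class, fall interval, and the severity the designed
noise-free profile implies), computed from the profile geometry rather
than by running the detector, so detector evaluation is not circular.

ADL signatures are oscillatory (walk, run, stairs, jump) or bump-like
(posture transitions) with peak SVM below 3.5 G at normal speed; fast
jumps (~6.6 G), fast stairs (~4.2 G) and fast lying-down (~3.9 G) exceed
the alarm thresholds by design, reproducing the false-alarm behavior
acute activities cause in practice.

What the generator does **not** emulate: sensor saturation (the ±5 G
range of real parts would clip 6.5 G impacts), orientation drift, soft
or oblique impacts with multi-peak structure, or subject-specific gait
spectra. Detector results on this data therefore validate the decision
logic, not field performance.

**RSSI rounds.** One round asks each generator in turn to broadcast;
every observer reports one integer RSSI per generator (an averaging
count and a packet-drop probability exist as knobs, both off by
default; dropped readings are masked out of distance computations
pairwise). Geometric distances are floored at 1 mm to keep the path-loss
law finite for co-located nodes. The default layout reconstructs the
reference deployment — 18 nodes on a centered 2 m grid in an
11 × 5.75 m room, 5 generators at the center and quadrant centers,
gateway at the center — since exact coordinates were never published;
any layout can be supplied instead.

### A note on the weighted-RSSI comparison

Under this simulator the class-weighted transform does **not** reduce the
mean error distance relative to raw RSSI matching (it adds ~0.1 m at
2 dB shadowing, consistently across seeds and noise levels). This is
structural, not a bug: the synthetic field is exactly log-linear and its
RSSI noise is homoskedastic (a constant σ·slope in RSSI units at every
distance), and an affine per-class rescaling applied identically to both
vectors changes signal and noise equally within a class — it can only
redistribute influence across classes and insert boundary
discontinuities. The transform earns its keep on real radios, whose
RSSI-distance curve is non-log-linear and whose strong-signal classes
are far noisier; there it compresses exactly the volatile coordinates.
Reproducing that benefit in simulation would require a heteroskedastic,
non-log-linear radio model, which is outside the scope of the shipped
generator. The package keeps both code paths (`use_weighting=True/False`)
so the comparison is one flag away on any data source.

## Numerical and degenerate-input choices

- Sampling must be uniform; the CSV reader rejects irregular timestamps
  (tolerance 1e-6 s) rather than resampling.
- Non-finite samples, empty traces, reversed integration windows,
  out-of-range RSSI, mismatched dimensions and out-of-room geometry all
  raise typed errors; nothing is silently clipped except the documented
  0–255 RSSI clamp.
- Applying the weighting to an already-weighted round is an error (the
  transform is not idempotent and weighted values leave the integer
  domain).
- All stochastic components (jitter, shadowing, scenario sampling) are
  driven by explicit integer seeds through independent generators;
  per-event sub-seeds in the pipeline derive from a seed sequence so
  results are reproducible bit-for-bit.

## Problem sizes

The shipped evaluation uses a 9-subject synthetic cohort (9 × 28 falls,
9 × 13 ADL trials, ~3.5 s traces at 200 Hz) and 200-trial positioning
sweeps per noise level on the 18-node layout — sizes chosen to give
stable Monte-Carlo means (standard errors ≈ 0.05 m on positioning) while
keeping a full run interactive.
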