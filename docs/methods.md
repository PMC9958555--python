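# Methods

## The measurement model

The chair measures two distances: seat sensor S1 to the underside of the
thigh, and backrest sensor S2 to the back of the trunk. The inverse model
is a planar two-link chain in the sagittal plane. Its coordinate frame —
left implicit by the arctangent formulas, fixed explicitly here — has the
origin at the knee centre, x positive toward the backrest, y positive
upward from the seat plane. S1 sits at (L_S1 + L_offset, 0) and fires along
(−cos φ_S1, +sin φ_S1); S2 sits at (L_seat, L_S2) and fires along
(−sin φ_S2, −cos φ_S2). In this frame the three conversion formulas
(thigh angle from d_thigh; hip position from the thigh angle and the preset
thigh length; trunk angle from d_trunk and the hip) are literal identities
of ray–line intersection, which the test suite verifies by round trip
against the independent ray-cast forward model to < 1e−6° over
θ_thigh ∈ [5°, 85°], θ_trunk ∈ [−30°, 70°].

Assumptions the model makes, each of which the synthetic module can
violate on purpose:

- the knee centre is fixed at L_offset behind the seat edge (violated by
  `knee_shift_mm`: the knee axis translates posteriorly during extension);
- the beams range to the skeletal segment lines (violated by
  `surface_offset_mm`: clothing and tissue put the measured surface closer
  to the sensor);
- the thigh length equals the preset L_thigh (violated by giving the
  simulated body a different `body_thigh_mm`);
- measurements are exact (violated by Gaussian distance/marker noise).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| φ_S1 | 63.5 | deg | seat-sensor installation angle from the seat plane |
| L_S1 | 130 | mm | seat sensor to seat edge |
| L_offset | 50 | mm | seat edge to knee centre (taken along the seat plane) |
| φ_S2 | 90 | deg | backrest-sensor angle from the backrest plane |
| L_seat | 550 | mm | seat depth |
| L_S2 | 465 | mm | backrest sensor height above the seat |
| L_thigh | 403 (alt. 446) | mm | preset model thigh length |
| seat height | 400 | mm | metadata only; no formula uses it |
| sensor max range | 2000 | mm | ToF-class ceiling; beyond it a sample is invalid |

Angles are degrees at every interface and radians internally. The
conversions use plain `atan`, not `atan2`: where a denominator is
non-positive (seat beam past the knee plane; trunk hit point at or below
hip height) the model has no physical meaning, so such samples are flagged
invalid — NaN angles with `valid=False` — rather than wrapped into another
quadrant. Series operations propagate these flags; scalar calls raise.

## Signal chain

Distances and marker coordinates are filtered identically: 4th-order
low-pass Butterworth, 6 Hz cutoff, applied at each stream's native rate
(30 Hz distances, 100 Hz markers); marker data are then cubic-spline
resampled onto the 30 Hz grid. Filtering is zero-phase (forward–backward,
`scipy.signal.filtfilt`) by default because a causal pass would delay the
waveform by tens of milliseconds and bias every event time; a causal mode
exists behind a flag. Edge handling is reflective padding of 3× the filter
order, which suppresses startup transients on trials only a few seconds
long. The nominal 6 Hz cutoff is per single pass; the doubled attenuation
of the forward–backward pass is not compensated (gain at the cutoff is 0.5
rather than 1/√2), which is irrelevant here because STS content lives below
~4 Hz.

## Events and excursions

Onset is the first sample whose trunk angle exceeds the quiet-sitting
baseline by ≥ 1°, where the baseline is the mean over the first 0.5 s
(robust to single-sample noise; the window length is a package choice).
A 3-sample non-decreasing confirmation rejects isolated glitches without
touching the 1° threshold itself. Maximum flexion is the post-onset argmax
of the trunk angle, maximum extension the post-peak argmin (the global one:
if the trunk oscillates after standing, the deepest extension ends the
analysis window — an interpretation, made deterministic by breaking ties to
the earliest index). Flexion excursion = angle(peak) − angle(onset);
extension excursion = angle(peak) − angle(extension bound). Both are
invariant to constant offsets, so the two measurement systems need not
share an angular origin.

Segmentation is always computed on the trunk series; the thigh is compared
over the same onset-to-extension window rather than per phase, since thigh
motion does not pause at peak trunk flexion.

## Validity statistics

Waveform similarity is the zero-lag normalised correlation of the two
systems' phase segments, each system segmented by its own events. Unequal
segment lengths (the systems may disagree on an event by a few samples) are
reconciled by spline-resampling both segments to the shorter one's sample
count — a phase-normalised, shape-to-shape comparison. Because the
estimator behind published "cross-correlation" figures is ambiguous, a
lag-search mode (maximum over integer lags within ±0.2 s) is provided;
zero-lag is the default and the two coincide for aligned clocks.
Correlations are averaged within a condition through Fisher's r-to-z
transform (tanh of the mean atanh), which behaves near the r = 1 ceiling
where plain averaging is biased; inputs at |r| = 1, which atanh cannot
represent, are clipped to 1 − 1e−7 with a warning. Excursion agreement is
reported as absolute error in degrees and as a percentage of the reference
(optical) excursion; across trials, Pearson's correlation of the excursions
measures whether the chair ranks movements the way the reference does.

## The synthetic generator

The generator emulates the study conditions the method is meant for: seven
movement conditions (normal; larger and smaller anterior trunk tilt; slow
and fast; right and left weight shift), five-trial averaging, 30 Hz
distance and 100 Hz marker streams. Trajectories are minimum-jerk profiles
— the standard smoothness model for point-to-point human movement, with
zero velocity and acceleration at segment boundaries. A trial is 0.5 s of
quiet sitting; trunk flexion from 0° to the condition amplitude over 45 %
of the movement duration; extension to a 5° overshoot past vertical over
the remainder; and a 0.4 s settle back to upright. The thigh rises from its
seated 5° to 90° between peak trunk flexion and the end of the settle.
Two timing choices are deliberate: the seated thigh angle is 5° because
exactly 0° is degenerate for the seat beam (the sensor origin lies on the
thigh line; a real seated thigh reads a small positive angle), and the
thigh completes its rise only at the end of the settle so that the 90°
posture — where the seat-beam inversion's denominator vanishes — occurs
after the trunk's maximum extension and never lands inside the analysis
window.

Condition presets (amplitudes in degrees, durations in seconds): normal
50/2.0, tilt increase 70/2.2, tilt decrease 30/1.8, slow 50/4.0, fast
50/1.0, weight shifts 45/2.2 with ±0.15 timing asymmetry. These are this
package's defaults for plausible young-adult STS motion, configurable per
preset; they are not measured values. Per-trial variability is a seeded
±5 % uniform jitter on amplitude and duration. The jitter seed
(`trajectory_seed`) is separate from the measurement-noise seed (`seed`),
so different noise realisations can share an identical noiseless core.

Rendering is exact ray–segment intersection: the thigh is the segment from
the (possibly shifted) knee to the hip; the trunk is a half-line from the
hip, because at deep flexion the backrest beam meets the trunk axis beyond
any literal C7 endpoint and the inverse model implicitly assumes the
intersection always exists. Clothing thickness is subtracted along the
beam (the simplest physically plausible surface model); the knee shift
ramps linearly from zero at peak flexion to its full value at the end of
extension, then holds. Markers are placed on the simulated body: condyle on
the knee axis, trochanter on the hip, sacrum 100 mm up the trunk line, C7 a
further 400 mm; Gaussian noise is added per coordinate.

Weight-shift conditions deserve a caveat: a lateral shift is inherently
3-D, and this model is sagittal. The presets carry its in-plane signature
(timing asymmetry), and `PerturbationSpec.thigh_distance_offset_mm` (with
`thigh_offset_for_weight_shift` as a scaling helper) adds the
distance-offset flavour — the off-centre seat sensor seeing the thigh
surface nearer or farther — as an explicit, opt-in model violation rather
than part of the condition itself, so that every preset retains the exact
perfect-model identity when unperturbed.

What passing tests on this generator do show: the inverse geometry, event
logic, statistics and pipeline plumbing are correct, and the method's
qualitative error structure (accurate flexion, knee-translation-corrupted
extension, insensitivity to the thigh preset) follows from the geometry
itself. What they do not show: performance on real bodies — deforming
tissue, clothing that wrinkles rather than offsetting uniformly, seat
compliance, inconsistent sitting positions, truly 3-D weight shifts — or
any subject-specific numeric result.

## Numerical choices

- Invalid samples are NaN + flag, interpolated linearly only to keep the
  filter well-posed; they stay flagged downstream and events ignore them.
- Peak/valley ties break to the earliest index (determinism).
- Correlation inputs with zero variance raise rather than return NaN.
- The acceptance script scales its studies to desk size — 10 000 postures
  for the round trip, 100 trials for the stochastic studies, single trials
  for the deterministic mechanism checks — sizes at which every reported
  quantity is stable to well within its tolerance.

## Known limitations

- The 80 mm lateral offset of the real seat sensor is a 3-D effect a
  sagittal model cannot represent; it is not modelled.
- Seat-off detection, repetition counting and lower-limb joint angles are
  out of scope; the chair measures trunk and thigh segment angles only.
- The extension phase is measured faithfully by the *pipeline*, but the
  method itself is unreliable there (see the knee-shift mechanism); the
  package reproduces that unreliability rather than fixing it.
- Percentage excursion errors use the optical excursion as denominator; a
  zero reference excursion yields a missing percentage, not an exception.
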