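# chairsts

Trunk and thigh kinematics during sit-to-stand (STS), measured by a chair
with laser range finders embedded in its seat and backrest.

The STS movement is a standard functional probe of lower-limb strength and
frailty, and the trunk's forward-flexion excursion while rising is one of
its most informative features: it shrinks in older adults and relates to
knee loading. Optical motion capture measures it well but lives in a lab.
A chair that measures it by itself — two time-of-flight distance sensors,
no markers, no cameras — can watch the movement in daily life. This package
implements the measurement model for such a chair, the validation pipeline
that compares it against marker-based reference angles, and a synthetic
trial generator so every stage can be exercised without hardware or
subjects.

## The model

Two sensors: S1 in the seat, aimed up-and-forward at the thigh at
installation angle φ_S1 = 63.5°; S2 in the backrest at height
L_S2 = 465 mm, aimed horizontally at the trunk (φ_S2 = 90°). A planar
two-link chain — thigh rotating about a fixed knee centre, trunk about the
hip — converts the two measured distances into segment angles:

```
θ_thigh = atan( d_thigh · sin φ_S1 / ((L_S1 + L_offset) − d_thigh · cos φ_S1) )

(x_hip, y_hip) = L_thigh · (cos θ_thigh, sin θ_thigh)

θ_trunk = atan( (d_trunk · sin φ_S2 − (L_seat − x_hip))
                / (L_S2 − d_trunk · cos φ_S2 − y_hip) )
```

with seat-edge lengths L_S1 = 130 mm, L_offset = 50 mm, seat depth
L_seat = 550 mm, and a preset model thigh length L_thigh of 403 mm (young-
adult population median; 446 mm as a taller alternative). θ_thigh is
measured from horizontal (0° seated, 90° standing), θ_trunk from vertical
(forward lean positive). Distances and markers are low-pass filtered
(4th-order Butterworth, 6 Hz, zero-phase), marker data resampled to the
sensors' 30 Hz; trials are segmented at STS onset (trunk angle 1° above
quiet-sitting baseline), maximum trunk flexion and maximum trunk extension;
per-phase waveform similarity uses the normalised zero-lag correlation, and
per-condition averages go through Fisher's r-to-z transform.

The synthetic module renders minimum-jerk ground-truth motions through
exact ray–segment geometry into virtual laser distances and virtual marker
trajectories (C7, sacrum, greater trochanter, lateral femoral condyle),
with controllable model violations: clothing thickness along the beam,
sensor/marker noise, and a posterior knee-axis translation ramped over the
extension phase — the mechanism that makes the chair's extension-phase
measurements unreliable while its flexion-phase measurements stay accurate.

## Worked example

`python examples/simulate_and_validate.py` simulates a noiseless "normal"
trial, runs the chair chain (filter → invert geometry) and the marker chain
(filter → resample → angles), and compares them:

```
simulated 'normal': 88 distance samples at 30 Hz, 291 marker frames at 100 Hz
programmed flexion excursion: 50.0 deg

chair-model flexion excursion:    48.732 deg
marker-based flexion excursion:   48.732 deg
flexion error:   0.0001 deg
extension error: 0.0035 deg
waveform similarity r (trunk flexion):   1.000000
waveform similarity r (trunk extension): 1.000000
waveform similarity r (thigh):           1.000000
```

Both chains measure the excursion from the *detected* onset — about 1°
above baseline — hence ~48.7° for a 50° programmed amplitude; what matters
is that they agree to well under 0.1°. The other examples show the failure
mode and the robustness that motivate the design:
`examples/knee_shift_mechanism.py` (extension error grows 0 → 9.7° as the
knee axis translates 0 → 30 mm posteriorly, flexion untouched),
`examples/thigh_length_robustness.py` (switching the thigh preset
403 ↔ 446 mm moves flexion excursion by ~6 %),
`examples/condition_report.py` (Fisher-averaged similarity and across-trial
Pearson correlation over five noisy trials), and
`examples/convert_distances.py` (the bare geometry inversion).

A thin CLI wraps the same pipeline for shell use:

```sh
chairsts simulate --preset normal --seed 1 --distance-noise 2 --out trial/
chairsts angles --distances trial/distances.csv --out chair_angles.csv
chairsts validate --chair chair_angles.csv --reference trial/markers.csv --out metrics.json
chairsts report --trials metrics.json --out summary.csv
```

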