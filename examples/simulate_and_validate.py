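"""Simulate one sit-to-stand trial and validate chair against markers.

Generates a noiseless "normal" trial, renders it both as laser distances
(30 Hz) and optical marker trajectories (100 Hz), runs each through its
processing chain, and compares phase excursions and waveform similarity.
With no perturbations the two chains must agree almost perfectly — the
inverse model is exact when its assumptions hold.
"""

from chairsts import (ChairGeometry, chair_angles, marker_angles,
                      simulate_trial, validate_trial)

geom = ChairGeometry()
trial = simulate_trial("normal", geom)
print(f"simulated {trial.preset.label!r}: "
      f"{len(trial.distances)} distance samples at 30 Hz, "
      f"{len(trial.markers)} marker frames at 100 Hz")
print(f"programmed flexion excursion: "
      f"{trial.events['true_flexion_excursion_deg']:.1f} deg")

chair = chair_angles(trial.distances, geom)   # filter -> invert geometry
ref = marker_angles(trial.markers)            # filter -> resample -> angles
res = validate_trial(chair, ref)

v = res.validation
print(f"\nchair-model flexion excursion:  {res.chair_excursions.flexion_deg:8.3f} deg")
print(f"marker-based flexion excursion: {res.ref_excursions.flexion_deg:8.3f} deg")
print(f"flexion error:   {v.abs_err_flexion_deg:.4f} deg")
print(f"extension error: {v.abs_err_extension_deg:.4f} deg")
print(f"waveform similarity r (trunk flexion):   {v.r_trunk_flexion:.6f}")
print(f"waveform similarity r (trunk extension): {v.r_trunk_extension:.6f}")
print(f"waveform similarity r (thigh):           {v.r_thigh:.6f}")

print("\nSub-0.1 degree errors and r ~ 1: the chair reproduces the reference"
      "\nangles exactly when clothing offset, knee translation and noise are"
      "\nabsent. (Excursions are measured from the detected onset, about one"
      "\ndegree above quiet-sitting baseline, hence ~1 degree below the"
      "\nprogrammed amplitude.)")
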