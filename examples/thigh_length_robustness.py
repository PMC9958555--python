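"""How much does the thigh-length preset matter?

The chair is meant to run without entering each user's anthropometry, so the
model thigh length is a fixed preset. Here a body with a 446 mm thigh is
measured under realistic sensing (2 mm range noise, 10 mm clothing offset)
and the recorded distances are inverted with both presets, 403 mm (the
population default) and 446 mm (the matched value). The flexion excursion
barely moves — which is why a single population-level preset suffices.
"""

import numpy as np

from chairsts import (ChairGeometry, PerturbationSpec, chair_angles,
                      marker_angles, simulate_trial, validate_trial)

geom = ChairGeometry()
body_thigh = 446.0
rels = []
for seed in range(20):
    perturb = PerturbationSpec(surface_offset_mm=10.0, distance_noise_sd_mm=2.0)
    trial = simulate_trial("normal", geom, perturb, seed=seed,
                           trajectory_seed=900 + seed, body_thigh_mm=body_thigh)
    ref = marker_angles(trial.markers)
    flex = {}
    for l_thigh in (403.0, 446.0):
        chair = chair_angles(trial.distances, geom.with_thigh_length(l_thigh))
        flex[l_thigh] = validate_trial(chair, ref).chair_excursions.flexion_deg
    rels.append(100.0 * abs(flex[403.0] - flex[446.0]) / flex[446.0])
    if seed < 3:
        print(f"trial {seed}: flexion excursion {flex[403.0]:6.2f} deg "
              f"(403 mm preset) vs {flex[446.0]:6.2f} deg (446 mm preset)")

print(f"\nrelative flexion-excursion change over {len(rels)} trials: "
      f"mean {np.mean(rels):.1f} %, max {np.max(rels):.1f} %")
print("A 43 mm mismatch in the thigh preset shifts flexion excursion by only"
      "\na few percent: the model is robust to the one anthropometric"
      "\nparameter it cannot measure.")
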