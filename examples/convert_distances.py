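"""Convert two laser distances into trunk and thigh segment angles.

Builds a tiny 30 Hz distance series by hand, runs the two-link inversion,
and prints the resulting angles: the seat beam gives the thigh angle from
horizontal, and — via the hip position implied by the model thigh length —
the backrest beam gives the trunk angle from vertical.
"""

import numpy as np

from chairsts import ChairGeometry, DistanceSeries, angles_from_distances

geom = ChairGeometry()  # the published chair: 63.5 deg seat beam, 403 mm thigh
print(f"chair geometry: phi_s1={geom.phi_s1} deg, l_thigh={geom.l_thigh} mm")

t = np.arange(8) / 30.0
d_thigh = np.linspace(30.0, 120.0, 8)   # thigh lifting off the seat
d_trunk = np.linspace(160.0, 260.0, 8)  # trunk leaning away from the backrest
series = DistanceSeries(t, d_thigh, d_trunk, fs=30.0)

angles = angles_from_distances(series, geom)
print(f"{'t (s)':>7} {'d_thigh':>8} {'d_trunk':>8} {'thigh (deg)':>12} {'trunk (deg)':>12}")
for i in range(len(angles)):
    print(f"{angles.t[i]:7.3f} {d_thigh[i]:8.1f} {d_trunk[i]:8.1f} "
          f"{angles.theta_thigh[i]:12.2f} {angles.theta_trunk[i]:12.2f}")

print("\nLarger seat-beam distances mean a more raised thigh; larger backrest"
      "\ndistances mean more forward trunk lean (flexion-positive).")
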