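"""Where is the point-dipole model of the capsule magnet valid?

Compares the dipole field of the 10x10 mm N52 magnet with a brute-force
superposition of 10,000 sub-volume dipoles along a ray, from two magnet
lengths out to the sensor-ring distance.
"""

import numpy as np

import magtrack as mt

magnet = mt.get_magnet("10x10")
pose = mt.Pose(np.zeros(3), np.array([0.0, 0.0, 1.0]))
ray = np.array([0.6, 0.48, 0.64])  # oblique direction, unit norm

print(f"magnet: 10 mm x 10 mm, moment {magnet.moment_magnitude:.4f} A.m^2")
print(f"{'distance':>10} {'dipole |B|':>12} {'deviation':>10}")
for r_over_l in (2, 3, 5, 10, 20):
    r = r_over_l * magnet.length
    point = r * ray
    dipole = mt.dipole_field(magnet, pose, point)
    finite = mt.finite_volume_field(magnet, pose, point, 10_000)
    deviation = np.linalg.norm(finite - dipole) / np.linalg.norm(dipole)
    print(
        f"{r * 1e3:7.0f} mm {np.linalg.norm(dipole) * 1e6:9.3f} uT"
        f" {deviation * 100:9.3f} %"
    )

print(
    "\nThe deviation is the finite-size (quadrupole-order) correction the "
    "point-dipole model ignores;\nit falls roughly as 1/R^2 and is already "
    "below 1% at five magnet lengths, so the model is\nsafe at the >=100 mm "
    "sensor distances of the array."
)
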