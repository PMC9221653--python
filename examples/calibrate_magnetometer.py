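"""Hard-/soft-iron calibration by ellipsoid fitting.

A magnetometer swept through all attitudes in the clean geomagnetic field
should trace a 48 µT sphere.  We distort such a sweep with a known
soft-iron matrix and hard-iron offset, fit the ellipsoid, and show the
calibration restores the sphere.
"""

import numpy as np

import magtrack as mt

radius = 48e-6  # local geomagnetic magnitude [T]
rng = np.random.default_rng(3)
clean = mt.sphere_samples(400, radius, rng)

# known distortion: 20% anisotropic soft iron + ~10 µT hard-iron offset
soft = np.array([[1.2, 0.1, 0.0], [0.1, 0.9, 0.05], [0.0, 0.05, 1.05]])
hard = np.array([8e-6, -5e-6, 3e-6])
raw = mt.distort(clean, soft, hard)

model = mt.fit_ellipsoid(raw, reference_radius=radius)
calibrated = mt.apply_calibration(model, raw)

raw_radii = np.linalg.norm(raw, axis=1) * 1e6
cal_radii = np.linalg.norm(calibrated, axis=1) * 1e6
print(f"raw sample radii:        {raw_radii.min():6.2f} - {raw_radii.max():6.2f} uT")
print(f"calibrated sample radii: {cal_radii.min():6.2f} - {cal_radii.max():6.2f} uT")
print(f"recovered hard-iron offset [uT]: {model.hard_iron_offset * 1e6}")
print(f"max radius error after calibration: {abs(cal_radii / 48.0 - 1).max() * 100:.4f} %")

print(
    "\nThe fit recovers the injected offset and maps every distorted sample "
    "back onto the 48 µT\nreference sphere to a small fraction of a percent."
)
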