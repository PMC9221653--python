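"""Track one hand-speed traversal of the GIT-model trajectory.

Generates the 487.5 mm serpentine ground truth (100 non-uniform samples
over 40 s), simulates the noisy quantised 12-sensor measurements under a
48 µT background, tracks the magnet frame by frame, and reports the
traveled-distance and orientation errors.
"""

import numpy as np

import magtrack as mt

array = mt.build_array()
magnet = mt.get_magnet("10x10")
rng = np.random.default_rng(11)

params = mt.TrajectoryParams(z_plane=0.0, layout="x")  # defaults: 100 samples, jitter
truth = mt.generate_trajectory(params, rng)
frames = mt.simulate_dataset(
    truth, array, mt.SensorModel(), magnet, mt.GeomagneticField(), rng
)

result = mt.track(frames, array, magnet, truth=truth)

print(f"frames tracked / converged: {len(frames)} / {result.n_converged}")
print(f"ground-truth chordal length: {result.traveled_distance_true_mm:8.2f} mm")
print(f"estimated traveled distance: {result.traveled_distance_est_mm:8.2f} mm")
print(f"relative distance error:     {result.relative_distance_error_pct:8.3f} %")
print(f"mean orientation error:      {result.mean_orientation_error_deg:8.3f} deg")

per_frame = np.linalg.norm(result.estimated.positions - truth.positions, axis=1) * 1e3
print(f"median per-frame position error: {np.median(per_frame):.3f} mm")

print(
    "\nThe chordal sum over the 100 estimated poses overshoots the "
    "ground-truth sum slightly\n(position noise always lengthens a chordal "
    "path), giving a sub-percent distance error; the\naxis-angle orientation "
    "error stays a fraction of a degree."
)
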