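"""The differential method's core trick: the geomagnetic field cancels.

Simulates one measurement frame with a 48 µT homogeneous background, then
solves for the magnet pose three ways:

* differential (sensor-pair differences) — needs no background knowledge;
* standard per-sensor residuals with the *correct* background assumed;
* standard per-sensor residuals assuming zero background (i.e. what happens
  when the patient turns around and the assumed background is stale).
"""

import numpy as np

import magtrack as mt

array = mt.build_array()
magnet = mt.get_magnet("10x10")
geomagnetic = mt.GeomagneticField()  # 48 µT, oblique
truth = mt.Pose.with_direction([0.030, 0.040, -0.020], [0.0, 0.0, 1.0])

rng = np.random.default_rng(0)
frame = mt.simulate_measurement(
    array, mt.SensorModel(), magnet, truth, geomagnetic, rng
)

init = mt.Pose.with_direction(truth.position + [0.01, -0.01, 0.01], [0.2, 0.1, 1.0])


def report(label: str, est: mt.PoseEstimate) -> None:
    pos_err = np.linalg.norm(est.pose.position - truth.position) * 1e3
    ang_err = mt.orientation_error(est.pose.orientation, truth.orientation)
    print(f"{label:<38} {pos_err:8.3f} mm {ang_err:8.3f} deg")


print(f"{'method':<38} {'pos error':>11} {'orient error':>12}")
report("differential", mt.solve(frame, array, magnet, init=init))
report(
    "standard, correct background",
    mt.solve_standard(frame, array, magnet, geomagnetic, init=init),
)
report(
    "standard, stale (zero) background",
    mt.solve_standard(frame, array, magnet, mt.GeomagneticField.zero(), init=init),
)

print(
    "\nThe differential solve matches the correctly-informed standard solve "
    "without knowing the\nbackground at all, while a wrong background "
    "assumption biases the standard method by tens of mm."
)
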