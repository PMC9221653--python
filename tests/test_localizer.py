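"""Differential residuals, cost, LM solve, baselines and oracles."""

import numpy as np
import pytest

import magtrack as mt
from magtrack.localizer import SolverConfig

from conftest import noiseless_frame

TRUE_POSE = mt.Pose.with_direction([0.030, 0.040, -0.020], [0.0, 0.0, 1.0])


def position_error_mm(estimate: mt.PoseEstimate, truth: mt.Pose) -> float:
    return float(np.linalg.norm(estimate.pose.position - truth.position) * 1e3)


class TestPairResiduals:
    def test_zero_at_true_pose(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        res = mt.pair_residuals(frame, array, magnet_10x10, TRUE_POSE)
        assert res.shape == (66, 3)
        np.testing.assert_array_equal(res, np.zeros((66, 3)))

    def test_homogeneous_offset_cancels_bitwise_on_dyadic_frames(self, array, magnet_10x10):
        # readings and offset on a dyadic grid: every addition is exactly
        # representable, so the cancellation must be bit-for-bit
        grid = 2.0**-24
        base = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        readings = np.round(base.readings / grid) * grid
        frame = mt.MeasurementFrame(0.0, readings)
        g = grid * np.array([801.0, -333.0, 512.0])  # ~48/-20/31 µT
        shifted = mt.MeasurementFrame(0.0, readings + g)
        r0 = mt.pair_residuals(frame, array, magnet_10x10, TRUE_POSE)
        r1 = mt.pair_residuals(shifted, array, magnet_10x10, TRUE_POSE)
        np.testing.assert_array_equal(r0, r1)

    def test_homogeneous_offset_cancels_on_generic_frames(self, array, magnet_10x10, rng):
        frame = mt.simulate_measurement(
            array, mt.SensorModel(), magnet_10x10, TRUE_POSE, mt.GeomagneticField(), rng
        )
        g = np.array([48.3e-6, -17.9e-6, 33.1e-6])
        shifted = mt.MeasurementFrame(0.0, frame.readings + g)
        r0 = mt.pair_residuals(frame, array, magnet_10x10, TRUE_POSE)
        r1 = mt.pair_residuals(shifted, array, magnet_10x10, TRUE_POSE)
        np.testing.assert_allclose(r1, r0, rtol=0, atol=1e-18)

    def test_pair_difference_arithmetic(self, array, magnet_10x10):
        # readings = model + per-sensor offset: residual of pair (i, j) must be
        # offset_i - offset_j (hand arithmetic)
        model = mt.dipole_field(magnet_10x10, TRUE_POSE, array.positions)
        offsets = np.zeros((12, 3))
        offsets[0] = [3e-6, 0.0, 0.0]
        offsets[1] = [1e-6, 0.0, 0.0]
        frame = mt.MeasurementFrame(0.0, model + offsets)
        res = mt.pair_residuals(frame, array, magnet_10x10, TRUE_POSE)
        pair01 = array.pairs.index((0, 1))
        np.testing.assert_allclose(res[pair01], [2e-6, 0.0, 0.0], atol=1e-20)


class TestCost:
    def test_zero_residual(self):
        assert mt.cost(np.zeros((5, 3))) == 0.0

    def test_three_four_five(self):
        assert mt.cost(np.array([[3.0, 4.0, 0.0]])) == 25.0

    def test_k_pairs_of_equal_norm(self):
        r = np.tile([1.0, 2.0, 2.0], (7, 1))  # norm 3 each
        assert mt.cost(r) == pytest.approx(7 * 9.0)


class TestSolve:
    def test_noiseless_warm_start_recovers_truth(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        est = mt.solve(frame, array, magnet_10x10, init=TRUE_POSE)
        assert est.converged
        assert est.cost < 1e-20
        assert position_error_mm(est, TRUE_POSE) < 1e-6

    def test_perturbed_init_recovers_truth(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        init = mt.Pose.with_direction(
            TRUE_POSE.position + np.array([0.02, 0.0, 0.01]),
            [np.sin(np.deg2rad(20)), 0.0, np.cos(np.deg2rad(20))],
        )
        est = mt.solve(frame, array, magnet_10x10, init=init)
        assert position_error_mm(est, TRUE_POSE) < 1e-3
        assert mt.orientation_error(est.pose.orientation, TRUE_POSE.orientation) < 1e-3

    def test_cold_start_beats_grid_oracle(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        est = mt.solve(frame, array, magnet_10x10)
        grid = np.linspace(-0.08, 0.08, 5)
        positions = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        oracle = mt.grid_search_oracle(
            frame, array, magnet_10x10, positions, np.eye(3).tolist() + (-np.eye(3)).tolist()
        )
        assert est.cost <= oracle.cost

    def test_under_determined_array_rejected(self, magnet_10x10):
        tiny = mt.SensorArray(
            positions=np.array([[0.2, 0.0, 0.0], [-0.2, 0.0, 0.0]]),
            orientations=np.broadcast_to(np.eye(3), (2, 3, 3)).copy(),
            pairs=((0, 1),),
        )
        frame = mt.MeasurementFrame(0.0, np.zeros((2, 3)))
        with pytest.raises(ValueError, match="under-determined"):
            mt.solve(frame, tiny, magnet_10x10)

    def test_orientation_sign_follows_init(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        init_flipped = mt.Pose(TRUE_POSE.position, -TRUE_POSE.orientation)
        est = mt.solve(frame, array, magnet_10x10, init=init_flipped)
        assert float(est.pose.orientation @ init_flipped.orientation) >= 0

    def test_noiseless_identifiability_sample(self, array, magnet_10x10, rng):
        # cold-start recovery over random in-array poses (acceptance runs 100;
        # this spot-checks a smaller sample)
        for _ in range(15):
            pos = rng.uniform([-0.09, -0.09, -0.075], [0.09, 0.09, 0.075])
            direction = rng.standard_normal(3)
            truth = mt.Pose.with_direction(pos, direction)
            frame = noiseless_frame(array, magnet_10x10, truth)
            est = mt.solve(frame, array, magnet_10x10)
            assert position_error_mm(est, truth) < 0.1
            assert mt.orientation_error(est.pose.orientation, truth.orientation) < 0.1

    def test_noise_scaling_monotonic(self, array, magnet_10x10):
        # median position error grows with sensor noise
        medians = []
        for sigma_ut in (0.1, 0.3, 1.0):
            rng = np.random.default_rng(7)
            model = mt.SensorModel(noise_sigma=sigma_ut * 1e-6)
            errs = []
            for _ in range(25):
                frame = mt.simulate_measurement(
                    array, model, magnet_10x10, TRUE_POSE, mt.GeomagneticField(), rng
                )
                est = mt.solve(frame, array, magnet_10x10, init=TRUE_POSE)
                errs.append(position_error_mm(est, TRUE_POSE))
            medians.append(np.median(errs))
        assert medians[0] < medians[1] < medians[2]


class TestSolveStandard:
    def test_correct_background_recovers_truth(self, array, magnet_10x10, rng):
        geo = mt.GeomagneticField()
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE, geomagnetic=geo)
        est = mt.solve_standard(frame, array, magnet_10x10, geo, init=TRUE_POSE)
        assert position_error_mm(est, TRUE_POSE) < 1e-6

    def test_wrong_background_biases_standard_not_differential(self, array, magnet_10x10):
        geo = mt.GeomagneticField()  # true background 48 µT
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE, geomagnetic=geo)
        std = mt.solve_standard(
            frame, array, magnet_10x10, mt.GeomagneticField.zero(), init=TRUE_POSE
        )
        diff = mt.solve(frame, array, magnet_10x10, init=TRUE_POSE)
        assert position_error_mm(std, TRUE_POSE) > position_error_mm(diff, TRUE_POSE)
        assert position_error_mm(diff, TRUE_POSE) < 1e-6

    def test_methods_coincide_without_background(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        std = mt.solve_standard(
            frame, array, magnet_10x10, mt.GeomagneticField.zero(), init=TRUE_POSE
        )
        diff = mt.solve(frame, array, magnet_10x10, init=TRUE_POSE)
        assert np.linalg.norm(std.pose.position - diff.pose.position) < 1e-9


class TestGridSearchOracle:
    def test_finds_true_pose_on_grid(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        positions = [TRUE_POSE.position, [0.0, 0.0, 0.0], [-0.05, 0.02, 0.01]]
        orientations = [TRUE_POSE.orientation, [1.0, 0.0, 0.0]]
        oracle = mt.grid_search_oracle(frame, array, magnet_10x10, positions, orientations)
        np.testing.assert_array_equal(oracle.pose.position, TRUE_POSE.position)
        assert oracle.cost == 0.0

    def test_argmin_within_one_cell_of_truth(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        offsets = np.linspace(-0.025, 0.025, 11)  # 5 mm cells around truth
        positions = TRUE_POSE.position + np.array(
            np.meshgrid(offsets, offsets, offsets)
        ).reshape(3, -1).T
        oracle = mt.grid_search_oracle(
            frame, array, magnet_10x10, positions, [TRUE_POSE.orientation]
        )
        assert np.linalg.norm(oracle.pose.position - TRUE_POSE.position) <= 0.005 * np.sqrt(3) + 1e-12

    def test_lm_refinement_only_descends(self, array, magnet_10x10, rng):
        frame = mt.simulate_measurement(
            array, mt.SensorModel(), magnet_10x10, TRUE_POSE, mt.GeomagneticField(), rng
        )
        positions = [[0.02, 0.03, -0.01]]
        orientations = [[0.0, 0.0, 1.0]]
        oracle = mt.grid_search_oracle(frame, array, magnet_10x10, positions, orientations)
        refined = mt.solve(frame, array, magnet_10x10, init=oracle.pose)
        assert refined.cost <= oracle.cost

    def test_empty_grid_rejected(self, array, magnet_10x10):
        frame = noiseless_frame(array, magnet_10x10, TRUE_POSE)
        with pytest.raises(ValueError):
            mt.grid_search_oracle(frame, array, magnet_10x10, np.empty((0, 3)), [[0, 0, 1]])
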