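"""Pose estimation from one measurement frame.

The differential method forms, for every pair (i, j) of equally oriented
sensors, the residual

    [measured_i - model_i(pose)] - [measured_j - model_j(pose)],

where ``model`` is the dipole field at the sensor position.  Any additive
field common to all sensors — in particular the geomagnetic background —
cancels in the measured difference, so no assumption about the background
enters the fit.  The 3K residuals are minimised over six unknowns (three
position components plus a free three-vector orientation, normalised inside
the field model) with Levenberg–Marquardt.

A per-sensor (non-differential) baseline ``solve_standard`` and a
brute-force ``grid_search_oracle`` are provided for comparison and
verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .magnet import GeomagneticField, Magnet, Pose, dipole_field
from .sensors import MeasurementFrame, SensorArray

# internal solver scale: residuals in µT keep the LM trust region well conditioned
_T_TO_UT = 1e6


@dataclass(frozen=True)
class SolverConfig:
    """Levenberg–Marquardt settings and the cold-start grid."""

    max_iterations: int = 200
    cost_tol: float = 1e-10  # relative cost-reduction tolerance
    grid_extent: tuple[float, float, float] = (0.15, 0.12, 0.10)  # half-spans [m]
    grid_points: int = 5
    n_refine: int = 5  # LM refinements from the best grid starts


@dataclass(frozen=True)
class PoseEstimate:
    """Solver output: pose, final cost [T^2], iteration count, convergence flag."""

    pose: Pose
    cost: float
    n_iterations: int
    converged: bool


def pair_residuals(
    frame: MeasurementFrame, array: SensorArray, magnet: Magnet, trial_pose: Pose
) -> np.ndarray:
    """Differential residuals, one 3-vector per sensor pair [(K, 3), T].

    Exactly invariant (in real arithmetic) to adding any constant vector to
    all readings: the homogeneous term cancels in ``measured_i - measured_j``.
    The measured difference is formed before the model is subtracted so that
    the cancellation also survives floating point whenever the shifted
    readings are exactly representable.
    """
    model = dipole_field(magnet, trial_pose, array.positions)
    idx_i = np.fromiter((p[0] for p in array.pairs), dtype=int)
    idx_j = np.fromiter((p[1] for p in array.pairs), dtype=int)
    measured_diff = frame.readings[idx_i] - frame.readings[idx_j]
    model_diff = model[idx_i] - model[idx_j]
    return measured_diff - model_diff


def cost(residuals: np.ndarray) -> float:
    """Sum of squared pair-residual norms [T^2]."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * r))


def _params_to_pose(params: np.ndarray) -> Pose:
    return Pose.with_direction(params[:3], params[3:])


def _residual_vector(
    params: np.ndarray,
    frame: MeasurementFrame,
    array: SensorArray,
    magnet: Magnet,
    geomagnetic_assumed: GeomagneticField | None,
) -> np.ndarray:
    """Flat residual vector in µT; differential unless a background is assumed."""
    n = np.linalg.norm(params[3:])
    if n == 0.0:
        # LM should never step here from a valid start; keep it finite anyway
        return np.full(
            3 * (array.n_pairs if geomagnetic_assumed is None else array.n_sensors),
            1e6,
        )
    pose = _params_to_pose(params)
    if geomagnetic_assumed is None:
        res = pair_residuals(frame, array, magnet, pose)
    else:
        model = dipole_field(magnet, pose, array.positions)
        res = frame.readings - model - geomagnetic_assumed.vector
    return res.ravel() * _T_TO_UT


def _run_lm(
    x0: np.ndarray,
    frame: MeasurementFrame,
    array: SensorArray,
    magnet: Magnet,
    geomagnetic_assumed: GeomagneticField | None,
    config: SolverConfig,
) -> tuple[np.ndarray, float, int, bool]:
    result = least_squares(
        _residual_vector,
        x0,
        args=(frame, array, magnet, geomagnetic_assumed),
        method="lm",
        ftol=config.cost_tol,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=config.max_iterations * (len(x0) + 1),
    )
    cost_t2 = 2.0 * result.cost / _T_TO_UT**2  # scipy cost is 0.5 * sum(r^2)
    converged = bool(result.status > 0)
    return result.x, cost_t2, int(result.nfev), converged


def _grid_starts(config: SolverConfig) -> tuple[np.ndarray, np.ndarray]:
    ex, ey, ez = config.grid_extent
    g = config.grid_points
    xs = np.linspace(-ex, ex, g)
    ys = np.linspace(-ey, ey, g)
    zs = np.linspace(-ez, ez, g)
    positions = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    orientations = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    return positions, orientations


def _apply_sign_convention(pose: Pose, reference_orientation: np.ndarray) -> Pose:
    """Resolve the dipole axis-sign ambiguity toward the reference direction."""
    if float(pose.orientation @ reference_orientation) < 0:
        return Pose(pose.position, -pose.orientation)
    return pose


def solve(
    frame: MeasurementFrame,
    array: SensorArray,
    magnet: Magnet,
    init: Pose | None = None,
    config: SolverConfig = SolverConfig(),
) -> PoseEstimate:
    """Estimate the magnet pose by LM on the differential pair residuals.

    With ``init`` the solver warm-starts from that pose; otherwise it
    evaluates the differential cost on a coarse position/orientation grid
    spanning the array interior and LM-refines the best starts, keeping the
    lowest-cost solution.  The reported orientation has a non-negative dot
    product with the (winning) initial orientation.
    """
    if 3 * array.n_pairs < 6:
        raise ValueError("under-determined system: need at least 2 sensor pairs")
    return _solve_impl(frame, array, magnet, None, init, config)


def solve_standard(
    frame: MeasurementFrame,
    array: SensorArray,
    magnet: Magnet,
    geomagnetic_assumed: GeomagneticField,
    init: Pose | None = None,
    config: SolverConfig = SolverConfig(),
) -> PoseEstimate:
    """Non-differential baseline: per-sensor residuals minus an assumed background.

    A wrong ``geomagnetic_assumed`` biases this estimate, which is exactly
    the failure mode the differential method removes.
    """
    if 3 * array.n_sensors < 6:
        raise ValueError("under-determined system: need at least 2 sensors")
    return _solve_impl(frame, array, magnet, geomagnetic_assumed, init, config)


def _solve_impl(
    frame: MeasurementFrame,
    array: SensorArray,
    magnet: Magnet,
    geomagnetic_assumed: GeomagneticField | None,
    init: Pose | None,
    config: SolverConfig,
) -> PoseEstimate:
    if init is not None:
        starts = [np.concatenate([init.position, init.orientation])]
        ref_orientation = init.orientation
    else:
        positions, orientations = _grid_starts(config)
        # rank all grid poses by cost, refine the best few
        costs = np.empty(len(positions) * len(orientations))
        params = np.empty((len(positions) * len(orientations), 6))
        k = 0
        for p in positions:
            for o in orientations:
                params[k, :3] = p
                params[k, 3:] = o
                r = _residual_vector(params[k], frame, array, magnet, geomagnetic_assumed)
                costs[k] = r @ r
                k += 1
        order = np.argsort(costs)[: config.n_refine]
        starts = [params[i] for i in order]
        ref_orientation = None

    best: tuple[np.ndarray, float, int, bool] | None = None
    best_start_orientation = starts[0][3:]
    for x0 in starts:
        res = _run_lm(x0, frame, array, magnet, geomagnetic_assumed, config)
        if best is None or res[1] < best[1]:
            best = res
            best_start_orientation = x0[3:]
    x, final_cost, nfev, converged = best
    pose = _params_to_pose(x)
    ref = ref_orientation if ref_orientation is not None else best_start_orientation
    pose = _apply_sign_convention(pose, np.asarray(ref, dtype=float))
    return PoseEstimate(pose=pose, cost=final_cost, n_iterations=nfev, converged=converged)


def grid_search_oracle(
    frame: MeasurementFrame,
    array: SensorArray,
    magnet: Magnet,
    positions: Sequence,
    orientations: Sequence,
) -> PoseEstimate:
    """Exhaustive cost evaluation over a finite pose grid (verification oracle)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    if positions.size == 0 or orientations.size == 0:
        raise ValueError("empty grid")
    best_cost = np.inf
    best_pose = None
    for p in positions:
        for o in orientations:
            pose = Pose.with_direction(p, o)
            c = cost(pair_residuals(frame, array, magnet, pose))
            if c < best_cost:
                best_cost = c
                best_pose = pose
    return PoseEstimate(pose=best_pose, cost=best_cost, n_iterations=0, converged=True)
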