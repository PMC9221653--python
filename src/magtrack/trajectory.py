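"""Synthetic gastrointestinal-tract-scale trajectories and measurement datasets.

The ground-truth path (preset ``serpentine-v1``) is a planar three-half-lobe
sinusoid embedded in a tilted plane:

* in-plane axis ``u`` spans ``hypot(footprint, rise)`` so that the
  horizontal extent is exactly the 180 mm footprint and the vertical rise
  exactly 49 mm (tilt ``atan(49/180) ≈ 15.2°``);
* the lateral coordinate is ``v(u) = A sin(3 pi u / U)``, with amplitude
  ``A`` solved numerically so the total arc length is 487.5 mm;
* the path is resampled to uniform (or hand-motion-jittered) arc length,
  traversed in 40 s, and may be offset in z (−60/0/+60 mm planes) and laid
  out along x or y.

The magnet's axis is perpendicular (default) or parallel to the local
tangent, matching how the physical magnets were moved along the track.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .magnet import GeomagneticField, Magnet, Pose
from .sensors import (
    MeasurementFrame,
    SensorArray,
    SensorModel,
    simulate_measurement,
)

DEFAULT_ARC_LENGTH = 0.4875
"""Total travel length of the default path [m]."""

DEFAULT_FOOTPRINT = 0.180
"""Horizontal extent of the path along its main axis [m]."""

DEFAULT_VERTICAL_DISPLACEMENT = 0.049
"""Vertical rise of the magnet over the full traversal [m]."""

DEFAULT_DURATION = 40.0
"""Traversal time [s]."""

_N_HALF_LOBES = 3
_DENSE_N = 200_001  # dense polyline used for arc-length calibration/resampling


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the synthetic path and its sampling."""

    arc_length: float = DEFAULT_ARC_LENGTH
    footprint: float = DEFAULT_FOOTPRINT
    vertical_displacement: float = DEFAULT_VERTICAL_DISPLACEMENT
    z_plane: float = 0.0  # ring-frame z offset of the path centre [m]
    layout: str = "x"  # main axis of the path: "x" or "y"
    orientation_mode: str = "perpendicular"  # magnet axis vs local tangent
    n_samples: int = 100
    duration: float = DEFAULT_DURATION
    jitter: float = 0.3  # hand-motion non-uniformity of arc spacing (0 = uniform)

    def __post_init__(self) -> None:
        if self.layout not in ("x", "y"):
            raise ValueError("layout must be 'x' or 'y'")
        if self.orientation_mode not in ("perpendicular", "parallel"):
            raise ValueError("orientation_mode must be 'perpendicular' or 'parallel'")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 <= self.jitter < 1.0:
            raise ValueError("jitter must be in [0, 1)")


@dataclass(frozen=True)
class Trajectory:
    """Ordered timestamps, positions and magnet orientations."""

    times: np.ndarray  # (M,) strictly increasing [s]
    positions: np.ndarray  # (M, 3) [m]
    orientations: np.ndarray  # (M, 3) unit vectors
    params: TrajectoryParams | None = None
    tangents: np.ndarray | None = None  # (M, 3) analytic unit tangents, if known

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        o = np.asarray(self.orientations, dtype=float)
        if len(t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if p.shape != (len(t), 3) or o.shape != (len(t), 3):
            raise ValueError("positions and orientations must be (M, 3)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "orientations", o)

    def __len__(self) -> int:
        return len(self.times)

    def poses(self) -> list[Pose]:
        return [Pose(p, o) for p, o in zip(self.positions, self.orientations)]


# ---------------------------------------------------------------------------
# path geometry
# ---------------------------------------------------------------------------


def _plane_span(footprint: float, rise: float) -> float:
    return float(np.hypot(footprint, rise))


def _inplane_arc_length(amplitude: float, span: float) -> float:
    """Dense polyline length of u -> (u, A sin(3 pi u / U)) over [0, U]."""
    u = np.linspace(0.0, span, _DENSE_N)
    v = amplitude * np.sin(_N_HALF_LOBES * np.pi * u / span)
    seg = np.hypot(np.diff(u), np.diff(v))
    return float(seg.sum())


@lru_cache(maxsize=32)
def _solve_amplitude(arc_length: float, footprint: float, rise: float) -> float:
    """Amplitude A making the serpentine arc length match ``arc_length``."""
    span = _plane_span(footprint, rise)
    if arc_length <= span:
        raise ValueError(
            f"requested arc length {arc_length} m is shorter than the straight "
            f"span {span:.4f} m"
        )
    a_max = footprint / 2.0  # lateral half-extent may not exceed the footprint
    if _inplane_arc_length(a_max, span) < arc_length:
        raise ValueError(
            "requested footprint cannot accommodate the requested arc length"
        )
    return brentq(
        lambda a: _inplane_arc_length(a, span) - arc_length,
        0.0,
        a_max,
        xtol=1e-12,
    )


def _path_points(params: TrajectoryParams, u: np.ndarray) -> np.ndarray:
    """Map in-plane coordinates u in [0, U] to 3D ring-frame positions."""
    span = _plane_span(params.footprint, params.vertical_displacement)
    amp = _solve_amplitude(params.arc_length, params.footprint, params.vertical_displacement)
    cos_a = params.footprint / span
    sin_a = params.vertical_displacement / span
    v = amp * np.sin(_N_HALF_LOBES * np.pi * u / span)
    x = (u - span / 2.0) * cos_a
    y = v
    z = (u - span / 2.0) * sin_a + params.z_plane
    pts = np.column_stack([x, y, z])
    if params.layout == "y":
        pts = pts[:, [1, 0, 2]] * np.array([-1.0, 1.0, 1.0])
    return pts


def _path_tangents(params: TrajectoryParams, u: np.ndarray) -> np.ndarray:
    span = _plane_span(params.footprint, params.vertical_displacement)
    amp = _solve_amplitude(params.arc_length, params.footprint, params.vertical_displacement)
    cos_a = params.footprint / span
    sin_a = params.vertical_displacement / span
    k = _N_HALF_LOBES * np.pi / span
    dv = amp * k * np.cos(k * u)
    t = np.column_stack([np.full_like(u, cos_a), dv, np.full_like(u, sin_a)])
    if params.layout == "y":
        t = t[:, [1, 0, 2]] * np.array([-1.0, 1.0, 1.0])
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _orientations_from_tangents(tangents: np.ndarray, mode: str) -> np.ndarray:
    if mode == "parallel":
        return tangents.copy()
    z_hat = np.array([0.0, 0.0, 1.0])
    perp = np.cross(tangents, z_hat)
    norms = np.linalg.norm(perp, axis=1)
    bad = norms < 1e-12
    if np.any(bad):  # vertical tangent: fall back to the x axis
        perp[bad] = np.cross(tangents[bad], np.array([1.0, 0.0, 0.0]))
        norms[bad] = np.linalg.norm(perp[bad], axis=1)
    return perp / norms[:, None]


def generate_trajectory(
    params: TrajectoryParams = TrajectoryParams(),
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Generate the ground-truth trajectory for one traversal.

    Samples are uniform in arc length when ``params.jitter == 0``; otherwise
    interior sample positions are perturbed by up to ``jitter`` of the mean
    spacing (hand-moved magnets do not progress uniformly).  Timestamps are
    uniform over ``params.duration``.
    """
    span = _plane_span(params.footprint, params.vertical_displacement)
    u_dense = np.linspace(0.0, span, _DENSE_N)
    pts_dense = _path_points(params, u_dense)
    seg = np.linalg.norm(np.diff(pts_dense, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_dense[-1]

    frac = np.linspace(0.0, 1.0, params.n_samples)
    if params.jitter > 0:
        if rng is None:
            raise ValueError("jitter > 0 requires an rng")
        step = 1.0 / (params.n_samples - 1)
        frac = frac.copy()
        frac[1:-1] += rng.uniform(-0.5, 0.5, params.n_samples - 2) * params.jitter * step
        frac = np.sort(frac)
    s_targets = frac * total
    u_samples = np.interp(s_targets, s_dense, u_dense)

    positions = _path_points(params, u_samples)
    tangents = _path_tangents(params, u_samples)
    orientations = _orientations_from_tangents(tangents, params.orientation_mode)
    times = np.linspace(0.0, params.duration, params.n_samples)
    return Trajectory(
        times=times,
        positions=positions,
        orientations=orientations,
        params=params,
        tangents=tangents,
    )


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------


def simulate_dataset(
    trajectory: Trajectory,
    array: SensorArray,
    sensor_model: SensorModel,
    magnet: Magnet,
    geomagnetic: GeomagneticField,
    rng: np.random.Generator,
) -> list[MeasurementFrame]:
    """One measurement frame per trajectory sample."""
    frames = []
    for t, pose in zip(trajectory.times, trajectory.poses()):
        frames.append(
            simulate_measurement(
                array, sensor_model, magnet, pose, geomagnetic, rng, timestamp=t
            )
        )
    return frames


# ---------------------------------------------------------------------------
# trajectory CSV I/O (mm at the boundary)
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["t_s", "x_mm", "y_mm", "z_mm", "ox", "oy", "oz"]


def trajectory_to_csv(trajectory: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack(
            [
                trajectory.times,
                trajectory.positions * 1e3,
                trajectory.orientations,
            ]
        ),
        columns=_TRAJ_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.12g")


def trajectory_from_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    if list(df.columns) != _TRAJ_COLUMNS:
        raise ValueError(
            f"malformed trajectory CSV {path}: expected columns {_TRAJ_COLUMNS}"
        )
    return Trajectory(
        times=df["t_s"].to_numpy(),
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy() * 1e-3,
        orientations=df[["ox", "oy", "oz"]].to_numpy(),
    )
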