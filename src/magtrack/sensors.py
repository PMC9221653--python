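"""Sensor array geometry and the magnetometer measurement chain.

Twelve three-axis magnetometers sit on three elliptical rings (semi-axes
200 x 165 mm, four sensors per ring at parametric angles 0/90/180/270 deg)
whose planes lie at z = -100, 0, +100 mm — an abdomen-sized cage.  All
sensors share one orientation frame, so every pair of sensors is "equally
oriented" and qualifies for the differential method.

The measurement chain per sensor and sample mirrors a physical ADC:
add background -> add Gaussian noise -> clip to full scale -> quantise to
the LSB -> average ``n_average`` samples.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .magnet import GeomagneticField, Magnet, Pose, total_field

logger = logging.getLogger(__name__)

N_SENSORS = 12


@dataclass(frozen=True)
class SensorArray:
    """Positions [m], orientation frames and differencing pairs of the array.

    ``orientations[i]`` maps array-frame vectors into sensor i's frame.
    ``pairs`` lists index pairs (i, j), i < j, of equally oriented sensors
    used for differential residuals.
    """

    positions: np.ndarray
    orientations: np.ndarray
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if ori.shape != (pos.shape[0], 3, 3):
            raise ValueError("orientations must be (N, 3, 3)")
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        for i, j in pairs:
            if not (0 <= i < j < pos.shape[0]):
                raise ValueError(f"invalid pair ({i}, {j})")
            if not np.allclose(ori[i], ori[j], atol=1e-12):
                raise ValueError(
                    f"pair ({i}, {j}) references sensors with different orientations"
                )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SensorModel:
    """Magnetometer front-end parameters.

    full_scale : clip level [T] (default ±800 µT)
    lsb        : quantisation step [T] (default 32 nT/LSB; 0 disables quantisation)
    noise_sigma: per-axis Gaussian noise std before averaging [T]
    n_average  : samples averaged per reading
    """

    full_scale: float = 800e-6
    lsb: float = 32e-9
    noise_sigma: float = 0.3e-6
    n_average: int = 3

    def __post_init__(self) -> None:
        if self.full_scale <= 0 or self.lsb < 0:
            raise ValueError("full_scale must be positive and lsb non-negative")
        if self.noise_sigma < 0 or self.n_average < 1:
            raise ValueError("noise_sigma must be >= 0 and n_average >= 1")

    @classmethod
    def ideal(cls) -> "SensorModel":
        """Noise-free, unquantised chain (for oracles)."""
        return cls(noise_sigma=0.0, lsb=0.0, n_average=1)


@dataclass(frozen=True)
class MeasurementFrame:
    """One time-stamped set of three-axis readings, in the array frame [T]."""

    timestamp: float
    readings: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.readings, dtype=float)
        if r.ndim != 2 or r.shape[1] != 3:
            raise ValueError("readings must be (N, 3)")
        object.__setattr__(self, "readings", r)


def build_array(
    semi_axes: tuple[float, float] = (0.200, 0.165),
    ring_z: tuple[float, ...] = (-0.100, 0.0, 0.100),
    angles_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0),
    pairing: str = "all",
) -> SensorArray:
    """Construct the elliptical-ring array.

    Sensors are indexed ring-major (ring order as in ``ring_z``, angle order
    as in ``angles_deg``); all orientation frames are the identity (aligned
    with the array frame).

    pairing : ``"all"`` -> all C(N,2) unordered pairs; ``"disjoint"`` -> a
    partition into N/2 pairs (outer rings paired across at equal angle,
    middle ring paired across the centre).
    """
    a, b = semi_axes
    positions = []
    for z in ring_z:
        for ang in angles_deg:
            t = np.deg2rad(ang)
            positions.append([a * np.cos(t), b * np.sin(t), z])
    positions = np.array(positions)
    n = len(positions)
    if n < 2:
        raise ValueError("need at least 2 equally oriented sensors to form pairs")
    orientations = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()

    if pairing == "all":
        pairs = tuple(itertools.combinations(range(n), 2))
    elif pairing == "disjoint":
        if n != 12:
            raise ValueError("disjoint pairing is defined for the 12-sensor layout")
        pairs = ((0, 8), (1, 9), (2, 10), (3, 11), (4, 6), (5, 7))
    else:
        raise ValueError(f"unknown pairing mode {pairing!r}")
    return SensorArray(positions, orientations, pairs)


def simulate_measurement(
    array: SensorArray,
    sensor_model: SensorModel,
    magnet: Magnet,
    pose: Pose,
    geomagnetic: GeomagneticField,
    rng: np.random.Generator,
    timestamp: float = 0.0,
) -> MeasurementFrame:
    """Simulate one frame of the 12-sensor measurement chain.

    Per sensor: the true total field is rotated into the sensor frame, then
    for each of ``n_average`` samples Gaussian per-axis noise is added, the
    value is clipped to ±full_scale and rounded to the nearest LSB; the
    samples are averaged and rotated back into the array frame.
    Deterministic for a given ``rng`` state.
    """
    truth = total_field(magnet, pose, array.positions, geomagnetic)  # (N, 3)
    m = sensor_model
    # into sensor frames
    local = np.einsum("nij,nj->ni", array.orientations, truth)
    draws = local[None, :, :] + (
        rng.standard_normal((m.n_average,) + local.shape) * m.noise_sigma
        if m.noise_sigma > 0
        else 0.0
    )
    draws = np.broadcast_to(draws, (m.n_average,) + local.shape)
    n_clipped = int(np.sum(np.abs(draws) > m.full_scale))
    if n_clipped:
        logger.warning("%d sample components clipped to full scale", n_clipped)
    clipped = np.clip(draws, -m.full_scale, m.full_scale)
    quantised = np.round(clipped / m.lsb) * m.lsb if m.lsb > 0 else clipped
    averaged = quantised.mean(axis=0)
    # back into the array frame
    readings = np.einsum("nji,nj->ni", array.orientations, averaged)
    return MeasurementFrame(timestamp=timestamp, readings=readings)


# ---------------------------------------------------------------------------
# I/O: array geometry (JSON, mm) and measurement frames (CSV, µT)
# ---------------------------------------------------------------------------


def array_to_json(array: SensorArray, path: str | Path) -> None:
    payload = {
        "sensor_positions_mm": (array.positions * 1e3).tolist(),
        "sensor_orientations": array.orientations.tolist(),
        "pairing": [list(p) for p in array.pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def array_from_json(path: str | Path) -> SensorArray:
    raw = json.loads(Path(path).read_text())
    return SensorArray(
        positions=np.asarray(raw["sensor_positions_mm"]) * 1e-3,
        orientations=np.asarray(raw["sensor_orientations"]),
        pairs=tuple(tuple(p) for p in raw["pairing"]),
    )


def _measurement_columns(n_sensors: int) -> list[str]:
    return [
        f"s{i:02d}{axis}_uT" for i in range(n_sensors) for axis in ("x", "y", "z")
    ]


def frames_to_csv(frames: list[MeasurementFrame], path: str | Path) -> None:
    """Write frames as CSV: ``t_s, s00x_uT, ..., s11z_uT`` (µT)."""
    if not frames:
        raise ValueError("no frames to write")
    n = frames[0].readings.shape[0]
    rows = [
        [f.timestamp] + list(f.readings.ravel() * 1e6) for f in frames
    ]
    df = pd.DataFrame(rows, columns=["t_s"] + _measurement_columns(n))
    df.to_csv(path, index=False, float_format="%.12g")


def frames_from_csv(path: str | Path, n_sensors: int = N_SENSORS) -> list[MeasurementFrame]:
    df = pd.read_csv(path)
    expected = ["t_s"] + _measurement_columns(n_sensors)
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        raise ValueError(
            f"malformed measurement CSV {path}: expected columns {expected[:4]}...; "
            f"missing {missing[:4]}"
        )
    frames = []
    for _, row in df.iterrows():
        readings = row[expected[1:]].to_numpy(dtype=float).reshape(n_sensors, 3) * 1e-6
        frames.append(MeasurementFrame(timestamp=float(row["t_s"]), readings=readings))
    return frames
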