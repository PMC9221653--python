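"""Hard-/soft-iron magnetometer calibration by ellipsoid fitting.

A magnetometer rotated through all attitudes in a clean homogeneous field
traces a sphere of the local field magnitude.  Hard-iron (additive offset)
and soft-iron (linear, symmetric) distortions turn that sphere into an
offset ellipsoid.  Fitting the general quadric

    x' Q x + 2 q' x + c = 0

to the samples by algebraic least squares, verifying it is an ellipsoid,
and extracting the symmetric positive-definite square root gives a model
``calibrated = W (raw - h)`` that maps the ellipsoid back onto the
reference sphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class CalibrationModel:
    """Soft-iron matrix W (symmetric positive definite) and hard-iron offset h [T]."""

    soft_iron_matrix: np.ndarray
    hard_iron_offset: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.soft_iron_matrix, dtype=float).reshape(3, 3)
        h = np.asarray(self.hard_iron_offset, dtype=float).reshape(3)
        if not np.allclose(w, w.T, atol=1e-9 * max(1.0, np.abs(w).max())):
            raise ValueError("soft-iron matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(w) <= 0):
            raise ValueError("soft-iron matrix must be positive definite")
        object.__setattr__(self, "soft_iron_matrix", w)
        object.__setattr__(self, "hard_iron_offset", h)

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(np.eye(3), np.zeros(3))


class EllipsoidFitError(ValueError):
    """Degenerate samples or a fitted quadric that is not an ellipsoid."""


def fit_ellipsoid(samples, reference_radius: float) -> CalibrationModel:
    """Fit an ellipsoid to raw magnetometer samples and invert the distortion.

    Parameters
    ----------
    samples : (N, 3) array-like
        Raw readings [T]; N >= 9 and the points must span a non-degenerate
        ellipsoid (not coplanar).
    reference_radius : float
        Radius of the sphere the calibrated samples should lie on
        (conventionally the local geomagnetic magnitude) [T].

    Returns
    -------
    CalibrationModel
        ``W (x - h)`` lies on the reference sphere in the least-squares sense.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("samples must be (N, 3)")
    if x.shape[0] < 9:
        raise EllipsoidFitError("at least 9 samples are required for an ellipsoid fit")

    # normalise scale for conditioning
    scale = np.abs(x).max()
    if scale == 0:
        raise EllipsoidFitError("all samples are zero")
    u = x / scale

    d = np.column_stack(
        [
            u[:, 0] ** 2,
            u[:, 1] ** 2,
            u[:, 2] ** 2,
            2 * u[:, 0] * u[:, 1],
            2 * u[:, 0] * u[:, 2],
            2 * u[:, 1] * u[:, 2],
            2 * u[:, 0],
            2 * u[:, 1],
            2 * u[:, 2],
            np.ones(len(u)),
        ]
    )
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    if s[-2] <= 1e-10 * s[0]:
        raise EllipsoidFitError("degenerate samples (coplanar or rank deficient)")
    p = vt[-1]

    q = np.array(
        [
            [p[0], p[3], p[4]],
            [p[3], p[1], p[5]],
            [p[4], p[5], p[2]],
        ]
    )
    lin = p[6:9]
    const = p[9]

    eigvals = np.linalg.eigvalsh(q)
    if np.all(eigvals < 0):
        q, lin, const = -q, -lin, -const
        eigvals = -eigvals[::-1]
    if np.any(eigvals <= 0):
        raise EllipsoidFitError("fitted quadric is not an ellipsoid")

    centre = -np.linalg.solve(q, lin)
    # (x - c)' Q (x - c) = c' Q c - const
    rhs = centre @ q @ centre - const
    if rhs <= 0:
        raise EllipsoidFitError("fitted quadric is not an ellipsoid (imaginary radii)")
    m = q / rhs  # (x - c)' M (x - c) = 1 in scaled units

    # SPD square root; reference sphere of requested radius in physical units
    w_scaled = _spd_sqrt(m)
    soft_iron = reference_radius * w_scaled / scale
    offset = centre * scale
    return CalibrationModel(soft_iron_matrix=soft_iron, hard_iron_offset=offset)


def _spd_sqrt(m: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(m)
    if np.any(vals <= 0):
        raise EllipsoidFitError("quadric matrix not positive definite")
    return (vecs * np.sqrt(vals)) @ vecs.T


def apply_calibration(model: CalibrationModel, raw) -> np.ndarray:
    """Apply ``W (raw - h)`` to one 3-vector or an (N, 3) batch."""
    r = np.asarray(raw, dtype=float)
    return (r - model.hard_iron_offset) @ model.soft_iron_matrix.T


def distort(samples, soft_iron_inverse: np.ndarray, hard_iron_offset) -> np.ndarray:
    """Forward distortion generator (test oracle): ``raw = S u + h``.

    ``soft_iron_inverse`` is the distortion matrix S whose inverse the fit
    should recover (up to the reference-radius normalisation).
    """
    u = np.asarray(samples, dtype=float)
    return u @ np.asarray(soft_iron_inverse, dtype=float).T + np.asarray(
        hard_iron_offset, dtype=float
    )


def sphere_samples(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform random points on a sphere of the given radius."""
    v = rng.standard_normal((n, 3))
    return radius * v / np.linalg.norm(v, axis=1, keepdims=True)


def calibration_to_json(models: dict[str, CalibrationModel], path: str | Path) -> None:
    """Write per-sensor calibration models (matrix dimensionless, offset µT)."""
    payload = {
        key: {
            "soft_iron_matrix": m.soft_iron_matrix.tolist(),
            "hard_iron_offset_uT": (m.hard_iron_offset * 1e6).tolist(),
        }
        for key, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def calibration_from_json(path: str | Path) -> dict[str, CalibrationModel]:
    raw = json.loads(Path(path).read_text())
    return {
        key: CalibrationModel(
            soft_iron_matrix=np.asarray(entry["soft_iron_matrix"]),
            hard_iron_offset=np.asarray(entry["hard_iron_offset_uT"]) * 1e-6,
        )
        for key, entry in raw.items()
    }
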