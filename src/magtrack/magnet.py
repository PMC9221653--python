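"""Magnetic sources: cylindrical permanent magnets and the geomagnetic background.

A capsule endoscope is assumed to carry an axially magnetised cylindrical
NdFeB magnet.  At observation distances large compared with the magnet's
dimensions its flux density is the point-dipole field

    B(P) = (mu0 * mur / 4 pi) * m * [ 3 <o, R> R / |R|^5  -  o / |R|^3 ],

with ``R = P - position``, unit axis ``o`` and moment magnitude
``m = M0 * pi * k^2 * l`` (magnetisation times cylinder volume).  Human
tissue has relative permeability ~1, so ``mur`` is fixed to 1.

A finite-volume evaluator (superposition of sub-volume dipoles on an
equal-volume cylindrical grid) serves as an independent check of the dipole
approximation at finite distance.

All quantities are strictly SI internally: metres, tesla, A/m.  Millimetres
and microtesla appear only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

MU_0 = 4e-7 * np.pi
"""Vacuum permeability [H/m]."""

MU_R = 1.0
"""Relative permeability of human tissue (not configurable)."""

DEFAULT_GEOMAGNETIC_MAGNITUDE = 48e-6
"""Default homogeneous background magnitude [T]."""


@dataclass(frozen=True)
class Magnet:
    """Axially magnetised cylindrical permanent magnet.

    Parameters
    ----------
    radius : float
        Cylinder radius k [m].
    length : float
        Cylinder length l [m].
    magnetisation : float
        Axial magnetisation M0 [A/m].
    """

    radius: float
    length: float
    magnetisation: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0 or self.magnetisation <= 0:
            raise ValueError("radius, length and magnetisation must be positive")

    @property
    def volume(self) -> float:
        """Cylinder volume [m^3]."""
        return np.pi * self.radius**2 * self.length

    @property
    def moment_magnitude(self) -> float:
        """Dipole moment magnitude m = M0 * pi * k^2 * l [A·m^2]."""
        return self.magnetisation * self.volume


@dataclass(frozen=True)
class Pose:
    """Position and unit orientation of the magnet at one instant."""

    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        ori = np.asarray(self.orientation, dtype=float).reshape(3)
        norm = np.linalg.norm(ori)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"orientation must be a unit vector (norm {norm:.3e})")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", ori)

    @classmethod
    def with_direction(cls, position, direction) -> "Pose":
        """Build a pose, normalising an arbitrary nonzero direction vector."""
        d = np.asarray(direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0.0:
            raise ValueError("direction vector must be nonzero")
        return cls(np.asarray(position, dtype=float), d / n)


def _default_geomagnetic_vector() -> np.ndarray:
    # oblique direction: nothing in the pipeline should rely on axis alignment
    return DEFAULT_GEOMAGNETIC_MAGNITUDE * np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)


@dataclass(frozen=True)
class GeomagneticField:
    """Homogeneous background flux density across the whole workspace [T]."""

    vector: np.ndarray = field(default_factory=_default_geomagnetic_vector)

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float).reshape(3)
        if not np.all(np.isfinite(v)):
            raise ValueError("geomagnetic vector must be finite")
        object.__setattr__(self, "vector", v)

    @classmethod
    def zero(cls) -> "GeomagneticField":
        return cls(np.zeros(3))

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


def dipole_field(magnet: Magnet, pose: Pose, observation_points) -> np.ndarray:
    """Point-dipole flux density at one or many observation points [T].

    ``observation_points`` may be a single 3-vector or an (N, 3) array;
    the result has the same shape.

    Raises
    ------
    ValueError
        If any observation point coincides with the magnet position
        (singular evaluation).
    """
    pts = np.asarray(observation_points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    r = pts - pose.position  # (N, 3)
    dist = np.linalg.norm(r, axis=1)
    if np.any(dist == 0.0):
        raise ValueError("observation point coincides with the magnet position")
    o = pose.orientation
    prefactor = MU_0 * MU_R * magnet.moment_magnitude / (4.0 * np.pi)
    proj = r @ o  # <o, R> per point
    b = prefactor * (
        3.0 * proj[:, None] * r / dist[:, None] ** 5 - o[None, :] / dist[:, None] ** 3
    )
    return b[0] if single else b


def total_field(
    magnet: Magnet, pose: Pose, observation_points, geomagnetic: GeomagneticField
) -> np.ndarray:
    """Dipole field plus the homogeneous geomagnetic background [T]."""
    return dipole_field(magnet, pose, observation_points) + geomagnetic.vector


def _subdivision_counts(n_subdivisions: int) -> tuple[int, int, int]:
    """Equal-volume cylindrical grid counts (radial, angular, axial)."""
    if n_subdivisions < 1:
        raise ValueError("n_subdivisions must be >= 1")
    base = int(np.ceil(n_subdivisions ** (1.0 / 3.0)))
    n_r = base
    n_phi = base
    n_z = int(np.ceil(n_subdivisions / (n_r * n_phi)))
    return n_r, n_phi, n_z


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the local +z axis onto ``axis`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def finite_volume_field(
    magnet: Magnet, pose: Pose, observation_point, n_subdivisions: int
) -> np.ndarray:
    """Superpose sub-volume dipole fields over an equal-volume cylinder grid.

    The magnet is partitioned into ``>= n_subdivisions`` cells (radial shells
    x angular sectors x axial slabs, each cell of identical volume).  Each
    cell contributes a point dipole of moment ``M0 * dV`` along the magnet
    axis, placed at the cell centroid.  With one cell this collapses exactly
    to :func:`dipole_field`.
    """
    n_r, n_phi, n_z = _subdivision_counts(n_subdivisions)
    k, length = magnet.radius, magnet.length

    # equal-area radial shells: boundaries at k*sqrt(i/n_r)
    r_edges = k * np.sqrt(np.arange(n_r + 1) / n_r)
    dphi = 2.0 * np.pi / n_phi
    phi_centres = (np.arange(n_phi) + 0.5) * dphi - np.pi
    z_centres = (np.arange(n_z) + 0.5) * (length / n_z) - length / 2.0

    # sector centroid radius per shell; -> 0 for the full disc (n_r=n_phi=1)
    r1, r2 = r_edges[:-1], r_edges[1:]
    denom = r2**2 - r1**2
    sinc_half = np.sinc(dphi / (2.0 * np.pi))  # sin(dphi/2)/(dphi/2)
    r_cent = (2.0 / 3.0) * (r2**3 - r1**3) / denom * sinc_half

    rr, pp, zz = np.meshgrid(r_cent, phi_centres, z_centres, indexing="ij")
    local = np.column_stack(
        [(rr * np.cos(pp)).ravel(), (rr * np.sin(pp)).ravel(), zz.ravel()]
    )
    rot = _rotation_from_z(pose.orientation)
    centres = pose.position + local @ rot.T

    dv = magnet.volume / (n_r * n_phi * n_z)
    sub_moment = magnet.magnetisation * dv

    pt = np.asarray(observation_point, dtype=float).reshape(3)
    r = pt[None, :] - centres
    dist = np.linalg.norm(r, axis=1)
    if np.any(dist == 0.0):
        raise ValueError("observation point lies inside a sub-volume centre")
    o = pose.orientation
    proj = r @ o
    pref = MU_0 * MU_R * sub_moment / (4.0 * np.pi)
    contributions = pref * (
        3.0 * proj[:, None] * r / dist[:, None] ** 5 - o[None, :] / dist[:, None] ** 3
    )
    return contributions.sum(axis=0)


def load_magnet_catalog(path: str | Path | None = None) -> dict[str, Magnet]:
    """Load a named magnet catalog from JSON (mm / kA·m⁻¹ at the boundary)."""
    if path is None:
        text = resources.files("magtrack.data").joinpath("magnets.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    catalog = {}
    for name, entry in raw.items():
        catalog[name] = Magnet(
            radius=entry["diameter_mm"] / 2.0 * 1e-3,
            length=entry["length_mm"] * 1e-3,
            magnetisation=entry["magnetisation_kA_per_m"] * 1e3,
        )
    return catalog


def get_magnet(name: str, path: str | Path | None = None) -> Magnet:
    """Look up a magnet by catalog name (``10x10``, ``5x10``, ``3x10``)."""
    catalog = load_magnet_catalog(path)
    if name not in catalog:
        raise KeyError(
            f"unknown magnet {name!r}; available: {', '.join(sorted(catalog))}"
        )
    return catalog[name]
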