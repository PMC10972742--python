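"""Core geometry: ideal helices, rigid/screw transforms, superposition.

This is the numeric substrate of the package.  A twistless-helix-repeat
(THR) protein is built from ideal straight alpha-helices whose axes are all
parallel to z; the repeat-to-repeat geometry is fully described by the
triple ``(d, dh, dtheta)``:

* ``d``      -- in-plane (x-y) displacement between the axes of
                corresponding helices of successive repeats, in Angstrom;
* ``dh``     -- displacement along z per repeat, in Angstrom;
* ``dtheta`` -- change in helix phase per repeat, in degrees.

``repeat_rigid_transform`` converts that triple into an explicit rigid
(screw) transform: for ``dtheta != 0`` a rotation by ``dtheta`` about a
z-parallel axis at radius ``R = d / (2 sin(|dtheta| / 2))`` from the
reference helix plus a z-translation ``dh``; for ``dtheta == 0`` a pure
translation ``(d, 0, dh)`` (propagation along +x by convention).

Conventions (fixed once, used everywhere):

* helix phase = azimuth of the first residue's CA about the helix axis,
  counterclockwise from +x viewed from +z, stored in [0, 360);
* positive ``dtheta`` is counterclockwise viewed from +z;
* phases are reported in [0, 360), phase differences in (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ATOM_ORDER, GEOM_TOL, IDEAL_HELIX

__all__ = [
    "HelixSpec",
    "HelixCoords",
    "RepeatTransform",
    "RigidTransform",
    "make_ideal_helix",
    "fit_helix_axis",
    "repeat_rigid_transform",
    "kabsch_superpose",
    "compose_n",
    "wrap_angle",
    "norm_phase",
]


class GeometryError(ValueError):
    """Invalid geometric specification or degenerate input."""


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def norm_phase(angle: float) -> float:
    """Normalize a phase in degrees to [0, 360)."""
    a = math.fmod(angle, 360.0)
    if a < 0.0:
        a += 360.0
    return 0.0 if a == 360.0 else a


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise GeometryError("rotation must be proper (det = +1)")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation_about(
        cls,
        axis_dir: np.ndarray,
        point: np.ndarray,
        angle_deg: float,
        shift_along_axis: float = 0.0,
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about the line (point, axis_dir), plus an
        optional translation along the axis (a screw transform)."""
        u = np.asarray(axis_dir, dtype=float)
        n = np.linalg.norm(u)
        if n == 0.0:
            raise GeometryError("axis direction must be nonzero")
        u = u / n
        p = np.asarray(point, dtype=float).reshape(3)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * u).as_matrix()
        t = p - R @ p + shift_along_axis * u
        return cls(R, t)

    @classmethod
    def from_translation(cls, t: np.ndarray) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_vector(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def rotation_angle(self) -> float:
        """Rotation magnitude in degrees, in [0, 180]."""
        return float(
            np.rad2deg(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def is_identity(self, atol: float = GEOM_TOL) -> bool:
        return (
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.linalg.norm(self.translation) <= atol
        )


def compose_n(t: RigidTransform, n: int) -> RigidTransform:
    """Compose ``t`` with itself ``n`` times; ``n = 0`` gives the identity."""
    if n < 0:
        raise GeometryError("n must be >= 0")
    out = RigidTransform.identity()
    for _ in range(n):
        out = t @ out
    return out


# ---------------------------------------------------------------------------
# helix specification and construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HelixSpec:
    """Placement of one ideal straight helix, axis parallel to z.

    ``phase`` is the azimuth of the first residue's CA about the axis
    (degrees, CCW from +x viewed from +z); for ``flipped`` helices it is the
    phase of the as-built helix before the 180 deg flip about the x
    direction through the helix midpoint.
    """

    n_res: int
    phase: float = 0.0
    axis_xy: Tuple[float, float] = (0.0, 0.0)
    z_start: float = 0.0
    flipped: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_res < 4:
            raise GeometryError("helix needs at least 4 residues (axis fit undefined)")
        object.__setattr__(self, "phase", norm_phase(float(self.phase)))
        object.__setattr__(
            self, "axis_xy", (float(self.axis_xy[0]), float(self.axis_xy[1]))
        )

    def with_phase(self, phase: float) -> "HelixSpec":
        return replace(self, phase=phase)


@dataclass(frozen=True)
class HelixCoords:
    """Backbone coordinates (N, CA, C, O per residue) of one helix.

    ``coords`` has shape (n_res, 4, 3) in the atom order of
    :data:`thrkit.constants.ATOM_ORDER`; residue indices are 0-based here
    and become 1-based in output files.
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[1] != len(ATOM_ORDER) or c.shape[2] != 3:
            raise GeometryError("coords must have shape (n_res, 4, 3)")
        object.__setattr__(self, "coords", c)

    @property
    def n_res(self) -> int:
        return self.coords.shape[0]

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, ATOM_ORDER.index("CA"), :]

    def atom(self, name: str) -> np.ndarray:
        return self.coords[:, ATOM_ORDER.index(name), :]

    def transformed(self, t: RigidTransform) -> "HelixCoords":
        return HelixCoords(t.apply(self.coords.reshape(-1, 3)).reshape(self.coords.shape))


def make_ideal_helix(spec: HelixSpec) -> HelixCoords:
    """Realize an ideal straight alpha-helix from its placement spec.

    The helix axis is parallel to z (antiparallel if ``spec.flipped``),
    passes through ``spec.axis_xy``, the first CA sits at azimuth
    ``spec.phase`` and height ``spec.z_start``.
    """
    p = IDEAL_HELIX
    i = np.arange(spec.n_res)[:, None]  # (n, 1)
    ax, ay = spec.axis_xy
    coords = np.empty((spec.n_res, len(ATOM_ORDER), 3), dtype=float)
    for k, atom in enumerate(ATOM_ORDER):
        r, dphi, dz = p.atom_cylinders[atom]
        az = np.deg2rad(spec.phase + i * p.twist + dphi)
        coords[:, k, 0] = (ax + r * np.cos(az)).ravel()
        coords[:, k, 1] = (ay + r * np.sin(az)).ravel()
        coords[:, k, 2] = (spec.z_start + i * p.rise + dz).ravel()
    if spec.flipped:
        # 180 deg rotation about the x direction through the helix midpoint:
        # keeps the axis on axis_xy, reverses the run direction to -z.
        z_mid = spec.z_start + (spec.n_res - 1) * p.rise / 2.0
        coords[..., 1] = 2.0 * ay - coords[..., 1]
        coords[..., 2] = 2.0 * z_mid - coords[..., 2]
    return HelixCoords(coords)


def fit_helix_axis(coords: HelixCoords | np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Fit the axis of an (ideal) helix from its CA trace.

    Returns ``(point, direction, phase)``: a point on the axis (at the z of
    the first CA for z-parallel helices; in general the axis point closest
    to the first CA's axial position), a unit direction oriented from the
    first toward the last residue, and the azimuth of the first CA about
    the axis in degrees ([0, 360), measured from +x for near-z axes, else
    from an axis-orthogonal reference built deterministically).
    """
    ca = coords.ca if isinstance(coords, HelixCoords) else np.asarray(coords, float)
    if ca.ndim != 2 or ca.shape[1] != 3 or ca.shape[0] < 4:
        raise GeometryError("axis fit needs >= 4 CA positions")
    v = np.diff(ca, axis=0)
    d2 = np.diff(v, axis=0)  # second differences are perpendicular to the axis
    _, s, vt = np.linalg.svd(d2)
    direction = vt[-1]
    if direction @ (ca[-1] - ca[0]) < 0:
        direction = -direction
    # project CAs onto the plane perpendicular to the axis and fit the circle
    t = ca @ direction
    # orthonormal in-plane basis; deterministic and continuous for z-like axes
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ direction) * direction
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    flat = ca - np.outer(t, direction)
    xy = np.c_[flat @ e1, flat @ e2]
    # algebraic (Kasa) circle fit -- exact for noiseless circles
    A = np.c_[2.0 * xy, np.ones(len(xy))]
    b = (xy**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise GeometryError("degenerate CA trace: cannot fit helix axis")
    center = sol[0] * e1 + sol[1] * e2
    point = center + (t[0]) * direction
    rel = ca[0] - point
    rel -= (rel @ direction) * direction
    # report azimuth in the global x-y frame when the axis is (anti)parallel z
    if abs(abs(direction[2]) - 1.0) < 1e-9:
        phase = math.degrees(math.atan2(rel[1], rel[0]))
    else:
        phase = math.degrees(math.atan2(rel @ e2, rel @ e1))
    return point, direction, norm_phase(phase)


# ---------------------------------------------------------------------------
# repeat transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatTransform:
    """The (d, dh, dtheta) repeat triple of a THR block."""

    d: float
    dh: float = 0.0
    dtheta: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0.0:
            raise GeometryError("d must be > 0")
        object.__setattr__(self, "dtheta", wrap_angle(float(self.dtheta)))

    @property
    def curvature_radius(self) -> float:
        """Radius of the repeat-anchor circle, ``d / (2 sin(|dtheta|/2))``.

        Infinite for straight (dtheta = 0) repeats.
        """
        if self.dtheta == 0.0:
            return math.inf
        return self.d / (2.0 * math.sin(math.radians(abs(self.dtheta)) / 2.0))


def repeat_rigid_transform(rt: RepeatTransform) -> RigidTransform:
    """Rigid (screw) transform equivalent to a repeat triple.

    For ``dtheta == 0``: pure translation ``(d, 0, dh)``.  Otherwise a
    rotation by ``dtheta`` about a z-parallel axis through
    ``(0, sign(dtheta) * R)`` with ``R = d / (2 sin(|dtheta|/2))``, composed
    with a translation ``dh`` along z; applied to a helix at the origin this
    displaces its axis by exactly ``d`` in x-y and advances its phase by
    exactly ``dtheta``.
    """
    if rt.dtheta == 0.0:
        return RigidTransform.from_translation([rt.d, 0.0, rt.dh])
    R = rt.curvature_radius
    center = np.array([0.0, math.copysign(R, rt.dtheta), 0.0])
    return RigidTransform.from_rotation_about(
        np.array([0.0, 0.0, 1.0]), center, rt.dtheta, shift_along_axis=rt.dh
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Tuple[RigidTransform, float]:
    """Least-squares superposition of point set ``P`` onto ``Q``.

    Returns the proper rigid transform minimizing the RMSD of ``P`` onto
    ``Q`` and the residual RMSD in Angstrom.  Raises on size mismatch or
    (near-)collinear degenerate sets, for which the rotation is not unique.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("point sets must both have shape (n, 3)")
    if P.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 points")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    # degenerate (collinear) configurations leave the rotation underdetermined
    if np.linalg.matrix_rank(P0, tol=1e-8 * max(1.0, np.abs(P0).max())) < 2:
        raise GeometryError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = Qc - R @ Pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return RigidTransform(R, t), rmsd
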