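"""Point-group frame sets and C2 handshake interfaces.

Cyclic (Cn) and polyhedral (T, O, I) rotation groups with face/edge axis
enumeration, in a canonical orientation (one face axis on +z, one edge axis
in the xz plane) so that downstream output is byte-reproducible.

The out-of-plane "handshake" angle of an architecture is the dihedral angle
of the corresponding polyhedron, computed here as 180 deg minus the angle
between two adjacent face axes -- never hard-coded:

* T3 (tetrahedron, C3 faces)    : 180 - 109.47 = 70.53 deg
* O3 (octahedron, C3 faces)     : 180 - 70.53  = 109.47 deg
* I3 (icosahedron, C3 faces)    : 180 - 41.81  = 138.19 deg
* O4 (cube, C4 faces of O)      : 180 - 90     = 90 deg
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .blocks import THRBlock, realize_block
from .constants import CLASH_CUTOFF
from .geometry import GeometryError, RigidTransform
from .model import BackboneModel

__all__ = [
    "SymmetryFrameSet",
    "HandshakeInterface",
    "make_frames",
    "handshake_angle",
    "build_handshake",
    "sample_handshake_offsets",
    "measure_dimer_angle",
    "ARCHITECTURES",
]

#: architecture -> (point group, face symmetry order)
ARCHITECTURES: Dict[str, Tuple[str, int]] = {
    "T3": ("T", 3),
    "O3": ("O", 3),
    "I3": ("I", 3),
    "O4": ("O", 4),
}


class SymmetryError(GeometryError):
    pass


@dataclass(frozen=True)
class SymmetryFrameSet:
    """Rotation frames of a point group plus labelled face/edge axes.

    ``face_axes`` maps a face label like ``"C3"`` or ``"C4"`` to directed
    unit vectors, one per polyhedron face (the O group exposes both its
    octahedron C3 faces and its cube C4 faces).  ``edge_axes`` holds one
    directed unit vector per polyhedron edge midpoint (2-fold axes).
    """

    group: str
    frames: Tuple[RigidTransform, ...]
    face_axes: Dict[str, np.ndarray]
    edge_axes: Dict[str, np.ndarray]

    @property
    def order(self) -> int:
        return len(self.frames)


def _axes_from_rotations(rots: Rotation, angle_deg: float) -> np.ndarray:
    """Directed unit axes of all group elements with the given rotation angle."""
    out = []
    for r in rots:
        rv = r.as_rotvec()
        ang = np.linalg.norm(rv)
        if abs(math.degrees(ang) - angle_deg) < 1e-6:
            out.append(rv / ang)
    if not out:
        return np.empty((0, 3))
    axes = np.array(out)
    # deduplicate directed axes
    uniq: List[np.ndarray] = []
    for a in axes:
        if not any(np.allclose(a, b, atol=1e-9) for b in uniq):
            uniq.append(a)
    return np.array(sorted(uniq, key=lambda v: (round(v[2], 9), round(v[1], 9), round(v[0], 9))))


def _canonical_rotation(face: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Rotation matrix putting ``face`` on +z and one edge axis in xz (x>0)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(face, z)
    s = np.linalg.norm(v)
    c = float(face @ z)
    if s < 1e-12:
        R1 = np.eye(3) if c > 0 else Rotation.from_rotvec([math.pi, 0, 0]).as_matrix()
    else:
        R1 = Rotation.from_rotvec(v / s * math.atan2(s, c)).as_matrix()
    e = edges @ R1.T
    # pick the edge axis with the smallest nonnegative azimuth, spin it to y=0
    az = np.arctan2(e[:, 1], e[:, 0])
    horiz = np.hypot(e[:, 1], e[:, 0]) > 1e-9
    az = np.where(horiz, np.mod(az, 2 * math.pi), np.inf)
    k = int(np.argmin(az))
    R2 = Rotation.from_rotvec([0.0, 0.0, -az[k]]).as_matrix()
    return R2 @ R1


def make_frames(group: str | Tuple[str, int], n: Optional[int] = None) -> SymmetryFrameSet:
    """Frame set for Cn, T, O or I in canonical orientation.

    ``group`` may be ``"T" | "O" | "I"``, ``"C6"``-style strings, or
    ``("C", n)``.  Frame counts: n (Cn), 12 (T), 24 (O), 60 (I).
    """
    if isinstance(group, tuple):
        label, n = group
        group = f"{label}{n}"
    group = str(group)
    if group.upper().startswith("C"):
        if n is None:
            try:
                n = int(group[1:])
            except ValueError:
                raise SymmetryError(f"unknown group {group!r}") from None
        if n < 1:
            raise SymmetryError("cyclic order must be >= 1")
        frames = tuple(
            RigidTransform.from_rotation_about([0, 0, 1], [0, 0, 0], 360.0 * k / n)
            for k in range(n)
        )
        face = {f"C{n}": np.array([[0.0, 0.0, 1.0]])}
        return SymmetryFrameSet(f"C{n}", frames, face, {})
    if group not in ("T", "O", "I"):
        raise SymmetryError(f"unknown group {group!r}")
    rots = Rotation.create_group(group)
    if group == "T":
        c3 = _axes_from_rotations(rots, 120.0)  # 8 directions
        edges = _axes_from_rotations(rots, 180.0)  # 3 axes -> need both signs
        edges = np.vstack([edges, -edges])
        # one of the two dual tetrahedra: a maximal set with pairwise dot -1/3
        seed = c3[-1]
        faces = np.array([a for a in c3 if np.allclose(a @ seed, 1.0, atol=1e-9)
                          or abs(a @ seed + 1.0 / 3.0) < 1e-9])
        face_axes = {"C3": faces}
    elif group == "O":
        c3 = _axes_from_rotations(rots, 120.0)  # octahedron faces, 8
        c4 = _axes_from_rotations(rots, 90.0)  # cube faces, 6
        edges = _axes_from_rotations(rots, 180.0)
        # 180-deg elements include both C4^2 (cube face axes) and true edge
        # axes; drop the ones parallel to C4 axes
        edges = np.array(
            [a for a in edges if not any(abs(abs(a @ f) - 1.0) < 1e-9 for f in c4)]
        )
        edges = np.vstack([edges, -edges])
        face_axes = {"C3": c3, "C4": c4}
    else:  # I
        c3 = _axes_from_rotations(rots, 120.0)  # 20 icosahedron faces
        c5 = _axes_from_rotations(rots, 72.0)  # 12 dodecahedron faces
        edges = _axes_from_rotations(rots, 180.0)
        edges = np.vstack([edges, -edges])
        face_axes = {"C3": c3, "C5": c5}
    # canonicalize: primary face axis on +z, one edge axis in the xz plane
    primary = "C3" if "C3" in face_axes else "C4"
    f0 = face_axes[primary][np.lexsort(face_axes[primary].T[::-1])][-1]
    # prefer the face direction with max z (then y, x) for determinism
    order = np.lexsort((face_axes[primary][:, 0], face_axes[primary][:, 1], face_axes[primary][:, 2]))
    f0 = face_axes[primary][order[-1]]
    Rc = _canonical_rotation(f0, edges)
    frames = tuple(
        RigidTransform(Rc @ r.as_matrix() @ Rc.T, np.zeros(3)) for r in rots
    )
    face_axes = {
        k: _sorted_axes(v @ Rc.T) for k, v in face_axes.items()
    }
    edge_axes = {"C2": _sorted_axes(edges @ Rc.T)}
    return SymmetryFrameSet(group, frames, face_axes, edge_axes)


def _sorted_axes(a: np.ndarray) -> np.ndarray:
    a = np.where(np.abs(a) < 1e-12, 0.0, a)
    return a[np.lexsort((np.round(a[:, 0], 9), np.round(a[:, 1], 9), np.round(a[:, 2], 9)))][::-1]


def adjacent_face_pair(faces: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Two adjacent (minimal-angle) face axes and the angle between them."""
    best = None
    for i in range(len(faces)):
        for j in range(i + 1, len(faces)):
            c = float(np.clip(faces[i] @ faces[j], -1.0, 1.0))
            ang = math.degrees(math.acos(c))
            if ang > 1e-6 and (best is None or ang < best[2]):
                best = (faces[i], faces[j], ang)
    if best is None:
        raise SymmetryError("need at least two distinct face axes")
    return best


def handshake_angle(architecture: str) -> float:
    """Out-of-plane C2 handshake angle of a cage architecture, in degrees.

    Computed as 180 deg minus the angle between two adjacent face axes of
    the architecture's polyhedron (its dihedral angle), from the generated
    frame set.
    """
    if architecture not in ARCHITECTURES:
        raise SymmetryError(
            f"unknown architecture {architecture!r}; one of {sorted(ARCHITECTURES)}"
        )
    group, face_order = ARCHITECTURES[architecture]
    fs = make_frames(group)
    faces = fs.face_axes[f"C{face_order}"]
    _, _, ang = adjacent_face_pair(faces)
    return 180.0 - ang


@dataclass(frozen=True)
class HandshakeInterface:
    """A C2-symmetric pairing of two straight THR blocks.

    ``angle`` is the out-of-plane angle between the two block planes (each
    spanned by the block's helix-axis direction and propagation direction);
    ``offset`` the perpendicular spacing between the two propagation lines;
    ``c2_axis``/``c2_point`` define the exact 2-fold.
    """

    angle: float
    offset: float
    c2_axis: np.ndarray
    c2_point: np.ndarray
    clashing: bool = False

    @property
    def transform(self) -> RigidTransform:
        return RigidTransform.from_rotation_about(self.c2_axis, self.c2_point, 180.0)


def build_handshake(
    block: THRBlock, angle: float, offset: float, clash_cutoff: float = CLASH_CUTOFF
) -> Tuple[HandshakeInterface, BackboneModel]:
    """Place two copies of a straight block as an exact C2 dimer.

    The copies' propagation axes stay parallel (antiparallel orientation),
    their block planes meet at ``angle`` and their propagation lines are
    separated by ``offset``; only the offset is free when sampling, exactly
    the one degree of freedom of the handshake design.
    """
    if block.block_class not in ("linear", "stair"):
        raise SymmetryError("handshake requires a straight (linear/stair) block")
    beta = math.radians(angle) / 2.0
    u = np.array([0.0, math.cos(beta), math.sin(beta)])  # C2 axis direction
    w = np.array([0.0, math.sin(beta), -math.cos(beta)])  # u x x_hat
    q = 0.5 * offset * w
    iface = HandshakeInterface(float(angle), float(offset), u, q)
    half = realize_block(block)
    mate = half.transformed(iface.transform)
    dimer = half.merged(mate)
    dimer.meta["architecture"] = "handshake"
    from .validation import detect_clashes

    clashing = bool(detect_clashes(dimer, cutoff=clash_cutoff))
    if clashing:
        iface = HandshakeInterface(float(angle), float(offset), u, q, clashing=True)
    return iface, dimer


def sample_handshake_offsets(
    block: THRBlock,
    angle: float,
    offset_range: Tuple[float, float] = (0.0, 15.0),
    step: float = 0.5,
) -> List[HandshakeInterface]:
    """Non-clashing handshake interfaces over a deterministic offset grid."""
    if step <= 0:
        raise SymmetryError("step must be > 0")
    lo, hi = offset_range
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    out = []
    for k in range(n):
        off = lo + k * step
        iface, _ = build_handshake(block, angle, off)
        if not iface.clashing:
            out.append(iface)
    return out


def measure_dimer_angle(dir_a: np.ndarray, dir_b: np.ndarray) -> float:
    """Out-of-plane angle of a handshake dimer from the two halves'
    directed helix-axis directions: 180 deg minus the angle between them."""
    a = np.asarray(dir_a, float)
    b = np.asarray(dir_b, float)
    c = float(np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0))
    return 180.0 - math.degrees(math.acos(c))
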