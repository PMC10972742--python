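"""Architectures composed from THR blocks and symmetry frames.

Closed rings and their cyclic splits, polygons with turn-module corners,
strutted concentric double rings, polyhedral handshake nanocages (one- and
two-component) and 1D train-track lattices.  Every builder returns an
:class:`AssemblyBlueprint` -- a list of placed components plus interface
declarations and expansion handles -- which realizes to a
:class:`~thrkit.model.BackboneModel`.

Size expansion never touches an interface: expanding a blueprint re-runs
its builder with more repeats in a designated straight segment, and because
every inter-block contact is built from repeat-periodic geometry the
interface-local coordinates are reproduced exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .blocks import (
    BlockError,
    RepeatUnit,
    THRBlock,
    build_curve_thr,
    insert_repeats,
    realize_block,
)
from .geometry import (
    GeometryError,
    RepeatTransform,
    RigidTransform,
    compose_n,
    repeat_rigid_transform,
)
from .model import BackboneModel, chain_id_for
from .symmetry import ARCHITECTURES, adjacent_face_pair, handshake_angle, make_frames

__all__ = [
    "RingSpec",
    "AssemblyBlueprint",
    "PlacedComponent",
    "ClosureError",
    "build_ring",
    "build_polygon",
    "strut_compatibility",
    "build_strutted_rings",
    "build_cage",
    "expand_assembly",
    "build_o43_locked_component",
    "dock_two_component",
    "DockCandidate",
    "build_train_track",
]


class AssemblyError(GeometryError):
    pass


class ClosureError(AssemblyError):
    """A declared cycle does not close; carries the gap transform."""

    def __init__(self, msg: str, gap: RigidTransform):
        super().__init__(msg)
        self.gap = gap

    @property
    def gap_rotation(self) -> float:
        return self.gap.rotation_angle


# ---------------------------------------------------------------------------
# blueprint container
# ---------------------------------------------------------------------------


@dataclass
class PlacedComponent:
    name: str
    block: THRBlock
    frame: RigidTransform


@dataclass
class AssemblyBlueprint:
    architecture: str
    components: List[PlacedComponent] = field(default_factory=list)
    interfaces: List[dict] = field(default_factory=list)
    expansion_handles: Dict[str, dict] = field(default_factory=dict)
    params: Dict[str, object] = field(default_factory=dict)

    def realize(self, loop_mode: str = "break") -> BackboneModel:
        model = BackboneModel()
        for i, comp in enumerate(self.components):
            m = realize_block(comp.block, loop_mode=loop_mode).transformed(comp.frame)
            chain = m.chains[0]
            chain.chain_id = chain_id_for(i)
            model.chains.append(chain)
        model.meta["architecture"] = self.architecture
        model.meta["component_names"] = [c.name for c in self.components]
        return model

    def closure_cycles(self) -> List[Tuple[str, RigidTransform, int]]:
        """(name, step transform, multiplicity) for every closed cycle."""
        p = self.params
        arch = self.architecture
        if arch == "ring":
            spec: RingSpec = p["spec"]  # type: ignore[assignment]
            return [("ring", repeat_rigid_transform(spec.repeat_transform), spec.n)]
        if arch == "polygon":
            return [("polygon", _polygon_step(p["side_length"], p["corner_angle"]), p["n_sides"])]
        if arch == "strutted_rings":
            outer: RingSpec = p["outer"]  # type: ignore[assignment]
            inner: RingSpec = p["inner"]  # type: ignore[assignment]
            return [
                ("outer_ring", repeat_rigid_transform(outer.repeat_transform), outer.n),
                ("inner_ring", repeat_rigid_transform(inner.repeat_transform), inner.n),
            ]
        if arch.startswith("cage") or arch in ARCHITECTURES or arch == "O43":
            spec = p.get("ring")
            if spec is not None:
                return [("face_ring", repeat_rigid_transform(spec.repeat_transform), spec.n)]
        return []


# ---------------------------------------------------------------------------
# rings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingSpec:
    """A closed curve-THR ring with ``n`` repeats split into ``n/m`` chains.

    ``dtheta = 360/n`` exactly, so the ring closes perfectly; ``m`` repeats
    per chain with ``m | n`` gives cyclic symmetry ``C_{n/m}``.
    """

    n: int
    m: int
    unit: RepeatUnit
    d: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise AssemblyError("ring needs n >= 3 repeats")
        if self.m < 1 or self.n % self.m != 0:
            raise AssemblyError(f"m = {self.m} must divide n = {self.n}")

    @property
    def dtheta(self) -> float:
        return 360.0 / self.n

    @property
    def n_chains(self) -> int:
        return self.n // self.m

    @property
    def repeat_transform(self) -> RepeatTransform:
        return RepeatTransform(d=self.d, dh=0.0, dtheta=self.dtheta)

    @property
    def radius(self) -> float:
        """Anchor-circle radius d / (2 sin(180/n))."""
        return self.repeat_transform.curvature_radius

    def chain_block(self) -> THRBlock:
        return build_curve_thr(self.unit, self.d, self.dtheta, self.m, caps=(False, False))


def build_ring(spec: RingSpec) -> AssemblyBlueprint:
    """Closed ring of ``n`` repeats as ``n/m`` uncapped chains (C_{n/m}).

    The ring is centered on the z axis: the screw-rotation center of the
    repeat transform is translated to the origin, then chains are generated
    by C_{n/m} rotations.
    """
    block = spec.chain_block()
    center = np.array([0.0, math.copysign(spec.radius, spec.dtheta), 0.0])
    recenter = RigidTransform.from_translation(-center)
    bp = AssemblyBlueprint("ring", params={"spec": spec})
    for k in range(spec.n_chains):
        rot = RigidTransform.from_rotation_about([0, 0, 1], [0, 0, 0], k * spec.m * spec.dtheta)
        bp.components.append(PlacedComponent(f"chain{k}", block, rot @ recenter))
    bp.interfaces = [
        {"type": "uncapped_stack", "between": (f"chain{k}", f"chain{(k + 1) % spec.n_chains}")}
        for k in range(spec.n_chains)
    ]
    return bp


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------


def _polygon_step(side_length: float, corner_angle: float) -> RigidTransform:
    """Transform carrying one polygon side frame to the next: advance by the
    side length along local +x, then turn by the corner angle about the
    new vertex."""
    advance = RigidTransform.from_translation([side_length, 0.0, 0.0])
    turn = RigidTransform.from_rotation_about(
        [0, 0, 1], [side_length, 0.0, 0.0], corner_angle
    )
    return turn @ advance


def build_polygon(
    n_sides: int, edge: THRBlock, corner: THRBlock
) -> AssemblyBlueprint:
    """Closed polygon: straight edges joined by turn-module corners.

    The corner's turn angle must equal 360/n_sides; otherwise the polygon
    cannot close and a :class:`ClosureError` reporting the gap transform is
    raised.  Expanding the edges changes the side length by ``k * d`` per
    ``k`` inserted repeats while the corner geometry is untouched.
    """
    if n_sides < 3:
        raise AssemblyError("polygon needs >= 3 sides")
    if edge.block_class != "linear":
        raise AssemblyError("polygon edges must be linear blocks")
    if corner.block_class != "turn":
        raise AssemblyError("polygon corners must be turn modules")
    tau = corner.turn_angle
    d = edge.transform.d
    dc = corner.transform.d
    # side = edge repeats at spacing d, one d of clearance on each side of
    # the edge run, plus the corner module's own a0->c0 span
    side = (edge.n_repeats + 1) * d + dc
    gap = compose_n(_polygon_step(side, tau), n_sides)
    if not gap.is_identity(atol=1e-6):
        raise ClosureError(
            f"corner angle {tau:.6g} deg does not close an {n_sides}-gon "
            f"(gap rotation {gap.rotation_angle:.6g} deg)",
            gap,
        )
    apothem = side / (2.0 * math.tan(math.pi / n_sides))
    v0 = np.array([-side / 2.0, -apothem, 0.0])
    v1 = np.array([+side / 2.0, -apothem, 0.0])
    edge_frame0 = RigidTransform.from_translation(v0 + np.array([d, 0.0, 0.0]))
    corner_frame0 = RigidTransform.from_translation(v1 - np.array([dc, 0.0, 0.0]))
    bp = AssemblyBlueprint(
        "polygon",
        params={
            "n_sides": n_sides,
            "edge": edge,
            "corner": corner,
            "side_length": side,
            "corner_angle": tau,
        },
    )
    for k in range(n_sides):
        rot = RigidTransform.from_rotation_about([0, 0, 1], [0, 0, 0], k * 360.0 / n_sides)
        bp.components.append(PlacedComponent(f"edge{k}", edge, rot @ edge_frame0))
        bp.components.append(PlacedComponent(f"corner{k}", corner, rot @ corner_frame0))
    bp.interfaces = [
        {"type": "corner_fusion", "between": (f"edge{k}", f"corner{k}")} for k in range(n_sides)
    ]
    bp.expansion_handles["edge"] = {
        "criterion": "normal_to_axis",
        "symmetry_axis": (0.0, 0.0, 1.0),
        "propagation": (1.0, 0.0, 0.0),
        "param": "edge_repeats",
    }
    return bp


# ---------------------------------------------------------------------------
# strutted concentric rings
# ---------------------------------------------------------------------------


class StrutCompatibility(NamedTuple):
    g: int
    r_a: int
    r_b: int

    @property
    def rotation_per_subunit(self) -> float:
        return 360.0 / self.g


def strut_compatibility(n_a: int, n_b: int) -> StrutCompatibility:
    """Concentric-nesting arithmetic for two ring repeat counts.

    ``g = gcd(n_a, n_b)`` copies of a composite subunit made of
    ``r_a = n_a/g`` repeats of ring a fused to ``r_b = n_b/g`` repeats of
    ring b close both rings simultaneously; each subunit advances both
    rings by the same ``360/g`` degrees.
    """
    if n_a < 3 or n_b < 3:
        raise AssemblyError("ring repeat counts must be >= 3")
    g = math.gcd(n_a, n_b)
    return StrutCompatibility(g, n_a // g, n_b // g)


def build_strutted_rings(
    outer: RingSpec,
    inner: RingSpec,
    strut: THRBlock,
    z_offset: float = 0.0,
    twist: float = 0.0,
    strut_start_radius: Optional[float] = None,
) -> AssemblyBlueprint:
    """Concentric rings joined by a radial linear-THR strut (C_g assembly).

    The two rings share the z axis; the inner ring may be rotated
    (``twist``) and shifted (``z_offset``) relative to the outer -- the two
    sampled placement degrees of freedom.  The strut propagates radially
    in the mid-annulus between the rings.
    """
    if strut.block_class != "linear":
        raise AssemblyError("strut must be a linear block")
    comp = strut_compatibility(outer.n, inner.n)
    if comp.g < 3:
        raise AssemblyError(
            f"rings with {outer.n} and {inner.n} repeats share gcd {comp.g} < 3; "
            "not concentrically compatible"
        )
    if outer.m != comp.r_a or inner.m != comp.r_b:
        raise AssemblyError(
            f"ring splits must match compatibility: outer m = {comp.r_a}, inner m = {comp.r_b}"
        )
    bp = AssemblyBlueprint(
        "strutted_rings",
        params={
            "outer": outer,
            "inner": inner,
            "strut": strut,
            "z_offset": z_offset,
            "twist": twist,
            "compatibility": comp,
        },
    )
    out_center = np.array([0.0, outer.radius, 0.0])
    in_center = np.array([0.0, inner.radius, 0.0])
    inner_local = RigidTransform.from_rotation_about(
        [0, 0, 1], [0, 0, 0], twist
    ) @ RigidTransform.from_translation(-in_center + np.array([0.0, 0.0, z_offset]))
    outer_local = RigidTransform.from_translation(-out_center)
    # strut: propagation along the outward radial at the azimuth of the
    # asymmetric unit's mid-repeat; anchors at -90 deg + j * dtheta
    phi = -90.0 + (outer.m - 1) * outer.dtheta / 2.0
    extent = (strut.n_repeats - 1) * strut.transform.d + max(
        h.axis_xy[0] for h in strut.unit.helices
    )
    if strut_start_radius is None:
        # center the strut in the free annulus between the rings' helix edges
        lo = inner.radius + _ring_unit_halfwidth(inner.unit)
        hi = outer.radius - _ring_unit_halfwidth(outer.unit)
        strut_start_radius = (lo + hi) / 2.0 - extent / 2.0
    r_hat = np.array([math.cos(math.radians(phi)), math.sin(math.radians(phi)), 0.0])
    Rcol = np.column_stack([r_hat, np.cross([0, 0, 1.0], r_hat), [0, 0, 1.0]])
    strut_local = RigidTransform(Rcol, strut_start_radius * r_hat)
    for k in range(comp.g):
        rot = RigidTransform.from_rotation_about([0, 0, 1], [0, 0, 0], k * 360.0 / comp.g)
        bp.components.append(
            PlacedComponent(f"outer{k}", outer.chain_block(), rot @ outer_local)
        )
        bp.components.append(
            PlacedComponent(f"inner{k}", inner.chain_block(), rot @ inner_local)
        )
        bp.components.append(PlacedComponent(f"strut{k}", strut, rot @ strut_local))
        bp.interfaces.append({"type": "strut", "between": (f"outer{k}", f"inner{k}")})
    return bp


# ---------------------------------------------------------------------------
# polyhedral handshake cages
# ---------------------------------------------------------------------------


def _cage_edge_basis(a1: np.ndarray, a2: np.ndarray):
    """Basis of the face/edge geometry shared by the cage builders.

    Returns ``(e, d1, w, psi)``: the edge 2-fold direction ``e`` (bisector
    of the two face axes), the in-face radial ``d1`` from face-1 center
    toward the edge, the unit normal ``w`` of the plane spanned by the two
    axes, and ``psi`` the angle between ``a1`` and ``e`` in radians.
    """
    e = a1 + a2
    e = e / np.linalg.norm(e)
    d1 = e - (e @ a1) * a1
    d1 = d1 / np.linalg.norm(d1)
    w = np.cross(a1, e)
    w = w / np.linalg.norm(w)
    psi = math.acos(np.clip(a1 @ e, -1.0, 1.0))
    return e, d1, w, psi


def _frame_from_zx(zdir: np.ndarray, xdir: np.ndarray, origin: np.ndarray) -> RigidTransform:
    z = zdir / np.linalg.norm(zdir)
    x = xdir - (xdir @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return RigidTransform(np.column_stack([x, y, z]), np.asarray(origin, float))


def _ring_unit_halfwidth(unit: RepeatUnit) -> float:
    return max(abs(h.axis_xy[1]) for h in unit.helices)


def build_cage(
    architecture: str,
    ring: RingSpec,
    arm: THRBlock,
    arm_repeats: int,
    offset: float = 10.0,
    overlap: Optional[float] = None,
    arm_clearance: float = 9.0,
    ring_phase: float = 0.0,
) -> AssemblyBlueprint:
    """Polyhedral nanocage: flat rings on the face axes, linear arms
    projecting outward, C2 handshake dimers on every edge.

    Each face carries one ring (C3 split for T3/O3/I3, C4 for O4); every
    ring subunit is fused to a straight arm that runs parallel to an
    in-face radial vector but laterally offset by ``offset/2`` normal to
    the plane of the face axis and the edge 2-fold axis, so that the two
    arms meeting at an edge form an exact C2 dimer about the edge axis
    (which is a radial vector of the cage, and a group element -- the
    2-fold is exact by construction).  The face-center distance is solved
    so the terminal ``overlap`` of the two arms straddles the edge axis;
    growing the arm by k repeats therefore grows the ring-center-to-C2
    distance by exactly ``k * d`` without touching the interface.
    """
    if architecture not in ARCHITECTURES:
        raise AssemblyError(f"unknown cage architecture {architecture!r}")
    group, face_order = ARCHITECTURES[architecture]
    if ring.n_chains != face_order:
        raise AssemblyError(
            f"{architecture} needs a C{face_order} ring split; got C{ring.n_chains} "
            f"(n = {ring.n}, m = {ring.m})"
        )
    if arm.block_class != "linear":
        raise AssemblyError("cage arms must be linear blocks")
    if arm_repeats < 1:
        raise AssemblyError("arm_repeats must be >= 1")
    d_arm = arm.transform.d
    if overlap is None:
        overlap = 2.0 * d_arm
    fs = make_frames(group)
    faces = fs.face_axes[f"C{face_order}"]
    # reference face: the face axis nearest +z (on +z for the group's primary
    # face set; tilted for the cube faces of O, whose canonical z is a C3 axis)
    a1 = max(faces, key=lambda f: (round(f[2], 9), round(f[1], 9), round(f[0], 9)))
    # adjacent face: maximal dot product with a1 among the others
    others = [f for f in faces if not np.allclose(f, a1, atol=1e-9)]
    a2 = max(others, key=lambda f: (round(float(f @ a1), 9), round(f[0], 9), round(f[1], 9)))
    e, d1, w, psi = _cage_edge_basis(a1, a2)
    w_half = _ring_unit_halfwidth(ring.unit)
    r_attach = ring.radius + w_half + arm_clearance
    s_tip = r_attach + (arm_repeats - 1) * d_arm
    min_reach = ring.radius + w_half + 5.0 + overlap / 2.0
    if s_tip < min_reach:
        need = math.ceil((min_reach - r_attach) / d_arm) + 1
        raise AssemblyError(
            f"arm too short to reach the C2 position: need arm_repeats >= {need}"
        )
    f_dist = (s_tip - overlap / 2.0) / math.tan(psi)
    arm_block = replace(arm, n_repeats=arm_repeats)
    # asymmetric unit in the reference face's frame (ring plane normal to a1)
    ring_center = np.array([0.0, math.copysign(ring.radius, ring.dtheta), 0.0])
    ring_local = (
        RigidTransform.from_rotation_about([0, 0, 1], [0, 0, 0], ring_phase)
        @ RigidTransform.from_translation(-ring_center)
    )
    face_frame = _frame_from_zx(a1, d1, f_dist * a1)
    arm_origin = f_dist * a1 + (offset / 2.0) * w + r_attach * d1
    arm_frame = _frame_from_zx(a1, d1, arm_origin)
    chain_block = ring.chain_block()
    bp = AssemblyBlueprint(
        architecture,
        params={
            "builder": "cage",
            "architecture": architecture,
            "ring": ring,
            "arm": arm,
            "arm_repeats": arm_repeats,
            "offset": offset,
            "overlap": overlap,
            "arm_clearance": arm_clearance,
            "ring_phase": ring_phase,
            "face_distance": f_dist,
            "c2_distance": s_tip - overlap / 2.0,
            "handshake_angle": handshake_angle(architecture),
            "edge_axis_asym": tuple(float(x) for x in e),
            "face_axis": tuple(float(x) for x in a1),
            "asym_index": int(
                np.argmin([fr.rotation_angle for fr in fs.frames])
            ),
        },
    )
    for k, frame in enumerate(fs.frames):
        bp.components.append(
            PlacedComponent(f"ring{k}", chain_block, frame @ face_frame @ ring_local)
        )
        bp.components.append(PlacedComponent(f"arm{k}", arm_block, frame @ arm_frame))
    for ax in fs.edge_axes["C2"]:
        bp.interfaces.append(
            {
                "type": "handshake",
                "angle": handshake_angle(architecture),
                "edge_axis": tuple(float(x) for x in ax),
            }
        )
    bp.expansion_handles["arm"] = {
        "criterion": "parallel_to_axis_plane",
        "axis_a": tuple(float(x) for x in a1),
        "axis_b": tuple(float(x) for x in e),
        "propagation": tuple(float(x) for x in d1),
        "param": "arm_repeats",
    }
    return bp


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


def expand_assembly(bp: AssemblyBlueprint, handle: str, k_repeats: int) -> AssemblyBlueprint:
    """Re-blueprint with ``k_repeats`` extra repeats in a straight segment.

    The handle must satisfy the architecture's expandability criterion;
    interfaces of the expanded model superpose exactly onto the base
    model's because all inter-block geometry is repeat-periodic.
    """
    from .validation import check_expandable

    if k_repeats < 0:
        raise AssemblyError("k_repeats must be >= 0")
    rep = check_expandable(bp, handle)
    if not rep.summary:
        bad = [c.name for c in rep.checks if not c.passed]
        raise AssemblyError(f"handle {handle!r} violates expandability criterion: {bad}")
    if k_repeats == 0:
        return bp
    p = bp.params
    if bp.architecture == "polygon" and handle == "edge":
        return build_polygon(p["n_sides"], insert_repeats(p["edge"], k_repeats), p["corner"])
    if p.get("builder") == "cage" and handle == "arm":
        return build_cage(
            p["architecture"],
            p["ring"],
            p["arm"],
            p["arm_repeats"] + k_repeats,
            offset=p["offset"],
            overlap=p["overlap"],
            arm_clearance=p["arm_clearance"],
            ring_phase=p["ring_phase"],
        )
    if p.get("builder") == "o43" and handle == "arm":
        return build_o43_locked_component(
            p["ring"],
            p["arm"],
            p["arm_repeats"] + k_repeats,
            offset=p["offset"],
            tip_axis_distance=p["tip_axis_distance"],
            arm_clearance=p["arm_clearance"],
        )
    if bp.architecture == "track":
        if handle == "rail":
            return build_train_track(
                p["rail"], p["tie"], p["tie_spacing_repeats"] + k_repeats, p["n_cells"],
                rail_clearance=p["rail_clearance"], tie_z_gap=p["tie_z_gap"],
            )
        if handle == "tie":
            return build_train_track(
                p["rail"], insert_repeats(p["tie"], k_repeats), p["tie_spacing_repeats"],
                p["n_cells"], rail_clearance=p["rail_clearance"], tie_z_gap=p["tie_z_gap"],
            )
    raise AssemblyError(
        f"architecture {bp.architecture!r} has no expansion rule for handle {handle!r}"
    )


# ---------------------------------------------------------------------------
# two-component O43 docking
# ---------------------------------------------------------------------------


def build_o43_locked_component(
    ring: RingSpec,
    arm: THRBlock,
    arm_repeats: int,
    offset: float = 10.0,
    tip_axis_distance: float = 52.0,
    arm_clearance: float = 9.0,
) -> AssemblyBlueprint:
    """The rotation-locked trimer component of an O43 two-component cage.

    C3 rings with outward arms are placed on the eight octahedral C3 axes;
    each arm points toward an adjacent C4 axis, in the plane spanned by the
    C3 and C4 axes -- the expandability constraint that fixes (locks) the
    trimer's rotation about its own symmetry axis.  The face-center
    distance is solved so the arm tip sits at ``tip_axis_distance`` from
    the partner's C4 axis; growing the arm re-solves the distance with the
    tip-to-axis geometry unchanged, so a docked partner interface is
    preserved exactly under expansion (the partner slides out along its
    axis).
    """
    if ring.n_chains != 3:
        raise AssemblyError("O43 locked component needs a C3 ring split")
    if arm.block_class != "linear":
        raise AssemblyError("O43 arms must be linear blocks")
    d_arm = arm.transform.d
    fs = make_frames("O")
    # trimer on the C3 axis nearest +z in octahedral canonical orientation
    c3 = fs.face_axes["C3"]
    a1 = max(c3, key=lambda f: (round(f[2], 9), round(f[1], 9), round(f[0], 9)))
    c4 = fs.face_axes["C4"]
    a4 = max(c4, key=lambda f: (round(float(f @ a1), 9), round(f[0], 9), round(f[1], 9)))
    e, d1, w, psi = _cage_edge_basis(a1, a4)
    w_half = _ring_unit_halfwidth(ring.unit)
    r_attach = ring.radius + w_half + arm_clearance
    s_tip = r_attach + (arm_repeats - 1) * d_arm
    # solve f: |f*a1 + c0| perpendicular to the a4 axis == tip_axis_distance
    c0 = (offset / 2.0) * w + s_tip * d1
    cc = float(a1 @ a4)
    A = 1.0 - cc * cc
    B = 2.0 * (float(a1 @ c0) - cc * float(a4 @ c0))
    C = float(c0 @ c0) - float(a4 @ c0) ** 2 - tip_axis_distance**2
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        raise AssemblyError(
            "arm cannot reach the prescribed distance from the partner axis; "
            "increase arm_repeats or tip_axis_distance"
        )
    f_dist = (-B + math.sqrt(disc)) / (2.0 * A)
    if f_dist <= ring.radius:
        raise AssemblyError("arm too short: solved face distance collapses onto the ring")
    ring_center = np.array([0.0, math.copysign(ring.radius, ring.dtheta), 0.0])
    ring_local = RigidTransform.from_translation(-ring_center)
    lift = RigidTransform.from_translation(f_dist * a1)
    arm_origin = f_dist * a1 + (offset / 2.0) * w + r_attach * d1
    arm_frame = _frame_from_zx(a1, d1, arm_origin)
    arm_block = replace(arm, n_repeats=arm_repeats)
    chain_block = ring.chain_block()
    bp = AssemblyBlueprint(
        "O43",
        params={
            "builder": "o43",
            "ring": ring,
            "arm": arm,
            "arm_repeats": arm_repeats,
            "offset": offset,
            "tip_axis_distance": tip_axis_distance,
            "arm_clearance": arm_clearance,
            "trimer_axis": tuple(float(x) for x in a1),
            "partner_axis": tuple(float(x) for x in a4),
            "face_distance": f_dist,
            "tip_axial": float((f_dist * a1 + c0) @ a4),
            "trimer_rotation": 0.0,
        },
    )
    for k, frame in enumerate(fs.frames):
        bp.components.append(
            PlacedComponent(f"trimer_ring{k}", chain_block, frame @ lift @ ring_local)
        )
        bp.components.append(PlacedComponent(f"trimer_arm{k}", arm_block, frame @ arm_frame))
    bp.expansion_handles["arm"] = {
        "criterion": "parallel_to_axis_plane",
        "axis_a": tuple(float(x) for x in a1),
        "axis_b": tuple(float(x) for x in a4),
        "propagation": tuple(float(x) for x in d1),
        "param": "arm_repeats",
    }
    return bp


@dataclass(frozen=True)
class DockCandidate:
    partner_rotation: float
    partner_radius: float
    contacts: int
    trimer_rotation: float


def dock_two_component(
    locked: AssemblyBlueprint,
    partner: RingSpec,
    rotations: Sequence[float],
    radii: Sequence[float],
    architecture: str = "O43",
    contact_cutoff: float = 8.0,
    clash_cutoff: float = 3.5,
    seed: Optional[int] = None,
    subsample: Optional[int] = None,
) -> List[DockCandidate]:
    """Dock a free C4 partner against the rotation-locked trimer component.

    The locked component's rotation about its symmetry axis is never
    sampled (it is pinned by the expandability constraint); the partner's
    rotation about its C4 axis and its radial position run over the given
    deterministic grids.  Candidates are clash-free placements ranked by
    cross-component CA contact count.  ``seed``/``subsample`` optionally
    thin the grid reproducibly.
    """
    from .validation import detect_clashes

    if architecture != "O43":
        raise AssemblyError("only the O43 two-component architecture is supported")
    if locked.params.get("builder") != "o43":
        raise AssemblyError("locked component must come from build_o43_locked_component")
    if partner.n_chains != 4:
        raise AssemblyError("partner must have a C4 split")
    grid = [(float(rot), float(rad)) for rot in rotations for rad in radii]
    if subsample is not None and subsample < len(grid):
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(grid), size=subsample, replace=False).tolist())
        grid = [grid[i] for i in keep]
    locked_model = locked.realize()
    locked_ca = locked_model.ca_coords()
    fs = make_frames("O")
    c4 = fs.face_axes["C4"]
    partner_block = partner.chain_block()
    ring_center = np.array([0.0, math.copysign(partner.radius, partner.dtheta), 0.0])
    out: List[DockCandidate] = []
    from scipy.spatial import cKDTree

    tree = cKDTree(locked_ca)
    for rot, rad in grid:
        partner_model = BackboneModel()
        for ai, axis in enumerate(c4):
            base = _frame_from_zx(
                axis,
                _any_perpendicular(axis),
                rad * axis,
            )
            spin = RigidTransform.from_rotation_about(axis, rad * axis, rot)
            for kc in range(partner.n_chains):
                cyc = RigidTransform.from_rotation_about(
                    axis, rad * axis, kc * 360.0 / partner.n_chains
                )
                frame = cyc @ spin @ base @ RigidTransform.from_translation(-ring_center)
                m = realize_block(partner_block).transformed(frame)
                partner_model.chains.extend(m.chains)
        partner_model.reassign_chain_ids()
        pca = partner_model.ca_coords()
        dmin = tree.query(pca, k=1)[0]
        if float(dmin.min()) < clash_cutoff:
            continue
        contacts = int(sum(len(x) for x in tree.query_ball_point(pca, contact_cutoff)))
        if contacts == 0:
            continue
        out.append(
            DockCandidate(
                rot,
                rad,
                contacts,
                trimer_rotation=float(locked.params.get("trimer_rotation", 0.0)),
            )
        )
    out.sort(key=lambda c: (-c.contacts, c.partner_rotation, c.partner_radius))
    return out


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(v @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = ref - (ref @ v) * v
    return p / np.linalg.norm(p)


# ---------------------------------------------------------------------------
# train tracks
# ---------------------------------------------------------------------------


def build_train_track(
    rail: THRBlock,
    tie: THRBlock,
    tie_spacing_repeats: int,
    n_cells: int,
    rail_clearance: float = 9.0,
    tie_z_gap: float = 10.0,
) -> AssemblyBlueprint:
    """Finite model of the unbounded antiparallel train-track lattice.

    Two antiparallel uncapped rails propagate along x; C2 ties (an
    antiparallel pair of straight blocks related by a 2-fold about the rail
    axis) connect them every ``tie_spacing_repeats`` rail repeats.  Adding
    r repeats to the rail spacing grows the tie-to-tie distance by
    ``r * d_rail``; adding t repeats to each tie half grows the rail
    separation by ``t * d_tie``.  Successive unit cells are related by a
    pure translation (a 1D lattice).
    """
    if rail.block_class != "linear":
        raise AssemblyError("rails must be linear blocks")
    if rail.cap_n or rail.cap_c:
        raise AssemblyError("rails must be uncapped for end-to-end assembly")
    if tie.block_class != "linear":
        raise AssemblyError("ties must be linear blocks")
    if tie.cap_c:
        raise AssemblyError("tie lacks a C2 interface at its midpoint (cap_c must be False)")
    if tie_spacing_repeats < 1 or n_cells < 1:
        raise AssemblyError("tie_spacing_repeats and n_cells must be >= 1")
    d_rail = rail.transform.d
    d_tie = tie.transform.d
    cell = tie_spacing_repeats * d_rail
    tie_span = (tie.n_repeats - 1) * d_tie
    separation = tie_span + 2.0 * rail_clearance
    rail_block = replace(rail, n_repeats=tie_spacing_repeats * n_cells)
    bp = AssemblyBlueprint(
        "track",
        params={
            "rail": rail,
            "tie": tie,
            "tie_spacing_repeats": tie_spacing_repeats,
            "n_cells": n_cells,
            "rail_clearance": rail_clearance,
            "tie_z_gap": tie_z_gap,
            "cell_length": cell,
            "rail_separation": separation,
        },
    )
    # rail A along +x at y = +separation/2; rail B is its C2 image about the
    # x axis through the origin (antiparallel, helices flipped)
    frame_a = RigidTransform.from_translation([0.0, separation / 2.0, 0.0])
    c2 = RigidTransform.from_rotation_about([1, 0, 0], [0, 0, 0], 180.0)
    bp.components.append(PlacedComponent("railA", rail_block, frame_a))
    bp.components.append(PlacedComponent("railB", rail_block, c2 @ frame_a))
    # ties: each a C2 pair of straight blocks spanning the rail gap,
    # propagating -y, offset along z on either side of the C2 axis
    y_top = separation / 2.0 - rail_clearance
    down = RigidTransform(
        np.column_stack([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
        np.zeros(3),
    )
    for k in range(n_cells):
        x_k = k * cell
        t_frame = RigidTransform.from_translation([x_k, y_top, tie_z_gap / 2.0]) @ down
        bp.components.append(PlacedComponent(f"tie{k}a", tie, t_frame))
        bp.components.append(PlacedComponent(f"tie{k}b", tie, c2 @ t_frame))
        bp.interfaces.append({"type": "branch", "rail": "railA", "tie": f"tie{k}a", "x": x_k})
        bp.interfaces.append({"type": "branch", "rail": "railB", "tie": f"tie{k}b", "x": x_k})
    bp.expansion_handles["rail"] = {
        "criterion": "parallel_to_extension_axis",
        "extension_axis": (1.0, 0.0, 0.0),
        "propagation": (1.0, 0.0, 0.0),
        "param": "tie_spacing_repeats",
    }
    bp.expansion_handles["tie"] = {
        "criterion": "parallel_to_extension_axis",
        "extension_axis": (0.0, 1.0, 0.0),
        "propagation": (0.0, -1.0, 0.0),
        "param": "tie_repeats",
    }
    return bp
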