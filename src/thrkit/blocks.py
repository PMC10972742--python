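"""THR building blocks: linear, stair-stepping, curve and turn modules.

A block is a repeat unit of 1-4 parallel ideal helices plus a repeat
transform and a repeat count.  Block classes:

* ``linear`` -- dtheta = 0, dh = 0: successive repeats are pure in-plane
  translations; the block is perfectly straight.
* ``stair``  -- dtheta = 0, dh != 0: straight but stepping along z.
* ``curve``  -- dtheta != 0: repeats trace an in-plane arc of radius
  ``d / (2 sin(|dtheta|/2))``; choosing dtheta = 360/n closes an n-ring.
* ``turn``   -- an extra corner helix, collinear with the propagation line
  of the flanking repeats, redirects propagation by the phase difference
  ``theta_c - theta_a``.

Capping is metadata only: a capped end would carry polar outward-facing
residues at the sequence level, but the backbone of a terminal repeat is
identical to an internal one either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import (
    GeometryError,
    HelixCoords,
    HelixSpec,
    RepeatTransform,
    RigidTransform,
    compose_n,
    make_ideal_helix,
    repeat_rigid_transform,
    wrap_angle,
)
from .model import BackboneModel, Chain, Segment

__all__ = [
    "RepeatUnit",
    "THRBlock",
    "build_linear_thr",
    "build_curve_thr",
    "build_turn_module",
    "realize_block",
    "insert_repeats",
]

#: Residues used for placeholder loops between consecutive helices.
LOOP_RES = 3
#: Placeholder loops spanning more than this are flagged as unrealistic.
LOOP_SPAN_WARN = 12.0


class BlockError(GeometryError):
    pass


@dataclass(frozen=True)
class RepeatUnit:
    """1-4 helices forming one repeat, in N->C traversal order.

    Physically traversable chains alternate helix direction (up/down);
    :attr:`is_traversable` reports whether this unit does.
    """

    helices: Tuple[HelixSpec, ...]

    def __post_init__(self) -> None:
        hs = tuple(self.helices)
        if not 1 <= len(hs) <= 4:
            raise BlockError("repeat unit must contain 1-4 helices")
        names = [h.name for h in hs if h.name]
        if len(names) != len(set(names)):
            raise BlockError("helix names within a unit must be unique")
        object.__setattr__(self, "helices", hs)

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    @property
    def is_traversable(self) -> bool:
        flips = [h.flipped for h in self.helices]
        return all(a != b for a, b in zip(flips, flips[1:]))

    def realize(self) -> List[HelixCoords]:
        return [make_ideal_helix(h) for h in self.helices]

    def helix_named(self, name: str) -> HelixSpec:
        for h in self.helices:
            if h.name == name:
                return h
        raise BlockError(f"unit has no helix named {name!r}")


@dataclass(frozen=True)
class THRBlock:
    """A repeat unit propagated ``n_repeats`` times by its repeat transform."""

    unit: RepeatUnit
    transform: RepeatTransform
    n_repeats: int
    block_class: str
    cap_n: bool = True
    cap_c: bool = True
    turn_theta_a: Optional[float] = None
    turn_phase_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise BlockError("n_repeats must be >= 1")
        cls = self.block_class
        rt = self.transform
        if cls == "linear" and not (rt.dtheta == 0.0 and rt.dh == 0.0):
            raise BlockError("linear block requires dtheta = 0 and dh = 0")
        if cls == "stair" and not (rt.dtheta == 0.0 and rt.dh != 0.0):
            raise BlockError("stair block requires dtheta = 0 and dh != 0")
        if cls == "curve" and rt.dtheta == 0.0:
            raise BlockError("curve block requires dtheta != 0")
        if cls == "turn" and (self.turn_theta_a is None or self.turn_phase_c is None):
            raise BlockError("turn block requires theta_a and theta_c")
        if cls not in ("linear", "stair", "curve", "turn"):
            raise BlockError(f"unknown block class {cls!r}")

    @property
    def rigid(self) -> RigidTransform:
        return repeat_rigid_transform(self.transform)

    @property
    def turn_angle(self) -> float:
        """Propagation direction change of a turn module, in (-180, 180]."""
        if self.block_class != "turn":
            raise BlockError("turn_angle is defined for turn modules only")
        return wrap_angle(self.turn_phase_c - self.turn_theta_a)

    def anchors(self) -> np.ndarray:
        """Reference-helix axis positions of every repeat, shape (n, 3)."""
        a0 = self.unit.helices[0]
        p0 = np.array([a0.axis_xy[0], a0.axis_xy[1], a0.z_start])
        step = self.rigid
        out = np.empty((self.n_repeats, 3))
        cur = RigidTransform.identity()
        for i in range(self.n_repeats):
            out[i] = cur.apply(p0)
            cur = step @ cur
        return out

    def propagation_direction(self) -> np.ndarray:
        """Unit direction of repeat propagation (first-to-second anchor).

        For straight blocks with dh = 0 this is +x by convention; stair
        blocks tilt out of plane; single-repeat blocks return the transform
        applied to the anchor.
        """
        step = self.rigid
        a0 = self.unit.helices[0]
        p0 = np.array([a0.axis_xy[0], a0.axis_xy[1], a0.z_start])
        v = step.apply(p0) - p0
        n = np.linalg.norm(v)
        if n == 0.0:
            raise BlockError("degenerate repeat transform")
        return v / n


def build_linear_thr(
    unit: RepeatUnit,
    d: float,
    dh: float = 0.0,
    n_repeats: int = 1,
    caps: Tuple[bool, bool] = (True, True),
) -> THRBlock:
    """Straight THR: dtheta = 0; pure translation (d, 0, dh) per repeat."""
    rt = RepeatTransform(d=d, dh=dh, dtheta=0.0)
    cls = "stair" if dh != 0.0 else "linear"
    return THRBlock(unit, rt, n_repeats, cls, cap_n=caps[0], cap_c=caps[1])


def build_curve_thr(
    unit: RepeatUnit,
    d: float,
    dtheta: float,
    n_repeats: int = 1,
    caps: Tuple[bool, bool] = (True, True),
) -> THRBlock:
    """Curved THR: nonzero phase change per repeat bends the trajectory
    in-plane onto a circle of radius ``d / (2 sin(|dtheta|/2))``."""
    if dtheta == 0.0:
        raise BlockError("dtheta = 0 is a linear block; use build_linear_thr")
    rt = RepeatTransform(d=d, dh=0.0, dtheta=dtheta)
    return THRBlock(unit, rt, n_repeats, "curve", cap_n=caps[0], cap_c=caps[1])


def build_turn_module(
    unit: RepeatUnit, theta_a: float, theta_c: float, d: Optional[float] = None
) -> THRBlock:
    """Turn module: corner helix c0 on the a0->a1 propagation line.

    The two outgoing propagation directions of the corner differ by
    ``theta_c - theta_a``.  The unit must contain helices named ``a0`` and
    ``c0`` with ``c0`` collinear with the +x propagation line through
    ``a0``; their phases are overwritten with ``theta_a`` / ``theta_c``.
    """
    a0 = unit.helix_named("a0")
    c0 = unit.helix_named("c0")
    if abs(c0.axis_xy[1] - a0.axis_xy[1]) > 1e-9:
        raise BlockError("corner helix c0 must lie on the a0->a1 propagation line")
    if d is None:
        d = abs(c0.axis_xy[0] - a0.axis_xy[0])
        if d == 0.0:
            raise BlockError("c0 must be displaced from a0 along the propagation line")
    new_helices = []
    for h in unit.helices:
        if h.name == "a0":
            new_helices.append(h.with_phase(theta_a))
        elif h.name == "c0":
            new_helices.append(h.with_phase(theta_c))
        else:
            new_helices.append(h)
    return THRBlock(
        RepeatUnit(tuple(new_helices)),
        RepeatTransform(d=d, dh=0.0, dtheta=0.0),
        n_repeats=1,
        block_class="turn",
        turn_theta_a=float(theta_a),
        turn_phase_c=float(theta_c),
    )


def _placeholder_loop(end_xyz: np.ndarray, start_xyz: np.ndarray) -> Segment:
    """Flagged 3-residue straight-line placeholder between two helix ends.

    Loop conformations are sequence-level design and out of scope; the
    placeholder only records connectivity and is labelled as such.
    """
    span = float(np.linalg.norm(start_xyz[0] - end_xyz[-1]))
    frac = np.linspace(0.0, 1.0, LOOP_RES + 2)[1:-1]
    coords = np.empty((LOOP_RES, 4, 3))
    for j, f in enumerate(frac):
        pos = end_xyz[-1] + f * (start_xyz[0] - end_xyz[-1])
        # degenerate backbone: all four atoms collapsed on the line, spread
        # slightly along it so records remain distinct
        for k in range(4):
            coords[j, k] = pos + (k - 1.5) * 0.05 * (start_xyz[0] - end_xyz[-1]) / max(span, 1e-9)
    flags = {"placeholder": True}
    if span > LOOP_SPAN_WARN:
        flags["long_loop"] = True
    return Segment(coords, helix="loop", kind="loop", flags=flags)


def realize_block(block: THRBlock, loop_mode: str = "break") -> BackboneModel:
    """Full backbone for ``n_repeats`` copies of the unit.

    ``loop_mode``: ``"break"`` omits loops (chain breaks between helices);
    ``"placeholder"`` inserts flagged 3-residue straight-line loops.
    """
    if loop_mode not in ("break", "placeholder"):
        raise BlockError(f"unknown loop_mode {loop_mode!r}")
    step = block.rigid
    base = block.unit.realize()
    chain = Chain("A")
    prev_end: Optional[np.ndarray] = None
    cur = RigidTransform.identity()
    for i in range(block.n_repeats):
        for h_idx, (spec, coords) in enumerate(zip(block.unit.helices, base)):
            placed = coords.transformed(cur)
            if loop_mode == "placeholder" and prev_end is not None:
                chain.segments.append(_placeholder_loop(prev_end, placed.coords[0]))
            name = spec.name or f"h{h_idx}"
            chain.segments.append(
                Segment(placed.coords.copy(), helix=name, repeat=i, kind="helix")
            )
            prev_end = placed.coords[-1]
        cur = step @ cur
    model = BackboneModel([chain])
    model.meta["block_class"] = block.block_class
    model.meta["caps"] = (block.cap_n, block.cap_c)
    return model


def insert_repeats(block: THRBlock, k: int) -> THRBlock:
    """Grow a straight block by ``k`` repeats.

    Only linear/stair blocks are expandable this way (rings are resized by
    choosing a different n); the expanded block's first/last repeats
    superpose exactly onto the original's after a ``k * d`` translation
    along the propagation axis.
    """
    if block.block_class not in ("linear", "stair"):
        raise BlockError("insert_repeats applies to linear or stair blocks only")
    if k < 0:
        raise BlockError("k must be >= 0")
    return replace(block, n_repeats=block.n_repeats + k)
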