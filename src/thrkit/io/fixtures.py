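"""Deterministic demo blueprints for each architecture class.

The registry reproduces the architecture class and stated repeat counts /
splits / angles of named published designs (R12B, strut_C10_8, cage_T3_101,
...).  Intra-repeat helix placements are this package's own: chosen so all
helix-axis separations stay at comfortable packing distances (>= ~8.6 A,
i.e. CA clearance above the 3.5 A clash cutoff) for every fixture.  They
make no claim of atom-level identity to any deposited model.

Unit factories double as the package's standard repeat units:

* ``two_helix_unit``      -- zigzag 2-helix unit for linear/stair blocks;
* ``four_helix_ring_unit``-- 2x2 staggered unit for circular rings (four
  helices per repeat, radial half-width ``w``);
* ``turn_unit``           -- a0/b0/c0 corner unit for turn modules.
"""

from __future__ import annotations

from typing import Callable, Dict, List

from ..blocks import RepeatUnit
from ..geometry import HelixSpec
from .blueprint import (
    BlueprintFile,
    BlockModel,
    CageAssembly,
    O43Assembly,
    PolygonAssembly,
    RingAssembly,
    RingParams,
    StrutAssembly,
    TrackAssembly,
    UnitModel,
)

__all__ = [
    "two_helix_unit",
    "four_helix_ring_unit",
    "turn_unit",
    "make_fixture",
    "fixture_names",
]

HELIX_LEN = 20  # residues; 28.5 A tall at 1.5 A rise


def two_helix_unit(d: float = 10.0, offy: float = -8.0, n_res: int = HELIX_LEN) -> RepeatUnit:
    """Zigzag two-helix repeat: a0 on the propagation line, b0 flanking.

    ``offy`` is the flank offset perpendicular to propagation; its sign
    picks which side the flank row packs on (e.g. outward-facing for
    polygon edges and rails).
    """
    return RepeatUnit(
        (
            HelixSpec(n_res, 0.0, (0.0, 0.0), 0.0, False, "a0"),
            HelixSpec(n_res, 0.0, (d / 2.0, offy), 0.0, True, "b0"),
        )
    )


def four_helix_ring_unit(d: float = 20.0, w: float = 4.5, n_res: int = HELIX_LEN) -> RepeatUnit:
    """Four helices per repeat for circular rings: two staggered radial
    columns; local +y points toward the ring center (|y| = w is the radial
    half-width)."""
    return RepeatUnit(
        (
            HelixSpec(n_res, 0.0, (0.0, -w), 0.0, False, "a0"),
            HelixSpec(n_res, 0.0, (0.0, +w), 0.0, True, "b0"),
            HelixSpec(n_res, 0.0, (d / 2.0, +w), 0.0, False, "b1"),
            HelixSpec(n_res, 0.0, (d / 2.0, -w), 0.0, True, "b2"),
        )
    )


def turn_unit(d: float = 10.0, offy: float = -8.0, n_res: int = HELIX_LEN) -> RepeatUnit:
    """Corner unit: a0 and c0 on the propagation line, b0 flanking outside."""
    return RepeatUnit(
        (
            HelixSpec(n_res, 0.0, (0.0, 0.0), 0.0, False, "a0"),
            HelixSpec(n_res, 0.0, (d / 2.0, offy), 0.0, True, "b0"),
            HelixSpec(n_res, 0.0, (d, 0.0), 0.0, False, "c0"),
        )
    )


def _unit(u: RepeatUnit) -> UnitModel:
    return UnitModel.from_unit(u)


def _linear_block(d=10.0, dh=0.0, n_repeats=4, caps=(True, True), offy=-8.0) -> BlockModel:
    return BlockModel(
        block_class="stair" if dh else "linear",
        unit=_unit(two_helix_unit(d, offy)),
        d=d, dh=dh, n_repeats=n_repeats, cap_n=caps[0], cap_c=caps[1],
    )


def _turn_block(theta_c: float) -> BlockModel:
    return BlockModel(
        block_class="turn", unit=_unit(turn_unit()), d=10.0,
        theta_a=0.0, theta_c=theta_c,
    )


def _ring(n: int, m: int, d: float = 20.0) -> RingParams:
    return RingParams(n=n, m=m, unit=_unit(four_helix_ring_unit(d)), d=d)


def _bf(**kw) -> BlueprintFile:
    return BlueprintFile(**kw)


def _linear_thr(name: str, d: float = 10.0, dh: float = 0.0, n_repeats: int = 6) -> BlueprintFile:
    return _bf(blocks={name: _linear_block(d=d, dh=dh, n_repeats=n_repeats)})


def _ring_fixture(n: int, m: int) -> BlueprintFile:
    return _bf(assemblies={"ring": RingAssembly(ring=_ring(n, m))})


def _polygon_fixture(n_sides: int, edge_repeats: int = 3) -> BlueprintFile:
    return _bf(
        blocks={
            "edge": _linear_block(n_repeats=edge_repeats),
            "corner": _turn_block(360.0 / n_sides),
        },
        assemblies={
            "polygon": PolygonAssembly(n_sides=n_sides, edge="edge", corner="corner")
        },
    )


def _strut_fixture(n_outer: int, m_outer: int, n_inner: int, m_inner: int) -> BlueprintFile:
    return _bf(
        blocks={"strut": _linear_block(n_repeats=2)},
        assemblies={
            "strut": StrutAssembly(
                outer=_ring(n_outer, m_outer, 22.0),
                inner=_ring(n_inner, m_inner, 19.0),
                strut="strut",
            )
        },
    )


def _cage_fixture(architecture: str, extra_arm_repeats: int = 0) -> BlueprintFile:
    m = 3 if architecture == "O4" else 4  # C4 split for O4, C3 otherwise
    # arm flank faces away from the C2 dimer midplane (offy > 0)
    return _bf(
        blocks={"arm": _linear_block(n_repeats=3, offy=8.0)},
        assemblies={
            "cage": CageAssembly(
                architecture=architecture, ring=_ring(12, m), arm="arm",
                arm_repeats=3 + extra_arm_repeats,
            )
        },
    )


def _o43_fixture(extra_arm_repeats: int = 0) -> BlueprintFile:
    return _bf(
        blocks={"arm": _linear_block(n_repeats=3, offy=8.0)},
        assemblies={
            "cage": O43Assembly(
                ring=_ring(12, 4), arm="arm", arm_repeats=3 + extra_arm_repeats
            )
        },
    )


def _track_fixture(spacing: int = 6, tie_repeats: int = 4) -> BlueprintFile:
    return _bf(
        blocks={
            "rail": _linear_block(n_repeats=1, caps=(False, False), offy=8.0),
            "tie": BlockModel(
                block_class="linear", unit=_unit(two_helix_unit()), d=10.0,
                n_repeats=tie_repeats, cap_n=True, cap_c=False,
            ),
        },
        assemblies={
            "track": TrackAssembly(rail="rail", tie="tie", tie_spacing_repeats=spacing)
        },
    )


_REGISTRY: Dict[str, Callable[[], BlueprintFile]] = {
    # straight blocks (crystallographically characterized classes)
    "THR1": lambda: _linear_thr("THR1", d=10.0),
    "THR3": lambda: _linear_thr("THR3", d=8.7),
    "THR4": lambda: _linear_thr("THR4", d=10.0, dh=3.0),
    # closed rings and their cyclic splits
    "R12B": lambda: _ring_fixture(12, 3),   # 12 repeats tested as C4
    "R18A": lambda: _ring_fixture(18, 3),   # C6
    "R20A": lambda: _ring_fixture(20, 5),   # C4
    "R30A": lambda: _ring_fixture(30, 5),   # C6
    # polygons from turn modules
    "120_C3_A": lambda: _polygon_fixture(3),
    "90_C4_B": lambda: _polygon_fixture(4),
    "sC4": lambda: _polygon_fixture(4),
    "sC4_+6": lambda: _polygon_fixture(4, edge_repeats=6),  # +6 helices/chain
    # strutted concentric rings
    "strut_C10_8": lambda: _strut_fixture(30, 3, 20, 2),
    "strut_C10": lambda: _strut_fixture(30, 3, 20, 2),
    "strut_C6_21": lambda: _strut_fixture(30, 5, 18, 3),
    # handshake nanocages (expansion variants count added helices)
    "cage_T3_101": lambda: _cage_fixture("T3"),
    "cage_O3_20": lambda: _cage_fixture("O3"),
    "cage_I3_8": lambda: _cage_fixture("I3"),
    "cage_O4_34": lambda: _cage_fixture("O4"),
    "cage_O4_34_+4": lambda: _cage_fixture("O4", 2),
    "cage_O4_34_+8": lambda: _cage_fixture("O4", 4),
    "cage_O4_34_+12": lambda: _cage_fixture("O4", 6),
    # two-component O43 locked trimer component
    "cage_O43_129": lambda: _o43_fixture(),
    "cage_O43_129_+4": lambda: _o43_fixture(2),
    # train tracks: base, doubled tie spacing, lengthened ties, both
    "track": lambda: _track_fixture(),
    "track_long": lambda: _track_fixture(spacing=12),
    "track_wide": lambda: _track_fixture(tie_repeats=8),
    "track_wide_long": lambda: _track_fixture(spacing=12, tie_repeats=8),
}


def fixture_names() -> List[str]:
    return sorted(_REGISTRY)


def make_fixture(name: str) -> BlueprintFile:
    """Blueprint for a named demo architecture (deterministic)."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    return _REGISTRY[name]()
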