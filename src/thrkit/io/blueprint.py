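"""Blueprint file schema (JSON) and conversion to domain objects.

A blueprint file declares blocks (repeat units + repeat parameters) and
assemblies (architecture + references to blocks).  The schema is strict:
unknown keys are rejected, units are declared explicitly in a header
(Angstrom / degrees) to prevent silent misreads, and read/write round-trips
are identical.
"""

from __future__ import annotations

import json
from typing import Dict, List, Literal, Optional, Tuple, Union

from pydantic import BaseModel, ConfigDict, Field

from ..assemblies import (
    AssemblyBlueprint,
    RingSpec,
    build_cage,
    build_o43_locked_component,
    build_polygon,
    build_ring,
    build_strutted_rings,
    build_train_track,
)
from ..blocks import (
    RepeatUnit,
    THRBlock,
    build_curve_thr,
    build_linear_thr,
    build_turn_module,
)
from ..geometry import HelixSpec

SCHEMA_VERSION = "1.0"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class UnitsDecl(_Strict):
    length: Literal["angstrom"] = "angstrom"
    angle: Literal["degrees"] = "degrees"


class HelixModel(_Strict):
    n_res: int
    phase: float = 0.0
    axis_xy: Tuple[float, float] = (0.0, 0.0)
    z_start: float = 0.0
    flipped: bool = False
    name: str = ""

    def to_spec(self) -> HelixSpec:
        return HelixSpec(**self.model_dump())

    @classmethod
    def from_spec(cls, h: HelixSpec) -> "HelixModel":
        return cls(
            n_res=h.n_res, phase=h.phase, axis_xy=h.axis_xy,
            z_start=h.z_start, flipped=h.flipped, name=h.name,
        )


class UnitModel(_Strict):
    helices: List[HelixModel]

    def to_unit(self) -> RepeatUnit:
        return RepeatUnit(tuple(h.to_spec() for h in self.helices))

    @classmethod
    def from_unit(cls, u: RepeatUnit) -> "UnitModel":
        return cls(helices=[HelixModel.from_spec(h) for h in u.helices])


class BlockModel(_Strict):
    block_class: Literal["linear", "stair", "curve", "turn"]
    unit: UnitModel
    d: float
    dh: float = 0.0
    dtheta: float = 0.0
    n_repeats: int = 1
    cap_n: bool = True
    cap_c: bool = True
    theta_a: Optional[float] = None
    theta_c: Optional[float] = None

    def to_block(self) -> THRBlock:
        unit = self.unit.to_unit()
        caps = (self.cap_n, self.cap_c)
        if self.block_class in ("linear", "stair"):
            return build_linear_thr(unit, self.d, self.dh, self.n_repeats, caps)
        if self.block_class == "curve":
            return build_curve_thr(unit, self.d, self.dtheta, self.n_repeats, caps)
        if self.theta_a is None or self.theta_c is None:
            raise ValueError("turn block requires theta_a and theta_c")
        return build_turn_module(unit, self.theta_a, self.theta_c)

    @classmethod
    def from_block(cls, b: THRBlock) -> "BlockModel":
        return cls(
            block_class=b.block_class,
            unit=UnitModel.from_unit(b.unit),
            d=b.transform.d,
            dh=b.transform.dh,
            dtheta=b.transform.dtheta,
            n_repeats=b.n_repeats,
            cap_n=b.cap_n,
            cap_c=b.cap_c,
            theta_a=b.turn_theta_a,
            theta_c=b.turn_phase_c,
        )


class RingParams(_Strict):
    n: int
    m: int
    unit: UnitModel
    d: float

    def to_spec(self) -> RingSpec:
        return RingSpec(self.n, self.m, self.unit.to_unit(), self.d)


class RingAssembly(_Strict):
    architecture: Literal["ring"] = "ring"
    ring: RingParams


class PolygonAssembly(_Strict):
    architecture: Literal["polygon"] = "polygon"
    n_sides: int
    edge: str
    corner: str


class StrutAssembly(_Strict):
    architecture: Literal["strutted_rings"] = "strutted_rings"
    outer: RingParams
    inner: RingParams
    strut: str
    z_offset: float = 0.0
    twist: float = 0.0


class CageAssembly(_Strict):
    architecture: Literal["T3", "O3", "I3", "O4"]
    ring: RingParams
    arm: str
    arm_repeats: int
    offset: float = 10.0
    overlap: Optional[float] = None
    arm_clearance: float = 9.0
    ring_phase: float = 0.0


class O43Assembly(_Strict):
    architecture: Literal["O43"] = "O43"
    ring: RingParams
    arm: str
    arm_repeats: int
    offset: float = 10.0
    tip_axis_distance: float = 52.0
    arm_clearance: float = 9.0


class TrackAssembly(_Strict):
    architecture: Literal["track"] = "track"
    rail: str
    tie: str
    tie_spacing_repeats: int
    n_cells: int = 2
    rail_clearance: float = 9.0
    tie_z_gap: float = 10.0


AssemblyModel = Union[
    RingAssembly, PolygonAssembly, StrutAssembly, CageAssembly, O43Assembly, TrackAssembly
]


class BlueprintFile(_Strict):
    version: str = SCHEMA_VERSION
    units: UnitsDecl = Field(default_factory=UnitsDecl)
    seed: Optional[int] = None
    tolerances: Dict[str, float] = Field(default_factory=dict)
    blocks: Dict[str, BlockModel] = Field(default_factory=dict)
    assemblies: Dict[str, AssemblyModel] = Field(default_factory=dict)


def load_blueprint(path: str) -> BlueprintFile:
    with open(path) as fh:
        return BlueprintFile.model_validate_json(fh.read())


def save_blueprint(bf: BlueprintFile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(bf.model_dump_json(indent=2))
        fh.write("\n")


def blueprint_blocks(bf: BlueprintFile) -> Dict[str, THRBlock]:
    return {name: bm.to_block() for name, bm in bf.blocks.items()}


def build_assembly(bf: BlueprintFile, name: Optional[str] = None) -> AssemblyBlueprint:
    """Instantiate a declared assembly as an AssemblyBlueprint."""
    if not bf.assemblies:
        raise ValueError("blueprint declares no assemblies")
    if name is None:
        name = next(iter(bf.assemblies))
    if name not in bf.assemblies:
        raise ValueError(f"no assembly {name!r}; available: {sorted(bf.assemblies)}")
    am = bf.assemblies[name]
    blocks = blueprint_blocks(bf)

    def ref(key: str) -> THRBlock:
        if key not in blocks:
            raise ValueError(f"assembly {name!r} references unknown block {key!r}")
        return blocks[key]

    if isinstance(am, RingAssembly):
        return build_ring(am.ring.to_spec())
    if isinstance(am, PolygonAssembly):
        return build_polygon(am.n_sides, ref(am.edge), ref(am.corner))
    if isinstance(am, StrutAssembly):
        return build_strutted_rings(
            am.outer.to_spec(), am.inner.to_spec(), ref(am.strut), am.z_offset, am.twist
        )
    if isinstance(am, CageAssembly):
        return build_cage(
            am.architecture, am.ring.to_spec(), ref(am.arm), am.arm_repeats,
            offset=am.offset, overlap=am.overlap,
            arm_clearance=am.arm_clearance, ring_phase=am.ring_phase,
        )
    if isinstance(am, O43Assembly):
        return build_o43_locked_component(
            am.ring.to_spec(), ref(am.arm), am.arm_repeats,
            offset=am.offset, tip_axis_distance=am.tip_axis_distance,
            arm_clearance=am.arm_clearance,
        )
    if isinstance(am, TrackAssembly):
        return build_train_track(
            ref(am.rail), ref(am.tie), am.tie_spacing_repeats, am.n_cells,
            rail_clearance=am.rail_clearance, tie_z_gap=am.tie_z_gap,
        )
    raise ValueError(f"unhandled assembly model {type(am).__name__}")
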