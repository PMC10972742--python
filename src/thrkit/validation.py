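"""Quantitative checks on blocks and assemblies.

Closure of rings/polygons, expandability criteria, CA clash detection,
ring diameter measurement and model-vs-model RMSD.  Every check returns a
:class:`ValidationReport`; the report's ``summary`` is the conjunction of
its individual pass flags.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .constants import CLASH_CUTOFF, DIAMETER_PROBE, GEOM_TOL
from .geometry import GeometryError, RigidTransform, compose_n, kabsch_superpose
from .model import BackboneModel

__all__ = [
    "ValidationReport",
    "CheckResult",
    "closure_gap",
    "check_closure",
    "check_expandable",
    "detect_clashes",
    "measure_ring_diameter",
    "compare_models",
    "validate_assembly",
]


class ValidationError(ValueError):
    pass


@dataclass
class CheckResult:
    name: str
    passed: bool
    value: float
    units: str
    tolerance: float


@dataclass
class ValidationReport:
    checks: List[CheckResult] = field(default_factory=list)
    worst_clash: Optional[float] = None

    @property
    def summary(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, value: float, units: str, tolerance: float) -> None:
        self.checks.append(
            CheckResult(name, bool(abs(value) <= tolerance), float(value), units, tolerance)
        )

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "worst_clash": self.worst_clash,
            "checks": [vars(c) for c in self.checks],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def closure_gap(step: RigidTransform, n: int) -> Tuple[float, float]:
    """Gap transform after ``n`` applications of ``step``: (rotation deg,
    translation A) distance from the identity."""
    g = compose_n(step, n)
    return g.rotation_angle, float(np.linalg.norm(g.translation))


def check_closure(bp) -> ValidationReport:
    """Closure of every cycle declared by a blueprint.

    For rings: the repeat transform composed n times must be the identity.
    For polygons: (corner turn + edge translation) composed n_sides times.
    For strutted rings: both member rings close.
    """
    from .assemblies import AssemblyBlueprint  # local import, avoids cycle

    if not isinstance(bp, AssemblyBlueprint):
        raise ValidationError("check_closure expects an AssemblyBlueprint")
    rep = ValidationReport()
    cycles = bp.closure_cycles()
    if not cycles:
        raise ValidationError(
            f"architecture {bp.architecture!r} declares no closed cycles"
        )
    for name, step, n in cycles:
        rot, trans = closure_gap(step, n)
        rep.add(f"{name}.rotation_gap", rot, "deg", 1e-6)
        rep.add(f"{name}.translation_gap", trans, "A", 1e-6)
    return rep


def check_expandable(bp, handle: str) -> ValidationReport:
    """Architecture-specific expandability criterion for a named handle.

    * cyclic (ring/polygon): the straight segment's propagation axis must be
      normal to the cyclic symmetry axis;
    * cage: the arm's propagation axis must be parallel to the plane spanned
      by the two symmetry axes the arm connects (face axis and edge C2);
    * track: rail propagation must be parallel to the extension axis.

    The report carries the offending angle in degrees when failing.
    """
    from .assemblies import AssemblyBlueprint

    if not isinstance(bp, AssemblyBlueprint):
        raise ValidationError("check_expandable expects an AssemblyBlueprint")
    if handle not in bp.expansion_handles:
        raise ValidationError(
            f"unknown handle {handle!r}; available: {sorted(bp.expansion_handles)}"
        )
    info = bp.expansion_handles[handle]
    prop = np.asarray(info["propagation"], dtype=float)
    prop = prop / np.linalg.norm(prop)
    rep = ValidationReport()
    kind = info["criterion"]
    if kind == "normal_to_axis":
        axis = np.asarray(info["symmetry_axis"], dtype=float)
        axis = axis / np.linalg.norm(axis)
        dev = abs(90.0 - math.degrees(math.acos(np.clip(abs(prop @ axis), 0, 1))))
        rep.add(f"{handle}.propagation_normal_to_symmetry_axis", dev, "deg", 1e-6)
    elif kind == "parallel_to_axis_plane":
        a1 = np.asarray(info["axis_a"], dtype=float)
        a2 = np.asarray(info["axis_b"], dtype=float)
        normal = np.cross(a1, a2)
        nn = np.linalg.norm(normal)
        if nn == 0.0:
            raise ValidationError("handle axes are parallel; plane undefined")
        normal /= nn
        dev = math.degrees(math.asin(min(1.0, abs(prop @ normal))))
        rep.add(f"{handle}.propagation_in_symmetry_axis_plane", dev, "deg", 1e-6)
    elif kind == "parallel_to_extension_axis":
        axis = np.asarray(info["extension_axis"], dtype=float)
        axis = axis / np.linalg.norm(axis)
        dev = math.degrees(math.acos(np.clip(abs(prop @ axis), 0, 1)))
        rep.add(f"{handle}.propagation_parallel_to_extension_axis", dev, "deg", 1e-6)
    else:
        raise ValidationError(f"unknown expandability criterion {kind!r}")
    return rep


def detect_clashes(
    model: BackboneModel, cutoff: float = CLASH_CUTOFF
) -> List[Tuple[Tuple[int, int], Tuple[int, int], float]]:
    """CA-CA pairs closer than ``cutoff``, excluding near neighbours.

    Residues within 2 positions on the same chain are ignored (they are
    covalently constrained).  Returns ``((chain_i, res_i), (chain_j, res_j),
    distance)`` triples in deterministic sorted order.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    ca = model.ca_coords()
    if len(ca) == 0:
        return []
    idx = model.ca_index()
    tree = cKDTree(ca)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out = []
    for i, j in pairs:
        ci, ri = idx[i]
        cj, rj = idx[j]
        if ci == cj and abs(ri - rj) <= 2:
            continue
        d = float(np.linalg.norm(ca[i] - ca[j]))
        out.append(((ci, ri), (cj, rj), d))
    out.sort()
    return out


def measure_ring_diameter(model: BackboneModel) -> Tuple[float, float]:
    """(outer, inner) diameter of a ring model about its z symmetry axis.

    Convention: outer = 2 * (max radial CA distance + probe radius 2.0 A);
    inner = 2 * (min radial CA distance - probe radius).  This approximates
    the solvent-excluded silhouette seen in EM projections; the probe is a
    documented package convention.
    """
    arch = model.meta.get("architecture")
    if arch not in ("ring", "strutted_rings"):
        raise ValidationError("diameter measurement requires a ring architecture")
    ca = model.ca_coords()
    r = np.hypot(ca[:, 0], ca[:, 1])
    outer = 2.0 * (float(r.max()) + DIAMETER_PROBE)
    inner = 2.0 * max(0.0, float(r.min()) - DIAMETER_PROBE)
    return outer, inner


def validate_assembly(bp, model: Optional[BackboneModel] = None) -> ValidationReport:
    """Run every applicable check on a blueprint: cycle closure, clash
    freedom of the realized model, and expandability of declared handles."""
    rep = ValidationReport()
    if bp.closure_cycles():
        rep.checks.extend(check_closure(bp).checks)
    if model is None:
        model = bp.realize()
    clashes = detect_clashes(model)
    rep.worst_clash = min((c[2] for c in clashes), default=None)
    rep.add("clash_count", float(len(clashes)), "pairs", 0.0)
    for handle in bp.expansion_handles:
        rep.checks.extend(check_expandable(bp, handle).checks)
    return rep


def compare_models(
    a: BackboneModel,
    b: BackboneModel,
    selection: Optional[Callable[[int, int], bool]] = None,
    superpose: bool = True,
) -> float:
    """CA RMSD between two models with 1:1 residue correspondence.

    ``selection(chain_index, residue_index) -> bool`` restricts the residue
    set (applied identically to both models).  With ``superpose`` the RMSD
    is minimized over rigid transforms; otherwise computed in place.
    """
    def pick(m: BackboneModel) -> np.ndarray:
        ca = m.ca_coords()
        if selection is None:
            return ca
        keep = [k for k, (ci, ri) in enumerate(m.ca_index()) if selection(ci, ri)]
        return ca[keep]

    pa, pb = pick(a), pick(b)
    if pa.shape != pb.shape or len(pa) == 0:
        raise ValidationError(
            f"selections do not map 1:1 ({pa.shape[0]} vs {pb.shape[0]} residues)"
        )
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
    _, rmsd = kabsch_superpose(pa, pb)
    return rmsd
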