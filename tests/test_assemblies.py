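"""Rings, polygons, strutted rings, cages, docking and train tracks."""

import math

import numpy as np
import pytest

from thrkit.assemblies import (
    AssemblyError,
    ClosureError,
    RingSpec,
    build_cage,
    build_o43_locked_component,
    build_polygon,
    build_ring,
    build_strutted_rings,
    build_train_track,
    dock_two_component,
    expand_assembly,
    strut_compatibility,
)
from thrkit.blocks import build_linear_thr, build_turn_module, realize_block
from thrkit.geometry import (
    HelixSpec,
    RigidTransform,
    compose_n,
    fit_helix_axis,
    kabsch_superpose,
    repeat_rigid_transform,
)
from thrkit.io.fixtures import four_helix_ring_unit, turn_unit, two_helix_unit
from thrkit.symmetry import handshake_angle, measure_dimer_angle
from thrkit.validation import check_closure, detect_clashes


class TestRings:
    @pytest.mark.parametrize("n,m,chains", [(12, 3, 4), (12, 4, 3), (30, 5, 6), (18, 3, 6)])
    def test_split_into_cyclic_chains(self, ring_unit, n, m, chains):
        spec = RingSpec(n, m, ring_unit, 20.0)
        assert spec.n_chains == chains
        bp = build_ring(spec)
        assert len(bp.components) == chains

    def test_nondivisor_split_rejected(self, ring_unit):
        with pytest.raises(AssemblyError):
            RingSpec(12, 5, ring_unit, 20.0)

    @pytest.mark.parametrize("n", [12, 18, 20, 30])
    def test_ring_closes(self, ring_unit, n):
        spec = RingSpec(n, n // _a_divisor(n), ring_unit, 20.0)
        rep = check_closure(build_ring(spec))
        assert rep.summary

    def test_cyclic_symmetry_of_realized_model(self, ring12_c4):
        model = build_ring(ring12_c4).realize()
        rot = RigidTransform.from_rotation_about([0, 0, 1], [0, 0, 0], 90.0)
        a = model.ca_coords()
        b = rot.apply(a)
        # rotation by 360/4 permutes chains: same coordinate multiset
        assert np.allclose(
            np.sort(np.round(a, 6).view("f8").reshape(len(a), 3), axis=0),
            np.sort(np.round(b, 6).view("f8").reshape(len(b), 3), axis=0),
            atol=1e-5,
        )

    def test_ring_is_clash_free(self, ring12_c4):
        assert not detect_clashes(build_ring(ring12_c4).realize())


def _a_divisor(n):
    return {12: 4, 18: 6, 20: 4, 30: 6}[n]


class TestPolygons:
    @pytest.mark.parametrize("n_sides", [3, 4, 5, 6])
    def test_regular_polygons_close_and_pack(self, n_sides):
        edge = build_linear_thr(two_helix_unit(), 10.0, n_repeats=3)
        corner = build_turn_module(turn_unit(), 0.0, 360.0 / n_sides)
        bp = build_polygon(n_sides, edge, corner)
        assert check_closure(bp).summary
        assert not detect_clashes(bp.realize())
        assert len(bp.components) == 2 * n_sides

    def test_wrong_corner_angle_reports_gap(self):
        edge = build_linear_thr(two_helix_unit(), 10.0, n_repeats=3)
        corner80 = build_turn_module(turn_unit(), 0.0, 80.0)
        with pytest.raises(ClosureError) as err:
            build_polygon(4, edge, corner80)
        assert err.value.gap_rotation == pytest.approx(40.0, abs=1e-6)

    def test_single_bad_corner_gap_is_the_angle_deficit(self):
        """Three 90-deg corners plus one 80-deg corner leave a 10-deg gap."""
        from thrkit.assemblies import _polygon_step

        step90 = _polygon_step(40.0, 90.0)
        step80 = _polygon_step(40.0, 80.0)
        cycle = step80 @ step90 @ step90 @ step90
        assert cycle.rotation_angle == pytest.approx(10.0, abs=1e-9)

    def test_edge_expansion_preserves_corner_placement(self, corner90):
        edge = build_linear_thr(two_helix_unit(), 10.0, n_repeats=3)
        base = build_polygon(4, edge, corner90)
        grown = expand_assembly(base, "edge", 3)  # +6 helices per chain
        assert grown.params["side_length"] == base.params["side_length"] + 30.0

        def corner_cas(bp):
            c = next(c for c in bp.components if c.name == "corner0")
            return realize_block(c.block).transformed(c.frame).ca_coords()

        _, rmsd = kabsch_superpose(corner_cas(base), corner_cas(grown))
        assert rmsd < 1e-9


class TestStrutCompatibility:
    def test_printed_c10_arithmetic(self):
        comp = strut_compatibility(20, 30)
        assert comp == (10, 2, 3)
        assert comp.rotation_per_subunit == pytest.approx(36.0)

    def test_printed_c6_arithmetic(self):
        comp = strut_compatibility(30, 18)
        assert comp == (6, 5, 3)
        assert comp.rotation_per_subunit == pytest.approx(60.0)
        assert 6 * comp.rotation_per_subunit == pytest.approx(360.0)

    def test_equal_rings_are_fully_compatible(self):
        assert strut_compatibility(24, 24) == (24, 1, 1)


class TestStruttedRings:
    def _c10(self):
        outer = RingSpec(30, 3, four_helix_ring_unit(22.0), 22.0)
        inner = RingSpec(20, 2, four_helix_ring_unit(19.0), 19.0)
        strut = build_linear_thr(two_helix_unit(), 10.0, n_repeats=2)
        return build_strutted_rings(outer, inner, strut)

    def test_c10_single_component_construction(self):
        bp = self._c10()
        # 10 copies of (outer chain + inner chain + strut)
        assert len(bp.components) == 30
        comp = bp.params["compatibility"]
        assert comp.g == 10
        placed_repeats = comp.g * (comp.r_a + comp.r_b)
        assert placed_repeats == 50
        assert check_closure(bp).summary
        assert not detect_clashes(bp.realize())

    def test_strut_propagation_is_radial(self):
        bp = self._c10()
        strut0 = next(c for c in bp.components if c.name == "strut0")
        prop = strut0.frame.rotation[:, 0]
        origin = strut0.frame.translation
        radial = origin / np.linalg.norm(origin)
        assert abs(prop @ radial) == pytest.approx(1.0, abs=1e-9)

    def test_two_component_c6(self):
        outer = RingSpec(30, 5, four_helix_ring_unit(22.0), 22.0)
        inner = RingSpec(18, 3, four_helix_ring_unit(19.0), 19.0)
        strut = build_linear_thr(two_helix_unit(), 10.0, n_repeats=2)
        bp = build_strutted_rings(outer, inner, strut)
        assert bp.params["compatibility"].g == 6
        assert not detect_clashes(bp.realize())

    def test_mismatched_split_rejected(self):
        outer = RingSpec(30, 5, four_helix_ring_unit(22.0), 22.0)
        inner = RingSpec(20, 2, four_helix_ring_unit(19.0), 19.0)  # needs m=2 per C10
        strut = build_linear_thr(two_helix_unit(), 10.0, n_repeats=2)
        with pytest.raises(AssemblyError):
            build_strutted_rings(outer, inner, strut)  # outer m=5 vs required 3

    def test_incompatible_rings_rejected(self):
        outer = RingSpec(25, 5, four_helix_ring_unit(22.0), 22.0)
        inner = RingSpec(12, 4, four_helix_ring_unit(19.0), 19.0)  # gcd 1
        strut = build_linear_thr(two_helix_unit(), 10.0, n_repeats=2)
        with pytest.raises(AssemblyError):
            build_strutted_rings(outer, inner, strut)


def _arm():
    return build_linear_thr(two_helix_unit(offy=8.0), 10.0, n_repeats=3)


def _edge_dimer_arms(bp):
    """The asymmetric-unit arm and its exact C2 partner across the edge."""
    e = np.array(bp.params["edge_axis_asym"])
    c2 = RigidTransform.from_rotation_about(e, [0, 0, 0], 180.0)
    arm0 = next(c for c in bp.components if c.name == f"arm{bp.params['asym_index']}")
    target = c2 @ arm0.frame
    mate = next(
        c
        for c in bp.components
        if c.name.startswith("arm")
        and np.allclose(c.frame.rotation, target.rotation, atol=1e-9)
        and np.allclose(c.frame.translation, target.translation, atol=1e-9)
    )
    return arm0, mate


CAGE_EXPECT = {"T3": (12, 6), "O3": (24, 12), "I3": (60, 30), "O4": (24, 12)}


class TestCages:
    @pytest.mark.parametrize("arch", ["T3", "O3", "I3", "O4"])
    def test_counts_and_clash_freedom(self, ring12_c3, ring12_c4, arch):
        ring = ring12_c4 if arch == "O4" else ring12_c3
        bp = build_cage(arch, ring, _arm(), 3)
        frames, edges = CAGE_EXPECT[arch]
        assert len(bp.components) == 2 * frames  # ring chain + arm per frame
        assert len(bp.interfaces) == edges
        assert not detect_clashes(bp.realize())

    @pytest.mark.parametrize("arch", ["T3", "O3", "I3", "O4"])
    def test_measured_dimer_angle_matches_architecture(self, ring12_c3, ring12_c4, arch):
        ring = ring12_c4 if arch == "O4" else ring12_c3
        bp = build_cage(arch, ring, _arm(), 3)
        arm0, mate = _edge_dimer_arms(bp)
        dirs = []
        for c in (arm0, mate):
            model = realize_block(c.block).transformed(c.frame)
            seg = model.chains[0].segments[0]  # a0 helix, runs +z in block frame
            _, direction, _ = fit_helix_axis(seg.ca)
            dirs.append(direction)
        assert measure_dimer_angle(dirs[0], dirs[1]) == pytest.approx(
            handshake_angle(arch), abs=1e-3
        )

    def test_exact_c2_dimer_on_edge(self, ring12_c4):
        bp = build_cage("O4", ring12_c4, _arm(), 3)
        e = np.array(bp.interfaces[0]["edge_axis"])
        c2 = RigidTransform.from_rotation_about(e, [0, 0, 0], 180.0)
        model = bp.realize()
        a = model.ca_coords()
        b = c2.apply(a)
        assert np.allclose(np.sort(a, axis=0), np.sort(b, axis=0), atol=1e-6)

    def test_ring_symmetry_mismatch_rejected(self, ring12_c4):
        with pytest.raises(AssemblyError):
            build_cage("T3", ring12_c4, _arm(), 3)  # T3 needs C3 split

    def test_arm_too_short_reports_minimum(self, ring12_c3):
        with pytest.raises(AssemblyError, match="arm_repeats >="):
            build_cage("T3", ring12_c3, _arm(), 1)

    def test_expansion_series_affine_growth(self, ring12_c4):
        base = build_cage("O4", ring12_c4, _arm(), 3)
        ks = [0, 2, 4, 6]
        dists = []
        for k in ks:
            bp = expand_assembly(base, "arm", k)
            # measured: distance between ring-chain centroids of two adjacent faces
            by_face = {}
            for c in bp.components:
                if not c.name.startswith("ring"):
                    continue
                axis = tuple(np.round(c.frame.rotation @ [0, 0, 1], 6))
                cas = realize_block(c.block).transformed(c.frame).ca_coords()
                by_face.setdefault(axis, []).append(cas.mean(axis=0))
            centroids = {a: np.mean(v, axis=0) for a, v in by_face.items()}
            ref = tuple(np.round(np.array(bp.params["face_axis"]), 6))
            top = centroids[ref]
            nearest = min(
                np.linalg.norm(top - c) for a, c in centroids.items() if a != ref
            )
            dists.append(nearest)
        diffs = np.diff(dists)
        assert np.ptp(diffs) < 1e-6  # perfectly affine in k
        assert diffs[0] > 0

    def test_expansion_c2_distance_grows_by_k_d(self, ring12_c4):
        base = build_cage("O4", ring12_c4, _arm(), 3)
        grown = expand_assembly(base, "arm", 5)
        assert grown.params["c2_distance"] - base.params["c2_distance"] == pytest.approx(
            5 * 10.0, abs=1e-9
        )

    def test_expansion_preserves_interface_coordinates(self, ring12_c3):
        base = build_cage("T3", ring12_c3, _arm(), 3)
        grown = expand_assembly(base, "arm", 4)

        def dimer_tail_cas(bp):
            pts = []
            for c in _edge_dimer_arms(bp):
                cas = realize_block(c.block).transformed(c.frame).ca_coords()
                pts.append(cas[-80:])  # last two repeats (2 helices x 20 res)
            return np.concatenate(pts)

        _, rmsd = kabsch_superpose(dimer_tail_cas(base), dimer_tail_cas(grown))
        assert rmsd < 1e-9

    def test_expansion_k0_is_same_blueprint(self, ring12_c4):
        base = build_cage("O4", ring12_c4, _arm(), 3)
        assert expand_assembly(base, "arm", 0) is base

    def test_unknown_handle_rejected(self, ring12_c4):
        base = build_cage("O4", ring12_c4, _arm(), 3)
        with pytest.raises(Exception):
            expand_assembly(base, "strut", 1)


class TestO43Docking:
    def _locked(self, ring12_c3, k=0):
        return build_o43_locked_component(ring12_c3, _arm(), 3 + k)

    def test_locked_component_is_clash_free(self, ring12_c3):
        assert not detect_clashes(self._locked(ring12_c3).realize())

    def test_candidates_keep_trimer_rotation_locked(self, ring12_c3, ring12_c4):
        locked = self._locked(ring12_c3)
        ax0 = locked.params["tip_axial"]
        cands = dock_two_component(
            locked, ring12_c4, rotations=range(0, 90, 15), radii=[ax0 - 19, ax0 - 14]
        )
        assert cands
        assert all(c.trimer_rotation == 0.0 for c in cands)

    def test_expansion_preserves_tip_to_partner_geometry(self, ring12_c3):
        base = self._locked(ring12_c3)
        grown = expand_assembly(base, "arm", 1)
        a4 = np.array(base.params["partner_axis"])

        def tip_perp(bp):
            c = next(c for c in bp.components if c.name == "trimer_arm0")
            tip = c.frame.apply([(c.block.n_repeats - 1) * 10.0, 0.0, 0.0])
            return np.linalg.norm(tip - (tip @ a4) * a4)

        assert tip_perp(base) == pytest.approx(tip_perp(grown), abs=1e-9)

    def test_empty_grid_gives_empty_result(self, ring12_c3, ring12_c4):
        assert dock_two_component(self._locked(ring12_c3), ring12_c4, [], []) == []


class TestTrainTracks:
    def _blocks(self):
        rail = build_linear_thr(two_helix_unit(offy=8.0), 10.0, n_repeats=1, caps=(False, False))
        tie = build_linear_thr(two_helix_unit(), 10.0, n_repeats=4, caps=(True, False))
        return rail, tie

    def test_track_builds_clash_free(self):
        rail, tie = self._blocks()
        bp = build_train_track(rail, tie, 6, 3)
        assert not detect_clashes(bp.realize())

    def test_rail_expansion_scales_tie_spacing(self):
        rail, tie = self._blocks()
        base = build_train_track(rail, tie, 6, 2)
        doubled = expand_assembly(base, "rail", 6)  # +12 helices on a 2-helix repeat
        assert doubled.params["cell_length"] == pytest.approx(2 * base.params["cell_length"])

    def test_tie_expansion_scales_rail_separation(self):
        rail, tie = self._blocks()
        base = build_train_track(rail, tie, 6, 2)
        wider = expand_assembly(base, "tie", 4)  # +8 helices per tie half
        assert wider.params["rail_separation"] - base.params["rail_separation"] == pytest.approx(
            4 * 10.0
        )

    def test_lattice_periodicity(self):
        """The middle cell of a 3-cell model equals the 1-cell model shifted."""
        rail, tie = self._blocks()
        one = build_train_track(rail, tie, 4, 1)
        three = build_train_track(rail, tie, 4, 3)
        cell = one.params["cell_length"]

        def cell_cas(bp, idx):
            pts = []
            for c in bp.components:
                if c.name.startswith("rail"):
                    model = realize_block(c.block).transformed(c.frame)
                    for seg in model.chains[0].segments:
                        if idx * 4 <= seg.repeat < (idx + 1) * 4:
                            pts.append(seg.ca)
                elif c.name.startswith(f"tie{idx}"):
                    pts.append(realize_block(c.block).transformed(c.frame).ca_coords())
            return np.concatenate(pts)

        a = cell_cas(one, 0)
        b = cell_cas(three, 1)
        assert np.allclose(a + [cell, 0, 0], b, atol=1e-9)

    def test_capped_rail_rejected(self):
        _, tie = self._blocks()
        capped = build_linear_thr(two_helix_unit(offy=8.0), 10.0, n_repeats=1, caps=(True, True))
        with pytest.raises(AssemblyError):
            build_train_track(capped, tie, 6, 2)

    def test_tie_without_c2_interface_rejected(self):
        rail, _ = self._blocks()
        capped_tie = build_linear_thr(two_helix_unit(), 10.0, n_repeats=4, caps=(True, True))
        with pytest.raises(AssemblyError, match="C2"):
            build_train_track(rail, capped_tie, 6, 2)
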