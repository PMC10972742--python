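"""THR block construction: linear, stair, curve and turn modules."""

import math

import numpy as np
import pytest

from thrkit.blocks import (
    BlockError,
    RepeatUnit,
    build_curve_thr,
    build_linear_thr,
    build_turn_module,
    insert_repeats,
    realize_block,
)
from thrkit.geometry import HelixSpec, fit_helix_axis, kabsch_superpose
from thrkit.io.fixtures import turn_unit, two_helix_unit


def _segment_cas(model, **match):
    out = []
    for _, seg in model.iter_segments():
        if all(getattr(seg, k) == v for k, v in match.items()):
            out.append(seg.ca)
    return out


class TestRepeatUnit:
    def test_helix_count_bounds(self):
        h = HelixSpec(10, name="a0")
        with pytest.raises(BlockError):
            RepeatUnit(tuple())
        with pytest.raises(BlockError):
            RepeatUnit(tuple(HelixSpec(10, name=f"h{i}") for i in range(5)))

    def test_traversable_units_alternate_direction(self, unit2):
        assert unit2.is_traversable
        same_way = RepeatUnit((HelixSpec(10, name="a0"), HelixSpec(10, name="b0")))
        assert not same_way.is_traversable


class TestLinear:
    def test_successive_repeats_pure_translation(self, linear_block):
        model = realize_block(linear_block)
        r0 = np.concatenate(_segment_cas(model, repeat=0))
        r1 = np.concatenate(_segment_cas(model, repeat=1))
        t, rmsd = kabsch_superpose(r0, r1)
        assert rmsd < 1e-9
        assert t.rotation_angle == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.norm(t.translation) == pytest.approx(10.0, abs=1e-9)

    def test_compact_packing_d_is_realized(self):
        block = build_linear_thr(two_helix_unit(d=8.7), d=8.7, n_repeats=2)
        model = realize_block(block)
        cas = _segment_cas(model, helix="a0")
        p0, _, _ = fit_helix_axis(cas[0])
        p1, _, _ = fit_helix_axis(cas[1])
        assert np.linalg.norm(p1[:2] - p0[:2]) == pytest.approx(8.7, abs=1e-6)

    def test_stair_anchor_heights_are_arithmetic(self, unit2):
        block = build_linear_thr(unit2, d=10, dh=3, n_repeats=4)
        assert block.block_class == "stair"
        assert block.anchors()[:, 2] == pytest.approx([0, 3, 6, 9])

    def test_all_axes_stay_parallel_to_z(self, linear_block):
        model = realize_block(linear_block)
        for _, seg in model.iter_segments():
            _, direction, _ = fit_helix_axis(seg.ca)
            assert abs(abs(direction[2]) - 1.0) < 1e-9


class TestCurve:
    def test_anchor_circle_radius(self, unit2):
        block = build_curve_thr(unit2, d=10, dtheta=30, n_repeats=12, caps=(False, False))
        anchors = block.anchors()
        R = 10 / (2 * math.sin(math.radians(15)))
        assert R == pytest.approx(19.319, abs=1e-3)
        center = np.array([0.0, R, 0.0])
        assert np.linalg.norm(anchors - center, axis=1) == pytest.approx(R, abs=1e-6)

    def test_five_repeats_of_12_degrees_sweep_60(self, unit2):
        block = build_curve_thr(unit2, d=10, dtheta=12, n_repeats=6)
        anchors = block.anchors()
        R = block.transform.curvature_radius
        center = np.array([0.0, R, 0.0])
        v0 = anchors[0] - center
        v5 = anchors[5] - center
        swept = math.degrees(math.acos(np.clip(v0 @ v5 / (R * R), -1, 1)))
        assert swept == pytest.approx(60.0, abs=1e-6)

    def test_trajectory_stays_in_plane(self, unit2):
        block = build_curve_thr(unit2, d=12, dtheta=20, n_repeats=10)
        assert np.ptp(block.anchors()[:, 2]) < 1e-6

    def test_zero_dtheta_rejected(self, unit2):
        with pytest.raises(BlockError):
            build_curve_thr(unit2, d=10, dtheta=0)


class TestTurn:
    @pytest.mark.parametrize("theta_c,expected", [(90, 90), (120, 120), (0, 0)])
    def test_turn_angle_is_phase_difference(self, theta_c, expected):
        block = build_turn_module(turn_unit(), 0.0, theta_c)
        assert block.turn_angle == pytest.approx(expected)

    def test_turn_angle_wraps_mod_360(self):
        block = build_turn_module(turn_unit(), 300.0, 30.0)
        assert block.turn_angle == pytest.approx(90.0)

    def test_corner_phases_applied_to_helices(self):
        block = build_turn_module(turn_unit(), 10.0, 100.0)
        assert block.unit.helix_named("a0").phase == pytest.approx(10.0)
        assert block.unit.helix_named("c0").phase == pytest.approx(100.0)

    def test_offline_corner_helix_rejected(self):
        bad = RepeatUnit(
            (
                HelixSpec(20, name="a0"),
                HelixSpec(20, axis_xy=(5, -8), flipped=True, name="b0"),
                HelixSpec(20, axis_xy=(10, 2.0), name="c0"),  # off the line
            )
        )
        with pytest.raises(BlockError):
            build_turn_module(bad, 0, 90)


class TestRealize:
    def test_repeat_annotations(self, unit2):
        model = realize_block(build_linear_thr(unit2, 10, n_repeats=3))
        repeats = [seg.repeat for _, seg in model.iter_segments()]
        assert repeats == [0, 0, 1, 1, 2, 2]

    def test_single_repeat_equals_unit(self, unit2):
        model = realize_block(build_linear_thr(unit2, 10, n_repeats=1))
        unit_cas = np.concatenate([h.ca for h in unit2.realize()])
        assert np.allclose(model.ca_coords(), unit_cas)

    def test_placeholder_loops_flagged(self, unit2):
        model = realize_block(build_linear_thr(unit2, 10, n_repeats=2), loop_mode="placeholder")
        loops = [seg for _, seg in model.iter_segments() if seg.kind == "loop"]
        assert len(loops) == 3  # between 4 helices
        assert all(seg.flags.get("placeholder") for seg in loops)
        assert all(seg.n_res == 3 for seg in loops)

    def test_long_placeholder_loop_warns(self):
        wide = RepeatUnit(
            (
                HelixSpec(20, name="a0"),
                HelixSpec(20, axis_xy=(10.0, 14.0), flipped=True, name="b0"),
            )
        )
        model = realize_block(build_linear_thr(wide, 21.0, n_repeats=1), loop_mode="placeholder")
        loops = [seg for _, seg in model.iter_segments() if seg.kind == "loop"]
        assert any(seg.flags.get("long_loop") for seg in loops)

    def test_uncapped_concatenation_identity(self, unit2):
        """One 2n-repeat block equals two n-repeat blocks joined end-to-end."""
        whole = realize_block(build_linear_thr(unit2, 10, n_repeats=6, caps=(False, False)))
        half_block = build_linear_thr(unit2, 10, n_repeats=3, caps=(False, False))
        first = realize_block(half_block)
        from thrkit.geometry import compose_n

        shift = compose_n(half_block.rigid, 3)
        second = realize_block(half_block).transformed(shift)
        joined = np.concatenate([first.ca_coords(), second.ca_coords()])
        assert np.allclose(whole.ca_coords(), joined, atol=1e-9)


class TestInsertRepeats:
    def test_helix_count_grows_by_k_times_unit_size(self):
        base = build_linear_thr(turn_unit(), 10, n_repeats=2)  # 3-helix unit
        grown = insert_repeats(base, 2)
        assert grown.n_repeats == 4
        added = (grown.n_repeats - base.n_repeats) * base.unit.n_helices
        assert added == 6  # two repeat units = six helices

    def test_zero_insertion_is_identity(self, linear_block):
        assert insert_repeats(linear_block, 0) == linear_block

    def test_end_repeats_superpose_after_translation(self, unit2):
        base = build_linear_thr(unit2, 10, n_repeats=4)
        grown = insert_repeats(base, 3)
        mb = realize_block(base)
        mg = realize_block(grown)
        last_base = np.concatenate(_segment_cas(mb, repeat=3))
        last_grown = np.concatenate(_segment_cas(mg, repeat=6))
        assert np.allclose(last_base + [30.0, 0, 0], last_grown, atol=1e-9)

    def test_curve_blocks_not_insertable(self, unit2):
        curve = build_curve_thr(unit2, 10, 30, 3)
        with pytest.raises(BlockError):
            insert_repeats(curve, 1)
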