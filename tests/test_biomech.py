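import numpy as np
import pytest

from footmech.biomech import (
    AnatomicalFrame,
    AngleDefinition,
    ConfigurationState,
    DEFAULT_ANGLES,
    LigamentFiber,
    build_anatomical_frame,
    ligament_length,
    ligament_strain,
    measure_angles,
    measure_table,
    projected_angle,
    relative_transform,
    rotation_amplitude,
    translation_amplitude,
)
from footmech.geometry import RigidTransform, compose


def _identity_frame():
    return AnatomicalFrame(np.array([1.0, 0, 0]), np.array([0.0, 0, 1]),
                           np.array([0.0, -1.0, 0]), np.zeros(3))


def _state(transforms, config_id="c", footwear="bare"):
    return ConfigurationState(config_id, transforms, "N", 1.0, footwear)


class TestRelativeMotion:
    def test_bone_moving_with_frame_is_identity(self):
        t = RigidTransform((0.2, 0.1, -0.3), (5, 2, 1))
        rel = relative_transform(t, t)
        assert np.allclose(rel.matrix, np.eye(4), atol=1e-9)

    def test_identity_frame_returns_bone_transform(self):
        t = RigidTransform((0.2, 0.1, -0.3), (5, 2, 1))
        rel = relative_transform(t, RigidTransform.identity())
        assert np.allclose(rel.matrix, t.matrix, atol=1e-12)

    def test_action_matches_matrix_composition(self, rng):
        bone = RigidTransform((0.4, -0.1, 0.2), (3, -2, 1))
        frame = RigidTransform((-0.2, 0.3, 0.1), (1, 4, -2))
        rel = relative_transform(bone, frame)
        pts = rng.normal(scale=20, size=(100, 3))
        from footmech.geometry import invert
        expected = invert(frame).apply(bone.apply(pts))
        np.testing.assert_allclose(rel.apply(pts), expected, atol=1e-9)


class TestAmplitudes:
    COM = {"a": np.array([10.0, 0, 0]), "b": np.zeros(3)}

    def test_no_motion_gives_zero(self):
        st = _state({"a": RigidTransform.identity(), "b": RigidTransform.identity()})
        assert translation_amplitude(st, "a", "b", self.COM) == pytest.approx(0.0)
        assert rotation_amplitude(st, "a", "b") == pytest.approx(0.0)

    def test_pure_translation_three_four_five(self):
        st = _state({"a": RigidTransform((0, 0, 0), (3, 4, 0)),
                     "b": RigidTransform.identity()})
        assert translation_amplitude(st, "a", "b", self.COM) == pytest.approx(5.0)
        assert rotation_amplitude(st, "a", "b") == pytest.approx(0.0, abs=1e-9)

    def test_off_axis_rotation_chord_length(self):
        # 10 deg rotation about z through the origin; COM at lever 10 mm:
        # chord = 2 * 10 * sin(5 deg)
        ang = np.radians(10)
        st = _state({"a": RigidTransform((ang, 0, 0), (0, 0, 0)),
                     "b": RigidTransform.identity()})
        assert rotation_amplitude(st, "a", "b") == pytest.approx(10.0, abs=1e-9)
        expected = 2 * 10 * np.sin(np.radians(5))
        assert translation_amplitude(st, "a", "b", self.COM) == pytest.approx(expected, abs=1e-9)

    def test_unknown_bone_errors(self):
        st = _state({"a": RigidTransform.identity(), "b": RigidTransform.identity()})
        with pytest.raises(KeyError):
            translation_amplitude(st, "ghost", "b", self.COM)


class TestAnatomicalFrame:
    COM = {"calcaneus": np.array([28.0, -2, 18]),
           "metatarsal_2": np.array([144.0, 0, 33]),
           "tibia": np.array([55.0, 0, 104])}

    def test_axis_aligned_phantom_gives_near_identity_axes(self):
        frame = build_anatomical_frame(self.COM, np.array([0.0, 0, 1.0]))
        assert np.degrees(np.arccos(np.clip(frame.superior @ [0, 0, 1], -1, 1))) < 2
        assert np.degrees(np.arccos(np.clip(frame.anterior @ [1, 0, 0], -1, 1))) < 2

    def test_axes_orthonormal(self):
        frame = build_anatomical_frame(self.COM, np.array([0.1, 0.05, 1.0]))
        for u, v in ((frame.anterior, frame.superior),
                     (frame.anterior, frame.medial),
                     (frame.superior, frame.medial)):
            assert abs(u @ v) < 1e-9
            assert np.linalg.norm(u) == pytest.approx(1.0)

    def test_side_flag_flips_medial_only(self):
        right = build_anatomical_frame(self.COM, np.array([0.0, 0, 1.0]), "right")
        left = build_anatomical_frame(self.COM, np.array([0.0, 0, 1.0]), "left")
        np.testing.assert_allclose(right.anterior, left.anterior)
        np.testing.assert_allclose(right.superior, left.superior)
        np.testing.assert_allclose(right.medial, -left.medial)

    def test_collinear_landmarks_error(self):
        com = dict(self.COM)
        com["metatarsal_2"] = com["calcaneus"] + np.array([0.0, 0, 50.0])
        with pytest.raises(ValueError):
            build_anatomical_frame(com, np.array([0.0, 0, 1.0]))


class TestProjectedAngle:
    def test_orthogonal_rays_ninety_degrees(self):
        frame = _identity_frame()
        ang = projected_angle(np.array([0, 0, 10.0]), np.zeros(3),
                              np.array([10.0, 0, 0]), frame, "sagittal")
        assert abs(ang) == pytest.approx(90.0)

    def test_collinear_points_180(self):
        frame = _identity_frame()
        ang = projected_angle(np.array([-5.0, 0, 0]), np.zeros(3),
                              np.array([10.0, 0, 0]), frame, "sagittal")
        assert abs(ang) == pytest.approx(180.0)

    def test_invariant_under_in_plane_rigid_motion(self):
        frame = _identity_frame()
        a, b, c = np.array([3.0, 0, 1]), np.array([1.0, 0, -2]), np.array([-4.0, 0, 2])
        base = projected_angle(a, b, c, frame, "sagittal")
        # in-plane (sagittal = x/z) rotation + translation
        th = 0.7
        rot = np.array([[np.cos(th), 0, -np.sin(th)], [0, 1, 0],
                        [np.sin(th), 0, np.cos(th)]])
        shift = np.array([4.0, 0, -7.0])
        moved = [rot @ p + shift for p in (a, b, c)]
        assert projected_angle(*moved, frame, "sagittal") == pytest.approx(base, abs=1e-9)

    def test_coincident_projection_errors(self):
        frame = _identity_frame()
        with pytest.raises(ValueError):
            projected_angle(np.zeros(3), np.zeros(3), np.array([1.0, 0, 0]),
                            frame, "sagittal")


class TestMeasureAngles:
    COM = {"tibia": np.array([55.0, 0, 104]), "talus": np.array([55.0, 0, 46]),
           "calcaneus": np.array([28.0, -2, 18]),
           "sesamoid_medial": np.array([164.0, 20, 17]),
           "metatarsal_2": np.array([144.0, 0, 33])}

    def _frame(self):
        return build_anatomical_frame(self.COM, np.array([0.0, 0, 1.0]))

    def test_reference_amplitudes_zero(self):
        ident = {b: RigidTransform.identity() for b in self.COM}
        st = _state(ident)
        table = measure_angles([st], self._frame(), self.COM,
                               DEFAULT_ANGLES, reference_state=st)
        np.testing.assert_allclose(table.amplitude_deg, 0.0, atol=1e-9)

    def test_four_rows_for_default_definitions(self):
        ident = {b: RigidTransform.identity() for b in self.COM}
        st = _state(ident)
        table = measure_angles([st], self._frame(), self.COM, DEFAULT_ANGLES)
        assert len(table) == 4
        assert set(zip(table.angle, table.plane)) == {
            ("TibTalCal", "sagittal"), ("TibTalCal", "coronal"),
            ("CalTalSM", "sagittal"), ("CalTalSM", "transverse")}

    def test_planned_sagittal_rotation_recovered(self):
        """Rotating the sesamoid about the talus by 5 deg in the sagittal
        plane changes the CalTalSM sagittal amplitude by 5 deg."""
        frame = self._frame()
        ident = {b: RigidTransform.identity() for b in self.COM}
        ref = _state(ident, "ref")
        ang = np.radians(5.0)
        # sagittal plane of the near-identity frame ~ x/z: rotate about -y axis
        rot = RigidTransform((0.0, -ang, 0.0)).rotation_matrix
        talus = self.COM["talus"]
        moved = dict(ident)
        moved["sesamoid_medial"] = RigidTransform.from_matrix(rot, talus - rot @ talus)
        st = _state(moved)
        table = measure_angles([st], frame, self.COM, DEFAULT_ANGLES, reference_state=ref)
        row = table[(table.angle == "CalTalSM") & (table.plane == "sagittal")]
        assert abs(abs(row.amplitude_deg.iloc[0]) - 5.0) < 0.5


class TestLigaments:
    FIBER = LigamentFiber("f", "a", (0.0, 0, 0), "b", (50.0, 0, 0))

    def _ref(self):
        return _state({"a": RigidTransform.identity(), "b": RigidTransform.identity()}, "ref")

    def test_no_motion_zero_strain(self):
        assert ligament_strain(self._ref(), self._ref(), self.FIBER) == pytest.approx(0.0)

    def test_two_percent_elongation(self):
        st = _state({"a": RigidTransform.identity(),
                     "b": RigidTransform((0, 0, 0), (1.0, 0, 0))})
        assert ligament_length(self._ref(), self.FIBER) == pytest.approx(50.0)
        assert ligament_strain(st, self._ref(), self.FIBER) == pytest.approx(2.0)

    def test_axial_translation_strain(self):
        fiber = LigamentFiber("f", "a", (0.0, 0, 0), "b", (40.0, 0, 0))
        st = _state({"a": RigidTransform.identity(),
                     "b": RigidTransform((0, 0, 0), (2.0, 0, 0))})
        assert ligament_strain(st, self._ref(), fiber) == pytest.approx(5.0)

    def test_zero_reference_length_errors(self):
        fiber = LigamentFiber("f", "a", (1.0, 1, 1), "b", (1.0, 1, 1))
        with pytest.raises(ValueError):
            ligament_strain(self._ref(), self._ref(), fiber)

    def test_global_rigid_motion_leaves_strain_unchanged(self):
        g = RigidTransform((0.3, -0.2, 0.1), (10, -5, 3))
        st = _state({"a": RigidTransform.identity(),
                     "b": RigidTransform((0, 0, 0), (1.0, 0, 0))})
        moved = _state({b: compose(g, t) for b, t in st.transforms.items()})
        assert ligament_strain(moved, self._ref(), self.FIBER) == pytest.approx(
            ligament_strain(st, self._ref(), self.FIBER), abs=1e-9)


def test_measure_table_layout():
    com = {"tibia": np.array([55.0, 0, 104]), "talus": np.array([55.0, 0, 46]),
           "calcaneus": np.array([28.0, -2, 18]),
           "sesamoid_medial": np.array([164.0, 20, 17]),
           "metatarsal_2": np.array([144.0, 0, 33])}
    frame = build_anatomical_frame(com, np.array([0.0, 0, 1.0]))
    ident = {b: RigidTransform.identity() for b in com}
    ref = _state(ident, "ref")
    states = [_state(ident, "c1", "bare"), _state(ident, "c1s", "shod")]
    fiber = LigamentFiber("f", "talus", tuple(com["talus"] + [0, 0, -10]),
                          "calcaneus", tuple(com["calcaneus"] + [0, 0, 10]))
    from footmech.biomech import LigamentDefinition
    table = measure_table(states, ref, com, frame,
                          [LigamentDefinition("lig", [fiber])])
    assert set(table.metric_type) == {
        "translation_mm", "rotation_deg", "angle_deg", "strain_pct"}
    assert set(table.columns) == {
        "config_id", "footwear", "metric_type", "entity", "frame_bone", "value"}
    # identity transforms: every value zero
    np.testing.assert_allclose(table.value, 0.0, atol=1e-9)
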