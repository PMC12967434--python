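"""The four parameter equations, wrist angles, deltas and classification."""

import numpy as np
import pandas as pd
import pytest

from ulnakin import (
    AnatomicalFrame,
    LandmarkSet,
    MovementLabel,
    RigidTransform,
    classify_uv,
    delta_series,
    epicentre_3d,
    mru_3d,
    ulnar_variance_3d,
    wrist_angle,
)

from .conftest import random_rigid

FRAME = AnatomicalFrame.canonical()


def landmark_set(
    head_palmar=(10.0, -10.0, -16.0),
    corner=(-28.0, -12.0, 0.0),
    palmar=(0.0, -9.0, -10.0),
    dorsal=(0.0, 9.0, -10.0),
    epicentre=(10.0, 0.0, -6.0),
    distal_ulnar=(10.0, 0.0, -6.0),
    sigmoid_distal=(0.0, 0.0, -7.0),
):
    palmar = np.asarray(palmar, float)
    dorsal = np.asarray(dorsal, float)
    return LandmarkSet(
        distal_ulnar_point=np.asarray(distal_ulnar, float),
        sigmoid_distal_point=np.asarray(sigmoid_distal, float),
        palmar_radial_corner=np.asarray(corner, float),
        palmar_margin=palmar,
        dorsal_margin=dorsal,
        notch_midpoint=0.5 * (palmar + dorsal),
        ulnar_epicentre=np.asarray(epicentre, float),
        ulnar_styloid_tip=(15.0, 0.0, -2.0),
        ulnar_head_palmar_point=np.asarray(head_palmar, float),
    )


class TestUlnarVariance:
    @pytest.mark.parametrize(
        "du_z, sd_z, expected",
        [(-7.4, -7.0, -0.4), (-7.0, -7.0, 0.0), (-5.3, -7.0, 1.7)],
    )
    def test_height_difference_along_longitudinal_axis(self, du_z, sd_z, expected):
        uv = ulnar_variance_3d((10.0, 0.0, du_z), (0.0, 0.0, sd_z), FRAME)
        assert uv == pytest.approx(expected, abs=1e-12)

    def test_pure_distal_translation_adds_exactly(self):
        lm = landmark_set()
        uv0 = ulnar_variance_3d(lm.distal_ulnar_point, lm.sigmoid_distal_point, FRAME)
        shift = RigidTransform(np.eye(3), [0, 0, 2.5])
        lm2 = lm.transformed_per_bone(RigidTransform.identity(), shift)
        uv1 = ulnar_variance_3d(lm2.distal_ulnar_point, lm2.sigmoid_distal_point, FRAME)
        assert uv1 - uv0 == pytest.approx(2.5, abs=1e-9)


class TestClassifyUV:
    @pytest.mark.parametrize(
        "uv, expected",
        [(-0.4, "neutral"), (0.99, "neutral"), (1.0, "positive"),
         (-1.0, "negative"), (-2.3, "negative"), (3.1, "positive")],
    )
    def test_neutral_band_below_one_mm(self, uv, expected):
        assert classify_uv(uv) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_uv(float("nan"))


class TestMru:
    def test_point_on_line_is_zero(self):
        # head point placed exactly on the (axial projection of the) B-C line
        lm = landmark_set(corner=(-20.0, -9.0, 0.0), palmar=(0.0, -9.0, -10.0),
                          head_palmar=(10.0, -9.0, -16.0))
        assert mru_3d(lm, FRAME) == pytest.approx(0.0, abs=1e-9)

    def test_palmar_displacement_is_positive_ten_percent(self):
        """2 mm palmar of the line, width 20 mm -> +10% (radius relatively dorsal)."""
        lm = landmark_set(corner=(-20.0, -9.0, 0.0), palmar=(0.0, -9.0, -10.0),
                          dorsal=(0.0, 11.0, -10.0), head_palmar=(10.0, -11.0, -16.0))
        assert mru_3d(lm, FRAME) == pytest.approx(10.0, abs=1e-9)

    def test_dorsal_displacement_is_negative(self):
        lm = landmark_set(corner=(-20.0, -9.0, 0.0), palmar=(0.0, -9.0, -10.0),
                          dorsal=(0.0, 11.0, -10.0), head_palmar=(10.0, -7.0, -16.0))
        assert mru_3d(lm, FRAME) == pytest.approx(-10.0, abs=1e-9)

    def test_longitudinal_offset_does_not_inflate(self):
        """Axial-view metric: moving the head point distally changes nothing."""
        lm1 = landmark_set(head_palmar=(10.0, -11.0, -16.0))
        lm2 = landmark_set(head_palmar=(10.0, -11.0, -3.0))
        assert mru_3d(lm1, FRAME) == pytest.approx(mru_3d(lm2, FRAME), abs=1e-9)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            landmark_set(dorsal=(0.0, -9.0, -10.0))


class TestEpicentre:
    def test_midpoint_projection_is_zero(self):
        lm = landmark_set(epicentre=(10.0, 0.0, -6.0))
        assert epicentre_3d(lm, FRAME) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("y, expected", [(-9.0, 50.0), (9.0, -50.0)])
    def test_margin_endpoints_are_plus_minus_fifty(self, y, expected):
        lm = landmark_set(epicentre=(10.0, y, -6.0))
        assert epicentre_3d(lm, FRAME) == pytest.approx(expected, abs=1e-9)

    def test_gross_dislocation_warns(self):
        lm = landmark_set(epicentre=(10.0, -40.0, -6.0))
        with pytest.warns(RuntimeWarning, match="dislocation"):
            epicentre_3d(lm, FRAME)


class TestLinearResponse:
    """Imposed DRUJ translations produce the closed-form parameter response."""

    @pytest.mark.parametrize("t", [0.5, 1.0, 2.0, 4.0])
    def test_dorsal_translation_of_ulna(self, default_wrist, default_landmarks, t):
        lm = default_landmarks
        W = lm.notch_width
        base_mru, base_epi = mru_3d(lm, FRAME), epicentre_3d(lm, FRAME)
        shift = RigidTransform(np.eye(3), np.array([0, t, 0.0]))
        lm2 = lm.transformed_per_bone(RigidTransform.identity(), shift)
        expected = -100.0 * t / W
        assert mru_3d(lm2, FRAME) - base_mru == pytest.approx(expected, abs=1.0)
        assert epicentre_3d(lm2, FRAME) - base_epi == pytest.approx(expected, abs=1.0)

    def test_distal_translation_changes_only_uv(self, default_landmarks):
        lm = default_landmarks
        shift = RigidTransform(np.eye(3), np.array([0, 0, 3.0]))
        lm2 = lm.transformed_per_bone(RigidTransform.identity(), shift)
        uv0 = ulnar_variance_3d(lm.distal_ulnar_point, lm.sigmoid_distal_point, FRAME)
        uv1 = ulnar_variance_3d(lm2.distal_ulnar_point, lm2.sigmoid_distal_point, FRAME)
        assert uv1 - uv0 == pytest.approx(3.0, abs=1e-9)
        assert mru_3d(lm2, FRAME) == pytest.approx(mru_3d(lm, FRAME), abs=1e-9)
        assert epicentre_3d(lm2, FRAME) == pytest.approx(epicentre_3d(lm, FRAME), abs=1e-9)


class TestWristAngles:
    def test_parallel_axes_are_zero(self):
        for mv in (MovementLabel.FE, MovementLabel.RUD):
            assert wrist_angle(mv, FRAME, capitate_axis=[0, 0, 1.0]) == pytest.approx(0.0)

    def test_sagittal_tilt_decomposition(self):
        """30° dorsal tilt: +30° extension in FE, 0° in RUD."""
        th = np.deg2rad(30)
        cap = np.array([0.0, np.sin(th), np.cos(th)])
        assert wrist_angle(MovementLabel.FE, FRAME, capitate_axis=cap) == pytest.approx(30.0)
        assert wrist_angle(MovementLabel.RUD, FRAME, capitate_axis=cap) == pytest.approx(0.0)

    def test_flexion_and_ulnar_deviation_are_negative(self):
        th = np.deg2rad(20)
        flexed = np.array([0.0, -np.sin(th), np.cos(th)])
        assert wrist_angle(MovementLabel.FE, FRAME, capitate_axis=flexed) == pytest.approx(-20.0)
        ulnar = np.array([np.sin(th), 0.0, np.cos(th)])
        assert wrist_angle(MovementLabel.RUD, FRAME, capitate_axis=ulnar) == pytest.approx(-20.0)

    def test_ps_angle_from_ulnar_axis(self):
        """Rotating the radius frame about e_lon reads back as the UR angle."""
        ulna_axis = np.array([5.0, 0.0, 3.5])  # epicentre -> styloid
        assert wrist_angle(MovementLabel.PS, FRAME, ulna_axis=ulna_axis) == pytest.approx(0.0)
        rot = RigidTransform.from_axis_angle([0, 0, 1], np.deg2rad(-35.0))
        fr = FRAME.transformed(rot)
        assert wrist_angle(MovementLabel.PS, fr, ulna_axis=ulna_axis) == pytest.approx(35.0)

    def test_degenerate_projection_warns(self):
        with pytest.warns(RuntimeWarning, match="perpendicular"):
            wrist_angle(MovementLabel.FE, FRAME, capitate_axis=[1.0, 0.001, 0.0])

    def test_missing_axis_rejected(self):
        with pytest.raises(ValueError):
            wrist_angle(MovementLabel.FE, FRAME)


class TestRigidInvariance:
    def test_parameters_invariant_under_joint_motion(
        self, default_wrist, default_landmarks, rng
    ):
        from ulnakin import ulnocarpal_proximity

        w, lm = default_wrist, default_landmarks
        base = {
            "uv": ulnar_variance_3d(lm.distal_ulnar_point, lm.sigmoid_distal_point, w.frame),
            "mru": mru_3d(lm, w.frame),
            "epi": epicentre_3d(lm, w.frame),
            "ucp_l": ulnocarpal_proximity(w.meshes["ulna"], w.meshes["lunate"])[0],
        }
        for _ in range(10):
            tf = random_rigid(rng, max_translation=40)
            lm2 = lm.transformed(tf)
            fr2 = w.frame.transformed(tf)
            assert ulnar_variance_3d(
                lm2.distal_ulnar_point, lm2.sigmoid_distal_point, fr2
            ) == pytest.approx(base["uv"], abs=1e-6)
            assert mru_3d(lm2, fr2) == pytest.approx(base["mru"], abs=1e-6)
            assert epicentre_3d(lm2, fr2) == pytest.approx(base["epi"], abs=1e-6)
            d, *_ = ulnocarpal_proximity(
                w.meshes["ulna"].transformed(tf), w.meshes["lunate"].transformed(tf)
            )
            assert d == pytest.approx(base["ucp_l"], abs=1e-6)


class TestDeltaSeries:
    def _series(self, values, angles=None):
        n = len(values)
        return pd.DataFrame(
            {
                "frame": range(n),
                "time_s": np.arange(n) / 10,
                "movement": "FE",
                "wrist_angle_deg": angles if angles is not None else [0.0] + [10.0] * (n - 1),
                "uv3d_mm": values,
                "ucp_l_mm": 3.0,
                "ucp_t_mm": 7.0,
                "mru3d_pct": 0.0,
                "epi3d_pct": 0.0,
            }
        )

    def test_constant_series_gives_zero_deltas(self):
        out = delta_series(self._series([1.3] * 5))
        assert (out["d_uv3d_mm"] == 0.0).all()

    def test_hand_computed_deltas(self):
        out = delta_series(self._series([1.0, 1.5, 0.8]))
        np.testing.assert_allclose(out["d_uv3d_mm"], [0.0, 0.5, -0.2], atol=1e-12)

    def test_neutral_frame_is_min_abs_angle_ties_earliest(self):
        out = delta_series(self._series([2.0, 5.0, 9.0], angles=[4.0, -2.0, 2.0]))
        assert out.at[1, "d_uv3d_mm"] == 0.0
        # tie between |−2| and |2|: earliest (index 1) wins
        assert out.at[0, "d_uv3d_mm"] == pytest.approx(-3.0)

    def test_empty_series_rejected(self):
        empty = self._series([1.0]).iloc[0:0]
        with pytest.raises(ValueError, match="empty"):
            delta_series(empty)
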