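"""Anatomical landmark detection against construction ground truth."""

import numpy as np
import pytest

from ulnakin import (
    AnatomicalFrame,
    LandmarkSet,
    WristParams,
    detect_landmarks,
    generate_wrist,
)
from ulnakin.landmarks import (
    _LANDMARK_BONES,
    LandmarkDetectionError,
    distal_ulnar_articular_point,
    sigmoid_notch_region,
    ulnar_epicentre,
    ulnar_head_palmar_point,
)

from .conftest import make_cylinder, make_sphere, random_rigid


def landmark_errors(detected, truth):
    return {
        name: float(np.linalg.norm(getattr(detected, name) - getattr(truth, name)))
        for name in _LANDMARK_BONES
    }


class TestDefaultWrist:
    def test_all_landmarks_exact(self, default_wrist, default_landmarks):
        """On the default wrist every landmark sits on an exact mesh vertex."""
        errs = landmark_errors(default_landmarks, default_wrist.landmarks)
        assert max(errs.values()) < 1e-6, errs

    def test_notch_midpoint_definition(self, default_landmarks):
        np.testing.assert_allclose(
            default_landmarks.notch_midpoint,
            0.5 * (default_landmarks.palmar_margin + default_landmarks.dorsal_margin),
            atol=1e-12,
        )

    def test_determinism(self, default_wrist, default_landmarks):
        w = default_wrist
        again = detect_landmarks(w.meshes["radius"], w.meshes["ulna"], w.frame)
        for name in _LANDMARK_BONES:
            np.testing.assert_array_equal(getattr(again, name), getattr(default_landmarks, name))


def test_population_accuracy_within_1p5mm():
    """Across seeded anatomical variation, detection stays within 1.5 mm."""
    worst = 0.0
    for seed in range(100):
        w = generate_wrist(WristParams.randomized(seed))
        lm = detect_landmarks(w.meshes["radius"], w.meshes["ulna"], w.frame)
        errs = landmark_errors(lm, w.landmarks)
        worst = max(worst, max(errs.values()))
    assert worst < 1.5


def test_rigid_equivariance(default_wrist, default_landmarks, rng):
    """Landmarks of a rigidly moved wrist are the moved landmarks."""
    w = default_wrist
    tf = random_rigid(rng, max_translation=30)
    lm2 = detect_landmarks(
        w.meshes["radius"].transformed(tf),
        w.meshes["ulna"].transformed(tf),
        w.frame.transformed(tf),
    )
    expected = default_landmarks.transformed(tf)
    errs = landmark_errors(lm2, expected)
    assert max(errs.values()) < 1e-6


class TestDistalUlnarPoint:
    def test_styloid_excluded(self, default_wrist):
        """The styloid tip is more distal but removed by the cylinder."""
        w = default_wrist
        p = distal_ulnar_articular_point(w.meshes["ulna"], w.frame, 4.0)
        np.testing.assert_allclose(p, w.landmarks.distal_ulnar_point, atol=1e-9)
        tip = w.landmarks.ulnar_styloid_tip
        assert tip[2] > p[2]  # styloid really is more distal

    def test_zero_radius_on_styloidless_ulna_matches(self, default_wrist):
        """Pre-removing the styloid + radius 0 gives the intact-pipeline result."""
        from ulnakin import TriangleMesh
        from ulnakin.synthetic import capped_cylinder, uv_sphere

        w, p = default_wrist, default_wrist.params
        head_c = w.head_center
        Vh, Fh = uv_sphere(p.head_radius, head_c)
        Vs, Fs = capped_cylinder(
            p.shaft_radius, head_c[2] - p.shaft_length, head_c[2], (head_c[0], head_c[1])
        )
        styloidless = TriangleMesh(
            np.vstack([Vh, Vs]), np.vstack([Fh, Fs + Vh.shape[0]]), "ulna"
        )
        a = distal_ulnar_articular_point(styloidless, w.frame, 0.0)
        b = distal_ulnar_articular_point(w.meshes["ulna"], w.frame, 4.0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_cylinder_covering_everything_errors(self, default_wrist):
        w = default_wrist
        with pytest.raises(LandmarkDetectionError, match="cylinder"):
            distal_ulnar_articular_point(w.meshes["ulna"], w.frame, 1e3)


class TestSigmoidNotch:
    def test_region_centroid_near_carve_center(self, default_wrist):
        w = default_wrist
        region, distal = sigmoid_notch_region(w.meshes["radius"], w.frame)
        centroid = w.meshes["radius"].vertices[region].mean(axis=0)
        carve_center = np.array([0.0, 0.0, -w.params.notch_center_depth])
        assert np.linalg.norm(centroid - carve_center) < 1.0
        np.testing.assert_allclose(distal, w.landmarks.sigmoid_distal_point, atol=1e-9)

    def test_threshold_above_notch_curvature_errors(self, default_wrist):
        w = default_wrist
        with pytest.raises(LandmarkDetectionError, match="threshold"):
            sigmoid_notch_region(w.meshes["radius"], w.frame, curvature_threshold=5.0)

    def test_directional_reading_also_detects(self, default_wrist):
        """The longitudinal-section curvature switch finds the same notch."""
        w = default_wrist
        region, distal = sigmoid_notch_region(
            w.meshes["radius"], w.frame, curvature_kind="directional"
        )
        assert np.linalg.norm(distal - w.landmarks.sigmoid_distal_point) < 1.0


class TestUlnaAxisLandmarks:
    def test_capped_cylinder_epicentre(self):
        """Axis of a capped cylinder exits through the cap centre."""
        m = make_cylinder(10.0, -50.0, 50.0)
        p = ulnar_epicentre(m, AnatomicalFrame.canonical())
        np.testing.assert_allclose(p, [0, 0, 50.0], atol=1e-6)

    def test_synthetic_epicentre(self, default_wrist):
        w = default_wrist
        p = ulnar_epicentre(w.meshes["ulna"], w.frame)
        assert np.linalg.norm(p - w.landmarks.ulnar_epicentre) < 0.5


class TestHeadPalmarPoint:
    def test_hemisphere_closed_form(self):
        """Most palmar point of a spherical head: centre − r·e_pd."""
        c = np.array([5.0, 2.0, 40.0])
        m = make_sphere(10.0, c)
        fr = AnatomicalFrame.canonical()
        p = ulnar_head_palmar_point(m, fr, head_window_fraction=0.8,
                                    styloid_cylinder_radius=0.0)
        np.testing.assert_allclose(p, c - 10 * fr.e_pd, atol=1e-9)

    def test_empty_window_errors(self, default_wrist):
        w = default_wrist
        with pytest.raises(LandmarkDetectionError, match="window"):
            ulnar_head_palmar_point(w.meshes["ulna"], w.frame,
                                    head_window_fraction=0.01,
                                    styloid_cylinder_radius=100.0)


class TestMirrorConsistency:
    def test_left_wrist_normalized_matches_right_twin(self):
        from ulnakin import mirror_to_right

        wl = generate_wrist(WristParams(side="left"))
        wr = generate_wrist(WristParams(side="right"))
        normalized = {
            m.bone_label: m
            for m in mirror_to_right(list(wl.meshes.values()), wl.frame.origin, wl.frame.e_ru)
        }
        lm_l = detect_landmarks(normalized["radius"], normalized["ulna"], wl.frame)
        lm_r = detect_landmarks(wr.meshes["radius"], wr.meshes["ulna"], wr.frame)
        errs = landmark_errors(lm_l, lm_r)
        assert max(errs.values()) < 1e-6


class TestJsonRoundTrip:
    def test_exact_roundtrip(self, default_landmarks, tmp_path):
        path = tmp_path / "lm.json"
        default_landmarks.to_json(path)
        back = LandmarkSet.from_json(path)
        for name in _LANDMARK_BONES:
            np.testing.assert_array_equal(getattr(back, name), getattr(default_landmarks, name))
        assert back.source == "auto"

    def test_missing_landmark_errors(self, default_landmarks, tmp_path):
        import json

        path = tmp_path / "lm.json"
        default_landmarks.to_json(path)
        doc = json.loads(path.read_text())
        doc["landmarks"] = doc["landmarks"][:-2]
        path.write_text(json.dumps(doc))
        with pytest.raises(LandmarkDetectionError, match="missing"):
            LandmarkSet.from_json(path)
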