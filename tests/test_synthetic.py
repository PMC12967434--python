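"""The synthetic wrist generator: construction ground truth vs closed forms."""

import numpy as np
import pytest

from ulnakin import (
    MotionParams,
    MovementLabel,
    WristParams,
    detect_landmarks,
    generate_wrist,
    min_distance,
    simulate_motion,
    ulnar_variance_3d,
)
from ulnakin.synthetic import angle_sweep, degrade, make_targets


class TestGeneration:
    def test_all_bones_watertight(self, default_wrist):
        for bone, mesh in default_wrist.meshes.items():
            rep = mesh.validity_report()
            assert rep["watertight"], bone
            assert rep["n_open_edge_vertices"] == 0

    def test_prescribed_uv_recovered_by_detector(self):
        w = generate_wrist(WristParams(uv3d=1.7))
        lm = detect_landmarks(w.meshes["radius"], w.meshes["ulna"], w.frame)
        uv = ulnar_variance_3d(lm.distal_ulnar_point, lm.sigmoid_distal_point, w.frame)
        assert uv == pytest.approx(1.7, abs=0.1)

    def test_prescribed_carpal_gaps(self):
        w = generate_wrist(WristParams(gap_lunate=3.2, gap_triquetrum=6.9))
        d_l, *_ = min_distance(w.meshes["ulna"], w.meshes["lunate"])
        d_t, *_ = min_distance(w.meshes["ulna"], w.meshes["triquetrum"])
        assert d_l == pytest.approx(3.2, abs=0.05)
        assert d_t == pytest.approx(6.9, abs=0.05)

    def test_neutral_epicentre_centred(self, default_wrist):
        assert default_wrist.static_parameters["epi3d_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="deeper"):
            WristParams(notch_depth=7.0, notch_depth_semiaxis=6.0)
        with pytest.raises(ValueError, match="grid"):
            WristParams(lunate_polar_deg=12.3)

    def test_left_twin_parameters_match_right(self):
        wl = generate_wrist(WristParams(side="left"))
        wr = generate_wrist(WristParams(side="right"))
        for key in wr.static_parameters:
            assert wl.static_parameters[key] == pytest.approx(
                wr.static_parameters[key], abs=1e-6
            )

    def test_notch_curvature_exceeds_threshold(self):
        for seed in range(5):
            p = WristParams.randomized(seed)
            assert p.curvature_at_notch_pole > 0.1


class TestAngleSweep:
    def test_shape_and_coverage(self):
        th = angle_sweep((-40.0, 60.0), 21)
        assert len(th) == 21
        assert th[0] == 0.0 and th[-1] == 0.0
        assert th.max() == 60.0 and th.min() == -40.0

    def test_neutral_first_frame(self):
        th = angle_sweep((-25.0, 10.0), 15)
        assert np.argmin(np.abs(th)) == 0


class TestMotion:
    def test_zero_amplitude_constant_truth(self, default_wrist):
        motion = MotionParams(MovementLabel.FE, (0.0, 0.0), n_frames=4)
        _, truth = simulate_motion(default_wrist, motion)
        for col in ("uv3d_mm", "ucp_l_mm", "ucp_t_mm", "mru3d_pct", "epi3d_pct"):
            assert truth[col].nunique() == 1
            assert truth[col].iloc[0] == pytest.approx(
                default_wrist.static_parameters[col], abs=1e-9
            )

    def test_linear_dp_translation_gives_closed_form_epi_range(self, default_wrist):
        """Linear dorso-palmar excursion t_max over PS: epi range = 100·t_max/W."""
        W = default_wrist.params.notch_width
        t_max = 2.0
        motion = MotionParams(
            MovementLabel.PS, (-50.0, 50.0), n_frames=11,
            dp_translation=lambda th: -t_max * th / 100.0,
        )
        _, truth = simulate_motion(default_wrist, motion)
        rng_epi = truth["epi3d_pct"].max() - truth["epi3d_pct"].min()
        assert rng_epi == pytest.approx(100.0 * t_max / W, rel=0.01)

    def test_amplitude_validation(self):
        with pytest.raises(ValueError, match="feasible"):
            MotionParams(MovementLabel.PS, (-120.0, 120.0))
        with pytest.raises(ValueError, match="neutral"):
            MotionParams(MovementLabel.FE, (10.0, 60.0))

    def test_truth_delta_zero_at_neutral(self, default_wrist):
        _, truth = simulate_motion(default_wrist, MotionParams.default("RUD", n_frames=9))
        assert truth.at[0, "d_uv3d_mm"] == 0.0
        assert truth.at[0, "d_epi3d_pct"] == 0.0


class TestDegrade:
    @pytest.fixture(scope="class")
    def sequence(self, default_wrist):
        seq, _ = simulate_motion(default_wrist, MotionParams.default("FE", n_frames=3))
        return make_targets(seq)

    def test_zero_noise_is_identity(self, sequence):
        out = degrade(sequence, vertex_jitter_sigma=0.0, seed=1)
        for fr0, fr1 in zip(sequence.targets, out.targets):
            for bone in fr0:
                np.testing.assert_array_equal(fr0[bone].points, fr1[bone].points)

    def test_same_seed_identical_bits(self, sequence):
        a = degrade(sequence, 0.25, 0.1, seed=5)
        b = degrade(sequence, 0.25, 0.1, seed=5)
        for fr0, fr1 in zip(a.targets, b.targets):
            for bone in fr0:
                np.testing.assert_array_equal(fr0[bone].points, fr1[bone].points)

    def test_excessive_decimation_rejected(self, sequence):
        with pytest.raises(ValueError, match="100"):
            degrade(sequence, 0.0, 0.99, seed=0)

    def test_invalid_noise_rejected(self, sequence):
        with pytest.raises(ValueError, match="sigma"):
            degrade(sequence, -1.0, 0.0, seed=0)
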