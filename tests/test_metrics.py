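import numpy as np
import pytest

from kscore.errors import ParameterError
from kscore.frame import normalize_frame
from kscore.metrics import (
    GRAVITY,
    estimate_leg_length,
    isolated_metrics,
    max_torso_acceleration,
    max_torso_flexion,
    max_torso_velocity,
    peak_sva,
)
from kscore.pipeline import prepare_subject
from kscore.io import SubjectMeta
from kscore.preprocess import butterworth_filter, drop_first_repetition, segment_repetitions
from kscore.simulate import AnthroProfile, ImpairmentParams, generate_subject

from conftest import rep_from_arrays


def _static_pose_rep(n=30, flexion_deg=0.0, trunk_len=0.5, fs=30.0,
                     anterior_offset=None, hip_y=0.45):
    """A motionless skeleton holding one pose."""
    t = np.arange(n) / fs
    theta = np.radians(flexion_deg)
    d = np.array([0.0, np.cos(theta), np.sin(theta)])
    spine_base = np.tile([0.0, hip_y, 0.0], (n, 1))
    neck = spine_base + trunk_len * d
    shoulder_c = spine_base + 0.95 * trunk_len * d
    if anterior_offset is not None:
        shoulder_c = spine_base + np.array([0.0, 0.3, anterior_offset])
    by_name = {
        "neck": neck,
        "spine_mid": spine_base + 0.5 * trunk_len * d,
        "spine_base": spine_base,
        "shoulder_l": shoulder_c + np.array([0.15, 0, 0]),
        "shoulder_r": shoulder_c - np.array([0.15, 0, 0]),
        "hip_l": spine_base + np.array([0.1, -0.04, 0]),
        "hip_r": spine_base + np.array([-0.1, -0.04, 0]),
        "knee_l": np.tile([0.1, 0.25, 0.1], (n, 1)),
        "knee_r": np.tile([-0.1, 0.25, 0.1], (n, 1)),
        "ankle_l": np.tile([0.1, 0.05, 0.05], (n, 1)),
        "ankle_r": np.tile([-0.1, 0.05, 0.05], (n, 1)),
    }
    return rep_from_arrays(t, by_name)


class TestFlexion:
    def test_vertical_torso_is_zero(self):
        assert max_torso_flexion(_static_pose_rep(flexion_deg=0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_45_degree_lean(self):
        assert max_torso_flexion(_static_pose_rep(flexion_deg=45.0)) == pytest.approx(45.0, abs=1e-9)

    def test_recovers_commanded_peak_flexion(self, config):
        trial = generate_subject(
            AnthroProfile.from_height(1.70), ImpairmentParams(), noise_sd=0.0, seed=4
        )
        p = prepare_subject(SubjectMeta("s", "CTRL"), trial.recording, config)
        commanded = max(trial.commanded_peak_flexion_deg[1:])  # rep 1 dropped
        measured = max(max_torso_flexion(r) for r in p.repetitions)
        assert measured == pytest.approx(commanded, abs=1.0)


class TestSVA:
    def test_shoulder_above_hip_is_zero(self):
        rep = _static_pose_rep(anterior_offset=0.0)
        assert peak_sva(rep, height=1.7) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_normalized_by_height(self):
        rep = _static_pose_rep(anterior_offset=0.30)
        assert peak_sva(rep, height=1.70) == pytest.approx(0.17647, abs=1e-4)

    def test_linearity_in_offset(self):
        a = peak_sva(_static_pose_rep(anterior_offset=0.15), height=1.7)
        b = peak_sva(_static_pose_rep(anterior_offset=0.30), height=1.7)
        assert b == pytest.approx(2 * a)

    def test_missing_height_rejected(self):
        with pytest.raises(ParameterError):
            peak_sva(_static_pose_rep(), height=0.0)


class TestVelocityAcceleration:
    def test_static_pose_zero(self):
        rep = _static_pose_rep()
        np.testing.assert_allclose(max_torso_velocity(rep, 0.9), 0.0, atol=1e-12)
        np.testing.assert_allclose(max_torso_acceleration(rep), 0.0, atol=1e-12)

    def test_constant_vertical_velocity_closed_form(self):
        n, fs = 60, 30.0
        t = np.arange(n) / fs
        rep = _static_pose_rep(n=n)
        rise = 0.5 * t  # 0.5 m/s straight up on every landmark
        pos = rep.positions + np.tile(np.column_stack([0 * t, rise, 0 * t]), (1, 11))
        rep.positions = pos
        sup, ant = max_torso_velocity(rep, leg_length=0.9)
        assert sup == pytest.approx(0.5 / np.sqrt(GRAVITY * 0.9), abs=1e-3)
        assert ant == pytest.approx(0.0, abs=1e-9)

    def test_sinusoid_acceleration_analytic(self):
        n, fs, A, f = 300, 100.0, 0.05, 1.0
        t = np.arange(n) / fs
        rep = _static_pose_rep(n=n, fs=fs)
        wave = A * np.sin(2 * np.pi * f * t)
        rep.positions = rep.positions + np.tile(
            np.column_stack([0 * t, wave, 0 * t]), (1, 11)
        )
        sup, _ = max_torso_acceleration(rep)
        expect = A * (2 * np.pi * f) ** 2 / GRAVITY
        assert sup == pytest.approx(expect, rel=0.02)

    def test_recovers_generator_peak_velocity(self, config):
        trial = generate_subject(
            AnthroProfile.from_height(1.70), ImpairmentParams(), noise_sd=0.002, seed=5
        )
        rec = normalize_frame(butterworth_filter(trial.recording), config.frame_mode)
        reps = drop_first_repetition(segment_repetitions(rec))
        leg = trial.anthro.leg_length
        sup = max(max_torso_velocity(r, leg)[0] for r in reps)
        expect = trial.commanded_peak_sup_vel / np.sqrt(GRAVITY * leg)
        assert sup == pytest.approx(expect, rel=0.05)


class TestLegLength:
    def test_generator_segment_lengths_recovered(self):
        trial = generate_subject(
            AnthroProfile.from_height(1.70), ImpairmentParams(), noise_sd=0.0, seed=6
        )
        rec = trial.recording
        rep = rep_from_arrays(
            rec.timestamps, {n: rec.landmark(n) for n in rec.landmark_set}
        )
        expect = trial.anthro.thigh + trial.anthro.shank
        assert estimate_leg_length(rep) == pytest.approx(expect, abs=1e-6)

    def test_symmetric_skeleton_sides_equal_and_scaling(self):
        rep = _static_pose_rep()
        base = estimate_leg_length(rep)
        scaled = rep_from_arrays(
            rep.timestamps,
            {
                n: 1.1 * rep.positions[:, rep.column_labels.index(f"{n}_x"):
                                        rep.column_labels.index(f"{n}_x") + 3]
                for n in ("hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r")
            },
        )
        assert estimate_leg_length(scaled) == pytest.approx(1.1 * base, rel=1e-9)


class TestInvariances:
    def test_metrics_invariant_to_global_translation(self):
        rep = _static_pose_rep(flexion_deg=30.0, anterior_offset=None)
        shifted = rep_from_arrays(
            rep.timestamps,
            {
                n: rep.positions[:, 3 * i: 3 * i + 3] + np.array([1.0, -2.0, 3.0])
                for i, n in enumerate(
                    ("neck", "shoulder_l", "shoulder_r", "spine_mid", "spine_base",
                     "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r")
                )
            },
        )
        assert max_torso_flexion(shifted) == pytest.approx(max_torso_flexion(rep), abs=1e-9)
        assert peak_sva(shifted, 1.7) == pytest.approx(peak_sva(rep, 1.7), abs=1e-12)
        np.testing.assert_allclose(
            max_torso_velocity(shifted, 0.9), max_torso_velocity(rep, 0.9), atol=1e-12
        )

    def test_normalized_metrics_invariant_to_uniform_body_scaling(self, config):
        """Scaling geometry and height together leaves the unitless metrics
        unchanged (velocity scales with sqrt(leg), handled via leg length)."""
        trial = generate_subject(
            AnthroProfile.from_height(1.60), ImpairmentParams(), noise_sd=0.0, seed=7
        )
        meta = SubjectMeta("s", "CTRL", height=1.60)
        p = prepare_subject(meta, trial.recording, config)
        m1 = isolated_metrics(p.repetitions, height=1.60)
        sva_direct = max(peak_sva(r, 1.60) for r in p.repetitions)
        scale = 1.15
        rec2 = trial.recording
        rec2 = type(rec2)(
            subject_id="s2",
            timestamps=rec2.timestamps,
            positions=scale * rec2.positions,
            landmark_set=rec2.landmark_set,
            sampling_rate=rec2.sampling_rate,
        )
        p2 = prepare_subject(SubjectMeta("s2", "CTRL"), rec2, config)
        m2 = isolated_metrics(p2.repetitions, height=scale * 1.60)
        assert m2.max_torso_flexion_deg == pytest.approx(m1.max_torso_flexion_deg, rel=1e-6)
        assert m2.peak_sva_norm == pytest.approx(m1.peak_sva_norm, rel=1e-6)
        assert m2.leg_length == pytest.approx(scale * m1.leg_length, rel=1e-6)
        assert sva_direct >= 0


def test_isolated_metrics_estimates_height_when_absent(config):
    trial = generate_subject(
        AnthroProfile.from_height(1.80), ImpairmentParams(), noise_sd=0.0, seed=8
    )
    p = prepare_subject(SubjectMeta("s", "CTRL"), trial.recording, config)
    m = isolated_metrics(p.repetitions, height=None)
    assert m.height_used == pytest.approx(1.80, rel=0.12)
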