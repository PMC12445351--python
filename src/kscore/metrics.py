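"""Traditional isolated torso metrics.

Comparator measures computed per repetition and aggregated per subject:
maximum torso flexion angle (degrees, vs the vertical in the sagittal plane),
peak sagittal vertical alignment (shoulder-over-hip anterior offset divided by
height), and peak superior/anterior torso velocity and acceleration, each
normalized (velocity by sqrt(g * leg length), acceleration by g) so the
results are unitless.

Coordinates are expected in the anatomical frame (y superior, z anterior);
the torso center-of-mass proxy is the unweighted mean of the five trunk
landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .landmarks import AXES, TRUNK_NAMES
from .preprocess import Repetition

GRAVITY = 9.80665  # m/s^2


@dataclass
class IsolatedMetrics:
    subject_id: str
    max_torso_flexion_deg: float
    peak_sva_norm: float
    max_sup_vel_norm: float
    max_ant_vel_norm: float
    max_sup_acc_norm: float
    max_ant_acc_norm: float
    leg_length: float
    height_used: float


def _channel(rep: Repetition, landmark: str, axis: str) -> np.ndarray:
    label = f"{landmark}_{axis}"
    try:
        return rep.positions[:, rep.column_labels.index(label)]
    except ValueError:
        raise ParameterError(f"repetition lacks channel {label}") from None


def _landmark(rep: Repetition, name: str) -> np.ndarray:
    return np.column_stack([_channel(rep, name, a) for a in AXES])


def max_torso_flexion(rep: Repetition) -> float:
    """Peak angle (degrees) of the spine_base->neck axis from vertical,
    measured in the sagittal (superior-anterior) plane."""
    torso = _landmark(rep, "neck") - _landmark(rep, "spine_base")
    sup, ant = torso[:, 1], torso[:, 2]
    if np.any(np.hypot(sup, ant) < 1e-9):
        raise ParameterError("zero-length torso vector in the sagittal plane")
    angles = np.degrees(np.arctan2(ant, sup))
    return float(np.max(np.abs(angles)))


def peak_sva(rep: Repetition, height: float) -> float:
    """Max anterior shoulder-midpoint offset from the hip midpoint, / height."""
    if height is None or not height > 0:
        raise ParameterError("peak_sva needs a positive subject height")
    shoulder = 0.5 * (_landmark(rep, "shoulder_l") + _landmark(rep, "shoulder_r"))
    hip = 0.5 * (_landmark(rep, "hip_l") + _landmark(rep, "hip_r"))
    anterior = shoulder[:, 2] - hip[:, 2]
    return float(np.max(anterior) / height)


def _torso_com(rep: Repetition) -> np.ndarray:
    return np.mean([_landmark(rep, n) for n in TRUNK_NAMES], axis=0)


def _gradient(values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Central differences on the original clock, one-sided at the ends."""
    if t.size < 3:
        raise ParameterError("need at least 3 frames to differentiate")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("degenerate timestamps")
    return np.gradient(values, t, axis=0)


def max_torso_velocity(rep: Repetition, leg_length: float) -> tuple[float, float]:
    """(superior, anterior) peak torso COM speed, / sqrt(g * leg length)."""
    if not leg_length > 0:
        raise ParameterError("leg_length must be positive")
    vel = _gradient(_torso_com(rep), rep.timestamps)
    norm = np.sqrt(GRAVITY * leg_length)
    return (
        float(np.max(np.abs(vel[:, 1])) / norm),
        float(np.max(np.abs(vel[:, 2])) / norm),
    )


def max_torso_acceleration(rep: Repetition) -> tuple[float, float]:
    """(superior, anterior) peak torso COM acceleration magnitude, / g."""
    com = _torso_com(rep)
    acc = _gradient(_gradient(com, rep.timestamps), rep.timestamps)
    return (
        float(np.max(np.abs(acc[:, 1])) / GRAVITY),
        float(np.max(np.abs(acc[:, 2])) / GRAVITY),
    )


def estimate_leg_length(rep: Repetition) -> float:
    """Hip->knee + knee->ankle distance at the first (seated rest) frame,
    averaged over sides."""
    lengths = []
    for side in ("l", "r"):
        hip = _landmark(rep, f"hip_{side}")[0]
        knee = _landmark(rep, f"knee_{side}")[0]
        ankle = _landmark(rep, f"ankle_{side}")[0]
        lengths.append(np.linalg.norm(hip - knee) + np.linalg.norm(knee - ankle))
    return float(np.mean(lengths))


def isolated_metrics(
    reps: list[Repetition],
    height: float | None = None,
    leg_length: float | None = None,
) -> IsolatedMetrics:
    """Per-subject metrics: per-repetition values averaged across repetitions.

    If ``height`` is missing it is estimated from the skeleton (leg length
    plus trunk length at the first frame, divided by the standing fraction
    those segments represent, ~0.78 of stature).
    """
    if not reps:
        raise ParameterError("no repetitions")
    leg = leg_length if leg_length else float(np.mean([estimate_leg_length(r) for r in reps]))
    if height is None or not height > 0:
        trunk = float(
            np.mean(
                [
                    np.linalg.norm(
                        _landmark(r, "neck")[0] - _landmark(r, "spine_base")[0]
                    )
                    for r in reps
                ]
            )
        )
        height = (leg + trunk) / 0.78
    per_rep = np.array(
        [
            [
                max_torso_flexion(r),
                peak_sva(r, height),
                *max_torso_velocity(r, leg),
                *max_torso_acceleration(r),
            ]
            for r in reps
        ]
    )
    flex, sva, sv, av, sa, aa = per_rep.mean(axis=0)
    return IsolatedMetrics(
        subject_id=reps[0].subject_id,
        max_torso_flexion_deg=float(flex),
        peak_sva_norm=float(sva),
        max_sup_vel_norm=float(sv),
        max_ant_vel_norm=float(av),
        max_sup_acc_norm=float(sa),
        max_ant_acc_norm=float(aa),
        leg_length=float(leg),
        height_used=float(height),
    )
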