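"""Anatomical frame estimation.

Markerless capture expresses positions in an arbitrary camera frame. All
downstream logic (segmentation on the superior neck coordinate, sagittal-plane
metrics) needs a consistent anatomical frame, so preprocessing re-expresses
every recording in a frame estimated from the data itself:

* lateral axis: time-averaged direction from right to left across the
  shoulder and hip landmark pairs;
* superior axis: average trunk direction (spine_base -> neck) over the frames
  of greatest leg extension (standing), orthogonalized against the lateral
  axis;
* anterior axis: their cross product, with the sign fixed so the trunk leans
  toward +anterior at peak flexion.

Every step is equivariant under global rotation, translation and positive
scaling of the input, which is what makes the whole scoring pipeline
similarity-invariant. With ``mode="fixed"`` the configured world axes
(y superior, z anterior) are trusted instead and no re-expression happens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError
from .io import TrialRecording

#: Quantile of leg extension above which frames count as "standing".
_STANDING_QUANTILE = 0.95


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal, right-handed basis: rows are (lateral, superior, anterior)."""

    basis: np.ndarray  # 3x3, rows x/y/z-hat
    origin: np.ndarray  # length 3

    def express(self, points: np.ndarray) -> np.ndarray:
        """Coordinates of T x 3 world points in this frame."""
        return (points - self.origin) @ self.basis.T


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DataValidationError("degenerate geometry while estimating frame")
    return v / n


def estimate_frame(rec: TrialRecording) -> AnatomicalFrame:
    """Estimate the anatomical frame of a sit-to-stand recording."""
    neck = rec.landmark("neck")
    spine_base = rec.landmark("spine_base")
    lateral = np.mean(
        (rec.landmark("shoulder_l") - rec.landmark("shoulder_r"))
        + (rec.landmark("hip_l") - rec.landmark("hip_r")),
        axis=0,
    )
    x_hat = _unit(lateral)

    hip_mid = 0.5 * (rec.landmark("hip_l") + rec.landmark("hip_r"))
    ankle_mid = 0.5 * (rec.landmark("ankle_l") + rec.landmark("ankle_r"))
    extension = np.linalg.norm(hip_mid - ankle_mid, axis=1)
    standing = extension >= np.quantile(extension, _STANDING_QUANTILE)
    trunk = neck - spine_base
    up = np.mean(trunk[standing], axis=0)
    up = up - (up @ x_hat) * x_hat
    y_hat = _unit(up)
    z_hat = np.cross(x_hat, y_hat)

    # Fix the anterior sign from the trunk lean at peak flexion (the frame of
    # largest trunk angle from vertical).
    cosang = (trunk @ y_hat) / np.linalg.norm(trunk, axis=1)
    lean_frame = int(np.argmin(cosang))
    if trunk[lean_frame] @ z_hat < 0:
        x_hat, z_hat = -x_hat, -z_hat

    basis = np.vstack([x_hat, y_hat, z_hat])
    origin = np.mean(spine_base, axis=0)
    return AnatomicalFrame(basis=basis, origin=origin)


def reexpress(rec: TrialRecording, frame: AnatomicalFrame) -> TrialRecording:
    """Return the recording with every landmark expressed in ``frame``."""
    L = len(rec.landmark_set)
    pos = rec.positions.reshape(rec.n_frames, L, 3)
    new = (pos - frame.origin) @ frame.basis.T
    return TrialRecording(
        subject_id=rec.subject_id,
        timestamps=rec.timestamps.copy(),
        positions=new.reshape(rec.n_frames, 3 * L),
        landmark_set=rec.landmark_set,
        sampling_rate=rec.sampling_rate,
    )


def normalize_frame(rec: TrialRecording, mode: str = "auto") -> TrialRecording:
    """Re-express a recording in its estimated anatomical frame.

    mode="auto" estimates the frame from the data (similarity-equivariant);
    mode="fixed" returns the recording unchanged, trusting the stored axes.
    """
    if mode == "fixed":
        return rec
    if mode != "auto":
        raise ValueError(f"unknown frame mode {mode!r}")
    return reexpress(rec, estimate_frame(rec))
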