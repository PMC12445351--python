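"""Filtering, repetition segmentation, temporal normalization, standardization.

This stage turns a raw multi-repetition sit-to-stand recording into one
standardized, time-normalized matrix per repetition: zero-phase low-pass
filtering, threshold-based extraction of the seated-to-standing transitions,
min-max rescaling of time onto a 0..100 % grid, and per-channel z-scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, SegmentationError, StaticRecordingError
from .io import TrialRecording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types


@dataclass
class Repetition:
    """One seated-to-standing transition cut out of a recording."""

    subject_id: str
    index: int  # 1-based repetition number within the trial
    timestamps: np.ndarray  # original clock, seconds
    positions: np.ndarray  # T x (3*L), meters
    column_labels: list[str]

    @property
    def transition_duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class MotionMatrix:
    """Standardized, time-normalized channel matrix of one repetition.

    ``values`` is T_grid x J, dimensionless; each retained column has zero
    mean and unit variance (ddof=1). ``time_grid`` spans exactly 0..100.
    """

    subject_id: str
    values: np.ndarray
    time_grid: np.ndarray
    column_labels: list[str]
    dropped_columns: list[str] = field(default_factory=list)
    repetition_index: int = 0
    transition_duration: float = float("nan")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the threshold-based transition detector."""

    signal_landmark: str = "neck"
    plateau_frac: float = 0.05  # band half-width, fraction of seated-standing span
    dwell_s: float = 0.2  # time the signal must stay inside the band
    min_displacement_m: float = 0.10  # below this span the recording is static
    min_prominence_frac: float = 0.10  # dip prominence floor, fraction of span


# ---------------------------------------------------------------------------
# filtering


def butterworth_filter(
    rec: TrialRecording, cutoff: float = 5.0, order: int = 2
) -> TrialRecording:
    """Zero-phase (forward-backward) low-pass Butterworth filter per channel.

    The bidirectional pass squares the magnitude response and cancels the
    phase, so a constant passes unchanged and plateaus keep their level.
    """
    nyquist = rec.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyquist:g}) Hz"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=rec.sampling_rate, output="sos")
    padlen = 3 * (2 * order + 1)
    if rec.n_frames <= padlen:
        raise ParameterError(
            f"recording too short to filter: need more than {padlen} samples, "
            f"got {rec.n_frames}"
        )
    filtered = sps.sosfiltfilt(sos, rec.positions, axis=0)
    return replace_positions(rec, filtered)


def replace_positions(rec: TrialRecording, positions: np.ndarray) -> TrialRecording:
    return TrialRecording(
        subject_id=rec.subject_id,
        timestamps=rec.timestamps.copy(),
        positions=np.asarray(positions, dtype=float),
        landmark_set=rec.landmark_set,
        sampling_rate=rec.sampling_rate,
    )


# ---------------------------------------------------------------------------
# segmentation


def detect_transitions(
    y: np.ndarray,
    timestamps: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> list[tuple[int, int]]:
    """Find (onset, offset) sample indices of each seated-to-standing rise.

    Seated and standing levels are the 10th/90th percentiles of the superior
    signal; an upward crossing of their midpoint marks a rise, whose onset is
    the last prominent local minimum before the crossing (the forward-lean
    dip) and whose offset is the first sample from which the signal dwells
    inside a plateau band around the standing level.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    seated, standing = np.percentile(y, [10.0, 90.0])
    span = standing - seated
    if span < params.min_displacement_m:
        raise StaticRecordingError(
            f"vertical span {span * 1e3:.1f} mm below the "
            f"{params.min_displacement_m * 1e3:.0f} mm minimum: static recording?"
        )
    threshold = 0.5 * (seated + standing)
    above = y >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        raise SegmentationError("no repetitions: signal never crosses threshold")

    dt = float(np.median(np.diff(t)))
    dwell_n = max(1, int(round(params.dwell_s / dt)))
    band = params.plateau_frac * span
    minima, _ = sps.find_peaks(-y, prominence=params.min_prominence_frac * span)

    events: list[tuple[int, int]] = []
    prev_end = 0
    for c in crossings:
        if c < prev_end:  # crossing inside a previously accepted transition
            continue
        window_min = minima[(minima >= prev_end) & (minima < c)]
        onset = int(window_min[-1]) if window_min.size else int(prev_end + np.argmin(y[prev_end:c]))
        inside = np.abs(y - standing) <= band
        offset = None
        for f in range(c, len(y) - dwell_n + 1):
            if inside[f : f + dwell_n].all():
                offset = f
                break
        if offset is None:
            logger.warning("rise at sample %d never settles on the plateau; skipped", c)
            continue
        events.append((onset, offset))
        prev_end = offset + 1
    if not events:
        raise SegmentationError("no repetitions: no rise settled on the standing plateau")
    return events


def segment_repetitions(
    rec: TrialRecording, params: SegmentationParams = SegmentationParams()
) -> list[Repetition]:
    """Cut a filtered recording into seated-to-standing repetitions."""
    y = rec.channel(params.signal_landmark, "y")
    events = detect_transitions(y, rec.timestamps, params)
    labels = rec.landmark_set.column_labels()
    reps = []
    for k, (onset, offset) in enumerate(events, start=1):
        reps.append(
            Repetition(
                subject_id=rec.subject_id,
                index=k,
                timestamps=rec.timestamps[onset : offset + 1].copy(),
                positions=rec.positions[onset : offset + 1].copy(),
                column_labels=list(labels),
            )
        )
    return reps


def drop_first_repetition(reps: list[Repetition]) -> list[Repetition]:
    """Discard repetition 1 (habituation); keep indices >= 2."""
    kept = [r for r in reps if r.index >= 2]
    if not kept:
        logger.warning("fewer than 2 repetitions: nothing left after dropping the first")
    return kept


# ---------------------------------------------------------------------------
# temporal normalization and standardization


def normalize_time(rep: Repetition, grid_size: int = 101) -> MotionMatrix:
    """Min-max rescale time to 0..100 % and resample onto a uniform grid.

    Positions are linearly interpolated; the grid endpoints are exactly 0
    and 100 so the first/last frames are preserved.
    """
    if rep.n_frames < 2:
        raise ParameterError("repetition needs at least 2 samples to normalize")
    if grid_size < 2:
        raise ParameterError("grid_size must be >= 2")
    t = rep.timestamps
    duration = t[-1] - t[0]
    if duration <= 0:
        raise ParameterError("zero-duration repetition")
    percent = (t - t[0]) / duration * 100.0
    grid = np.linspace(0.0, 100.0, grid_size)
    values = np.empty((grid_size, rep.positions.shape[1]))
    for j in range(rep.positions.shape[1]):
        values[:, j] = np.interp(grid, percent, rep.positions[:, j])
    return MotionMatrix(
        subject_id=rep.subject_id,
        values=values,
        time_grid=grid,
        column_labels=list(rep.column_labels),
        repetition_index=rep.index,
        transition_duration=rep.transition_duration,
    )


#: Columns whose sd falls below this fraction of the median column sd are
#: treated as constant and dropped instead of amplifying noise.
_SD_FLOOR_FRAC = 1e-8


def standardize(m: MotionMatrix) -> MotionMatrix:
    """Center each channel over time and scale to unit variance (ddof=1).

    Near-constant channels (sd below 1e-8 of the median channel sd) are
    dropped and recorded in ``dropped_columns``.
    """
    if m.values.shape[0] < 3:
        raise ParameterError("need at least 3 time points to standardize")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    floor = _SD_FLOOR_FRAC * np.median(sd)
    keep = sd > floor
    if not keep.any():
        raise ParameterError("all channels are (near-)constant; nothing to standardize")
    dropped = [c for c, k in zip(m.column_labels, keep) if not k]
    if dropped:
        logger.warning("%s rep %d: dropped near-constant channels %s",
                       m.subject_id, m.repetition_index, dropped)
    values = (m.values[:, keep] - mean[keep]) / sd[keep]
    return MotionMatrix(
        subject_id=m.subject_id,
        values=values,
        time_grid=m.time_grid.copy(),
        column_labels=[c for c, k in zip(m.column_labels, keep) if k],
        dropped_columns=list(m.dropped_columns) + dropped,
        repetition_index=m.repetition_index,
        transition_duration=m.transition_duration,
    )


def restrict_columns(m: MotionMatrix, columns: list[str]) -> MotionMatrix:
    """Project a (pre-standardization) matrix onto a shared column set."""
    missing = [c for c in columns if c not in m.column_labels]
    if missing:
        raise ParameterError(f"matrix lacks required columns {missing}")
    idx = [m.column_labels.index(c) for c in columns]
    return replace(
        m,
        values=m.values[:, idx],
        column_labels=list(columns),
        dropped_columns=[c for c in m.column_labels if c not in columns]
        + list(m.dropped_columns),
    )
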