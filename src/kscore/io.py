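"""Readers, writers and validation for trial recordings and subject manifests.

Canonical trial format is a long-header CSV: a ``time_s`` column plus one
``<landmark>_<axis>`` column per scalar channel (e.g. ``neck_y``), meters.
Column order in the file is free; parsing normalizes it to the landmark-set
order. Manifests are CSVs with one row per (subject, trial file).
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, SchemaError
from .landmarks import CANONICAL, LandmarkSet

logger = logging.getLogger(__name__)

GROUPS = ("CTRL", "PATIENT")

#: Allowed relative deviation of any timestamp step from the nominal period.
_DT_TOLERANCE = 0.20


@dataclass
class TrialRecording:
    """Raw (or filtered) timestamped 3D positions of one recording.

    positions is T x (3*L), landmark-major then x, y, z, meters.
    """

    subject_id: str
    timestamps: np.ndarray
    positions: np.ndarray
    landmark_set: LandmarkSet = field(default=CANONICAL)
    sampling_rate: float = 30.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        validate_recording(self)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def channel(self, landmark: str, axis: str) -> np.ndarray:
        return self.positions[:, self.landmark_set.channel_index(landmark, axis)]

    def landmark(self, name: str) -> np.ndarray:
        """T x 3 trajectory of one landmark."""
        return self.positions[:, self.landmark_set.slice_of(name)]


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    group: str
    sex: str = "unknown"
    age: float | None = None
    height: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.height is not None and not self.height > 0:
            raise DataValidationError(
                f"height must be positive, got {self.height} for {self.subject_id}"
            )


@dataclass(frozen=True)
class ManifestEntry:
    meta: SubjectMeta
    trial_path: Path


def validate_recording(rec: TrialRecording) -> None:
    t, pos = rec.timestamps, rec.positions
    if t.ndim != 1 or pos.ndim != 2 or pos.shape[0] != t.shape[0]:
        raise DataValidationError("timestamps and positions must share T rows")
    if pos.shape[1] != rec.landmark_set.n_channels:
        raise DataValidationError(
            f"expected {rec.landmark_set.n_channels} position columns, "
            f"got {pos.shape[1]}"
        )
    if not np.all(np.isfinite(t)):
        raise DataValidationError("non-finite timestamp")
    bad = np.argwhere(~np.isfinite(pos))
    if bad.size:
        r, c = bad[0]
        label = rec.landmark_set.column_labels()[c]
        raise DataValidationError(f"non-finite position at row {r} column {label}")
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise DataValidationError(f"timestamps not strictly increasing at row {i + 1}")
        nominal = 1.0 / rec.sampling_rate
        if np.any(np.abs(dt - nominal) > _DT_TOLERANCE * nominal):
            i = int(np.argmax(np.abs(dt - nominal) > _DT_TOLERANCE * nominal))
            raise DataValidationError(
                f"timestamp spacing {dt[i]:.4f}s at row {i + 1} deviates more than "
                f"{_DT_TOLERANCE:.0%} from nominal {nominal:.4f}s"
            )


def _infer_sampling_rate(timestamps: np.ndarray) -> float:
    if timestamps.size < 2:
        return 30.0
    return 1.0 / float(np.median(np.diff(timestamps)))


def read_trial(
    path: str | Path,
    landmark_set: LandmarkSet = CANONICAL,
    column_map: Mapping[str, str] | None = None,
    subject_id: str | None = None,
) -> TrialRecording:
    """Read one trial CSV into a validated :class:`TrialRecording`.

    Parameters
    ----------
    path:
        CSV with header ``time_s`` plus ``<landmark>_<axis>`` columns.
    column_map:
        Optional adapter mapping canonical column names to the names actually
        present in the file.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    column_map = dict(column_map or {})

    def col(name: str) -> str:
        return column_map.get(name, name)

    required = ["time_s"] + landmark_set.column_labels()
    for name in required:
        if col(name) not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col(name)!r}")

    t = df[col("time_s")].to_numpy(dtype=float)
    pos = df[[col(c) for c in landmark_set.column_labels()]].to_numpy(dtype=float)
    nan_rows = np.argwhere(pd.isna(df[[col(c) for c in required]]).to_numpy())
    if nan_rows.size:
        raise DataValidationError(f"{path.name}: NaN cell at data row {int(nan_rows[0][0])}")
    return TrialRecording(
        subject_id=subject_id or path.stem,
        timestamps=t,
        positions=pos,
        landmark_set=landmark_set,
        sampling_rate=_infer_sampling_rate(t),
    )


def write_trial(rec: TrialRecording, path: str | Path) -> None:
    """Write a recording back to the canonical CSV layout (lossless round-trip)."""
    df = pd.DataFrame(rec.positions, columns=rec.landmark_set.column_labels())
    df.insert(0, "time_s", rec.timestamps)
    df.to_csv(path, index=False, float_format="%.17g")


_MANIFEST_COLUMNS = ["subject_id", "group", "sex", "age", "height_m", "bmi", "trial_path"]


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a subject manifest CSV into ``ManifestEntry`` records.

    Trial paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for name in _MANIFEST_COLUMNS:
        if name not in df.columns:
            raise SchemaError(f"{path.name}: missing manifest column {name!r}")
    seen: set[tuple[str, str]] = set()
    entries: list[ManifestEntry] = []
    for _, row in df.iterrows():
        key = (str(row["subject_id"]), str(row["trial_path"]))
        if key in seen:
            raise DataValidationError(f"duplicate manifest row for {key}")
        seen.add(key)

        def opt(name: str) -> float | None:
            v = row[name]
            if pd.isna(v):
                logger.warning("manifest %s: %s missing for %s", path.name, name, key[0])
                return None
            return float(v)

        sex = row["sex"]
        meta = SubjectMeta(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            sex="unknown" if pd.isna(sex) else str(sex),
            age=opt("age"),
            height=opt("height_m"),
            bmi=opt("bmi"),
        )
        trial = Path(str(row["trial_path"]))
        if not trial.is_absolute():
            trial = path.parent / trial
        entries.append(ManifestEntry(meta=meta, trial_path=trial))
    return entries


def write_manifest(entries: Iterable[ManifestEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        m = e.meta
        rows.append(
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "sex": m.sex,
                "age": m.age,
                "height_m": m.height,
                "bmi": m.bmi,
                "trial_path": str(e.trial_path),
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)


SCORE_COLUMNS = [
    "subject_id",
    "group",
    "k_score",
    "deviation_factor",
    "mean_transition_time",
    "time_ratio",
    "n_reps",
]


def write_scores(results: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write per-subject score records with a stable column order.

    Extra keys in the records are appended after the canonical columns.
    """
    df = pd.DataFrame(list(results))
    cols = [c for c in SCORE_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in SCORE_COLUMNS
    ]
    if df.empty:
        df = pd.DataFrame(columns=SCORE_COLUMNS)
        cols = SCORE_COLUMNS
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
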