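"""The Kinematic Composite Score chain.

Per repetition, PCA is applied to the standardized T x J motion matrix
X (scores P = X W, all K = J components kept). Score configurations are
treated as shapes (T_grid points in K dimensions): a control cohort defines a
GPA consensus, every subject is full-Procrustes fitted to that frozen
consensus, and the eigenvalue-weighted sum of the aligned score trajectories
forms the K-Profile. The deviation factor DF is the integral over the 0..100 %
grid of the absolute difference from the control-average K-Profile, and

    K-Score = 100 - (1/alpha) * (T / T_control) * DF

with alpha calibrated once so the control cohort's mean score hits a target
(default 94). Anchoring every subject to the *control-only* consensus is what
makes a subject's score independent of which other subjects are in the batch.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .preprocess import MotionMatrix
from .procrustes import ProcrustesTransform, generalized_procrustes, procrustes_fit

_STANDARDIZED_MEAN_TOL = 1e-9
_STANDARDIZED_SD_TOL = 1e-3


# ---------------------------------------------------------------------------
# per-subject PCA


@dataclass
class SubjectPCA:
    """Complete (K = J) PCA of one repetition's motion matrix."""

    subject_id: str
    scores: np.ndarray  # T_grid x K
    loadings: np.ndarray  # J x K, orthonormal columns
    eigenvalues: np.ndarray  # length K, non-increasing
    time_grid: np.ndarray
    column_labels: list[str]
    repetition_index: int = 0
    transition_duration: float = float("nan")

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def subject_pca(m: MotionMatrix) -> SubjectPCA:
    """Eigendecomposition of the channel covariance of a standardized matrix.

    Components are sorted by eigenvalue (descending). Sign convention: each
    loading column's largest-magnitude entry is positive (first such entry on
    ties), and the basis is then canonicalized to det(W) = +1 by flipping the
    last (least influential) column if needed, so score configurations of
    similar subjects never differ by an improper transform.
    """
    X = m.values
    if X.shape[0] < 2:
        raise ParameterError("need more than one time point for PCA")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.max(np.abs(mean)) > _STANDARDIZED_MEAN_TOL or np.max(np.abs(sd - 1)) > _STANDARDIZED_SD_TOL:
        raise ParameterError("subject_pca expects a standardized MotionMatrix")
    cov = (X.T @ X) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    W = evecs[:, order]
    # deterministic signs
    flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    flip[flip == 0] = 1.0
    W = W * flip
    if np.linalg.det(W) < 0:
        W[:, -1] *= -1.0
    return SubjectPCA(
        subject_id=m.subject_id,
        scores=X @ W,
        loadings=W,
        eigenvalues=evals,
        time_grid=m.time_grid.copy(),
        column_labels=list(m.column_labels),
        repetition_index=m.repetition_index,
        transition_duration=m.transition_duration,
    )


# ---------------------------------------------------------------------------
# alignment and profiles


@dataclass
class AlignedScores:
    """A subject's PC scores after full-Procrustes fit onto the reference."""

    subject_id: str
    values: np.ndarray  # T_grid x K
    transform: ProcrustesTransform
    residual: float
    time_grid: np.ndarray
    repetition_index: int = 0


@dataclass
class KProfile:
    """Eigenvalue-weighted aligned score trajectory on the 0..100 % grid."""

    subject_id: str
    time_grid: np.ndarray
    values: np.ndarray
    n_reps_averaged: int = 1


@dataclass
class ControlReference:
    """Frozen control-cohort reference every subject is scored against."""

    consensus_scores: np.ndarray  # T_grid x K, t=0 row at the origin
    mean_profile: np.ndarray  # control-average K-Profile
    time_grid: np.ndarray
    mean_transition_time: float
    alpha: float
    n_controls: int
    column_labels: list[str]
    alpha_target: float = 94.0

    @property
    def k(self) -> int:
        return self.consensus_scores.shape[1]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "consensus_scores": self.consensus_scores.tolist(),
            "mean_profile": self.mean_profile.tolist(),
            "time_grid": self.time_grid.tolist(),
            "mean_transition_time": self.mean_transition_time,
            "alpha": self.alpha,
            "alpha_target": self.alpha_target,
            "n_controls": self.n_controls,
            "column_labels": self.column_labels,
        }
        payload = json.dumps(doc, sort_keys=True)
        doc["provenance_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ControlReference":
        doc = json.loads(Path(path).read_text())
        return cls(
            consensus_scores=np.asarray(doc["consensus_scores"], dtype=float),
            mean_profile=np.asarray(doc["mean_profile"], dtype=float),
            time_grid=np.asarray(doc["time_grid"], dtype=float),
            mean_transition_time=float(doc["mean_transition_time"]),
            alpha=float(doc["alpha"]),
            n_controls=int(doc["n_controls"]),
            column_labels=list(doc["column_labels"]),
            alpha_target=float(doc.get("alpha_target", 94.0)),
        )


@dataclass
class KScoreResult:
    subject_id: str
    deviation_factor: float
    transition_time: float
    time_ratio: float
    k_score: float
    n_reps: int = 1


def align_subject(p: SubjectPCA, ref: ControlReference) -> AlignedScores:
    """Single-pass full Procrustes fit of one score configuration onto the
    frozen control consensus (never onto an all-subject consensus)."""
    if p.scores.shape != ref.consensus_scores.shape:
        raise ParameterError(
            f"score configuration {p.scores.shape} does not match the "
            f"reference {ref.consensus_scores.shape}"
        )
    tf, residual = procrustes_fit(p.scores, ref.consensus_scores)
    return AlignedScores(
        subject_id=p.subject_id,
        values=tf.apply(p.scores),
        transform=tf,
        residual=residual,
        time_grid=p.time_grid.copy(),
        repetition_index=p.repetition_index,
    )


def compute_kprofile(aligned: AlignedScores, eigenvalues: np.ndarray) -> KProfile:
    """Pointwise eigenvalue-weighted sum of the aligned score trajectories."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if eigenvalues.shape[0] != aligned.values.shape[1]:
        raise ParameterError("eigenvalue count must equal the component count")
    return KProfile(
        subject_id=aligned.subject_id,
        time_grid=aligned.time_grid.copy(),
        values=aligned.values @ eigenvalues,
        n_reps_averaged=1,
    )


def aggregate_repetitions(
    profiles: Sequence[KProfile], durations: Sequence[float]
) -> tuple[KProfile, float]:
    """Average per-repetition profiles pointwise; mean repetition duration."""
    if not profiles:
        raise ParameterError("no repetition profiles to aggregate")
    if len(profiles) != len(durations):
        raise ParameterError("profiles and durations must pair up")
    grid = profiles[0].time_grid
    for p in profiles[1:]:
        if not np.array_equal(p.time_grid, grid):
            raise ParameterError("repetition profiles are on different grids")
    mean_profile = KProfile(
        subject_id=profiles[0].subject_id,
        time_grid=grid.copy(),
        values=np.mean([p.values for p in profiles], axis=0),
        n_reps_averaged=len(profiles),
    )
    return mean_profile, float(np.mean(durations))


def deviation_factor(profile: KProfile, ref: ControlReference) -> float:
    """Trapezoidal integral of |profile - control mean| over the 0..100 grid."""
    if not np.array_equal(profile.time_grid, ref.time_grid):
        raise ParameterError("profile grid does not match the reference grid")
    return float(
        np.trapezoid(np.abs(profile.values - ref.mean_profile), ref.time_grid)
    )


def kscore(
    df: float,
    transition_time: float,
    ref: ControlReference,
    subject_id: str = "",
    n_reps: int = 1,
) -> KScoreResult:
    """Transform a deviation factor into the 100-anchored composite score."""
    if ref.alpha <= 0:
        raise ParameterError("alpha must be positive")
    if transition_time <= 0 or ref.mean_transition_time <= 0:
        raise ParameterError("transition times must be positive")
    ratio = transition_time / ref.mean_transition_time
    score = 100.0 - (1.0 / ref.alpha) * ratio * df
    return KScoreResult(
        subject_id=subject_id,
        deviation_factor=float(df),
        transition_time=float(transition_time),
        time_ratio=float(ratio),
        k_score=float(score),
        n_reps=n_reps,
    )


def calibrate_alpha(
    dfs: Sequence[float],
    transition_times: Sequence[float],
    mean_transition_time: float,
    target_mean_score: float = 94.0,
) -> float:
    """Choose alpha so the control cohort's mean K-Score equals the target.

    alpha = mean over controls of (T_i / T_mean) * DF_i, divided by
    (100 - target); substituting back into the score gives the target exactly.
    """
    if not 0 < target_mean_score < 100:
        raise ParameterError("target mean score must lie strictly between 0 and 100")
    dfs = np.asarray(dfs, dtype=float)
    times = np.asarray(transition_times, dtype=float)
    if dfs.shape != times.shape or dfs.size == 0:
        raise ParameterError("need matching, non-empty DF and time sequences")
    weighted = (times / mean_transition_time) * dfs
    if np.all(weighted == 0):
        raise ParameterError("no deviation to calibrate: all control DFs are zero")
    return float(np.mean(weighted) / (100.0 - target_mean_score))


# ---------------------------------------------------------------------------
# reference building and subject scoring


def subject_profile(
    reps: Sequence[SubjectPCA], ref_consensus: np.ndarray
) -> tuple[KProfile, float]:
    """Align each repetition to a consensus, weight, and average.

    Helper shared by reference building and scoring so controls and patients
    go through the identical path.
    """
    profiles: list[KProfile] = []
    durations: list[float] = []
    for p in reps:
        tf, _ = procrustes_fit(p.scores, ref_consensus)
        aligned = AlignedScores(
            subject_id=p.subject_id,
            values=tf.apply(p.scores),
            transform=tf,
            residual=0.0,
            time_grid=p.time_grid.copy(),
            repetition_index=p.repetition_index,
        )
        profiles.append(compute_kprofile(aligned, p.eigenvalues))
        durations.append(p.transition_duration)
    return aggregate_repetitions(profiles, durations)


def build_control_reference(
    control_reps: Sequence[Sequence[SubjectPCA]],
    alpha_target: float = 94.0,
    gpa_tol: float = 1e-9,
    gpa_max_iter: int = 100,
) -> ControlReference:
    """Build the frozen scoring reference from a control cohort.

    ``control_reps`` holds, per control subject, that subject's per-repetition
    PCAs (all on one grid with one shared column set). GPA runs over every
    control repetition's score configuration; the converged consensus is
    re-anchored so its t=0 row (the resting position) sits at the origin.
    """
    if len(control_reps) < 2:
        raise ParameterError("need at least 2 control subjects to build a reference")
    all_reps = [p for reps in control_reps for p in reps]
    shapes = {p.scores.shape for p in all_reps}
    if len(shapes) != 1:
        raise ParameterError(f"control score configurations differ in shape: {shapes}")
    grid = all_reps[0].time_grid
    labels = list(all_reps[0].column_labels)

    consensus, _, _ = generalized_procrustes(
        [p.scores for p in all_reps], tol=gpa_tol, max_iter=gpa_max_iter
    )
    consensus = consensus - consensus[0]  # resting position (t = 0) at the origin

    profiles: list[KProfile] = []
    times: list[float] = []
    for reps in control_reps:
        prof, t_mean = subject_profile(reps, consensus)
        profiles.append(prof)
        times.append(t_mean)
    mean_profile = np.mean([p.values for p in profiles], axis=0)
    mean_time = float(np.mean(times))

    stub = ControlReference(
        consensus_scores=consensus,
        mean_profile=mean_profile,
        time_grid=grid.copy(),
        mean_transition_time=mean_time,
        alpha=1.0,
        n_controls=len(control_reps),
        column_labels=labels,
        alpha_target=alpha_target,
    )
    dfs = [deviation_factor(p, stub) for p in profiles]
    stub.alpha = calibrate_alpha(dfs, times, mean_time, alpha_target)
    return stub


def score_subject(reps: Sequence[SubjectPCA], ref: ControlReference) -> KScoreResult:
    """Full scoring chain for one subject against a frozen reference."""
    if not reps:
        raise ParameterError("no repetitions to score")
    for p in reps:
        if p.scores.shape != ref.consensus_scores.shape:
            raise ParameterError(
                f"{p.subject_id}: configuration {p.scores.shape} does not match "
                f"reference {ref.consensus_scores.shape}"
            )
    profile, t_mean = subject_profile(reps, ref.consensus_scores)
    df = deviation_factor(profile, ref)
    return kscore(df, t_mean, ref, subject_id=reps[0].subject_id, n_reps=len(reps))
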