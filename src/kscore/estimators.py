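"""scikit-learn-style estimators over the scoring pipeline.

``KScoreScorer`` is the package's front door: ``fit`` on healthy-control
recordings builds the frozen reference (GPA consensus, control-average
profile and transition time, calibrated alpha) and ``predict`` scores any
subjects against it, one at a time, so a subject's score never depends on who
else is in the batch. ``PopulationPCAModel`` (re-exported from
:mod:`kscore.population`) is the across-patient baseline with the opposite
property.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import FilterParams, RunConfig
from .core import ControlReference, KScoreResult
from .errors import ParameterError
from .io import SubjectMeta, TrialRecording
from .population import PopulationPCAModel
from .preprocess import SegmentationParams
from .pipeline import fit_reference, prepare_subject, score_prepared

__all__ = ["KScoreScorer", "PopulationPCAModel"]


def _as_pairs(X) -> list[tuple[SubjectMeta, TrialRecording]]:
    pairs = []
    for i, item in enumerate(X):
        if isinstance(item, TrialRecording):
            meta = SubjectMeta(subject_id=item.subject_id or f"subject_{i}", group="PATIENT")
            pairs.append((meta, item))
        else:
            meta, rec = item
            pairs.append((meta, rec))
    return pairs


class KScoreScorer(BaseEstimator):
    """Composite movement-deviation scorer.

    Parameters mirror the pipeline configuration: zero-phase Butterworth
    filter (``cutoff_hz``, ``filter_order``), anatomical ``frame_mode``
    ("auto" or "fixed"), the 0..100 % ``grid_size``, segmentation tunables,
    GPA convergence settings and the control-mean score ``alpha_target``.

    Attributes
    ----------
    reference_ : ControlReference
        Frozen control reference after :meth:`fit`.
    n_controls_ : int
    """

    def __init__(
        self,
        cutoff_hz: float = 5.0,
        filter_order: int = 2,
        frame_mode: str = "auto",
        grid_size: int = 101,
        alpha_target: float = 94.0,
        signal_landmark: str = "neck",
        plateau_frac: float = 0.05,
        dwell_s: float = 0.2,
        gpa_tol: float = 1e-9,
        gpa_max_iter: int = 100,
    ):
        self.cutoff_hz = cutoff_hz
        self.filter_order = filter_order
        self.frame_mode = frame_mode
        self.grid_size = grid_size
        self.alpha_target = alpha_target
        self.signal_landmark = signal_landmark
        self.plateau_frac = plateau_frac
        self.dwell_s = dwell_s
        self.gpa_tol = gpa_tol
        self.gpa_max_iter = gpa_max_iter

    def _config(self) -> RunConfig:
        return RunConfig(
            filter=FilterParams(cutoff_hz=self.cutoff_hz, order=self.filter_order),
            segmentation=SegmentationParams(
                signal_landmark=self.signal_landmark,
                plateau_frac=self.plateau_frac,
                dwell_s=self.dwell_s,
            ),
            frame_mode=self.frame_mode,
            grid_size=self.grid_size,
            alpha_target=self.alpha_target,
            gpa_tol=self.gpa_tol,
            gpa_max_iter=self.gpa_max_iter,
        )

    def fit(self, X, y=None) -> "KScoreScorer":
        """Build the control reference from healthy-control recordings.

        ``X`` is a sequence of ``TrialRecording`` or ``(SubjectMeta,
        TrialRecording)`` pairs; all are treated as controls.
        """
        pairs = _as_pairs(X)
        if len(pairs) < 2:
            raise ParameterError("need at least 2 control recordings to fit")
        cfg = self._config()
        prepared = [prepare_subject(m, r, cfg) for m, r in pairs]
        self.reference_ = fit_reference(prepared, cfg)
        self.n_controls_ = len(pairs)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_"):
            raise ParameterError("KScoreScorer is not fitted yet; call fit() first")

    def score_subject(self, recording: TrialRecording, meta: SubjectMeta | None = None) -> KScoreResult:
        """Score one subject against the frozen reference."""
        self._check_fitted()
        meta = meta or SubjectMeta(subject_id=recording.subject_id, group="PATIENT")
        cfg = self._config()
        return score_prepared(prepare_subject(meta, recording, cfg), self.reference_)

    def predict(self, X) -> np.ndarray:
        """K-Scores for a batch of recordings (independent per subject)."""
        return np.array([self.score_subject(rec, meta).k_score for meta, rec in _as_pairs(X)])

    def transform(self, X) -> pd.DataFrame:
        """Full per-subject result table (score, DF, time ratio, reps used)."""
        rows = []
        for meta, rec in _as_pairs(X):
            r = self.score_subject(rec, meta)
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "k_score": r.k_score,
                    "deviation_factor": r.deviation_factor,
                    "mean_transition_time": r.transition_time,
                    "time_ratio": r.time_ratio,
                    "n_reps": r.n_reps,
                }
            )
        return pd.DataFrame(rows)

    def save_reference(self, path) -> None:
        self._check_fitted()
        self.reference_.to_json(path)

    @classmethod
    def from_reference(cls, reference: ControlReference, **params) -> "KScoreScorer":
        """Rehydrate a scorer around a previously fitted reference."""
        est = cls(**params)
        est.reference_ = reference
        est.n_controls_ = reference.n_controls
        return est
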