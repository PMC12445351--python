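"""Across-patient PCA baseline.

The conventional approach the composite score is compared against: each
repetition's time-normalized 11-landmark pose sequence is per-frame
Procrustes-aligned to a reference pose (the control-average seated pose at
t = 0), flattened into one long row (time-major), and a single PCA is fitted
across all rows after column-wise centering and scaling. The per-trial PC
scores are the baseline metric; unlike the composite score they change
whenever rows are added or removed, which is exactly the sample-size
dependence this module exists to demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .errors import ParameterError
from .preprocess import MotionMatrix
from .procrustes import generalized_procrustes, procrustes_fit


@dataclass
class PopulationPCAResult:
    scores: np.ndarray  # n_rows x m
    loadings: np.ndarray  # (T_grid * J) x m
    explained_variance_ratio: np.ndarray  # length m
    m: int
    row_index: list[tuple[str, int]]  # (subject_id, repetition index)


def _frames(m: MotionMatrix) -> np.ndarray:
    """T_grid x L x 3 poses from a (non-standardized) motion matrix."""
    if len(m.column_labels) % 3:
        raise ParameterError("motion matrix channels are not landmark triplets")
    return m.values.reshape(m.values.shape[0], -1, 3)


def reference_pose(controls: list[MotionMatrix]) -> np.ndarray:
    """Control-average seated pose at t = 0 (GPA consensus of first frames)."""
    first = [_frames(m)[0] for m in controls]
    if len(first) < 2:
        return first[0] - first[0].mean(axis=0)
    consensus, _, _ = generalized_procrustes(first)
    return consensus


def frame_procrustes_align(m: MotionMatrix, ref_pose: np.ndarray) -> MotionMatrix:
    """Full-Procrustes fit (translation, proper rotation, scale) of every
    frame's landmark configuration onto the reference pose."""
    frames = _frames(m)
    if frames.shape[1:] != ref_pose.shape:
        raise ParameterError(
            f"pose shape {frames.shape[1:]} does not match reference {ref_pose.shape}"
        )
    aligned = np.empty_like(frames)
    for i, f in enumerate(frames):
        tf, _ = procrustes_fit(f, ref_pose, allow_reflection=False)
        aligned[i] = tf.apply(f)
    return MotionMatrix(
        subject_id=m.subject_id,
        values=aligned.reshape(frames.shape[0], -1),
        time_grid=m.time_grid.copy(),
        column_labels=list(m.column_labels),
        dropped_columns=list(m.dropped_columns),
        repetition_index=m.repetition_index,
        transition_duration=m.transition_duration,
    )


def vectorize(m: MotionMatrix) -> np.ndarray:
    """Flatten to one (T_grid * J) row, time-major: all channels of the first
    grid point, then the second, and so on."""
    return m.values.reshape(-1)


def unvectorize(row: np.ndarray, t_grid: int) -> np.ndarray:
    return np.asarray(row).reshape(t_grid, -1)


def fit_population_pca(rows: np.ndarray, retention: float = 0.90) -> "PopulationPCAModel":
    """Convenience wrapper over :class:`PopulationPCAModel`."""
    return PopulationPCAModel(retention=retention).fit(rows)


class PopulationPCAModel:
    """sklearn-style estimator for the across-patient PCA baseline.

    Parameters
    ----------
    retention:
        Fraction of variance the retained components must reach; ``m`` is the
        smallest component count whose cumulative explained variance ratio is
        at or above it.
    """

    def __init__(self, retention: float = 0.90):
        self.retention = retention

    def get_params(self, deep: bool = True) -> dict:
        return {"retention": self.retention}

    def set_params(self, **params) -> "PopulationPCAModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "PopulationPCAModel":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ParameterError("need a 2-D matrix with at least 2 rows")
        if not 0 < self.retention <= 1:
            raise ParameterError("retention must lie in (0, 1]")
        self.scaler_ = StandardScaler()
        Z = self.scaler_.fit_transform(X)
        if not np.any(self.scaler_.var_ > 0):
            raise ParameterError("all columns are constant: zero variance to analyze")
        pca = PCA(svd_solver="full", random_state=0)
        scores = pca.fit_transform(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        m = int(np.searchsorted(cum, self.retention) + 1)
        m = min(m, scores.shape[1])
        # deterministic signs: largest-magnitude loading entry positive
        comps = pca.components_[:m]
        flip = np.sign(comps[np.arange(m), np.argmax(np.abs(comps), axis=1)])
        flip[flip == 0] = 1.0
        self.loadings_ = (comps * flip[:, None]).T
        self.scores_ = scores[:, :m] * flip[None, :]
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[:m]
        self.n_components_ = m
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new rows into the fitted component space."""
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        return Z @ self.loadings_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def result(self, row_index: list[tuple[str, int]] | None = None) -> PopulationPCAResult:
        n = self.scores_.shape[0]
        return PopulationPCAResult(
            scores=self.scores_,
            loadings=self.loadings_,
            explained_variance_ratio=self.explained_variance_ratio_,
            m=self.n_components_,
            row_index=row_index or [("", i) for i in range(n)],
        )
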