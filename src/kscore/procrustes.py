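"""Ordinary and generalized Procrustes analysis.

Used in two places: aligning per-subject PC score configurations (T_grid
points in K dimensions) to the control consensus, and aligning 11-point 3D
body poses to a reference pose for the across-patient PCA baseline. The
rotation solution is the standard orthogonal (polar/SVD) one; reflections are
forbidden by default (determinant +1) to preserve chirality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, ParameterError


@dataclass(frozen=True)
class ProcrustesTransform:
    """Similarity transform ``x -> scale * (x @ rotation.T) + translation``."""

    scale: float
    rotation: np.ndarray  # d x d, orthogonal, det +1 unless reflections allowed
    translation: np.ndarray  # length d

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (points @ self.rotation.T) + self.translation


def procrustes_fit(
    source: np.ndarray,
    target: np.ndarray,
    allow_reflection: bool = False,
    with_scale: bool = True,
) -> tuple[ProcrustesTransform, float]:
    """Full Procrustes fit of ``source`` onto ``target`` (same n x d shape).

    Returns the optimal similarity transform and the residual (Frobenius
    distance between the transformed source and the target).
    """
    A = np.asarray(source, dtype=float)
    B = np.asarray(target, dtype=float)
    if A.shape != B.shape:
        raise ParameterError(f"shape mismatch: {A.shape} vs {B.shape}")
    a_mean = A.mean(axis=0)
    b_mean = B.mean(axis=0)
    Ac = A - a_mean
    Bc = B - b_mean
    norm_a = np.linalg.norm(Ac)
    if norm_a < 1e-15:
        raise ParameterError("degenerate source configuration (zero size)")
    M = Ac.T @ Bc
    U, sv, Vt = np.linalg.svd(M)
    d = np.ones(len(sv))
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        d[-1] = -1.0
    Q = (U * d) @ Vt  # source is multiplied on the right: Ac @ Q
    trace = float(np.sum(sv * d))
    scale = trace / float(norm_a**2) if with_scale else 1.0
    if scale <= 0:
        # Pathological anti-correlated configurations; fall back to unit scale.
        scale = 1.0
    rotation = Q.T
    translation = b_mean - scale * (a_mean @ Q)
    tf = ProcrustesTransform(scale=scale, rotation=rotation, translation=translation)
    residual = float(np.linalg.norm(tf.apply(A) - B))
    return tf, residual


def generalized_procrustes(
    configs: list[np.ndarray],
    tol: float = 1e-9,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> tuple[np.ndarray, list[ProcrustesTransform], list[float]]:
    """Iterative GPA: align all configurations to an evolving consensus.

    The consensus is centered and normalized to unit Frobenius size each
    round (the usual guard against shrinkage under full-Procrustes scaling)
    and iteration stops when it moves less than ``tol``.

    Returns (consensus, transforms, residuals) with transforms/residuals from
    the final single-pass fit of each configuration onto the converged
    consensus.
    """
    if len(configs) < 2:
        raise ParameterError("GPA needs at least 2 configurations")
    shapes = {c.shape for c in configs}
    if len(shapes) != 1:
        raise ParameterError(f"configurations differ in shape: {sorted(shapes)}")

    def canon(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=0)
        return xc / np.linalg.norm(xc)

    consensus = canon(configs[0])
    history: list[float] = []
    for _ in range(max_iter):
        aligned = [procrustes_fit(c, consensus, allow_reflection)[0].apply(c) for c in configs]
        new = canon(np.mean(aligned, axis=0))
        # The consensus orientation/sign is only defined up to the fit; anchor
        # the sign to the previous iterate for a monotone convergence measure.
        change = float(np.linalg.norm(new - consensus))
        history.append(change)
        consensus = new
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations; "
            f"last changes {['%.3e' % h for h in history[-5:]]}"
        )
    fits = [procrustes_fit(c, consensus, allow_reflection) for c in configs]
    return consensus, [f[0] for f in fits], [f[1] for f in fits]
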