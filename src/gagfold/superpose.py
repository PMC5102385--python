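"""Rigid-body superposition (Kabsch) and the SSM-style Q-score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuperpositionResult", "kabsch_superpose", "q_score", "R0_DEFAULT"]

#: Q-score distance scale in Å (the SSM convention).
R0_DEFAULT = 3.0


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation, det = +1
    translation: np.ndarray  # Å; maps centred B onto A as A ≈ B @ R.T + t
    rmsd: float  # Å
    degenerate: bool = False  # collinear/rank-deficient input


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``coords_b`` onto ``coords_a``.

    Uses the SVD form of the Kabsch algorithm with the determinant sign
    correction, so reflections are never returned and the RMSD is the global
    minimum over proper rigid motions.

    Raises
    ------
    ValueError
        If fewer than 3 point pairs are supplied ("underdetermined").
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shapes")
    n = len(a)
    if n < 3:
        raise ValueError("underdetermined: need at least 3 point pairs")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    # rank-deficient cross-covariance -> rotation about the degenerate axis
    # is unconstrained; flag rather than fail
    degenerate = np.linalg.matrix_rank(h, tol=1e-8 * max(s[0], 1.0)) < 2
    b_fit = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((b_fit - a0) ** 2, axis=1))))
    translation = ca - cb @ rot.T
    return SuperpositionResult(rot, translation, rmsd, degenerate)


def q_score(n_align: int, rmsd: float, n1: int, n2: int, r0: float = R0_DEFAULT) -> float:
    """SSM quality score ``Q = n_align² / ((1 + (rmsd/R0)²) · n1 · n2)``.

    Q = 1 exactly for a full-length self-superposition at zero RMSD and
    decays toward 0 as RMSD grows or coverage shrinks.
    """
    if n1 <= 0 or n2 <= 0 or n_align <= 0:
        raise ValueError("counts must be positive")
    if n_align > min(n1, n2):
        raise ValueError("n_align cannot exceed min(n1, n2)")
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    return n_align**2 / ((1.0 + (rmsd / r0) ** 2) * n1 * n2)
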