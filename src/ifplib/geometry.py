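"""Rigid-body superposition (Kabsch) and RMSD.

This is the numerical core shared by fragment-pair clustering and complex
assembly: least-squares optimal proper rotation + translation between
corresponded point sets, with mirror reflections explicitly forbidden
(protein chirality must be preserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "kabsch_fit", "apply_transform", "rmsd_after_fit",
           "batch_rmsd"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``y = R x + t``.

    ``rotation`` is a 3x3 orthonormal matrix with det +1; ``translation``
    is in Angstrom, like every coordinate in this package.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (mirror) rejected")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def apply_transform(t: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Apply ``y_i = R x_i + t`` to an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    return coords @ t.rotation.T + t.translation


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper superposition of ``mobile`` onto ``target``.

    Points correspond positionally (i-th to i-th). Returns the transform
    minimizing the RMSD over proper rotations and translations, and that
    RMSD (A). Degenerate (collinear, coincident) point sets still return a
    minimizing transform; the sign of the smallest singular value is
    corrected so det(R) = +1 always.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # fully degenerate covariance; pick the proper branch
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    # rmsd via the singular-value identity, clipped against round-off
    e0 = (P0 ** 2).sum() + (Q0 ** 2).sum()
    msd = max(e0 - 2.0 * (S[0] + S[1] + d * S[2]), 0.0) / n
    return RigidTransform(R, t), float(np.sqrt(msd))


def rmsd_after_fit(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD (A) between two corresponded point sets after optimal
    superposition."""
    return kabsch_fit(a, b)[1]


def batch_rmsd(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Superposition RMSD for many point-set pairs at once.

    ``mobile`` and ``target`` are (m, n, 3) stacks; pair k is
    ``mobile[k]`` vs ``target[k]``. Returns an (m,) array of RMSDs. Used
    for all-vs-all fragment-pair distance matrices and window/entry scans,
    where looping over individual 3x3 SVDs would dominate runtime.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 3 or P.shape[2] != 3:
        raise ValueError("mobile and target must both be (m, n, 3)")
    m, n, _ = P.shape
    if m == 0:
        return np.zeros(0)
    P0 = P - P.mean(axis=1, keepdims=True)
    Q0 = Q - Q.mean(axis=1, keepdims=True)
    H = np.einsum("kni,knj->kij", P0, Q0)
    S = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    sgn = np.where(det < 0, -1.0, 1.0)
    trace = S[:, 0] + S[:, 1] + sgn * S[:, 2]
    e0 = (P0 ** 2).sum(axis=(1, 2)) + (Q0 ** 2).sum(axis=(1, 2))
    msd = np.maximum(e0 - 2.0 * trace, 0.0) / n
    return np.sqrt(msd)
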