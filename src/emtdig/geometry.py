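"""Coordinate frames and rigid registration.

All positions are Cartesian coordinates in millimeters; all frames are
right-handed.  The head coordinate frame follows the Neuromag/MEGIN
convention built from the three cardinal landmarks (nasion, left and right
preauricular points):

* +x runs from LPA toward RPA;
* the origin lies on the LPA-RPA segment at the foot of the perpendicular
  dropped from the nasion;
* +y runs from the origin toward the nasion;
* +z = x cross y (up, out of the top of the head).

Rigid registration is the Kabsch/Umeyama least-squares fit (rotation +
translation, no scaling, determinant +1 enforced) and an iterative
closest-point (ICP) loop built on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform",
    "FiducialSet",
    "DegenerateFiducialsError",
    "head_frame_from_fiducials",
    "fit_rigid",
    "icp_register",
]

_ORTHO_TOL = 1e-9


class DegenerateFiducialsError(ValueError):
    """Raised when the three cardinal points are collinear or duplicated."""


def _as_points(pts) -> np.ndarray:
    a = np.asarray(pts, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[-1] != 3:
        raise ValueError(f"expected points of shape (..., 3), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("points must have finite coordinates")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.3e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class FiducialSet:
    """Nasion, LPA and RPA positions (mm) in some source frame."""

    nasion: np.ndarray
    lpa: np.ndarray
    rpa: np.ndarray

    def __post_init__(self):
        for name in ("nasion", "lpa", "rpa"):
            object.__setattr__(self, name, _as_points(getattr(self, name))[0])

    def triangle_area(self) -> float:
        return 0.5 * float(
            np.linalg.norm(np.cross(self.rpa - self.lpa, self.nasion - self.lpa))
        )


def head_frame_from_fiducials(fids: FiducialSet) -> RigidTransform:
    """Source -> head transform from the three cardinal landmarks.

    After the transform, LPA and RPA lie on the x-axis (LPA at negative x),
    the nasion lies on the +y axis, and the origin is the foot of the
    perpendicular from the nasion onto the LPA-RPA segment.
    """
    if fids.triangle_area() <= 1e-6:
        raise DegenerateFiducialsError(
            "cardinal points are collinear or duplicated "
            f"(triangle area {fids.triangle_area():.3e} mm^2)"
        )
    ex = fids.rpa - fids.lpa
    ex = ex / np.linalg.norm(ex)
    # foot of the perpendicular from nasion onto the LPA-RPA line
    origin = fids.lpa + np.dot(fids.nasion - fids.lpa, ex) * ex
    ey = fids.nasion - origin
    ey = ey / np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    R = np.vstack([ex, ey, ez])  # rows = head-frame axes in source coords
    return RigidTransform(R, -R @ origin)


class UnderdeterminedError(ValueError):
    """Raised when a rigid fit has too few or collinear correspondences."""


def fit_rigid(source_pts, target_pts) -> tuple[RigidTransform, float]:
    """Least-squares rigid alignment (Kabsch) of paired point sets.

    Returns the transform mapping source onto target and the residual
    root-mean-square distance (mm) after alignment.  No scaling; a
    determinant of -1 in the optimal orthogonal matrix is corrected by
    flipping the smallest-singular-value axis.
    """
    src = _as_points(source_pts)
    tgt = _as_points(target_pts)
    if src.shape != tgt.shape:
        raise ValueError(f"point sets differ in shape: {src.shape} vs {tgt.shape}")
    n = src.shape[0]
    if n < 3:
        raise UnderdeterminedError(f"need >= 3 correspondences, got {n}")
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    src0, tgt0 = src - sc, tgt - tc
    # collinearity check: rank of the centered source configuration
    if np.linalg.matrix_rank(src0, tol=1e-9 * max(1.0, np.abs(src0).max())) < 2:
        raise UnderdeterminedError("source points are collinear")
    H = src0.T @ tgt0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    T = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((T.apply(src) - tgt) ** 2, axis=1))))
    return T, rmsd


def icp_register(
    cloud,
    reference_cloud,
    init: RigidTransform | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[RigidTransform, float]:
    """Iterative closest point: align ``cloud`` onto ``reference_cloud``.

    Point-to-point nearest-neighbour matching (ties resolved toward the
    lowest reference index), rigid Kabsch update each iteration, stopping
    when the RMSD improves by less than ``tol`` mm or after ``max_iter``
    iterations.  The returned RMSD is the best seen, and the sequence of
    accepted RMSDs is non-increasing.
    """
    src = _as_points(cloud)
    ref = _as_points(reference_cloud)
    if src.size == 0 or ref.size == 0:
        raise ValueError("ICP requires non-empty point clouds")
    T = init if init is not None else RigidTransform.identity()
    tree = cKDTree(ref)
    moved = T.apply(src)
    _, idx = tree.query(moved)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref[idx]) ** 2, axis=1))))
    best_T, best_rmsd = T, rmsd
    for _ in range(max_iter):
        T_new, _ = fit_rigid(src, ref[idx])
        moved = T_new.apply(src)
        _, idx = tree.query(moved)
        rmsd_new = float(np.sqrt(np.mean(np.sum((moved - ref[idx]) ** 2, axis=1))))
        if rmsd_new < best_rmsd:
            best_T, best_rmsd = T_new, rmsd_new
        if rmsd - rmsd_new < tol:
            break
        rmsd = rmsd_new
    return best_T, best_rmsd
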