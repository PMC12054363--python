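"""Rigid-body superposition and rotation decomposition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateFitError, InvalidRotationError

__all__ = ["SuperpositionResult", "superpose", "rotation_angle_axis"]


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid fit: x_fixed ≈ R @ x_moving + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    angle: float  # degrees
    axis: np.ndarray  # unit vector

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def superpose(moving: np.ndarray, fixed: np.ndarray, correspondence=None) -> SuperpositionResult:
    """Least-squares proper-rotation superposition (Kabsch).

    Parameters
    ----------
    moving, fixed
        (N, 3) Cartesian coordinate arrays.
    correspondence
        Optional sequence of (moving_index, fixed_index) pairs; by default
        points correspond positionally.

    Only proper rotations (det = +1) are considered, so a mirrored set fits
    with a nonzero rmsd rather than through an improper operation.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if correspondence is not None:
        idx = np.asarray(list(correspondence), dtype=int)
        moving = moving[idx[:, 0]]
        fixed = fixed[idx[:, 1]]
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise DegenerateFitError("moving and fixed must be matching (N, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateFitError(f"need at least 3 corresponding points, got {n}")
    mc = moving - moving.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)
    # collinearity check: rank of either centred set < 2
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2 or np.linalg.matrix_rank(fc, tol=1e-8) < 2:
        raise DegenerateFitError("point set is collinear; rotation is underdetermined")
    rot, _ = Rotation.align_vectors(fc, mc)  # proper rotation by construction
    matrix = rot.as_matrix()
    translation = fixed.mean(axis=0) - matrix @ moving.mean(axis=0)
    diff = fc - mc @ matrix.T
    rmsd = float(np.sqrt((diff**2).sum() / n))
    angle, axis = rotation_angle_axis(matrix)
    return SuperpositionResult(matrix, translation, rmsd, angle, axis)


def rotation_angle_axis(rotation: np.ndarray, tol: float = 1e-6):
    """Angle (degrees, in [0, 180]) and unit axis of a proper rotation.

    The angle is acos((trace − 1)/2); the axis is the +1 eigenvector,
    oriented to match the rotation's sense (for angle 0 the axis is the
    arbitrary convention (0, 0, 1)).
    """
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=tol) or np.linalg.det(r) < 0:
        raise InvalidRotationError("input is not a proper orthonormal rotation matrix")
    rot = Rotation.from_matrix(r)
    rotvec = rot.as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < 1e-12:
        return 0.0, np.array([0.0, 0.0, 1.0])
    axis = rotvec / np.linalg.norm(rotvec)
    return angle, axis
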