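"""Coordinate unification between sensors.

Covers the three registration primitives a multi-camera capture rig needs:
chaining board-based extrinsics (camera -> calibration board -> world),
closed-form rigid alignment of matched point sets (A = R B + T, for
cross-calibrating an optical tracker against a depth camera), and
point-to-point ICP refinement of overlapping clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import FrameCloud
from .errors import (
    DegenerateConfigurationError,
    InvalidTransformError,
    RegistrationError,
)

__all__ = ["RigidTransform", "board_to_world", "solve_rigid", "icp_register"]


@dataclass
class RigidTransform:
    """Proper rigid motion: ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-9:
            raise InvalidTransformError(
                f"rotation is not orthonormal (max |R^T R - I| = {err:.3e})"
            )
        if np.linalg.det(self.rotation) < 0:
            raise InvalidTransformError("rotation has determinant -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_dict(self) -> dict:
        return {
            "R": [float(x) for x in self.rotation.ravel()],
            "t": [float(x) for x in self.translation],
            "units": "mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["R"], dtype=float).reshape(3, 3), np.asarray(d["t"], dtype=float))


def board_to_world(
    cloud: FrameCloud,
    cam_to_board: RigidTransform,
    board_to_world: RigidTransform,
) -> FrameCloud:
    """Map camera-frame points to world via the calibration board.

    Camera coordinates ``x_s`` first go to the board frame as
    ``x_m = R_s (x_s - t_s)`` — ``cam_to_board`` holds ``R_s`` and board
    center ``t_s`` — then to world as ``x_c = R_m x_m + t_m`` with the known
    board pose ``board_to_world``.  Point count and colors are preserved.
    """
    rs, ts = cam_to_board.rotation, cam_to_board.translation
    xm = (cloud.points - ts) @ rs.T
    xc = board_to_world.apply(xm)
    return cloud.with_points(xc)


def solve_rigid(pairs_A: np.ndarray, pairs_B: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion with ``A_i ~= R B_i + T`` (Kabsch/SVD).

    Centroid subtraction followed by SVD of the cross-covariance, with the
    determinant sign corrected so a proper rotation (never a reflection) is
    returned.  Exact to machine precision on noiseless correspondences.

    Raises
    ------
    DegenerateConfigurationError
        Fewer than 3 correspondences, mismatched lengths, or (near-)collinear
        points, which leave a rotation about the common line unconstrained.
    """
    A = np.asarray(pairs_A, dtype=float).reshape(-1, 3)
    B = np.asarray(pairs_B, dtype=float).reshape(-1, 3)
    if len(A) != len(B):
        raise DegenerateConfigurationError("correspondence lists differ in length")
    if len(A) < 3:
        raise DegenerateConfigurationError(f"need >= 3 correspondences, got {len(A)}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinearity: second singular value of the centered source points ~ 0
    sv = np.linalg.svd(B0, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("correspondences are collinear")
    H = B0.T @ A0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    T = ca - R @ cb
    return RigidTransform(R, T)


def icp_register(
    P: FrameCloud,
    Q: FrameCloud,
    max_iter: int = 50,
    tol: float = 1e-6,
    max_pair_dist: float = np.inf,
) -> tuple[RigidTransform, float]:
    """Point-to-point ICP aligning ``P`` onto ``Q``.

    Alternates nearest-neighbor pairing (k-d tree, pairs farther than
    ``max_pair_dist`` discarded) with the closed-form rigid fit, until the
    relative change of the mean squared pairing error
    ``E(R, t) = (1/n) sum ||q_i - (R p_i + t)||^2`` drops below ``tol`` or
    ``max_iter`` is reached.  The accepted error sequence is monotonically
    non-increasing.  Returns the cumulative transform and the final E.
    """
    if len(P) == 0 or len(Q) == 0:
        raise RegistrationError("both clouds must be non-empty")
    tree = cKDTree(Q.points)
    current = RigidTransform.identity()
    moved = P.points.copy()
    prev_err = np.inf
    final_err = np.inf
    for _ in range(max_iter):
        dist, idx = tree.query(moved, k=1)
        keep = np.isfinite(dist) & (dist <= max_pair_dist)
        if not np.any(keep):
            raise RegistrationError(
                f"no correspondences within max_pair_dist={max_pair_dist}"
            )
        try:
            step = solve_rigid(Q.points[idx[keep]], moved[keep])
        except DegenerateConfigurationError as exc:
            raise RegistrationError(f"degenerate correspondence set: {exc}") from exc
        candidate = step.compose(current)
        cand_pts = candidate.apply(P.points)
        d2, _ = tree.query(cand_pts, k=1)
        k2 = d2 <= max_pair_dist
        err = float(np.mean(d2[k2] ** 2)) if np.any(k2) else np.inf
        if err > prev_err:  # reject uphill step, keep best alignment
            break
        current, moved, final_err = candidate, cand_pts, err
        if prev_err - err < tol * max(prev_err, 1e-30):
            break
        prev_err = err
    if not np.isfinite(final_err):
        # zero iterations accepted; report the initial error
        dist, _ = tree.query(moved, k=1)
        keep = dist <= max_pair_dist
        final_err = float(np.mean(dist[keep] ** 2))
    return current, final_err
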