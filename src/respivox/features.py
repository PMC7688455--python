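"""Low-dimensional respiratory features of the voxel-model sequence.

The frame occupancy vectors live on (approximately) a one-dimensional
manifold swept out by the breathing state, so a nonlinear embedding
recovers the respiratory signal.  Locally linear embedding reconstructs
each frame from its K nearest neighbor frames with weights summing to one,
then finds the low-dimensional coordinates best preserving those weights:
the bottom nonzero eigenvectors of (I - W)^T (I - W) (the constant
eigenvector at eigenvalue ~0 is discarded).

Downstream, per-dimension Pearson correlation with the internal target
motion selects the single respiratory dimension, and the characterization
vector Gamma = [V, S, psi_1..psi_m] bundles the physical and intrinsic
features per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, UndefinedCorrelationError

logger = logging.getLogger("respivox.features")

__all__ = ["FeatureSeries", "lle_embed", "pearson", "select_dimension", "assemble_gamma"]


@dataclass
class FeatureSeries:
    """Per-frame respiratory features: physical (V, S) and intrinsic (psi)."""

    times: np.ndarray
    V: np.ndarray
    S: np.ndarray
    psi: np.ndarray  # (n_frames, d)
    gamma: np.ndarray  # (n_frames, 2 + m)
    m: int
    selected_dim: int | None = None
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("V", "S", "psi", "gamma"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per frame")
        if self.selected_dim is not None and self.selected_dim >= self.psi.shape[1]:
            raise ValueError("selected_dim out of range")


def lle_embed(
    X: np.ndarray,
    K: int = 12,
    d: int = 10,
    reg: float = 1e-3,
) -> np.ndarray:
    """Locally linear embedding of the frame vectors.

    Parameters
    ----------
    X : (n, D) array
        One row per frame; binary occupancy vectors in the pipeline, but any
        real-valued rows work.  Neighbors are found in Euclidean metric (on
        binary vectors this is a monotone transform of Hamming distance).
    K : neighbor count (``d <= K < n``).
    d : embedding dimension.
    reg : Tikhonov regularization of each local Gram matrix, applied as
        ``G += reg * trace(G) / K * I`` — binary vectors make the local Gram
        rank-deficient, and this standard conditioning keeps the weight
        solve well-posed.

    Returns
    -------
    (n, d) array of embedding coordinates, columns ordered by ascending
    eigenvalue.  The eigenvector sign is unidentifiable; each column is
    flipped, if necessary, so its correlation with the frame index is
    non-negative (first nonzero correlation), making repeated runs
    byte-identical.
    """
    X = np.asarray(X, dtype=np.float32)
    n = len(X)
    if K >= n:
        raise ValueError(f"neighbor count K={K} must be < n={n}")
    if not (1 <= d <= K):
        raise ValueError(f"need 1 <= d <= K, got d={d}, K={K}")
    if n >= 2 and np.all(X == X[0]):
        raise ValueError("rows of X are all identical; no structure to embed")

    # brute-force neighbor search: n is a frame count (small), D may be huge,
    # where a spatial tree degenerates to brute force with extra overhead
    sq = np.einsum("nd,nd->n", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)
    nbr = np.argsort(d2, axis=1)[:, :K]

    W = np.zeros((n, n))
    ones = np.ones(K)
    for i in range(n):
        Z = (X[nbr[i]] - X[i]).astype(float)  # (K, D)
        G = Z @ Z.T
        G += np.eye(K) * (reg * np.trace(G) / K if np.trace(G) > 0 else reg)
        try:
            w = np.linalg.solve(G, ones)
        except np.linalg.LinAlgError:
            w = np.linalg.lstsq(G, ones, rcond=None)[0]
        W[i, nbr[i]] = w / w.sum()

    A = np.eye(n) - W
    M = A.T @ A
    evals, evecs = np.linalg.eigh(M)
    # discard the constant eigenvector at eigenvalue ~ 0
    embedding = evecs[:, 1 : d + 1]

    frame_idx = np.arange(n, dtype=float)
    fc = frame_idx - frame_idx.mean()
    cols = embedding.copy()
    for j in range(cols.shape[1]):
        c = float(cols[:, j] @ fc)
        if c < 0:
            cols[:, j] *= -1.0
    return cols


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation rho = cov(x, y) / (sigma_x sigma_y), in [-1, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    rho = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


def select_dimension(
    psi: np.ndarray,
    tumor: np.ndarray,
    thresh: float = 0.5,
) -> tuple[int, float, np.ndarray]:
    """Pick the embedding dimension most correlated with the target motion.

    Computes |rho| for every column of ``psi`` against ``tumor`` and returns
    ``(best_index, best_abs_rho, all_abs_rhos)``.  A healthy respiratory
    embedding has exactly one column above ``thresh``; any other count is
    logged as a warning (the selection still proceeds by argmax).
    """
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    rhos = np.array([abs(pearson(psi[:, j], tumor)) for j in range(psi.shape[1])])
    n_above = int((rhos > thresh).sum())
    if n_above != 1:
        logger.warning(
            "select_dimension: %d dimensions exceed |rho| > %.2f (expected exactly 1)",
            n_above, thresh,
        )
    best = int(np.argmax(rhos))
    return best, float(rhos[best]), rhos


def assemble_gamma(
    V: np.ndarray,
    S: np.ndarray,
    psi: np.ndarray,
    m: int,
    times: np.ndarray | None = None,
    selected_dim: int | None = None,
) -> FeatureSeries:
    """Characterization vector Gamma = [V, S, psi_1..psi_m] per frame.

    Components are stored raw; per-component z-score metadata (mean, sd) is
    kept alongside so consumers can normalize scale-free features (the
    embedding coordinates have arbitrary scale) without losing the
    physical units of V and S.
    """
    V = np.asarray(V, dtype=float).ravel()
    S = np.asarray(S, dtype=float).ravel()
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if m > psi.shape[1]:
        raise DimensionError(f"m={m} exceeds embedding dimension d={psi.shape[1]}")
    gamma = np.column_stack([V, S, psi[:, :m]])
    norm = {
        "mean": gamma.mean(axis=0).tolist(),
        "std": gamma.std(axis=0).tolist(),
        "components": ["V_mm3", "S_mm2"] + [f"psi_{j + 1}" for j in range(m)],
    }
    if times is None:
        times = np.arange(len(V), dtype=float)
    return FeatureSeries(
        times=np.asarray(times, dtype=float),
        V=V,
        S=S,
        psi=psi,
        gamma=gamma,
        m=m,
        selected_dim=selected_dim,
        normalization=norm,
    )
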