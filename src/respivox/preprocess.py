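"""Per-frame point-cloud cleaning.

The stage order is fixed — bilateral denoising, statistical outlier
removal, distance/color ROI segmentation, moving-least-squares smoothing —
and every stage is deterministic.  Smoothing stages preserve the point
count; filtering stages only ever remove points.

All neighborhood queries run on a scipy k-d tree; local surface normals
come from PCA over a k-neighborhood, oriented toward a viewpoint (the
simulated camera sits far along +z by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import FrameCloud
from .errors import InsufficientPointsError

logger = logging.getLogger("respivox.preprocess")

__all__ = [
    "estimate_normals",
    "statistical_outlier_removal",
    "bilateral_filter",
    "segment_roi",
    "mls_smooth",
    "PreprocessParams",
    "preprocess_frame",
]

_DEFAULT_VIEWPOINT = np.array([0.0, 0.0, 1.0e6])


def _neighborhoods(points: np.ndarray, k: int):
    """Indices of the k nearest neighbors of every point (self excluded)."""
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k + 1)
    return dist[:, 1:], idx[:, 1:]


def estimate_normals(
    points: np.ndarray,
    k: int = 20,
    viewpoint: np.ndarray | None = None,
    neighbor_idx: np.ndarray | None = None,
):
    """Unit normals by local PCA; smallest-eigenvector of the k-neighborhood.

    Returns ``(normals, degenerate)`` where ``degenerate`` flags points whose
    neighborhood is (near-)collinear, leaving the normal undefined.  Normals
    are oriented to point toward ``viewpoint``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n <= k:
        raise InsufficientPointsError(f"normal estimation needs N > k ({n} <= {k})")
    if neighbor_idx is None:
        _, neighbor_idx = _neighborhoods(points, k)
    neigh = points[neighbor_idx]  # (N, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    evals, evecs = np.linalg.eigh(cov)  # ascending
    normals = evecs[:, :, 0]
    # collinear neighborhood: two vanishing eigenvalues
    scale = np.maximum(evals[:, 2], 1e-300)
    degenerate = evals[:, 1] / scale < 1e-10
    vp = _DEFAULT_VIEWPOINT if viewpoint is None else np.asarray(viewpoint, dtype=float)
    flip = np.einsum("ni,ni->n", normals, vp - points) < 0
    normals[flip] *= -1.0
    return normals, degenerate


def statistical_outlier_removal(cloud: FrameCloud, k: int = 20, n_sigma: float = 2.0) -> FrameCloud:
    """Drop points whose mean k-NN distance exceeds mean + n_sigma * sd.

    The classic statistical filter: sparse stragglers far from the surface
    have anomalously large mean neighbor distances and are removed; on a
    uniform sample nothing is removed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(cloud)
    if n <= k:
        raise InsufficientPointsError(f"statistical filter needs N > k ({n} <= {k})")
    dist, _ = _neighborhoods(cloud.points, k)
    mean_d = dist.mean(axis=1)
    thresh = mean_d.mean() + n_sigma * mean_d.std()
    keep = mean_d <= thresh
    logger.info("statistical_outlier_removal: kept %d / %d points", int(keep.sum()), n)
    return cloud.with_points(cloud.points[keep], keep_mask=keep)


def bilateral_filter(
    cloud: FrameCloud,
    sigma_s: float = 5.0,
    sigma_r: float = 2.0,
    k: int = 20,
) -> FrameCloud:
    """Feature-preserving denoising along the surface normal.

    Each point moves along its estimated normal by a bilaterally weighted
    average of its neighbors' normal-projected offsets: the spatial kernel
    (width ``sigma_s`` mm) favors close neighbors, the range kernel (width
    ``sigma_r`` mm) discounts neighbors far off the local surface, so steps
    and creases are not smeared.  Point count is unchanged; points with a
    degenerate (collinear) neighborhood are left as-is with a warning.
    """
    if sigma_s <= 0 or sigma_r <= 0:
        raise ValueError("sigma_s and sigma_r must be > 0")
    n = len(cloud)
    if n <= k:
        raise InsufficientPointsError(f"bilateral filter needs N > k ({n} <= {k})")
    pts = cloud.points
    dist, idx = _neighborhoods(pts, k)
    normals, degenerate = estimate_normals(pts, k=k, neighbor_idx=idx)
    offsets = pts[idx] - pts[:, None, :]  # (N, k, 3)
    d = np.einsum("nkj,nj->nk", offsets, normals)  # normal-projected offsets
    w = np.exp(-(dist**2) / (2.0 * sigma_s**2)) * np.exp(-(d**2) / (2.0 * sigma_r**2))
    wsum = w.sum(axis=1)
    delta = np.where(wsum > 0, (w * d).sum(axis=1) / np.maximum(wsum, 1e-300), 0.0)
    delta[degenerate] = 0.0
    if degenerate.any():
        logger.warning(
            "bilateral_filter: %d points with degenerate normals left unmodified",
            int(degenerate.sum()),
        )
    return cloud.with_points(pts + delta[:, None] * normals)


def segment_roi(
    cloud: FrameCloud,
    box: np.ndarray,
    color_range: np.ndarray | None = None,
) -> FrameCloud:
    """Keep points inside an axis-aligned box (and color range, if given).

    ``box`` is ((xmin, ymin, zmin), (xmax, ymax, zmax)) in mm; bounds are
    inclusive.  ``color_range`` has the same shape in [0, 1] and only
    applies when the cloud carries colors.  Order is preserved; an empty
    result is legal and logged.
    """
    box = np.asarray(box, dtype=float).reshape(2, 3)
    if np.any(box[0] >= box[1]):
        raise ValueError("box must satisfy min < max on every axis")
    keep = np.all((cloud.points >= box[0]) & (cloud.points <= box[1]), axis=1)
    if color_range is not None and cloud.colors is not None:
        cr = np.asarray(color_range, dtype=float).reshape(2, 3)
        keep &= np.all((cloud.colors >= cr[0]) & (cloud.colors <= cr[1]), axis=1)
    if not keep.any():
        logger.info("segment_roi: no points inside ROI")
    return cloud.with_points(cloud.points[keep], keep_mask=keep)


def mls_smooth(
    cloud: FrameCloud,
    radius: float = 10.0,
    degree: int = 2,
    max_neighbors: int = 32,
) -> FrameCloud:
    """Moving-least-squares projection onto local polynomial patches.

    For each point, neighbors within ``radius`` (capped at
    ``max_neighbors`` nearest) are expressed in a local frame aligned with
    the neighborhood PCA normal; a degree-1 or degree-2 bivariate
    polynomial is fitted by Gaussian-weighted least squares (kernel width
    ``radius / 2``) and the point is moved along the normal onto the fitted
    patch.  Planes are exact fixed points.  Points with fewer than
    ``(degree+1)(degree+2)/2`` usable neighbors are left unmodified with a
    warning.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    pts = cloud.points
    n = len(pts)
    m_coef = (degree + 1) * (degree + 2) // 2
    if n < 2:
        if n:
            logger.warning("mls_smooth: single point left unmodified")
        return cloud.with_points(pts.copy())

    tree = cKDTree(pts)
    kq = min(n, max_neighbors + 1)
    dist, idx = tree.query(pts, k=kq, distance_upper_bound=radius)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    valid = np.isfinite(dist)
    idx = np.where(valid, idx, 0)
    dist = np.where(valid, dist, 0.0)
    counts = valid.sum(axis=1)
    fit_mask = counts >= m_coef
    if not fit_mask.all():
        logger.warning(
            "mls_smooth: %d points with < %d neighbors in radius left unmodified",
            int((~fit_mask).sum()), m_coef,
        )
    k_eff = idx.shape[1]
    if k_eff == 0 or not fit_mask.any():
        return cloud.with_points(pts.copy())

    # local frames from the PCA of each radius-neighborhood
    neigh = pts[idx]  # (N, k, 3)
    wvalid = valid.astype(float)
    msum = np.maximum(wvalid.sum(axis=1), 1.0)
    mean = (neigh * wvalid[..., None]).sum(axis=1) / msum[:, None]
    centered = (neigh - mean[:, None, :]) * wvalid[..., None]
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, evecs = np.linalg.eigh(cov)
    normal, e1, e2 = evecs[:, :, 0], evecs[:, :, 1], evecs[:, :, 2]

    off = neigh - pts[:, None, :]
    x = np.einsum("nkj,nj->nk", off, e1)
    y = np.einsum("nkj,nj->nk", off, e2)
    z = np.einsum("nkj,nj->nk", off, normal)
    h = radius / 2.0
    w = np.exp(-(dist**2) / (2.0 * h * h)) * wvalid
    cols = [np.ones_like(x), x, y]
    if degree == 2:
        cols += [x * x, x * y, y * y]
    A = np.stack(cols, axis=2)  # (N, k, m)
    Aw = A * w[..., None]
    G = np.einsum("nkm,nkl->nml", Aw, A)
    b = np.einsum("nkm,nk->nm", Aw, z)
    # tiny ridge keeps near-degenerate neighborhoods solvable
    G += 1e-12 * np.trace(G, axis1=1, axis2=2)[:, None, None] * np.eye(m_coef)
    try:
        coef = np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        coef = np.einsum("nml,nl->nm", np.linalg.pinv(G), b)
    c0 = np.where(fit_mask, coef[:, 0], 0.0)
    # an ill-conditioned local fit must not fling the point out of its own
    # neighborhood; such points are left unmodified
    wild = np.abs(c0) > radius
    if wild.any():
        logger.warning("mls_smooth: %d ill-conditioned fits left unmodified", int(wild.sum()))
        c0[wild] = 0.0
    return cloud.with_points(pts + c0[:, None] * normal)


@dataclass
class PreprocessParams:
    """Stage parameters for the fixed cleaning pipeline (all mm where dimensional)."""

    bilateral_sigma_s: float = 5.0
    bilateral_sigma_r: float = 2.0
    k: int = 20
    # statistical removal is iterated to convergence (sigma clipping): gross
    # outliers inflate the sd so early passes only trim the far tail; once
    # they are gone the threshold tightens.  The high multiplier spares
    # legitimately stretched surface regions (e.g. the inflating abdomen).
    sor_n_sigma: float = 5.0
    sor_max_passes: int = 6
    mls_radius: float = 10.0
    mls_degree: int = 2
    box: tuple | None = None
    color_range: tuple | None = None


def preprocess_frame(cloud: FrameCloud, params: PreprocessParams | None = None) -> FrameCloud:
    """Run the fixed stage order: bilateral -> statistical -> ROI -> MLS."""
    p = params or PreprocessParams()
    out = bilateral_filter(cloud, p.bilateral_sigma_s, p.bilateral_sigma_r, p.k)
    for _ in range(p.sor_max_passes):
        n_before = len(out)
        out = statistical_outlier_removal(out, p.k, p.sor_n_sigma)
        if len(out) == n_before:
            break
    if p.box is not None:
        out = segment_roi(out, np.asarray(p.box), None if p.color_range is None else np.asarray(p.color_range))
    out = mls_smooth(out, p.mls_radius, p.mls_degree)
    return out
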