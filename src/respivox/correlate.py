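"""External-internal correlation: phase-split polynomial surrogate model.

Lung hysteresis makes inhale and exhale trace different external-internal
curves, so a single polynomial in the surrogate cannot follow both.  The
breathing cycle is therefore segmented at the peaks and valleys of the
external surrogate, and two degree-N polynomials — one per phase — map the
(normalized) surrogate value r to the internal target position:

    x_T = sum_j A_j^+ r^j   during exhale (peak -> valley)
    x_T = sum_j A_j^- r^j   during inhale (valley -> peak)

Degrees 2-3 are preferred; higher degrees overfit.  The surrogate is
z-scored with training statistics before fitting because embedding
coordinates carry no physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    AlignmentError,
    FlatSignalError,
    InsufficientDataError,
    PhaseError,
)
from .features import pearson

__all__ = [
    "PhaseSegmentation",
    "CorrelationModel",
    "segment_phases",
    "fit_model",
    "predict",
    "evaluate_mse",
    "compare_surrogates",
]

EXHALE, INHALE = 0, 1  # labels: peak->valley descent is exhale


@dataclass
class PhaseSegmentation:
    """Alternating peak/valley extrema and per-frame phase labels."""

    extrema_indices: np.ndarray  # frame indices, alternating peak/valley
    extrema_kinds: np.ndarray  # +1 peak, -1 valley, per extremum
    labels: np.ndarray  # per frame: EXHALE or INHALE
    k: np.ndarray  # per-extremum dividing surrogate values k_i

    def __post_init__(self) -> None:
        kinds = np.asarray(self.extrema_kinds)
        if len(kinds) >= 2 and np.any(kinds[1:] == kinds[:-1]):
            raise ValueError("extrema must alternate peak/valley")


@dataclass
class CorrelationModel:
    """Two coefficient sets (exhale A^+, inhale A^-) of a degree-N model."""

    degree: int
    coeffs_exhale: np.ndarray  # A_0..A_N, ascending powers
    coeffs_inhale: np.ndarray
    surrogate_shift: float = 0.0
    surrogate_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.degree <= 3:
            raise ValueError("degree must be in {1, 2, 3}")
        for c in (self.coeffs_exhale, self.coeffs_inhale):
            if len(c) != self.degree + 1:
                raise ValueError("coefficient sets must have length degree + 1")

    def normalize(self, r: np.ndarray) -> np.ndarray:
        return (np.asarray(r, dtype=float) - self.surrogate_shift) / self.surrogate_scale

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coeffs_exhale": [float(c) for c in self.coeffs_exhale],
            "coeffs_inhale": [float(c) for c in self.coeffs_inhale],
            "surrogate_shift": self.surrogate_shift,
            "surrogate_scale": self.surrogate_scale,
        }


def segment_phases(
    surrogate: np.ndarray,
    min_prominence: float = 0.2,
    smooth_window: int = 5,
) -> PhaseSegmentation:
    """Split the breathing cycle at surrogate peaks and valleys.

    The surrogate is moving-average smoothed over ``smooth_window`` frames;
    local extrema with prominence below ``min_prominence`` times the global
    peak-to-peak range are discarded; consecutive same-kind extrema keep
    only the more extreme one so peaks and valleys strictly alternate.
    Frames from a peak to the next valley are labeled exhale, valley to
    peak inhale; the open runs before the first and after the last extremum
    take the phase consistent with the adjacent extremum.  A frame exactly
    at an extremum starts the segment that begins there.
    """
    r = np.asarray(surrogate, dtype=float).ravel()
    n = len(r)
    if n < 5:
        raise FlatSignalError("need at least 5 frames to segment phases")
    w = max(1, int(smooth_window))
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.pad(r, pad, mode="edge")
        smooth = np.convolve(padded, kernel, mode="same")[pad : pad + n]
    else:
        smooth = r
    ptp = smooth.max() - smooth.min()
    if ptp <= 0:
        raise FlatSignalError("surrogate is constant")
    prom = min_prominence * ptp
    peaks, _ = find_peaks(smooth, prominence=prom)
    valleys, _ = find_peaks(-smooth, prominence=prom)
    if len(peaks) == 0 and len(valleys) == 0:
        raise FlatSignalError("no respiratory extrema found")

    ext = np.concatenate([peaks, valleys])
    kind = np.concatenate([np.ones(len(peaks), int), -np.ones(len(valleys), int)])
    order = np.argsort(ext)
    ext, kind = ext[order], kind[order]

    # enforce alternation: of a same-kind run keep the most extreme
    keep_ext, keep_kind = [], []
    for e, s in zip(ext, kind):
        if keep_kind and s == keep_kind[-1]:
            better = smooth[e] > smooth[keep_ext[-1]] if s == 1 else smooth[e] < smooth[keep_ext[-1]]
            if better:
                keep_ext[-1] = e
        else:
            keep_ext.append(int(e))
            keep_kind.append(int(s))
    ext = np.array(keep_ext, dtype=int)
    kind = np.array(keep_kind, dtype=int)

    labels = np.empty(n, dtype=int)
    # before the first extremum: rising into a peak = inhale, falling into a valley = exhale
    labels[: ext[0]] = INHALE if kind[0] == 1 else EXHALE
    for i in range(len(ext)):
        start = ext[i]
        stop = ext[i + 1] if i + 1 < len(ext) else n
        labels[start:stop] = EXHALE if kind[i] == 1 else INHALE
    return PhaseSegmentation(
        extrema_indices=ext,
        extrema_kinds=kind,
        labels=labels,
        k=r[ext],
    )


def fit_model(
    r: np.ndarray,
    xt: np.ndarray,
    seg: PhaseSegmentation | None,
    N: int = 2,
) -> CorrelationModel:
    """Least-squares fit of the phase-split polynomial model.

    Fits separate degree-``N`` polynomials on the exhale- and inhale-labeled
    (r, x_t) pairs of the training series, after z-scoring r with training
    statistics.  Passing ``seg=None`` fits one polynomial on all frames and
    stores it in both branches — the unsplit baseline that a hysteretic
    phantom should beat.
    """
    r = np.asarray(r, dtype=float).ravel()
    xt = np.asarray(xt, dtype=float).ravel()
    if len(r) != len(xt):
        raise AlignmentError(f"surrogate ({len(r)}) and target ({len(xt)}) lengths differ")
    if N > 3:
        raise ValueError(
            f"degree N={N} rejected: degrees above 3 are prone to overfitting"
        )
    if N < 1:
        raise ValueError("degree must be >= 1")
    shift = float(r.mean())
    scale = float(r.std())
    if scale == 0:
        scale = 1.0
    rn = (r - shift) / scale

    def polyfit(mask: np.ndarray, phase: str) -> np.ndarray:
        if mask.sum() < N + 2:
            raise InsufficientDataError(
                f"{phase} phase has {int(mask.sum())} frames; need >= {N + 2} for degree {N}"
            )
        return np.polynomial.polynomial.polyfit(rn[mask], xt[mask], N)

    if seg is None:
        coef = polyfit(np.ones(len(r), dtype=bool), "single")
        ce, ci = coef, coef.copy()
    else:
        if len(seg.labels) != len(r):
            raise AlignmentError("segmentation labels do not match the series length")
        ce = polyfit(seg.labels == EXHALE, "exhale")
        ci = polyfit(seg.labels == INHALE, "inhale")
    return CorrelationModel(
        degree=N,
        coeffs_exhale=ce,
        coeffs_inhale=ci,
        surrogate_shift=shift,
        surrogate_scale=scale,
    )


def predict(model: CorrelationModel, r: np.ndarray, seg: PhaseSegmentation) -> np.ndarray:
    """Evaluate the branch polynomial matching each frame's phase label."""
    r = np.asarray(r, dtype=float).ravel()
    if seg is None or len(seg.labels) != len(r):
        raise PhaseError("every frame needs a phase label from segment_phases")
    rn = model.normalize(r)
    exhale = np.polynomial.polynomial.polyval(rn, model.coeffs_exhale)
    inhale = np.polynomial.polynomial.polyval(rn, model.coeffs_inhale)
    return np.where(seg.labels == EXHALE, exhale, inhale)


def evaluate_mse(estimate: np.ndarray, actual: np.ndarray) -> float:
    """Mean squared error between estimated and actual positions (mm^2)."""
    estimate = np.asarray(estimate, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if len(estimate) != len(actual):
        raise AlignmentError(f"length mismatch: {len(estimate)} vs {len(actual)}")
    if len(estimate) == 0:
        raise AlignmentError("series must be non-empty")
    return float(np.mean((estimate - actual) ** 2))


def _fit_eval(surrogate, tumor, n_train, N, min_prominence, smooth_window):
    r_tr, r_te = surrogate[:n_train], surrogate[n_train:]
    x_tr, x_te = tumor[:n_train], tumor[n_train:]
    seg_tr = segment_phases(r_tr, min_prominence, smooth_window)
    model = fit_model(r_tr, x_tr, seg_tr, N)
    seg_te = segment_phases(r_te, min_prominence, smooth_window)
    est = predict(model, r_te, seg_te)
    return {
        "train_pearson": pearson(r_tr, x_tr),
        "test_mse": evaluate_mse(est, x_te),
        "model": model.to_dict(),
    }


def compare_surrogates(
    marker_traj: np.ndarray,
    reduced_feat: np.ndarray,
    tumor: np.ndarray,
    split: float = 0.5,
    N: int = 2,
    min_prominence: float = 0.2,
    smooth_window: int = 5,
) -> dict:
    """Head-to-head evaluation of marker vs reduced-feature surrogates.

    Chronological train/test split at ``split``; for each surrogate a
    phase-split model is fitted on the training part and evaluated on the
    held-out part.  The report carries per-surrogate training Pearson
    correlation with the target and held-out MSE, plus which surrogate won
    each metric.
    """
    marker_traj = np.asarray(marker_traj, dtype=float).ravel()
    reduced_feat = np.asarray(reduced_feat, dtype=float).ravel()
    tumor = np.asarray(tumor, dtype=float).ravel()
    if not len(marker_traj) == len(reduced_feat) == len(tumor):
        raise AlignmentError("all series must be frame-aligned")
    if not 0.0 < split < 1.0:
        raise ValueError("split must be in (0, 1)")
    n_train = int(round(split * len(tumor)))
    report = {
        "marker": _fit_eval(marker_traj, tumor, n_train, N, min_prominence, smooth_window),
        "reduced_feature": _fit_eval(reduced_feat, tumor, n_train, N, min_prominence, smooth_window),
        "n_train": n_train,
        "n_test": len(tumor) - n_train,
    }
    report["winner_pearson"] = max(
        ("marker", "reduced_feature"),
        key=lambda k: abs(report[k]["train_pearson"]),
    )
    report["winner_mse"] = min(
        ("marker", "reduced_feature"),
        key=lambda k: report[k]["test_mse"],
    )
    return report
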