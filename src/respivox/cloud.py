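"""Core point-cloud container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["FrameCloud"]


@dataclass
class FrameCloud:
    """One timestamped point cloud of the torso surface.

    Parameters
    ----------
    points : (N, 3) float array, millimeters.
    colors : optional (N, 3) float array in [0, 1].
    frame_index : non-negative integer frame counter.
    time : acquisition time in seconds.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    frame_index: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=float).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError(
                    f"colors ({len(self.colors)}) and points ({len(self.points)}) "
                    "must have the same length"
                )
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray, keep_mask: np.ndarray | None = None) -> "FrameCloud":
        """Copy of this frame with new coordinates.

        ``keep_mask`` subsets the colors consistently when the operation
        dropped points (filtering); without it the colors are kept as-is,
        which requires an equal point count (smoothing).
        """
        colors = self.colors
        if colors is not None and keep_mask is not None:
            colors = colors[keep_mask]
        return replace(self, points=np.asarray(points, dtype=float).reshape(-1, 3), colors=colors)
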