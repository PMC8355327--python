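"""Core filament-contour containers shared across the toolkit.

A tubule contour is an ordered 2D polyline in pixel coordinates (origin at
the top-left pixel centre, x rightward, y downward).  Physical lengths are
converted to micrometres only at reporting time via ``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FilamentContour", "ContourTimeSeries", "resample_contour"]


@dataclass
class FilamentContour:
    """Ordered backbone points of one tubule in one frame.

    Parameters
    ----------
    points : (n, 2) array
        Ordered (x, y) positions in pixels.  At least two points; repeated
        consecutive points are not allowed (zero-length segments).
    pixel_size : float
        Physical pixel size in micrometres per pixel.
    frame_index : int
        Index of the video frame this contour belongs to.
    """

    points: np.ndarray
    pixel_size: float = 1.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        if len(pts) < 2:
            raise ValueError("a contour needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour points must be finite")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("repeated consecutive points (zero-length segment)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.points = pts

    # -- derived geometry (pixel units unless stated otherwise) ------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def segment_lengths(self) -> np.ndarray:
        """Per-segment lengths Delta-s_k in pixels (length n-1)."""
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arclength_midpoints(self) -> np.ndarray:
        """Arclength s_k at each segment midpoint: sum of the preceding
        segments plus half the current one (length n-1, pixels)."""
        ds = self.segment_lengths
        return np.concatenate(([0.0], np.cumsum(ds)[:-1])) + 0.5 * ds

    @property
    def length_px(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def length_um(self) -> float:
        """Total contour length L in micrometres."""
        return self.length_px * self.pixel_size

    @property
    def end_to_end_um(self) -> float:
        """End-to-end distance R in micrometres."""
        return float(np.linalg.norm(self.points[-1] - self.points[0])) * self.pixel_size


def resample_contour(points: np.ndarray, n_out: int) -> np.ndarray:
    """Resample a polyline to ``n_out`` points equally spaced in arclength."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    if s[-1] <= 0:
        raise ValueError("degenerate (zero-length) polyline")
    target = np.linspace(0.0, s[-1], n_out)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    return np.column_stack([x, y])


@dataclass
class ContourTimeSeries:
    """A tubule contour tracked over video frames.

    All frames hold the same number K of backbone points so that per-point
    statistics across time are well defined; points correspond across frames
    by fractional arclength.
    """

    contours: list  # list[FilamentContour], one per frame
    times: np.ndarray  # frame times in seconds, strictly increasing
    flagged: np.ndarray = None  # per-frame tracking-problem flags
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.contours) == 0:
            raise ValueError("empty contour series")
        ks = {c.n_points for c in self.contours}
        if len(ks) != 1:
            raise ValueError(f"all frames must share one K; got {sorted(ks)}")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.contours):
            raise ValueError("times and contours length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.contours), dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    @property
    def k_points(self) -> int:
        return self.contours[0].n_points

    @property
    def pixel_size(self) -> float:
        return self.contours[0].pixel_size

    def coordinates(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, K, 2), pixels."""
        return np.stack([c.points for c in self.contours])

    def to_dataframe(self):
        """Long-form table: tubule-frame-k-x-y rows (pixels)."""
        import pandas as pd

        frames, ks, xs, ys = [], [], [], []
        for i, c in enumerate(self.contours):
            frames.extend([i] * c.n_points)
            ks.extend(range(c.n_points))
            xs.extend(c.points[:, 0])
            ys.extend(c.points[:, 1])
        return pd.DataFrame({"frame": frames, "k": ks, "x": xs, "y": ys})

    @classmethod
    def from_coordinates(
        cls,
        coords: np.ndarray,
        times: np.ndarray,
        pixel_size: float = 1.0,
        params: dict | None = None,
    ) -> "ContourTimeSeries":
        coords = np.asarray(coords, dtype=float)
        contours = [
            FilamentContour(coords[i], pixel_size=pixel_size, frame_index=i)
            for i in range(coords.shape[0])
        ]
        return cls(contours=contours, times=times, params=params or {})
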