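"""Whole-contour tracking of tubules across video frames.

An open active contour (snake) with elasticity and stiffness internal
forces and a ridge-attraction external force follows the tubule in each
frame, seeded from the converged contour of the previous frame.  Backbone
statistics over the tracked series - per-point transverse variance,
bias-corrected skewness with its standard error, and the line density of
significantly skewed points - are the activity read-outs: thermal
fluctuations are symmetric about the backbone, so significant skewness
marks driven (non-thermal) motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contour import ContourTimeSeries, FilamentContour, resample_contour

__all__ = [
    "SnakeParams",
    "evolve_open_contour",
    "track_contour_video",
    "BackboneStats",
    "compute_backbone_stats",
    "skewness_test",
    "skewed_line_density",
    "Z_CRIT",
]

Z_CRIT = 3.29  # 5% two-sided significance adjusted for large samples


@dataclass
class SnakeParams:
    """Open-snake parameters (pixel units).

    elasticity penalises stretching, stiffness penalises bending of the
    discrete contour; external_weight scales the ridge-attraction force
    (gradient of the Gaussian-smoothed image, normalised to unit maximum).
    """

    elasticity: float = 0.5
    stiffness: float = 0.5
    external_weight: float = 2.0
    smoothing_sigma: float = 1.0
    step: float = 0.5  # gradient-descent time step gamma
    n_points: int = 30
    max_iter: int = 400
    tol: float = 5e-3  # max point displacement for convergence (px)
    length_jump_guard: float = 0.2  # fractional frame-to-frame length change


def _internal_matrix(k: int, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Implicit-step matrix (I + gamma*(alpha*L2 + beta*L4)) for an open
    snake with pinned endpoints (Dirichlet rows at 0 and k-1)."""
    L2 = np.zeros((k, k))
    for i in range(1, k - 1):
        L2[i, i - 1] += -1.0
        L2[i, i] += 2.0
        L2[i, i + 1] += -1.0
    L4 = np.zeros((k, k))
    for i in range(2, k - 2):
        L4[i, i - 2] += 1.0
        L4[i, i - 1] += -4.0
        L4[i, i] += 6.0
        L4[i, i + 1] += -4.0
        L4[i, i + 2] += 1.0
    M = np.eye(k) + gamma * (alpha * L2 + beta * L4)
    M[0, :] = 0.0
    M[0, 0] = 1.0
    M[-1, :] = 0.0
    M[-1, -1] = 1.0
    return M


def _external_force_field(image: np.ndarray, sigma: float):
    smooth = ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma)
    gy, gx = np.gradient(smooth)
    scale = max(np.abs(gx).max(), np.abs(gy).max(), 1e-12)
    return gx / scale, gy / scale


def evolve_open_contour(
    image: np.ndarray,
    initial_contour: FilamentContour,
    params: SnakeParams | None = None,
) -> FilamentContour:
    """Deform an open contour onto the ridge in one image frame.

    Iterates an implicit internal step (elasticity + stiffness, endpoints
    pinned during the solve) and an explicit external ridge-attraction step
    (all points, endpoints included), then resamples to ``params.n_points``
    equally spaced points.  Converges when the largest point displacement
    per iteration drops below ``params.tol``.  If the contour length jumps
    beyond the guard relative to the input, the input contour is returned
    flagged via a warning.
    """
    p = params or SnakeParams()
    img = np.asarray(image, dtype=float)
    gx, gy = _external_force_field(img, p.smoothing_sigma)
    pts = resample_contour(initial_contour.points, p.n_points)
    if len(pts) < 3:
        raise ValueError("contour collapsed below 3 points")
    k = len(pts)
    M = _internal_matrix(k, p.elasticity, p.stiffness, p.step)
    Minv = np.linalg.inv(M)
    L0 = _polyline_length(pts)
    h, w = img.shape
    for _ in range(p.max_iter):
        fx = ndimage.map_coordinates(gx, [pts[:, 1], pts[:, 0]], order=1, mode="nearest")
        fy = ndimage.map_coordinates(gy, [pts[:, 1], pts[:, 0]], order=1, mode="nearest")
        f = np.column_stack([fx, fy])
        # free ends move only transversely: remove the tangential force
        # component at the tips so the contour cannot slide/shrink along
        # the ridge
        for idx, nb in ((0, 1), (-1, -2)):
            t = pts[nb] - pts[idx]
            t = t / (np.linalg.norm(t) + 1e-12)
            f[idx] -= np.dot(f[idx], t) * t
        rhs = pts + p.step * p.external_weight * f
        new = Minv @ rhs
        new[:, 0] = np.clip(new[:, 0], 0, w - 1)
        new[:, 1] = np.clip(new[:, 1], 0, h - 1)
        new = resample_contour(new, k)
        disp = np.max(np.linalg.norm(new - pts, axis=1))
        pts = new
        if disp < p.tol:
            break
    L1 = _polyline_length(pts)
    if L0 > 0 and abs(L1 - L0) / L0 > p.length_jump_guard:
        warnings.warn("contour length jumped beyond guard; reverting", stacklevel=2)
        return FilamentContour(
            resample_contour(initial_contour.points, p.n_points),
            pixel_size=initial_contour.pixel_size,
            frame_index=initial_contour.frame_index,
        )
    return FilamentContour(
        pts, pixel_size=initial_contour.pixel_size, frame_index=initial_contour.frame_index
    )


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def track_contour_video(
    video: np.ndarray,
    endpoints_frame0,
    params: SnakeParams | None = None,
    frame_interval: float = 0.03,
    pixel_size: float = 0.104,
) -> ContourTimeSeries:
    """Track a tubule contour through a video.

    The user supplies the two tubule endpoints in frame 0 only; the frame-0
    contour is seeded as the straight line between them, and every later
    frame is seeded from the converged contour of its predecessor.  A
    length-jump guard re-evolves suspicious frames with stronger internal
    weights and flags them if the jump persists (the previous contour is
    kept for that frame).
    """
    p = params or SnakeParams()
    video = np.asarray(video, dtype=float)
    (x0, y0), (x1, y1) = np.asarray(endpoints_frame0, dtype=float)
    seed_pts = np.column_stack(
        [np.linspace(x0, x1, p.n_points), np.linspace(y0, y1, p.n_points)]
    )
    prev = FilamentContour(seed_pts, pixel_size=pixel_size, frame_index=0)
    contours, flags = [], []
    prev_len = None
    for t in range(video.shape[0]):
        cand = evolve_open_contour(video[t], prev, p)
        flagged = False
        if prev_len is not None and prev_len > 0:
            jump = abs(cand.length_px - prev_len) / prev_len
            if jump > p.length_jump_guard:
                stiff = SnakeParams(**{**p.__dict__})
                stiff.elasticity *= 4.0
                stiff.stiffness *= 4.0
                cand = evolve_open_contour(video[t], prev, stiff)
                jump = abs(cand.length_px - prev_len) / prev_len
                if jump > p.length_jump_guard:
                    cand = FilamentContour(
                        prev.points.copy(), pixel_size=pixel_size, frame_index=t
                    )
                    flagged = True
        cand.frame_index = t
        contours.append(cand)
        flags.append(flagged)
        prev = cand
        prev_len = cand.length_px
    flags = np.asarray(flags)
    if flags.mean() >= 0.2:
        warnings.warn(
            f"{flags.sum()} of {len(flags)} frames flagged by the length guard",
            stacklevel=2,
        )
    return ContourTimeSeries(
        contours=contours,
        times=np.arange(video.shape[0]) * frame_interval,
        flagged=flags,
        params={"snake": p.__dict__},
    )


# ---------------------------------------------------------------------------
# Backbone statistics
# ---------------------------------------------------------------------------


@dataclass
class BackboneStats:
    """Per-backbone-point statistics of transverse displacement."""

    backbone: np.ndarray  # (K, 2) mean contour, aligned, pixels
    transverse: np.ndarray  # (n_frames, K) y-displacement from backbone, pixels
    variance: np.ndarray  # per-point population variance, um^2
    skewness: np.ndarray  # per-point bias-corrected skewness
    ses: np.ndarray  # standard error of skewness
    zscores: np.ndarray
    significant: np.ndarray  # |z| > z_crit
    pixel_size: float
    n_frames: int

    @property
    def backbone_length_um(self) -> float:
        return _polyline_length(self.backbone) * self.pixel_size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": np.arange(len(self.variance)),
                "x": self.backbone[:, 0],
                "y": self.backbone[:, 1],
                "variance_um2": self.variance,
                "skewness": self.skewness,
                "ses": self.ses,
                "z": self.zscores,
                "significant": self.significant,
            }
        )


def _align_endpoints_to_x(coords: np.ndarray) -> np.ndarray:
    """Rigidly rotate/translate all frames by one common transform so the
    time-mean backbone endpoints lie on the x-axis (first end at origin)."""
    backbone = coords.mean(axis=0)
    p0, p1 = backbone[0], backbone[-1]
    d = p1 - p0
    phi = np.arctan2(d[1], d[0])
    c, s = np.cos(-phi), np.sin(-phi)
    R = np.array([[c, -s], [s, c]])
    return (coords - p0) @ R.T


def skewness_test(x, z_crit: float = Z_CRIT, ses_form: str = "standard"):
    """Bias-corrected skewness of a sample with its standard error.

    s = sqrt(n(n-1))/(n-2) * m3 / m2^(3/2) with the biased central moments
    m2, m3.  The standard error of skewness defaults to the Cramer form
    sqrt(6n(n-1) / ((n-2)(n+1)(n+3))); ``ses_form="as_printed"`` selects the
    variant sqrt(6n(n-1)) / ((n+1)(n+3)(n-2)) instead.  Returns
    ``(s, ses, z, significant)``; a zero-variance sample gives NaN skewness
    and is never significant.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for skewness")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    if ses_form == "standard":
        ses = float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))
    elif ses_form == "as_printed":
        ses = float(np.sqrt(6.0 * n * (n - 1)) / ((n + 1) * (n + 3) * (n - 2)))
    else:
        raise ValueError(f"unknown ses_form {ses_form!r}")
    if m2 == 0:
        return np.nan, ses, np.nan, False
    s = float(np.sqrt(n * (n - 1)) / (n - 2) * m3 / m2**1.5)
    z = s / ses
    return s, ses, float(z), bool(abs(z) > z_crit)


def compute_backbone_stats(
    series: ContourTimeSeries,
    z_crit: float = Z_CRIT,
    ses_form: str = "standard",
    min_frames: int = 20,
) -> BackboneStats:
    """Backbone and per-point transverse statistics of a tracked contour.

    All frames are rotated/translated by the rigid transform that puts the
    time-mean backbone endpoints on the x-axis; transverse displacement at
    matched fractional-arclength points is then the y-deviation from the
    backbone.  Per-point variance is the population variance; skewness
    significance uses |z| > ``z_crit``.
    """
    if series.n_frames < min_frames:
        raise ValueError(f"need at least {min_frames} frames")
    coords = _align_endpoints_to_x(series.coordinates())
    backbone = coords.mean(axis=0)
    trans = coords[:, :, 1] - backbone[None, :, 1]
    var = trans.var(axis=0) * series.pixel_size**2
    K = coords.shape[1]
    s = np.full(K, np.nan)
    ses = np.full(K, np.nan)
    z = np.full(K, np.nan)
    sig = np.zeros(K, dtype=bool)
    for k in range(K):
        s[k], ses[k], z[k], sig[k] = skewness_test(
            trans[:, k], z_crit=z_crit, ses_form=ses_form
        )
    return BackboneStats(
        backbone=backbone,
        transverse=trans,
        variance=var,
        skewness=s,
        ses=ses,
        zscores=z,
        significant=sig,
        pixel_size=series.pixel_size,
        n_frames=series.n_frames,
    )


def skewed_line_density(stats: BackboneStats) -> float:
    """Number of significantly skewed backbone points per micrometre."""
    length = stats.backbone_length_um
    if length <= 0:
        raise ValueError("zero-length backbone")
    return float(stats.significant.sum()) / length
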