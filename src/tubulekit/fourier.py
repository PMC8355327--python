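"""Fourier cosine-mode decomposition of tubule tangent angles.

The tubule shape is expressed through its tangent-angle profile
theta(s) = sqrt(2/L) * sum_n a_n cos(n pi s / L); cosine modes suit free
(network-attached, non-stationary) ends.  A mode whose time-mean amplitude
stands clear of its own fluctuations (|<a_n>| - 1.5 sd > 0) marks sustained
curvature - a signature of prestress rather than thermal bending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .contour import ContourTimeSeries, FilamentContour

__all__ = [
    "tangent_geometry",
    "max_mode_count",
    "decompose_modes",
    "reconstruct_tangent",
    "ModeAmplitudeSeries",
    "decompose_series",
    "sustained_curvature",
]

DEFAULT_N_MODES = 10


def tangent_geometry(contour: FilamentContour):
    """Tangent angles and arclength bookkeeping of a contour.

    Returns ``(theta, ds, s, L)`` in pixel units: per-segment tangent angle
    theta_k (two-argument arctangent of the point differences, unwrapped to
    avoid +/-pi jumps), segment lengths ds_k, segment-midpoint arclengths
    s_k = sum_{j<k} ds_j + ds_k / 2, and the total length L.
    """
    pts = contour.points
    if len(pts) < 3:
        raise ValueError("need at least 3 points for tangent geometry")
    d = np.diff(pts, axis=0)
    ds = np.linalg.norm(d, axis=1)
    if np.any(ds == 0):
        raise ValueError("repeated identical points")
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    s = np.concatenate(([0.0], np.cumsum(ds)[:-1])) + 0.5 * ds
    return theta, ds, s, float(ds.sum())


def max_mode_count(ds: np.ndarray, L: float) -> int:
    """Largest usable mode number: at least two samples per mode wavelength
    (n <= L / max ds, conservative for nonuniform segments) and n <= N - 2
    for N segments."""
    return int(min(np.floor(L / np.max(ds)), len(ds) - 2))


def decompose_modes(theta, ds, s, L, n_max: int | None = None) -> np.ndarray:
    """Cosine-mode amplitudes a_0..a_n_max of a tangent-angle profile:
    a_n = sqrt(2/L) * sum_k theta_k ds_k cos(n pi s_k / L).

    ``n_max`` defaults to min(10, Nyquist cap, N-2); a larger request is
    capped with a warning.
    """
    theta = np.asarray(theta, dtype=float)
    ds = np.asarray(ds, dtype=float)
    s = np.asarray(s, dtype=float)
    cap = max_mode_count(ds, L)
    if n_max is None:
        n_max = min(DEFAULT_N_MODES, cap)
    elif n_max > cap:
        warnings.warn(f"n_max {n_max} above mode cap {cap}; capping", stacklevel=2)
        n_max = cap
    n = np.arange(n_max + 1)
    cos = np.cos(np.pi * np.outer(n, s) / L)
    return np.sqrt(2.0 / L) * cos @ (theta * ds)


def reconstruct_tangent(amplitudes, s, L) -> np.ndarray:
    """Tangent-angle profile from cosine-mode amplitudes:
    theta(s_k) = sqrt(2/L) * (a_0/2 + sum_{n>=1} a_n cos(n pi s_k / L)).

    The n = 0 term carries the standard cosine-series half weight; with the
    amplitude definition of :func:`decompose_modes` this makes
    decompose -> reconstruct the identity on band-limited profiles (a
    uniform summation over all modes would double the mean angle).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    s = np.asarray(s, dtype=float)
    n = np.arange(len(amplitudes))
    cos = np.cos(np.pi * np.outer(n, s) / L)
    weighted = amplitudes.copy()
    weighted[0] *= 0.5
    return np.sqrt(2.0 / L) * weighted @ cos


@dataclass
class ModeAmplitudeSeries:
    """Per-frame cosine-mode amplitudes of one tracked tubule."""

    amplitudes: np.ndarray  # (n_frames, n_modes+1), a_n(t)
    lengths: np.ndarray  # per-frame contour length L
    n_segments: np.ndarray  # per-frame N
    times: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.amplitudes.shape[1] - 1

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            self.amplitudes,
            columns=[f"a{n}" for n in range(self.amplitudes.shape[1])],
        )
        df.insert(0, "frame", np.arange(len(df)))
        df["L"] = self.lengths
        return df


def decompose_series(series: ContourTimeSeries, n_max: int | None = None) -> ModeAmplitudeSeries:
    """Mode amplitudes for every frame of a tracked contour series.

    The mode count is the smallest cap over frames so the amplitude matrix
    is rectangular.
    """
    geos = [tangent_geometry(c) for c in series.contours]
    cap = min(max_mode_count(g[1], g[3]) for g in geos)
    if n_max is None:
        n_max = min(DEFAULT_N_MODES, cap)
    else:
        n_max = min(n_max, cap)
    amps = np.stack(
        [decompose_modes(th, ds, s, L, n_max=n_max) for th, ds, s, L in geos]
    )
    return ModeAmplitudeSeries(
        amplitudes=amps,
        lengths=np.array([g[3] for g in geos]),
        n_segments=np.array([len(g[1]) for g in geos]),
        times=series.times,
    )


@dataclass
class SustainedCurvature:
    """Per-mode sustained-curvature classification of one tubule."""

    sustained: np.ndarray  # flags for modes 1..n_max
    mean_amplitude: np.ndarray
    sd_amplitude: np.ndarray
    one_sided_fraction: np.ndarray  # empirical fraction of frames on the majority side
    any_sustained: bool


def sustained_curvature(
    series: ModeAmplitudeSeries, multiplier: float = 1.5, min_frames: int = 20
) -> SustainedCurvature:
    """Flag modes whose amplitude keeps one sign: |<a_n>| - 1.5 sd > 0.

    Mode 0 (mean orientation) is excluded - any non-horizontal straight
    tubule has a_0 != 0 without being curved.  The tubule carries sustained
    curvature if any mode n >= 1 is flagged.  The empirical fraction of
    frames on the majority side of zero is reported alongside the flag
    (under the 1.5 sd rule with Gaussian fluctuations it is about 93%).
    """
    a = series.amplitudes
    if a.shape[0] < min_frames:
        raise ValueError(f"need at least {min_frames} frames")
    modes = a[:, 1:]  # drop a_0
    mean = modes.mean(axis=0)
    sd = modes.std(axis=0)
    sustained = (np.abs(mean) - multiplier * sd) > 0
    pos_frac = (modes > 0).mean(axis=0)
    one_sided = np.maximum(pos_frac, 1.0 - pos_frac)
    return SustainedCurvature(
        sustained=sustained,
        mean_amplitude=mean,
        sd_amplitude=sd,
        one_sided_fraction=one_sided,
        any_sustained=bool(sustained.any()),
    )
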