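"""Small 1D ordinary-kriging interpolator.

Exact interpolation of an intensity profile with a Gaussian covariance model
and zero nugget; used to upsample sparse cross-tubule intensity profiles
before Gaussian centre fitting.  Falls back to a cubic spline when the
kriging system is ill-conditioned.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["krig_interpolate"]


def _gaussian_cov(h: np.ndarray, length_scale: float, sill: float) -> np.ndarray:
    return sill * np.exp(-((h / length_scale) ** 2))


def krig_interpolate(
    x: np.ndarray,
    y: np.ndarray,
    x_out: np.ndarray,
    length_scale: float | None = None,
    cond_limit: float = 1e10,
):
    """Ordinary kriging of samples (x, y) onto x_out.

    Returns ``(y_out, used_fallback)``.  ``length_scale`` defaults to twice
    the mean sample spacing.  When the covariance matrix condition number
    exceeds ``cond_limit`` the function falls back to a natural cubic spline
    and reports it via the flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to kriging")
    n = len(x)
    if length_scale is None:
        length_scale = 2.0 * float(np.mean(np.diff(x)))
    sill = float(np.var(y))
    if sill == 0.0:
        return np.full_like(x_out, y[0]), False

    h = np.abs(x[:, None] - x[None, :])
    C = _gaussian_cov(h, length_scale, sill)
    # kriging with a linear drift (universal kriging): the two Lagrange
    # rows enforce unbiasedness and exact reproduction of linear trends
    A = np.zeros((n + 2, n + 2))
    A[:n, :n] = C
    A[n, :n] = A[:n, n] = 1.0
    A[n + 1, :n] = A[:n, n + 1] = x
    if np.linalg.cond(C) > cond_limit:
        return CubicSpline(x, y)(x_out), True
    c_out = _gaussian_cov(np.abs(x[:, None] - x_out[None, :]), length_scale, sill)
    rhs = np.vstack([c_out, np.ones((1, len(x_out))), x_out[None, :]])
    try:
        w = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return CubicSpline(x, y)(x_out), True
    return w[:n].T @ y, False
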