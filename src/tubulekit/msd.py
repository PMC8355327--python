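"""Mean squared displacement analysis of tracked tubule points.

Time-averaged MSD, power-law (anomalous-diffusion) exponent fitting, and a
lognormal population summary of exponents.  The exponent alpha classifies
the motion: alpha < 1 sub-diffusive (alpha < 0.4 "strongly sub-diffusive"),
alpha ~ 1 Brownian, 1 < alpha < 2 super-diffusive.  Thermally fluctuating
semiflexible filaments give 3/4 without tension and 1/2 when tension
dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .point_tracker import TrackedPointSeries

__all__ = [
    "MSDResult",
    "compute_msd",
    "average_msd",
    "fit_msd_exponent",
    "summarize_exponents",
    "STRONG_SUBDIFFUSIVE_CUT",
]

STRONG_SUBDIFFUSIVE_CUT = 0.4


@dataclass
class MSDResult:
    """Time-averaged MSD curve with (optionally) a fitted power law."""

    lags: np.ndarray  # lag times tau, seconds, strictly increasing
    msd: np.ndarray  # micrometres^2
    n_pairs: np.ndarray  # valid ordered pairs per lag
    alpha: float | None = None
    alpha_stderr: float | None = None
    prefactor: float | None = None  # MSD ~ prefactor * tau^alpha
    fit_range: tuple | None = None  # (tau_min, tau_max) used in the fit

    def summary(self) -> str:
        lines = [f"MSD over {len(self.lags)} lags ({self.lags[0]:.3g}-{self.lags[-1]:.3g} s)"]
        if self.alpha is not None:
            lines.append(
                f"power-law exponent alpha = {self.alpha:.3f} +/- "
                f"{self.alpha_stderr:.3f}, prefactor {self.prefactor:.4g} um^2/s^alpha"
            )
        return "\n".join(lines)


def _displacement_xy(track: TrackedPointSeries) -> np.ndarray:
    """(n, 2) coordinates in micrometres; NaN rows at invalid frames."""
    if track.xy_positions is not None or track.line_endpoints is not None:
        xy = track.xy()
    else:
        xy = np.column_stack([track.positions, np.zeros_like(track.positions)])
    return xy * track.pixel_size


def compute_msd(
    track: TrackedPointSeries,
    max_lag_fraction: float = 0.5,
    min_pairs: int = 3,
) -> MSDResult:
    """Time-averaged 2D MSD over all valid ordered frame pairs per lag.

    Invalid frames are excluded pairwise (a pair contributes only when both
    frames are valid); lags with fewer than ``min_pairs`` pairs are dropped.
    """
    xy = _displacement_xy(track)
    valid = track.valid & np.all(np.isfinite(xy), axis=1)
    if valid.sum() < 10:
        raise ValueError("need at least 10 valid frames for an MSD")
    n = len(xy)
    max_lag = max(int(np.floor(n * max_lag_fraction)), 1)
    lags, msds, counts = [], [], []
    for lag in range(1, max_lag + 1):
        ok = valid[:-lag] & valid[lag:]
        if ok.sum() < min_pairs:
            continue
        d = xy[lag:][ok] - xy[:-lag][ok]
        lags.append(lag * track.frame_interval)
        msds.append(float(np.mean(np.sum(d**2, axis=1))))
        counts.append(int(ok.sum()))
    return MSDResult(
        lags=np.asarray(lags), msd=np.asarray(msds), n_pairs=np.asarray(counts)
    )


def average_msd(results) -> MSDResult:
    """Ensemble-average MSD curves of replicate tracks sharing a lag grid.

    The mean is taken per lag across replicates and pair counts are summed;
    replicates must have been computed on identical lag grids.
    """
    results = list(results)
    lags = results[0].lags
    for r in results[1:]:
        if len(r.lags) != len(lags) or not np.allclose(r.lags, lags):
            raise ValueError("replicates must share one lag grid")
    return MSDResult(
        lags=lags,
        msd=np.mean([r.msd for r in results], axis=0),
        n_pairs=np.sum([r.n_pairs for r in results], axis=0),
    )


def fit_msd_exponent(msd: MSDResult, fit_range: tuple | None = None) -> MSDResult:
    """Fit MSD ~ A * tau^alpha by weighted linear regression in log-log
    space (weights = pair counts).

    ``fit_range`` is a (tau_min, tau_max) window; the default runs from the
    2nd lag point to a tenth of the longest computed lag, avoiding the
    localisation-noise floor at the first lag and the long lags whose
    time-averaged values are dominated by correlated fluctuations of the
    single trajectory.  Weights combine the pair counts with the
    approximate variance growth of time-averaged MSD with lag index.
    Returns a new MSDResult carrying alpha, its standard error and the
    prefactor.
    """
    if fit_range is None:
        if len(msd.lags) < 8:
            fit_range = (msd.lags[0], msd.lags[-1])
        else:
            # at least the first 8 lags even for short tracks
            hi = max(msd.lags[-1] / 10.0, msd.lags[min(len(msd.lags) - 1, 7)])
            fit_range = (msd.lags[1], hi)
    lo, hi = fit_range
    sel = (msd.lags >= lo) & (msd.lags <= hi) & (msd.msd > 0)
    if sel.sum() < 4:
        raise ValueError("fewer than 4 usable lags in the fit range")
    x = np.log(msd.lags[sel])
    y = np.log(msd.msd[sel])
    # lag index k: relative variance of a time-averaged MSD point grows
    # roughly as (2k^2+1)/(k n_pairs), so weight by its inverse
    kk = np.maximum(np.round(msd.lags[sel] / msd.lags[0]), 1.0)
    w = msd.n_pairs[sel] * kk / (2.0 * kk**2 + 1.0)
    w = w / w.mean()  # relative weights, normalised to mean 1
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    sxx = (w * (x - xb) ** 2).sum()
    alpha = float((w * (x - xb) * (y - yb)).sum() / sxx)
    intercept = yb - alpha * xb
    resid = y - (intercept + alpha * x)
    dof = max(sel.sum() - 2, 1)
    s2 = float((w * resid**2).sum() / dof)
    stderr = float(np.sqrt(s2 / sxx))
    return MSDResult(
        lags=msd.lags,
        msd=msd.msd,
        n_pairs=msd.n_pairs,
        alpha=alpha,
        alpha_stderr=stderr,
        prefactor=float(np.exp(intercept)),
        fit_range=(float(lo), float(hi)),
    )


@dataclass
class ExponentSummary:
    """Population summary of per-track MSD exponents."""

    mean: float  # mean of the fitted lognormal distribution
    sem: float  # delta-method standard error of that mean
    mu: float  # lognormal log-scale location
    sigma: float  # lognormal log-scale width
    n: int
    classification: list  # per-track labels
    strongly_subdiffusive: np.ndarray  # alpha < 0.4 flags

    def summary(self) -> str:
        return (
            f"lognormal mean exponent {self.mean:.3f} +/- {self.sem:.3f} "
            f"(n = {self.n}; mu = {self.mu:.3f}, sigma = {self.sigma:.3f})"
        )


def classify_alpha(alpha: float) -> str:
    if alpha < 1.0:
        return "sub-diffusive"
    if alpha > 1.0:
        return "super-diffusive"
    return "diffusive"


def summarize_exponents(alphas, histogram_fit: bool = False, n_bins: int = 20) -> ExponentSummary:
    """Lognormal summary of a population of MSD exponents.

    By default a maximum-likelihood lognormal fit on the exponent samples
    (bin-free); ``histogram_fit=True`` instead least-squares fits the
    lognormal density to a histogram.  The reported mean is the distribution
    mean exp(mu + sigma^2/2) with a delta-method standard error.  Exponents
    <= 0 are excluded with a warning.
    """
    alphas = np.asarray(alphas, dtype=float)
    bad = alphas <= 0
    if bad.any():
        warnings.warn(f"excluding {bad.sum()} non-positive exponents", stacklevel=2)
        alphas = alphas[~bad]
    if len(alphas) < 3:
        raise ValueError("need at least 3 positive exponents")
    logs = np.log(alphas)
    n = len(alphas)
    if histogram_fit:
        from scipy.optimize import curve_fit as _cf
        from scipy.stats import lognorm

        counts, edges = np.histogram(alphas, bins=n_bins, density=True)
        mids = 0.5 * (edges[:-1] + edges[1:])

        def pdf(x, mu, sigma):
            return lognorm.pdf(x, s=max(sigma, 1e-9), scale=np.exp(mu))

        p0 = (float(np.mean(logs)), float(np.std(logs)) or 0.1)
        (mu, sigma), _ = _cf(pdf, mids, counts, p0=p0, maxfev=5000)
        sigma = abs(sigma)
    else:
        mu = float(np.mean(logs))
        sigma = float(np.std(logs))  # MLE (1/n) variance
    mean = float(np.exp(mu + sigma**2 / 2.0))
    # delta method: var(mean) = mean^2 (var(mu_hat) + sigma^2 var(sigma_hat))
    var_mu = sigma**2 / n
    var_sigma = sigma**2 / (2.0 * n)
    sem = float(mean * np.sqrt(var_mu + sigma**2 * var_sigma))
    return ExponentSummary(
        mean=mean,
        sem=sem,
        mu=mu,
        sigma=sigma,
        n=n,
        classification=[classify_alpha(a) for a in alphas],
        strongly_subdiffusive=alphas < STRONG_SUBDIFFUSIVE_CUT,
    )
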