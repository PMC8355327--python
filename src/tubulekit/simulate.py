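"""Synthetic filament data with known ground truth.

Static worm-like chains, overdamped Langevin dynamics of a semiflexible
bead chain (thermal, tensioned, or actively kicked), Brownian point tracks,
and rendering of coordinate ground truth into noisy microscopy-like image
stacks.  Every generator is seeded and bit-reproducible.

Units: length in micrometres, time in seconds, energy in units of the
thermal energy kT (so bending rigidity kappa = Lp * kT and forces are
kT / um).  Drag is per bead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contour import ContourTimeSeries, FilamentContour
from .point_tracker import TrackedPointSeries

__all__ = [
    "FilamentSimConfig",
    "RenderConfig",
    "sample_wlc",
    "sample_wlc_ensemble",
    "simulate_filament_dynamics",
    "simulate_filament_ensemble",
    "simulate_brownian_track",
    "midpoint_transverse_track",
    "relaxation_time",
    "render_video",
    "thermal_free_config",
    "tension_dominated_config",
    "active_kick_config",
]


# ---------------------------------------------------------------------------
# Static worm-like chains
# ---------------------------------------------------------------------------


def sample_wlc(Lp: float, L: float, n_points: int = 50, convention: str = "2d",
               seed=None, pixel_size: float = 1.0) -> FilamentContour:
    """Sample one worm-like chain as a tangent-angle random walk.

    convention "2d": per-step angle variance ds/Lp (tangent correlation
    decays as exp(-s/2Lp), the planar convention).  convention "eq1": per-
    step variance 2*ds/Lp so the correlation decays as exp(-s/Lp), matching
    the three-dimensional Kratky-Porod end-to-end relation.
    """
    if Lp <= 0 or L <= 0:
        raise ValueError("Lp and L must be positive")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    pts = _wlc_points(rng, Lp, L, n_points, convention, 1)[0]
    return FilamentContour(pts, pixel_size=pixel_size)


def _wlc_points(rng, Lp, L, n_points, convention, n_chains):
    ds = L / (n_points - 1)
    if convention.lower() in ("2d", "planar"):
        var = ds / Lp
    elif convention.lower() in ("eq1", "eq1-matching", "3d"):
        var = 2.0 * ds / Lp
    else:
        raise ValueError(f"unknown convention {convention!r}")
    dtheta = rng.normal(0.0, np.sqrt(var), size=(n_chains, n_points - 1))
    dtheta[:, 0] = 0.0  # first segment along +x
    theta = np.cumsum(dtheta, axis=1)
    steps = ds * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    pts = np.concatenate(
        [np.zeros((n_chains, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    return pts


def sample_wlc_ensemble(Lp, L_values, n_points: int = 50, convention: str = "eq1",
                        seed=None):
    """Sample one chain per entry of ``L_values``; returns (L, R) arrays in
    the chain's length units (vectorised over chains of equal point count)."""
    rng = np.random.default_rng(seed)
    L_values = np.asarray(L_values, dtype=float)
    Ls, Rs = np.empty(len(L_values)), np.empty(len(L_values))
    for i, L in enumerate(L_values):
        pts = _wlc_points(rng, Lp, L, n_points, convention, 1)[0]
        Ls[i] = L
        Rs[i] = np.linalg.norm(pts[-1] - pts[0])
    return Ls, Rs


# ---------------------------------------------------------------------------
# Filament dynamics
# ---------------------------------------------------------------------------


@dataclass
class FilamentSimConfig:
    """Configuration of the overdamped semiflexible bead-chain simulation.

    Active forcing is a burst (telegraph) process: each active site feels a
    constant force ``active_amplitude`` along ``active_direction`` during
    bursts that start at rate ``active_burst_rate`` and last (exponentially
    distributed) ``active_burst_duration`` on average - an intermittent,
    direction-biased drive that produces skewed transverse displacements.
    """

    length: float = 3.0  # contour length, um
    persistence_length: float = 5.0  # um (bending rigidity kappa = Lp * kT)
    n_beads: int = 21
    tension: float = 0.0  # kT / um, requires pinned ends
    kT: float = 1.0  # thermal energy factor
    drag: float = 1.0  # per-bead drag, kT s / um^2
    dt: float = 2e-5  # integrator step, s
    n_frames: int = 2000
    record_every: int = 50  # steps between recorded frames
    ends: str = "pinned"  # "pinned" | "free"
    pinned_slack: float = 0.95  # pinned end separation / L when untensioned
    k_stretch: float = 2000.0  # bond spring constant, kT / um^2
    warmup_time: float | None = None  # defaults to 2x the slowest relaxation
    active_sites: tuple = ()
    active_amplitude: float = 0.0  # kT / um
    active_direction: tuple = (0.0, 1.0)
    active_burst_rate: float = 2.0  # bursts / s
    active_burst_duration: float = 0.05  # mean burst length, s
    seed: int = 0

    @property
    def bond_length(self) -> float:
        return self.length / (self.n_beads - 1)

    @property
    def kappa(self) -> float:
        return self.persistence_length * self.kT

    def stability_limit(self) -> float:
        """Largest stable Euler step: 1 / lambda_max of the force Jacobian."""
        a = self.bond_length
        lam = max(4.0 * self.k_stretch, 16.0 * self.kappa / a**3) / self.drag
        return 1.0 / lam

    def validate(self) -> None:
        if self.tension > 0 and self.ends != "pinned":
            raise ValueError("tension requires pinned ends")
        if self.tension < 0:
            raise ValueError("tension must be >= 0")
        limit = self.stability_limit()
        if self.dt > limit:
            raise ValueError(
                f"dt={self.dt:g} unstable for the stiffest mode; use dt <= {limit:.2g}"
            )


def relaxation_time(config: FilamentSimConfig) -> float:
    """Relaxation time of the slowest transverse mode.

    Tension-dominated: tau_1 = xi / (T q1^2) with q1 = pi/L; bending:
    tau_1 = xi / (kappa q1^4) with q1 = pi/L for pinned ends and 4.73/L for
    the first free-free bending mode (xi = drag per unit length).
    """
    xi = config.drag / config.bond_length
    L = config.length
    if config.tension > 0:
        q1 = np.pi / L
        return xi / (config.tension * q1**2)
    q1 = np.pi / L if config.ends == "pinned" else 4.73 / L
    return xi / (config.kappa * q1**4)


def _initial_shape(config: FilamentSimConfig) -> np.ndarray:
    n = config.n_beads
    L = config.length
    if config.ends == "free" or config.tension > 0:
        x = np.linspace(0.0, L, n)
        return np.column_stack([x, np.zeros(n)])
    # pinned with slack: shallow sine arc whose arclength ~ L over span D
    D = config.pinned_slack * L
    A = 2.0 * np.sqrt(max(D * (L - D), 0.0)) / np.pi
    x = np.linspace(0.0, D, n)
    y = A * np.sin(np.pi * x / D)
    return np.column_stack([x, y])


def simulate_filament_ensemble(
    config: FilamentSimConfig, n_replicates: int = 1
) -> list:
    """Integrate ``n_replicates`` independent filaments jointly.

    Overdamped Euler-Maruyama integration of a bead chain with harmonic
    bonds (pre-strained when tension > 0), discrete bending forces, thermal
    noise, and optional burst-active forces.  Returns one
    :class:`ContourTimeSeries` (ground truth, um) per replicate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, N = n_replicates, config.n_beads
    a = config.bond_length
    a0 = a - config.tension / config.k_stretch if config.tension > 0 else a
    kb = config.kappa / a**3
    ks = config.k_stretch
    dt = config.dt
    noise_sd = np.sqrt(2.0 * config.kT * config.drag / dt) if config.kT > 0 else 0.0
    pinned = config.ends == "pinned"

    pos = np.broadcast_to(_initial_shape(config), (R, N, 2)).copy()
    ends0 = pos[:, 0].copy()
    ends1 = pos[:, -1].copy()

    sites = np.asarray(config.active_sites, dtype=int)
    direction = np.asarray(config.active_direction, dtype=float)
    direction = direction / np.linalg.norm(direction) if direction.any() else direction
    burst_on = np.zeros((R, len(sites)), dtype=bool)
    p_start = config.active_burst_rate * dt
    p_stop = dt / config.active_burst_duration if config.active_burst_duration > 0 else 1.0

    warmup = config.warmup_time
    if warmup is None:
        warmup = 0.0 if config.ends == "free" else 2.0 * relaxation_time(config)
    warm_steps = int(np.ceil(warmup / dt))
    total_steps = warm_steps + config.n_frames * config.record_every

    coords = np.empty((R, config.n_frames, N, 2))
    frame = 0
    max_step = a  # instability guard: a bead moving a bond length per step

    for step in range(total_steps):
        F = np.zeros_like(pos)
        # bonds
        d = pos[:, 1:] - pos[:, :-1]
        ln = np.linalg.norm(d, axis=-1, keepdims=True)
        fb = ks * (ln - a0) * (d / ln)
        F[:, :-1] += fb
        F[:, 1:] -= fb
        # bending (fourth-difference of the discrete curvature)
        if kb > 0 and N >= 3:
            c = pos[:, 2:] - 2.0 * pos[:, 1:-1] + pos[:, :-2]
            F[:, :-2] -= kb * c
            F[:, 1:-1] += 2.0 * kb * c
            F[:, 2:] -= kb * c
        # active bursts
        if len(sites) and config.active_amplitude != 0.0:
            start = rng.random((R, len(sites))) < p_start
            stop = rng.random((R, len(sites))) < p_stop
            burst_on = (burst_on & ~stop) | (~burst_on & start)
            F[:, sites] += (
                config.active_amplitude * burst_on[..., None] * direction[None, None, :]
            )
        if noise_sd > 0:
            F += rng.normal(0.0, noise_sd, size=F.shape)
        disp = (dt / config.drag) * F
        if np.max(np.abs(disp)) > max_step:
            raise RuntimeError(
                "integration unstable (bead displacement exceeded the bond "
                f"length); reduce dt below {config.stability_limit():.2g} s"
            )
        pos = pos + disp
        if pinned:
            pos[:, 0] = ends0
            pos[:, -1] = ends1
        if step >= warm_steps and (step - warm_steps) % config.record_every == 0:
            coords[:, frame] = pos
            frame += 1
    times = np.arange(config.n_frames) * dt * config.record_every
    return [
        ContourTimeSeries.from_coordinates(
            coords[r], times, pixel_size=1.0, params={"config": config.__dict__}
        )
        for r in range(R)
    ]


def simulate_filament_dynamics(config: FilamentSimConfig) -> ContourTimeSeries:
    """Single-filament convenience wrapper around the ensemble integrator."""
    return simulate_filament_ensemble(config, n_replicates=1)[0]


# regime presets ------------------------------------------------------------


def thermal_free_config(seed: int = 0, n_frames: int = 10_000) -> FilamentSimConfig:
    """Untensioned thermal filament with free ends (transverse MSD of the
    midpoint grows as tau^(3/4) below the slowest bending relaxation)."""
    return FilamentSimConfig(
        length=10.0, persistence_length=5.0, n_beads=65, tension=0.0,
        ends="free", dt=2e-5, record_every=50, n_frames=n_frames,
        k_stretch=2000.0, seed=seed,
    )


def tension_dominated_config(seed: int = 0, n_frames: int = 10_000) -> FilamentSimConfig:
    """Strongly tensioned, weakly bending filament between pinned ends
    (transverse MSD grows as tau^(1/2))."""
    return FilamentSimConfig(
        length=5.0, persistence_length=0.1, n_beads=33, tension=50.0,
        ends="pinned", dt=2e-5, record_every=50, n_frames=n_frames,
        k_stretch=2000.0, seed=seed,
    )


def active_kick_config(seed: int = 0, n_frames: int = 150) -> FilamentSimConfig:
    """Lightly tensioned pinned filament with strong direction-biased force
    bursts at its centre bead (intermittent kicks a few thermal SDs strong);
    the thermal control is the same config with ``active_amplitude = 0``.
    Frames are recorded about one relaxation time apart so successive
    transverse displacements are nearly independent."""
    return FilamentSimConfig(
        length=1.5, persistence_length=0.5, n_beads=11, tension=3.0,
        ends="pinned", kT=0.08, drag=0.05, dt=1e-5,
        record_every=2500, n_frames=n_frames, k_stretch=500.0,
        active_sites=(5,), active_amplitude=12.0, active_direction=(0.0, 1.0),
        active_burst_rate=1.5, active_burst_duration=0.08, seed=seed,
    )


# ---------------------------------------------------------------------------
# Brownian point track
# ---------------------------------------------------------------------------


def simulate_brownian_track(
    D: float, dt: float, n_frames: int, seed=None, pixel_size: float = 1.0
) -> TrackedPointSeries:
    """2D Brownian trajectory: Gaussian increments of variance 2 D dt per
    axis (D in um^2/s; coordinates stored in pixels of ``pixel_size`` um)."""
    if D < 0 or dt <= 0:
        raise ValueError("need D >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, 2))
    xy_um = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    xy_px = xy_um / pixel_size
    return TrackedPointSeries(
        positions=np.zeros(n_frames),
        valid=np.ones(n_frames, dtype=bool),
        frame_interval=dt,
        pixel_size=pixel_size,
        xy_positions=xy_px,
    )


def midpoint_transverse_track(series: ContourTimeSeries) -> TrackedPointSeries:
    """Transverse coordinate of the filament midpoint per frame.

    Each frame is rotated so its end-to-end axis lies along x; the signed
    perpendicular offset of the middle bead from that axis is returned as a
    1D track (removes rigid-body translation/rotation of free filaments).
    """
    coords = series.coordinates()
    e0 = coords[:, 0]
    axis = coords[:, -1] - e0
    axis = axis / np.linalg.norm(axis, axis=1, keepdims=True)
    mid = coords[:, coords.shape[1] // 2] - e0
    transverse = axis[:, 0] * mid[:, 1] - axis[:, 1] * mid[:, 0]
    dt = float(series.times[1] - series.times[0]) if series.n_frames > 1 else 1.0
    return TrackedPointSeries(
        positions=transverse / series.pixel_size,
        valid=np.ones(series.n_frames, dtype=bool),
        frame_interval=dt,
        pixel_size=series.pixel_size,
    )


# ---------------------------------------------------------------------------
# Rendering to microscopy-like image stacks
# ---------------------------------------------------------------------------


@dataclass
class RenderConfig:
    """Rendering of coordinate ground truth into noisy image stacks."""

    pixel_size: float = 0.104  # um / pixel
    psf_sigma: float = 1.5  # PSF width, pixels
    peak_intensity: float = 100.0  # tubule ridge peak above background
    background: float = 10.0
    gaussian_noise: float = 0.0  # additive noise SD
    poisson_noise: bool = False
    image_shape: tuple = (64, 64)  # (rows, cols)
    origin: tuple = (0.0, 0.0)  # um offset of pixel (0, 0)
    source_spacing: float = 0.2  # px between line-source samples
    seed: int = 0


def render_video(truth: ContourTimeSeries, config: RenderConfig):
    """Render a filament coordinate series as a noisy fluorescence stack.

    Each frame draws the contour as a dense line source convolved with a
    Gaussian PSF (cross-section: a Gaussian of the configured sigma,
    peaking at ``peak_intensity`` on the line), adds the background, then
    applies Poisson and/or Gaussian noise.  Returns ``(video, truth_px)``
    where ``truth_px`` is the ground-truth coordinate series converted to
    pixel units of the rendering.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    margin = 3.0 * config.psf_sigma
    video = np.empty((truth.n_frames, h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    truth_coords = []
    for i, contour in enumerate(truth.contours):
        pts_px = (contour.points * contour.pixel_size - np.asarray(config.origin)) / config.pixel_size
        truth_coords.append(pts_px)
        if (
            pts_px[:, 0].min() < margin or pts_px[:, 0].max() > w - 1 - margin
            or pts_px[:, 1].min() < margin or pts_px[:, 1].max() > h - 1 - margin
        ):
            raise ValueError(f"frame {i}: filament exits the frame (margin {margin:.1f} px)")
        src = _densify(pts_px, config.source_spacing)
        # line source x Gaussian PSF: per-sample amplitude normalised so the
        # on-ridge peak equals peak_intensity
        amp = config.peak_intensity * config.source_spacing / (
            np.sqrt(2.0 * np.pi) * config.psf_sigma
        )
        d2 = (xx[None] - src[:, 0, None, None]) ** 2 + (yy[None] - src[:, 1, None, None]) ** 2
        frame = config.background + amp * np.exp(-d2 / (2.0 * config.psf_sigma**2)).sum(axis=0)
        if config.poisson_noise:
            frame = rng.poisson(np.maximum(frame, 0)).astype(float)
        if config.gaussian_noise > 0:
            frame = frame + rng.normal(0.0, config.gaussian_noise, size=frame.shape)
        video[i] = frame
    truth_px = ContourTimeSeries.from_coordinates(
        np.stack(truth_coords), truth.times, pixel_size=config.pixel_size
    )
    return video, truth_px


def _densify(pts: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    n = max(int(np.ceil(s[-1] / spacing)) + 1, 2)
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])])
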