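"""Morphometrics of a traced tubule network.

Works on the text output of SOAX-style network tracing (snakes = tubule
polylines, plus junction coordinates): tubule contour lengths, junction
coordination numbers, junction angles, and worm-like-chain persistence-length
estimation from end-to-end statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .contour import FilamentContour

__all__ = [
    "NetworkGraph",
    "PersistenceFit",
    "parse_soax_output",
    "write_soax",
    "contour_length",
    "find_junction_members",
    "junction_angles",
    "coordination_summary",
    "wlc_mean_square_end_to_end",
    "fit_persistence_length",
]


class SoaxParseError(ValueError):
    """Raised when a snake file cannot be parsed; names the offending line."""


@dataclass
class NetworkGraph:
    """Traced tubule network: polyline tubules plus junction positions."""

    tubules: list  # list[FilamentContour]
    junctions: np.ndarray  # (m, 2) junction (x, y) in pixels
    pixel_size: float = 1.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.junctions = np.asarray(self.junctions, dtype=float).reshape(-1, 2)

    @property
    def n_tubules(self) -> int:
        return len(self.tubules)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


# ---------------------------------------------------------------------------
# SOAX snake text I/O
#
# Layout handled (the columnar layout SOAX writes, junction section after
# the snakes):
#
#   <optional "key value" parameter lines>
#   s  p  x  y  z  fg_int  bg_int
#   0  0  1.0  2.0  0.0  200  50
#   ...
#   #
#   x  y  z          <- one junction per line
# ---------------------------------------------------------------------------


def parse_soax_output(path, pixel_size: float = 1.0) -> NetworkGraph:
    """Read a SOAX snake text file into a :class:`NetworkGraph`.

    Snake records are grouped by their snake id into one
    :class:`FilamentContour` each; junction coordinates are preserved.
    Coordinates are kept in pixels. Single-point snakes are rejected.
    """
    params: dict = {}
    snakes: dict = {}
    junctions: list = []
    in_points = False
    in_junctions = False
    with open(path) as fh:
        lines = fh.readlines()
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            in_junctions = True
            in_points = False
            continue
        toks = line.replace(",", " ").split()
        if in_junctions:
            try:
                vals = [float(t) for t in toks[:2]]
            except ValueError as e:
                raise SoaxParseError(f"line {ln}: bad junction record {line!r}") from e
            junctions.append(vals)
            continue
        low = [t.lower() for t in toks]
        if low[:2] == ["s", "p"]:
            in_points = True
            continue
        if not in_points:
            # header parameter line: "name value" (value may be non-numeric)
            if len(toks) >= 2:
                params[toks[0].rstrip(":")] = " ".join(toks[1:])
                continue
            raise SoaxParseError(f"line {ln}: unrecognised header line {line!r}")
        try:
            sid = int(float(toks[0]))
            x, y = float(toks[2]), float(toks[3])
        except (ValueError, IndexError) as e:
            raise SoaxParseError(f"line {ln}: malformed snake record {line!r}") from e
        snakes.setdefault(sid, []).append((x, y))
    if not snakes:
        raise SoaxParseError(f"{path}: no snake records found")
    tubules = []
    for sid in sorted(snakes):
        pts = np.asarray(snakes[sid], dtype=float)
        if len(pts) < 2:
            raise SoaxParseError(f"snake {sid} has fewer than 2 points")
        tubules.append(FilamentContour(pts, pixel_size=pixel_size))
    return NetworkGraph(
        tubules=tubules,
        junctions=np.asarray(junctions, dtype=float).reshape(-1, 2),
        pixel_size=pixel_size,
        params=params,
    )


def write_soax(graph: NetworkGraph, path) -> None:
    """Write a :class:`NetworkGraph` in the snake text layout read by
    :func:`parse_soax_output` (round-trips identically)."""
    with open(path, "w") as fh:
        for k, v in graph.params.items():
            fh.write(f"{k} {v}\n")
        fh.write("s p x y z fg_int bg_int\n")
        for sid, tub in enumerate(graph.tubules):
            for p, (x, y) in enumerate(tub.points):
                fh.write(f"{sid} {p} {float(x)!r} {float(y)!r} 0.0 0 0\n")
        fh.write("#\n")
        for x, y in graph.junctions:
            fh.write(f"{float(x)!r} {float(y)!r} 0.0\n")


# ---------------------------------------------------------------------------
# Lengths, junctions, angles
# ---------------------------------------------------------------------------


def contour_length(contour: FilamentContour) -> float:
    """Tubule contour length L in micrometres (sum of segment lengths)."""
    return contour.length_um


def find_junction_members(graph: NetworkGraph, radius: float = 2.0) -> list:
    """Map each junction to the tubule ends lying within ``radius`` pixels.

    Returns a list (one entry per junction) of ``(tubule_index, end)`` tuples
    with ``end`` 0 for the first point and -1 for the last.  The coordination
    number of a junction is the number of members; junctions with fewer than
    two members are returned with their (short) member list and are excluded
    from angle analysis by callers.
    """
    ends = []
    for ti, tub in enumerate(graph.tubules):
        ends.append((ti, 0, tub.points[0]))
        ends.append((ti, -1, tub.points[-1]))
    out = []
    for j in graph.junctions:
        members = [
            (ti, e)
            for ti, e, pos in ends
            if np.linalg.norm(pos - j) <= radius
        ]
        out.append(members)
    return out


def _end_direction(tubule: FilamentContour, end: int, n_fit: int = 5) -> np.ndarray:
    """Unit direction of a tubule emanating from one of its ends, from a
    least-squares line through the ``n_fit`` points closest to that end
    (all points if fewer).  Direction points away from the junction end."""
    pts = tubule.points if end == 0 else tubule.points[::-1]
    pts = pts[: min(n_fit, len(pts))]
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate direction fit: coincident points")
    # principal axis of the point cloud = total-least-squares line
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    # orient along increasing arclength away from the end
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    return d / np.linalg.norm(d)


def junction_angles(
    graph: NetworkGraph,
    junction_index: int,
    radius: float = 2.0,
    n_fit: int = 5,
) -> np.ndarray:
    """Angles (degrees) between tubules meeting at one junction.

    Member directions come from a line fit to the ``n_fit`` points nearest
    the junction.  Two-way junctions return the single smallest angle
    between the two emanating rays, in (0, 180].  Junctions with three or
    more members return the angles between angularly adjacent rays (which
    sum to 360 degrees).
    """
    members = find_junction_members(graph, radius=radius)[junction_index]
    if len(members) < 2:
        raise ValueError("junction has fewer than 2 member tubule ends")
    dirs = []
    for ti, e in members:
        try:
            dirs.append(_end_direction(graph.tubules[ti], e, n_fit=n_fit))
        except ValueError:
            import warnings

            warnings.warn(f"skipping degenerate member (tubule {ti})", stacklevel=2)
    if len(dirs) < 2:
        raise ValueError("fewer than 2 usable member directions")
    dirs = np.asarray(dirs)
    if len(dirs) == 2:
        cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
        ang = np.degrees(np.arccos(cosang))
        if ang == 0.0:
            ang = 180.0  # parallel rays meeting head-on -> collinear tubules
        return np.array([ang])
    # n-way: sort rays by polar angle, take consecutive differences
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    phi = np.sort(np.mod(phi, 2 * np.pi))
    gaps = np.diff(np.concatenate([phi, [phi[0] + 2 * np.pi]]))
    return np.degrees(gaps)


def coordination_summary(graph: NetworkGraph, radius: float = 2.0) -> dict:
    """Fraction of junctions per coordination number (fractions sum to 1).

    Coordination numbers of 5 or more are reported but are rare in real
    tubule networks; junctions with fewer than two members are counted
    under their (degenerate) coordination number as well so the fractions
    remain a partition.
    """
    members = find_junction_members(graph, radius=radius)
    if not members:
        raise ValueError("graph has no junctions")
    counts: dict = {}
    for m in members:
        counts[len(m)] = counts.get(len(m), 0) + 1
    total = sum(counts.values())
    return {k: counts[k] / total for k in sorted(counts)}


# ---------------------------------------------------------------------------
# Persistence length from end-to-end statistics
# ---------------------------------------------------------------------------


def wlc_mean_square_end_to_end(L, Lp):
    """Kratky-Porod mean square end-to-end distance
    <R^2> = 2 Lp (L - Lp (1 - exp(-L/Lp)))."""
    L = np.asarray(L, dtype=float)
    # expm1 keeps the small-L/Lp limit (L^2) accurate
    return 2.0 * Lp * (L + Lp * np.expm1(-L / Lp))


@dataclass
class PersistenceFit:
    """Result of a worm-like-chain persistence-length fit."""

    Lp: float  # micrometres
    Lp_stderr: float  # micrometres
    residual: float  # root-mean-square residual of R^2 (um^2)
    n_tubules: int
    near_rigid: bool = False  # Lp at upper bound: data indistinguishable from rods

    def summary(self) -> str:
        flag = "  [near-rigid: Lp at bound]" if self.near_rigid else ""
        return (
            f"Persistence length Lp = {self.Lp:.4g} +/- {self.Lp_stderr:.2g} um "
            f"(n = {self.n_tubules} tubules, RMS residual {self.residual:.3g} um^2)"
            + flag
        )


def fit_persistence_length(
    tubules,
    n_bins: int | None = None,
    bounds=(1e-3, 1e4),
) -> PersistenceFit:
    """Fit the persistence length to (L, R^2) pairs of traced tubules.

    Nonlinear least squares of the Kratky-Porod relation
    ``<R^2> = 2 Lp (L - Lp (1 - e^{-L/Lp}))`` to per-tubule contour length L
    and squared end-to-end distance R^2 (both micrometres).  By default the
    raw pairs are fit; with ``n_bins`` the tubules are first grouped into
    equal-count L bins and the mean R^2 per bin is fit, as in classic WLC
    analyses.

    Accepts FilamentContour objects or (L, R) tuples.
    """
    pairs = []
    for t in tubules:
        if isinstance(t, FilamentContour):
            pairs.append((t.length_um, t.end_to_end_um))
        else:
            pairs.append((float(t[0]), float(t[1])))
    L = np.array([p[0] for p in pairs])
    R2 = np.array([p[1] ** 2 for p in pairs])
    if len(L) < 3:
        raise ValueError("need at least 3 tubules for a persistence fit")
    if np.any(L <= 0):
        raise ValueError("all contour lengths must be positive")

    if n_bins is not None:
        order = np.argsort(L)
        idx_groups = np.array_split(order, n_bins)
        L = np.array([L[g].mean() for g in idx_groups if len(g)])
        R2 = np.array([R2[g].mean() for g in idx_groups if len(g)])

    def resid(p):
        return wlc_mean_square_end_to_end(L, p[0]) - R2

    p0 = np.array([np.median(L)])
    sol = least_squares(resid, p0, bounds=([bounds[0]], [bounds[1]]))
    if not sol.success:
        raise RuntimeError(f"persistence-length fit did not converge: {sol.message}")
    Lp = float(sol.x[0])
    near_rigid = Lp >= 0.99 * bounds[1]
    # standard error from the Gauss-Newton covariance
    r = sol.fun
    dof = max(len(L) - 1, 1)
    s2 = float(r @ r) / dof
    JtJ = float((sol.jac.T @ sol.jac).item())
    stderr = float(np.sqrt(s2 / JtJ)) if JtJ > 0 else np.inf
    return PersistenceFit(
        Lp=Lp,
        Lp_stderr=stderr,
        residual=float(np.sqrt(np.mean(r**2))),
        n_tubules=len(pairs),
        near_rigid=near_rigid,
    )
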