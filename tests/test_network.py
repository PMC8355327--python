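import numpy as np
import pytest

from tubulekit.contour import FilamentContour
from tubulekit.network import (
    NetworkGraph,
    PersistenceFit,
    SoaxParseError,
    contour_length,
    coordination_summary,
    find_junction_members,
    fit_persistence_length,
    junction_angles,
    parse_soax_output,
    wlc_mean_square_end_to_end,
    write_soax,
)


def _graph(tubule_points, junctions):
    return NetworkGraph(
        tubules=[FilamentContour(np.asarray(p, dtype=float)) for p in tubule_points],
        junctions=np.asarray(junctions, dtype=float),
    )


# ---------------------------------------------------------------------------
# SOAX I/O
# ---------------------------------------------------------------------------


SOAX_TEXT = """\
alpha 0.01
beta 0.1
s p x y z fg_int bg_int
0 0 1.0 1.0 0.0 200 50
0 1 5.0 1.0 0.0 210 50
1 0 5.0 1.0 0.0 190 50
1 1 5.0 6.0 0.0 185 50
#
5.0 1.0 0.0
"""


class TestSoaxIO:
    def test_counts(self, tmp_path):
        f = tmp_path / "net.txt"
        f.write_text(SOAX_TEXT)
        g = parse_soax_output(f)
        assert g.n_tubules == 2
        assert g.n_junctions == 1
        np.testing.assert_allclose(g.junctions[0], [5.0, 1.0])

    def test_single_point_snake_rejected(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("s p x y z fg_int bg_int\n0 0 1.0 1.0 0.0 1 1\n")
        with pytest.raises(SoaxParseError):
            parse_soax_output(f)

    def test_malformed_record_names_line(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("s p x y z fg_int bg_int\n0 0 1.0 oops 0.0 1 1\n")
        with pytest.raises(SoaxParseError, match="line 2"):
            parse_soax_output(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("")
        with pytest.raises(SoaxParseError):
            parse_soax_output(f)

    def test_write_parse_roundtrip(self, tmp_path):
        f = tmp_path / "net.txt"
        f.write_text(SOAX_TEXT)
        g = parse_soax_output(f)
        f2 = tmp_path / "roundtrip.txt"
        write_soax(g, f2)
        g2 = parse_soax_output(f2)
        assert g2.n_tubules == g.n_tubules
        for a, b in zip(g.tubules, g2.tubules):
            np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(g.junctions, g2.junctions)


# ---------------------------------------------------------------------------
# Lengths, junction membership, angles
# ---------------------------------------------------------------------------


def test_contour_length_345_triangle():
    c = FilamentContour(np.array([[0.0, 0.0], [3.0, 4.0]]))
    assert contour_length(c) == pytest.approx(5.0)


def test_contour_length_micrometres():
    c = FilamentContour(np.array([[0.0, 0.0], [10.0, 0.0]]), pixel_size=0.104)
    assert contour_length(c) == pytest.approx(1.04)


class TestJunctionMembers:
    def test_radius_inclusion(self):
        g = _graph(
            [
                [[1.5, 0.0], [8.0, 0.0]],  # end at distance 1.5 -> in
                [[0.0, 2.5], [0.0, 8.0]],  # end at distance 2.5 -> out
                [[-1.0, 0.0], [-8.0, 0.0]],  # distance 1 -> in
            ],
            [[0.0, 0.0]],
        )
        members = find_junction_members(g, radius=2.0)[0]
        assert len(members) == 2
        assert {m[0] for m in members} == {0, 2}

    def test_coordination_number(self):
        g = _graph(
            [
                [[0.5, 0.0], [8.0, 0.0]],
                [[0.0, 0.5], [0.0, 8.0]],
                [[-0.5, 0.0], [-8.0, 0.0]],
            ],
            [[0.0, 0.0]],
        )
        assert len(find_junction_members(g)[0]) == 3


class TestJunctionAngles:
    def test_perpendicular_tubules(self):
        g = _graph(
            [
                [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]],
                [[0.0, 0.0], [0.0, 1.0], [0.0, 2.0], [0.0, 3.0]],
            ],
            [[0.0, 0.0]],
        )
        angles = junction_angles(g, 0)
        assert angles == pytest.approx([90.0])

    def test_symmetric_three_way(self):
        tubules = []
        for phi in np.radians([0.0, 120.0, 240.0]):
            d = np.array([np.cos(phi), np.sin(phi)])
            tubules.append([d * r for r in (0.0, 1.0, 2.0, 3.0)])
        g = _graph(tubules, [[0.0, 0.0]])
        np.testing.assert_allclose(junction_angles(g, 0), [120.0] * 3, atol=1e-9)

    def test_collinear_opposite_tubules(self):
        g = _graph(
            [
                [[0.0, 0.0], [3.0, 0.0], [6.0, 0.0]],
                [[0.0, 0.0], [-3.0, 0.0], [-6.0, 0.0]],
            ],
            [[0.0, 0.0]],
        )
        assert junction_angles(g, 0) == pytest.approx([180.0])

    def test_rigid_motion_invariance(self):
        """Angles are unchanged by global rotation + translation."""
        rng = np.random.default_rng(3)
        tubules = [rng.normal(size=(6, 2)).cumsum(axis=0) * 0.5 for _ in range(3)]
        tubules = [t - t[0] for t in tubules]  # all ends at origin
        g = _graph(tubules, [[0.0, 0.0]])
        base = junction_angles(g, 0)
        phi = 0.7321
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        shift = np.array([12.3, -4.5])
        g2 = _graph([t @ R.T + shift for t in tubules], [shift])
        np.testing.assert_allclose(junction_angles(g2, 0), base, atol=1e-9)


class TestCoordinationSummary:
    def test_balanced_mixture(self):
        tubules, junctions = [], []
        for j in range(10):
            centre = np.array([10.0 * j, 0.0])
            n = 3 if j < 5 else 2
            for phi in np.linspace(0, 2 * np.pi, n, endpoint=False):
                d = np.array([np.cos(phi), np.sin(phi)])
                tubules.append([centre + d * r for r in (0.5, 2.0, 4.0)])
            junctions.append(centre)
        g = _graph(tubules, junctions)
        summary = coordination_summary(g)
        assert summary == {2: pytest.approx(0.5), 3: pytest.approx(0.5)}
        assert sum(summary.values()) == pytest.approx(1.0)

    def test_known_mixture_recovered(self):
        """A synthetic 56/35/9 mix of 3-/2-/4-way junctions is counted back."""
        rng = np.random.default_rng(11)
        tubules, junctions = [], []
        mix = [3] * 56 + [2] * 35 + [4] * 9
        for j, n in enumerate(mix):
            centre = np.array([20.0 * j, 0.0])
            phis = np.linspace(0, 2 * np.pi, n, endpoint=False) + rng.uniform(0, 1)
            for phi in phis:
                d = np.array([np.cos(phi), np.sin(phi)])
                tubules.append([centre + d * r for r in (0.5, 2.0, 4.0)])
            junctions.append(centre)
        summary = coordination_summary(_graph(tubules, junctions))
        assert summary[3] == pytest.approx(0.56)
        assert summary[2] == pytest.approx(0.35)
        assert summary[4] == pytest.approx(0.09)


# ---------------------------------------------------------------------------
# Persistence length
# ---------------------------------------------------------------------------


class TestPersistenceFit:
    def test_exact_forward_model_recovered(self):
        """(L, R) pairs generated from the Kratky-Porod relation at
        Lp = 8.3 um are fitted back to machine precision."""
        L = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        R = np.sqrt(wlc_mean_square_end_to_end(L, 8.3))
        fit = fit_persistence_length(list(zip(L, R)))
        assert isinstance(fit, PersistenceFit)
        assert fit.Lp == pytest.approx(8.3, abs=1e-6)
        assert fit.n_tubules == 6

    def test_rigid_rod_limit_flagged(self):
        L = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_persistence_length(list(zip(L, L)))  # R = L exactly
        assert fit.near_rigid

    def test_too_few_tubules(self):
        with pytest.raises(ValueError):
            fit_persistence_length([(1.0, 0.9), (2.0, 1.7)])

    def test_binned_fit_close_to_unbinned(self):
        rng = np.random.default_rng(5)
        L = rng.uniform(0.5, 6.0, size=400)
        R2 = wlc_mean_square_end_to_end(L, 4.0) * rng.normal(1.0, 0.05, size=400)
        pairs = list(zip(L, np.sqrt(R2)))
        raw = fit_persistence_length(pairs)
        binned = fit_persistence_length(pairs, n_bins=10)
        assert raw.Lp == pytest.approx(4.0, rel=0.1)
        assert binned.Lp == pytest.approx(raw.Lp, rel=0.1)


class TestWlcModelLimits:
    def test_small_L_limit_is_L_squared(self):
        Lp = 8.0
        L = Lp / 100.0
        assert wlc_mean_square_end_to_end(L, Lp) == pytest.approx(L**2, rel=0.01)

    def test_large_L_limit_is_2LpL(self):
        Lp = 0.05
        L = 100.0 * Lp
        assert wlc_mean_square_end_to_end(L, Lp) == pytest.approx(2 * Lp * L, rel=0.02)
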