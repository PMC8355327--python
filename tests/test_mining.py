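import numpy as np
import pandas as pd
import pytest

from _oracles import _as_set, brute_force_rules
from tubulekit.mining import (
    COLUMNS,
    build_property_matrix,
    classify_peripheral,
    mine_rules,
    rules_to_dataframe,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle (naive loops, no shared code with the miner)
# ---------------------------------------------------------------------------


# ---------------------------------------------------------------------------
# peripheral classification
# ---------------------------------------------------------------------------


def _circle(r, n=400):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


class TestClassifyPeripheral:
    def test_backbone_on_cell_edge(self):
        peripheral, depth = classify_peripheral(
            _circle(19.99, 12), _circle(10), _circle(20)
        )
        assert depth == pytest.approx(1.0, abs=2e-3)
        assert peripheral

    def test_backbone_on_nuclear_envelope(self):
        peripheral, depth = classify_peripheral(
            _circle(10.01, 12), _circle(10), _circle(20)
        )
        assert depth == pytest.approx(0.0, abs=2e-3)
        assert not peripheral

    def test_concentric_ring_at_95_percent(self):
        peripheral, depth = classify_peripheral(
            _circle(19.5, 24), _circle(10), _circle(20)
        )
        assert depth == pytest.approx(0.95, abs=5e-3)
        assert peripheral

    def test_point_outside_cell_rejected(self):
        with pytest.raises(ValueError):
            classify_peripheral([[25.0, 0.0]], _circle(10), _circle(20))

    def test_point_inside_nucleus_rejected(self):
        with pytest.raises(ValueError):
            classify_peripheral([[1.0, 0.0]], _circle(10), _circle(20))

    def test_max_aggregation_option(self):
        pts = np.array([[10.5, 0.0], [19.5, 0.0]])
        _, mean_depth = classify_peripheral(pts, _circle(10), _circle(20))
        peripheral_max, max_depth = classify_peripheral(
            pts, _circle(10), _circle(20), aggregate="max"
        )
        assert max_depth > mean_depth
        assert peripheral_max


# ---------------------------------------------------------------------------
# property matrix
# ---------------------------------------------------------------------------


class TestBuildPropertyMatrix:
    def test_documented_row_encoding(self):
        m = build_property_matrix(
            {
                "t1": {
                    "sustained_curvature": False,
                    "peripheral": True,
                    "msd_exponent": 0.3,
                    "significant_skewness": False,
                }
            }
        )
        assert list(m.columns) == list(COLUMNS)
        assert m.loc["t1"].tolist() == [0, 1, 1, 0, 0, 1, 0, 1]

    def test_presence_absence_partition(self):
        rng = np.random.default_rng(0)
        recs = {
            i: {
                "sustained_curvature": bool(rng.integers(2)),
                "peripheral": bool(rng.integers(2)),
                "msd_exponent": float(rng.uniform(0, 2)),
                "significant_skewness": bool(rng.integers(2)),
            }
            for i in range(30)
        }
        m = build_property_matrix(recs)
        for i in range(0, 8, 2):
            np.testing.assert_array_equal(
                m.iloc[:, i] + m.iloc[:, i + 1], np.ones(30, dtype=int)
            )

    def test_exponent_boundary_is_present(self):
        m = build_property_matrix(
            {
                "t": {
                    "sustained_curvature": False,
                    "peripheral": False,
                    "msd_exponent": 0.4,
                    "significant_skewness": False,
                }
            }
        )
        assert m.loc["t", "msd_exponent_ge_0.4=yes"] == 1

    def test_missing_determination_excluded(self):
        with pytest.warns(UserWarning):
            m = build_property_matrix(
                {
                    "ok": {
                        "sustained_curvature": True,
                        "peripheral": False,
                        "msd_exponent": 1.0,
                        "significant_skewness": True,
                    },
                    "bad": {"peripheral": True},
                }
            )
        assert list(m.index) == ["ok"]

    def test_empty_matrix_refused_by_miner(self):
        m = build_property_matrix({})
        with pytest.raises(ValueError):
            mine_rules(m)


# ---------------------------------------------------------------------------
# rule mining
# ---------------------------------------------------------------------------


def _matrix_from_rows(rows, columns=None):
    if columns is None:
        columns = [f"i{j}=yes" for j in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=columns)


class TestMineRules:
    def test_perfect_implication(self):
        rows = [[1, 1]] * 5 + [[0, 0]] * 5
        rules = mine_rules(_matrix_from_rows(rows), min_support=0.1, min_confidence=0.9)
        fwd = [r for r in rules if r.antecedent == frozenset({"i0=yes"})]
        assert len(fwd) == 1
        assert fwd[0].support == pytest.approx(0.5)
        assert fwd[0].confidence == pytest.approx(1.0)
        assert fwd[0].lift == pytest.approx(2.0)

    def test_independent_items_lift_one(self):
        rows = [[1, 1], [1, 0], [0, 1], [0, 0]] * 3
        rules = mine_rules(_matrix_from_rows(rows), min_support=0.01, min_confidence=0.01)
        r = [x for x in rules if x.antecedent == frozenset({"i0=yes"}) and x.consequent == frozenset({"i1=yes"})][0]
        assert r.lift == pytest.approx(1.0)

    def test_rare_item_filtered_by_support(self):
        rows = [[1, 0]] + [[0, 1]] * 19
        rules = mine_rules(_matrix_from_rows(rows), min_support=0.1, min_confidence=0.5)
        assert not any("i0=yes" in (r.antecedent | r.consequent) for r in rules)

    def test_threshold_validation(self):
        m = _matrix_from_rows([[1, 0]] * 10)
        with pytest.raises(ValueError):
            mine_rules(m, min_support=0.0)
        with pytest.raises(ValueError):
            mine_rules(m, min_confidence=1.5)

    def test_metric_identities_on_random_matrices(self):
        """confidence = supp(AuB)/supp(A) and lift = confidence/supp(B)
        hold identically for every emitted rule."""
        rng = np.random.default_rng(1)
        X = (rng.random((40, 6)) < 0.4).astype(int)
        m = _matrix_from_rows(X.tolist())
        for r in mine_rules(m, min_support=0.05, min_confidence=0.3):
            rows = [set(m.columns[m.iloc[i].astype(bool).to_numpy()]) for i in range(len(m))]
            sa = sum(1 for q in rows if r.antecedent <= q) / len(rows)
            sb = sum(1 for q in rows if r.consequent <= q) / len(rows)
            sab = sum(1 for q in rows if (r.antecedent | r.consequent) <= q) / len(rows)
            assert r.support == pytest.approx(sab, abs=1e-12)
            assert r.confidence == pytest.approx(sab / sa, abs=1e-12)
            assert r.lift == pytest.approx(sab / sa / sb, abs=1e-12)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        X = (rng.random((30, 6)) < 0.5).astype(int)
        m = _matrix_from_rows(X.tolist())
        base = _as_set(mine_rules(m, min_support=0.1, min_confidence=0.5))
        assert _as_set(mine_rules(m, min_support=0.2, min_confidence=0.5)) <= base
        assert _as_set(mine_rules(m, min_support=0.1, min_confidence=0.7)) <= base

    @pytest.mark.parametrize("seed", range(12))
    def test_equivalence_with_brute_force_oracle(self, seed):
        """Identical rule sets and metrics to an independent enumerator on
        random 8-column presence/absence matrices."""
        rng = np.random.default_rng(seed)
        flags = rng.random((50, 4)) < rng.uniform(0.2, 0.8, size=4)
        rows = []
        for f in flags:
            row = []
            for v in f:
                row.extend([int(v), int(not v)])
            rows.append(row)
        m = pd.DataFrame(rows, columns=list(COLUMNS))
        got = _as_set(mine_rules(m, min_support=0.1, min_confidence=0.9))
        want = brute_force_rules(m, 0.1, 0.9)
        assert got == want

    def test_dataframe_output_columns(self):
        rows = [[1, 1]] * 10
        df = rules_to_dataframe(mine_rules(_matrix_from_rows(rows), 0.1, 0.9))
        assert list(df.columns) == ["antecedent", "consequent", "support", "confidence", "lift"]
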