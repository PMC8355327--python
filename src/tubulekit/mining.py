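"""Association-rule mining over binary tubule-property profiles.

Each tubule gets an 8-column presence/absence encoding of four properties
(sustained curvature, peripheral position, MSD exponent >= 0.4, significant
skewness); frequent itemsets and rules are enumerated exhaustively (at most
255 nonempty itemsets over 8 items) and scored by support, confidence and
lift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "PROPERTIES",
    "COLUMNS",
    "classify_peripheral",
    "build_property_matrix",
    "AssociationRule",
    "mine_rules",
    "rules_to_dataframe",
]

# fixed, documented column order: (presence, absence) per property
PROPERTIES = (
    "sustained_curvature",
    "peripheral",
    "msd_exponent_ge_0.4",
    "significant_skewness",
)
COLUMNS = tuple(
    f"{prop}={tag}" for prop in PROPERTIES for tag in ("yes", "no")
)

MSD_EXPONENT_CUT = 0.4
PERIPHERAL_BAND = 0.9  # outermost 10% of the nucleus-to-edge distance


def classify_peripheral(
    backbone_points,
    nucleus_boundary,
    cell_boundary,
    threshold: float = PERIPHERAL_BAND,
    aggregate: str = "mean",
):
    """Peripheral / perinuclear classification of a tubule backbone.

    For each backbone point the normalised depth is
    d = dist(point, nucleus boundary) / (dist to nucleus + dist to cell
    edge); the tubule is peripheral when the aggregated depth (mean by
    default, ``aggregate="max"`` for whole-contour max) reaches
    ``threshold`` (default: outermost 10% of the nucleus-to-edge distance).
    Returns ``(peripheral, depth)``.  Points outside the cell or inside the
    nucleus are errors.
    """
    from shapely.geometry import Point, Polygon

    nucleus = Polygon(np.asarray(nucleus_boundary, dtype=float))
    cell = Polygon(np.asarray(cell_boundary, dtype=float))
    if not nucleus.within(cell):
        raise ValueError("nucleus boundary must lie inside the cell boundary")
    depths = []
    for xy in np.asarray(backbone_points, dtype=float):
        pt = Point(xy)
        if not cell.covers(pt):
            raise ValueError(f"backbone point {tuple(xy)} outside the cell")
        if nucleus.contains(pt):  # strict interior; boundary points allowed
            raise ValueError(f"backbone point {tuple(xy)} inside the nucleus")
        dn = nucleus.boundary.distance(pt)
        dc = cell.boundary.distance(pt)
        depths.append(dn / (dn + dc) if (dn + dc) > 0 else 0.5)
    depths = np.asarray(depths)
    depth = float(depths.mean() if aggregate == "mean" else depths.max())
    return depth >= threshold, depth


def build_property_matrix(records) -> pd.DataFrame:
    """Encode per-tubule determinations as the 8-column binary matrix.

    ``records`` maps tubule ids to dicts with keys ``sustained_curvature``
    (bool), ``peripheral`` (bool), ``msd_exponent`` (float) and
    ``significant_skewness`` (bool; at least one backbone point
    significant).  An MSD exponent of exactly 0.4 counts as present.
    Tubules missing any determination are excluded with a warning.
    """
    rows, index = [], []
    items = records.items() if isinstance(records, dict) else enumerate(records)
    for tid, rec in items:
        try:
            flags = (
                bool(rec["sustained_curvature"]),
                bool(rec["peripheral"]),
                float(rec["msd_exponent"]) >= MSD_EXPONENT_CUT,
                bool(rec["significant_skewness"]),
            )
        except (KeyError, TypeError, ValueError):
            warnings.warn(f"tubule {tid!r}: missing determination; excluded", stacklevel=2)
            continue
        row = []
        for f in flags:
            row.extend([int(f), int(not f)])
        rows.append(row)
        index.append(tid)
    return pd.DataFrame(rows, index=index, columns=list(COLUMNS), dtype=int)


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float

    def __str__(self) -> str:
        a = " & ".join(sorted(self.antecedent))
        c = " & ".join(sorted(self.consequent))
        return (
            f"{a} -> {c}  (support {self.support:.2g}, "
            f"confidence {self.confidence:.2g}, lift {self.lift:.2g})"
        )


def _contradictory(itemset, columns) -> bool:
    props = [columns[i].rsplit("=", 1)[0] for i in itemset]
    return len(props) != len(set(props))


def mine_rules(
    matrix: pd.DataFrame,
    min_support: float = 0.1,
    min_confidence: float = 0.9,
) -> list:
    """Exhaustive association-rule mining on a binary matrix.

    All nonempty itemsets are enumerated; itemsets pairing a property's
    presence with its own absence are pruned.  Rules A -> B over every
    bipartition of each frequent itemset are kept when
    support(A u B) >= ``min_support`` and confidence = support(A u B) /
    support(A) >= ``min_confidence``; lift = confidence / support(B).
    """
    if not (0 < min_support <= 1) or not (0 < min_confidence <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    X = matrix.to_numpy(dtype=bool)
    n_rows, n_items = X.shape
    if n_rows < 10:
        raise ValueError("need at least 10 rows to mine rules")
    columns = list(matrix.columns)

    support: dict = {}
    for size in range(1, n_items + 1):
        for combo in combinations(range(n_items), size):
            if _contradictory(combo, columns):
                continue
            s = float(X[:, combo].all(axis=1).mean())
            if s > 0:
                support[frozenset(combo)] = s

    rules = []
    for itemset, s_all in support.items():
        if s_all < min_support or len(itemset) < 2:
            continue
        items = sorted(itemset)
        for a_size in range(1, len(items)):
            for ante in combinations(items, a_size):
                A = frozenset(ante)
                B = itemset - A
                s_a = support.get(A, 0.0)
                s_b = support.get(B, 0.0)
                if s_a == 0 or s_b == 0:
                    continue
                conf = s_all / s_a
                if conf < min_confidence:
                    continue
                rules.append(
                    AssociationRule(
                        antecedent=frozenset(columns[i] for i in A),
                        consequent=frozenset(columns[i] for i in B),
                        support=s_all,
                        confidence=conf,
                        lift=conf / s_b,
                    )
                )
    rules.sort(key=lambda r: (-r.support, -r.confidence, sorted(r.antecedent)))
    return rules


def rules_to_dataframe(rules) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "antecedent": [" & ".join(sorted(r.antecedent)) for r in rules],
            "consequent": [" & ".join(sorted(r.consequent)) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
        }
    )
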