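"""Independent brute-force association-rule enumerator (naive loops,
no shared code with the package's miner)."""

from itertools import combinations

import pandas as pd


def brute_force_rules(matrix: pd.DataFrame, min_support, min_confidence):
    rows = [set(matrix.columns[matrix.iloc[i].astype(bool).to_numpy()]) for i in range(len(matrix))]
    n = len(rows)
    cols = list(matrix.columns)

    def prop(c):
        return c.rsplit("=", 1)[0]

    def supp(items):
        return sum(1 for r in rows if items <= r) / n

    found = set()
    for size in range(2, len(cols) + 1):
        for itemset in combinations(cols, size):
            iset = set(itemset)
            if len({prop(c) for c in iset}) != len(iset):
                continue  # presence+absence of one property
            s_all = supp(iset)
            if s_all < min_support:
                continue
            for a_size in range(1, size):
                for ante in combinations(sorted(iset), a_size):
                    A = set(ante)
                    B = iset - A
                    sa, sb = supp(A), supp(B)
                    if sa == 0 or sb == 0:
                        continue
                    conf = s_all / sa
                    if conf >= min_confidence:
                        found.add(
                            (frozenset(A), frozenset(B),
                             round(s_all, 12), round(conf, 12), round(conf / sb, 12))
                        )
    return found


def _as_set(rules):
    return {
        (r.antecedent, r.consequent, round(r.support, 12),
         round(r.confidence, 12), round(r.lift, 12))
        for r in rules
    }


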