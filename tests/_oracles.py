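"""Independent brute-force oracles used by the test suite.

These are deliberately naive transcriptions of the definitions (loops,
no vectorization) kept separate from the library implementations.
"""

import numpy as np

from lfqtobit.containers import ALL_ZERO, CENSORED, OBSERVED


def brute_force_censoring(y_star, design):
    """Literal application of the minimum-positive-value censoring rule.

    Returns None when every observation is zero (rule undefined).
    """
    y_star = np.asarray(y_star, dtype=float)
    positives = [v for v in y_star if v > 0]
    if not positives:
        return None
    c = min(positives)
    y = list(y_star)
    flags = [OBSERVED] * len(y)
    for _, cell in design.groupby(["substrate", "time"]):
        idx = list(cell.index)
        cell_vals = [y_star[i] for i in idx]
        if all(v == 0 for v in cell_vals):
            for i in idx:
                flags[i] = ALL_ZERO
        elif any(v == 0 for v in cell_vals):
            for i in idx:
                if y_star[i] == 0:
                    y[i] = c
                    flags[i] = CENSORED
    return np.array(y), np.array(flags, dtype=object), c


def brute_force_bh(pvalues):
    """Step-up Benjamini-Hochberg by direct evaluation of the definition."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for pos, i in enumerate(order):
        rank = pos + 1
        candidates = [
            p[j] * m / (sorted_rank + 1)
            for sorted_rank, j in enumerate(order)
            if sorted_rank + 1 >= rank
        ]
        q[i] = min(1.0, min(candidates))
    # ties share the same q (order-independent definition)
    for i in range(m):
        for j in range(m):
            if p[i] == p[j]:
                q[i] = min(q[i], q[j])
    return np.array(q)
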