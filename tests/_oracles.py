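"""Independent brute-force oracles used by the test suite.

Deliberately written with plain Python loops and the stdlib, separate from
the package's vectorized implementations.
"""

import statistics


def median_polish_oracle(matrix, max_iter=100, tol=1e-8):
    """Row/column median sweep with explicit loops; None/NaN cells skipped.

    Sweep order mirrors Tukey's convention: rows first, then columns, with
    the medians of the accumulated effects folded into the overall term.
    Returns (overall, row_effects, col_effects, residuals).
    """

    def med(values):
        vals = [v for v in values if v == v]  # drop NaN
        return statistics.median(vals) if vals else 0.0

    nr = len(matrix)
    nc = len(matrix[0])
    z = [[matrix[i][j] for j in range(nc)] for i in range(nr)]
    overall = 0.0
    row = [0.0] * nr
    col = [0.0] * nc

    for _ in range(max_iter):
        delta = 0.0

        for i in range(nr):
            m = med(z[i])
            for j in range(nc):
                z[i][j] -= m
            row[i] += m
            delta = max(delta, abs(m))

        shift = statistics.median(col)
        for j in range(nc):
            col[j] -= shift
        overall += shift

        for j in range(nc):
            m = med(z[i][j] for i in range(nr))
            for i in range(nr):
                z[i][j] -= m
            col[j] += m
            delta = max(delta, abs(m))

        shift = statistics.median(row)
        for i in range(nr):
            row[i] -= shift
        overall += shift

        if delta < tol:
            break

    return overall, row, col, z


def bh_adjust_oracle(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values by direct enumeration."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(pvalues[idx] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def confusion_oracle(calls, truths):
    """Direct enumeration of TP/FP/TN/FN from (called, changed) pairs."""
    tp = fp = tn = fn = 0
    for called, changed in zip(calls, truths):
        if called and changed:
            tp += 1
        elif called and not changed:
            fp += 1
        elif not called and changed:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn
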