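"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: a textbook
affine-gap Smith-Waterman with traceback, scalar confusion-matrix metric
formulas, and a run-length enumerator.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_local(seq_a: str, seq_b: str, gap_open: float = 11.0,
             gap_extend: float = 1.0):
    """Affine-gap local alignment by explicit Gotoh DP with traceback.

    A gap of length g costs ``gap_open + (g-1)*gap_extend``.  Returns
    (score, identities, columns) of one optimal local alignment, or
    (score, 0, 0) when no positively scoring match exists.
    """
    n, m = len(seq_a), len(seq_b)
    NEG = -math.inf
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in seq_b (consume a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in seq_a (consume b)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 start,1 M,2 Ix,3 Iy
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 from M, 2 from Ix
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[seq_a[i - 1], seq_b[j - 1]]
            opts = (0.0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + s
            if M[i, j] < 0:
                M[i, j], k = 0.0, 0
            ptr_m[i, j] = k
            ox = (M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            ptr_x[i, j] = 1 + int(np.argmax(ox))
            Ix[i, j] = max(ox)
            oy = (M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            ptr_y[i, j] = 1 + int(np.argmax(oy))
            Iy[i, j] = max(oy)
            if M[i, j] > best:
                best, best_ij = M[i, j], (i, j)
    if best_ij is None or best <= 0:
        return 0.0, 0, 0
    # traceback from the best M cell
    i, j = best_ij
    state = "M"
    identities = columns = 0
    while True:
        if state == "M":
            columns += 1
            if seq_a[i - 1] == seq_b[j - 1]:
                identities += 1
            came = ptr_m[i, j]
            i, j = i - 1, j - 1
            if came == 0:
                break
            state = ("M", "X", "Y")[came - 1]
        elif state == "X":
            columns += 1
            came = ptr_x[i, j]
            i -= 1
            state = "M" if came == 1 else "X"
        else:
            columns += 1
            came = ptr_y[i, j]
            j -= 1
            state = "M" if came == 1 else "Y"
    return float(best), identities, columns


def metrics_scalar(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Plain scalar metric formulas; NaN for zero denominators."""

    def div(a, b):
        return a / b if b > 0 else math.nan

    precision = div(tp, tp + fp)
    recall = div(tp, tp + fn)
    neg_precision = div(tn, tn + fn)
    neg_recall = div(tn, tn + fp)
    balanced = (recall + neg_recall) / 2
    f1 = (
        math.nan
        if (recall != recall or precision != precision or recall + precision == 0)
        else 2 * recall * precision / (recall + precision)
    )
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = math.nan if den == 0 else (tp * tn - fp * fn) / den
    return {
        "precision": precision,
        "recall": recall,
        "negative_precision": neg_precision,
        "negative_recall": neg_recall,
        "balanced_accuracy": balanced,
        "f1": f1,
        "mcc": mcc,
    }


def runs_of_ones(bits) -> list[tuple[int, int]]:
    """Enumerate maximal runs of 1s by linear scan."""
    runs = []
    start = None
    for i, b in enumerate(list(bits) + [0]):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i))
            start = None
    return runs
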