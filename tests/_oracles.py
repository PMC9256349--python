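"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's internal algorithms: the MIC oracle
enumerates every admissible grid explicitly instead of running the dynamic
program, and the metrics oracle recomputes rates from raw prediction
vectors instead of confusion counts.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def equipartition_labels(v: np.ndarray, k: int) -> np.ndarray:
    """Rank-equipartition into at most k bins; ties share a bin."""
    n = len(v)
    order = np.argsort(v, kind="stable")
    sv = v[order]
    starts = [0] + [i for i in range(1, n) if sv[i] != sv[i - 1]]
    ends = starts[1:] + [n]
    labels_sorted = np.empty(n, dtype=int)
    b = filled = in_bin = 0
    for s, e in zip(starts, ends):
        size = e - s
        if in_bin > 0 and b < k - 1:
            target = (n - filled) / (k - b)
            if (in_bin + size - target > target - in_bin) or in_bin >= target:
                b += 1
                filled += in_bin
                in_bin = 0
        labels_sorted[s:e] = b
        in_bin += size
    out = np.empty(n, dtype=int)
    out[order] = labels_sorted
    return out


def mutual_information_bits(px: list, py: list) -> float:
    n = len(px)
    joint = Counter(zip(px, py))
    cx, cy = Counter(px), Counter(py)
    return sum(
        (c / n) * math.log2(c * n / (cx[a] * cy[b]))
        for (a, b), c in joint.items()
    )


def brute_force_mic(x: np.ndarray, y: np.ndarray, alpha: float = 0.6) -> float:
    """MIC by exhaustive enumeration of all admissible grids.

    For each orientation the second axis is rank-equipartitioned and every
    partition of the first axis at equal-value clump boundaries, for every
    grid size within the bound B(n) = max(n^alpha, 4), is evaluated
    explicitly.  Feasible only for small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    B = max(n ** alpha, 4.0)
    best = 0.0
    for a, b in ((x, y), (y, x)):
        order = np.argsort(a, kind="stable")
        av = a[order]
        clump_bounds = [i for i in range(1, n) if av[i] != av[i - 1]]
        for ny in range(2, int(B // 2) + 1):
            q = equipartition_labels(b, ny)[order]
            ny_eff = int(q.max()) + 1
            if ny_eff < 2:
                continue
            kmax = int(B // ny_eff)
            for k in range(2, kmax + 1):
                for n_bins in range(1, min(k, len(clump_bounds) + 1) + 1):
                    for cuts in itertools.combinations(clump_bounds,
                                                       n_bins - 1):
                        px = np.zeros(n, dtype=int)
                        for c in cuts:
                            px[c:] += 1
                        mi = mutual_information_bits(px.tolist(), q.tolist())
                        best = max(best, mi / math.log2(min(k, ny_eff)))
    return min(best, 1.0)


def brute_force_metrics(y_true: np.ndarray,
                        y_pred: np.ndarray) -> dict[str, float]:
    """ACC/SN/SP/MCC recomputed directly from prediction vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    n = len(y_true)
    acc = float((y_true == y_pred).mean())
    pos = y_true == 1
    neg = y_true == 0
    sn = float((y_pred[pos] == 1).mean()) if pos.any() else 0.0
    sp = float((y_pred[neg] == 0).mean()) if neg.any() else 0.0
    # MCC as the Pearson correlation of the two binary vectors
    if y_true.std() == 0 or y_pred.std() == 0:
        mcc = 0.0
    else:
        mcc = float(np.corrcoef(y_true, y_pred)[0, 1])
    return {"ACC": acc, "SN": sn, "SP": sp, "MCC": mcc}
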