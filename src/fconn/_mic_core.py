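"""Numba kernel for the grid search inside the MIC estimator.

Given points sorted along one axis (the "DP axis") and a fixed mass-equal
partition of the other axis into ``nA`` columns, finds for every row count
``b`` the partition of the DP axis (cuts restricted to candidate positions)
maximizing mutual information.  Uses the classic interval dynamic program:
refining a partition never lowers MI, so the best score for "at most b rows"
is monotone in ``b`` and one DP sweep yields all row counts at once.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def dp_best_scores(col_sorted, nA, nB_max, cand):  # pragma: no cover - jitted
    """Best sum of per-row-bin terms for every row count 1..nB_max.

    col_sorted : int32[n]  x-column index of each point, points in DP-axis order
    cand       : int64[m]  strictly increasing candidate prefix lengths, last == n
    returns    : float64[nB_max + 1]; entry b = max over partitions with <= b
                 rows (cuts at candidates) of  sum_bins [ sum_c d*log2(d)
                 - D*log2(D) ]  where d are per-column counts in the bin.
    """
    n = col_sorted.shape[0]
    m = cand.shape[0]
    cum = np.zeros((m + 1, nA), dtype=np.float64)
    start = 0
    for t in range(m):
        for c in range(nA):
            cum[t + 1, c] = cum[t, c]
        for idx in range(start, cand[t]):
            cum[t + 1, col_sorted[idx]] += 1.0
        start = cand[t]
    G = np.empty((m + 1, m + 1), dtype=np.float64)
    for j in range(m + 1):
        for t in range(j + 1, m + 1):
            s = 0.0
            total = 0.0
            for c in range(nA):
                d = cum[t, c] - cum[j, c]
                if d > 0.0:
                    s += d * np.log2(d)
                    total += d
            if total > 0.0:
                s -= total * np.log2(total)
            G[j, t] = s
    best = np.full(nB_max + 1, -np.inf)
    F_prev = np.empty(m + 1)
    F_cur = np.empty(m + 1)
    F_prev[0] = -np.inf
    for t in range(1, m + 1):
        F_prev[t] = G[0, t]
    best[1] = F_prev[m]
    for b in range(2, nB_max + 1):
        F_cur[0] = -np.inf
        for t in range(1, m + 1):
            vbest = F_prev[t]
            for j in range(1, t):
                v = F_prev[j] + G[j, t]
                if v > vbest:
                    vbest = v
            F_cur[t] = vbest
        for t in range(m + 1):
            F_prev[t] = F_cur[t]
        best[b] = F_prev[m]
    return best
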