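"""Numba kernel for all-pairs TCRdist; integer-exact vs the scalar metric."""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _gapped_cdr3(a, la, b, lb, cost, gap):
    """Single-contiguous-gap loop distance (unweighted); mirrors cdr_distance."""
    if la > lb:
        a, b = b, a
        la, lb = lb, la
    dlen = lb - la
    if la == 0:
        return dlen * gap
    if dlen == 0:
        total = 0
        for p in range(la):
            total += cost[a[p], b[p]]
        return total
    # cost(g) = sum_{p<g} cost[a_p, b_p] + sum_{p>=g} cost[a_p, b_{p+dlen}];
    # walk g upward maintaining a running total (leftmost minimum wins)
    cur = 0
    for p in range(la):
        cur += cost[a[p], b[p + dlen]]
    best = cur
    for g in range(la):
        cur += cost[a[g], b[g]] - cost[a[g], b[g + dlen]]
        if cur < best:
            best = cur
    return best + dlen * gap


@njit(cache=True)
def pairwise_kernel(seqs, lens, vidx, vcomp, cost, gap, w3):
    n = seqs.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        ai = seqs[i]
        li = lens[i]
        vi = vidx[i]
        for j in range(i + 1, n):
            d = vcomp[vi, vidx[j]]
            d += w3 * _gapped_cdr3(ai, li, seqs[j], lens[j], cost, gap)
            out[i, j] = d
            out[j, i] = d
    return out
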