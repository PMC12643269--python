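"""Numba range-count kernel for the nearest-neighbor estimators.

Counting the points of a 2D marginal strictly inside a per-point
Chebyshev box is the hot operation when screening many triads: a
binary-searched window on one (pre-sorted) coordinate followed by a
linear scan of the second is both exact under the strict-inequality
convention and much faster than a tree query at these sizes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def window_count_2d(sorted_a, b_by_a, qa, qb, eps):
    """Per query t: #{s : |a_s - qa_t| < eps_t and |b_s - qb_t| < eps_t}.

    ``sorted_a`` is the first coordinate sorted ascending and
    ``b_by_a`` the second coordinate in that same order.  The count
    includes the query point itself when it belongs to the data.
    """
    n = qa.shape[0]
    out = np.empty(n, np.int64)
    for t in range(n):
        e = eps[t]
        lo = np.searchsorted(sorted_a, qa[t] - e, side="right")
        hi = np.searchsorted(sorted_a, qa[t] + e, side="left")
        ql = qb[t] - e
        qh = qb[t] + e
        c = 0
        for i in range(lo, hi):
            v = b_by_a[i]
            if ql < v < qh:
                c += 1
        out[t] = c
    return out
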