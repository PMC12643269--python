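"""Independent naive persistent-homology oracle for small inputs.

Textbook boundary-matrix reduction over Z/2 with no optimizations:
enumerate every simplex up to dimension maxdim+1 below the threshold,
sort globally by (diameter, dimension, vertex tuple), build the full
boundary matrix with columns as Python-int bitsets, and run the
standard left-to-right reduction.  Written deliberately without any of
the machinery of the package engine so the two can disagree.
"""

from itertools import combinations

import numpy as np


def naive_vr_diagram(D, maxdim=2, threshold=None):
    """Return a list of (dim, birth, death) bars; death may be inf."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if threshold is None:
        threshold = float(np.min(np.max(D, axis=1))) if n > 1 else 0.0

    simplices = []  # (diam, dim, verts)
    for d in range(maxdim + 2):
        for verts in combinations(range(n), d + 1):
            diam = max((D[a, b] for a, b in combinations(verts, 2)),
                       default=0.0)
            if diam <= threshold:
                simplices.append((diam, d, verts))
    simplices.sort()
    index_of = {s[2]: i for i, s in enumerate(simplices)}

    # columns as int bitsets over row indices
    columns = []
    for diam, d, verts in simplices:
        col = 0
        if d > 0:
            for face in combinations(verts, d):
                col |= 1 << index_of[face]
        columns.append(col)

    low_inv = {}  # lowest set bit's row -> column index
    pairs = {}
    for j, col in enumerate(columns):
        while col:
            low = col.bit_length() - 1
            if low in low_inv:
                col ^= columns[low_inv[low]]
            else:
                break
        columns[j] = col
        if col:
            low = col.bit_length() - 1
            low_inv[low] = j
            pairs[low] = j

    bars = []
    paired_rows = set(pairs)
    paired_cols = set(pairs.values())
    for i, (diam, d, _) in enumerate(simplices):
        if i in paired_rows:
            death_diam = simplices[pairs[i]][0]
            bars.append((d, diam, death_diam))
        elif i not in paired_cols and d <= maxdim:
            bars.append((d, diam, float("inf")))
    return sorted(bars)
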