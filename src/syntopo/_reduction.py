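"""Numba kernels for Vietoris-Rips persistent homology.

The algorithm is a persistent-cohomology matrix reduction over Z/2 with
clearing, the same family of optimizations that make modern Rips codes
fast: columns are the d-simplices in reverse filtration order, the
coboundary of a column is enumerated implicitly from the distance
matrix (cofacets are never stored globally), and each reduced column is
represented by the list of d-simplices whose coboundaries sum to it, so
memory stays proportional to the number of additions actually
performed.  Clearing skips every d-simplex that was already paired as a
pivot while reducing dimension d-1, which removes the vast majority of
columns in the top dimension.

Simplices are encoded in the combinatorial number system: the simplex
with vertices ``v_0 < v_1 < ... < v_d`` has index ``sum_i C(v_i, i+1)``.
The filtration orders simplices by diameter, ties broken by dimension
and then by combinatorial index; the reported diagram (a multiset of
(dim, birth, death) triples) is independent of the within-diameter
tie-break.

Cohomology and homology reductions of the same filtration produce the
same persistence pairs, so the bars reported here are exactly those of
the textbook boundary-matrix reduction (which the test suite implements
independently as an oracle).
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import Dict, List

I64 = types.int64


@njit(cache=True)
def _comb_table(n: int, kmax: int) -> np.ndarray:
    binom = np.zeros((n + 1, kmax + 1), dtype=np.int64)
    for i in range(n + 1):
        binom[i, 0] = 1
        top = i if i < kmax else kmax
        for j in range(1, top + 1):
            binom[i, j] = binom[i - 1, j - 1] + binom[i - 1, j]
    return binom


@njit(cache=True)
def _decode(cidx, dim, binom, out):
    """Vertices (ascending) of the simplex with combinatorial index cidx."""
    rem = cidx
    hi = binom.shape[0] - 1
    for i in range(dim, -1, -1):
        # largest v with binom[v, i+1] <= rem (binary search; the
        # column is nondecreasing in v)
        lo = i
        top = hi
        while lo < top:
            mid = (lo + top + 1) // 2
            if binom[mid, i + 1] <= rem:
                lo = mid
            else:
                top = mid - 1
        out[i] = lo
        rem -= binom[lo, i + 1]
        hi = lo - 1


@njit(cache=True)
def _diam_of(verts, dim, D):
    dm = 0.0
    for a in range(dim + 1):
        for b in range(a + 1, dim + 1):
            dab = D[verts[a], verts[b]]
            if dab > dm:
                dm = dab
    return dm


@njit(cache=True)
def _heap_push(hd, hc, size, d, c):
    """Binary min-heap on (diameter, index) keys; grows by doubling."""
    if size >= hd.shape[0]:
        nhd = np.empty(2 * hd.shape[0], np.float64)
        nhc = np.empty(2 * hc.shape[0], np.int64)
        nhd[:size] = hd[:size]
        nhc[:size] = hc[:size]
        hd = nhd
        hc = nhc
    i = size
    hd[i] = d
    hc[i] = c
    size += 1
    while i > 0:
        par = (i - 1) // 2
        if hd[par] > hd[i] or (hd[par] == hd[i] and hc[par] > hc[i]):
            hd[par], hd[i] = hd[i], hd[par]
            hc[par], hc[i] = hc[i], hc[par]
            i = par
        else:
            break
    return hd, hc, size


@njit(cache=True)
def _heap_pop(hd, hc, size):
    d = hd[0]
    c = hc[0]
    size -= 1
    if size > 0:
        hd[0] = hd[size]
        hc[0] = hc[size]
        i = 0
        while True:
            left = 2 * i + 1
            if left >= size:
                break
            small = left
            right = left + 1
            if right < size and (hd[right] < hd[left] or
                                 (hd[right] == hd[left] and hc[right] < hc[left])):
                small = right
            if hd[small] < hd[i] or (hd[small] == hd[i] and hc[small] < hc[i]):
                hd[small], hd[i] = hd[i], hd[small]
                hc[small], hc[i] = hc[i], hc[small]
                i = small
            else:
                break
    return d, c, size


@njit(cache=True)
def _push_coboundary(hd, hc, size, verts, dim, D, binom, thresh):
    """Push every below-threshold cofacet of one simplex onto the heap."""
    n = D.shape[0]
    dw = _diam_of(verts, dim, D)
    nv = np.empty(dim + 2, np.int64)
    for v in range(n):
        member = False
        for a in range(dim + 1):
            if verts[a] == v:
                member = True
                break
        if member:
            continue
        dmax = dw
        for a in range(dim + 1):
            dv = D[v, verts[a]]
            if dv > dmax:
                dmax = dv
        if dmax > thresh:
            continue
        j = 0
        inserted = False
        for a in range(dim + 1):
            if not inserted and v < verts[a]:
                nv[j] = v
                j += 1
                inserted = True
            nv[j] = verts[a]
            j += 1
        if not inserted:
            nv[j] = v
        cc = np.int64(0)
        for a in range(dim + 2):
            cc += binom[nv[a], a + 1]
        hd, hc, size = _heap_push(hd, hc, size, dmax, cc)
    return hd, hc, size


@njit(cache=True)
def _pop_pivot(hd, hc, size):
    """Pop the surviving (odd-multiplicity) minimum entry, cancelling
    Z/2 pairs on the way.  Returns (found, diam, cindex, size)."""
    while size > 0:
        d, c, size = _heap_pop(hd, hc, size)
        odd = True
        while size > 0 and hc[0] == c:
            _, _, size = _heap_pop(hd, hc, size)
            odd = not odd
        if odd:
            return True, d, c, size
    return False, 0.0, np.int64(0), size


@njit(cache=True)
def _parity_dedupe(arr, m):
    """Sorted odd-multiplicity entries of arr[:m] (Z/2 generator list)."""
    a = np.sort(arr[:m])
    out = np.empty(m, np.int64)
    t = 0
    i = 0
    while i < m:
        j = i + 1
        while j < m and a[j] == a[i]:
            j += 1
        if ((j - i) & 1) == 1:
            out[t] = a[i]
            t += 1
        i = j
    return out[:t].copy()


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def _dim0(D, thresh, binom):
    """Union-find over edges: dim-0 deaths and the merged-edge indices."""
    n = D.shape[0]
    cap = n * (n - 1) // 2
    ec = np.empty(cap, np.int64)
    ed = np.empty(cap, np.float64)
    m = 0
    for v1 in range(1, n):
        for v0 in range(v1):
            d = D[v0, v1]
            if d <= thresh:
                ec[m] = binom[v1, 2] + binom[v0, 1]
                ed[m] = d
                m += 1
    order = np.argsort(ed[:m], kind="mergesort")  # cindex-ascending base order
    parent = np.arange(n)
    deaths = np.empty(m, np.float64)
    merged = np.empty(m, np.int64)
    verts = np.empty(2, np.int64)
    t = 0
    for oi in range(m):
        e = order[oi]
        _decode(ec[e], 1, binom, verts)
        ra = _find(parent, verts[0])
        rb = _find(parent, verts[1])
        if ra != rb:
            parent[rb] = ra
            deaths[t] = ed[e]
            merged[t] = ec[e]
            t += 1
    ncomp = 0
    for v in range(n):
        if _find(parent, v) == v:
            ncomp += 1
    return deaths[:t], merged[:t], ncomp


@njit(cache=True)
def _in_sorted(arr, x):
    lo = 0
    hi = arr.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo < arr.shape[0] and arr[lo] == x


@njit(cache=True)
def _enumerate_columns(D, thresh, dim, binom, cleared):
    n = D.shape[0]
    if dim == 1:
        cap = n * (n - 1) // 2
    else:
        cap = n * (n - 1) * (n - 2) // 6
    sc = np.empty(cap, np.int64)
    sd = np.empty(cap, np.float64)
    sv = np.empty((cap, dim + 1), np.int32)
    m = 0
    if dim == 1:
        for v1 in range(1, n):
            for v0 in range(v1):
                d01 = D[v0, v1]
                if d01 > thresh:
                    continue
                c = binom[v1, 2] + binom[v0, 1]
                if _in_sorted(cleared, c):
                    continue
                sc[m] = c
                sd[m] = d01
                sv[m, 0] = v0
                sv[m, 1] = v1
                m += 1
    else:
        for v2 in range(2, n):
            for v1 in range(1, v2):
                d12 = D[v1, v2]
                if d12 > thresh:
                    continue
                base = binom[v2, 3] + binom[v1, 2]
                for v0 in range(v1):
                    d = d12
                    if D[v0, v1] > d:
                        d = D[v0, v1]
                    if D[v0, v2] > d:
                        d = D[v0, v2]
                    if d > thresh:
                        continue
                    c = base + binom[v0, 1]
                    if _in_sorted(cleared, c):
                        continue
                    sc[m] = c
                    sd[m] = d
                    sv[m, 0] = v0
                    sv[m, 1] = v1
                    sv[m, 2] = v2
                    m += 1
    return sc[:m], sd[:m], sv[:m]


@njit(cache=True)
def _min_cofacet(verts, dim, diam, D, binom, thresh):
    """Pivot of a single simplex's coboundary: the cofacet minimizing
    (diameter, combinatorial index).  Returns (index, diameter) or
    (-1, 0.0) when no cofacet lies below the threshold."""
    n = D.shape[0]
    best_c = np.int64(-1)
    best_d = np.inf
    nv = np.empty(dim + 2, np.int64)
    for v in range(n):
        member = False
        for a in range(dim + 1):
            if verts[a] == v:
                member = True
                break
        if member:
            continue
        dmax = diam
        for a in range(dim + 1):
            dv = D[v, verts[a]]
            if dv > dmax:
                dmax = dv
        if dmax > thresh or dmax > best_d:
            continue
        j = 0
        inserted = False
        for a in range(dim + 1):
            if not inserted and v < verts[a]:
                nv[j] = v
                j += 1
                inserted = True
            nv[j] = verts[a]
            j += 1
        if not inserted:
            nv[j] = v
        cc = np.int64(0)
        for a in range(dim + 2):
            cc += binom[nv[a], a + 1]
        if dmax < best_d or cc < best_c:
            best_d = dmax
            best_c = cc
    if best_c < 0:
        return np.int64(-1), 0.0
    return best_c, best_d


@njit(cache=True)
def _reduce_dim(D, thresh, dim, binom, cleared):
    """Cohomology reduction of the dim-simplex columns.

    Returns (births, deaths) of finite dim-``dim`` bars, births of
    essential (threshold-truncated) classes, and the pivot cofacet
    indices for clearing the next dimension.
    """
    sc, sd, sv = _enumerate_columns(D, thresh, dim, binom, cleared)
    m = sc.shape[0]
    order = np.argsort(sd, kind="mergesort")
    pivot_map = Dict.empty(I64, I64)
    stored = List.empty_list(I64[::1])
    births = np.empty(m, np.float64)
    deaths = np.empty(m, np.float64)
    pivots = np.empty(m, np.int64)
    essential = np.empty(m, np.float64)
    verts = np.empty(dim + 1, np.int64)
    gverts = np.empty(dim + 1, np.int64)
    hd = np.empty(1024, np.float64)
    hc = np.empty(1024, np.int64)
    gens = np.empty(1024, np.int64)
    npairs = 0
    ness = 0
    # reverse filtration order: diameter descending, index descending
    for oi in range(m - 1, -1, -1):
        col = order[oi]
        for a in range(dim + 1):
            verts[a] = sv[col, a]
        # fast path: the pivot of a fresh column needs no sort, and
        # when unclaimed it pairs immediately (the overwhelmingly
        # common case: an apparent zero-persistence pair)
        p, pdiam = _min_cofacet(verts, dim, sd[col], D, binom, thresh)
        if p < 0:
            essential[ness] = sd[col]
            ness += 1
            continue
        if p not in pivot_map:
            W = np.empty(1, np.int64)
            W[0] = sc[col]
            pivot_map[p] = np.int64(len(stored))
            stored.append(W)
            births[npairs] = sd[col]
            deaths[npairs] = pdiam
            pivots[npairs] = p
            npairs += 1
            continue
        # slow path: genuine column additions, working column held
        # lazily in a heap of cofacets with Z/2 cancellation on pop
        size = 0
        hd, hc, size = _push_coboundary(hd, hc, size, verts, dim, D,
                                        binom, thresh)
        ngens = 1
        gens[0] = sc[col]
        while True:
            found, pd_, pc = False, 0.0, np.int64(0)
            found, pd_, pc, size = _pop_pivot(hd, hc, size)
            if not found:
                essential[ness] = sd[col]
                ness += 1
                break
            if pc in pivot_map:
                slot = pivot_map[pc]
                other = stored[slot]
                # restore the popped pivot; the matching entry in the
                # added column cancels it
                hd, hc, size = _heap_push(hd, hc, size, pd_, pc)
                for gi in range(other.shape[0]):
                    g = other[gi]
                    _decode(g, dim, binom, gverts)
                    hd, hc, size = _push_coboundary(
                        hd, hc, size, gverts, dim, D, binom, thresh)
                    if ngens >= gens.shape[0]:
                        ng = np.empty(2 * gens.shape[0], np.int64)
                        ng[:ngens] = gens[:ngens]
                        gens = ng
                    gens[ngens] = g
                    ngens += 1
            else:
                pivot_map[pc] = np.int64(len(stored))
                stored.append(_parity_dedupe(gens, ngens))
                births[npairs] = sd[col]
                deaths[npairs] = pd_
                pivots[npairs] = pc
                npairs += 1
                break
    return (births[:npairs], deaths[:npairs], essential[:ness],
            np.sort(pivots[:npairs]))


@njit(cache=True)
def vr_kernel(D, thresh, maxdim):
    """Full Rips persistence of a distance matrix up to dimension maxdim.

    Returns parallel arrays (dims, births, deaths); deaths may be inf.
    Zero-persistence bars are included.
    """
    n = D.shape[0]
    binom = _comb_table(n, maxdim + 3)
    out_dim = List.empty_list(I64)
    out_birth = List.empty_list(types.float64)
    out_death = List.empty_list(types.float64)

    deaths0, merged, ncomp = _dim0(D, thresh, binom)
    for i in range(deaths0.shape[0]):
        out_dim.append(np.int64(0))
        out_birth.append(0.0)
        out_death.append(deaths0[i])
    for _ in range(ncomp):
        out_dim.append(np.int64(0))
        out_birth.append(0.0)
        out_death.append(np.inf)

    cleared = np.sort(merged)
    for dim in range(1, maxdim + 1):
        births, deaths, essential, pivots = _reduce_dim(
            D, thresh, dim, binom, cleared)
        for i in range(births.shape[0]):
            out_dim.append(np.int64(dim))
            out_birth.append(births[i])
            out_death.append(deaths[i])
        for i in range(essential.shape[0]):
            out_dim.append(np.int64(dim))
            out_birth.append(essential[i])
            out_death.append(np.inf)
        cleared = pivots

    nd = len(out_dim)
    dims = np.empty(nd, np.int64)
    births_a = np.empty(nd, np.float64)
    deaths_a = np.empty(nd, np.float64)
    for i in range(nd):
        dims[i] = out_dim[i]
        births_a[i] = out_birth[i]
        deaths_a[i] = out_death[i]
    return dims, births_a, deaths_a
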