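"""Triad enumeration, circular-shift nulls, and significance labels.

A triad of channels from a multi-scan recording forms a 3D point cloud
whose O-information can be inflated by within-channel autocorrelation
alone.  The null model here destroys cross-channel dependence while
preserving each channel's marginal distribution and autocorrelation:
channel position ``c`` of a triad is circularly shifted by
``c * scan_length`` frames, so after the shift the three channels were
effectively recorded during different scans.  Pooling one null
O-information per triad gives a null distribution; a triad is called
significantly redundant (synergistic) when its raw O-information lies
more than ``sd_multiplier`` standard deviations above (below) the null
mean.

Estimating O for every triad and its null over shared channels is the
hot loop, so marginal KD-trees and sorted columns are cached per
(channel, shift) and reused across triads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bold import MultiScanSeries
from .info import InfoEstimate, estimate_all

__all__ = [
    "NullDistribution",
    "enumerate_triads",
    "circular_shift_triad",
    "triad_cloud",
    "estimate_triad",
    "build_null",
    "classify",
    "screen_triads",
    "TriadEstimatorCache",
]

LABELS = ("redundant", "synergistic", "neither")


@dataclass(frozen=True)
class NullDistribution:
    """Pooled moments of the circular-shift null O-informations."""

    mean: float
    sd: float
    count: int


def enumerate_triads(C: int) -> np.ndarray:
    """All sorted triples over C channels, lexicographic, as (m, 3) ints."""
    if C < 3:
        raise ValueError("need at least 3 channels")
    jj, kk = np.triu_indices(C, 1)
    total = int(jj.astype(np.int64).sum())
    j_full = np.repeat(jj, jj)
    k_full = np.repeat(kk, jj)
    offsets = np.concatenate([[0], np.cumsum(jj)[:-1]])
    i_full = np.arange(total) - np.repeat(offsets, jj)
    triads = np.column_stack([i_full, j_full, k_full]).astype(np.int32)
    order = np.lexsort((triads[:, 2], triads[:, 1], triads[:, 0]))
    return triads[order]


def _null_shifts(scan_length: int) -> tuple[int, int, int]:
    return (0, scan_length, 2 * scan_length)


def triad_cloud(series: MultiScanSeries, triad,
                shifts: tuple[int, int, int] = (0, 0, 0)) -> np.ndarray:
    """Three channels as a T x 3 cloud, each circularly shifted."""
    cols = [np.roll(series.data[:, c], s) for c, s in zip(triad, shifts)]
    return np.column_stack(cols)


def circular_shift_triad(series: MultiScanSeries, triad) -> np.ndarray:
    """Null surrogate of a triad: channel position c shifted by
    c * scan_length frames (wraparound over the full recording)."""
    if series.n_scans < 3:
        raise ValueError(
            "circular-shift null needs >= 3 scans so each channel can "
            "come from a different scan"
        )
    return triad_cloud(series, triad, _null_shifts(series.scan_length))


class TriadEstimatorCache:
    """Shared sorted marginal structures for many-triad estimation.

    Marginal structures depend only on (channel, shift) pairs, of which
    there are few, while triads are combinatorially many.
    """

    def __init__(self, series: MultiScanSeries):
        self.series = series
        self._pairs: dict = {}
        self._sorted: dict = {}

    def sorted_col(self, channel: int) -> np.ndarray:
        if channel not in self._sorted:
            self._sorted[channel] = np.sort(self.series.data[:, channel])
        return self._sorted[channel]

    def marginal_pair(self, a: int, sa: int, b: int, sb: int
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Sorted first channel + co-sorted second, both shifted."""
        key = (a, sa, b, sb)
        if key not in self._pairs:
            first = np.roll(self.series.data[:, a], sa)
            second = np.roll(self.series.data[:, b], sb)
            order = np.argsort(first, kind="stable")
            self._pairs[key] = (np.ascontiguousarray(first[order]),
                                np.ascontiguousarray(second[order]))
        return self._pairs[key]


def estimate_triad(series: MultiScanSeries, triad, k: int = 4,
                   shifts: tuple[int, int, int] = (0, 0, 0),
                   cache: TriadEstimatorCache | None = None) -> InfoEstimate:
    """Information estimate of one (possibly shifted) triad cloud."""
    cloud = triad_cloud(series, triad, shifts)
    if cache is None:
        return estimate_all(cloud, k, tie_noise=0.0)
    i, j, kk = triad
    si, sj, sk = shifts
    pairs = [
        cache.marginal_pair(j, sj, kk, sk),
        cache.marginal_pair(i, si, kk, sk),
        cache.marginal_pair(i, si, j, sj),
    ]
    sorted_cols = np.column_stack(
        [cache.sorted_col(c) for c in (i, j, kk)])
    return estimate_all(cloud, k, tie_noise=0.0, marginal_pairs=pairs,
                        sorted_cols=sorted_cols)


def build_null(series: MultiScanSeries, triads, k: int = 4,
               cache: TriadEstimatorCache | None = None,
               return_values: bool = False):
    """Pooled null distribution: one shifted O value per triad."""
    triads = np.atleast_2d(np.asarray(triads))
    if triads.shape[0] < 1:
        raise ValueError("need at least one triad")
    if series.n_scans < 3:
        raise ValueError("circular-shift null needs >= 3 scans")
    if cache is None:
        cache = TriadEstimatorCache(series)
    shifts = _null_shifts(series.scan_length)
    values = np.empty(triads.shape[0])
    for t, triad in enumerate(triads):
        values[t] = estimate_triad(series, triad, k, shifts, cache).o
    sd = float(values.std(ddof=0)) if values.size > 1 else 0.0
    null = NullDistribution(mean=float(values.mean()), sd=sd,
                            count=int(values.size))
    return (null, values) if return_values else null


def classify(o: float, null: NullDistribution,
             sd_multiplier: float = 3.0) -> str:
    """Label one O value against the null: beyond sd_multiplier SDs
    above the mean is redundant, below is synergistic."""
    if null.sd < 0:
        raise ValueError("null sd must be nonnegative")
    if o > null.mean + sd_multiplier * null.sd:
        return "redundant"
    if o < null.mean - sd_multiplier * null.sd:
        return "synergistic"
    return "neither"


def screen_triads(series: MultiScanSeries, triads=None, k: int = 4,
                  sd_multiplier: float = 3.0,
                  cache: TriadEstimatorCache | None = None
                  ) -> tuple[pd.DataFrame, NullDistribution]:
    """Estimate, null-test and label every triad.

    Returns a table with one row per triad (indices, tc, dtc, o, s,
    o_norm, label) and the pooled null distribution used.
    """
    if triads is None:
        triads = enumerate_triads(series.n_parcels)
    triads = np.atleast_2d(np.asarray(triads))
    if cache is None:
        cache = TriadEstimatorCache(series)

    rows = np.empty((triads.shape[0], 5))
    for t, triad in enumerate(triads):
        est = estimate_triad(series, triad, k, (0, 0, 0), cache)
        rows[t] = (est.tc, est.dtc, est.o, est.s, est.o_norm)
    null = build_null(series, triads, k, cache)
    labels = [classify(o, null, sd_multiplier) for o in rows[:, 2]]
    table = pd.DataFrame({
        "i": triads[:, 0], "j": triads[:, 1], "k": triads[:, 2],
        "tc": rows[:, 0], "dtc": rows[:, 1], "o": rows[:, 2],
        "s": rows[:, 3], "o_norm": rows[:, 4], "label": labels,
    })
    return table, null
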