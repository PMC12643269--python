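import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from syntopo.bold import SyntheticSpec, generate_bold
from syntopo.screen import (NullDistribution, TriadEstimatorCache,
                            build_null, circular_shift_triad, classify,
                            enumerate_triads, estimate_triad, screen_triads,
                            triad_cloud)


class TestEnumerateTriads:
    def test_minimal(self):
        assert enumerate_triads(3).tolist() == [[0, 1, 2]]

    def test_ten_channels(self):
        triads = enumerate_triads(10)
        assert triads.shape == (120, 3)
        assert np.all(triads[:, 0] < triads[:, 1])
        assert np.all(triads[:, 1] < triads[:, 2])

    def test_lexicographic_order(self):
        triads = enumerate_triads(5)
        as_tuples = list(map(tuple, triads))
        assert as_tuples == sorted(as_tuples)
        assert as_tuples[0] == (0, 1, 2)
        assert as_tuples[-1] == (2, 3, 4)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(C=st.integers(3, 40))
    def test_count_is_binomial(self, C):
        assert enumerate_triads(C).shape[0] == math.comb(C, 3)

    def test_rejects_too_few(self):
        with pytest.raises(ValueError):
            enumerate_triads(2)


class TestCircularShift:
    def test_first_channel_unshifted(self, small_series):
        series, _ = small_series
        shifted = circular_shift_triad(series, (0, 4, 7))
        assert np.array_equal(shifted[:, 0], series.data[:, 0])

    def test_channels_are_permutations(self, small_series):
        series, _ = small_series
        shifted = circular_shift_triad(series, (1, 2, 3))
        for pos, chan in enumerate((1, 2, 3)):
            assert np.array_equal(np.sort(shifted[:, pos]),
                                  np.sort(series.data[:, chan]))

    def test_shift_composes_to_identity(self, small_series):
        series, _ = small_series
        x = series.data[:, 2]
        rolled = x
        for _ in range(series.n_scans):
            rolled = np.roll(rolled, series.scan_length)
        assert np.array_equal(rolled, x)

    def test_requires_three_scans(self, rng):
        from syntopo.bold import MultiScanSeries
        series = MultiScanSeries(rng.standard_normal((100, 4)),
                                 scan_length=50, n_scans=2)
        with pytest.raises(ValueError):
            circular_shift_triad(series, (0, 1, 2))

    def test_shift_preserves_null_o_distribution(self):
        # on independent channels, shifting is distribution-preserving
        spec = SyntheticSpec(n_parcels=15, scan_length=300, n_scans=4,
                             ar_coefficient=0.6, seed=11)
        series, _ = generate_bold(spec)
        triads = enumerate_triads(15)[:200]
        cache = TriadEstimatorCache(series)
        raw = np.array([estimate_triad(series, t, cache=cache).o
                        for t in triads])
        _, null = build_null(series, triads, cache=cache,
                             return_values=True)
        assert ks_2samp(raw, null).pvalue > 0.01


class TestBuildNull:
    def test_single_triad_convention(self, small_series):
        series, _ = small_series
        null = build_null(series, [(6, 7, 8)])
        assert null.count == 1
        assert null.sd == 0.0

    def test_null_data_centered_near_zero(self):
        spec = SyntheticSpec(n_parcels=10, scan_length=250, n_scans=4,
                             ar_coefficient=0.5, seed=12)
        series, _ = generate_bold(spec)
        triads = enumerate_triads(10)[:100]
        null = build_null(series, triads)
        assert abs(null.mean) < 3 * max(null.sd / 10, 1e-3) + 0.02

    def test_planted_structure_destroyed_by_shift(self):
        # null moments with planted coupling match those of pure noise
        base = dict(n_parcels=9, scan_length=400, n_scans=4,
                    ar_coefficient=0.5, seed=13)
        planted, _ = generate_bold(SyntheticSpec(
            planted_redundant=(((0, 1, 2), 0.9),), **base))
        plain, _ = generate_bold(SyntheticSpec(**base))
        triads = enumerate_triads(9)
        null_planted = build_null(planted, triads)
        null_plain = build_null(plain, triads)
        assert abs(null_planted.mean - null_plain.mean) < 0.05
        assert abs(null_planted.sd - null_plain.sd) < 0.05


class TestClassify:
    @pytest.mark.parametrize("o,expected", [
        (-0.5, "synergistic"),
        (0.2, "neither"),    # exactly 2 SD
        (0.31, "redundant"),
    ])
    def test_threshold_rule(self, o, expected):
        null = NullDistribution(mean=0.0, sd=0.1, count=100)
        assert classify(o, null) == expected

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(o=st.floats(-5, 5), mean=st.floats(-1, 1),
           sd=st.floats(0, 1))
    def test_exhaustive_and_exclusive(self, o, mean, sd):
        label = classify(o, NullDistribution(mean, sd, 10))
        assert label in ("redundant", "synergistic", "neither")

    def test_raising_multiplier_shrinks_significant_sets(self, rng):
        null = NullDistribution(mean=0.0, sd=0.05, count=500)
        values = rng.normal(0, 0.2, 500)
        at3 = {m: sum(classify(o, null, 3.0) == m for o in values)
               for m in ("redundant", "synergistic")}
        at4 = {m: sum(classify(o, null, 4.0) == m for o in values)
               for m in ("redundant", "synergistic")}
        assert at4["redundant"] <= at3["redundant"]
        assert at4["synergistic"] <= at3["synergistic"]


class TestScreenTriads:
    def test_recovers_planted_structure_small(self, small_series):
        series, truth = small_series
        table, null = screen_triads(series)
        lookup = {(r.i, r.j, r.k): r.label for r in table.itertuples()}
        assert lookup[truth.redundant[0]] == "redundant"
        assert lookup[truth.synergistic[0]] == "synergistic"
        assert null.count == len(table)

    def test_cached_and_uncached_estimates_agree(self, small_series):
        series, _ = small_series
        cache = TriadEstimatorCache(series)
        a = estimate_triad(series, (1, 4, 8), cache=cache)
        b = estimate_triad(series, (1, 4, 8), cache=None)
        assert a.o == pytest.approx(b.o, abs=1e-12)
        assert a.tc == pytest.approx(b.tc, abs=1e-12)

    def test_shifted_cache_agrees_too(self, small_series):
        series, _ = small_series
        shifts = (0, series.scan_length, 2 * series.scan_length)
        cache = TriadEstimatorCache(series)
        a = estimate_triad(series, (0, 3, 6), shifts=shifts, cache=cache)
        b = estimate_triad(series, (0, 3, 6), shifts=shifts, cache=None)
        assert a.o == pytest.approx(b.o, abs=1e-12)


def test_triad_cloud_stacks_columns(small_series):
    series, _ = small_series
    cloud = triad_cloud(series, (2, 5, 9))
    assert cloud.shape == (series.n_frames, 3)
    assert np.array_equal(cloud[:, 1], series.data[:, 5])
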