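import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from naive_ph import naive_vr_diagram
from syntopo.persistence import (PersistenceDiagram, chebyshev_distances,
                                 enclosing_radius, read_diagram_tsv,
                                 subsample_rows, tda_summary, vr_diagram,
                                 write_diagram_tsv)

SQRT2 = np.sqrt(2.0)


def _bars(diag, dim):
    out = diag.bars(dim)
    return sorted(map(tuple, out))


def _euclid(pts):
    return squareform(pdist(np.asarray(pts, dtype=float)))


class TestChebyshevDistances:
    def test_hand_example(self):
        D = chebyshev_distances(np.array([[0, 0, 0], [1, 2, 0.5]]))
        assert D[0, 1] == 2.0

    def test_identical_points(self):
        D = chebyshev_distances(np.zeros((3, 2)))
        assert np.all(D == 0.0)

    def test_matches_double_loop(self, rng):
        pts = rng.standard_normal((50, 3))
        D = chebyshev_distances(pts)
        for a in range(50):
            for b in range(50):
                assert D[a, b] == pytest.approx(
                    np.max(np.abs(pts[a] - pts[b])), abs=1e-15)


class TestVrDiagram:
    def test_two_points(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        diag = vr_diagram(D, maxdim=2)
        assert _bars(diag, 0) == [(0.0, 3.0), (0.0, np.inf)]
        assert diag.bars(1).size == 0
        assert diag.bars(2).size == 0

    def test_square_has_one_cycle(self):
        D = _euclid([[1, 0], [0, 1], [-1, 0], [0, -1]])
        diag = vr_diagram(D, maxdim=2)
        finite = [b for b in _bars(diag, 1) if b[1] > b[0]]
        assert len(finite) == 1
        assert finite[0] == pytest.approx((SQRT2, 2.0), abs=1e-12)

    def test_octahedron_has_one_void(self):
        D = _euclid([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        diag = vr_diagram(D, maxdim=2)
        voids = [b for b in _bars(diag, 2) if b[1] > b[0]]
        assert len(voids) == 1
        assert voids[0] == pytest.approx((SQRT2, 2.0), abs=1e-12)

    def test_matches_naive_reduction(self, rng):
        for _ in range(6):
            n = int(rng.integers(6, 19))
            D = chebyshev_distances(rng.standard_normal((n, 3)))
            diag = vr_diagram(D, maxdim=2)
            mine = sorted(zip(diag.dims.tolist(), diag.births.tolist(),
                              diag.deaths.tolist()))
            assert np.allclose(
                np.array(mine), np.array(naive_vr_diagram(D)), atol=1e-12)

    def test_exactly_one_infinite_dim0_bar(self, rng):
        D = chebyshev_distances(rng.standard_normal((40, 3)))
        diag = vr_diagram(D, maxdim=1)
        infinite = ~np.isfinite(diag.deaths)
        assert infinite.sum() == 1
        assert diag.dims[infinite][0] == 0

    def test_dim0_count_monotone_in_points(self, rng):
        pts = rng.standard_normal((25, 3))
        for m in range(5, 25, 5):
            fewer = vr_diagram(chebyshev_distances(pts[:m]), maxdim=0)
            more = vr_diagram(chebyshev_distances(pts[:m + 5]), maxdim=0)
            assert more.bars(0).shape[0] >= fewer.bars(0).shape[0]

    def test_truncated_threshold_leaves_open_classes(self):
        D = _euclid([[1, 0], [0, 1], [-1, 0], [0, -1]])
        diag = vr_diagram(D, maxdim=1, threshold=1.5)
        cycle = diag.bars(1)
        assert cycle.shape[0] == 1
        assert cycle[0, 0] == pytest.approx(SQRT2)
        assert np.isinf(cycle[0, 1])

    def test_small_sphere_dominant_void(self, rng):
        g = rng.standard_normal((80, 3))
        sphere = g / np.linalg.norm(g, axis=1, keepdims=True)
        diag = vr_diagram(chebyshev_distances(sphere), maxdim=2)
        life = np.sort(np.diff(diag.bars(2), axis=1)[:, 0])[::-1]
        assert life[0] > 3 * life[1]

    def test_guard_refuses_large_dim2(self, rng):
        D = chebyshev_distances(rng.standard_normal((450, 3)))
        with pytest.raises(ValueError):
            vr_diagram(D, maxdim=2)
        vr_diagram(D, maxdim=1)  # dim 1 is fine at this size

    @pytest.mark.parametrize("bad", [
        np.array([[0.0, 1.0], [2.0, 0.0]]),      # asymmetric
        np.array([[0.0, -1.0], [-1.0, 0.0]]),    # negative
        np.array([[1.0, 1.0], [1.0, 0.0]]),      # nonzero diagonal
    ])
    def test_invalid_matrices_raise(self, bad):
        with pytest.raises(ValueError):
            vr_diagram(bad)


class TestTdaSummary:
    def test_octahedron_summary(self):
        D = _euclid([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        summ = tda_summary(vr_diagram(D, maxdim=2))
        assert summ.n_voids == 1
        assert summ.avg_persistence == pytest.approx(2.0 - SQRT2, abs=1e-12)
        assert summ.max_persistence == pytest.approx(2.0 - SQRT2, abs=1e-12)

    def test_no_dim2_bars(self):
        diag = PersistenceDiagram(np.array([0]), np.array([0.0]),
                                  np.array([np.inf]))
        summ = tda_summary(diag)
        assert (summ.n_voids, summ.avg_persistence,
                summ.max_persistence) == (0, 0.0, 0.0)

    def test_two_bars(self):
        diag = PersistenceDiagram(np.array([2, 2]), np.array([1.0, 1.0]),
                                  np.array([1.2, 1.4]))
        summ = tda_summary(diag)
        assert summ.n_voids == 2
        assert summ.avg_persistence == pytest.approx(0.3)
        assert summ.max_persistence == pytest.approx(0.4)

    def test_zero_persistence_bars_excluded(self):
        diag = PersistenceDiagram(np.array([2, 2]), np.array([1.0, 1.0]),
                                  np.array([1.0, 1.5]))
        assert tda_summary(diag).n_voids == 1


class TestSubsampleRows:
    def test_full_subsample_is_permutation(self, rng):
        cloud = rng.standard_normal((10, 3))
        out = subsample_rows(cloud, 10, seed=0)
        assert sorted(map(tuple, out)) == sorted(map(tuple, cloud))

    def test_deterministic(self, rng):
        cloud = rng.standard_normal((30, 3))
        assert np.array_equal(subsample_rows(cloud, 7, seed=3),
                              subsample_rows(cloud, 7, seed=3))

    def test_rejects_oversampling(self, rng):
        with pytest.raises(ValueError):
            subsample_rows(rng.standard_normal((5, 3)), 6, seed=0)


def test_diagram_tsv_round_trip(tmp_path, rng):
    D = chebyshev_distances(rng.standard_normal((15, 3)))
    diag = vr_diagram(D, maxdim=2)
    path = tmp_path / "diagram.tsv"
    write_diagram_tsv(diag, path)
    back = read_diagram_tsv(path)
    assert np.array_equal(back.dims, diag.dims)
    assert np.allclose(back.births, diag.births)
    assert np.allclose(back.deaths, diag.deaths)  # inf round-trips


def test_enclosing_radius_formula(rng):
    pts = rng.standard_normal((20, 3))
    D = chebyshev_distances(pts)
    assert enclosing_radius(D) == np.min(np.max(D, axis=1))
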