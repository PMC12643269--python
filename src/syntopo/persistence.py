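"""Vietoris-Rips persistence on Chebyshev distance matrices.

Public surface: build a Chebyshev distance matrix from a point cloud,
compute its Rips persistence diagram up to homology dimension 2 (so
that the "three-dimensional cavities" of an embedded cloud - the dim-2
classes - are fully resolved), and summarize the dim-2 bars by void
count, average persistence and maximum persistence.

By default the filtration is truncated at the enclosing radius of the
matrix (the smallest radius at which some point is within range of all
others).  At that scale the Rips complex is a cone, hence contractible,
so every class in dimension >= 1 has already died and the truncated
diagram equals the full one at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from ._reduction import vr_kernel

__all__ = [
    "PersistenceDiagram",
    "TdaSummary",
    "chebyshev_distances",
    "enclosing_radius",
    "vr_diagram",
    "tda_summary",
    "subsample_rows",
    "read_diagram_tsv",
    "write_diagram_tsv",
]

#: refuse the full dim-2 computation above this size unless forced;
#: the simplex count grows as n^4 and larger clouds should be subsampled
MAX_POINTS_DIM2 = 400


@dataclass(frozen=True)
class PersistenceDiagram:
    """Bars of a Rips filtration as parallel arrays.

    ``deaths`` may contain ``inf`` (the one essential dim-0 class of a
    connected complex, or classes truncated by an explicit threshold).
    Zero-persistence bars are retained here and filtered out only by
    :func:`tda_summary`.
    """

    dims: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    threshold: float = float("inf")

    def bars(self, dim: int) -> np.ndarray:
        """(birth, death) pairs of the requested dimension."""
        mask = self.dims == dim
        return np.column_stack([self.births[mask], self.deaths[mask]])


@dataclass(frozen=True)
class TdaSummary:
    """Dim-2 summary: void count, mean and max lifetime.

    Only bars with finite, strictly positive persistence count as
    voids; a diagram with none reports (0, 0.0, 0.0).
    """

    n_voids: int
    avg_persistence: float
    max_persistence: float


def chebyshev_distances(cloud: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev (max-norm) distance matrix of a cloud."""
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[0] < 1:
        raise ValueError("expected a non-empty (n, d) cloud")
    if cloud.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(cloud, metric="chebyshev"))


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(D < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(D, D.T, atol=1e-12, rtol=0.0):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return np.ascontiguousarray(D)


def enclosing_radius(D: np.ndarray) -> float:
    """min over points of the max distance to any other point."""
    if D.shape[0] == 1:
        return 0.0
    return float(np.min(np.max(D, axis=1)))


def vr_diagram(D: np.ndarray, maxdim: int = 2, threshold: float | None = None,
               force: bool = False) -> PersistenceDiagram:
    """Rips persistence of a precomputed distance matrix.

    Parameters
    ----------
    D
        Symmetric nonnegative matrix with zero diagonal (any metric).
    maxdim
        Largest homology dimension to resolve (0, 1 or 2); simplices up
        to dimension ``maxdim + 1`` enter the reduction so that deaths
        in dimension ``maxdim`` are final.
    threshold
        Filtration truncation; defaults to the enclosing radius, which
        yields the exact full diagram.  Smaller values leave truncated
        classes open (death = inf).
    force
        Allow ``maxdim == 2`` beyond :data:`MAX_POINTS_DIM2` points.
    """
    D = _check_distance_matrix(D)
    if maxdim not in (0, 1, 2):
        raise ValueError("maxdim must be 0, 1 or 2")
    n = D.shape[0]
    if maxdim == 2 and n > MAX_POINTS_DIM2 and not force:
        raise ValueError(
            f"dim-2 persistence on n={n} points exceeds the guard of "
            f"{MAX_POINTS_DIM2}; subsample the cloud (subsample_rows) "
            "or pass force=True"
        )
    if threshold is None:
        threshold = enclosing_radius(D)
    if n == 1:
        return PersistenceDiagram(np.zeros(1, dtype=np.int64), np.zeros(1),
                                  np.array([np.inf]), float(threshold))
    dims, births, deaths = vr_kernel(D, float(threshold), int(maxdim))
    return PersistenceDiagram(dims, births, deaths, float(threshold))


def tda_summary(diag: PersistenceDiagram, dim: int = 2) -> TdaSummary:
    """Void count and lifetime summaries over one homology dimension."""
    bars = diag.bars(dim)
    if bars.size:
        life = bars[:, 1] - bars[:, 0]
        life = life[np.isfinite(life) & (life > 0.0)]
    else:
        life = np.empty(0)
    if life.size == 0:
        return TdaSummary(0, 0.0, 0.0)
    return TdaSummary(int(life.size), float(life.mean()), float(life.max()))


def subsample_rows(cloud: np.ndarray, m: int, seed: int) -> np.ndarray:
    """Draw m rows uniformly without replacement (seed-deterministic)."""
    cloud = np.asarray(cloud)
    n = cloud.shape[0]
    if m > n:
        raise ValueError(f"cannot subsample {m} rows from {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=m, replace=False)
    return cloud[idx]


def write_diagram_tsv(diag: PersistenceDiagram, path) -> None:
    """Write bars as TSV (dim, birth, death); infinite deaths as 'inf'."""
    frame = pd.DataFrame({
        "dim": diag.dims,
        "birth": diag.births,
        "death": diag.deaths,
    })
    frame.to_csv(path, sep="\t", index=False)


def read_diagram_tsv(path) -> PersistenceDiagram:
    frame = pd.read_csv(path, sep="\t")
    return PersistenceDiagram(
        dims=frame["dim"].to_numpy(dtype=np.int64),
        births=frame["birth"].to_numpy(dtype=float),
        deaths=frame["death"].to_numpy(dtype=float),
    )
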