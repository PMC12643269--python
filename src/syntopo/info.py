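"""Nearest-neighbor estimators of higher-order information.

Implements Kozachenko-Leonenko differential entropy, the Kraskov
(KSG, algorithm 1) mutual information estimator, and the
entropy-combination estimator of total correlation (TC), dual total
correlation (DTC), O-information and S-information for an embedded
point cloud.  All higher-order quantities come from a *single*
k-nearest-neighbor search in the joint space followed by range counts
in the marginal spaces, which keeps the bias of the combined estimate
low: searching separately in spaces of different dimension would stack
dimension-dependent biases.

Quantities and conventions
--------------------------
For ``X = (X_1, ..., X_N)``::

    TC(X)  = sum_i H(X_i) - H(X)              collective constraints
    DTC(X) = H(X) - sum_i H(X_i | X_{-i})     shared information
    O(X)   = TC(X) - DTC(X)                   redundancy (+) vs synergy (-)
    S(X)   = TC(X) + DTC(X)                   total structured information

The estimator uses the Chebyshev (max-norm) metric in the joint and
marginal spaces, natural logarithms (all outputs in nats), ``k = 4``
neighbors by default, and strict range counts (distance strictly less
than the kth-neighbor radius) combined through digamma terms, exactly
as in KSG algorithm 1.  Writing ``F(m) = psi(m) - psi(n)`` and letting
``k_i(t)`` / ``k_{-i}(t)`` be the strict counts within the joint radius
``eps(t)`` in the marginals ``X_i`` / ``X_{-i}``::

    TC^  = F(k) - sum_i < F(k_i(t) + 1) >_t
    DTC^ = (N-1) F(k) - sum_i < F(k_{-i}(t) + 1) >_t

so that ``O^ = TC^ - DTC^`` and ``S^ = TC^ + DTC^`` hold exactly, by
construction, on every input.

A closed-form Gaussian oracle (:func:`gaussian_o_information`) is
provided for validation: for multivariate normal data every quantity is
a combination of log-determinants of the covariance and its marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from ._counts import window_count_2d

__all__ = [
    "InfoEstimate",
    "EstimatorError",
    "add_tie_noise",
    "estimate_all",
    "estimate_o_information",
    "kl_entropy",
    "pairwise_mi",
    "gaussian_entropy",
    "gaussian_o_information",
]

_LOG_2PIE = np.log(2.0 * np.pi * np.e)


class EstimatorError(ValueError):
    """Raised when a nearest-neighbor estimate cannot be formed."""


@dataclass(frozen=True)
class InfoEstimate:
    """Higher-order information estimates, in nats.

    ``o == tc - dtc`` and ``s == tc + dtc`` hold exactly because all
    four are computed from the same neighbor search and range counts.
    ``o_norm`` is ``o / s`` when ``s`` exceeds a small guard, else NaN
    (reported as missing, never coerced to zero).
    """

    tc: float
    dtc: float
    o: float
    s: float
    o_norm: float
    k: int
    n: int
    metric: str = "chebyshev"


def add_tie_noise(cloud: np.ndarray, amplitude: float = 1e-8,
                  seed: int | None = 0) -> np.ndarray:
    """Add uniform noise of the given amplitude to every coordinate.

    Needed to break exact ties (e.g. a cloud whose columns are exact
    duplicates), which would otherwise give zero nearest-neighbor
    radii.  Noise is uniform on ``[-amplitude, amplitude)``.
    """
    if amplitude == 0.0:
        return np.asarray(cloud, dtype=float)
    rng = np.random.default_rng(seed)
    cloud = np.asarray(cloud, dtype=float)
    return cloud + rng.uniform(-amplitude, amplitude, size=cloud.shape)


def _check_cloud(cloud: np.ndarray, k: int) -> np.ndarray:
    x = np.ascontiguousarray(cloud, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an (n, d) point cloud")
    n = x.shape[0]
    if k < 1 or n <= k:
        raise EstimatorError(f"need n > k >= 1, got n={n}, k={k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("point cloud contains non-finite entries")
    return x


def _joint_radii(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Chebyshev distance to the kth neighbor, and that neighbor's index."""
    tree = cKDTree(x)
    dist, idx = tree.query(x, k=k + 1, p=np.inf)
    eps = dist[:, k]
    if np.any(eps <= 0.0):
        raise EstimatorError(
            "zero kth-neighbor distance (duplicate points); "
            "enable tie-breaking noise"
        )
    return eps, idx[:, k]


def _counts_1d(col: np.ndarray, eps: np.ndarray,
               sorted_col: np.ndarray | None = None) -> np.ndarray:
    """Strict count of points with |x_s - x_t| < eps(t), excluding t."""
    xs = np.sort(col) if sorted_col is None else sorted_col
    hi = np.searchsorted(xs, col + eps, side="left")
    lo = np.searchsorted(xs, col - eps, side="right")
    return hi - lo - 1


def _counts_2d(sub: np.ndarray, eps: np.ndarray,
               pair_sorted: tuple[np.ndarray, np.ndarray] | None = None
               ) -> np.ndarray:
    """Strict count within eps(t) in a two-dimensional marginal.

    ``pair_sorted`` optionally provides (first coordinate sorted, second
    coordinate reordered the same way) precomputed by a caller that
    shares marginals across many estimates.
    """
    if pair_sorted is None:
        order = np.argsort(sub[:, 0])
        pair_sorted = (sub[order, 0], sub[order, 1])
    counts = window_count_2d(pair_sorted[0], pair_sorted[1],
                             np.ascontiguousarray(sub[:, 0]),
                             np.ascontiguousarray(sub[:, 1]), eps)
    return counts - 1  # the query point always falls in its own box


def _counts_marginal_nd(sub: np.ndarray, eps: np.ndarray,
                        at_radius: np.ndarray) -> np.ndarray:
    """Strict count within eps(t) in a marginal of dimension >= 3.

    A KD-tree ball count is inclusive at the boundary; ``at_radius``
    flags the points whose kth joint neighbor realizes the joint radius
    inside this marginal, the one boundary point a strict count must
    exclude.
    """
    tree = cKDTree(sub)
    within = tree.query_ball_point(sub, r=eps, p=np.inf, return_length=True)
    return within - 1 - at_radius.astype(np.int64)


def _marginal_radius_flags(x: np.ndarray, eps: np.ndarray,
                           kth: np.ndarray) -> np.ndarray:
    """For each marginal X_{-i}: does the kth neighbor sit at exactly eps?

    Returns a (d, n) boolean array; entry (i, t) is True when the
    Chebyshev distance from t to its kth joint neighbor, restricted to
    the coordinates other than i, equals the full joint distance.
    """
    delta = np.abs(x[kth] - x)  # (n, d)
    d = x.shape[1]
    tol = eps * 1e-12
    flags = np.empty((d, x.shape[0]), dtype=bool)
    for i in range(d):
        rest = np.delete(delta, i, axis=1).max(axis=1)
        flags[i] = rest >= eps - tol
    return flags


def estimate_all(cloud: np.ndarray, k: int = 4, *, tie_noise: float = 1e-8,
                 seed: int | None = 0, metric: str = "chebyshev",
                 marginal_pairs=None, sorted_cols=None) -> InfoEstimate:
    """Estimate TC, DTC, O and S of a cloud from one neighbor search.

    Parameters
    ----------
    cloud
        ``(n, d)`` array with ``d >= 3`` (the O-information requires at
        least a triad).
    k
        Neighbor order of the joint search.
    tie_noise, seed
        Amplitude and seed of the tie-breaking noise added to every
        coordinate before estimation; set ``tie_noise=0`` to disable
        (only safe for data without duplicated values).
    marginal_pairs, sorted_cols
        Optional precomputed (sorted first coordinate, co-sorted second
        coordinate) per 2D marginal ``X_{-i}``, and per-column sorted
        values, for callers that estimate many triads over shared
        channels (d = 3 only).  Only valid with ``tie_noise=0``.
    """
    if metric != "chebyshev":
        raise ValueError("only the Chebyshev metric is supported")
    x = _check_cloud(cloud, k)
    n, d = x.shape
    if d < 3:
        raise EstimatorError(
            "O-information needs at least 3 variables; "
            "use pairwise_mi for two"
        )
    if tie_noise > 0.0:
        if marginal_pairs is not None or sorted_cols is not None:
            raise ValueError("precomputed structures require tie_noise=0")
        x = add_tie_noise(x, tie_noise, seed)

    eps, kth = _joint_radii(x, k)

    mean_psi_1d = 0.0
    for i in range(d):
        sc = None if sorted_cols is None else sorted_cols[:, i]
        ki = _counts_1d(x[:, i], eps, sc)
        mean_psi_1d += float(np.mean(digamma(ki + 1)))

    flags = None if d == 3 else _marginal_radius_flags(x, eps, kth)
    mean_psi_rest = 0.0
    for i in range(d):
        sub = np.ascontiguousarray(np.delete(x, i, axis=1))
        if d == 3:
            pair = None if marginal_pairs is None else marginal_pairs[i]
            kmi = _counts_2d(sub, eps, pair)
        else:
            kmi = _counts_marginal_nd(sub, eps, flags[i])
        mean_psi_rest += float(np.mean(digamma(kmi + 1)))

    f_joint = float(digamma(k) - digamma(n))
    psi_n = float(digamma(n))
    tc = f_joint - (mean_psi_1d - d * psi_n)
    dtc = (d - 1) * f_joint - (mean_psi_rest - d * psi_n)
    o = tc - dtc
    s = tc + dtc
    o_norm = o / s if s > 1e-6 else float("nan")
    return InfoEstimate(tc=tc, dtc=dtc, o=o, s=s, o_norm=o_norm, k=k, n=n)


def estimate_o_information(cloud: np.ndarray, k: int = 4, **kwargs) -> float:
    """O-information of a cloud, in nats (see :func:`estimate_all`)."""
    return estimate_all(cloud, k, **kwargs).o


def kl_entropy(cloud: np.ndarray, k: int = 4, *, tie_noise: float = 0.0,
               seed: int | None = 0) -> float:
    """Kozachenko-Leonenko differential entropy, in nats.

    Uses the Chebyshev metric; the unit ball has volume ``2^d``, giving

        H^ = psi(n) - psi(k) + d log 2 + d < log eps(t) >_t
    """
    x = _check_cloud(cloud, k)
    if tie_noise > 0.0:
        x = add_tie_noise(x, tie_noise, seed)
    n, d = x.shape
    eps, _ = _joint_radii(x, k)
    return float(digamma(n) - digamma(k) + d * np.log(2.0)
                 + d * np.mean(np.log(eps)))


def pairwise_mi(cloud: np.ndarray, k: int = 4, *, tie_noise: float = 0.0,
                seed: int | None = 0) -> float:
    """KSG algorithm-1 mutual information of a two-column cloud, in nats."""
    x = _check_cloud(cloud, k)
    if x.shape[1] != 2:
        raise ValueError("pairwise_mi expects exactly two columns")
    if tie_noise > 0.0:
        x = add_tie_noise(x, tie_noise, seed)
    n = x.shape[0]
    eps, _ = _joint_radii(x, k)
    nx = _counts_1d(x[:, 0], eps)
    ny = _counts_1d(x[:, 1], eps)
    return float(digamma(k) + digamma(n)
                 - np.mean(digamma(nx + 1) + digamma(ny + 1)))


# ---------------------------------------------------------------------------
# Gaussian closed forms (validation oracle)
# ---------------------------------------------------------------------------

def _logdet_pd(cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance must be positive-definite")
    return float(logdet)


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy of a multivariate normal, in nats."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = cov.shape[0]
    return 0.5 * (d * _LOG_2PIE + _logdet_pd(cov))


def gaussian_o_information(cov: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form (tc, dtc, o, s) of a multivariate normal, in nats.

    Every term reduces to log-determinants of the covariance and its
    one- and (N-1)-dimensional principal minors.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    d = cov.shape[0]
    np.linalg.cholesky(cov)  # positive-definiteness check
    logdet = _logdet_pd(cov)
    tc = 0.5 * (float(np.sum(np.log(np.diag(cov)))) - logdet)
    sum_minor = 0.0
    for i in range(d):
        keep = [j for j in range(d) if j != i]
        sum_minor += _logdet_pd(cov[np.ix_(keep, keep)])
    # DTC = (1-N) H(X) + sum_i H(X_{-i}); the 2*pi*e terms cancel exactly
    dtc = 0.5 * ((1 - d) * logdet + sum_minor)
    o = tc - dtc
    return tc, dtc, o, tc + dtc
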