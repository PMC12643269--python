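"""PCA as a pure rotation of point clouds.

Used to separate "intrinsic" from "contextual" higher-order
information: the cloud is mean-centered and rotated onto the
eigenvectors of its sample covariance, with no scaling or whitening, so
pairwise Euclidean distances (and hence the topology of the cloud) are
preserved while the loading of the data onto the coordinate axes
changes.  Information measures computed on the rotated cloud therefore
quantify structure that survives re-embedding.

Determinism: principal axes are ordered by decreasing eigenvalue, ties
broken by input-axis order, and each axis is oriented so that its
largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PcaResult", "pca_rotate", "pc1_variance"]


@dataclass(frozen=True)
class PcaResult:
    """A centered, rotated cloud and the per-axis variance fractions."""

    rotated: np.ndarray
    explained_fractions: np.ndarray
    components: np.ndarray  # rows are principal axes in input coordinates


def pca_rotate(cloud: np.ndarray) -> PcaResult:
    """Center a cloud and rotate it onto its principal axes.

    Zero-variance directions are allowed (their fraction is 0); the
    transform is always a proper rotation or reflection, never a
    rescaling, so Euclidean pairwise distances are preserved.
    """
    x = np.asarray(cloud, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an (n, d) point cloud")
    n, d = x.shape
    if n <= d:
        raise ValueError(f"need more points than dimensions (n={n}, d={d})")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    # eigh returns ascending order; stable reversal keeps input-axis
    # order as the tie-break among equal eigenvalues
    order = np.argsort(-eigvals, kind="stable")
    eigvals = np.clip(eigvals[order], 0.0, None)
    axes = eigvecs[:, order].T
    # orient each axis so its largest-magnitude loading is positive
    for row in axes:
        pivot = np.argmax(np.abs(row))
        if row[pivot] < 0:
            row *= -1.0
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.full(d, 1.0 / d)
    return PcaResult(rotated=centered @ axes.T,
                     explained_fractions=fractions,
                     components=axes)


def pc1_variance(cloud: np.ndarray) -> float:
    """Fraction of total variance carried by the first principal axis."""
    return float(pca_rotate(cloud).explained_fractions[0])
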