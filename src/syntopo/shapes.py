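"""Benchmark point clouds sampled from manifolds with known topology.

Seven shape families are supported, all embedded in 3D: a line (one
coordinate copied into all three columns), a plane, the unit sphere, the
unit ball, the surface and the interior of a torus, and (p, q) torus
knots (the trefoil is the (2, 3) knot).  Each generator is deterministic
given a seed, and clouds can be rotated by fixed per-axis angles so that
low-dimensional structure is genuinely embedded in three dimensions.

Point clouds are plain ``(n, d)`` float arrays; they are the common
currency shared with the information estimators, PCA, and the
persistence machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SHAPE_KINDS",
    "ShapeSpec",
    "generate_shape",
    "rotate",
    "rotation_matrix",
    "read_cloud_tsv",
    "write_cloud_tsv",
]

SHAPE_KINDS = (
    "line",
    "plane",
    "sphere",
    "ball",
    "torus_hollow",
    "torus_filled",
    "torus_knot",
    "trefoil",
)


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one benchmark cloud.

    Parameters
    ----------
    kind
        One of :data:`SHAPE_KINDS`.
    n
        Number of points to sample.
    radius
        Sphere/ball radius.
    major_radius, minor_radius
        Torus radii (``minor_radius < major_radius`` required).
    p, q
        Torus-knot winding numbers; must be coprime positive integers.
    rotation
        Per-axis rotation angles in radians, applied about the fixed x,
        then y, then z axes after sampling.
    seed
        Seed for the sampling RNG.
    area_correct
        If True, torus-surface sampling is area-weighted (rejection in
        the poloidal angle); by default sampling is uniform in the two
        torus angles.
    """

    kind: str
    n: int
    radius: float = 1.0
    major_radius: float = 1.0
    minor_radius: float = 0.5
    p: int = 2
    q: int = 3
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    area_correct: bool = False

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind: {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.radius <= 0 or self.major_radius <= 0 or self.minor_radius <= 0:
            raise ValueError("radii must be positive")
        if self.kind in ("torus_hollow", "torus_filled", "torus_knot"):
            if self.minor_radius >= self.major_radius:
                raise ValueError("minor_radius must be < major_radius")
        if self.kind == "torus_knot":
            if self.p < 1 or self.q < 1 or math.gcd(self.p, self.q) != 1:
                raise ValueError("(p, q) must be coprime positive integers")


def rotation_matrix(angles: tuple[float, float, float]) -> np.ndarray:
    """Composite of single-axis rotations: ``R = Rx(ax) Ry(ay) Rz(az)``.

    The matrices compose in x, y, z listing order, so as an operator
    the z rotation acts on the cloud first and the x rotation last.
    Any composition order is an isometry; this one is pinned down
    because O-information is orientation-dependent and results must be
    reproducible.
    """
    ax, ay, az = angles
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def rotate(cloud: np.ndarray, angles: tuple[float, float, float]) -> np.ndarray:
    """Rotate a 3D cloud by per-axis angles (see :func:`rotation_matrix`)."""
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[1] != 3:
        raise ValueError("rotate requires an (n, 3) cloud")
    return cloud @ rotation_matrix(angles).T


def _sample_torus_angles(rng: np.random.Generator, n: int, ratio: float,
                         area_correct: bool) -> tuple[np.ndarray, np.ndarray]:
    """Toroidal/poloidal angles; optionally area-weighted in the poloidal one.

    ``ratio`` is minor/major radius; the surface element is proportional
    to ``1 + ratio*cos(phi)``, which rejection sampling targets when
    ``area_correct`` is on.
    """
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    if not area_correct:
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        return theta, phi
    phi = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, 2.0 * np.pi, 2 * (n - filled))
        accept = rng.uniform(0.0, 1.0 + ratio, cand.size) < 1.0 + ratio * np.cos(cand)
        good = cand[accept][: n - filled]
        phi[filled : filled + good.size] = good
        filled += good.size
    return theta, phi


def _torus_xyz(theta: np.ndarray, phi: np.ndarray, R: float, r: np.ndarray | float
               ) -> np.ndarray:
    x = (R + r * np.cos(phi)) * np.cos(theta)
    y = (R + r * np.cos(phi)) * np.sin(theta)
    z = r * np.sin(phi)
    return np.column_stack([x, y, z])


def generate_shape(spec: ShapeSpec) -> np.ndarray:
    """Sample a point cloud from the manifold described by ``spec``.

    Points lie exactly on the manifold for surface shapes and curves
    (sphere, hollow torus, knots, line, plane) and inside it for the
    ball and filled torus, then the whole cloud is rotated by
    ``spec.rotation``.
    """
    rng = np.random.default_rng(spec.seed)
    n, R, r = spec.n, spec.major_radius, spec.minor_radius

    if spec.kind == "line":
        x = rng.uniform(-1.0, 1.0, n)
        cloud = np.column_stack([x, x, x])
    elif spec.kind == "plane":
        x1 = rng.uniform(-1.0, 1.0, n)
        x2 = rng.uniform(-1.0, 1.0, n)
        cloud = np.column_stack([x1, x2, np.zeros(n)])
    elif spec.kind == "sphere":
        g = rng.standard_normal((n, 3))
        cloud = spec.radius * g / np.linalg.norm(g, axis=1, keepdims=True)
    elif spec.kind == "ball":
        g = rng.standard_normal((n, 3))
        direction = g / np.linalg.norm(g, axis=1, keepdims=True)
        # U^(1/3) scaling gives uniform density in the solid ball
        rad = spec.radius * rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
        cloud = direction * rad[:, None]
    elif spec.kind == "torus_hollow":
        theta, phi = _sample_torus_angles(rng, n, r / R, spec.area_correct)
        cloud = _torus_xyz(theta, phi, R, r)
    elif spec.kind == "torus_filled":
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        # sqrt(U) gives uniform density over the circular cross-section
        rad = r * np.sqrt(rng.uniform(0.0, 1.0, n))
        cloud = _torus_xyz(theta, phi, R, rad)
    elif spec.kind == "torus_knot":
        # (p, q) curve on the torus surface, uniform in the parameter:
        # q toroidal windings, p poloidal windings
        t = rng.uniform(0.0, 2.0 * np.pi, n)
        cloud = _torus_xyz(spec.q * t, spec.p * t, R, r)
    elif spec.kind == "trefoil":
        # classic standalone trefoil curve (not confined to the
        # package's torus); scale does not affect information measures
        t = rng.uniform(0.0, 2.0 * np.pi, n)
        cloud = np.column_stack([
            np.sin(t) + 2.0 * np.sin(2.0 * t),
            np.cos(t) - 2.0 * np.cos(2.0 * t),
            -np.sin(3.0 * t),
        ])
    else:  # pragma: no cover - guarded by ShapeSpec
        raise ValueError(spec.kind)

    if any(a != 0.0 for a in spec.rotation):
        cloud = rotate(cloud, spec.rotation)
    return cloud


def write_cloud_tsv(cloud: np.ndarray, path) -> None:
    """Write a cloud as headered TSV with columns x1..xd."""
    cloud = np.asarray(cloud, dtype=float)
    cols = [f"x{i + 1}" for i in range(cloud.shape[1])]
    pd.DataFrame(cloud, columns=cols).to_csv(path, sep="\t", index=False)


def read_cloud_tsv(path) -> np.ndarray:
    """Read a cloud written by :func:`write_cloud_tsv`."""
    frame = pd.read_csv(path, sep="\t")
    cloud = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(cloud)):
        raise ValueError("point cloud contains non-finite entries")
    return cloud
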