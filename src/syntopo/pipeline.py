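"""Orchestration of the two studies.

1. The *shape suite*: O-information of eight benchmark clouds (line,
   plane, sphere, ball, hollow/filled torus, trefoil and (5,3) torus
   knot), before and after PCA rotation, distinguishing contextual
   higher-order information (destroyed by rotation) from intrinsic
   higher-order information (preserved).

2. The *triad study*: screen every triad of a multi-scan time series
   against the circular-shift null, then, for each classified triad,
   join the information measures (raw and post-PCA), the dim-2 Rips
   persistence summaries of the subsampled raw cloud, and the PC1
   variance fraction, and correlate features within each significance
   class with Spearman's rank correlation.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import pca, persistence, screen
from .bold import MultiScanSeries
from .info import estimate_all
from .shapes import ShapeSpec, generate_shape

__all__ = [
    "SHAPE_SUITE",
    "run_shape_suite",
    "compute_triad_features",
    "correlate_features",
    "ks_compare",
    "run_triad_study",
]

log = logging.getLogger("syntopo")

_QUARTER = math.pi / 4.0

#: the eight benchmark configurations: (name, kind, shape kwargs)
SHAPE_SUITE: tuple[tuple[str, dict], ...] = (
    ("line", {"kind": "line"}),
    ("plane", {"kind": "plane", "rotation": (_QUARTER,) * 3}),
    ("sphere", {"kind": "sphere"}),
    ("ball", {"kind": "ball"}),
    ("torus_hollow", {"kind": "torus_hollow", "rotation": (_QUARTER,) * 3}),
    ("torus_filled", {"kind": "torus_filled", "rotation": (_QUARTER,) * 3}),
    ("trefoil", {"kind": "trefoil", "rotation": (_QUARTER,) * 3}),
    ("knot_5_3", {"kind": "torus_knot", "p": 5, "q": 3,
                  "rotation": (_QUARTER,) * 3}),
)


def run_shape_suite(n: int = 10_000, k: int = 4, seed: int = 0,
                    tie_noise: float = 1e-8) -> pd.DataFrame:
    """O-information of each benchmark shape, raw and after PCA.

    Each shape draws its own child seed from ``seed`` so the suite is
    reproducible as a whole.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(
        2 * len(SHAPE_SUITE))
    rows = []
    for idx, (name, kwargs) in enumerate(SHAPE_SUITE):
        t0 = time.perf_counter()
        spec = ShapeSpec(n=n, seed=int(child_seeds[2 * idx] % (2 ** 31)),
                         **kwargs)
        cloud = generate_shape(spec)
        noise_seed = int(child_seeds[2 * idx + 1] % (2 ** 31))
        o_raw = estimate_all(cloud, k, tie_noise=tie_noise,
                             seed=noise_seed).o
        rotated = pca.pca_rotate(cloud).rotated
        o_pca = estimate_all(rotated, k, tie_noise=tie_noise,
                             seed=noise_seed).o
        rows.append({"shape": name, "o_raw": o_raw, "o_after_pca": o_pca})
        log.info("shape %-12s o_raw=%+.3f o_pca=%+.3f (%.1fs)",
                 name, o_raw, o_pca, time.perf_counter() - t0)
    return pd.DataFrame(rows)


def compute_triad_features(series: MultiScanSeries, triads,
                           labels=None, k: int = 4,
                           subsample: int = 150, seed: int = 0,
                           cache: screen.TriadEstimatorCache | None = None,
                           tda_post_pca: bool = False) -> pd.DataFrame:
    """Per-triad feature rows: information (raw and post-PCA), dim-2
    persistence summaries of the subsampled raw cloud, PC1 variance.

    The subsampled frame indices are drawn once and shared by every
    triad so that topological features are comparable across triads.
    """
    triads = np.atleast_2d(np.asarray(triads))
    if cache is None:
        cache = screen.TriadEstimatorCache(series)
    rng = np.random.default_rng(seed)
    frame_idx = rng.choice(series.n_frames, size=min(subsample,
                                                     series.n_frames),
                           replace=False)
    rows = []
    for t, triad in enumerate(triads):
        t0 = time.perf_counter()
        est = screen.estimate_triad(series, triad, k, (0, 0, 0), cache)
        cloud = screen.triad_cloud(series, triad)
        res = pca.pca_rotate(cloud)
        est_pca = estimate_all(res.rotated, k, tie_noise=0.0)

        sub = cloud[frame_idx]
        diag = persistence.vr_diagram(persistence.chebyshev_distances(sub))
        summ = persistence.tda_summary(diag)
        row = {
            "i": int(triad[0]), "j": int(triad[1]), "k": int(triad[2]),
            "tc": est.tc, "dtc": est.dtc, "o": est.o, "s": est.s,
            "o_norm": est.o_norm,
            "tc_pca": est_pca.tc, "dtc_pca": est_pca.dtc,
            "o_pca": est_pca.o, "o_norm_pca": est_pca.o_norm,
            "n_voids": summ.n_voids,
            "avg_persistence": summ.avg_persistence,
            "max_persistence": summ.max_persistence,
            "pc1_variance": float(res.explained_fractions[0]),
        }
        if tda_post_pca:
            sub_pca = res.rotated[frame_idx]
            diag_pca = persistence.vr_diagram(
                persistence.chebyshev_distances(sub_pca))
            summ_pca = persistence.tda_summary(diag_pca)
            row["n_voids_pca"] = summ_pca.n_voids
            row["avg_persistence_pca"] = summ_pca.avg_persistence
        if labels is not None:
            row["label"] = labels[t]
        rows.append(row)
        log.debug("triad %s features in %.2fs", tuple(triad),
                  time.perf_counter() - t0)
    return pd.DataFrame(rows)


def correlate_features(rows: pd.DataFrame, pairs,
                       by: str | None = "label") -> pd.DataFrame:
    """Spearman rank correlation for requested feature pairs.

    Computed separately per class when ``by`` names a label column;
    classes with fewer than 3 rows are skipped with a warning.
    """
    groups = (rows.groupby(by) if by and by in rows.columns
              else [("all", rows)])
    out = []
    for cls, grp in groups:
        if len(grp) < 3:
            log.warning("class %r has %d rows (<3); skipped", cls, len(grp))
            continue
        for fx, fy in pairs:
            x = grp[fx].to_numpy(dtype=float)
            y = grp[fy].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 3:
                log.warning("pair (%s, %s) in class %r has <3 finite rows",
                            fx, fy, cls)
                continue
            rho, p = stats.spearmanr(x[keep], y[keep])
            out.append({"feature_x": fx, "feature_y": fy, "class": cls,
                        "rho": float(rho), "p": float(p),
                        "n": int(keep.sum())})
    return pd.DataFrame(out)


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class TriadStudyResult:
    """Everything the triad study produces."""

    screen_table: pd.DataFrame
    null: screen.NullDistribution
    features: pd.DataFrame
    correlations: pd.DataFrame


_DEFAULT_PAIRS = (
    ("o_norm", "n_voids"),
    ("o_norm", "avg_persistence"),
    ("o_norm", "pc1_variance"),
    ("tc", "avg_persistence"),
    ("tc", "n_voids"),
    ("dtc", "avg_persistence"),
    ("dtc", "n_voids"),
)


def run_triad_study(series: MultiScanSeries, k: int = 4,
                    sd_multiplier: float = 3.0, subsample: int = 150,
                    seed: int = 0, pairs=_DEFAULT_PAIRS,
                    features_for: str = "significant") -> TriadStudyResult:
    """Screen all triads, compute features, correlate.

    ``features_for`` selects which triads get the (expensive) TDA and
    PCA features: "significant" (default) or "all".
    """
    t0 = time.perf_counter()
    cache = screen.TriadEstimatorCache(series)
    table, null = screen.screen_triads(series, k=k,
                                       sd_multiplier=sd_multiplier,
                                       cache=cache)
    n_red = int((table["label"] == "redundant").sum())
    n_syn = int((table["label"] == "synergistic").sum())
    log.info("screened %d triads: %d redundant, %d synergistic "
             "(null mean %.4f sd %.4f) in %.1fs", len(table), n_red,
             n_syn, null.mean, null.sd, time.perf_counter() - t0)

    if features_for == "all":
        sel = table
    else:
        sel = table[table["label"] != "neither"]
    triads = sel[["i", "j", "k"]].to_numpy()
    features = compute_triad_features(
        series, triads, labels=sel["label"].to_list(), k=k,
        subsample=subsample, seed=seed, cache=cache)
    correlations = correlate_features(features, pairs)
    return TriadStudyResult(screen_table=table, null=null,
                            features=features, correlations=correlations)
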