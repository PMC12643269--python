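"""Synthetic multi-scan BOLD-like time series with planted triads.

Emulates the statistical skeleton of concatenated resting-state fMRI
parcel time series needed to exercise the triad-screening pipeline:

* every channel is an AR(1) process (the minimal model of the temporal
  autocorrelation that the circular-shift null is designed to
  preserve), re-initialized independently at each scan boundary;
* a *redundant* planted triad shares a common AR(1) latent source
  (synchrony), each member receiving it with a configurable coupling
  plus idiosyncratic AR(1) noise;
* a *synergistic* planted triad is a causal collider: two independent
  AR(1) parents and a third channel equal to their standardized sum
  plus observation noise, so the third is determined by the joint state
  of the first two but only weakly by either alone;
* all remaining channels are independent AR(1) noise, and every column
  is z-scored per scan (mirroring the scale of preprocessed BOLD).

It does not emulate hemodynamics, spatial structure, motion or
preprocessing artifacts; what it guarantees is known ground truth:
which triads carry genuine higher-order structure and of which sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MultiScanSeries",
    "SyntheticSpec",
    "GroundTruth",
    "generate_bold",
    "read_bold_csv",
    "write_bold_csv",
]


@dataclass(frozen=True)
class MultiScanSeries:
    """T x C matrix of frames by parcels with known scan boundaries."""

    data: np.ndarray
    scan_length: int
    n_scans: int
    columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("data must be a non-empty T x C matrix")
        if self.scan_length * self.n_scans != data.shape[0]:
            raise ValueError(
                f"scan_length * n_scans = {self.scan_length * self.n_scans} "
                f"!= T = {data.shape[0]}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic multi-scan dataset.

    ``planted_redundant`` maps sorted parcel triples to the coupling of
    each member onto the shared latent (0..1); ``planted_synergistic``
    maps triples ``(parent, parent, child)`` to the observation-noise
    standard deviation of the collider child.  Planted triads must be
    disjoint so that every non-planted triad is genuinely null.
    """

    n_parcels: int
    scan_length: int = 1100
    n_scans: int = 4
    ar_coefficient: float = 0.8
    planted_redundant: tuple[tuple[tuple[int, int, int], float], ...] = ()
    planted_synergistic: tuple[tuple[tuple[int, int, int], float], ...] = ()
    seed: int = 0
    zscore_per_scan: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must be in [0, 1)")
        used: set[int] = set()
        for triad, _ in (*self.planted_redundant, *self.planted_synergistic):
            if len(set(triad)) != 3 or any(
                    not 0 <= i < self.n_parcels for i in triad):
                raise ValueError(f"invalid triad {triad}")
            if used & set(triad):
                raise ValueError("planted triads must be disjoint")
            used |= set(triad)


@dataclass(frozen=True)
class GroundTruth:
    """Planted-triad labels; every other triad is implicitly null."""

    redundant: tuple[tuple[int, int, int], ...]
    synergistic: tuple[tuple[int, int, int], ...]

    def label(self, triad: tuple[int, int, int]) -> str:
        key = tuple(sorted(triad))
        if key in {tuple(sorted(t)) for t in self.redundant}:
            return "redundant"
        if key in {tuple(sorted(t)) for t in self.synergistic}:
            return "synergistic"
        return "neither"


def _ar1(rng: np.random.Generator, phi: float, length: int,
         size: int) -> np.ndarray:
    """Stationary AR(1) columns: x_t = phi x_{t-1} + sqrt(1-phi^2) e_t."""
    x = np.empty((length, size))
    x[0] = rng.standard_normal(size)
    innov = np.sqrt(1.0 - phi * phi)
    noise = rng.standard_normal((length - 1, size))
    for t in range(1, length):
        x[t] = phi * x[t - 1] + innov * noise[t - 1]
    return x


def generate_bold(spec: SyntheticSpec) -> tuple[MultiScanSeries, GroundTruth]:
    """Generate a synthetic multi-scan dataset with known triad labels."""
    rng = np.random.default_rng(spec.seed)
    T = spec.scan_length * spec.n_scans
    phi = spec.ar_coefficient
    data = np.empty((T, spec.n_parcels))

    for s in range(spec.n_scans):
        lo = s * spec.scan_length
        hi = lo + spec.scan_length
        # independent AR(1) background for every parcel, fresh per scan
        block = _ar1(rng, phi, spec.scan_length, spec.n_parcels)

        for (i, j, k), coupling in spec.planted_redundant:
            latent = _ar1(rng, phi, spec.scan_length, 1)[:, 0]
            resid = np.sqrt(1.0 - coupling * coupling)
            for c in (i, j, k):
                block[:, c] = coupling * latent + resid * block[:, c]

        for (p1, p2, child), noise in spec.planted_synergistic:
            # collider: standardized sum of the two parents plus noise
            block[:, child] = ((block[:, p1] + block[:, p2]) / np.sqrt(2.0)
                               + noise * _ar1(rng, phi, spec.scan_length,
                                              1)[:, 0])

        if spec.zscore_per_scan:
            block = (block - block.mean(axis=0)) / block.std(axis=0)
        data[lo:hi] = block

    truth = GroundTruth(
        redundant=tuple(tuple(sorted(t)) for t, _ in spec.planted_redundant),
        synergistic=tuple(tuple(sorted(t)) for t, _ in
                          spec.planted_synergistic),
    )
    series = MultiScanSeries(data=data, scan_length=spec.scan_length,
                             n_scans=spec.n_scans)
    return series, truth


def write_bold_csv(series: MultiScanSeries, path) -> None:
    """Write frames-by-parcels CSV (header row of parcel names)."""
    cols = series.columns or [f"parcel{i}" for i in range(series.n_parcels)]
    pd.DataFrame(series.data, columns=list(cols)).to_csv(path, index=False)


def read_bold_csv(path, scan_length: int, n_scans: int,
                  header: bool = True) -> MultiScanSeries:
    """Read a frames-by-parcels CSV; scan structure comes from config."""
    frame = pd.read_csv(path, header=0 if header else None)
    data = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("BOLD matrix contains non-numeric or missing cells")
    columns = tuple(str(c) for c in frame.columns) if header else None
    return MultiScanSeries(data=data, scan_length=scan_length,
                           n_scans=n_scans, columns=columns)
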