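"""Voxel-wise resting-state measures.

* seed-based functional connectivity: Pearson correlation of every in-mask
  voxel with the mean series of a spherical seed, Fisher r-to-z transformed;
* ALFF: the mean single-sided FFT amplitude (2|X_k|/N) over the 0.01-0.08 Hz
  bins of the demeaned voxel series;
* ReHo: Kendall's coefficient of concordance (W) of each voxel with its
  3x3x3-cube neighbors, with the standard tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .grids import FuncSeries, MetricMap

__all__ = [
    "SeedSpec",
    "seed_voxels",
    "fc_map",
    "fisher_z",
    "alff_map",
    "kendalls_w",
    "reho_map",
]


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed in world (mm) coordinates.

    The default is the posterior cingulate seed of the default-mode-network
    connectivity analysis: a 10 mm radius sphere at (0, -50, 31).
    """

    center_world_mm: tuple[float, float, float] = (0.0, -50.0, 31.0)
    radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("seed radius must be positive")


def seed_voxels(seed: SeedSpec, affine: np.ndarray, grid_shape, mask: np.ndarray) -> np.ndarray:
    """In-mask voxels whose center lies within the seed sphere (boundary
    inclusive), as an (n, 3) array of voxel indices."""
    affine = np.asarray(affine, dtype=np.float64)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    mask = np.asarray(mask).astype(bool)
    idx = np.indices(grid_shape).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]
    d2 = ((world - np.asarray(seed.center_world_mm).reshape(3, 1)) ** 2).sum(axis=0)
    inside = (d2 <= seed.radius_mm**2 + 1e-9).reshape(grid_shape) & mask
    if not inside.any():
        raise ValueError(
            f"seed sphere at {tuple(seed.center_world_mm)} mm (r={seed.radius_mm} mm) "
            "contains no in-mask voxel"
        )
    return np.argwhere(inside)


def seed_mean_timeseries(series: FuncSeries, seed: SeedSpec, mask: np.ndarray) -> np.ndarray:
    vox = seed_voxels(seed, series.affine, series.shape3, mask)
    return series.data[vox[:, 0], vox[:, 1], vox[:, 2]].mean(axis=0)


def fc_map(series: FuncSeries, seed_ts: np.ndarray, mask: np.ndarray) -> MetricMap:
    """Pearson correlation of every in-mask voxel series with ``seed_ts``.

    Constant voxels get r = 0 and are flagged.
    """
    seed_ts = np.asarray(seed_ts, dtype=np.float64).ravel()
    n = series.n_volumes
    if seed_ts.size != n:
        raise ValueError("seed time series length does not match the series")
    sc = seed_ts - seed_ts.mean()
    s_norm = np.sqrt(sc @ sc)
    if s_norm == 0:
        raise ValueError("seed time series is constant")
    mask = np.asarray(mask).astype(bool)
    flat = series.data.reshape(-1, n)
    xc = flat - flat.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xc**2).sum(axis=1))
    constant = x_norm == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ sc) / (x_norm * s_norm)
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0).reshape(series.shape3)
    return MetricMap(data=r, mask=mask, kind="fc_r",
                     provenance={"op": "fc_map", "n_volumes": n},
                     flags=constant.reshape(series.shape3) & mask)


def fisher_z(fc: MetricMap) -> MetricMap:
    """Fisher r-to-z transform, z = atanh(r); |r| = 1 is clipped to
    +/-(1 - 1e-7) before the transform and flagged."""
    if fc.kind != "fc_r":
        raise ValueError(f"fisher_z expects an fc_r map, got {fc.kind!r}")
    r = fc.data
    if np.any(np.abs(r[fc.mask]) > 1.0 + 1e-12):
        raise ValueError("correlation map contains |r| > 1; corrupt input")
    clipped = np.abs(r) >= 1.0
    z = np.arctanh(np.clip(r, -1.0 + 1e-7, 1.0 - 1e-7))
    flags = clipped & fc.mask
    if fc.flags is not None:
        flags = flags | fc.flags
    return MetricMap(data=z, mask=fc.mask, kind="fc_z",
                     provenance={**fc.provenance, "op": "fisher_z"},
                     flags=flags)


def alff_map(series: FuncSeries, mask: np.ndarray, low_hz: float = 0.01,
             high_hz: float = 0.08) -> MetricMap:
    """Amplitude of low-frequency fluctuation.

    Per voxel the demeaned series is Fourier transformed; the single-sided
    amplitude spectrum a_k = 2|X_k|/N is averaged over the bins with
    low_hz <= f_k <= high_hz (both edges inclusive).
    """
    n = series.n_volumes
    freqs = np.fft.rfftfreq(n, series.tr_s)
    band = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12) & (freqs > 0)
    if band.sum() < 2:
        raise ValueError(
            f"need >= 2 FFT bins inside [{low_hz}, {high_hz}] Hz; bin grid spacing is "
            f"{freqs[1] if n > 1 else float('nan'):.6g} Hz with {band.sum()} in-band bins"
        )
    flat = series.data.reshape(-1, n)
    flat = flat - flat.mean(axis=1, keepdims=True)
    amp = 2.0 * np.abs(np.fft.rfft(flat, axis=1)) / n
    alff = amp[:, band].mean(axis=1).reshape(series.shape3)
    return MetricMap(data=alff, mask=np.asarray(mask).astype(bool), kind="alff",
                     band_hz=(low_hz, high_hz),
                     provenance={"op": "alff_map", "amplitude_convention": "2|X_k|/N",
                                 "n_inband_bins": int(band.sum())})


def _tie_correction(values: np.ndarray) -> float:
    """Standard Kendall tie term sum(t^3 - t) over tie groups of one series."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(np.float64)
    return float((t**3 - t).sum())


def kendalls_w(series_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance W of K series over n time points.

    Each of the K series is ranked over time (average ranks for ties); with
    rank sums R_t across series,

        W = 12 * sum_t (R_t - mean R)^2 / (K^2 (n^3 - n) - K * T)

    where T is the tie-correction sum over all series.  All-constant input
    (denominator 0) is defined as 0.
    """
    x = np.asarray(series_matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a (K, n) matrix of K series")
    k, n = x.shape
    if k < 2 or n < 2:
        raise ValueError(f"need K >= 2 series of length n >= 2, got K={k}, n={n}")
    ranks = rankdata(x, axis=1)
    r_t = ranks.sum(axis=0)
    s = ((r_t - r_t.mean()) ** 2).sum()
    tie = sum(_tie_correction(row) for row in x)
    denom = k**2 * (n**3 - n) - k * tie
    if denom <= 0:
        return 0.0
    return float(min(max(12.0 * s / denom, 0.0), 1.0))


_NEIGHBORHOOD_OFFSETS = {
    7: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1],
    19: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if abs(dx) + abs(dy) + abs(dz) <= 2],
    27: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)],
}


def reho_map(series: FuncSeries, mask: np.ndarray, neighborhood: int = 27,
             min_neighbors: int = 13) -> MetricMap:
    """Regional homogeneity: Kendall's W of each voxel with its neighbors.

    ``neighborhood`` selects the cluster from the 3x3x3 cube: 7 (faces),
    19 (faces+edges) or 27 (full cube, i.e. the voxel and its 26 nearest
    neighbors).  Voxels with fewer than ``min_neighbors`` in-mask neighbors
    (center excluded from the count) are flagged and set to 0.

    Implementation note: ranks and per-voxel tie corrections are computed
    once, then rank sums over the neighborhood are accumulated by shifted
    slicing, so the cost is 27 array shifts rather than a Python loop over
    voxels.
    """
    if neighborhood not in _NEIGHBORHOOD_OFFSETS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOOD_OFFSETS)}, "
                         f"got {neighborhood}")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.shape3:
        raise ValueError("mask grid does not match the series grid")
    n = series.n_volumes
    if n < 2:
        raise ValueError("need at least 2 time points")

    data = series.data
    ranks = rankdata(data, axis=3)
    ranks[~mask] = 0.0
    tie = np.zeros(series.shape3)
    for i, j, kk in np.argwhere(mask):
        tie[i, j, kk] = _tie_correction(data[i, j, kk])

    pad = ((1, 1), (1, 1), (1, 1))
    ranks_p = np.pad(ranks, pad + ((0, 0),))
    mask_p = np.pad(mask, pad).astype(np.float64)
    tie_p = np.pad(tie, pad)

    sx, sy, sz = series.shape3
    r_sum = np.zeros((sx, sy, sz, n))
    k_count = np.zeros((sx, sy, sz))
    tie_sum = np.zeros((sx, sy, sz))
    for dx, dy, dz in _NEIGHBORHOOD_OFFSETS[neighborhood]:
        xs, ys, zs = slice(1 + dx, 1 + dx + sx), slice(1 + dy, 1 + dy + sy), slice(1 + dz, 1 + dz + sz)
        r_sum += ranks_p[xs, ys, zs]
        k_count += mask_p[xs, ys, zs]
        tie_sum += tie_p[xs, ys, zs]

    k = k_count
    # mean rank sum is K (n+1)/2 exactly, since each series' ranks sum to n(n+1)/2
    s = ((r_sum - (k * (n + 1) / 2.0)[..., None]) ** 2).sum(axis=3)
    denom = k**2 * (n**3 - n) - k * tie_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * s / denom, 0.0)
    w = np.clip(w, 0.0, 1.0)

    too_few = (k - 1) < min_neighbors  # neighbor count excludes the center voxel
    flags = (too_few | (denom <= 0)) & mask
    w = np.where(flags | ~mask, 0.0, w)
    return MetricMap(data=w, mask=mask, kind="reho",
                     provenance={"op": "reho_map", "neighborhood": neighborhood,
                                 "min_neighbors": min_neighbors,
                                 "tie_correction": True},
                     flags=flags)
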