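"""Cross-modality comparison layer.

Dice overlap of binary maps, voxel-wise one-sample and paired t maps with
family-wise error control (Bonferroni by default, optional sign-flip
permutation), per-network summary extraction, and across-network tests
(one-way ANOVA; Bonferroni-corrected paired t-tests per network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import MetricMap

__all__ = [
    "GroupResult",
    "dice",
    "one_sample_t",
    "paired_t",
    "fwe_threshold",
    "extract_rsn_means",
    "anova_across_rsns",
    "paired_t_by_rsn",
]

SUMMARY_COLUMNS = ["subject", "rsn", "modality", "metric", "value"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks are defined as 0 (no overlap to speak of).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / total


@dataclass
class GroupResult:
    """A group-level voxel-wise t map and its thresholded significance mask."""

    t_map: MetricMap
    df: int
    threshold: float = np.inf
    sig_mask: np.ndarray = None
    correction: str = "none"
    alpha: float = 0.05
    sided: str = "greater"  # 'greater' or 'two'
    degenerate: np.ndarray = None  # zero-variance voxels (QC)
    subject_maps: np.ndarray = field(default=None, repr=False)  # (n, x, y, z), for permutation

    def qc_table(self) -> pd.DataFrame:
        """Degenerate (zero-variance) voxels, reported rather than dropped."""
        if self.degenerate is None or not self.degenerate.any():
            return pd.DataFrame(columns=["x", "y", "z", "t"])
        idx = np.argwhere(self.degenerate)
        return pd.DataFrame({"x": idx[:, 0], "y": idx[:, 1], "z": idx[:, 2],
                             "t": self.t_map.data[self.degenerate]})


def _stack(maps: list[MetricMap | np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    arrays, mask = [], None
    for m in maps:
        if isinstance(m, MetricMap):
            arrays.append(m.data)
            mask = m.mask if mask is None else (mask & m.mask)
        else:
            arrays.append(np.asarray(m, dtype=np.float64))
    if mask is None:
        mask = np.ones(arrays[0].shape, dtype=bool)
    return np.stack(arrays), mask


def one_sample_t(maps: list[MetricMap | np.ndarray], sided: str = "greater") -> GroupResult:
    """Voxel-wise one-sample t-test of the subject maps against 0.

    t = mean / (sd / sqrt(n)), df = n - 1.  Zero-variance voxels get a
    signed-infinity sentinel (0 if the mean is also 0), are flagged, and are
    excluded from any significance mask derived later.
    """
    n = len(maps)
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if sided not in ("greater", "two"):
        raise ValueError("sided must be 'greater' or 'two'")
    stackd, mask = _stack(maps)
    mean = stackd.mean(axis=0)
    sd = stackd.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t[degenerate] = np.sign(mean[degenerate]) * np.inf
    t[degenerate & (mean == 0)] = 0.0
    tmap = MetricMap(data=t, mask=mask, kind="tstat",
                     provenance={"op": "one_sample_t", "n": n, "sided": sided},
                     flags=degenerate & mask)
    return GroupResult(t_map=tmap, df=n - 1, sided=sided,
                       degenerate=degenerate & mask, subject_maps=stackd)


def paired_t(maps_a: list[MetricMap | np.ndarray], maps_b: list[MetricMap | np.ndarray],
             sided: str = "two") -> GroupResult:
    """Voxel-wise paired t-test: one-sample t of the per-subject differences a - b."""
    if len(maps_a) != len(maps_b):
        raise ValueError(f"cohort sizes differ: {len(maps_a)} vs {len(maps_b)}")
    a, mask_a = _stack(maps_a)
    b, mask_b = _stack(maps_b)
    diffs = [MetricMap(d, mask_a & mask_b, "tstat") for d in (a - b)]
    result = one_sample_t(diffs, sided=sided)
    result.t_map.provenance["op"] = "paired_t"
    return result


def fwe_threshold(
    result: GroupResult,
    alpha: float = 0.05,
    method: str = "bonferroni",
    seed: int | None = None,
    n_permutations: int = 1000,
) -> GroupResult:
    """Family-wise error control over the in-mask voxels.

    bonferroni: per-voxel p from the t distribution with ``result.df``;
    significant iff p <= alpha / V.  permutation: max-|t| (or max-t) null
    distribution over random sign flips of the subject maps, threshold at the
    (1 - alpha) quantile; requires the subject maps and a seed.

    Degenerate voxels are never significant.
    """
    mask = result.t_map.mask
    v = int(mask.sum())
    if v < 1:
        raise ValueError("no in-mask voxels")
    t = result.t_map.data
    ok = mask & ~(result.degenerate if result.degenerate is not None else np.zeros_like(mask))
    if method == "bonferroni":
        thr = (stats.t.isf(alpha / v, result.df) if result.sided == "greater"
               else stats.t.isf(alpha / (2 * v), result.df))
        sig = ((t >= thr) if result.sided == "greater" else (np.abs(t) >= thr)) & ok
    elif method == "permutation":
        if result.subject_maps is None:
            raise ValueError("permutation FWE needs the subject maps on the GroupResult")
        if seed is None:
            raise ValueError("permutation FWE needs a seed")
        rng = np.random.default_rng(int(seed))
        data = result.subject_maps[:, mask]
        n = data.shape[0]
        null_max = np.empty(n_permutations)
        for p in range(n_permutations):
            signs = rng.choice((-1.0, 1.0), size=n)[:, None]
            flipped = data * signs
            mean = flipped.mean(axis=0)
            sd = flipped.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tp = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
            null_max[p] = tp.max() if result.sided == "greater" else np.abs(tp).max()
        thr = float(np.quantile(null_max, 1.0 - alpha))
        sig = ((t >= thr) if result.sided == "greater" else (np.abs(t) >= thr)) & ok
    else:
        raise ValueError(f"unknown FWE method {method!r}; use 'bonferroni' or 'permutation'")
    result.threshold = float(thr)
    result.sig_mask = sig
    result.correction = method
    result.alpha = alpha
    return result


def cluster_extent_filter(sig_mask: np.ndarray, k_min: int) -> np.ndarray:
    """Optional post-filter: drop connected components smaller than ``k_min`` voxels."""
    from scipy import ndimage
    labels, n = ndimage.label(sig_mask)
    if n == 0:
        return sig_mask.copy()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= k_min) + 1
    return np.isin(labels, keep)


def extract_rsn_means(
    metric_maps: dict[tuple[str, str, str], MetricMap | np.ndarray],
    rsn_masks: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-(subject, RSN, modality, metric) in-mask mean values.

    ``metric_maps`` is keyed by (subject, modality, metric).  Returns a tidy
    table with the fixed column order (subject, rsn, modality, metric, value).
    """
    for name, m in rsn_masks.items():
        if not np.asarray(m).any():
            raise ValueError(f"RSN mask {name!r} is empty")
    rows = []
    for (subject, modality, metric), mm in metric_maps.items():
        data = mm.data if isinstance(mm, MetricMap) else np.asarray(mm, dtype=np.float64)
        for rsn, m in rsn_masks.items():
            m = np.asarray(m).astype(bool)
            if m.shape != data.shape:
                raise ValueError(f"RSN mask {rsn!r} grid does not match map grid")
            rows.append((subject, rsn, modality, metric, float(data[m].mean())))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def anova_across_rsns(summary: pd.DataFrame, metric: str,
                      modality: str | None = None) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of subject-level means across RSN groups.

    Returns (F, (df_between, df_within), p).
    """
    sub = summary[summary["metric"] == metric]
    if modality is not None:
        sub = sub[sub["modality"] == modality]
    groups = [g["value"].to_numpy() for _, g in sub.groupby("rsn")]
    if len(groups) < 2:
        raise ValueError("need at least 2 RSN groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every RSN group needs at least 2 observations")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    return float(f), (k - 1, n_total - k), float(p)


def paired_t_by_rsn(summary: pd.DataFrame, metric: str, modality_a: str,
                    modality_b: str, alpha: float = 0.05) -> pd.DataFrame:
    """Per-RSN paired t-tests between two modalities, Bonferroni-corrected
    across the RSNs."""
    sub = summary[summary["metric"] == metric]
    rsns = sorted(sub["rsn"].unique())
    rows = []
    for rsn in rsns:
        block = sub[sub["rsn"] == rsn].pivot(index="subject", columns="modality", values="value")
        a = block[modality_a].to_numpy()
        b = block[modality_b].to_numpy()
        t, p = stats.ttest_rel(a, b)
        rows.append((rsn, float(np.mean(a - b)), float(t), a.size - 1, float(p)))
    out = pd.DataFrame(rows, columns=["rsn", "mean_diff", "t", "df", "p"])
    out["p_bonferroni"] = np.minimum(out["p"] * len(rsns), 1.0)
    out["significant"] = out["p_bonferroni"] <= alpha
    return out
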