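"""Group spatial ICA by temporal concatenation, with template matching.

Subject series are variance-normalized per voxel, stacked along time, and
decomposed into spatially independent components by FastICA (fixed-point
iteration, logcosh contrast, deflation) after internal whitening to exactly
``n_components`` dimensions.  Component maps are z-scored over in-mask
voxels, sign-fixed so each map's skewness is non-negative, and thresholded
at z >= 1 to form binary network masks.  Template matching replaces the
visual component selection of the classic workflow: a greedy one-to-one
assignment by spatial correlation labels the best-matching components as
networks and the rest as noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .grids import FuncSeries

__all__ = [
    "RSNSet",
    "ComponentMatch",
    "concatenate_temporal",
    "group_ica",
    "match_components",
    "ICAConvergenceError",
]


class ICAConvergenceError(RuntimeError):
    """FastICA failed to converge after the configured number of restarts."""


@dataclass
class RSNSet:
    """An ordered set of spatial components from one group ICA run."""

    spatial_maps: np.ndarray   # (C, V) raw loadings over in-mask voxels
    z_maps: np.ndarray         # (C, V) standardized maps (mean 0, sd 1 in-mask)
    masks: np.ndarray          # (C, V) boolean, z_map >= threshold_z
    timecourses: np.ndarray    # (T_total, C) mixing series
    mask: np.ndarray           # 3-D brain mask the V columns index into
    voxel_index: np.ndarray    # (V,) linear C-order indices of in-mask voxels
    n_components: int = 0
    threshold_z: float = 1.0
    seed: int = 0
    converged: bool = True
    restarts_used: int = 0

    def z_map_3d(self, c: int) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out.ravel()[self.voxel_index] = self.z_maps[c]
        return out

    def mask_3d(self, c: int) -> np.ndarray:
        out = np.zeros(self.mask.shape, dtype=bool)
        out.ravel()[self.voxel_index] = self.masks[c]
        return out


def concatenate_temporal(series_list: list[FuncSeries], mask: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Stack subjects along time into a (total time x in-mask voxels) matrix.

    Each subject's voxel series are demeaned and variance-normalized before
    stacking (zero-variance voxels are left at 0).  Returns the matrix and
    the linear C-order voxel index recording column order.
    """
    if not series_list:
        raise ValueError("need at least one series")
    mask = np.asarray(mask).astype(bool)
    voxel_index = np.flatnonzero(mask.ravel())
    blocks = []
    for i, series in enumerate(series_list):
        if series.shape3 != mask.shape:
            raise ValueError(f"series {i} grid {series.shape3} does not match the mask grid {mask.shape}")
        flat = series.data.reshape(-1, series.n_volumes)[voxel_index].T  # (t, v)
        flat = flat - flat.mean(axis=0)
        sd = flat.std(axis=0)
        nz = sd > 0
        flat[:, nz] /= sd[nz]
        blocks.append(flat)
    return np.vstack(blocks), voxel_index


def group_ica(
    data: np.ndarray,
    mask: np.ndarray,
    voxel_index: np.ndarray,
    n_components: int = 20,
    seed: int = 0,
    threshold_z: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-4,
    max_restarts: int = 5,
) -> RSNSet:
    """Spatial ICA of a (time x voxels) matrix into ``n_components`` maps.

    Deterministic for a given seed.  On non-convergence the decomposition is
    restarted with seeds derived from ``seed``; exhausting the restarts
    raises :class:`ICAConvergenceError` with diagnostics.
    """
    data = np.asarray(data, dtype=np.float64)
    if n_components > min(data.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(data shape)={min(data.shape)}"
        )
    attempt_seeds = [int(s) & 0x7FFFFFFF
                     for s in np.random.SeedSequence(int(seed)).generate_state(max_restarts + 1)]
    last_warning = None
    for attempt, attempt_seed in enumerate(attempt_seeds):
        ica = FastICA(
            n_components=n_components,
            algorithm="deflation",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=attempt_seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(data.T).T  # (C, V): spatially independent maps
        conv_warnings = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
        if not conv_warnings:
            break
        last_warning = conv_warnings[-1]
    else:
        raise ICAConvergenceError(
            f"FastICA did not converge in {max_iter} iterations after "
            f"{max_restarts + 1} attempts (tol={tol}); last warning: {last_warning.message}"
        )

    timecourses = ica.mixing_  # (T, C)
    # z-score over in-mask voxels; fix sign so spatial skewness >= 0
    z = sources - sources.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    flip = skew(z, axis=1) < 0
    z[flip] *= -1.0
    sources = sources.copy()
    sources[flip] *= -1.0
    timecourses = timecourses.copy()
    timecourses[:, flip] *= -1.0

    return RSNSet(
        spatial_maps=sources,
        z_maps=z,
        masks=z >= threshold_z,
        timecourses=timecourses,
        mask=np.asarray(mask).astype(bool),
        voxel_index=np.asarray(voxel_index),
        n_components=n_components,
        threshold_z=threshold_z,
        seed=int(seed),
        converged=True,
        restarts_used=attempt,
    )


@dataclass
class ComponentMatch:
    """Greedy one-to-one assignment of templates to components."""

    assignment: dict[int, int] = field(default_factory=dict)  # template index -> component index
    scores: dict[int, float] = field(default_factory=dict)    # template index -> spatial correlation
    noise_components: list[int] = field(default_factory=list)


def _template_vector(template: np.ndarray, mask: np.ndarray, voxel_index: np.ndarray) -> np.ndarray:
    template = np.asarray(template)
    if template.shape != mask.shape:
        raise ValueError("template grid does not match the analysis mask grid")
    return template.astype(np.float64).ravel()[voxel_index]


def match_components(rsns: RSNSet, templates: list[np.ndarray]) -> ComponentMatch:
    """Assign each template to its best-correlated component, one-to-one.

    Greedy on the spatial correlation between z-maps and template maps; ties
    are broken by template order, then component index.  Components left
    unassigned are labeled noise.
    """
    c = rsns.z_maps.shape[0]
    if len(templates) > c:
        raise ValueError(f"{len(templates)} templates but only {c} components")
    if not templates:
        return ComponentMatch(noise_components=list(range(c)))

    tvecs = np.array([_template_vector(t, rsns.mask, rsns.voxel_index) for t in templates])
    corr = np.zeros((len(templates), c))
    for i, tv in enumerate(tvecs):
        tc = tv - tv.mean()
        tn = np.sqrt(tc @ tc)
        for j in range(c):
            zc = rsns.z_maps[j] - rsns.z_maps[j].mean()
            zn = np.sqrt(zc @ zc)
            corr[i, j] = (tc @ zc) / (tn * zn) if tn > 0 and zn > 0 else 0.0

    match = ComponentMatch()
    free_t = list(range(len(templates)))
    free_c = list(range(c))
    while free_t:
        best = None  # (score, template order, component index)
        for i in free_t:
            for j in free_c:
                key = (-corr[i, j], i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        match.assignment[i] = j
        match.scores[i] = float(corr[i, j])
        free_t.remove(i)
        free_c.remove(j)
    match.noise_components = sorted(free_c)
    return match
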