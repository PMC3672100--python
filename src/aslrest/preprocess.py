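"""Temporal/spatial cleaning chain applied before metric computation.

Default order (recorded in provenance): Gaussian smoothing (4 mm FWHM) ->
linear detrend -> ideal band-pass (0.01-0.08 Hz) -> nuisance regression
(6 motion parameters, global mean, white-matter mean, CSF mean).  The
band-pass is an exact rectangular frequency-domain filter, matching the
classic resting-state toolchain and making every stage testable in closed
form.  When the target series has been band-passed, the nuisance regressors
are band-passed with the same filter before regression, so the cleanup cannot
reintroduce out-of-band variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import FuncSeries

__all__ = [
    "NuisanceSet",
    "MotionCheck",
    "check_motion",
    "smooth_gaussian",
    "detrend_linear",
    "bandpass",
    "regress_nuisance",
    "extract_mean_timeseries",
    "preprocess_chain",
]

DEFAULT_ORDER = ("smooth", "detrend", "bandpass", "nuisance")


@dataclass
class NuisanceSet:
    """Nuisance regressors: 6 motion parameters + global/WM/CSF mean signals."""

    motion: np.ndarray  # (n, 6)
    global_mean: np.ndarray
    wm_mean: np.ndarray
    csf_mean: np.ndarray

    NAMES = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
             "global", "wm", "csf")

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, dtype=np.float64))
        if self.motion.shape[1] != 6:
            raise ValueError("motion must have 6 columns")
        n = self.motion.shape[0]
        for name in ("global_mean", "wm_mean", "csf_mean"):
            v = np.asarray(getattr(self, name), dtype=np.float64).ravel()
            if v.size != n:
                raise ValueError(f"{name} length {v.size} != motion length {n}")
            setattr(self, name, v)

    def design_columns(self) -> np.ndarray:
        """Regressors as an (n, 9) matrix, ordered as ``NAMES``."""
        return np.column_stack([self.motion, self.global_mean, self.wm_mean, self.csf_mean])


@dataclass
class MotionCheck:
    passed: bool
    offending_volumes: np.ndarray
    max_translation_mm: float
    max_rotation_deg: float


def check_motion(motion_trace: np.ndarray, max_trans_mm: float = 2.0,
                 max_rot_deg: float = 2.0) -> MotionCheck:
    """Apply the head-motion exclusion rule: fail iff any translation
    *exceeds* ``max_trans_mm`` or any rotation *exceeds* ``max_rot_deg``
    in absolute value (strict inequality; boundary values pass)."""
    trace = np.atleast_2d(np.asarray(motion_trace, dtype=np.float64))
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got shape {trace.shape}")
    if not np.all(np.isfinite(trace)):
        raise ValueError("motion trace contains non-finite values")
    bad = (np.abs(trace[:, :3]) > max_trans_mm).any(axis=1) | \
          (np.abs(trace[:, 3:]) > max_rot_deg).any(axis=1)
    return MotionCheck(
        passed=not bad.any(),
        offending_volumes=np.flatnonzero(bad),
        max_translation_mm=float(np.abs(trace[:, :3]).max()),
        max_rotation_deg=float(np.abs(trace[:, 3:]).max()),
    )


def smooth_gaussian(series: FuncSeries, fwhm_mm: float = 4.0) -> FuncSeries:
    """Volume-wise isotropic 3-D Gaussian smoothing.

    sigma per axis = fwhm / (2*sqrt(2*ln 2)), converted from mm to voxels by
    the grid's voxel size.  fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return series.copy_with(series.data)
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / series.voxel_size_mm
    out = ndimage.gaussian_filter(series.data, sigma=tuple(sigma_vox) + (0.0,),
                                  mode="nearest", truncate=4.0)
    return series.copy_with(out)


def detrend_linear(series: FuncSeries) -> FuncSeries:
    """Remove the per-voxel OLS linear trend; the voxel mean is retained."""
    n = series.n_volumes
    if n < 3:
        raise ValueError(f"need at least 3 time points to detrend, got {n}")
    t = np.arange(n, dtype=np.float64)
    tc = t - t.mean()
    flat = series.data.reshape(-1, n)
    slope = (flat @ tc) / (tc @ tc)
    out = flat - slope[:, None] * tc
    return series.copy_with(out.reshape(series.data.shape))


def _band_keep(n: int, tr_s: float, low_hz: float, high_hz: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, tr_s)
    return (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12) & (freqs > 0)


def bandpass(series: FuncSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> FuncSeries:
    """Ideal rectangular band-pass: zero every FFT bin outside [low, high].

    Band edges are inclusive; the DC component is always removed, so the
    output is zero-mean per voxel.
    """
    nyq = series.nyquist_hz
    if high_hz > nyq + 1e-12:
        raise ValueError(
            f"band upper edge {high_hz} Hz exceeds the Nyquist frequency {nyq:.6g} Hz "
            f"(TR {series.tr_s} s)"
        )
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low_hz < high_hz, got ({low_hz}, {high_hz})")
    n = series.n_volumes
    keep = _band_keep(n, series.tr_s, low_hz, high_hz)
    if not keep.any():
        freqs = np.fft.rfftfreq(n, series.tr_s)
        raise ValueError(
            f"no FFT bins inside band ({low_hz}, {high_hz}) Hz; bin spacing is "
            f"{freqs[1]:.6g} Hz over {n} volumes"
        )
    spec = np.fft.rfft(series.data, axis=3)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=3)
    return series.copy_with(out)


def bandpass_vector(x: np.ndarray, tr_s: float, low_hz: float = 0.01,
                    high_hz: float = 0.08) -> np.ndarray:
    """Apply the same ideal band-pass to 1-D regressor(s), time on axis 0."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    keep = _band_keep(n, tr_s, low_hz, high_hz)
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def regress_nuisance(series: FuncSeries, nuisance: NuisanceSet) -> FuncSeries:
    """Regress out the nuisance set per voxel; residuals + intercept returned.

    Constant (zero-variance) regressor columns are dropped.  A rank-deficient
    design after cleanup is rejected, naming the collinear columns.
    """
    n = series.n_volumes
    cols = nuisance.design_columns()
    if cols.shape[0] != n:
        raise ValueError(f"nuisance length {cols.shape[0]} != series length {n}")
    keep = np.ptp(cols, axis=0) > 0
    names = [nm for nm, k in zip(NuisanceSet.NAMES, keep) if k]
    x = np.column_stack([np.ones(n), cols[:, keep]])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(1, x.shape[1]):
            xr = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(xr) == np.linalg.matrix_rank(x):
                collinear.append(names[j - 1])
        raise ValueError(f"nuisance design is rank deficient; collinear columns: {collinear}")
    if x.shape[1] == 1:  # every regressor was constant and dropped
        return series.copy_with(series.data)
    flat = series.data.reshape(-1, n)
    beta, *_ = np.linalg.lstsq(x, flat.T, rcond=None)
    resid = flat.T - x @ beta
    out = (resid + beta[0]).T.reshape(series.data.shape)
    return series.copy_with(out)


def extract_mean_timeseries(series: FuncSeries, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over in-mask voxels, per volume."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.shape3:
        raise ValueError("mask grid does not match the series grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return series.data[mask].mean(axis=0)


def preprocess_chain(
    series: FuncSeries,
    motion: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    fwhm_mm: float = 4.0,
    band_hz: tuple[float, float] = (0.01, 0.08),
    order: tuple[str, ...] = DEFAULT_ORDER,
) -> tuple[FuncSeries, list[dict]]:
    """Run the cleaning chain in ``order``; returns (series, provenance log).

    The nuisance stage extracts global/WM/CSF mean signals from the series at
    that point in the chain (hence already band-passed when band-pass precedes
    it) and band-passes the motion regressors to match.
    """
    valid = {"smooth", "detrend", "bandpass", "nuisance"}
    unknown = set(order) - valid
    if unknown:
        raise ValueError(f"unknown chain stages: {sorted(unknown)}")
    out = series
    provenance: list[dict] = []
    bandpassed = False
    for stage in order:
        if stage == "smooth":
            out = smooth_gaussian(out, fwhm_mm)
            provenance.append({"stage": "smooth", "fwhm_mm": fwhm_mm})
        elif stage == "detrend":
            out = detrend_linear(out)
            provenance.append({"stage": "detrend"})
        elif stage == "bandpass":
            out = bandpass(out, *band_hz)
            bandpassed = True
            provenance.append({"stage": "bandpass", "band_hz": list(band_hz)})
        elif stage == "nuisance":
            if motion is None or brain_mask is None:
                provenance.append({"stage": "nuisance", "skipped": "no regressors supplied"})
                continue
            mot = np.asarray(motion, dtype=np.float64)
            if bandpassed:
                mot = bandpass_vector(mot, out.tr_s, *band_hz)
            nuis = NuisanceSet(
                motion=mot,
                global_mean=extract_mean_timeseries(out, brain_mask),
                wm_mean=extract_mean_timeseries(out, wm_mask)
                if wm_mask is not None and wm_mask.any() else np.zeros(out.n_volumes),
                csf_mean=extract_mean_timeseries(out, csf_mask)
                if csf_mask is not None and csf_mask.any() else np.zeros(out.n_volumes),
            )
            out = regress_nuisance(out, nuis)
            provenance.append({"stage": "nuisance",
                               "regressors": list(NuisanceSet.NAMES),
                               "motion_bandpassed": bandpassed})
    return out, provenance
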