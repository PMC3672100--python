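"""Core data containers: 4-D functional series, ASL series, and 3-D metric maps.

All grids live on a single voxel lattice with a grid-to-world affine in mm
(NIfTI convention).  nibabel handles serialization; these classes only add the
timing/paradigm metadata the analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FuncSeries",
    "ASLSeries",
    "MetricMap",
    "load_series",
    "load_mask",
    "save_mask",
]

#: Metric kinds a MetricMap may carry.
METRIC_KINDS = ("fc_r", "fc_z", "alff", "reho", "cbf", "tstat", "deltam")


@dataclass
class FuncSeries:
    """A 4-D functional MRI series (x, y, z, t).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Voxel signal values.
    affine : ndarray, shape (4, 4)
        Grid-to-world affine, mm.
    tr_s : float
        Repetition time in seconds (temporal sampling interval).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"series must be 4-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each volume, seconds from the first volume."""
        return np.arange(self.n_volumes) * self.tr_s

    def copy_with(self, data: np.ndarray) -> "FuncSeries":
        return FuncSeries(data=np.array(data, dtype=np.float64), affine=self.affine.copy(), tr_s=self.tr_s)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = tuple(self.voxel_size_mm) + (self.tr_s,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FuncSeries":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        if data.ndim == 3:
            data = data[..., None]
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
        return cls(data=data, affine=np.asarray(img.affine), tr_s=tr)


def load_series(path: str | Path) -> FuncSeries:
    return FuncSeries.load(path)


@dataclass
class ASLSeries:
    """An interleaved label/control ASL series plus its paradigm and timing.

    ``paradigm`` holds one value in {-1, +1} per volume and must strictly
    alternate.  ``control_value`` records which sign marks control volumes
    (generator metadata; the convention is often left implicit).
    """

    series: FuncSeries
    paradigm: np.ndarray
    labeling_time_s: float = 1.77
    post_label_delay_s: float = 1.0
    control_value: int = 1

    def __post_init__(self) -> None:
        self.paradigm = np.asarray(self.paradigm, dtype=np.int64).ravel()
        if self.paradigm.size != self.series.n_volumes:
            raise ValueError(
                f"paradigm length {self.paradigm.size} != number of volumes {self.series.n_volumes}"
            )
        if not np.all(np.isin(self.paradigm, (-1, 1))):
            raise ValueError("paradigm values must be in {-1, +1}")
        if self.paradigm.size >= 2 and not np.all(self.paradigm[1:] == -self.paradigm[:-1]):
            raise ValueError("paradigm must strictly alternate between -1 and +1")
        if not (self.labeling_time_s > 0 and self.post_label_delay_s > 0):
            raise ValueError("labeling_time_s and post_label_delay_s must be positive")
        if self.control_value not in (-1, 1):
            raise ValueError("control_value must be -1 or +1")

    @property
    def n_pairs(self) -> int:
        return self.series.n_volumes // 2

    def control_index(self) -> np.ndarray:
        return np.flatnonzero(self.paradigm == self.control_value)

    def label_index(self) -> np.ndarray:
        return np.flatnonzero(self.paradigm == -self.control_value)


@dataclass
class MetricMap:
    """A 3-D scalar map (one value per in-mask voxel) with provenance.

    ``flags`` marks voxels whose value is degenerate (constant series, m0<=0,
    too few neighbors ...); flagged voxels carry a defined sentinel value but
    should be excluded from inference.
    """

    data: np.ndarray
    mask: np.ndarray
    kind: str
    band_hz: tuple[float, float] | None = None
    provenance: dict = field(default_factory=dict)
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("metric map must be 3-D")
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}; expected one of {METRIC_KINDS}")
        if self.flags is not None:
            self.flags = np.asarray(self.flags).astype(bool)
            if self.flags.shape != self.data.shape:
                raise ValueError("flags shape must match data shape")

    def in_mask(self) -> np.ndarray:
        """Values at in-mask voxels, as a flat vector (C order)."""
        return self.data[self.mask]

    def save(self, path: str | Path, affine: np.ndarray) -> Path:
        path = Path(path)
        out = np.where(self.mask, self.data, 0.0)
        nib.save(nib.Nifti1Image(out.astype(np.float32), np.asarray(affine)), str(path))
        return path


def save_mask(mask: np.ndarray, path: str | Path, affine: np.ndarray) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), np.asarray(affine))
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5
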