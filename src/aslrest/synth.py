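"""Synthetic paired cvBOLD / ASL resting-state data with known ground truth.

The generator emulates the acquisition the analyses assume: a conventional
BOLD EPI series (default 360 volumes at TR 0.9 s) and an interleaved pCASL
label/control series (default 60 volumes at TR 4 s) on one shared 3 mm grid.
Voxel signal is built additively from

* a tissue baseline (M0-like level inside the brain),
* band-limited (0.01-0.08 Hz) network time courses planted in binary spatial
  maps, shared between the two modalities and resampled at each TR,
* a +/- labeling modulation on the ASL series whose amplitude is the forward
  perfusion difference implied by a known CBF map under the same pCASL model
  the quantification inverts (round-trip consistency by construction),
* a per-voxel linear scanner drift, and
* white Gaussian thermal noise.

Motion parameter traces are emitted but not applied as spatial displacement:
realignment is out of scope, and the generator stays honest about it — the
motion exclusion rule is still exercised downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .asl import QuantificationConstants, deltam_from_cbf
from .grids import ASLSeries, FuncSeries, load_mask, save_mask

__all__ = [
    "AcquisitionSpec",
    "GeneratorConfig",
    "GroundTruth",
    "SubjectData",
    "BandlimitedTimecourse",
    "default_affine",
    "tissue_masks",
    "generate_subject",
    "generate_cohort",
    "write_subject",
    "read_subject",
]

#: World coordinate (mm) of the posterior cingulate seed used by the
#: connectivity analysis.  The affine is chosen so this point falls on the
#: gray-matter rind of the synthetic brain (not its white-matter/CSF core).
PCC_WORLD = np.array([0.0, -50.0, 31.0])

#: Normalized ellipsoid position (fraction of the semi-axis, y direction)
#: where the PCC anchor sits; 0.8 is mid-rind of the GM shell.
_PCC_ANCHOR_FRACTION = 0.8


def _semi_axes_mm(grid_shape, voxel_size_mm) -> np.ndarray:
    return 0.46 * np.asarray(grid_shape, dtype=np.float64) * np.asarray(voxel_size_mm, dtype=np.float64)


def grid_center_world(grid_shape, voxel_size_mm) -> np.ndarray:
    """World coordinate of the grid center, anchored so PCC_WORLD is in GM."""
    semi = _semi_axes_mm(grid_shape, voxel_size_mm)
    return PCC_WORLD - np.array([0.0, _PCC_ANCHOR_FRACTION * semi[1], 0.0])


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and timing of one functional acquisition."""

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 0.9
    n_volumes: int = 360
    modality: str = "cvBOLD"

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive reals")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be positive")
        if self.modality not in ("cvBOLD", "ASL"):
            raise ValueError("modality must be 'cvBOLD' or 'ASL'")
        if self.modality == "ASL" and self.n_volumes % 2 != 0:
            raise ValueError("ASL acquisitions need an even number of volumes (label/control pairs)")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)


def default_cvbold_spec(grid_shape=(24, 24, 12), voxel_mm=3.0) -> AcquisitionSpec:
    return AcquisitionSpec(tuple(grid_shape), (voxel_mm,) * 3, tr_s=0.9, n_volumes=360,
                           modality="cvBOLD")


def default_asl_spec(grid_shape=(24, 24, 12), voxel_mm=3.0) -> AcquisitionSpec:
    return AcquisitionSpec(tuple(grid_shape), (voxel_mm,) * 3, tr_s=4.0, n_volumes=60,
                           modality="ASL")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Amplitudes are in raw signal units on a brain baseline of ``baseline``;
    with the defaults the network fluctuation is a 2% signal change on the
    conventional BOLD series and a weaker 1.2% on the shorter-TE ASL series,
    thermal noise gives temporal SNR 50 (cvBOLD) and 100 (smoothed-EPI-like
    ASL), and CBF sits at 60/20/12 ml/100g/min in GM/WM/CSF with 5 ml/100g/min
    between-subject spread of the GM level.
    """

    n_networks: int = 3
    baseline: float = 1000.0
    network_amp_cv: float = 20.0
    network_amp_asl: float = 12.0
    noise_sd_cv: float = 20.0
    noise_sd_asl: float = 10.0
    drift_sd_per_s: float = 0.01
    band_hz: tuple[float, float] = (0.01, 0.08)
    gm_cbf: float = 60.0
    wm_cbf: float = 20.0
    csf_cbf: float = 12.0
    between_subject_cbf_sd: float = 5.0
    network_cbf_offset: float = 0.0
    motion_step_mm: float = 0.01
    motion_step_deg: float = 0.01
    constants: QuantificationConstants = field(default_factory=QuantificationConstants)
    labeling_time_s: float = 1.77
    post_label_delay_s: float = 1.0


@dataclass
class GroundTruth:
    """Everything a recovery test needs: what was planted and how."""

    network_maps: list[np.ndarray]
    network_timecourses_cv: np.ndarray  # (K, T_cv)
    network_timecourses_asl: np.ndarray  # (K, T_asl)
    cbf_true: np.ndarray
    drift_slope_cv: np.ndarray
    drift_slope_asl: np.ndarray
    noise_sd_cv: float
    noise_sd_asl: float
    motion_trace_cv: np.ndarray  # (T_cv, 6): 3 translations mm, 3 rotations deg
    motion_trace_asl: np.ndarray
    band_hz: tuple[float, float] = (0.01, 0.08)


@dataclass
class SubjectData:
    cvbold: FuncSeries
    asl: ASLSeries
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    truth: GroundTruth
    subject_id: str = "sub-000"
    rng_seed: int = 0
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry

def default_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    """Axis-aligned affine anchoring the grid so PCC_WORLD lies on the GM rind."""
    voxel = np.asarray(voxel_size_mm, dtype=np.float64)
    affine = np.diag(np.append(voxel, 1.0))
    center_vox = (np.asarray(grid_shape) - 1) / 2.0
    affine[:3, 3] = grid_center_world(grid_shape, voxel_size_mm) - center_vox * voxel
    return affine


def _normalized_radius(grid_shape) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=np.float64)
    center = (np.asarray(grid_shape, dtype=np.float64) - 1) / 2.0
    semi = 0.46 * np.asarray(grid_shape, dtype=np.float64)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2


def tissue_masks(grid_shape) -> dict[str, np.ndarray]:
    """Ellipsoidal brain with a concentric CSF core, WM shell, and GM rind.

    The three tissue masks are mutually disjoint and partition the brain mask.
    """
    r2 = _normalized_radius(grid_shape)
    brain = r2 <= 1.0
    csf = r2 <= 0.12
    wm = (r2 > 0.12) & (r2 <= 0.45)
    gm = (r2 > 0.45) & brain
    return {"brain": brain, "gm": gm, "wm": wm, "csf": csf}


def sphere_mask(grid_shape, affine, center_world, radius_mm) -> np.ndarray:
    idx = np.indices(grid_shape).reshape(3, -1)
    world = (affine[:3, :3] @ idx) + affine[:3, 3:4]
    d2 = ((world - np.asarray(center_world).reshape(3, 1)) ** 2).sum(axis=0)
    return (d2 <= radius_mm**2 + 1e-9).reshape(grid_shape)


def _network_blob_specs(n_networks: int, grid_shape, voxel_size_mm) -> list[list[tuple[np.ndarray, float]]]:
    """Blob centers (world mm) and radii per network.

    Network 0 is DMN-like: a posterior blob on the PCC seed coordinate plus a
    midline blob mirrored across the brain center (both on the GM rind).
    Further networks are single blobs staggered around the mid-surface of the
    brain ellipsoid.
    """
    semi_mm = _semi_axes_mm(grid_shape, voxel_size_mm)
    center = grid_center_world(grid_shape, voxel_size_mm)
    specs: list[list[tuple[np.ndarray, float]]] = []
    for k in range(n_networks):
        if k == 0:
            specs.append([
                (PCC_WORLD.copy(), 9.0),
                (center - np.array([0.0, _PCC_ANCHOR_FRACTION * semi_mm[1], 0.0]), 7.5),
            ])
        else:
            theta = 2.0 * np.pi * (k - 1) / 11.0 + 0.4
            z = 0.3 * semi_mm[2] * (1 if k % 2 else -1)
            blob = center + np.array(
                [0.75 * semi_mm[0] * np.cos(theta), 0.75 * semi_mm[1] * np.sin(theta), z]
            )
            specs.append([(blob, 7.5)])
    return specs


def network_maps(n_networks: int, grid_shape, voxel_size_mm, affine,
                 brain_mask: np.ndarray) -> list[np.ndarray]:
    maps = []
    for blobs in _network_blob_specs(n_networks, grid_shape, voxel_size_mm):
        m = np.zeros(grid_shape, dtype=bool)
        for center, radius in blobs:
            m |= sphere_mask(grid_shape, affine, center, radius)
        maps.append(m & brain_mask)
    return maps


# ---------------------------------------------------------------------------
# temporal structure

class BandlimitedTimecourse:
    """A zero-mean random time course with all power strictly inside a band.

    Synthesized as a finite sum of sinusoids on the in-band FFT bins of a
    reference sampling grid (random Gaussian quadrature amplitudes, i.e.
    uniform random phases), normalized to unit expected variance.  Because it
    is an explicit Fourier sum it can be sampled exactly on any time grid —
    the same underlying fluctuation drives both modalities.
    """

    def __init__(self, rng: np.random.Generator, n_ref: int, tr_ref_s: float,
                 band_hz: tuple[float, float]):
        low, high = band_hz
        nyq = 1.0 / (2.0 * tr_ref_s)
        if high > nyq + 1e-12:
            raise ValueError(
                f"band upper edge {high} Hz exceeds the Nyquist frequency {nyq:.6g} Hz "
                f"of the reference grid (TR {tr_ref_s} s)"
            )
        freqs = np.fft.rfftfreq(n_ref, tr_ref_s)
        sel = (freqs >= low - 1e-12) & (freqs <= high + 1e-12) & (freqs > 0)
        if not sel.any():
            raise ValueError(f"no FFT bins inside band {band_hz} on the reference grid")
        self.freqs = freqs[sel]
        self.a = rng.standard_normal(self.freqs.size)
        self.b = rng.standard_normal(self.freqs.size)
        norm = np.sqrt(0.5 * (self.a**2 + self.b**2).sum())
        self.a /= norm
        self.b /= norm

    def sample(self, times_s: np.ndarray) -> np.ndarray:
        phase = 2.0 * np.pi * np.outer(times_s, self.freqs)
        return np.cos(phase) @ self.a + np.sin(phase) @ self.b


# ---------------------------------------------------------------------------
# generation

def _motion_trace(rng: np.random.Generator, n: int, step_mm: float,
                  step_deg: float) -> np.ndarray:
    steps = rng.standard_normal((n, 6)) * np.array([step_mm] * 3 + [step_deg] * 3)
    trace = np.cumsum(steps, axis=0)
    return trace - trace[0]


def generate_subject(
    spec_cv: AcquisitionSpec = None,
    spec_asl: AcquisitionSpec = None,
    design: GeneratorConfig = None,
    seed: int = 0,
    subject_id: str = "sub-000",
) -> SubjectData:
    """Generate one subject's paired cvBOLD + ASL dataset with ground truth.

    Identical (specs, design, seed) yield bit-identical output.
    """
    spec_cv = spec_cv or default_cvbold_spec()
    spec_asl = spec_asl or default_asl_spec()
    design = design or GeneratorConfig()
    if spec_cv.grid_shape != spec_asl.grid_shape or spec_cv.voxel_size_mm != spec_asl.voxel_size_mm:
        raise ValueError("cvBOLD and ASL acquisitions must share one grid")
    for spec in (spec_cv, spec_asl):
        if design.n_networks > 0 and design.band_hz[1] > spec.nyquist_hz + 1e-12:
            raise ValueError(
                f"network band {design.band_hz} Hz exceeds Nyquist {spec.nyquist_hz:.6g} Hz "
                f"of the {spec.modality} acquisition (TR {spec.tr_s} s)"
            )

    rng = np.random.default_rng(int(seed))
    shape = spec_cv.grid_shape
    affine = default_affine(shape, spec_cv.voxel_size_mm)
    masks = tissue_masks(shape)
    brain = masks["brain"]

    nets = network_maps(design.n_networks, shape, spec_cv.voxel_size_mm, affine, brain)

    t_cv = np.arange(spec_cv.n_volumes) * spec_cv.tr_s
    t_asl = np.arange(spec_asl.n_volumes) * spec_asl.tr_s
    tcs = [BandlimitedTimecourse(rng, spec_cv.n_volumes, spec_cv.tr_s, design.band_hz)
           for _ in range(design.n_networks)]
    tc_cv = np.array([tc.sample(t_cv) for tc in tcs]).reshape(design.n_networks, spec_cv.n_volumes)
    tc_asl = np.array([tc.sample(t_asl) for tc in tcs]).reshape(design.n_networks, spec_asl.n_volumes)

    # true CBF map: tissue plateaus plus an optional network contrast
    cbf_true = np.zeros(shape)
    cbf_true[masks["gm"]] = design.gm_cbf
    cbf_true[masks["wm"]] = design.wm_cbf
    cbf_true[masks["csf"]] = design.csf_cbf
    for m in nets:
        cbf_true[m & brain] += design.network_cbf_offset
    cbf_true = np.clip(cbf_true, 0.0, None)

    baseline = np.where(brain, design.baseline, 0.0)

    drift_cv = rng.standard_normal(shape) * design.drift_sd_per_s
    drift_asl = rng.standard_normal(shape) * design.drift_sd_per_s

    # conventional BOLD series
    cv = np.empty(shape + (spec_cv.n_volumes,))
    cv[:] = baseline[..., None]
    for m, tc in zip(nets, tc_cv):
        cv[m] += design.network_amp_cv * tc
    cv += drift_cv[..., None] * t_cv
    if design.noise_sd_cv > 0:
        cv += rng.standard_normal(cv.shape) * design.noise_sd_cv

    # ASL series: BOLD-like term + labeling modulation encoding cbf_true
    paradigm = np.tile([-1, 1], spec_asl.n_volumes // 2)  # first volume is label
    deltam = deltam_from_cbf(cbf_true, baseline, design.constants,
                             design.labeling_time_s, design.post_label_delay_s)
    aslvol = np.empty(shape + (spec_asl.n_volumes,))
    aslvol[:] = baseline[..., None]
    for m, tc in zip(nets, tc_asl):
        aslvol[m] += design.network_amp_asl * tc
    aslvol += 0.5 * deltam[..., None] * paradigm
    aslvol += drift_asl[..., None] * t_asl
    if design.noise_sd_asl > 0:
        aslvol += rng.standard_normal(aslvol.shape) * design.noise_sd_asl

    motion_cv = _motion_trace(rng, spec_cv.n_volumes, design.motion_step_mm, design.motion_step_deg)
    motion_asl = _motion_trace(rng, spec_asl.n_volumes, design.motion_step_mm, design.motion_step_deg)

    truth = GroundTruth(
        network_maps=nets,
        network_timecourses_cv=tc_cv,
        network_timecourses_asl=tc_asl,
        cbf_true=cbf_true,
        drift_slope_cv=drift_cv,
        drift_slope_asl=drift_asl,
        noise_sd_cv=design.noise_sd_cv,
        noise_sd_asl=design.noise_sd_asl,
        motion_trace_cv=motion_cv,
        motion_trace_asl=motion_asl,
        band_hz=tuple(design.band_hz),
    )
    return SubjectData(
        cvbold=FuncSeries(cv, affine, spec_cv.tr_s),
        asl=ASLSeries(
            series=FuncSeries(aslvol, affine, spec_asl.tr_s),
            paradigm=paradigm,
            labeling_time_s=design.labeling_time_s,
            post_label_delay_s=design.post_label_delay_s,
            control_value=1,
        ),
        brain_mask=brain,
        gm_mask=masks["gm"],
        wm_mask=masks["wm"],
        csf_mask=masks["csf"],
        truth=truth,
        subject_id=subject_id,
        rng_seed=int(seed),
        metadata={
            "paradigm_convention": "first volume is label; paradigm +1 marks control",
            "control_value": 1,
            "tr_s": {"cvBOLD": spec_cv.tr_s, "ASL": spec_asl.tr_s},
            "n_volumes": {"cvBOLD": spec_cv.n_volumes, "ASL": spec_asl.n_volumes},
        },
    )


def generate_cohort(
    n_subjects: int,
    base_config: GeneratorConfig = None,
    seed: int = 0,
    spec_cv: AcquisitionSpec = None,
    spec_asl: AcquisitionSpec = None,
) -> list[SubjectData]:
    """Generate a cohort; per-subject seeds derive deterministically from ``seed``.

    Between-subject variation: each subject's gray-matter CBF level is drawn
    from N(gm_cbf, between_subject_cbf_sd), truncated at zero.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    base_config = base_config or GeneratorConfig()
    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_subjects, dtype=np.uint32)]
    between_rng = np.random.default_rng(ss.spawn(1)[0])
    cohort = []
    for i in range(n_subjects):
        gm = max(0.0, base_config.gm_cbf
                 + between_rng.standard_normal() * base_config.between_subject_cbf_sd)
        design_i = dataclasses.replace(base_config, gm_cbf=gm)
        cohort.append(
            generate_subject(spec_cv, spec_asl, design_i, seed=child_seeds[i],
                             subject_id=f"sub-{i:03d}")
        )
    return cohort


# ---------------------------------------------------------------------------
# disk layout

def write_subject(data: SubjectData, directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write one subject to disk: NIfTI grids, paradigm text file, JSON truth.

    Refuses to clobber existing files unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = data.cvbold.affine
    paths: dict[str, Path] = {}

    def target(name: str) -> Path:
        p = directory / name
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
        return p

    paths["cvbold"] = data.cvbold.save(target("cvbold.nii.gz"))
    paths["asl"] = data.asl.series.save(target("asl.nii.gz"))
    for name, mask in (("brain_mask", data.brain_mask), ("gm_mask", data.gm_mask),
                       ("wm_mask", data.wm_mask), ("csf_mask", data.csf_mask)):
        paths[name] = save_mask(mask, target(f"{name}.nii.gz"), affine)
    t = data.truth
    paths["cbf_true"] = target("cbf_true.nii.gz")
    nib.save(nib.Nifti1Image(t.cbf_true.astype(np.float32), affine), str(paths["cbf_true"]))
    for k, m in enumerate(t.network_maps):
        paths[f"network_{k:02d}"] = save_mask(m, target(f"network_{k:02d}_mask.nii.gz"), affine)

    paths["paradigm"] = target("paradigm.txt")
    np.savetxt(paths["paradigm"], data.asl.paradigm, fmt="%+d")

    sidecar = {
        "subject_id": data.subject_id,
        "rng_seed": data.rng_seed,
        "metadata": data.metadata,
        "tr_s_cvbold": data.cvbold.tr_s,
        "tr_s_asl": data.asl.series.tr_s,
        "labeling_time_s": data.asl.labeling_time_s,
        "post_label_delay_s": data.asl.post_label_delay_s,
        "control_value": data.asl.control_value,
        "n_networks": len(t.network_maps),
        "band_hz": list(t.band_hz),
        "noise_sd_cv": t.noise_sd_cv,
        "noise_sd_asl": t.noise_sd_asl,
        "network_timecourses_cv": t.network_timecourses_cv.tolist(),
        "network_timecourses_asl": t.network_timecourses_asl.tolist(),
        "drift_slope_cv": t.drift_slope_cv.tolist(),
        "drift_slope_asl": t.drift_slope_asl.tolist(),
        "motion_trace_cv": t.motion_trace_cv.tolist(),
        "motion_trace_asl": t.motion_trace_asl.tolist(),
    }
    paths["truth"] = target("truth.json")
    paths["truth"].write_text(json.dumps(sidecar))
    return paths


def read_subject(directory: str | Path) -> SubjectData:
    """Read a subject written by :func:`write_subject` back into memory."""
    directory = Path(directory)
    sidecar = json.loads((directory / "truth.json").read_text())
    cvbold = FuncSeries.load(directory / "cvbold.nii.gz")
    cvbold.tr_s = float(sidecar["tr_s_cvbold"])
    aslf = FuncSeries.load(directory / "asl.nii.gz")
    aslf.tr_s = float(sidecar["tr_s_asl"])
    paradigm = np.loadtxt(directory / "paradigm.txt", dtype=np.int64)
    masks = {name: load_mask(directory / f"{name}.nii.gz")
             for name in ("brain_mask", "gm_mask", "wm_mask", "csf_mask")}
    cbf_true = np.asarray(nib.load(str(directory / "cbf_true.nii.gz")).get_fdata(), dtype=np.float64)
    nets = [load_mask(directory / f"network_{k:02d}_mask.nii.gz")
            for k in range(int(sidecar["n_networks"]))]
    truth = GroundTruth(
        network_maps=nets,
        network_timecourses_cv=np.asarray(sidecar["network_timecourses_cv"], dtype=np.float64),
        network_timecourses_asl=np.asarray(sidecar["network_timecourses_asl"], dtype=np.float64),
        cbf_true=cbf_true,
        drift_slope_cv=np.asarray(sidecar["drift_slope_cv"], dtype=np.float64),
        drift_slope_asl=np.asarray(sidecar["drift_slope_asl"], dtype=np.float64),
        noise_sd_cv=float(sidecar["noise_sd_cv"]),
        noise_sd_asl=float(sidecar["noise_sd_asl"]),
        motion_trace_cv=np.asarray(sidecar["motion_trace_cv"], dtype=np.float64),
        motion_trace_asl=np.asarray(sidecar["motion_trace_asl"], dtype=np.float64),
        band_hz=tuple(sidecar["band_hz"]),
    )
    return SubjectData(
        cvbold=cvbold,
        asl=ASLSeries(
            series=aslf,
            paradigm=paradigm,
            labeling_time_s=float(sidecar["labeling_time_s"]),
            post_label_delay_s=float(sidecar["post_label_delay_s"]),
            control_value=int(sidecar["control_value"]),
        ),
        brain_mask=masks["brain_mask"],
        gm_mask=masks["gm_mask"],
        wm_mask=masks["wm_mask"],
        csf_mask=masks["csf_mask"],
        truth=truth,
        subject_id=sidecar["subject_id"],
        rng_seed=int(sidecar["rng_seed"]),
        metadata=sidecar["metadata"],
    )
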