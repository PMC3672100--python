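"""End-to-end orchestration: generate (or load) a cohort, run both BOLD
modality arms through preprocessing and the four resting-state measures,
quantify CBF, and emit maps, summary tables, Dice comparisons, and a
provenance manifest.

The two arms are: conventional BOLD (cvBOLD, the dedicated EPI series) and
concurrent BOLD (ccBOLD, extracted from the ASL series by regressing out the
labeling paradigm).  Every analysis is run identically on both, which is the
point of the comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asl as asl_mod
from . import compare, ica, metrics, preprocess, synth
from .grids import ASLSeries, FuncSeries, MetricMap, save_mask

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "demo_config"]


@dataclass
class RunConfig:
    """Fully serializable run configuration; every default is written back
    out with the results so a run is reproducible from its emitted config."""

    out_dir: str = "aslrest_out"
    seed: int = 0
    n_subjects: int = 10
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_mm: float = 3.0
    tr_cv_s: float = 0.9
    n_volumes_cv: int = 360
    tr_asl_s: float = 4.0
    n_volumes_asl: int = 60
    band_hz: tuple[float, float] = (0.01, 0.08)
    seed_sphere: tuple[float, float, float, float] = (0.0, -50.0, 31.0, 10.0)
    n_components: int = 8
    threshold_z: float = 1.0
    alpha: float = 0.05
    fwe_method: str = "bonferroni"
    max_trans_mm: float = 2.0
    max_rot_deg: float = 2.0
    fwhm_mm: float = 4.0
    chain_order: tuple[str, ...] = preprocess.DEFAULT_ORDER
    reho_neighborhood: int = 27
    subject_ica: bool = True
    write_maps: bool = True
    overwrite: bool = False
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    def validate(self) -> None:
        for tr, name in ((self.tr_cv_s, "cvBOLD"), (self.tr_asl_s, "ASL")):
            nyq = 1.0 / (2.0 * tr)
            if self.band_hz[1] > nyq + 1e-12:
                raise ValueError(
                    f"band upper edge {self.band_hz[1]} Hz exceeds the {name} Nyquist "
                    f"frequency {nyq:.6g} Hz (TR {tr} s)"
                )
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects for group statistics")
        if self.fwe_method not in ("bonferroni", "permutation"):
            raise ValueError(f"unknown FWE method {self.fwe_method!r}")
        if len(self.seed_sphere) != 4:
            raise ValueError("seed_sphere must be (x, y, z, radius) in mm")
        # constructing the generator config validates its fields too
        self.generator_config()

    def generator_config(self) -> synth.GeneratorConfig:
        return synth.GeneratorConfig(**self.generator)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["band_hz"] = list(d["band_hz"])
        d["seed_sphere"] = list(d["seed_sphere"])
        d["chain_order"] = list(d["chain_order"])
        d["generator"] = {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in d["generator"].items()
                          if k != "constants"}
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "band_hz", "seed_sphere", "chain_order"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def demo_config(seed: int = 7, out_dir: str = "aslrest_demo") -> RunConfig:
    """A quick-look configuration: 6 subjects, no per-subject ICA."""
    return RunConfig(out_dir=out_dir, seed=seed, n_subjects=6, n_components=6,
                     subject_ica=False)


@dataclass
class PipelineReport:
    config: RunConfig
    out_dir: Path
    motion: pd.DataFrame
    dice_table: pd.DataFrame
    rsn_summary: pd.DataFrame
    rsn_dice_group: pd.DataFrame
    rsn_dice_subject: pd.DataFrame | None
    anova: dict
    paired_rsn_tests: dict[str, pd.DataFrame]
    group_fc: dict[str, compare.GroupResult]
    paired_fc: compare.GroupResult
    rsns: dict[str, ica.RSNSet]
    manifest: dict[str, str]
    provenance: dict
    excluded_subjects: list[str]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preprocess_arm(series: FuncSeries, motion: np.ndarray, subject: synth.SubjectData,
                    config: RunConfig, order: tuple[str, ...]) -> FuncSeries:
    out, _ = preprocess.preprocess_chain(
        series,
        motion=motion,
        brain_mask=subject.brain_mask,
        wm_mask=subject.wm_mask,
        csf_mask=subject.csf_mask,
        fwhm_mm=config.fwhm_mm,
        band_hz=config.band_hz,
        order=order,
    )
    return out


def _subject_metrics(subject: synth.SubjectData, config: RunConfig,
                     seed_spec: metrics.SeedSpec) -> dict[str, dict[str, MetricMap]]:
    """All per-subject maps for both modality arms plus CBF."""
    brain = subject.brain_mask
    order = tuple(config.chain_order)
    order_nosmooth = tuple(s for s in order if s != "smooth")
    ccbold = asl_mod.extract_ccbold(subject.asl)
    arms = {
        "cvBOLD": (subject.cvbold, subject.truth.motion_trace_cv),
        "ccBOLD": (ccbold, subject.truth.motion_trace_asl),
    }
    out: dict[str, dict[str, MetricMap]] = {}
    for modality, (series, motion) in arms.items():
        pre = _preprocess_arm(series, motion, subject, config, order)
        pre_ns = _preprocess_arm(series, motion, subject, config, order_nosmooth)
        # ICA consumes the series after smoothing only (plus detrend): the
        # decomposition sees the full-band signal, not the nuisance-cleaned one
        pre_ica = _preprocess_arm(series, motion, subject, config, ("smooth", "detrend"))
        seed_ts = metrics.seed_mean_timeseries(pre, seed_spec, brain)
        fc = metrics.fc_map(pre, seed_ts, brain)
        out[modality] = {
            "fc_z": metrics.fisher_z(fc),
            "alff": metrics.alff_map(pre, brain, *config.band_hz),
            "reho": metrics.reho_map(pre_ns, brain, neighborhood=config.reho_neighborhood),
            "_pre": pre,
            "_pre_ica": pre_ica,
        }
    # CBF from the smoothed raw ASL series (labeling modulation intact)
    smoothed = preprocess.smooth_gaussian(subject.asl.series, config.fwhm_mm)
    asl_s = ASLSeries(series=smoothed, paradigm=subject.asl.paradigm,
                      labeling_time_s=subject.asl.labeling_time_s,
                      post_label_delay_s=subject.asl.post_label_delay_s,
                      control_value=subject.asl.control_value)
    m0 = asl_mod.m0_from_control_mean(asl_s, mask=brain)
    out["cbf"] = {"cbf": asl_mod.compute_cbf(asl_s, m0, mask=brain)}
    return out


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run the full cross-modality comparison on a generated cohort."""
    config.validate()
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def log_stage(name: str, **info):
        stages.append({"stage": name, "elapsed_s": round(time.time() - t0, 2), **info})

    spec_cv = synth.AcquisitionSpec(tuple(config.grid_shape), (config.voxel_mm,) * 3,
                                    config.tr_cv_s, config.n_volumes_cv, "cvBOLD")
    spec_asl = synth.AcquisitionSpec(tuple(config.grid_shape), (config.voxel_mm,) * 3,
                                     config.tr_asl_s, config.n_volumes_asl, "ASL")
    gen = config.generator_config()
    cohort = synth.generate_cohort(config.n_subjects, gen, seed=config.seed,
                                   spec_cv=spec_cv, spec_asl=spec_asl)
    log_stage("simulate", n_subjects=len(cohort))

    # motion exclusion rule
    motion_rows, excluded = [], []
    for s in cohort:
        for name, trace in (("cvBOLD", s.truth.motion_trace_cv),
                            ("ASL", s.truth.motion_trace_asl)):
            chk = preprocess.check_motion(trace, config.max_trans_mm, config.max_rot_deg)
            motion_rows.append((s.subject_id, name, chk.passed,
                                chk.max_translation_mm, chk.max_rotation_deg,
                                len(chk.offending_volumes)))
            if not chk.passed and s.subject_id not in excluded:
                excluded.append(s.subject_id)
    motion_table = pd.DataFrame(
        motion_rows, columns=["subject", "series", "passed", "max_trans_mm",
                              "max_rot_deg", "n_offending"])
    cohort = [s for s in cohort if s.subject_id not in excluded]
    if len(cohort) < 3:
        raise RuntimeError(f"motion exclusion left {len(cohort)} subjects; need >= 3")
    log_stage("motion_check", excluded=excluded)

    x, y, z, radius = config.seed_sphere
    seed_spec = metrics.SeedSpec((x, y, z), radius)
    per_subject = {s.subject_id: _subject_metrics(s, config, seed_spec) for s in cohort}
    log_stage("subject_metrics")

    brain = cohort[0].brain_mask
    affine = cohort[0].cvbold.affine
    truth_nets = cohort[0].truth.network_maps

    # ---- group seed-FC, both arms
    group_fc: dict[str, compare.GroupResult] = {}
    for modality in ("cvBOLD", "ccBOLD"):
        maps = [per_subject[s.subject_id][modality]["fc_z"] for s in cohort]
        res = compare.one_sample_t(maps, sided="greater")
        group_fc[modality] = compare.fwe_threshold(res, alpha=config.alpha,
                                                   method=config.fwe_method,
                                                   seed=config.seed + 1)
    paired_fc = compare.fwe_threshold(
        compare.paired_t([per_subject[s.subject_id]["cvBOLD"]["fc_z"] for s in cohort],
                         [per_subject[s.subject_id]["ccBOLD"]["fc_z"] for s in cohort]),
        alpha=config.alpha, method=config.fwe_method, seed=config.seed + 2)
    log_stage("group_fc")

    dice_rows = [
        ("group", "PCC-FC", "cvBOLD_vs_ccBOLD",
         compare.dice(group_fc["cvBOLD"].sig_mask, group_fc["ccBOLD"].sig_mask)),
    ]
    if truth_nets:
        dmn = truth_nets[0]
        dice_rows += [
            ("group", "PCC-FC", "cvBOLD_vs_truth", compare.dice(group_fc["cvBOLD"].sig_mask, dmn)),
            ("group", "PCC-FC", "ccBOLD_vs_truth", compare.dice(group_fc["ccBOLD"].sig_mask, dmn)),
        ]

    # ---- group ICA, both arms, matched to the planted network templates
    rsns: dict[str, ica.RSNSet] = {}
    matches: dict[str, ica.ComponentMatch] = {}
    templates = [m.astype(float) for m in truth_nets]
    for modality in ("cvBOLD", "ccBOLD"):
        series_list = [per_subject[s.subject_id][modality]["_pre_ica"] for s in cohort]
        data, voxel_index = ica.concatenate_temporal(series_list, brain)
        rsn = ica.group_ica(data, brain, voxel_index,
                            n_components=config.n_components, seed=config.seed,
                            threshold_z=config.threshold_z)
        rsns[modality] = rsn
        matches[modality] = ica.match_components(rsn, templates)
    log_stage("group_ica")

    rsn_names = [f"rsn{k:02d}" for k in range(len(templates))]
    rsn_dice_rows = []
    for k, name in enumerate(rsn_names):
        mv = rsns["cvBOLD"].mask_3d(matches["cvBOLD"].assignment[k])
        mc = rsns["ccBOLD"].mask_3d(matches["ccBOLD"].assignment[k])
        rsn_dice_rows.append((name, compare.dice(mv, mc),
                              compare.dice(mv, truth_nets[k]),
                              compare.dice(mc, truth_nets[k]),
                              matches["cvBOLD"].scores[k], matches["ccBOLD"].scores[k]))
        dice_rows.append(("group", name, "cvBOLD_vs_ccBOLD", compare.dice(mv, mc)))
    rsn_dice_group = pd.DataFrame(
        rsn_dice_rows, columns=["rsn", "dice_cv_cc", "dice_cv_truth", "dice_cc_truth",
                                "match_r_cv", "match_r_cc"])

    # ---- per-subject ICA reproducibility (individual-level Dice)
    rsn_dice_subject = None
    if config.subject_ica:
        rows = []
        for s in cohort:
            masks_by_mod = {}
            for modality in ("cvBOLD", "ccBOLD"):
                data, voxel_index = ica.concatenate_temporal(
                    [per_subject[s.subject_id][modality]["_pre_ica"]], brain)
                n_comp = min(config.n_components, data.shape[0])
                rsn = ica.group_ica(data, brain, voxel_index, n_components=n_comp,
                                    seed=config.seed, threshold_z=config.threshold_z)
                match = ica.match_components(rsn, templates)
                masks_by_mod[modality] = [rsn.mask_3d(match.assignment[k])
                                          for k in range(len(templates))]
            for k, name in enumerate(rsn_names):
                rows.append((s.subject_id, name,
                             compare.dice(masks_by_mod["cvBOLD"][k], masks_by_mod["ccBOLD"][k])))
        rsn_dice_subject = pd.DataFrame(rows, columns=["subject", "rsn", "dice_cv_cc"])
        for name in rsn_names:
            vals = rsn_dice_subject[rsn_dice_subject["rsn"] == name]["dice_cv_cc"]
            dice_rows.append(("subject_mean", name, "cvBOLD_vs_ccBOLD", float(vals.mean())))
        log_stage("subject_ica")

    dice_table = pd.DataFrame(dice_rows, columns=["level", "map", "pair", "dice"])

    # ---- RSN-wise summaries: CBF / ALFF / ReHo over each modality's matched masks
    metric_maps: dict[tuple[str, str, str], MetricMap] = {}
    summaries = []
    for modality in ("cvBOLD", "ccBOLD"):
        rsn_masks = {}
        for k, name in enumerate(rsn_names):
            m = rsns[modality].mask_3d(matches[modality].assignment[k])
            if not m.any():  # fall back to the template if thresholding left nothing
                m = truth_nets[k]
            rsn_masks[name] = m
        block: dict[tuple[str, str, str], MetricMap] = {}
        for s in cohort:
            block[(s.subject_id, modality, "cbf")] = per_subject[s.subject_id]["cbf"]["cbf"]
            block[(s.subject_id, modality, "alff")] = per_subject[s.subject_id][modality]["alff"]
            block[(s.subject_id, modality, "reho")] = per_subject[s.subject_id][modality]["reho"]
        metric_maps.update(block)
        summaries.append(compare.extract_rsn_means(block, rsn_masks))
    rsn_summary = pd.concat(summaries, ignore_index=True)[compare.SUMMARY_COLUMNS]

    anova = {}
    for modality in ("cvBOLD", "ccBOLD"):
        f, df, p = compare.anova_across_rsns(
            rsn_summary[rsn_summary["modality"] == modality], "cbf")
        anova[modality] = {"F": f, "df": list(df), "p": p}
    paired_rsn_tests = {
        metric: compare.paired_t_by_rsn(rsn_summary, metric, "cvBOLD", "ccBOLD",
                                        alpha=config.alpha)
        for metric in ("cbf", "alff", "reho")
    }
    log_stage("rsn_summaries")

    # ---- outputs
    manifest: dict[str, str] = {}

    def emit(path: Path):
        manifest[str(path.relative_to(out_dir))] = _sha256(path)

    if config.write_maps:
        maps_dir = out_dir / "maps"
        maps_dir.mkdir(exist_ok=True)
        for s in cohort:
            for modality in ("cvBOLD", "ccBOLD"):
                for metric in ("fc_z", "alff", "reho"):
                    p = maps_dir / f"{s.subject_id}_{modality}_{metric}.nii.gz"
                    per_subject[s.subject_id][modality][metric].save(p, affine)
                    emit(p)
            p = maps_dir / f"{s.subject_id}_cbf.nii.gz"
            per_subject[s.subject_id]["cbf"]["cbf"].save(p, affine)
            emit(p)
        for modality, res in group_fc.items():
            p = out_dir / f"group_fc_t_{modality}.nii.gz"
            res.t_map.save(p, affine)
            emit(p)
            p = out_dir / f"group_fc_sig_{modality}.nii.gz"
            save_mask(res.sig_mask, p, affine)
            emit(p)
        p = out_dir / "paired_fc_t.nii.gz"
        paired_fc.t_map.save(p, affine)
        emit(p)

    for name, frame in (("dice_table", dice_table), ("rsn_summary", rsn_summary),
                        ("rsn_dice_group", rsn_dice_group), ("motion", motion_table)):
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.10g")
        emit(p)
    if rsn_dice_subject is not None:
        p = out_dir / "rsn_dice_subject.csv"
        rsn_dice_subject.to_csv(p, index=False, float_format="%.10g")
        emit(p)
    for metric, frame in paired_rsn_tests.items():
        p = out_dir / f"paired_rsn_{metric}.csv"
        frame.to_csv(p, index=False, float_format="%.10g")
        emit(p)

    provenance = {
        "stages": stages,
        "anova_cbf": anova,
        "excluded_subjects": excluded,
        "fwe": {m: {"threshold": group_fc[m].threshold, "df": group_fc[m].df,
                    "method": group_fc[m].correction, "alpha": group_fc[m].alpha,
                    "sided": group_fc[m].sided}
                for m in group_fc},
        "chain_order": list(config.chain_order),
        "n_inmask_voxels": int(brain.sum()),
    }
    p = out_dir / "provenance.json"
    p.write_text(json.dumps(provenance, indent=2))
    emit(p)
    config.to_yaml(out_dir / "config.yaml")
    emit(out_dir / "config.yaml")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineReport(
        config=config, out_dir=out_dir, motion=motion_table, dice_table=dice_table,
        rsn_summary=rsn_summary, rsn_dice_group=rsn_dice_group,
        rsn_dice_subject=rsn_dice_subject, anova=anova,
        paired_rsn_tests=paired_rsn_tests, group_fc=group_fc, paired_fc=paired_fc,
        rsns=rsns, manifest=manifest, provenance=provenance,
        excluded_subjects=excluded,
    )
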