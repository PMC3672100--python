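"""Separation of ASL label/control series into concurrent BOLD and perfusion.

An interleaved ASL acquisition carries three signals: the slowly varying
BOLD-weighted signal, a +/- modulation following the label/control paradigm
whose amplitude is the perfusion-weighted difference dM, and thermal noise.
Regressing the paradigm out of the series leaves the concurrent BOLD
(ccBOLD); averaging pairwise control-label differences yields dM; a
single-compartment pCASL model converts dM and an equilibrium magnetization
(M0) image into cerebral blood flow in ml/100g/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ASLSeries, FuncSeries, MetricMap

__all__ = [
    "QuantificationConstants",
    "extract_ccbold",
    "perfusion_difference",
    "m0_from_control_mean",
    "compute_cbf",
    "deltam_from_cbf",
]


@dataclass(frozen=True)
class QuantificationConstants:
    """Constants of the single-compartment pCASL quantification model.

    Defaults are the widely used 3 T values: arterial blood T1 1.65 s,
    labeling efficiency 0.85, brain/blood partition coefficient 0.9 g/ml,
    and a scale of 6000 converting ml/g/s to ml/100g/min.
    """

    blood_t1_s: float = 1.65
    labeling_efficiency: float = 0.85
    partition_coefficient: float = 0.9
    scale: float = 6000.0

    def __post_init__(self) -> None:
        if not (self.blood_t1_s > 0 and self.partition_coefficient > 0 and self.scale > 0):
            raise ValueError("quantification constants must be strictly positive")
        if not (0 < self.labeling_efficiency <= 1):
            raise ValueError("labeling_efficiency must be in (0, 1]")


def extract_ccbold(asl: ASLSeries) -> FuncSeries:
    """Extract the concurrent BOLD series by regressing out the paradigm.

    Per voxel, ordinary least squares of the signal on [intercept, paradigm];
    the returned series is the residual plus the fitted intercept, so the mean
    signal level is preserved while the labeling modulation is removed exactly
    (the residuals are orthogonal to the paradigm by construction).
    """
    n = asl.series.n_volumes
    if n < 4:
        raise ValueError(f"need at least 4 volumes for ccBOLD extraction, got {n}")
    paradigm = asl.paradigm.astype(np.float64)
    if np.ptp(paradigm) == 0:
        raise ValueError("paradigm is constant; cannot regress it out")

    data = asl.series.data
    flat = data.reshape(-1, n)  # voxels x time
    x = np.column_stack([np.ones(n), paradigm])
    beta, *_ = np.linalg.lstsq(x, flat.T, rcond=None)  # (2, voxels)
    resid = flat.T - x @ beta
    out = (resid + beta[0]).T.reshape(data.shape)
    return asl.series.copy_with(out)


def perfusion_difference(asl: ASLSeries, mask: np.ndarray | None = None) -> MetricMap:
    """Mean pairwise control - label difference map (dM).

    Because the paradigm strictly alternates, the mean over consecutive
    pairs equals mean(control volumes) - mean(label volumes), and equals
    twice the OLS coefficient of the signal on the paradigm, signed by the
    recorded control convention.
    """
    n = asl.series.n_volumes
    if n % 2 != 0:
        raise ValueError(f"ASL series must have an even number of volumes, got {n}")
    data = asl.series.data
    ctrl = data[..., asl.control_index()].mean(axis=3)
    labl = data[..., asl.label_index()].mean(axis=3)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return MetricMap(
        data=ctrl - labl,
        mask=mask,
        kind="deltam",
        provenance={"op": "perfusion_difference", "control_value": asl.control_value,
                    "n_pairs": n // 2},
    )


def m0_from_control_mean(asl: ASLSeries, mask: np.ndarray | None = None) -> MetricMap:
    """M0 proxy: the mean control image (the unlabeled volumes)."""
    data = asl.series.data[..., asl.control_index()].mean(axis=3)
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    return MetricMap(data=data, mask=mask, kind="cbf",
                     provenance={"op": "m0_from_control_mean"})


def _cbf_factor(constants: QuantificationConstants, labeling_time_s: float,
                post_label_delay_s: float) -> float:
    """CBF = factor * dM / m0 under the single-compartment pCASL model."""
    c = constants
    return (
        c.scale
        * c.partition_coefficient
        * np.exp(post_label_delay_s / c.blood_t1_s)
        / (2.0 * c.labeling_efficiency * c.blood_t1_s * (1.0 - np.exp(-labeling_time_s / c.blood_t1_s)))
    )


def compute_cbf(
    asl: ASLSeries,
    m0: MetricMap | np.ndarray,
    constants: QuantificationConstants = QuantificationConstants(),
    mask: np.ndarray | None = None,
) -> MetricMap:
    """Quantify CBF (ml/100g/min) from an ASL series and an M0 image.

    Single-compartment pCASL model with label duration tau and post-labeling
    delay PLD::

        CBF = scale * lambda * dM * exp(PLD/T1b)
              / (2 * alpha * T1b * m0 * (1 - exp(-tau/T1b)))

    Voxels with m0 <= 0 are set to 0 and flagged.
    """
    dm = perfusion_difference(asl, mask=mask)
    m0_data = m0.data if isinstance(m0, MetricMap) else np.asarray(m0, dtype=np.float64)
    if m0_data.shape != dm.data.shape:
        raise ValueError("m0 grid does not match the ASL grid")
    factor = _cbf_factor(constants, asl.labeling_time_s, asl.post_label_delay_s)
    bad = ~(m0_data > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = factor * dm.data / m0_data
    cbf[bad] = 0.0
    return MetricMap(
        data=cbf,
        mask=dm.mask,
        kind="cbf",
        provenance={
            "op": "compute_cbf",
            "constants": {
                "blood_t1_s": constants.blood_t1_s,
                "labeling_efficiency": constants.labeling_efficiency,
                "partition_coefficient": constants.partition_coefficient,
                "scale": constants.scale,
            },
            "labeling_time_s": asl.labeling_time_s,
            "post_label_delay_s": asl.post_label_delay_s,
        },
        flags=bad,
    )


def deltam_from_cbf(
    cbf: np.ndarray,
    m0: np.ndarray,
    constants: QuantificationConstants,
    labeling_time_s: float,
    post_label_delay_s: float,
) -> np.ndarray:
    """Forward model: the dM a given CBF map implies (inverse of compute_cbf)."""
    factor = _cbf_factor(constants, labeling_time_s, post_label_delay_s)
    return np.asarray(cbf, dtype=np.float64) * np.asarray(m0, dtype=np.float64) / factor
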