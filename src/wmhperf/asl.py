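"""Pulsed-ASL perfusion quantification and total-brain normalization.

The control/label time series is collapsed to a perfusion-weighted
difference image dM (``surround_subtract``), converted to CBF in
ml/100g/min with the single-compartment QUIPSS II closed form
(``pasl_cbf``)

    CBF = 6000 * lambda * dM * exp(TI / T1b) / (2 * alpha * TI1_s * M0)

and normalized to each subject's total-brain mean, yielding the
dimensionless relative CBF used throughout the analysis
(``relative_cbf``).  The normalizing mean is taken over the *full* brain
mask including CSF/ventricular voxels; because CSF carries almost no
perfusion signal, this pulls the normalizer below parenchymal CBF, which
is why GM and WM relative values can both exceed 1.

Default constants: blood T1 1650 ms, labeling efficiency 0.98,
blood-brain partition coefficient 0.9 ml/g, inversion time 1800 ms,
bolus duration 1650 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volumes import LabelVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantParams:
    """Single-compartment PASL quantification constants."""

    t1_blood_ms: float = 1650.0
    label_efficiency: float = 0.98
    partition_coefficient: float = 0.9  # ml/g
    ti_ms: float = 1800.0
    ti1_ms: float = 1650.0  # bolus duration
    m0_threshold_fraction: float = 0.10  # of robust max, guards the division

    def __post_init__(self) -> None:
        if min(self.t1_blood_ms, self.label_efficiency, self.partition_coefficient, self.ti_ms, self.ti1_ms) <= 0:
            raise ValueError("all quantification constants must be positive")
        if self.label_efficiency > 1:
            raise ValueError(f"labeling efficiency must be <= 1, got {self.label_efficiency}")


def surround_subtract(
    control: np.ndarray, label: np.ndarray, scheme: str = "pairwise"
) -> np.ndarray:
    """Collapse an alternating control/label series to a mean dM volume.

    Parameters
    ----------
    control, label
        4D arrays (x, y, z, pair index) with equal pair counts.
    scheme
        ``"pairwise"`` (default): dM_k = control_k - label_k.
        ``"surround"``: dM_k = control_k - (label_{k-1} + label_k)/2 at
        interior indices (first pair stays pairwise), which cancels a
        linear temporal drift to first order.
    """
    control = np.asarray(control, dtype=float)
    label = np.asarray(label, dtype=float)
    if control.shape != label.shape:
        raise ValueError(f"control {control.shape} and label {label.shape} series differ in shape")
    if control.ndim != 4 or control.shape[3] < 1:
        raise ValueError("expected 4D series with at least one control/label pair")
    if scheme == "pairwise":
        diffs = control - label
    elif scheme == "surround":
        diffs = control - label
        if control.shape[3] > 1:
            diffs[..., 1:] = control[..., 1:] - 0.5 * (label[..., :-1] + label[..., 1:])
    else:
        raise ValueError(f"unknown subtraction scheme {scheme!r}")
    return diffs.mean(axis=3)


def split_series(series: np.ndarray, first: str = "control") -> tuple[np.ndarray, np.ndarray]:
    """Split an interleaved 4D ASL series into (control, label) stacks."""
    series = np.asarray(series)
    if series.ndim != 4 or series.shape[3] % 2:
        raise ValueError("interleaved series must be 4D with an even number of volumes")
    a, b = series[..., 0::2], series[..., 1::2]
    return (a, b) if first == "control" else (b, a)


def pasl_cbf(
    delta_m: np.ndarray,
    m0: np.ndarray,
    params: QuantParams = QuantParams(),
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """CBF (ml/100g/min) from dM and M0 via the QUIPSS II closed form.

    Voxels whose M0 falls below ``m0_threshold_fraction`` of the robust
    (99th-percentile) maximum are masked to zero; their count is logged.
    """
    delta_m = np.asarray(delta_m, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if delta_m.shape != m0.shape:
        raise ValueError(f"dM {delta_m.shape} and M0 {m0.shape} differ in shape")
    robust_max = float(np.percentile(m0[m0 > 0], 99)) if (m0 > 0).any() else 0.0
    threshold = params.m0_threshold_fraction * robust_max
    valid = m0 > threshold
    if brain_mask is not None:
        n_bad = int(np.count_nonzero(np.asarray(brain_mask, dtype=bool) & ~valid))
        if n_bad:
            log.warning("masked %d brain voxels with M0 <= %.3g", n_bad, threshold)
    scale = (
        6000.0
        * params.partition_coefficient
        * np.exp(params.ti_ms / params.t1_blood_ms)
        / (2.0 * params.label_efficiency * (params.ti1_ms / 1000.0))
    )
    cbf = np.zeros_like(delta_m)
    np.divide(delta_m, m0, out=cbf, where=valid)
    return scale * cbf


def relative_cbf(cbf: LabelVolume, brain_mask: LabelVolume) -> tuple[LabelVolume, float]:
    """Normalize CBF by the subject's mean over the full brain mask.

    Returns the rCBF volume and the normalizer (ml/100g/min).  The mean of
    rCBF over the brain mask is exactly 1 by construction.
    """
    cbf.require_same_grid(brain_mask, "CBF and brain mask")
    mask = brain_mask.astype_mask()
    if not mask.any():
        raise ValueError("brain mask is empty")
    normalizer = float(np.asarray(cbf.data, dtype=float)[mask].mean())
    if normalizer <= 0:
        raise ValueError(f"total-brain mean CBF must be positive, got {normalizer}")
    return LabelVolume(data=np.asarray(cbf.data, dtype=float) / normalizer, voxel_size_mm=cbf.voxel_size_mm), normalizer
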