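"""The long ROI measurement table and its model-ready transforms.

One row per (subject, session, tissue, region): mean rCBF over the ROI,
its volume in mm^3, volume relative to total brain volume (rVol), and —
after ``transform`` — natural-log columns and the mean-centred log rVol
used as the volume covariate in the mixed models.  Empty ROIs (e.g. a
subject with no deep WMH) become explicit missing rows with a reason
code, mirroring how subjects lacking lesions in a region are excluded
from region-wise models rather than silently dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .volumes import LabelVolume

log = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "subject",
    "session",
    "tissue",
    "region",
    "mean_rcbf",
    "volume_mm3",
    "rvol",
    "n_voxels",
    "missing_reason",
]


def roi_mean_row(
    rcbf: LabelVolume,
    roi_mask: np.ndarray,
    subject: str,
    session: str,
    tissue: str,
    region: str,
    total_brain_volume_mm3: float,
) -> dict:
    """One measurement row; an empty ROI yields a missing row, not a crash."""
    roi = np.asarray(roi_mask, dtype=bool)
    n = int(np.count_nonzero(roi))
    row = {
        "subject": subject,
        "session": session,
        "tissue": tissue,
        "region": region,
        "n_voxels": n,
        "missing_reason": None,
    }
    if n == 0:
        row.update(mean_rcbf=np.nan, volume_mm3=0.0, rvol=0.0, missing_reason="empty_roi")
        return row
    volume = n * rcbf.voxel_volume_mm3
    row.update(
        mean_rcbf=float(np.asarray(rcbf.data, dtype=float)[roi].mean()),
        volume_mm3=volume,
        rvol=volume / total_brain_volume_mm3,
    )
    return row


def extract_roi_means(
    rcbf: LabelVolume,
    rois: dict[tuple[str, str], np.ndarray],
    subject: str,
    session: str,
    brain_mask: LabelVolume,
) -> pd.DataFrame:
    """Long table of mean rCBF for a dict of (tissue, region) -> mask."""
    rcbf.require_same_grid(brain_mask, "rCBF and brain mask")
    total = brain_mask.volume_mm3()
    rows = [
        roi_mean_row(rcbf, mask, subject, session, tissue, region, total)
        for (tissue, region), mask in rois.items()
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def transform(table: pd.DataFrame, log_base: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Add log rCBF / log rVol columns and the mean-centred log rVol.

    Natural log by default (``log_base`` overrides).  The centring constant
    is the mean log rVol of the WMH rows over the analysis set, computed
    once and returned in the metadata so downstream coefficients are
    interpretable at the average lesion burden.  Rows with nonpositive
    values are flagged, logged and excluded from the transformed columns.
    """
    out = table.copy()
    scale = 1.0 if log_base is None else float(np.log(log_base))

    def safe_log(x: pd.Series) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.log(x.to_numpy(dtype=float)) / scale
        v[~(x.to_numpy(dtype=float) > 0)] = np.nan
        return pd.Series(v, index=x.index)

    out["log_rcbf"] = safe_log(out["mean_rcbf"])
    out["log_rvol"] = safe_log(out["rvol"])
    n_bad = int((out["mean_rcbf"].notna() & ~(out["mean_rcbf"] > 0)).sum())
    if n_bad:
        log.warning("dropped %d rows with nonpositive rCBF from log columns", n_bad)

    wmh_logs = out.loc[(out["tissue"] == "WMH") & out["log_rvol"].notna(), "log_rvol"]
    center = float(wmh_logs.mean()) if len(wmh_logs) else 0.0
    out["log_rvol_centered"] = out["log_rvol"] - center
    meta = {"log_base": "e" if log_base is None else log_base, "rvol_centering_constant": center}
    return out, meta
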