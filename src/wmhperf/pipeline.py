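"""End-to-end orchestration: masks -> quantify -> track -> extract -> fit.

Each stage is a plain function over in-memory volumes and tables so the
analysis drivers, the CLI and the tests all share one code path.  The
pipeline only ever sees raw masks (ventricle, GM, WM, CSF, WMH) and a
perfusion volume; every derived region (distance bands, penumbra shells,
NAWM, lesion clusters) is reconstructed here with the geometry and
tracking modules, never taken from a generator's internal labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import asl, geometry, models, roistats, tracking
from .geometry import DEFAULT_BAND_THRESHOLDS_MM, DEFAULT_PENUMBRA_RADII_MM
from .volumes import LabelVolume

log = logging.getLogger(__name__)

TISSUES = ("GM", "WM", "WMH", "P4", "P8", "NAWM")
REGIONS = ("JV", "PV", "D")


@dataclass
class SubjectMasks:
    """Raw co-registered inputs for one subject/session."""

    ventricle: LabelVolume
    gm: LabelVolume
    wm: LabelVolume
    csf: LabelVolume
    brain: LabelVolume
    wmh: LabelVolume


@dataclass
class RegionProducts:
    """Everything the geometry stage derives from the raw masks."""

    distance: geometry.DistanceMap
    bands: geometry.RegionBands
    shells: geometry.PenumbraShells
    nawm: LabelVolume


def derive_regions(
    masks: SubjectMasks,
    band_thresholds_mm: tuple[float, float] = DEFAULT_BAND_THRESHOLDS_MM,
    penumbra_radii_mm: tuple[float, float] = DEFAULT_PENUMBRA_RADII_MM,
    penumbra_mode: str = "cumulative",
) -> RegionProducts:
    """Distance map, JV/PV/D bands, penumbra shells and NAWM from raw masks."""
    dist = geometry.ventricular_distance(masks.ventricle)
    wm_plus_wmh = LabelVolume(
        masks.wm.astype_mask() | masks.wmh.astype_mask(), masks.wm.voxel_size_mm
    )
    bands = geometry.band_regions(dist, wm_plus_wmh, band_thresholds_mm)
    shells = geometry.penumbra_shells(
        masks.wmh, masks.wm, radii_mm=penumbra_radii_mm, mode=penumbra_mode
    )
    nawm = geometry.nawm_mask(masks.wm, masks.wmh, shells.p8)
    return RegionProducts(distance=dist, bands=bands, shells=shells, nawm=nawm)


def build_roi_masks(masks: SubjectMasks, regions: RegionProducts) -> dict[tuple[str, str], np.ndarray]:
    """The (tissue, region) -> mask dictionary feeding the measurement table.

    Whole-brain rows for every tissue plus banded rows for the white-matter
    tissues (WMH, P4, P8, NAWM).  "WM" is the full white-matter mask;
    "NAWM" excludes lesions and their 8-mm penumbra.
    """
    wmh = masks.wmh.astype_mask()
    tissue_masks: dict[str, np.ndarray] = {
        "GM": masks.gm.astype_mask(),
        "WM": masks.wm.astype_mask() | wmh,
        "WMH": wmh,
        "P4": regions.shells.p4,
        "P8": regions.shells.p8,
        "NAWM": regions.nawm.astype_mask(),
    }
    rois: dict[tuple[str, str], np.ndarray] = {}
    for tissue, mask in tissue_masks.items():
        rois[(tissue, "whole")] = mask
        if tissue in ("WMH", "P4", "P8", "NAWM"):
            for region in REGIONS:
                rois[(tissue, region)] = mask & regions.bands.mask(region)
    return rois


def quantify_session(
    masks: SubjectMasks, cbf: LabelVolume
) -> tuple[LabelVolume, float]:
    """Total-brain-normalized rCBF for one session."""
    return asl.relative_cbf(cbf, masks.brain)


def extract_subject(
    subject: str,
    session: str,
    masks: SubjectMasks,
    cbf: LabelVolume,
    band_thresholds_mm: tuple[float, float] = DEFAULT_BAND_THRESHOLDS_MM,
    penumbra_radii_mm: tuple[float, float] = DEFAULT_PENUMBRA_RADII_MM,
    penumbra_mode: str = "cumulative",
) -> pd.DataFrame:
    """Raw masks + CBF -> tidy ROI rows for one subject/session."""
    rcbf, normalizer = quantify_session(masks, cbf)
    regions = derive_regions(masks, band_thresholds_mm, penumbra_radii_mm, penumbra_mode)
    rois = build_roi_masks(masks, regions)
    table = roistats.extract_roi_means(rcbf, rois, subject, session, masks.brain)
    table["normalizer"] = normalizer
    return table


def track_subject(
    subject: str,
    masks_bl: SubjectMasks,
    masks_fu: SubjectMasks,
    cbf_bl: LabelVolume,
    cbf_fu: LabelVolume,
    connectivity: int = 26,
    min_volume_mm3: float = tracking.DEFAULT_MIN_VOLUME_MM3,
    penumbra_radii_mm: tuple[float, float] = DEFAULT_PENUMBRA_RADII_MM,
) -> pd.DataFrame:
    """Lesion-level longitudinal table for one subject.

    One row per lesion per tissue (WMH/P4/P8) per session, with the lesion's
    band (centroid rule), category, volume and mean baseline/follow-up rCBF.
    New lesions get baseline rows by back-projecting the follow-up footprint
    onto the baseline rCBF map.
    """
    rcbf_bl, _ = quantify_session(masks_bl, cbf_bl)
    rcbf_fu, _ = quantify_session(masks_fu, cbf_fu)
    dist = geometry.ventricular_distance(masks_bl.ventricle)

    clusters_bl = tracking.label_clusters(masks_bl.wmh, "baseline", connectivity, min_volume_mm3)
    clusters_fu = tracking.label_clusters(masks_fu.wmh, "followup", connectivity, min_volume_mm3)
    for cl in clusters_bl + clusters_fu:
        tracking.assign_band(cl, dist)
    trajectories = tracking.match_clusters(clusters_bl, clusters_fu)

    by_id_bl = {c.id: c for c in clusters_bl}
    by_id_fu = {c.id: c for c in clusters_fu}
    rows = []
    for traj in trajectories:
        if traj.category == tracking.VANISHED:
            continue
        fu = by_id_fu.get(traj.followup_id) if traj.followup_id else None
        bl = by_id_bl.get(traj.baseline_id) if traj.baseline_id else None
        anchor = fu if fu is not None else bl
        assert anchor is not None
        lesion_key = f"{subject}:{anchor.session}:{anchor.id}"
        for session, cluster, rcbf, masks in (
            ("baseline", bl, rcbf_bl, masks_bl),
            ("followup", fu, rcbf_fu, masks_fu),
        ):
            footprint_cluster = cluster if cluster is not None else anchor
            # new lesions: baseline ROI = follow-up footprint back-projected
            _, shells = tracking.lesion_rois(
                footprint_cluster, masks.wm, masks.wmh, radii_mm=penumbra_radii_mm
            )
            for tissue, roi in (
                ("WMH", footprint_cluster.voxels),
                ("P4", shells.p4),
                ("P8", shells.p8),
            ):
                mean, n_excluded = tracking.backproject_roi_mean(roi, rcbf, masks.brain)
                rows.append(
                    {
                        "subject": subject,
                        "lesion": lesion_key,
                        "session": session,
                        "tissue": tissue,
                        "location": anchor.band,
                        "category": traj.category,
                        "mean_rcbf": mean,
                        "volume_mm3": (cluster.volume_mm3 if cluster is not None else np.nan),
                        "centroid_distance_mm": anchor.centroid_ventricular_distance_mm,
                        "volume_change_fraction": traj.volume_change_fraction,
                        "n_excluded_voxels": n_excluded,
                    }
                )
    table = pd.DataFrame(rows)
    if len(table):
        with np.errstate(divide="ignore", invalid="ignore"):
            table["log_rcbf"] = np.where(
                table["mean_rcbf"].astype(float) > 0, np.log(table["mean_rcbf"].astype(float)), np.nan
            )
    return table


def cohort_tables(spec, subjects: range | None = None, progress: bool = False):
    """Generate a synthetic cohort in memory and push it through the pipeline.

    Returns (roi_table, lesion_table).  The generator hands over only raw
    masks and painted CBF volumes; all regions are re-derived here.
    """
    from . import synthetic

    roi_parts, lesion_parts = [], []
    indices = subjects if subjects is not None else range(spec.n_subjects)
    for s in indices:
        data = synthetic.generate_subject(spec, s)
        anatomy = data["anatomy"]
        per_session_masks = {}
        for session, sess in data["sessions"].items():
            labels = (
                data["lesions"].baseline_labels if session == "baseline" else data["lesions"].followup_labels
            )
            masks = SubjectMasks(
                ventricle=anatomy.as_volume("ventricle"),
                gm=anatomy.as_volume("gm"),
                wm=anatomy.as_volume("wm"),
                csf=anatomy.as_volume("csf"),
                brain=anatomy.as_volume("brain"),
                wmh=LabelVolume(labels > 0, anatomy.voxel_size_mm),
            )
            per_session_masks[session] = (masks, sess["cbf"])
            roi_parts.append(extract_subject(f"sub-{s:03d}", session, masks, sess["cbf"]))
        if "followup" in per_session_masks:
            (m_bl, c_bl), (m_fu, c_fu) = per_session_masks["baseline"], per_session_masks["followup"]
            lesion_parts.append(track_subject(f"sub-{s:03d}", m_bl, m_fu, c_bl, c_fu))
        if progress:
            log.info("processed subject %d", s)
    roi_table = pd.concat(roi_parts, ignore_index=True)
    lesion_table = (
        pd.concat([t for t in lesion_parts if len(t)], ignore_index=True)
        if any(len(t) for t in lesion_parts)
        else pd.DataFrame()
    )
    return roi_table, lesion_table


def fit_all(roi_table: pd.DataFrame, lesion_table: pd.DataFrame | None = None) -> dict:
    """Fit the three model families plus supplementary analyses."""
    transformed, meta = roistats.transform(roi_table)
    out: dict = {"transform_meta": meta}
    out["tissue_location"] = models.fit_tissue_location_model(transformed)
    try:
        out["volume_location"] = models.fit_volume_location_model(transformed)
    except ValueError as err:
        log.warning("volume-location model skipped: %s", err)
    try:
        out["anova_volume"] = models.anova_volume_by_location(transformed)
    except ValueError as err:
        log.warning("volume ANOVA skipped: %s", err)
    if lesion_table is not None and len(lesion_table):
        out["table2"] = models.table2_report(lesion_table)
        out["centroid_distance"] = models.centroid_distance_model(lesion_table)
    return out


def summarize_tissue_means(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean (and SE) rCBF per tissue/region — the figure-level summary."""
    grp = roi_table.dropna(subset=["mean_rcbf"]).groupby(["tissue", "region"])["mean_rcbf"]
    out = grp.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_rcbf", "sem": "se", "count": "n"})
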