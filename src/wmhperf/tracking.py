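"""Individual-lesion identification, cross-session matching and trajectories.

A lesion is a connected component of the WMH mask (26-connectivity by
default) with physical volume of at least 10 mm^3; smaller clusters are
treated as segmentation noise and dropped.  Follow-up lesions are matched
to baseline lesions by voxel overlap and classified by fractional volume
change: growing (> +10%), stagnant (|change| < 10%), shrinking (<= -10%),
new (present only at follow-up), vanished (present only at baseline).
The boundary at exactly +10% is stagnant (the growing rule is a strict
inequality); shrinking and vanished lesions are first-class outputs but
are excluded from the three-category longitudinal models.

Per-lesion penumbra ROIs are 4/8-mm WM shells around the single lesion,
always excluding *all* WMH voxels of the session so adjacent lesions never
leak into each other's shells.  For new lesions, baseline perfusion is read
by back-projecting the follow-up footprint onto the baseline rCBF map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import geometry
from .geometry import DistanceMap, PenumbraShells
from .volumes import LabelVolume

STAGNANT, GROWING, NEW, SHRINKING, VANISHED = "stagnant", "growing", "new", "shrinking", "vanished"
MODEL_CATEGORIES = (STAGNANT, GROWING, NEW)
DEFAULT_MIN_VOLUME_MM3 = 10.0
DEFAULT_GROWTH_THRESHOLD = 0.10

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LesionCluster:
    """One connected WMH lesion in one session."""

    id: int
    session: str
    voxels: np.ndarray  # boolean mask on the full grid
    volume_mm3: float
    centroid_mm: tuple[float, float, float]
    band: str | None = None
    centroid_ventricular_distance_mm: float | None = None
    majority_band: str | None = None
    band_rules_disagree: bool = False


@dataclass
class LesionTrajectory:
    """A lesion tracked across the two sessions."""

    baseline_id: int | None
    followup_id: int | None
    category: str
    volume_change_fraction: float | None
    baseline_volume_mm3: float | None = None
    followup_volume_mm3: float | None = None
    merged_parents: tuple[int, ...] = ()
    below_floor_parent: bool = False


def label_clusters(
    wmh: LabelVolume,
    session: str = "baseline",
    connectivity: int = 26,
    min_volume_mm3: float = DEFAULT_MIN_VOLUME_MM3,
) -> list[LesionCluster]:
    """Connected-component lesions with the < 10 mm^3 noise floor applied.

    Clusters with volume strictly below ``min_volume_mm3`` are dropped;
    a cluster at exactly the floor is kept.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}, got {connectivity}")
    mask = wmh.astype_mask()
    labels, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    vox_vol = wmh.voxel_volume_mm3
    clusters: list[LesionCluster] = []
    next_id = 1
    for lab in range(1, n + 1):
        voxels = labels == lab
        volume = float(np.count_nonzero(voxels)) * vox_vol
        if volume < min_volume_mm3:
            continue
        idx = np.argwhere(voxels)
        centroid = tuple(float(c) for c in (idx.mean(axis=0) * np.asarray(wmh.voxel_size_mm)))
        clusters.append(
            LesionCluster(id=next_id, session=session, voxels=voxels, volume_mm3=volume, centroid_mm=centroid)  # type: ignore[arg-type]
        )
        next_id += 1
    return clusters


def assign_band(
    cluster: LesionCluster,
    dist: DistanceMap,
    rule: str = "centroid",
    thresholds_mm: tuple[float, float] = geometry.DEFAULT_BAND_THRESHOLDS_MM,
) -> str:
    """Assign a JV/PV/D band to a lesion and record both rules' answers.

    ``centroid`` (default) bands the ventricular distance at the lesion
    centroid; ``majority`` takes the modal voxelwise band.  The centroid
    distance is always recorded (it is the covariate of the supplementary
    distance model), and a flag is set when the two rules disagree, as can
    happen for elongated lesions spanning a band boundary.
    """
    if rule not in ("centroid", "majority"):
        raise ValueError(f"unknown band rule {rule!r}")
    vs = np.asarray(dist.voxel_size_mm)
    centroid_vox = np.asarray(cluster.centroid_mm) / vs
    # distance at the voxel whose centre is nearest the centroid
    nearest = tuple(int(round(c)) for c in centroid_vox)
    nearest = tuple(np.clip(nearest, 0, np.asarray(dist.values.shape) - 1))
    d_centroid = float(dist.values[nearest])
    centroid_band = geometry.band_of_distance(d_centroid, thresholds_mm)

    voxel_d = dist.values[cluster.voxels]
    voxel_bands = [geometry.band_of_distance(d, thresholds_mm) for d in voxel_d]
    values, counts = np.unique(voxel_bands, return_counts=True)
    majority_band = str(values[np.argmax(counts)])

    cluster.centroid_ventricular_distance_mm = d_centroid
    cluster.majority_band = majority_band
    cluster.band_rules_disagree = centroid_band != majority_band
    cluster.band = centroid_band if rule == "centroid" else majority_band
    return cluster.band


def match_clusters(
    baseline: list[LesionCluster],
    followup: list[LesionCluster],
    min_overlap_fraction: float = 0.0,
    below_floor_baseline: np.ndarray | None = None,
) -> list[LesionTrajectory]:
    """Match follow-up lesions to baseline lesions by voxel overlap.

    A follow-up cluster is matched to the baseline cluster with which it
    shares the most voxels (>= 1 voxel, or ``min_overlap_fraction`` of the
    follow-up volume if set); ties go to the lower baseline id.  Unmatched
    follow-up clusters are new; unmatched baseline clusters are vanished.
    A follow-up cluster overlapping several baseline clusters (a merge) is
    assigned to the largest-overlap parent with all parents recorded.

    ``below_floor_baseline``: optional mask of baseline WMH voxels that fell
    below the size floor; a "new" lesion overlapping it is flagged, since its
    baseline partner existed but was discarded as noise.

    The assignment is one-to-one: a baseline cluster whose footprint splits
    into several follow-up clusters is paired with the largest-overlap one
    only, so every follow-up cluster lands in exactly one trajectory and
    every baseline cluster in at most one.
    """
    overlaps_by_fu: dict[int, list[tuple[int, int]]] = {}
    edges: list[tuple[int, int, int]] = []  # (overlap voxels, baseline id, followup id)
    for fu in followup:
        overlaps: list[tuple[int, int]] = []
        for bl in baseline:
            if bl.voxels.shape != fu.voxels.shape:
                raise ValueError("baseline and follow-up masks are on different grids")
            ov = int(np.count_nonzero(bl.voxels & fu.voxels))
            if ov > 0 and ov >= min_overlap_fraction * np.count_nonzero(fu.voxels):
                overlaps.append((ov, bl.id))
                edges.append((ov, bl.id, fu.id))
        overlaps.sort(key=lambda t: (-t[0], t[1]))
        overlaps_by_fu[fu.id] = overlaps

    # greedy maximal-overlap one-to-one assignment, ties by lower ids
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    parent_of: dict[int, int] = {}
    matched_baseline: set[int] = set()
    for ov, bl_id, fu_id in edges:
        if fu_id in parent_of or bl_id in matched_baseline:
            continue
        parent_of[fu_id] = bl_id
        matched_baseline.add(bl_id)

    by_id_bl = {c.id: c for c in baseline}
    trajectories: list[LesionTrajectory] = []
    for fu in followup:
        if fu.id not in parent_of:
            flagged = bool(
                below_floor_baseline is not None and np.count_nonzero(fu.voxels & below_floor_baseline)
            )
            trajectories.append(
                LesionTrajectory(
                    baseline_id=None,
                    followup_id=fu.id,
                    category=NEW,
                    volume_change_fraction=None,
                    followup_volume_mm3=fu.volume_mm3,
                    below_floor_parent=flagged,
                )
            )
            continue
        parent = by_id_bl[parent_of[fu.id]]
        overlaps = overlaps_by_fu[fu.id]
        fraction = (fu.volume_mm3 - parent.volume_mm3) / parent.volume_mm3
        trajectories.append(
            LesionTrajectory(
                baseline_id=parent.id,
                followup_id=fu.id,
                category=categorize(fraction),
                volume_change_fraction=fraction,
                baseline_volume_mm3=parent.volume_mm3,
                followup_volume_mm3=fu.volume_mm3,
                merged_parents=tuple(bid for _, bid in overlaps) if len(overlaps) > 1 else (),
            )
        )
    for bl in baseline:
        if bl.id not in matched_baseline:
            trajectories.append(
                LesionTrajectory(
                    baseline_id=bl.id,
                    followup_id=None,
                    category=VANISHED,
                    volume_change_fraction=-1.0,
                    baseline_volume_mm3=bl.volume_mm3,
                )
            )
    return trajectories


def categorize(volume_change_fraction: float, threshold: float = DEFAULT_GROWTH_THRESHOLD) -> str:
    """Category from fractional volume change (V_fu - V_bl)/V_bl.

    Strictly > +threshold is growing; |change| < threshold is stagnant;
    <= -threshold is shrinking.  Exactly +threshold is stagnant.
    """
    if volume_change_fraction > threshold:
        return GROWING
    if volume_change_fraction <= -threshold:
        return SHRINKING
    return STAGNANT


def lesion_rois(
    cluster: LesionCluster,
    wm: LabelVolume,
    all_wmh: LabelVolume,
    radii_mm: tuple[float, float] = geometry.DEFAULT_PENUMBRA_RADII_MM,
    mode: str = "cumulative",
) -> tuple[np.ndarray, PenumbraShells]:
    """Lesion mask plus its per-lesion 4/8-mm penumbra shells.

    Shells are centred on this lesion but exclude every WMH voxel of the
    session, so adjacent lesions never contribute voxels to each other's
    penumbra.  The penumbra ROI inherits the lesion's trajectory category.
    """
    single = LabelVolume(data=cluster.voxels, voxel_size_mm=wm.voxel_size_mm)
    shells = geometry.penumbra_shells(
        single, wm, radii_mm=radii_mm, mode=mode, exclude_wmh=all_wmh.astype_mask()
    )
    return cluster.voxels, shells


def backproject_roi_mean(roi_mask: np.ndarray, baseline_rcbf: LabelVolume, baseline_brain_mask: LabelVolume) -> tuple[float | None, int]:
    """Mean baseline rCBF under a follow-up footprint (pre-lesional tissue).

    Voxels falling outside the baseline brain mask are excluded and counted;
    an empty footprint yields (None, excluded count) rather than an error.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    brain = baseline_brain_mask.astype_mask()
    usable = roi & brain
    n_excluded = int(np.count_nonzero(roi & ~brain))
    if not usable.any():
        return None, n_excluded
    return float(np.asarray(baseline_rcbf.data, dtype=float)[usable].mean()), n_excluded
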