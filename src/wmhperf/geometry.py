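"""Distance-based white-matter geometry.

Everything downstream of segmentation rests on four operations:

* a Euclidean distance transform from the ventricular surface, computed in
  physical millimetres on anisotropic grids (``ventricular_distance``);
* the partition of white matter into juxtaventricular (JV, distance <= 3 mm),
  periventricular (PV, 3-10 mm) and deep (D, > 10 mm) bands
  (``band_regions``);
* penumbra shells of white matter within 4 and 8 mm of a lesion
  (``penumbra_shells``), in cumulative (0-r mm) or annular mode;
* normal-appearing white matter, i.e. WM with lesions and their 8-mm
  penumbra removed (``nawm_mask``).

Distances are measured from voxel centre to the nearest source voxel centre
(standard exact-EDT semantics), so a threshold of "3 mm" is interpretable
voxel-by-voxel.  Band boundaries are closed on the inner side: d = 3 mm is
JV, d = 10 mm is PV, keeping the three bands a partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, VoxelSize

JV, PV, DEEP = "JV", "PV", "D"
BAND_CODES = {JV: 1, PV: 2, DEEP: 3}
DEFAULT_BAND_THRESHOLDS_MM = (3.0, 10.0)
DEFAULT_PENUMBRA_RADII_MM = (4.0, 8.0)


@dataclass
class DistanceMap:
    """Per-voxel physical distance (mm) to the nearest source-mask voxel."""

    values: np.ndarray
    voxel_size_mm: VoxelSize

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class RegionBands:
    """JV/PV/D band label per WM(+WMH) voxel; 0 outside the mask."""

    labels: np.ndarray  # uint8 coded via BAND_CODES
    thresholds_mm: tuple[float, float] = DEFAULT_BAND_THRESHOLDS_MM

    def mask(self, band: str) -> np.ndarray:
        return self.labels == BAND_CODES[band]


@dataclass
class PenumbraShells:
    """WM shells around lesions; lesion voxels are never part of a shell."""

    p4: np.ndarray
    p8: np.ndarray
    radii_mm: tuple[float, float] = DEFAULT_PENUMBRA_RADII_MM
    mode: str = "cumulative"


def distance_from_mask(mask: np.ndarray, voxel_size_mm: VoxelSize) -> np.ndarray:
    """Exact EDT in mm from the voxel centres of ``mask`` (0 on the mask)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("source mask is empty; distances are undefined")
    return ndimage.distance_transform_edt(~mask, sampling=voxel_size_mm)


def ventricular_distance(ventricle: LabelVolume, voxel_size_mm: VoxelSize | None = None) -> DistanceMap:
    """Distance map (mm) from the ventricular system.

    Raises
    ------
    ValueError
        If the ventricle mask is empty (the JV/PV/D bands would be undefined).
    """
    vs = voxel_size_mm if voxel_size_mm is not None else ventricle.voxel_size_mm
    mask = ventricle.astype_mask()
    if not mask.any():
        raise ValueError("ventricle mask is empty: JV/PV/D bands are undefined")
    return DistanceMap(values=distance_from_mask(mask, vs), voxel_size_mm=tuple(vs))  # type: ignore[arg-type]


def band_regions(
    dist: DistanceMap,
    wm_plus_wmh: LabelVolume,
    thresholds_mm: tuple[float, float] = DEFAULT_BAND_THRESHOLDS_MM,
) -> RegionBands:
    """Partition the WM+WMH voxel set into JV/PV/D by ventricular distance.

    Every mask voxel gets exactly one band: JV iff d <= t1, PV iff
    t1 < d <= t2, D iff d > t2 (defaults t1, t2 = 3, 10 mm).
    """
    if dist.values.shape != wm_plus_wmh.shape:
        raise ValueError(
            f"distance map {dist.values.shape} and mask {wm_plus_wmh.shape} are on different grids"
        )
    t1, t2 = thresholds_mm
    if not 0 < t1 < t2:
        raise ValueError(f"band thresholds must satisfy 0 < t1 < t2, got {thresholds_mm}")
    mask = wm_plus_wmh.astype_mask()
    d = dist.values
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[mask & (d <= t1)] = BAND_CODES[JV]
    labels[mask & (d > t1) & (d <= t2)] = BAND_CODES[PV]
    labels[mask & (d > t2)] = BAND_CODES[DEEP]
    return RegionBands(labels=labels, thresholds_mm=(float(t1), float(t2)))


def band_of_distance(d_mm: float, thresholds_mm: tuple[float, float] = DEFAULT_BAND_THRESHOLDS_MM) -> str:
    """Band of a single physical distance, same boundary convention as above."""
    t1, t2 = thresholds_mm
    if d_mm <= t1:
        return JV
    if d_mm <= t2:
        return PV
    return DEEP


def penumbra_shells(
    wmh: LabelVolume,
    wm: LabelVolume,
    radii_mm: tuple[float, float] = DEFAULT_PENUMBRA_RADII_MM,
    mode: str = "cumulative",
    exclude_wmh: np.ndarray | None = None,
) -> PenumbraShells:
    """WM shells within 4 and 8 mm of a lesion mask.

    ``wmh`` may be a single lesion (lesion-specific ROIs) or the union of all
    lesions (cross-sectional masks).  Shells always exclude ``exclude_wmh``
    (defaults to ``wmh`` itself); pass the union of all lesions there when
    building per-lesion ROIs so no shell contains any lesion voxel.

    In ``cumulative`` mode shell r = {WM : 0 < d <= r}; in ``annular`` mode
    the outer shell is {WM : r1 < d <= r2}.
    """
    wm.require_same_grid(wmh, "WM and WMH masks")
    if mode not in ("cumulative", "annular"):
        raise ValueError(f"mode must be 'cumulative' or 'annular', got {mode!r}")
    r1, r2 = radii_mm
    if not 0 < r1 < r2:
        raise ValueError(f"penumbra radii must satisfy 0 < r1 < r2, got {radii_mm}")
    wmh_mask = wmh.astype_mask()
    wm_mask = wm.astype_mask()
    excl = wmh_mask if exclude_wmh is None else np.asarray(exclude_wmh, dtype=bool)
    if not wmh_mask.any():
        warnings.warn("empty WMH mask: penumbra shells are empty", stacklevel=2)
        empty = np.zeros(wm_mask.shape, dtype=bool)
        return PenumbraShells(p4=empty, p8=empty.copy(), radii_mm=(float(r1), float(r2)), mode=mode)
    d = distance_from_mask(wmh_mask, wmh.voxel_size_mm)
    eligible = wm_mask & ~excl
    p4 = eligible & (d > 0) & (d <= r1)
    if mode == "cumulative":
        p8 = eligible & (d > 0) & (d <= r2)
    else:
        p8 = eligible & (d > r1) & (d <= r2)
    return PenumbraShells(p4=p4, p8=p8, radii_mm=(float(r1), float(r2)), mode=mode)


def nawm_mask(wm: LabelVolume, wmh: LabelVolume, p8: np.ndarray) -> LabelVolume:
    """Normal-appearing WM: WM minus lesions and their 8-mm penumbra."""
    wm.require_same_grid(wmh, "WM and WMH masks")
    if np.asarray(p8).shape != wm.shape:
        raise ValueError(f"P8 shell shape {np.asarray(p8).shape} != WM shape {wm.shape}")
    nawm = wm.astype_mask() & ~wmh.astype_mask() & ~np.asarray(p8, dtype=bool)
    return LabelVolume(data=nawm, voxel_size_mm=wm.voxel_size_mm)
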