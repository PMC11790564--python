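"""Synthetic two-session WMH/perfusion cohorts with known ground truth.

No public dataset accompanies the analysis this package implements, so every
stage is exercised on simulated cohorts that emulate its FLAIR-space inputs:
~1x1x2 mm grids holding a central ventricular system, a white-matter shell
around it, an outer gray-matter ribbon, WMH lesions planted at controlled
ventricular distances with log-normal-ish sizes, two sessions ~2 years apart
with planted stagnant/growing/new lesions, and perfusion volumes painted so
that each tissue's total-brain-relative mean equals a configurable factor.

Two levels of simulation are provided:

* image-level (``generate_anatomy`` / ``plant_lesions`` / ``paint_cbf`` /
  ``emit_cohort``): full volumes, used to test the geometric pipeline
  end-to-end.  The generator paints perfusion using its *own* labels and its
  own band/shell computations; the pipeline must independently reconstruct
  the same regions from the raw masks.
* table-level (``simulate_tissue_location_table`` and friends): draws
  measurement tables directly from the mixed-model data-generating process,
  used to test coefficient recovery at realistic cohort sizes without
  volumetric cost.

Lesions are spherical-ish blobs clipped to WM; growing lesions expand by
geodesic dilation inside WM so masks stay physically valid.  Voxel noise is
independent Gaussian with a configurable coefficient of variation; there is
no spatial autocorrelation (a documented limitation).  The CSF/ventricular
compartment is painted at the single value that makes the pre-noise mean
over the brain mask equal the nominal brain CBF exactly, so the total-brain
normalizer is conserved by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelVolume

BAND_NAMES = ("JV", "PV", "D")
CATEGORIES = ("stagnant", "growing", "new", "shrinking")

# Fig-2-level tissue factors (relative to the total-brain mean):
# GM 1.315, NAWM 1.067, WMH 0.814, penumbra 0-4 mm 0.845, cumulative
# 0-8 mm 0.880.  "P8" is the *cumulative* 0-8 mm target; the 4-8 mm annulus
# value is solved per subject so the cumulative mean lands on target.
DEFAULT_FACTORS = {"GM": 1.315, "NAWM": 1.067, "WMH": 0.814, "P4": 0.845, "P8": 0.880}

# Fig-3-level band-specific factors for WMH and NAWM.
BANDED_FACTORS = {
    "GM": 1.315,
    "WMH": 0.814,
    "P4": 0.845,
    "P8": 0.880,
    "WMH:JV": 0.495,
    "WMH:PV": 0.592,
    "WMH:D": 0.892,
    "NAWM:JV": 0.816,
    "NAWM:PV": 0.973,
    "NAWM:D": 1.156,
    "NAWM": 1.067,
}


@dataclass
class CohortSpec:
    """Everything the generator needs; defaults mirror the study cohort.

    ``n_subjects`` / ``n_longitudinal`` default to the study's 300 baseline /
    90 follow-up participants; experiments typically scale these down.
    Demographics default to the reported baseline table: age 77 (7.9) years,
    MMSE 28 (2.4), 199/300 female, inter-scan interval 1.9 (0.7) years.
    ``nominal_brain_cbf`` is a free parameter (no absolute per-tissue CBF is
    reported); 40 ml/100g/min is a typical whole-brain value for this age.
    """

    n_subjects: int = 300
    n_longitudinal: int = 90
    grid_shape: tuple[int, int, int] = (96, 96, 48)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    tissue_rcbf_factors: dict = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    nominal_brain_cbf: float = 40.0  # ml/100g/min
    voxel_noise_cv: float = 0.05
    lesion_count_dist: dict = field(default_factory=lambda: {"kind": "poisson", "mean": 8.0, "min": 3})
    lesion_radius_dist_mm: dict = field(
        default_factory=lambda: {"kind": "lognormal", "median": 3.0, "sigma": 0.35, "min": 1.6, "max": 7.0}
    )
    category_fractions: dict = field(
        default_factory=lambda: {"stagnant": 0.5, "growing": 0.3, "new": 0.2, "shrinking": 0.0}
    )
    band_fractions: dict = field(default_factory=lambda: {"JV": 0.4, "PV": 0.35, "D": 0.25})
    growth_factor_dist: dict = field(
        default_factory=lambda: {"kind": "lognormal", "median": 1.30, "sigma": 0.10, "min": 1.15, "max": 2.0}
    )
    shrink_factor: float = 0.70
    new_lesion_baseline_log_offset: float = 0.0  # planted pre-lesional deficit
    inter_scan_years: tuple[float, float] = (1.9, 0.7)
    age_years: tuple[float, float] = (77.0, 7.9)
    mmse: tuple[float, float] = (28.0, 2.4)
    female_fraction: float = 199 / 300
    band_thresholds_mm: tuple[float, float] = (3.0, 10.0)
    penumbra_radii_mm: tuple[float, float] = (4.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_fractions must sum to 1, got {total}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if self.voxel_noise_cv < 0:
            raise ValueError("voxel_noise_cv must be >= 0")
        if any(v <= 0 for v in self.tissue_rcbf_factors.values()):
            raise ValueError("tissue_rcbf_factors must all be positive")
        if abs(sum(self.band_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("band_fractions must sum to 1")


@dataclass
class Anatomy:
    """Per-subject anatomical labels; mutually disjoint, tiling the brain."""

    ventricle: np.ndarray
    csf: np.ndarray
    wm: np.ndarray
    gm: np.ndarray
    brain: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def as_volume(self, name: str) -> LabelVolume:
        return LabelVolume(data=getattr(self, name), voxel_size_mm=self.voxel_size_mm)


@dataclass
class PlantedLesions:
    """Baseline and follow-up lesion label maps plus the truth table."""

    baseline_labels: np.ndarray  # int lesion ids, 0 = background
    followup_labels: np.ndarray
    truth: pd.DataFrame  # one row per lesion


@dataclass
class PaintedTruth:
    """Region labels the generator itself used when painting a session."""

    band_labels: np.ndarray  # 1=JV, 2=PV, 3=D over WM+WMH, 0 elsewhere
    p4: np.ndarray
    p8_annulus: np.ndarray
    nawm: np.ndarray
    factor_map: np.ndarray
    csf_value_factor: float
    p8_annulus_factor: float


# --------------------------------------------------------------------------
# random draws

def _rng(spec: CohortSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, *stream])


def _draw(dist: dict, rng: np.random.Generator, size: int | None = None):
    kind = dist["kind"]
    if kind == "poisson":
        x = rng.poisson(dist["mean"], size=size)
        return np.maximum(x, dist.get("min", 0))
    if kind == "lognormal":
        x = np.exp(rng.normal(np.log(dist["median"]), dist["sigma"], size=size))
        return np.clip(x, dist.get("min", 0.0), dist.get("max", np.inf))
    if kind == "fixed":
        return np.full(size, dist["value"]) if size else dist["value"]
    raise ValueError(f"unknown distribution kind {kind!r}")


def _choice(rng: np.random.Generator, fractions: dict) -> str:
    names = sorted(fractions)
    p = np.array([fractions[n] for n in names], dtype=float)
    return str(rng.choice(names, p=p / p.sum()))


# --------------------------------------------------------------------------
# anatomy

def _ellipsoid(shape, voxel_size, center_mm, semiaxes_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(shape, voxel_size)], indexing="ij"
    )
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return rho2 <= 1.0


def generate_anatomy(spec: CohortSpec, subject_index: int) -> Anatomy:
    """Nested-shell anatomy: ventricle, thin CSF rim, WM shell, GM ribbon.

    Deterministic given (spec.seed, subject_index).  Raises a sizing error
    naming the limiting axis when the WM shell cannot contain the deep band
    (ventricular distance beyond the outer band threshold).
    """
    rng = _rng(spec, subject_index, 0)
    shape = spec.grid_shape
    vs = spec.voxel_size_mm
    extent = np.array(shape) * np.array(vs)
    center = extent / 2.0

    brain_ax = extent / 2.0 - 3.0 + rng.uniform(-1.5, 1.5, size=3)
    vent_ax = np.array([10.0, 16.0, 8.0]) * rng.uniform(0.85, 1.15, size=3)
    vent_center = center + rng.uniform(-2.0, 2.0, size=3)

    # nested shells (fractions of the brain radius): an outer sulcal-CSF
    # ribbon, a GM ribbon, then WM surrounding the periventricular CSF rim
    # and ventricle.  The sizeable CSF fraction (~20% of the brain mask) is
    # what lets parenchymal factors > 1 coexist with a total-brain mean of 1.
    gm_outer = 0.93 * brain_ax
    wm_outer = 0.80 * brain_ax
    csf_ax = vent_ax + 1.2  # thin ependymal CSF rim around the ventricle

    _, t2 = spec.band_thresholds_mm
    margin = 3.0  # mm of deep WM beyond the outer threshold
    for axis, name in enumerate("xyz"):
        if wm_outer[axis] - csf_ax[axis] < t2 + margin:
            raise ValueError(
                f"grid too small along {name}: WM shell spans "
                f"{wm_outer[axis] - csf_ax[axis]:.1f} mm but the deep band needs "
                f"> {t2 + margin:.1f} mm beyond the ventricular surface"
            )

    brain = _ellipsoid(shape, vs, center, brain_ax)
    gm_region = _ellipsoid(shape, vs, center, gm_outer)
    wm_region = _ellipsoid(shape, vs, center, wm_outer)
    ventricle = _ellipsoid(shape, vs, vent_center, vent_ax)
    csf_rim = _ellipsoid(shape, vs, vent_center, csf_ax)

    vent = ventricle & brain
    csf = (csf_rim & ~ventricle & brain) | (brain & ~gm_region)
    wm = wm_region & ~csf_rim & brain
    gm = gm_region & ~wm_region & brain
    return Anatomy(ventricle=vent, csf=csf, wm=wm, gm=gm, brain=brain, voxel_size_mm=vs)


# --------------------------------------------------------------------------
# lesions

TRUTH_COLUMNS = [
    "subject",
    "lesion",
    "category",
    "band",
    "centroid_distance_mm",
    "baseline_voxels",
    "followup_voxels",
    "baseline_volume_mm3",
    "followup_volume_mm3",
    "growth_factor_target",
    "growth_factor_actual",
    "baseline_log_offset",
]

_MIN_GROWING_VOXELS = 25  # keeps one-voxel rounding within 2% of the target ratio


def plant_lesions(anatomy: Anatomy, spec: CohortSpec, subject_index: int) -> PlantedLesions:
    """Plant lesions with known band, category and growth factor.

    Each lesion is a spherical-ish blob clipped to WM, placed so its centroid
    ventricular distance falls inside the target band; growing lesions are
    dilated geodesically inside WM at follow-up, adding the nearest outside
    WM voxels until the volume ratio is within one voxel of the sampled
    growth factor (within +/-2% given the enforced minimum baseline size).
    All planted lesions have volume >= 10 mm^3.
    """
    rng = _rng(spec, subject_index, 1)
    vs = np.asarray(anatomy.voxel_size_mm)
    vox_vol = float(np.prod(vs))
    wm = anatomy.wm
    vent_dist = ndimage.distance_transform_edt(~anatomy.ventricle, sampling=tuple(vs))
    t1, t2 = spec.band_thresholds_mm

    band_windows = {
        "JV": (0.0, t1 - 0.4),
        "PV": (t1 + 0.8, t2 - 0.8),
        "D": (t2 + 1.2, np.inf),
    }

    n_lesions = int(_draw(spec.lesion_count_dist, rng))
    baseline = np.zeros(anatomy.wm.shape, dtype=np.int32)
    followup = np.zeros_like(baseline)
    occupied = np.zeros(anatomy.wm.shape, dtype=bool)
    rows = []
    lesion_id = 0

    for _ in range(n_lesions):
        category = _choice(rng, spec.category_fractions)
        band = _choice(rng, spec.band_fractions)
        placed = None
        for _attempt in range(30):
            radius = float(_draw(spec.lesion_radius_dist_mm, rng))
            if category == "growing":
                radius = max(radius, 2.6)  # baseline must be big enough to dilate precisely
            lo, hi = band_windows[band]
            candidates = wm & (vent_dist > lo) & (vent_dist <= hi) & ~_near(occupied, vs, radius + 5.0)
            idx = np.flatnonzero(candidates)
            if idx.size == 0:
                continue
            center_flat = int(rng.choice(idx))
            center = np.unravel_index(center_flat, wm.shape)
            center_mm = np.asarray(center) * vs
            semiaxes = radius * rng.uniform(0.85, 1.2, size=3)
            blob = _ellipsoid(wm.shape, tuple(vs), center_mm, semiaxes) & wm & ~occupied
            n_vox = int(np.count_nonzero(blob))
            if n_vox * vox_vol < 10.0:
                continue
            if category == "growing" and n_vox < _MIN_GROWING_VOXELS:
                continue
            d_centroid = _centroid_distance(blob, vent_dist)
            if not (band_windows[band][0] < d_centroid <= min(band_windows[band][1], 1e9)):
                if _band_of(d_centroid, t1, t2) != band:
                    continue
            placed = (blob, n_vox, d_centroid)
            break
        if placed is None:
            continue  # placement failure after retries; reported via truth counts
        blob, n_vox, d_centroid = placed
        lesion_id += 1
        target_f = np.nan
        actual_f = np.nan
        if category == "stagnant":
            baseline[blob] = lesion_id
            followup[blob] = lesion_id
            n_bl, n_fu = n_vox, n_vox
            actual_f = 1.0
        elif category == "growing":
            target_f = float(_draw(spec.growth_factor_dist, rng))
            grown = _geodesic_resize(blob, wm & ~occupied, vs, round(n_vox * target_f))
            baseline[blob] = lesion_id
            followup[grown] = lesion_id
            n_bl, n_fu = n_vox, int(np.count_nonzero(grown))
            actual_f = n_fu / n_bl
            blob = grown  # occupied must cover the grown extent
        elif category == "shrinking":
            target_f = spec.shrink_factor
            shrunk = _geodesic_resize(blob, wm, vs, max(5, round(n_vox * target_f)))
            baseline[blob] = lesion_id
            followup[shrunk] = lesion_id
            n_bl, n_fu = n_vox, int(np.count_nonzero(shrunk))
            actual_f = n_fu / n_bl
        else:  # new
            followup[blob] = lesion_id
            n_bl, n_fu = 0, n_vox
            actual_f = np.nan
        occupied |= blob
        rows.append(
            {
                "subject": subject_index,
                "lesion": lesion_id,
                "category": category,
                "band": _band_of(d_centroid, t1, t2),
                "centroid_distance_mm": d_centroid,
                "baseline_voxels": n_bl,
                "followup_voxels": n_fu,
                "baseline_volume_mm3": n_bl * vox_vol,
                "followup_volume_mm3": n_fu * vox_vol,
                "growth_factor_target": target_f,
                "growth_factor_actual": actual_f,
                "baseline_log_offset": spec.new_lesion_baseline_log_offset if category == "new" else 0.0,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return PlantedLesions(baseline_labels=baseline, followup_labels=followup, truth=truth)


def _near(occupied: np.ndarray, vs: np.ndarray, radius_mm: float) -> np.ndarray:
    """Voxels within radius_mm of any occupied voxel (cheap exclusion zone)."""
    if not occupied.any():
        return np.zeros_like(occupied)
    d = ndimage.distance_transform_edt(~occupied, sampling=tuple(vs))
    return d <= radius_mm


def _centroid_distance(blob: np.ndarray, vent_dist: np.ndarray) -> float:
    idx = np.argwhere(blob)
    c = idx.mean(axis=0)
    nearest = tuple(int(round(x)) for x in c)
    nearest = tuple(np.clip(nearest, 0, np.asarray(blob.shape) - 1))
    return float(vent_dist[nearest])


def _band_of(d: float, t1: float, t2: float) -> str:
    return "JV" if d <= t1 else ("PV" if d <= t2 else "D")


def _geodesic_resize(blob: np.ndarray, allowed: np.ndarray, vs: np.ndarray, target_voxels: int) -> np.ndarray:
    """Grow (or trim) a blob to target_voxels, staying inside ``allowed``.

    Growth adds outside-but-allowed voxels in order of physical distance to
    the blob (ties by flat index, so the result is deterministic); trimming
    removes the outermost blob voxels by distance from the blob's complement.
    """
    n = int(np.count_nonzero(blob))
    if target_voxels == n:
        return blob.copy()
    if target_voxels > n:
        d = ndimage.distance_transform_edt(~blob, sampling=tuple(vs))
        candidates = np.flatnonzero(allowed & ~blob)
        order = candidates[np.lexsort((candidates, d.ravel()[candidates]))]
        take = order[: target_voxels - n]
        out = blob.copy()
        out.ravel()[take] = True
        return out
    d_in = ndimage.distance_transform_edt(blob, sampling=tuple(vs))
    inside = np.flatnonzero(blob)
    order = inside[np.lexsort((inside, d_in.ravel()[inside]))]  # shallowest first
    drop = order[: n - target_voxels]
    out = blob.copy()
    out.ravel()[drop] = False
    return out


# --------------------------------------------------------------------------
# perfusion painting

def paint_cbf(
    anatomy: Anatomy,
    lesions: PlantedLesions,
    spec: CohortSpec,
    session: str,
) -> tuple[LabelVolume, PaintedTruth]:
    """Paint a perfusion volume for one session from the generator's labels.

    Voxel value = nominal_brain_cbf x factor(tissue at voxel) x (1 + noise),
    where the tissue factor comes from ``spec.tissue_rcbf_factors`` (keys like
    ``"GM"``, ``"WMH"``, ``"P4"``, ``"NAWM"``; band-specific overrides like
    ``"WMH:JV"``).  ``"P8"`` is the cumulative 0-8 mm penumbra target and the
    4-8 mm annulus value is solved per subject so the cumulative mean lands on
    it exactly.  CSF/ventricle voxels get the single calibrated value that
    makes the pre-noise brain-mask mean equal nominal_brain_cbf exactly.

    Planted "new" lesions may carry a baseline log-rCBF offset (pre-lesional
    hypoperfusion) applied under their follow-up footprint at baseline.
    """
    if session not in ("baseline", "followup"):
        raise ValueError(f"session must be 'baseline' or 'followup', got {session!r}")
    vs = np.asarray(anatomy.voxel_size_mm)
    factors = spec.tissue_rcbf_factors
    wmh = (lesions.baseline_labels if session == "baseline" else lesions.followup_labels) > 0
    t1, t2 = spec.band_thresholds_mm
    r1, r2 = spec.penumbra_radii_mm

    vent_dist = ndimage.distance_transform_edt(~anatomy.ventricle, sampling=tuple(vs))
    band_labels = np.zeros(wmh.shape, dtype=np.uint8)
    banded_mask = anatomy.wm | wmh
    band_labels[banded_mask & (vent_dist <= t1)] = 1
    band_labels[banded_mask & (vent_dist > t1) & (vent_dist <= t2)] = 2
    band_labels[banded_mask & (vent_dist > t2)] = 3

    if wmh.any():
        wmh_dist = ndimage.distance_transform_edt(~wmh, sampling=tuple(vs))
    else:
        wmh_dist = np.full(wmh.shape, np.inf)
    wm_only = anatomy.wm & ~wmh
    p4 = wm_only & (wmh_dist > 0) & (wmh_dist <= r1)
    p8_annulus = wm_only & (wmh_dist > r1) & (wmh_dist <= r2)
    nawm = wm_only & ~p4 & ~p8_annulus

    def f(tissue: str, band_code: int | None = None) -> float:
        if band_code:
            key = f"{tissue}:{('JV', 'PV', 'D')[band_code - 1]}"
            if key in factors:
                return factors[key]
        return factors[tissue]

    factor_map = np.zeros(wmh.shape, dtype=float)
    factor_map[anatomy.gm] = f("GM")
    for code in (1, 2, 3):
        sel = wmh & (band_labels == code)
        factor_map[sel] = f("WMH", code)
        sel = nawm & (band_labels == code)
        factor_map[sel] = f("NAWM", code)
    factor_map[p4] = f("P4")

    # solve the 4-8 mm annulus factor so the cumulative 0-8 mm mean hits "P8"
    n4, nann = int(p4.sum()), int(p8_annulus.sum())
    if nann > 0:
        f_ann = ((n4 + nann) * f("P8") - n4 * f("P4")) / nann
    else:
        f_ann = f("P8")
    if f_ann <= 0:
        raise ValueError("P4/P8 factors are inconsistent: solved annulus factor is nonpositive")
    factor_map[p8_annulus] = f_ann

    # pre-lesional deficit under future lesions at baseline
    if session == "baseline" and spec.new_lesion_baseline_log_offset != 0.0:
        new_ids = lesions.truth.loc[lesions.truth["category"] == "new", "lesion"]
        foot = np.isin(lesions.followup_labels, new_ids.to_numpy())
        factor_map[foot & anatomy.wm] *= np.exp(spec.new_lesion_baseline_log_offset)

    # CSF/ventricle calibration: brain-mask mean == nominal, pre-noise
    csf_mask = (anatomy.ventricle | anatomy.csf) & anatomy.brain
    parenchyma = anatomy.brain & ~csf_mask
    n_brain = int(anatomy.brain.sum())
    n_csf = int(csf_mask.sum())
    if n_csf == 0:
        raise ValueError("anatomy has no CSF/ventricular voxels to calibrate against")
    csf_factor = (n_brain * 1.0 - factor_map[parenchyma].sum()) / n_csf
    if csf_factor <= 0:
        raise ValueError(
            "CSF calibration is nonpositive: the tissue factors are inconsistent "
            "with a total-brain normalizer of 1 (lower some factors or add CSF volume)"
        )
    factor_map[csf_mask] = csf_factor

    values = spec.nominal_brain_cbf * factor_map
    if spec.voxel_noise_cv > 0:
        subject = int(lesions.truth["subject"].iloc[0]) if len(lesions.truth) else 0
        rng = _rng(spec, 2, subject, 0 if session == "baseline" else 1)
        values = values * (1.0 + spec.voxel_noise_cv * rng.standard_normal(values.shape))
    volume = LabelVolume(data=values, voxel_size_mm=tuple(vs))
    truth = PaintedTruth(
        band_labels=band_labels,
        p4=p4,
        p8_annulus=p8_annulus,
        nawm=nawm,
        factor_map=factor_map,
        csf_value_factor=float(csf_factor),
        p8_annulus_factor=float(f_ann),
    )
    return volume, truth


# --------------------------------------------------------------------------
# whole-cohort emission

def subject_sessions(spec: CohortSpec, subject_index: int) -> list[str]:
    sessions = ["baseline"]
    if subject_index < spec.n_longitudinal:
        sessions.append("followup")
    return sessions


def generate_subject(spec: CohortSpec, subject_index: int) -> dict:
    """All in-memory products for one subject."""
    anatomy = generate_anatomy(spec, subject_index)
    lesions = plant_lesions(anatomy, spec, subject_index)
    out = {"anatomy": anatomy, "lesions": lesions, "sessions": {}}
    for session in subject_sessions(spec, subject_index):
        cbf, painted = paint_cbf(anatomy, lesions, spec, session)
        out["sessions"][session] = {"cbf": cbf, "painted": painted}
    return out


def demographics_table(spec: CohortSpec) -> pd.DataFrame:
    rng = _rng(spec, 3)
    n = spec.n_subjects
    ages = rng.normal(*spec.age_years, size=n)
    mmse = np.clip(rng.normal(*spec.mmse, size=n), 0, 30)
    female = rng.random(n) < spec.female_fraction
    interval = np.full(n, np.nan)
    interval[: spec.n_longitudinal] = np.clip(
        rng.normal(*spec.inter_scan_years, size=spec.n_longitudinal), 0.5, None
    )
    return pd.DataFrame(
        {
            "subject": np.arange(n),
            "age_years": ages,
            "sex": np.where(female, "F", "M"),
            "mmse": mmse,
            "inter_scan_years": interval,
            "longitudinal": np.arange(n) < spec.n_longitudinal,
        }
    )


def emit_cohort(spec: CohortSpec, outdir: str | Path) -> Path:
    """Write the cohort to disk: volumes, truth tables and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_tables = []
    for s in range(spec.n_subjects):
        data = generate_subject(spec, s)
        anatomy: Anatomy = data["anatomy"]
        sdir = outdir / f"sub-{s:03d}"
        for name in ("ventricle", "csf", "wm", "gm", "brain"):
            anatomy.as_volume(name).save(sdir / "anat" / f"{name}.nii.gz")
        for session, sess in data["sessions"].items():
            labels = (
                data["lesions"].baseline_labels if session == "baseline" else data["lesions"].followup_labels
            )
            ses_dir = sdir / f"ses-{session}"
            LabelVolume(labels > 0, anatomy.voxel_size_mm).save(ses_dir / "wmh_mask.nii.gz")
            LabelVolume(labels, anatomy.voxel_size_mm).save(ses_dir / "wmh_labels.nii.gz")
            sess["cbf"].save(ses_dir / "cbf.nii.gz")
        truth_tables.append(data["lesions"].truth)
    truth = pd.concat(truth_tables, ignore_index=True) if truth_tables else pd.DataFrame(columns=TRUTH_COLUMNS)
    truth.to_csv(outdir / "lesion_truth.csv", index=False)
    demographics_table(spec).to_csv(outdir / "subjects.csv", index=False)
    manifest = {"spec": _spec_dict(spec), "seed": spec.seed, "n_subjects": spec.n_subjects}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _spec_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def load_manifest_spec(cohort_dir: str | Path) -> CohortSpec:
    manifest = json.loads((Path(cohort_dir) / "manifest.json").read_text())
    d = manifest["spec"]
    for k in ("grid_shape", "voxel_size_mm", "inter_scan_years", "age_years", "mmse", "band_thresholds_mm", "penumbra_radii_mm"):
        d[k] = tuple(d[k])
    return CohortSpec(**d)


# --------------------------------------------------------------------------
# table-level simulators (effect recovery at cohort scale)

def simulate_tissue_location_table(
    n_subjects: int,
    tissue_effects: dict[str, float],
    location_effects: dict[str, float],
    intercept: float = 0.0,
    subject_sd: float = 0.1,
    resid_sd: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Additive tissue + location log-rCBF draws, subject random intercepts."""
    rng = np.random.default_rng(seed)
    tissues = list(tissue_effects)
    locations = list(location_effects)
    u = rng.normal(0, subject_sd, size=n_subjects)
    rows = []
    for s in range(n_subjects):
        for t in tissues:
            for loc in locations:
                y = intercept + tissue_effects[t] + location_effects[loc] + u[s] + rng.normal(0, resid_sd)
                rows.append({"subject": s, "session": "baseline", "tissue": t, "region": loc, "log_rcbf": y})
    return pd.DataFrame(rows)


def simulate_volume_location_table(
    n_subjects: int,
    slopes: dict[str, float],
    location_effects: dict[str, float] | None = None,
    intercept: float = 0.0,
    x_sd: float = 1.0,
    subject_sd: float = 0.1,
    resid_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Region-specific slope of log rCBF on centred log rVol."""
    rng = np.random.default_rng(seed)
    locations = list(slopes)
    loc_eff = location_effects or {loc: 0.0 for loc in locations}
    u = rng.normal(0, subject_sd, size=n_subjects)
    rows = []
    for s in range(n_subjects):
        for loc in locations:
            x = rng.normal(0, x_sd)
            y = intercept + loc_eff[loc] + slopes[loc] * x + u[s] + rng.normal(0, resid_sd)
            rows.append(
                {
                    "subject": s,
                    "session": "baseline",
                    "tissue": "WMH",
                    "region": loc,
                    "log_rcbf": y,
                    "log_rvol_centered": x,
                }
            )
    return pd.DataFrame(rows)


def simulate_lesion_category_table(
    n_subjects: int,
    lesions_per_subject: float,
    location: str,
    stagnant_intercept: float,
    category_effects: dict[str, float],
    session_effects: dict[str, float] | None = None,
    interaction: dict[str, float] | None = None,
    category_fractions: dict[str, float] | None = None,
    subject_sd: float = 0.08,
    resid_sd: float = 0.12,
    tissue: str = "WMH",
    seed: int = 0,
) -> pd.DataFrame:
    """Lesion-level category x session draws for the longitudinal model.

    Every lesion contributes a baseline and a follow-up row ("new" lesions'
    baseline rows model the back-projected pre-lesional tissue).
    """
    rng = np.random.default_rng(seed)
    fractions = category_fractions or {"stagnant": 0.45, "growing": 0.3, "new": 0.25}
    sess_eff = session_effects or {"baseline": 0.0, "followup": 0.0}
    inter = interaction or {}
    cats = sorted(fractions)
    p = np.array([fractions[c] for c in cats])
    u = rng.normal(0, subject_sd, size=n_subjects)
    rows = []
    lesion_id = 0
    for s in range(n_subjects):
        n_les = max(1, rng.poisson(lesions_per_subject))
        for _ in range(n_les):
            lesion_id += 1
            cat = str(rng.choice(cats, p=p / p.sum()))
            lesion_noise = 0.0
            for session in ("baseline", "followup"):
                y = (
                    stagnant_intercept
                    + category_effects.get(cat, 0.0)
                    + sess_eff[session]
                    + (inter.get(cat, 0.0) if session == "followup" else 0.0)
                    + u[s]
                    + lesion_noise
                    + rng.normal(0, resid_sd)
                )
                rows.append(
                    {
                        "subject": s,
                        "lesion": lesion_id,
                        "session": session,
                        "location": location,
                        "tissue": tissue,
                        "category": cat,
                        "log_rcbf": y,
                    }
                )
    return pd.DataFrame(rows)
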