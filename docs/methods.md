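# Methods

## The measurement model

Every quantity in the package is a mean of total-brain-relative cerebral
blood flow (rCBF) over a geometrically defined region of interest, or a
coefficient of a linear mixed model over such means.  The chain is:

1. a perfusion volume in ml/100g/min (either supplied, or quantified from
   a pulsed-ASL control/label series);
2. division by the subject's mean over the **full brain mask, including
   CSF and ventricles**, giving dimensionless rCBF with brain-mask mean
   exactly 1;
3. region construction from raw masks (ventricle, GM, WM, WMH) by
   physical-distance operations;
4. tabulation of mean rCBF and volumes per (subject, session, tissue,
   region), log transforms, and mixed-effects fits.

### Why the normalizer includes CSF

Published tissue-relative values in this design put both GM (≈1.32) and
white matter (≈1.07) above 1, which is arithmetically impossible if the
normalizer averaged only GM and WM.  A brain mask that includes
low-signal CSF/ventricular voxels pulls the normalizer below parenchymal
CBF and makes such values attainable; the package therefore defines the
total-brain mean over GM + WM + CSF + ventricles, and the synthetic
anatomy carries a realistic ≈20% CSF fraction (sulcal ribbon plus
ventricular system).  Relative volume (rVol) uses the same brain mask.

## Geometry

Distances are voxel-centre to nearest source-voxel-centre Euclidean
distances computed in physical millimetres (`scipy.ndimage`
exact EDT with the voxel size as sampling), never on resampled grids.
This is standard EDT semantics: a threshold of "3 mm" selects voxels whose
centre lies within 3 mm of some ventricle-voxel centre, not of a sub-voxel
surface.

- **Bands.**  JV iff d ≤ 3 mm, PV iff 3 < d ≤ 10 mm, D iff d > 10 mm over
  the WM ∪ WMH voxel set.  The verbal definitions ("within 3 mm",
  "10 mm or further") collide at exactly 10 mm; boundaries are closed on
  the inner side (d = 3 → JV, d = 10 → PV) so the three bands always
  partition the mask.
- **Penumbra shells.**  P_r = {WM voxels with 0 < d(WMH) ≤ r}, r = 4 and
  8 mm, always excluding every WMH voxel.  Default mode is *cumulative*
  (P4 ⊆ P8, "within 8 mm" read literally); an *annular* mode
  (4 < d ≤ 8) is provided because group statistics could be reported
  either way.  The acceptance experiments use cumulative.
- **NAWM** = WM \ (WMH ∪ P8), intersectable with the bands.

## ASL quantification

The perfusion-weighted signal is the mean over pairs of control − label
differences; a *surround* variant subtracts the average of the two
neighbouring label volumes, cancelling linear signal drift to first order
(the plain pairwise scheme is the default since the acquisition's exact
scheme is not specified).  CBF uses the single-compartment QUIPSS II
closed form with the consensus constants (λ = 0.9 ml/g, α = 0.98,
T1b = 1650 ms, TI = 1800 ms, TI1 = 1650 ms); at ΔM/M0 = 0.01 this gives
49.7 ml/100g/min, which the tests pin against an independent evaluation.
A variational-Bayes fitter would add spatial regularization but no
closed-form testability; with the constants fixed, the deterministic
expression is fully determined and is what the package implements.
Voxels with M0 below 10% of its robust (99th percentile) maximum are
masked to avoid division blow-ups.  Precomputed CBF volumes bypass this
stage and give bit-identical downstream results.

## Lesion tracking

Lesions are connected components of the WMH mask — 26-connectivity by
default, since "connected in a 3D neighbourhood" is ambiguous; 6 and 18
are selectable.  Components under 10 mm³ are dropped as segmentation
noise (strictly `< 10`; exactly 10 mm³ is kept).  Follow-up clusters
match the baseline cluster with maximal voxel overlap, greedily and
one-to-one (ties to the lower id), so every follow-up cluster lands in
exactly one trajectory and every baseline cluster in at most one; merges
and splits are recorded via a parent list.  Volume-change categories use
a strict +10% threshold (exactly +10% is stagnant); decreases ≤ −10% are
*shrinking* and lesions with no follow-up partner *vanished* — both
first-class outputs excluded from the three-category models, matching the
design's silence about them.  A follow-up lesion whose baseline partner
fell below the size floor is treated as new with a flag.

Lesion bands use the ventricular distance at the lesion centroid by
default (the centroid distance is also the covariate of the supplementary
distance model); a majority-voxel rule is available, and disagreement
between the two — possible for elongated lesions spanning a boundary —
sets a flag with both labels retained.

Per-lesion penumbra shells exclude *all* WMH voxels of the session, so
adjacent lesions never contribute to each other's penumbra.  For new
lesions, baseline perfusion is read under the follow-up footprint
(back-projection), measuring the pre-lesional tissue; footprint voxels
outside the baseline brain mask are excluded and counted, and an empty
footprint yields an explicit missing value.

## Models

All models are linear mixed models with per-subject random intercepts,
fit by REML (statsmodels `MixedLM`, BFGS with a Powell fallback — both
deterministic), with Wald 95% CIs (estimate ± 1.96·SE).  Log transforms
use the natural log (base configurable and recorded); log rVol is centred
by the mean log WMH rVol over the analysis set, stored in the output
metadata.

- *Tissue × location*: log rCBF ~ tissue + location, references NAWM and
  JV, so the D coefficient is the deep-vs-juxtaventricular offset.
- *Volume × location*: log rCBF ~ centred log rVol × location with deep
  as reference, so the JV and PV interaction terms are slope differences
  relative to deep.  The printed coefficients are implemented as
  D-referenced interactions (they are described as interactions, though
  region-specific slopes would be an alternative reading).
- *Lesion longitudinal*: per (location, tissue), lesion log rCBF ~
  category × session with stagnant/baseline references; the category main
  effects are baseline mean differences.  Categories with fewer than two
  lesions are flagged non-estimable.
- Supplementary: centroid-distance covariate model; one-way ANOVA of log
  lesion volume by location.

Multiplicity correction defaults to Benjamini–Hochberg within each
category's nine location × tissue contrasts — the family implied by a
nine-row contrast table with one corrected column per category — with
Holm and Bonferroni selectable and the family definition logged.

## The synthetic cohort generator

The generator emulates the *inputs* of the analysis, not MRI physics: no
k-space, FLAIR intensities, registration error, motion or atrophy.

- **Anatomy**: nested jittered ellipsoids on a 96×96×48 grid of
  1×1×2 mm voxels — central ventricle (semi-axes ≈10/16/8 mm), thin
  ependymal CSF rim, WM shell, GM ribbon, outer sulcal CSF.  Labels are
  disjoint and tile the brain mask.  A sizing check raises, naming the
  limiting axis, if the WM shell cannot hold the deep band.
- **Lesions**: spherical-ish blobs (jittered ellipsoids clipped to WM) —
  shape realism is irrelevant to the region means under test.  Each lesion
  draws a category (default mix 50% stagnant / 30% growing / 20% new, a
  shrinking fraction defaulting to 0), a target band, and a log-normal
  radius (median 3 mm).  Placement retries until the centroid lands in
  the target band with a margin; lesions keep ≥5 mm physical separation so
  they never merge.  Growing lesions dilate geodesically inside WM by
  adding nearest-outside voxels until the voxel count rounds to the
  sampled growth factor (enforced ≥25 baseline voxels keeps the realized
  ratio within ±2% of target); new lesions exist only at follow-up; all
  lesions are ≥ 10 mm³.
- **Perfusion painting**: voxel value = nominal brain CBF × tissue factor
  × (1 + Gaussian noise, CV 5% by default, voxelwise independent — no
  spatial autocorrelation, which suffices for mean-recovery tests but
  understates ROI-mean variance under correlated noise).  Default factors
  are the cross-sectional tissue means (GM 1.315, NAWM 1.067, WMH 0.814,
  P4 0.845, cumulative P8 0.880); a banded set adds per-band WMH and NAWM
  factors.  The penumbra profile is two-step radial: the P4 value on
  0–4 mm and a 4–8 mm annulus value solved per subject so the cumulative
  0–8 mm mean hits its target exactly, making both cumulative and annular
  read-outs testable.  The CSF/ventricular value solves one linear
  equation so the pre-noise brain-mask mean equals the nominal CBF
  exactly (40 ml/100g/min by default — absolute units are a free
  parameter since only relative values are analysed); an infeasible
  calibration (nonpositive CSF value) raises with an explanation.
  Optionally, planted new lesions carry a baseline log-rCBF offset under
  their future footprint (pre-lesional hypoperfusion), applied before
  calibration so conservation still holds.
- **Demographics** mirror the study cohort table: 300 subjects (90
  longitudinal) by default, age 77 (7.9), MMSE 28 (2.4), 199/300 female,
  inter-scan interval 1.9 (0.7) years.

**Anti-circularity.**  The generator computes its own band/shell labels
directly (its own scipy calls on its own masks) and paints from them; the
pipeline receives only the raw masks and volumes and must reconstruct the
regions independently.  Tests assert voxel-for-voxel agreement and exact
(zero-noise) factor recovery, and the recovery experiments assert it at
cohort scale under noise.  What passing shows: the geometric and
statistical machinery is correct on inputs with the planted structure.
What it does not show: robustness to segmentation error, registration
error, partial-volume effects or spatially correlated noise, none of
which the generator emulates.

## Problem sizes and numerical choices

Image-level recovery experiments use 40 subjects (tests use 8) on the
full 96×96×48 grid with 5% voxel noise — ROI means aggregate thousands of
voxels, so cohort-mean Monte-Carlo error is ≪ the ±0.02 bands the
experiments target.  Model-level recoveries use the cohort sizes the
models are meant for (300 subjects; 60 subjects × ~5 lesions) and report
estimates averaged over a handful of seeded replicate cohorts, which
tests recovery bias rather than one realization's sampling noise.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical (spec, seed) gives bit-identical
cohorts, and model fits are deterministic given their input tables.

## Known limitations

- Ellipsoidal-shell anatomy: no gyrification, no hemisphere split, one
  connected ventricular compartment.
- Independent voxel noise; no arterial-transit-time structure or
  ASL-specific artefacts.
- Cross-session registration is assumed perfect (masks share one grid);
  the matcher has a minimum-overlap-fraction option but no deformable
  alignment.
- Partial-volume correction is out of scope; region means near CSF
  interfaces would shift under it.
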