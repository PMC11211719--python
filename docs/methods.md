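# Methods

## Overview

`pagflat` analyzes the topography of the BOLD response in the human
periaqueductal gray (PAG) during an N-back working-memory task, and
ships a synthetic-data generator that produces every input the analysis
consumes, with ground truth, so the whole chain is testable without any
acquisition.  The pipeline stages are:

1. task-schedule generation and behavior scoring;
2. brainstem phantom + BOLD-run + physiological-trace simulation;
3. aqueduct detection and hollow PAG shell masking;
4. cylindrical parameterization, ventral exclusion, rank assignment,
   and 2D flattening;
5. subject-level GLM with nuisance regression;
6. cardiac IBI / respiratory-rate extraction and epoch change scores;
7. group-level mixed-effects topography model and voxelwise
   correlations.

## Task model

A run is 12 blocks of 10 letter trials (letters Q, W, R, S, T; 1 s
stimulus + 1 s blank), each block preceded by a 3 s cue and followed by
25 s of fixation; block load alternates between 1-back and 3-back in a
counterbalanced 1-3-3-1 or 3-1-1-3 order.  Proportions are exact by
construction: every block carries 2 targets (20 % of trials overall)
and 1 lure (12.5 % of nontargets; 2-back matches in 1-back blocks,
2-/4-back in 3-back blocks).  Nontarget letters are rejection-sampled
so that no unflagged trial matches the block's n-back position or a
lure offset; an inconsistent draw retries the block and bounded retries
(default 1000) raise rather than relax the proportions.  The lead-in
fixation defaults to 12 TRs (28.08 s); with TR = 2.34 s the default run
is 259 volumes.  Run length is a parameter, not a constant, because the
design leaves the lead-in/out unspecified.

## Phantom and BOLD model

The phantom is a 40x40x40 voxel grid at 1.1 mm isotropic holding a
14 mm straight tube (the cerebral aqueduct, radius 1.2 mm) surrounded
by a hollow gray-matter shell (thickness 3 mm).  The grid is placed so
the tube sits inside the midbrain bounding box (-42 < y < -22 mm,
z > -14 mm); the tube axis defaults to +z and can be tilted about x to
emulate between-subject obliquity.  The ground-truth task effect on the
shell is

    beta(rc, theta) = s_cond * (b0 + b_rc*rc~ + b_deg*|theta~| + b_int*rc~*|theta~|)

with rc~ in [0, 1] caudal-to-rostral, |theta~| = |theta|/180, defaults
b0 = 0.1, b_rc = 0.5, b_deg = 0.4, b_int = 0.3 (arbitrary units on a
baseline of 100, i.e. roughly percent signal change) and condition
scales s_1back = 1, s_3back = 2.  The map is bilaterally symmetric in
|theta| by construction.

A simulated run is baseline + HRF-convolved condition boxcars x truth
effect + low-frequency drift (linear + 128 s cosine, subject-random
amplitudes, SD 0.5) + i.i.d. Gaussian noise (SD 1.0 by default, roughly
1 % of baseline) — no temporal autocorrelation is modeled, matching a
GLM that relies on nuisance regression rather than prewhitening.
Aqueduct voxels additionally receive a 0.3 Hz oscillation of amplitude
5 (an aliased-CSF-pulsation surrogate), which is what makes the
aqueduct the dominant temporal-variance structure.  Motion parameters
are a slow random walk; optional spike volumes inject 1 mm translation
steps.  With zero noise and zero drift the run is exactly invertible by
the GLM because generator and analysis share one HRF convolution.

What the phantom does *not* emulate: MR physics, spatial noise
correlations, vascular geometry, true motion fields, multi-run
sessions, or non-straight aqueducts.  Passing tests therefore
demonstrate the correctness and calibration of the analysis chain, not
its performance against scanner artifacts.

## Aqueduct detection and shell mask

Temporal SD is computed per voxel after linear detrending; voxels above
the 95th percentile (configurable) within a search region are reduced
to the largest 6-connected component.  The search region should be
drawn tightly around the expected aqueduct: the percentile threshold is
relative to the region, and a region of roughly a thousand voxels keeps
it above task-driven parenchymal variance (the pipeline uses a center
box of 8x8x14 voxels).  Detection is invariant to global intensity
scaling.

The shell mask is built by dilating the aqueduct mask by exactly two
voxels — the 6-connected cross applied twice, so "two voxels" is 2.2 mm
in grid steps rather than a diagonal distance — then removing aqueduct
voxels, keeping voxels with gray-matter probability > 0.5, and clipping
to the world-mm bounding box (-42 < y < -22, z > -14, read as a closed
box through the affine).

Instead of volumetric subject-to-group registration, subjects are
pooled in cylindrical parameter space: each subject's retained voxels
are binned on a common (normalized rc x signed degree) grid (default
14 x 27 cells) and cell means are stacked.  This preserves exactly the
geometry the topography model uses while avoiding nonlinear
registration entirely.  Subjects with fewer than 50 retained shell
voxels are excluded with a warning.

## Cylindrical parameterization

The longitudinal axis is the first principal component of shell-voxel
world coordinates; its sign is chosen to project positively on the
anterior-superior diagonal (+y+z)/sqrt(2), the rostral direction for
the midbrain aqueduct (configurable, since the sign convention is
otherwise arbitrary).  The degree of a voxel is the signed angle of its
radial vector: 0 deg at the dorsal reference (the projection of world
-y into the plane orthogonal to the axis), right-lateral positive,
range (-180, 180].  Chirality is arbitrary; it is fixed and documented
rather than inferred.  rc is the axial projection shifted so the caudal
pole is 0.  Voxels exactly on the axis get radius 0 / degree 0 with a
warning.

The ventral-most 90 deg (|degree| > 135) is excluded; the bound is
closed, so a voxel at exactly 135 deg is retained (deterministic
tie-break).  Rostral-caudal position is split into 4 equal-width ranks
over the subject's observed rc range (3.5 mm per rank on a 14 mm axis
— the observed range is used rather than a fixed 14 mm because subject
masks vary in length), and |degree| into 10 bilateral ranks of 13.5 deg
over [0, 135].  Bins are half-open with the final bin closed.
Flattening grids retained-voxel values onto (rc x degree) maps per 1 mm
radial annulus; cells average contributing voxels, so count-weighted
cell means conserve voxel means exactly.

## Subject-level GLM

Trial-wise 1 s boxcars are laid on a 0.1 s grid, convolved with a
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6, length 32 s —
canonical defaults, configurable), normalized so one isolated event
peaks at 1, summed within condition, and sampled at volume times.
Nuisance columns: intercept, 6 motion parameters, 5 CSF + 5 WM aCompCor
components (linearly detrended, variance-normalized voxel series; top
principal components via a time-domain Gram matrix), a DCT high-pass
set with minimum period 264 s (K = floor(2T/264) columns), and one-hot
spike regressors at volumes with framewise displacement > 0.5 mm
(Power formulation, 50 mm rotation sphere).  Subjects with spikes in
more than 20 % of volumes are flagged for exclusion.  Fitting is
voxelwise OLS; no prewhitening.  Contrast z-maps convert t through the
normal quantile of the t CDF; zero-variance voxels get guarded zeros at
the subject level and are flagged (NaN), never capped, at the group
level.  VIF for the task regressors is 1/(1-R^2) against all other
columns (the auxiliary regression includes an intercept so R^2 is the
centered coefficient of determination); perfect collinearity reports
+inf.

PAG analyses operate at 0.5 mm: subject beta maps are smoothed with a
1 mm FWHM Gaussian and trilinearly resampled from 1.1 to 0.5 mm; the
resampled map is renormalized to conserve its total integral exactly,
since trilinear sampling alone only conserves it approximately for
spatially concentrated inputs.  The shell mask is resampled alongside
and re-parameterized on the fine grid — at native resolution the thin
shell under-samples some 13.5 deg bins, while the fine grid fills all
40 rank cells.

## Physiological pipeline

Cardiac: 0.3-9 Hz band-pass, then a two-pass peak detector — pass 1
takes local maxima above 40 % of normalized amplitude with minimum
spacing 60/90 s (the spacing of a 90 bpm rhythm; the published spacing
clause is ambiguous and this reading is an interpretation); pass 2
re-detects with spacing adapted to the pass-1 mean rate (0.6 x mean
IBI, clipped to [0.25, 1.8] s).  Respiratory: 1 Hz low-pass, local
maxima in sliding 500 ms windows, excursions below 0.5 SD of run-wide
belt tension rejected.

Instantaneous rate from inter-peak intervals is interpolated to a 10 Hz
grid, smoothed with a 6 s centered rolling average, and sampled at TR
midpoints; heart rate is converted to IBI (60/HR) only after smoothing
and down-sampling.  TR midpoints falling inside a block's cue+task
interval belong to that block's task epoch (cue handling is
configurable); all other TRs are fixation.  Change scores are epoch
mean minus fixation mean.

Quality classes are a reproducible proxy for what was originally a
visual judgment: sparse artifacts are seconds whose local SD exceeds
5 x the median per-second SD; minutes are checked for physiologically
plausible intervals (IBI in [0.3, 2] s; RR in 7-20 breaths/min) and
interval regularity (CV <= 0.5).  A trace is *high* when every minute
is plausible and regular with at most 5 % affected seconds, *unusable*
when most minutes are irregular or any minute is half covered by
artifacts, and *noisy* otherwise.  A sample-level 5-SD rule alone was
rejected because heavy contamination inflates its own threshold.  Only
high-quality traces enter analysis.

## Group model

Per subject and condition, retained-voxel betas are averaged within the
4 x 10 rank cells — 40 estimates per subject per condition (the
per-condition reading; the model needs both conditions, giving 80 rows
per subject).  The mixed model is

    mean_beta ~ condition * rc * degree + (condition * rc * degree | subject)

fit by REML with rc/degree as centered numeric rank scores (so each
fixed effect is a 1-df test; categorical coding is available) and
condition coded -1/2, +1/2.  The full random-slope covariance (8 terms,
36 parameters) is often singular at small n; fitting falls back to
uncorrelated slopes, then a random intercept, and records the structure
used.  The backend (statsmodels MixedLM) provides no Satterthwaite
approximation, so tests use t (and F = t^2) with a between-subject
denominator df of n_subjects - 1, labelled as such in the output; an
independent lme4/lmerTest fit cross-checks the fixed-effect estimates
in the test suite.  Simulation studies in the acceptance suite fit the
uncorrelated-slopes structure, matching their generating process.

Condition-map similarity is the Pearson correlation over voxel (cell)
pairs with a percentile CI from 10,000 bootstrap resamples of voxel
pairs (the resampling unit is a design choice; subject-level bootstrap
is available).  Brain-body coupling maps are per-cell between-subject
correlations of beta with the IBI/RR change score; cells with zero
variance or fewer than 3 finite pairs are NaN.  Group maps are one-
sample t across subjects converted to z, with no cluster-level
correction.

## Problem sizes and numerical choices

The simulated cohort used by the acceptance script is 8 subjects at the
default 40^3 grid and 259 volumes, which the package's statistics
resolve comfortably; calibration simulations use 200 null replicates
(20 subjects) and 100 recovery replicates (40 subjects) on directly
simulated rank tables, 100 seeded physiological runs, and 50 bootstrap
coverage seeds at 5000 voxel pairs.  BOLD arrays are float32 by default
(float64 available for exact-inversion checks).  Random state is a
single master seed expanded through `numpy.random.SeedSequence` into
per-component seeds.

## Known limitations

* The straight-line PCA axis cannot follow a curved aqueduct; no spline
  centerline is attempted.
* Pooling in parameter space assumes the cylindrical coordinates are
  comparable across subjects; it cannot model residual misalignment the
  way volumetric registration could.
* The between-subject df approximation is exact only for balanced
  between-subject contrasts; within-subject effects are tested
  conservatively relative to a Satterthwaite approximation.
* Physiological quality classes are a proxy; they reproduce the
  documented class definitions on synthetic traces but have not been
  validated against human raters.
* No multiple-comparison correction (TFCE or otherwise) is applied to
  voxelwise maps.
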