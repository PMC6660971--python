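# Methods

## The problem

The pipeline asks two questions of a radiomics panel for sub-2 cm lung
nodules: which features remain reproducible when the extraction setting
changes (native anisotropic voxels vs. a common 2 mm isotropic grid; default
vs. reduced histogram bin counts), and what physically characterizes the
nodules for which neighbourhood-based texture features cannot be computed at
all.  Because no clinical cohort ships with the package, a synthetic-nodule
generator provides cohorts with known, planted structure; every downstream
claim the tests make is therefore a claim about this generator's cohorts,
not about clinical CT.

## Synthetic cohorts

Each case is a CT-like volume in Hounsfield units on an anisotropic grid
(in-plane 0.49–0.9 mm, slice 1–2.5 mm by default) with one embedded nodule
and its exact binary mask.  The nodule model is part-solid: a solid core at
`core_intensity` (default +20 HU) surrounded by a homogeneous ground-glass
shell whose density is the `ggo_fraction`-weighted blend of the solid and
pure-GGO (−600 HU) values, with a narrow (0.8 mm) core–shell interface and a
shell thickness of 0.35 of the radius.  The shell is deliberately a density
*plateau*: sub-solid nodules present as fairly homogeneous haze, and a
plateau makes the ROI extremes (min/max) tissue properties rather than
noise order statistics — the property that lets extreme-value features be
reproducible across voxel settings at all.  Intensity falls to lung
background (−850 HU) through a logistic sigmoid in the signed distance to
the surface whose 10–90% width is `margin_width` (mm).  Inside the nodule a
spatially correlated texture field (Gaussian-smoothed white noise, 1.5 mm
scale, amplitude `texture_amplitude` HU) is added; iid Gaussian noise
(default 20 HU) covers the whole volume.  Shapes are spheres, volume-
preserving ellipsoids (axis factors 1.25/1.0/0.8), or spheres with a
low-order spherical-harmonic radial perturbation ("lobulated").

Class effects are additive offsets on diameter, core density, margin width
(malignant sharper), texture amplitude and GGO fraction.  The default
profile is moderate; `WELL_SEPARATED` plants large effects for validation
runs where a classifier is expected to succeed.  A configurable fraction of
cases (default 0.25) is drawn at 3.5–6 mm diameter so that, after 2 mm
resampling, NGTDM and sub-sampled GLCM computations fail — the population
the failure audit studies.  Default cohort size is 180 cases at 72%
malignant prevalence, mirroring a small-nodule training cohort; the
validation cohort is generated independently (external-validation design)
rather than split off.

All randomness flows from one `numpy.random.Generator`; identical
configuration reproduces bit-identical cohorts.  What the generator does
*not* model: scanner reconstruction kernels, dose, lung anatomy (vessels,
pleura), segmentation error.  Passing tests therefore show the machinery is
correct and calibrated, not that any specific feature is reproducible in
clinical data.

## Preprocessing

Isotropic resampling (default 2 mm) interpolates intensities linearly and
resamples the mask as a partial-volume fraction (linear interpolation of the
binary field, threshold 0.5).  The partial-volume rule matters: nearest-
neighbour masks admit boundary voxels whose centers lie outside the true
surface, which systematically pulls the ROI minimum toward lung background
(−54 HU observed on a 60-case cohort; −5 HU with partial-volume masks).
The ROI is partitioned into an inner core and outer rim purely by volume:
iterative 6-connected erosion stops at the depth whose core volume is
nearest 2/3 of the whole (ties go deeper).  If one erosion empties the mask
the partition is degenerate (single-voxel core, flag set) and the regional
features fail.  "Positive" voxels are those strictly above 0 HU (water).

## The feature panel

252 features per (case, setting), all failures recorded per feature:

| family | count | notes |
|---|---|---|
| histogram | 60 | 19 whole + 14 positive + 9 core + 9 rim + 9 rim−core |
| shape | 19 | 10 3D + 3 largest-axial-slice 2D + 6 sigmoid margin |
| fractal | 15 | box-counting dim + lacunarity r∈2..8 + blanket signature ε∈2..8 |
| GLCM | 44+44 | 11 measures × whole/core/rim/delta, full and 2× sub-sampled |
| ISZM | 2 | zone percentage, large-zone emphasis (32 × 256 matrix) |
| NGTDM | 5 | Amadasun–King, complete 26-neighbourhoods only |
| LoG | 63 | 9 statistics × σ ∈ {0.5..3.5} voxels |

Conventions: logs base 2 with 0·log 0 := 0; histogram entropy/uniformity
binned over the fixed CT range [−1024, 3071] HU (4096 bins ⇒ 1 HU/bin);
GLCM/ISZM/NGTDM binned equal-width over the per-ROI min–max; GLCM pools the
13 unique distance-1 offsets symmetrically into one normalized matrix;
histogram "energy" is the mean squared intensity (intensive) so that
homogeneous nodules have exactly zero rim−core deltas; kurtosis is
non-excess (normal = 3); moments of constant samples are defined as 0.
Surface area comes from a marching-cubes mesh, the 2D perimeter from the
4-direction Crofton estimator (exact in the smooth limit, biased high on
axis-aligned corners), and the maximum 3D diameter from the convex hull of
surface voxels.

Sigmoid margin features fit s(t) = a + b/(1 + exp(−(t−c)/w)) to intensity
profiles sampled every 0.5 mm along outward surface normals (gradient of
the σ = 1 voxel Gaussian-smoothed mask) over ±L mm, L ∈ {3, 5, 7}; the
slope of a line is b/(4w) and the features are its mean and SD over
surface voxels (at most 96, thinned deterministically).  The fit is a
self-contained damped Levenberg–Marquardt with an analytic Jacobian, fixed
initialization (a = line min, b = range, c = 0, w = 1 mm), at most 200
iterations, and relative cost tolerance 1e−10 — a pure function of its
inputs, which is what makes whole-pipeline reruns byte-identical.  Fits
whose inflection leaves the window, or whose width falls below the sampling
resolution (0.02 mm) or above 2L, count as non-converged; a length fails if
more than half its lines do.  The slope is signed along the outward normal,
so dense nodules in dark lung have negative slopes.

Failure contract: empty ROI, too few voxels (e.g. no complete NGTDM
neighbourhood; sub-sampled grid under 2 voxels; fractal bounding box under
4 voxels per axis), degenerate matrix (no co-occurrence pairs), or fit
non-convergence.  A feature vector always carries the full 252-name roster.

Known approximations: the 2× sub-sampled GLCM pools blocks anchored at the
mask bounding box, so it is only statistically (not voxel-wise) invariant
to 90° in-plane rotation; margin features are exactly rotation-invariant
only when no surface thinning occurs.

## Screening, selection, validation

ICC(A,1) — two-way random effects, absolute agreement, single measurement —
treats the two extraction settings as raters; absolute agreement is the
right form because a systematic shift between settings is exactly the
non-reproducibility being screened for.  Cases with a failed value are
dropped pairwise per feature; fewer than 3 complete pairs leaves the ICC
undefined (feature excluded, logged); identical constant columns define
ICC = 1.  Features failing in more than 20% of cases in either table are
excluded from analysis up front, mirroring the exclusion of high-error
families before any screening.  The screen keeps ICC ≥ 0.7.

LASSO selection is an L1-penalized logistic regression on z-scored
candidates (training mean/SD, ddof = 1; constants excluded), with the
penalty chosen on a 25-point log grid by 10-fold stratified CV at minimum
mean deviance, fixed fold seed.  The signature is the intersection of the
per-setting selections in roster order.  The binning experiment holds
histogram and ISZM features at their default bins and sweeps only the GLCM
bin count {32, 64, 128} against the default 256, so histogram columns are
identical across the pair and their ICC is exactly 1 by construction.

Validation trains a 200-tree random forest (√p candidate splits, seeded)
on the training cohort restricted to the signature and reports trapezoidal
AUC, plus accuracy/sensitivity/specificity at probability threshold 0.5
(malignant positive).  OOB permutation importance re-derives each tree's
bootstrap sample from its seed and measures the OOB accuracy drop when one
feature is permuted, averaged over trees.

## Failure audit

A case is in the error group for a family (NGTDM or sub-sampled GLCM) iff
at least one of the family's features failed.  Groups are compared over 26
always-computable features (19 whole-ROI histogram + 7 shape) by one-tailed
Welch t-tests, the direction taken from the observed mean difference; no
multiplicity correction by default (a Holm flag exists).  Because the
direction is data-chosen, "p < 0.05 in the chosen direction" is a
level-0.10 procedure under the null; the calibrated 5% statement — verified
by simulation in the acceptance suite — is the rate of the specific
directional conclusion (e.g. falsely concluding the non-error group is
larger).  Size guidelines are the lower 95% t-CI bound of the non-error
group, floored to feature-appropriate precision (100 mm³ for volume, 1 mm
for diameter, 10 mm² for surface area).

## Problem sizes and numerical choices

The packaged validation runs use 60 training + 40 test cases with the
well-separated effect profile, 1000-rep type-I simulations, and 100-rep
LASSO recovery studies; these sizes give stable pass/fail behaviour while a
full run stays in the minutes range on one CPU.  Tie-breaks are fixed
everywhere (deeper erosion on ties, lower slice index for equal areas,
roster order for signatures).  ε = 1e−12 guards zero denominators in NGTDM
coarseness/strength.

## Known limitations

On these synthetic cohorts the ROI maximum keeps ICC ≥ 0.7 across voxel
geometries but the minimum plateaus near 0.6: the 2 mm grid under-samples
the extremes of the 1.5 mm-scale texture field relative to the fine native
grid.  This is a property of the simulated texture (clinical minima are set
by air/GGO content at larger spatial scales) and is reported, not patched.
The lobulated shape uses a fixed spherical-harmonic perturbation rather
than per-case random lobulation.  The exact membership of the clinical
252-feature roster is configuration-driven and can be re-pointed if a
definitive list is adopted.
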