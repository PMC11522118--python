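# Methods

## Problem and statistic

`hetrad` quantifies *interlesional intrapatient heterogeneity* in
multi-lesion CT: how much the texture of a patient's lesions varies from
lesion to lesion.  The pipeline is

1. split a label mask into individual lesions and drop lesions whose
   equivalent-sphere diameter is below 5 mm,
2. extract 75 second-order texture features per lesion,
3. for each patient and feature, compute the coefficient of variation
   across that patient's lesions,

       CV = sigma / mu * 100%        (sigma: sample sd, n-1 denominator)

4. compare the patient-wise CVs of two cohorts feature by feature with a
   two-sided Welch t-test at alpha = 0.05.

A high CV means a feature disagrees strongly between the lesions of one
patient; a cohort whose CVs are systematically higher carries more
interlesional heterogeneity.

## Lesion definition and size filter

Lesions are distinct positive labels of an integer mask; a purely binary
mask is first partitioned into 26-connected components.  "Size" for the
5 mm exclusion rule is the diameter of the sphere with the lesion's total
voxel volume, d = (6V/pi)^(1/3), and the boundary is inclusive (d = 5 mm
is kept).  Whether a clinical 0.5 cm rule means in-plane, maximal-3-D or
volume-equivalent diameter is under-determined; the volume-equivalent
reading matches size-by-voxel-volume bookkeeping and is the one
implemented.  No resampling is performed: spacing is taken from the file
header and used only for volume/diameter conversion.

## Texture features

Intensities inside a lesion are discretized with a fixed bin width
(default 25 HU, appropriate for calibrated CT) anchored at the lesion's
minimum: level i covers [min + (i-1)w, min + i*w), Ng =
floor((max-min)/w) + 1.  Anchoring at the minimum makes all 75 features
exactly invariant under any constant intensity shift.  No intensity
normalization precedes discretization.

Five matrix families are built on the discretized grid (0 = outside
mask), following the image-biomarker reference definitions:

* **GLCM** — ordered level pairs at Chebyshev distance 1 along each of
  the 13 unique 3-D directions; each per-angle matrix is symmetrized
  (transpose added) and normalized.  24 features.
* **GLRLM** — maximal collinear runs of equal level per direction,
  indexed (level, run length).  16 features.
* **GLSZM** — 26-connected iso-level zones, indexed (level, size);
  direction-free.  16 features.
* **GLDM** — per-voxel dependence counts: 26-neighbours within level
  tolerance alpha (default 0); column j holds voxels with j-1 dependent
  neighbours, and feature formulas use j, which keeps small-dependence
  emphases finite.  14 features.
* **NGTDM** — per-level counts, probabilities and summed absolute
  differences from the in-mask neighbourhood mean, over voxels with at
  least one in-mask neighbour.  5 features.

Angle-dependent families evaluate features per direction and average the
13 values; direction-free families are evaluated once.  Feature names
follow the `original_<family>_<Feature>` convention.

Numerical conventions (all unit-tested):

* entropies sum only over positive probabilities, so flat textures give
  exactly 0 — no epsilon padding;
* GLCM Correlation and MCC are 1 on a single gray level;
* NGTDM Coarseness returns the cap 1e6 when its denominator is 0;
  Busyness and Strength return 0 on zero denominators;
* GLCM Idmn/Idn normalize by the discretization Ng (which may include
  empty levels between min and max); NGTDM's Ngp counts only levels
  actually present, as its formulas require;
* a FeatureVector never contains NaN; degenerate single-voxel input is
  modelled as a flat one-pair texture.

Every matrix builder is verified against an independent brute-force
enumeration (plain per-voxel loops) on hundreds of random small grids,
and the full 75-feature vector against an independent loop-based
implementation of the same formulas on phantom lesions.

## CV matrix and screen

CVs use the sample (n-1) standard deviation.  Entries with non-positive
mean are *flagged* but kept (the CV's magnitude is not interpretable on
sign-mixed domains; an |mu|-denominator variant exists as an option).
Patients with fewer than two surviving lesions have no defined CV and
are dropped with a logged count.  The cohort summary ("mean CV") is the
across-patient mean of patient-wise CVs; a feature can be excluded from
plotting summaries (e.g. a dominating ClusterShade) without affecting
the screen.

The primary screen is Welch's unequal-variance two-sided t-test per
feature with no multiple-testing correction; Benjamini–Hochberg q-values
are reported alongside without altering the primary significance flag.
A pooled-variance option and a drop-flagged sensitivity mode exist.
Cohorts are bound alphabetically to the report's A/B slots, so swapping
cohort labels flips the direction column and leaves p-values unchanged.
Study descriptives (lesion counts and sizes per cohort) are compared
with the Wilcoxon–Mann–Whitney test, exact in small tie-free samples.

## Synthetic phantoms and ground truth

Real multi-lesion CT with per-lesion masks is not redistributable, so
validation uses phantoms with a *known* interlesional dispersion:

* a lesion is an ellipsoid (radius parameter, ±30% per-axis anisotropy)
  in a constant 60 HU liver-like background, default spacing
  (0.7, 0.7, 1.5) mm;
* its texture is white Gaussian noise N(mean_hu, sd_hu) smoothed by an
  isotropic Gaussian of scale `correlation_length_vox` and rescaled by
  the kernel's exact variance-shrinkage factor so the field keeps sd_hu;
* patient parameters are drawn around the cohort prior with a fixed
  lognormal log-sd of 0.1 (between-patient variability);
* each lesion's parameters are the patient's multiplied by independent
  lognormal factors of log-sd **tau** — the interlesional-dispersion
  ground truth.  For a lognormal factor, the parameter CV is
  sqrt(exp(tau^2) - 1), so tau maps directly onto the quantity the CV
  statistic estimates.  Factors are truncated at ±2.5 log-sd (affecting
  <1.3% of draws) so a single extreme draw cannot produce a degenerate
  or gigantic lesion;
* lesions are packed into one volume by rejection sampling of
  non-overlapping bounding boxes; the default per-patient lesion count
  is uniform on [2, 85], the range observed in multi-lesion metastasis
  cohorts.

Everything is a pure function of (spec, seed); studies re-generate
byte-identically.

What the phantoms do **not** emulate: scanner physics and noise texture,
contrast phases, liver anatomy and lesion-boundary effects, correlated
per-lesion parameters, and non-lognormal dispersion.  Passing recovery
tests therefore shows the statistic recovers a known multiplicative
dispersion from images — not that clinical effect sizes would match.

## Validation experiments and problem sizes

The experiment sizes below were chosen to give stable statistics at
desk-scale runtimes:

* **Dispersion recovery** — cohorts at tau in {0, 0.1, 0.2, 0.4, 0.8}
  (8 patients each, 2–6 lesions, radius-7 lesions, ~16 voxel extent):
  the median across features of the cohort-mean CV is strictly
  increasing (Spearman vs tau >= 0.9), intensity-scale features track
  tau individually, and the tau = 0 cohort sits below tau = 0.8 for at
  least 80% of features.
* **Two-cohort screen** — 20 + 15 patients, 2–10 lesions each, with
  tau_B = 2 tau_A (0.4 vs 0.2): significant features overwhelmingly
  point at the high-dispersion cohort.
* **Null calibration** — 200 replicate studies of 24 + 24 patients with
  equal tau = 0.2 and reduced (radius-3) lesions: the across-feature
  mean rejection rate of non-flagged features at alpha = 0.05 must lie
  in [0.03, 0.07].  Cohort sizes of ~24 per arm keep the t-test within
  its validity regime given the skew of patient-wise CVs from few
  lesions; at 200 replicates the per-feature binomial noise (SE ~0.015)
  makes a per-feature band assertion meaningless, so the band is
  asserted on the across-feature mean and median.

## Known limitations

* The GLSZM/GLDM/NGTDM families use 26-connectivity only; 6-connectivity
  variants are not implemented.
* The CV is undefined for patients with one lesion and unstable for
  features whose mean crosses zero; such entries are flagged, not fixed.
* Exact Wilcoxon p-values require tie-free small samples; with ties the
  normal approximation is used automatically.
* Phantom realism is deliberately minimal (see above); parameter
  defaults (90 HU lesion mean, 20 HU sd, correlation length 1.5 vox,
  radius 7 vox) describe a plausible hypodense liver lesion but are not
  fitted to data.
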