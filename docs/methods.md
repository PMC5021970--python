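# Methods

This note documents the models and procedures implemented in `mitoganglia`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that make
runs reproducible.

## Image model and segmentation

The pipeline consumes already-deconvolved single-channel 3D stacks
(z, y, x order, 0-based) of a mitochondrial stain acquired in
photon-counting mode, so voxel values are non-negative integer counts and
the dominant noise is Poisson. Deconvolution itself is out of scope.

**Bit-depth adjustment.** 12-bit stacks are rescaled by `65535 / max(stack)`
using the per-stack maximum, with round-half-away-from-zero to integers.
This keeps integer photon-count semantics, maps the brightest voxel to
65535 exactly, and preserves intensity order. An all-zero stack has no
defined scale and is rejected.

**Dual pixel rules.** A voxel is mitochondrial when both hold:

* *local*: Gaussian-smoothed intensity (5×5 kernel, σ = 2, truncated and
  renormalized to unit sum) ≥ 1.25 × a 10×10 box-filter background
  estimate. Where the background estimate is ≤ 0 the ratio is undefined;
  the voxel passes iff the smoothed signal is positive, so a bright spot on
  an empty field is foreground.
* *global*: intensity after illumination correction (per-slice subtraction
  of a 20×20 box-filtered image, clamped at 0 because photon counts cannot
  be negative) strictly above a global Otsu threshold.

All linear filters run 2D per z-slice — the kernels are specified as 2D
sizes and slices are acquired independently — with replicate-edge padding so
borders do not produce spurious dark rims that would inflate the 1.25 ratio.
3D filter variants exist behind `SegmentationSettings.filters_3d` but are
off by default. Even-sized box kernels follow scipy's window convention
(a size-n window spans offsets −n//2 … n − n//2 − 1).

**Otsu.** The corrected stack's intensities are histogrammed into 256
equal-width bins over [min, max]; the threshold maximizes the between-class
variance w₀w₁(μ₀ − μ₁)², ties resolving to the lowest bin; the returned
threshold is that bin's centre, and foreground is *strictly above* it. A
constant stack has no separable classes and is an error. The implementation
(vectorized cumulative sums) is tested for exact agreement with a
brute-force exhaustive search and cross-checked against scikit-image.

**Components.** Connected components use 26-connectivity by default
(configurable 6/18/26; the component connectivity is not dictated by the
method description, unlike the 6-connected erosion element). Components with
fewer than 8 voxels are removed as shot noise and components with more than
10⁶ voxels as artefacts — both bounds inclusive on the keep side (8 kept,
10⁶ kept). Gating keeps *whole* components that intersect the ganglion mask
in at least one voxel; nothing is clipped.

## Ganglion masks

Per-slice ROI polygons ((x, y) pixel coordinates, ≥ 3 vertices) are
rasterized independently per slice — no interpolation between slices — with
pixel-centre-inclusive semantics: a centre on the polygon boundary counts as
inside. Volumes are voxel counts × dx·dy·dz; the x/y pixel size must always
be supplied since it depends on scan settings (only dz has a default,
0.18 μm).

## Morphometrics

* **Surface/body**: one erosion with the 6-connected structuring element;
  out-of-bounds neighbours count as background, so border voxels are
  surface. Surface + body = volume is an exact partition, property-tested.
* **Skeleton**: topology-preserving 3D thinning (Lee's method via
  scikit-image). Thinning is translation-invariant but only approximately
  symmetric under 90° rotations for blobby shapes; erosion-based features
  are exactly rotation-symmetric.
* **Nodes and degrees**: skeleton voxels are adjacent under 26-connectivity;
  a node has ≠ 2 skeleton neighbours (endpoint: 1, branchpoint: ≥ 3; an
  isolated voxel is one node of degree 0). A node's degree is the cumulated
  number of skeleton voxels over its incident branch segments, where a
  segment is the chain of degree-2 voxels plus the far terminal node. Plain
  graph degrees are recorded alongside for diagnostics. In a pure cycle
  there are no nodes; a loop attached to one node is counted once per
  incident branch end, i.e. its interior contributes twice to that node.
* **Skeleton length**: sum of anisotropic Euclidean steps
  √(Δx²dx² + Δy²dy² + Δz²dz²) between consecutive voxels along every branch,
  each branch measured once.

The per-ganglion feature vector is GanglionVolume plus seven mitochondrial
features. Three are fixed by their definitions (MitoCount = N/volume,
MitoVolumeMean, MitoVolumeTotal = Σvolume/volume); the remaining four
(surface fraction, nodes per object, mean cumulative node degree, mean
skeleton length) are reconstructions chosen to span exactly the
surface/body and branching analyses, and are labelled as such. With zero
objects the density features are 0 and the mean features are missing (NaN),
never 0. MitoVolumeMean is reported in μm³, consistent with GanglionVolume.

## Synthetic data

**Stacks.** `simulate_stack` renders rods, Y-branches (three arms along
pairwise non-adjacent corner diagonals) and blobs at a constant peak photon
count inside an ellipsoidal ganglion; adds base background plus a planar
ramp (and optional Gaussian vignette) — the simplest fields the 20×20
correction should remove; convolves with an anisotropic Gaussian PSF;
applies Poisson noise; and clips to 12 bits (to exercise the bit-depth
adjustment). Ground truth keeps the pre-blur object masks, exact volumes
(voxels × dx·dy·dz) and per-shape analytic node counts (rod 2, Y 4,
blob 1). Default conditions: 20×128×128 voxels at (0.1, 0.1, 0.18) μm,
30 objects of length 8–12 and radius 1.0–1.4 voxels, peak 150 counts,
background 3 + ramp amplitude 2, PSF σ = (0.5, 1, 1) voxels — a
peak-to-background ratio ≈ 30 after blur, typical of a well-stained
deconvolved stack. Object placement enforces a dilated-mask clearance
(2 voxels per object) so objects are disjoint and do not merge under the
PSF. The simulator is *not* optically realistic beyond a Gaussian PSF (no
Gibson–Lanni model, no depth-dependent aberrations, no neurofilament/DAPI
channels), so passing recovery tests shows the algorithm's correctness
under its stated assumptions, not performance on real tissue.

**Cohorts.** `simulate_cohort` draws each per-ganglion feature from a
log-normal — all features are positive and right-skewed, and are plotted on
log scales in this field — with multiplicative group and colon-side effects
as additive log-shifts. Control medians/log-sd defaults: GanglionVolume
(21,000 μm³, 0.71), the σ matching a cohort with mean ≈ 27,000 μm³ and
CV ≈ 0.81; mitochondrial summaries average over many objects and get
σ = 0.35 (CV ≈ 0.36), except the bounded surface fraction (σ = 0.08) and
node-count/degree summaries (0.15/0.30). Patient effects default to the
reported directions (volume ×0.63, count ×1.4, mass ×1.3, slight
fragmentation); right-colon effects ×1.25 on volume and ×0.9 on mean
object volume. Patient UPDRS-III scores are coupled to the log-deviation
of MitoVolumeMean with correlation −0.3 (fragmentation tracks worsening
motor score); controls carry only age. Features are conditionally
independent given group and side: there is no latent per-ganglion severity
factor, so two indicators (SVM score, ganglion volume) agree less often
within patients than in real data — the combined classifier's sensitivity
on synthetic cohorts (≈ 0.3) is accordingly conservative, while its
specificity (≈ 0.9) is representative.

## Statistics

* **Permutation test**: statistic |mean(x) − mean(y)|; labels reshuffled
  preserving group sizes (a permutation, not a bootstrap); p-value
  (1 + #{≥ observed}) / (n_perm + 1), never exactly 0, two-sided by
  construction. Permuted means of identical values can differ from the
  observed one by a few ulp depending on summation order, so exceedances
  are counted with a ~1e-9-relative tolerance; calibration is verified
  against exhaustive enumeration and by the type-I error over null
  simulations. Ganglia (not subjects) are the exchangeable units, matching
  the per-ganglion sample sizes; within-subject correlation is ignored — a
  caveat for real data.
* **Spearman** via midrank ties, two-sided p.
* **ROC/AUC**: trapezoidal integration, equal to the tie-aware
  pairwise-ordering fraction; optional permutation p-value against
  AUC = 0.5, with a Mann–Whitney normal approximation as the fast
  alternative.
* **PCA** on z-scored features (they span orders of magnitude); constant
  features are dropped with a warning; optional log10 transform upstream.
* **Clustermap**: pairwise-complete Spearman matrix, rows reordered by
  average-linkage clustering on Euclidean distances between correlation
  rows; no imputation of missing clinical values.

## Classification

The linear SVM is z-scored per training set (inside cross-validation the
scaler is fitted on training folds only — no leakage). "Assume an outlier
fraction f" is implemented as robust trimming: fit a linear C-SVM (C = 1),
drop the ⌊f·n⌋ training points with the worst signed margins, refit. A
ν-parameterization was considered and rejected: ν upper-bounds the margin-
violator fraction, so ν = 0.01 is infeasible once the classes overlap by
more than 1% and the solver degenerates. Cross-validation is stratified
(with ~40/65 class sizes, unstratified folds risk single-class test sets);
each repeat draws a fresh partition from a per-repeat seed, and the
held-out scores of the k folds are pooled into one AUC per repeat.

The combined classifier uses empirical quantiles with linear interpolation
between order statistics (numpy default; the 0.6/0.4 thresholds usually sit
between observations at n ≈ 100). Predictions — not the threshold values —
are invariant under strictly monotone transforms of scores and volumes. The
combination rule defaults to AND (predict patient only when the
mitochondrial score is high *and* the ganglion volume low), matching a
high-specificity use case; OR is available in configuration.

## Reproducibility

One top-level seed expands into per-stage child seeds via
`numpy.random.SeedSequence` (all < 2³¹), so stages can be re-run in
isolation; cohort subsampling uses a seeded Mersenne-Twister generator and
honours, when feasible, at least two ganglia per subject per colon side.
Re-running a pipeline config reproduces byte-identical outputs; the run log
records every numeric parameter of the segmentation (filter sizes, the 1.25
ratio, the 8 and 10⁶ cutoffs, Otsu threshold and per-filter removal counts)
so a run is auditable.

Test and acceptance problem sizes are deliberate package choices: 20
simulated stacks of 20×128×128 with 30 objects for recovery checks; 1,000
random histograms/score vectors for the Otsu and AUC oracle equivalences;
100 seeded cohort replicates at n = 50/group with 2,000-shuffle permutation
tests for effect-direction recovery (2,000 shuffles resolve p = 0.05
comfortably; the 100,000 default is used for single analyses); 1,000 null
datasets for type-I calibration.

## Known limitations

* No deconvolution, no ROI drawing, no vendor formats beyond TIFF/OME-TIFF.
* Skeleton-based features inherit the mild rotational asymmetry of 3D
  thinning; loop-rich skeletons use the documented per-branch-end degree
  convention.
* The cohort generator's conditional independence understates how jointly
  informative correlated biomarkers are (see above).
* No subject-level aggregation or mixed-effects modelling: ganglia are the
  analysis units throughout, and raw p-values are reported without
  multiple-testing correction.
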