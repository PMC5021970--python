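# mitoganglia

Quantitative 3D morphometrics of mitochondria inside enteric (submucosal)
ganglia from confocal fluorescence stacks — segmentation, per-ganglion
feature extraction, group statistics, and biomarker classification — plus a
synthetic-data generator so the entire chain is testable with known ground
truth.

## Who this is for

Researchers analysing immunofluorescence z-stacks of gut-wall ganglia (e.g.
colon biopsies stained for mitochondria and neurofilament) who want an
unbiased, reproducible 3D quantification of mitochondrial morphology and
ganglion volume, and a way to ask whether those morphometrics discriminate a
patient group from controls. Inputs are already-deconvolved TIFF/OME-TIFF
stacks with 12-bit photon-counting voxel values, per-slice ganglion ROI
polygons (or pre-rasterized binary masks), and the voxel geometry
(x/y pixel size in μm; z-step, default 0.18 μm).

## The method

**Segmentation.** A 12-bit stack is first rescaled to the full 16-bit range
(`v → round(v · 65535 / max)`), then a voxel counts as mitochondrial when two
independent rules agree:

1. *local rule* — its 5×5 Gaussian-smoothed (σ = 2) intensity is at least
   25% brighter than the surrounding background estimated with a 10×10
   average filter;
2. *global rule* — after illumination correction (subtracting a 20×20
   average-filtered image per slice, clamped at 0) it lies strictly above a
   global Otsu threshold, i.e. the 256-bin histogram split maximizing the
   between-class variance w₀w₁(μ₀ − μ₁)².

Connected components (26-connectivity by default) are filtered to
8 ≤ voxels ≤ 10⁶ (shot-noise and artefact removal) and restricted to
components intersecting the ganglion volume mask.

**Morphometrics.** Each object is split into *surface* (voxels removed by
one 6-connected erosion) and *body* (survivors), and skeletonized by 3D
topology-preserving thinning. Skeleton voxels with ≠ 2 neighbours
(26-adjacency) are *nodes* — endpoints and branchpoints — and a node's
*degree* is the cumulated count of skeleton voxels over its incident branch
segments (a straight n-voxel rod has 2 nodes of degree n − 1; a Y with three
3-voxel arms has 4 nodes, branchpoint degree 9). Per ganglion the feature
vector holds GanglionVolume (μm³) and seven mitochondrial features:
MitoCount (objects/μm³), MitoVolumeMean (μm³), MitoVolumeTotal
(volume fraction), MitoSurfaceFractionMean, MitoNodesMean,
MitoNodeDegreeMean and MitoSkeletonLengthMean (μm).

**Statistics & classification.** Group differences use a label-permutation
test on the absolute mean difference (default 100,000 shuffles, add-one
p-value estimator); correlations use Spearman's rank test; biomarker
performance uses trapezoidal ROC AUC. A robust linear SVM (z-scored
features; the assumed outlier fraction is trimmed and the model refitted) is
validated by 100 repeats of stratified 5-fold cross-validation, and an
integrated classifier thresholds the SVM score at its 0.6-quantile and the
ganglion volume at its 0.4-quantile (the 60/40 patient/control prior),
predicting *patient* when the score is high AND the volume low.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/01_simulate_and_segment.py` prints

```
stack: (20, 128, 128) voxels, 12-bit, max count 139
Otsu threshold (16-bit scale): 14609
components: 30 raw, 0 removed as shot noise (< 8 voxels), 30 kept
recovered 30/30 simulated objects (Jaccard >= 0.5), 0 spurious
```

— all 30 simulated mitochondria are recovered, with no false objects, on a
stack with a planar illumination gradient and Poisson photon noise. And
`python examples/04_classification.py`:

```
repeated 5-fold CV: mean AUC 0.726 over 100 repeats
combined classifier (score >= q0.6 AND volume <= q0.4):
  sensitivity 0.31, specificity 0.98
```

AUC 0.73 means mitochondrial morphology alone separates synthetic patients
from controls well above chance (0.5); the AND rule trades sensitivity for a
very low false-positive rate.

The command-line interface mirrors the same stages:

```bash
mitoganglia simulate --out demo --n-stacks 4 --seed 3
mitoganglia run-all --config demo/config.yaml
mitoganglia segment --stack s.ome.tif --ganglion-mask g.tif \
    --pixel-size-xy 0.1 --z-step 0.18 --out labels.tif --report seg.json
```

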