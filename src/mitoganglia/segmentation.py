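"""Mitochondrial segmentation: dual pixel rules, component filters, gating.

A voxel is accepted as mitochondrial when two independent rules agree:

1. *local rule* — its 5×5 Gaussian-smoothed (σ = 2) intensity is at least 25%
   brighter than the surrounding background estimated by a 10×10 average
   filter;
2. *global rule* — after illumination correction (subtracting a 20×20 average
   filtered version of each slice) it lies strictly above a global Otsu
   threshold of the corrected stack.

Connected components of the combined mask are then filtered by size
(shot-noise removal at < 8 voxels, oversized artefacts at > 10⁶ voxels) and
restricted to components touching the ganglion volume.

All linear filters operate 2D per z-slice with replicate-edge padding; 3D
variants can be requested but are off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ImageStack

__all__ = [
    "MitoComponent",
    "SegmentationSettings",
    "SegmentationReport",
    "local_rule_mask",
    "illumination_correct",
    "otsu_from_histogram",
    "otsu_threshold",
    "mito_pixel_mask",
    "label_components",
    "filter_components",
    "gate_by_ganglion",
    "segment_stack",
    "components_to_labels",
    "MIN_COMPONENT_VOXELS",
    "MAX_COMPONENT_VOXELS",
    "LOCAL_BRIGHTNESS_RATIO",
]

#: shot-noise filter: components below this voxel count are removed
MIN_COMPONENT_VOXELS = 8
#: oversized-artefact filter: components above this voxel count are removed
MAX_COMPONENT_VOXELS = 10**6
#: local rule: smoothed signal must exceed background by this factor
LOCAL_BRIGHTNESS_RATIO = 1.25


@dataclass
class MitoComponent:
    """One connected mitochondrial object."""

    id: int
    voxels: np.ndarray  # (N, 3) int array of (z, y, x) coordinates

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass
class SegmentationSettings:
    """Tunable parameters of the segmentation stage (defaults as documented)."""

    gaussian_size: int = 5
    gaussian_sigma: float = 2.0
    background_size: int = 10
    illumination_size: int = 20
    brightness_ratio: float = LOCAL_BRIGHTNESS_RATIO
    min_voxels: int = MIN_COMPONENT_VOXELS
    max_voxels: int = MAX_COMPONENT_VOXELS
    connectivity: int = 26
    otsu_bins: int = 256
    filters_3d: bool = False


@dataclass
class SegmentationReport:
    """Audit record of one segmentation run."""

    otsu_threshold: float = 0.0
    n_local_voxels: int = 0
    n_global_voxels: int = 0
    n_mito_voxels: int = 0
    n_components_raw: int = 0
    n_removed_small: int = 0
    n_removed_large: int = 0
    n_removed_outside: int = 0
    n_components_final: int = 0
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _per_slice(func, voxels: np.ndarray, filters_3d: bool) -> np.ndarray:
    if filters_3d:
        return func(voxels, True)
    out = np.empty(voxels.shape, dtype=np.float64)
    for z in range(voxels.shape[0]):
        out[z] = func(voxels[z], False)
    return out


def _gaussian(img, is3d, sigma=2.0, size=5):
    # truncate at the kernel radius so the discrete kernel has the requested
    # width; scipy renormalizes the truncated kernel to unit sum
    radius = (size - 1) // 2
    return ndimage.gaussian_filter(
        np.asarray(img, np.float64), sigma=sigma, truncate=radius / sigma, mode="nearest"
    )


def _boxmean(img, is3d, size=10):
    return ndimage.uniform_filter(np.asarray(img, np.float64), size=size, mode="nearest")


def local_rule_mask(
    stack: ImageStack, settings: SegmentationSettings | None = None
) -> np.ndarray:
    """Local-contrast rule of the mitochondrial pixel definition.

    True where the Gaussian-smoothed signal is >= ``brightness_ratio`` times
    the 10×10 box-filtered background. Where the background estimate is zero
    the ratio is undefined; such voxels pass when the smoothed signal is
    positive (a bright spot on an empty field is foreground).
    """
    s = settings or SegmentationSettings()
    if min(stack.shape[1:]) < s.background_size:
        warnings.warn("stack smaller than the background filter support")
    smooth = _per_slice(
        lambda im, d: _gaussian(im, d, s.gaussian_sigma, s.gaussian_size),
        stack.voxels,
        s.filters_3d,
    )
    background = _per_slice(
        lambda im, d: _boxmean(im, d, s.background_size), stack.voxels, s.filters_3d
    )
    mask = smooth >= s.brightness_ratio * background
    mask &= smooth > 0
    return mask


def illumination_correct(
    stack: ImageStack, settings: SegmentationSettings | None = None
) -> np.ndarray:
    """Subtract a 20×20 average-filtered version of each slice, clamped at 0.

    Removes smooth non-uniform illumination; the subtraction can go negative
    but photon counts cannot, so negatives are clipped. Returns float64.
    """
    s = settings or SegmentationSettings()
    low = _per_slice(
        lambda im, d: _boxmean(im, d, s.illumination_size), stack.voxels, s.filters_3d
    )
    return np.clip(stack.voxels.astype(np.float64) - low, 0.0, None)


def otsu_from_histogram(counts: np.ndarray, bin_centers: np.ndarray) -> int:
    """Index of the Otsu threshold bin for a given histogram.

    Maximizes the between-class variance w0·w1·(μ0 − μ1)² over all splits
    where both classes are non-empty; foreground is everything in bins
    strictly above the returned index. Ties resolve to the lowest index.
    """
    counts = np.asarray(counts, np.float64)
    centers = np.asarray(bin_centers, np.float64)
    w0 = np.cumsum(counts)
    total = w0[-1]
    if total <= 0:
        raise ValueError("empty histogram")
    w1 = total - w0
    m = np.cumsum(counts * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    if not np.isfinite(sigma_b).any():
        raise ValueError("histogram has a single occupied bin; classes not separable")
    return int(np.argmax(sigma_b))


def otsu_threshold(
    corrected: np.ndarray, n_bins: int = 256
) -> tuple[float, np.ndarray]:
    """Global Otsu threshold of a (corrected) stack.

    The stack's intensities are binned into ``n_bins`` equal-width bins; the
    returned threshold is the centre of the Otsu bin and the mask contains
    voxels strictly above it.
    """
    data = np.asarray(corrected, np.float64)
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("constant stack: no separable classes for Otsu")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    idx = otsu_from_histogram(counts, centers)
    threshold = float(centers[idx])
    return threshold, data > threshold


def mito_pixel_mask(
    stack16: ImageStack,
    settings: SegmentationSettings | None = None,
    report: SegmentationReport | None = None,
) -> np.ndarray:
    """Combined mitochondrial pixel mask: local rule AND global Otsu rule."""
    s = settings or SegmentationSettings()
    local = local_rule_mask(stack16, s)
    corrected = illumination_correct(stack16, s)
    threshold, global_mask = otsu_threshold(corrected, s.otsu_bins)
    mask = local & global_mask
    if report is not None:
        report.otsu_threshold = threshold
        report.n_local_voxels = int(local.sum())
        report.n_global_voxels = int(global_mask.sum())
        report.n_mito_voxels = int(mask.sum())
    return mask


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components(mask: np.ndarray, connectivity: int = 26) -> list[MitoComponent]:
    """Connected components of a binary mask (labels contiguous from 1)."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    comps = []
    coords = np.argwhere(labels > 0)
    if len(coords):
        lab = labels[tuple(coords.T)]
        order = np.argsort(lab, kind="stable")
        coords, lab = coords[order], lab[order]
        starts = np.searchsorted(lab, np.arange(1, n + 1))
        ends = np.append(starts[1:], len(lab))
        for i in range(n):
            comps.append(MitoComponent(i + 1, coords[starts[i] : ends[i]]))
    return comps


def filter_components(
    components: list[MitoComponent],
    min_voxels: int = MIN_COMPONENT_VOXELS,
    max_voxels: int = MAX_COMPONENT_VOXELS,
) -> list[MitoComponent]:
    """Keep components with ``min_voxels <= size <= max_voxels`` (inclusive)."""
    return [c for c in components if min_voxels <= c.voxel_count <= max_voxels]


def gate_by_ganglion(
    components: list[MitoComponent], ganglion: np.ndarray
) -> list[MitoComponent]:
    """Keep whole components that intersect the ganglion mask in >= 1 voxel."""
    ganglion = np.asarray(ganglion, bool)
    if not ganglion.any():
        raise ValueError("empty ganglion mask")
    return [c for c in components if ganglion[tuple(c.voxels.T)].any()]


def segment_stack(
    stack16: ImageStack,
    ganglion: np.ndarray | None = None,
    settings: SegmentationSettings | None = None,
) -> tuple[list[MitoComponent], SegmentationReport]:
    """Full segmentation: pixel rules -> components -> size filter -> gating."""
    s = settings or SegmentationSettings()
    report = SegmentationReport(settings=vars(s).copy())
    mask = mito_pixel_mask(stack16, s, report)
    comps = label_components(mask, s.connectivity)
    report.n_components_raw = len(comps)
    kept = filter_components(comps, s.min_voxels, s.max_voxels)
    report.n_removed_small = sum(
        1 for c in comps if c.voxel_count < s.min_voxels
    )
    report.n_removed_large = sum(
        1 for c in comps if c.voxel_count > s.max_voxels
    )
    if ganglion is not None:
        gated = gate_by_ganglion(kept, ganglion)
        report.n_removed_outside = len(kept) - len(gated)
        kept = gated
    # relabel contiguously after filtering
    kept = [MitoComponent(i + 1, c.voxels) for i, c in enumerate(kept)]
    report.n_components_final = len(kept)
    return kept, report


def components_to_labels(
    components: list[MitoComponent], shape: tuple[int, int, int]
) -> np.ndarray:
    """Render a component list as a 32-bit label image."""
    labels = np.zeros(shape, dtype=np.int32)
    for c in components:
        labels[tuple(c.voxels.T)] = c.id
    return labels
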