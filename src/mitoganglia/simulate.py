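"""Ground-truthed synthetic data: confocal-like stacks and feature cohorts.

Two generators make every downstream stage testable without microscope data:

``simulate_stack``
    renders bright tubular/branched mitochondrial objects inside an
    ellipsoidal ganglion, adds a smooth non-uniform background (planar ramp
    plus optional Gaussian vignette), blurs with a Gaussian PSF, and applies
    Poisson photon-counting noise, clipped to 12 bits. The returned ground
    truth holds the pre-blur object masks, their exact volumes and the
    analytic skeleton node count of each shape.

``simulate_cohort``
    draws per-ganglion morphometric features from log-normal distributions
    with multiplicative group (patient vs control) and colon-side effects,
    mirroring the directions reported for enteric ganglia in Parkinson's
    disease: patients with smaller ganglia, more mitochondria per volume and
    higher total mitochondrial mass. Features are positive and right-skewed,
    which is why a log-normal model is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageStack, VoxelGeometry, MITO_FEATURES

__all__ = [
    "MitoObjectSpec",
    "StackSimSpec",
    "GroundTruth",
    "CohortSimSpec",
    "simulate_stack",
    "simulate_cohort",
    "random_stack_spec",
    "RecoveryResult",
    "evaluate_recovery",
    "CONTROL_FEATURE_PARAMS",
    "PATIENT_EFFECTS",
    "SIDE_EFFECTS",
]

#: analytic skeleton node count per object shape (endpoints + branchpoints)
_SHAPE_NODES = {"rod": 2, "ybranch": 4, "blob": 1}


@dataclass
class MitoObjectSpec:
    """One simulated mitochondrial object.

    ``length``/``radius`` are in voxels (isotropic in index space); ``peak``
    is the photon count rendered inside the object before PSF blur.
    """

    shape: str  # rod | ybranch | blob
    position: tuple[float, float, float]  # (z, y, x) center, voxels
    length: float = 10.0
    radius: float = 1.0
    peak: float = 150.0
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)  # (z, y, x)

    def __post_init__(self) -> None:
        if self.shape not in _SHAPE_NODES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.peak <= 0:
            raise ValueError("peak intensity must be positive")

    @property
    def expected_nodes(self) -> int:
        return _SHAPE_NODES[self.shape]


@dataclass
class StackSimSpec:
    """Full recipe for one synthetic stack; ``seed`` fixes the realization."""

    shape: tuple[int, int, int] = (20, 128, 128)
    geometry: VoxelGeometry = field(default_factory=lambda: VoxelGeometry(0.1, 0.1, 0.18))
    ganglion_center: tuple[float, float, float] | None = None  # defaults to stack center
    ganglion_semiaxes: tuple[float, float, float] = (9.0, 55.0, 55.0)
    objects: list[MitoObjectSpec] = field(default_factory=list)
    background: float = 3.0
    gradient_amplitude: float = 2.0  # planar ramp, peak-to-base, photons
    vignette_amplitude: float = 0.0  # optional Gaussian vignette depth
    psf_sigma: tuple[float, float, float] = (0.5, 1.0, 1.0)  # (z, y, x) voxels
    noise: str = "poisson"  # poisson | none
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background < 0 or self.gradient_amplitude < 0:
            raise ValueError("intensities must be non-negative")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("PSF sigmas must be non-negative")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


@dataclass
class GroundTruth:
    """What the simulator actually drew, before optics and noise."""

    object_labels: np.ndarray  # int label image, 0 = background
    object_specs: list[MitoObjectSpec]
    ganglion_mask: np.ndarray
    geometry: VoxelGeometry

    @property
    def n_objects(self) -> int:
        return len(self.object_specs)

    def object_mask(self, i: int) -> np.ndarray:
        """Binary mask of object ``i`` (1-based label ``i + 1`` is not used;
        labels are 1-based, ``i`` is the 0-based object index)."""
        return self.object_labels == i + 1

    @property
    def object_volumes_um3(self) -> list[float]:
        vv = self.geometry.voxel_volume
        counts = np.bincount(self.object_labels.ravel(), minlength=self.n_objects + 1)
        return [counts[i + 1] * vv for i in range(self.n_objects)]

    @property
    def expected_node_counts(self) -> list[int]:
        return [o.expected_nodes for o in self.object_specs]


def _unit(v: tuple[float, float, float]) -> np.ndarray:
    a = np.asarray(v, float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("orientation must be non-zero")
    return a / n


def _render_segment(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Set voxels whose centre lies within ``radius`` of segment p0-p1."""
    lo = np.floor(np.minimum(p0, p1) - radius).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        *[np.arange(lo[i], hi[i], dtype=float) for i in range(3)], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - closest, axis=-1)
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub |= dist <= radius


def render_object_mask(obj: MitoObjectSpec, shape: tuple[int, int, int]) -> np.ndarray:
    """Voxelize one object spec into a binary mask."""
    mask = np.zeros(shape, dtype=bool)
    c = np.asarray(obj.position, float)
    if obj.shape == "blob":
        _render_segment(mask, c, c, obj.radius)
    elif obj.shape == "rod":
        d = _unit(obj.orientation) * (obj.length / 2.0)
        _render_segment(mask, c - d, c + d, obj.radius)
    else:  # ybranch: three arms 120 degrees apart in the plane normal-ish to z
        d = _unit(obj.orientation)
        # arm directions: rotate the orientation around z by 0, 120, 240 deg
        for k in range(3):
            ang = 2.0 * math.pi * k / 3.0
            cos, sin = math.cos(ang), math.sin(ang)
            arm = np.array(
                [d[0], d[1] * cos - d[2] * sin, d[1] * sin + d[2] * cos]
            )
            arm = _unit(tuple(arm)) * (obj.length / 2.0)
            _render_segment(mask, c, c + arm, obj.radius)
    if not mask.any():
        raise ValueError("object rendered outside the stack bounds")
    return mask


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def simulate_stack(spec: StackSimSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic 12-bit mitochondrial channel plus its ground truth."""
    shape = tuple(spec.shape)
    center = spec.ganglion_center or tuple((s - 1) / 2.0 for s in shape)
    ganglion = _ellipsoid_mask(shape, center, spec.ganglion_semiaxes)

    labels = np.zeros(shape, dtype=np.int32)
    signal = np.zeros(shape, dtype=np.float64)
    for i, obj in enumerate(spec.objects):
        m = render_object_mask(obj, shape)
        overlap = labels[m] != 0
        if overlap.any():
            raise ValueError(f"object {i} overlaps a previously placed object")
        labels[m] = i + 1
        signal[m] = np.maximum(signal[m], obj.peak)

    # smooth non-uniform illumination: planar ramp across x + optional vignette
    nz, ny, nx = shape
    field_img = np.full(shape, float(spec.background))
    if spec.gradient_amplitude > 0:
        ramp = np.linspace(0.0, spec.gradient_amplitude, nx)
        field_img += ramp[None, None, :]
    if spec.vignette_amplitude > 0:
        yy, xx = np.meshgrid(np.arange(ny, float), np.arange(nx, float), indexing="ij")
        r2 = ((yy - ny / 2) / (ny / 2)) ** 2 + ((xx - nx / 2) / (nx / 2)) ** 2
        field_img += spec.vignette_amplitude * np.exp(-r2)[None, :, :]

    image = field_img + signal
    if any(s > 0 for s in spec.psf_sigma):
        image = ndimage.gaussian_filter(image, sigma=spec.psf_sigma, mode="nearest")
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        image = rng.poisson(image).astype(np.float64)
    voxels = np.clip(np.round(image), 0, 4095).astype(np.uint16)

    stack = ImageStack(voxels, 12, spec.geometry, channel="mito")
    truth = GroundTruth(labels, list(spec.objects), ganglion, spec.geometry)
    return stack, truth


def random_stack_spec(
    seed: int,
    n_objects: int = 30,
    shape: tuple[int, int, int] = (20, 128, 128),
    clearance: int = 2,
    shapes: tuple[str, ...] = ("rod", "rod", "ybranch"),
    peak: float = 150.0,
    **overrides,
) -> StackSimSpec:
    """Draw a stack spec with ``n_objects`` well-separated objects inside the
    ganglion ellipsoid.

    Separation is enforced geometrically: each candidate object is rendered
    and accepted only when it keeps at least ``2 * clearance`` empty voxels
    from every previously placed object (checked on masks dilated by
    ``clearance``), so objects are disjoint and do not merge under a
    voxel-scale PSF.
    """
    rng = np.random.default_rng(seed)
    spec = StackSimSpec(shape=shape, seed=int(seed), **overrides)
    center = np.asarray(spec.ganglion_center or tuple((s - 1) / 2.0 for s in shape))
    semi = np.asarray(spec.ganglion_semiaxes)
    struct = ndimage.generate_binary_structure(3, 3)
    occupied = np.zeros(shape, dtype=bool)  # union of dilated object masks
    objects: list[MitoObjectSpec] = []
    attempts = 0
    while len(objects) < n_objects:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place objects with the requested clearance")
        u = rng.uniform(-0.9, 0.9, size=3)
        if (u**2).sum() > 0.9**2:  # keep centres inside the ellipsoid
            continue
        pos = center + u * semi
        margin = 4.0
        if np.any(pos < margin) or np.any(pos > np.asarray(shape) - 1 - margin):
            continue
        kind = shapes[len(objects) % len(shapes)]
        theta = rng.uniform(0, 2 * math.pi)
        orient = (0.35 * rng.uniform(-1, 1), math.sin(theta), math.cos(theta))
        obj = MitoObjectSpec(
            shape=kind,
            position=tuple(pos),
            length=float(rng.uniform(8, 12)),
            radius=float(rng.uniform(1.0, 1.4)),
            peak=peak,
            orientation=orient,
        )
        try:
            mask = render_object_mask(obj, shape)
        except ValueError:
            continue
        dilated = ndimage.binary_dilation(mask, struct, iterations=clearance)
        if (dilated & occupied).any():
            continue
        objects.append(obj)
        occupied |= dilated
    spec.objects = objects
    return spec


# ---------------------------------------------------------------------------
# Ground-truth recovery scoring


@dataclass
class RecoveryResult:
    """How well a segmentation recovered the simulated objects.

    A ground-truth object counts as *recovered* when some predicted component
    overlaps it with Jaccard >= ``min_jaccard`` (greedy one-to-one matching,
    best Jaccard first); unmatched predicted components are *spurious*.
    """

    n_truth: int
    n_predicted: int
    n_recovered: int
    n_spurious: int
    jaccards: list[float]

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")


def evaluate_recovery(
    truth: GroundTruth, components, min_jaccard: float = 0.5
) -> RecoveryResult:
    """Match predicted components against ground-truth object masks."""
    labels = truth.object_labels
    pairs = []  # (jaccard, truth_label, component_index)
    truth_sizes = np.bincount(labels.ravel(), minlength=truth.n_objects + 1)
    for ci, comp in enumerate(components):
        overlap_labels = labels[tuple(comp.voxels.T)]
        for lab in np.unique(overlap_labels):
            if lab == 0:
                continue
            inter = int((overlap_labels == lab).sum())
            union = int(truth_sizes[lab]) + comp.voxel_count - inter
            pairs.append((inter / union, int(lab), ci))
    pairs.sort(reverse=True)
    matched_truth: set[int] = set()
    matched_comp: set[int] = set()
    jaccards: list[float] = []
    for jac, lab, ci in pairs:
        if jac < min_jaccard:
            break
        if lab in matched_truth or ci in matched_comp:
            continue
        matched_truth.add(lab)
        matched_comp.add(ci)
        jaccards.append(jac)
    return RecoveryResult(
        n_truth=truth.n_objects,
        n_predicted=len(components),
        n_recovered=len(matched_truth),
        n_spurious=len(components) - len(matched_comp),
        jaccards=jaccards,
    )


# ---------------------------------------------------------------------------
# Cohorts of per-ganglion features

#: control-group log-normal parameters (median, log-scale sigma) per feature.
#: GanglionVolume matches a cohort with mean ≈ 27,000 μm³ and CV ≈ 0.8;
#: the per-ganglion mitochondrial summaries average over many objects and are
#: given a tighter spread (sigma 0.35, CV ≈ 0.36), except the bounded surface
#: fraction which varies little.
CONTROL_FEATURE_PARAMS: dict[str, tuple[float, float]] = {
    "GanglionVolume": (21000.0, 0.71),
    "MitoCount": (0.02, 0.35),
    "MitoVolumeMean": (0.20, 0.35),
    "MitoVolumeTotal": (0.004, 0.35),
    "MitoSurfaceFractionMean": (0.80, 0.08),
    "MitoNodesMean": (2.5, 0.15),
    "MitoNodeDegreeMean": (6.0, 0.30),
    "MitoSkeletonLengthMean": (1.0, 0.35),
}

#: multiplicative patient-vs-control effects, following the reported
#: directions: shrunken ganglia, more and fragmented mitochondria, higher mass
PATIENT_EFFECTS: dict[str, float] = {
    "GanglionVolume": 0.63,
    "MitoCount": 1.4,
    "MitoVolumeMean": 0.9,
    "MitoVolumeTotal": 1.3,
    "MitoSurfaceFractionMean": 1.05,
    "MitoNodesMean": 0.95,
    "MitoNodeDegreeMean": 0.9,
    "MitoSkeletonLengthMean": 0.95,
}

#: multiplicative right-colon (vs left) effects applied to both groups
SIDE_EFFECTS: dict[str, float] = {
    "GanglionVolume": 1.25,
    "MitoVolumeMean": 0.9,
}


@dataclass
class CohortSimSpec:
    """Two-group per-ganglion feature cohort recipe."""

    n_patients: int = 65
    n_controls: int = 41
    n_patient_subjects: int = 11
    n_control_subjects: int = 4
    control_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CONTROL_FEATURE_PARAMS)
    )
    patient_effects: dict[str, float] = field(
        default_factory=lambda: dict(PATIENT_EFFECTS)
    )
    side_effects: dict[str, float] = field(default_factory=lambda: dict(SIDE_EFFECTS))
    updrs_coupling: float = -0.3  # correlation of patient UPDRS-III with
    # the log-deviation of MitoVolumeMean (negative: fragmentation tracks
    # worsening motor score)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        for name, (med, sig) in self.control_params.items():
            if med <= 0 or sig <= 0:
                raise ValueError(f"non-positive log-normal parameters for {name}")
        for d in (self.patient_effects, self.side_effects):
            if any(e <= 0 for e in d.values()):
                raise ValueError("multiplicative effects must be positive")


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a two-group per-ganglion feature table.

    Each feature is log-normal: ``log X ~ Normal(log median + log effects,
    sigma)`` with group and side effects entering as additive log-shifts.
    Clinical scores are attached to patients only (controls keep age).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    n_subj = {"patient": spec.n_patient_subjects, "control": spec.n_control_subjects}
    counters = {"patient": 0, "control": 0}
    for i, group in enumerate(groups):
        idx = counters[group]
        counters[group] += 1
        subject = f"{group[0].upper()}{idx % n_subj[group] + 1:02d}"
        side = "right" if rng.random() < 0.5 else "left"
        row: dict = {
            "ganglion_id": f"G{i + 1:03d}",
            "subject_id": subject,
            "group": group,
            "side": side,
        }
        for name, (median, sigma) in spec.control_params.items():
            mu = math.log(median)
            if group == "patient":
                mu += math.log(spec.patient_effects.get(name, 1.0))
            if side == "right":
                mu += math.log(spec.side_effects.get(name, 1.0))
            z = rng.standard_normal()
            row[name] = math.exp(mu + sigma * z)
            if name == "MitoVolumeMean":
                mvm_z = z
        if group == "patient":
            # UPDRS rises as MitoVolumeMean falls (rho < 0 couples them)
            rho = spec.updrs_coupling
            noise = math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
            row["UPDRSIII"] = max(0.0, 10.7 + 8.1 * (rho * mvm_z + noise))
            row["SumMMSE"] = float(np.clip(round(28 + 2 * rng.standard_normal()), 0, 30))
            row["SchwabEngland"] = float(np.clip(round(90 + 8 * rng.standard_normal()), 0, 100))
            row["age"] = round(70 + 6 * rng.standard_normal(), 1)
        else:
            row["UPDRSIII"] = np.nan
            row["SumMMSE"] = np.nan
            row["SchwabEngland"] = np.nan
            row["age"] = round(65 + 5 * rng.standard_normal(), 1)
        rows.append(row)
    df = pd.DataFrame(rows)
    assert set(MITO_FEATURES) <= set(df.columns)
    return df
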