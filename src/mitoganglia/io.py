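"""Reading and writing image stacks, ROI files, masks and feature tables.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)``, 0-based;
* ROI polygons live in ``(x, y)`` pixel coordinates on a single z-slice;
* physical voxel geometry is carried explicitly (``VoxelGeometry``) because
  x/y pixel size depends on the scan settings and is never assumed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "GanglionROI",
    "adjust_to_16bit",
    "read_stack",
    "write_stack",
    "read_roi_json",
    "write_roi_json",
    "rasterize_roi",
    "read_mask",
    "write_mask",
    "FEATURE_COLUMNS",
    "MITO_FEATURES",
    "METADATA_COLUMNS",
    "CLINICAL_COLUMNS",
    "write_feature_table",
    "read_feature_table",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel size in micrometres.

    ``dz`` defaults to 0.18 μm, the z-step used for the confocal stacks this
    pipeline targets; ``dx``/``dy`` must always be supplied because the lateral
    pixel size depends on zoom and image size.
    """

    dx: float
    dy: float
    dz: float = 0.18

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel sizes must be positive, got {self}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dx * self.dy * self.dz


@dataclass
class ImageStack:
    """One channel's 3D voxel grid with bit depth and physical geometry.

    ``voxels`` is a non-negative integer array of shape ``(z, y, x)``.
    """

    voxels: np.ndarray
    bit_depth: int
    geometry: VoxelGeometry
    channel: str = "mito"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("stack must be a 3D (z, y, x) array with >= 1 slice")
        if self.bit_depth not in (12, 16):
            raise ValueError(f"bit_depth must be 12 or 16, got {self.bit_depth}")
        if self.voxels.size and (
            self.voxels.min() < 0 or self.voxels.max() > 2**self.bit_depth - 1
        ):
            raise ValueError(
                f"voxel values out of range for {self.bit_depth}-bit data"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class GanglionROI:
    """Per-slice closed polygons outlining the ganglion.

    ``polygons`` maps slice index -> list of ``(N, 2)`` vertex arrays in
    ``(x, y)`` pixel coordinates. A slice may carry several polygons; slices
    without an entry contribute nothing to the mask (no interpolation between
    slices is performed).
    """

    polygons: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def add(self, slice_index: int, vertices: Sequence[Sequence[float]]) -> None:
        arr = np.asarray(vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        self.polygons.setdefault(int(slice_index), []).append(arr)

    @property
    def n_polygons(self) -> int:
        return sum(len(v) for v in self.polygons.values())


def adjust_to_16bit(stack: ImageStack) -> ImageStack:
    """Rescale a 12-bit stack to the full 16-bit range.

    Every voxel is multiplied by ``65535 / max(stack)`` (the per-stack maximum)
    and rounded half-away-from-zero, so the brightest voxel maps to 65535
    exactly and the intensity order is preserved.
    """
    if stack.bit_depth == 16:
        return stack
    vmax = int(stack.voxels.max())
    if vmax == 0:
        raise ValueError("cannot adjust an all-zero stack (scale undefined)")
    scale = 65535.0 / vmax
    # values are non-negative so floor(v + 0.5) == round-half-away-from-zero
    out = np.floor(stack.voxels.astype(np.float64) * scale + 0.5).astype(np.uint16)
    return ImageStack(out, 16, stack.geometry, stack.channel)


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF stacks


def _geometry_from_tiff(tif: tifffile.TiffFile) -> VoxelGeometry | None:
    """Extract physical voxel sizes from OME metadata, if present."""
    if tif.ome_metadata is None:
        return None
    import xml.etree.ElementTree as ET

    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            try:
                dx = float(el.attrib["PhysicalSizeX"])
                dy = float(el.attrib["PhysicalSizeY"])
                dz = float(el.attrib["PhysicalSizeZ"])
            except (KeyError, ValueError):
                return None
            return VoxelGeometry(dx, dy, dz)
    return None


def read_stack(
    path: str | Path,
    geometry: VoxelGeometry | None = None,
    *,
    bit_depth: int = 16,
    channel: str = "mito",
    force_geometry: bool = False,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack.

    Geometry embedded in OME metadata takes precedence over the ``geometry``
    argument unless ``force_geometry`` is set; an error is raised when neither
    source provides it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: pages have inconsistent shapes {sorted(shapes)}")
        voxels = tif.asarray()
        meta_geom = _geometry_from_tiff(tif)
    if voxels.ndim == 2:
        voxels = voxels[None]
    if voxels.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {voxels.shape}")
    if force_geometry and geometry is not None:
        geom = geometry
    else:
        geom = meta_geom or geometry
    if geom is None:
        raise ValueError(f"{path}: no voxel geometry in metadata and none supplied")
    return ImageStack(voxels, bit_depth, geom, channel)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with its voxel sizes in the metadata."""
    g = stack.geometry
    tifffile.imwrite(
        Path(path),
        stack.voxels.astype(np.uint16),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": g.dx,
            "PhysicalSizeY": g.dy,
            "PhysicalSizeZ": g.dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


# ---------------------------------------------------------------------------
# ROI files and rasterization

ROI_SCHEMA_NOTE = (
    "ROI JSON schema: {'rois': [{'slice': int, 'vertices': [[x, y], ...]}, ...]}"
)


def read_roi_json(path: str | Path) -> GanglionROI:
    with open(path) as fh:
        data = json.load(fh)
    roi = GanglionROI()
    for entry in data["rois"]:
        roi.add(entry["slice"], entry["vertices"])
    return roi


def write_roi_json(roi: GanglionROI, path: str | Path) -> None:
    entries = [
        {"slice": z, "vertices": poly.tolist()}
        for z, polys in sorted(roi.polygons.items())
        for poly in polys
    ]
    with open(path, "w") as fh:
        json.dump({"rois": entries, "_schema": ROI_SCHEMA_NOTE}, fh, indent=1)


def rasterize_roi(
    roi: GanglionROI,
    shape: tuple[int, int, int],
    *,
    strict: bool = True,
) -> np.ndarray:
    """Rasterize per-slice polygons into a 3D boolean ganglion mask.

    A voxel is set when its pixel centre ``(x, y)`` lies inside or on the
    boundary of one of that slice's polygons. Slices without a polygon stay
    empty. With ``strict`` (default) an ROI without any polygon raises;
    otherwise an all-false mask is returned with a warning.
    """
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    if roi.n_polygons == 0:
        if strict:
            raise ValueError("ROI contains no polygons")
        warnings.warn("ROI contains no polygons; returning empty mask")
        return mask
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    pts = shapely.points(xs.ravel(), ys.ravel())
    for z, polys in roi.polygons.items():
        if not 0 <= z < nz:
            raise ValueError(f"ROI slice index {z} outside stack depth {nz}")
        for poly in polys:
            geom = shapely.Polygon(poly)
            inside = shapely.covers(geom, pts).reshape(ny, nx)
            mask[z] |= inside
    return mask


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit 0/255 mask TIFF as a boolean array."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(
        Path(path), np.asarray(mask, bool) * np.uint8(255), photometric="minisblack"
    )


# ---------------------------------------------------------------------------
# Feature tables

#: the seven per-ganglion mitochondrial morphology features
MITO_FEATURES = [
    "MitoCount",
    "MitoVolumeMean",
    "MitoVolumeTotal",
    "MitoSurfaceFractionMean",
    "MitoNodesMean",
    "MitoNodeDegreeMean",
    "MitoSkeletonLengthMean",
]

METADATA_COLUMNS = ["ganglion_id", "subject_id", "group", "side"]
CLINICAL_COLUMNS = ["UPDRSIII", "SumMMSE", "SchwabEngland", "age"]

#: fixed column order of feature tables on disk
FEATURE_COLUMNS = METADATA_COLUMNS + ["GanglionVolume"] + MITO_FEATURES + CLINICAL_COLUMNS


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-ganglion feature table as CSV in the documented column order.

    Missing values (e.g. clinical scores of controls, mean features of empty
    ganglia) are written as empty cells, never as 0.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(Path(path), index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    for col in ("group", "side", "subject_id", "ganglion_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df
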