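"""End-to-end orchestration: stacks -> segmentation -> features -> stats ->
classification, driven by a YAML config, with reproducible subsampling.

One top-level seed is expanded into per-stage child seeds through
``numpy.random.SeedSequence`` (stable derivation), so individual stages can be
re-run in isolation with the same randomness. Re-running an unchanged config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .io import MITO_FEATURES, VoxelGeometry
from .morphometrics import component_shape, ganglion_features, ganglion_volume
from .segmentation import (
    MitoComponent,
    SegmentationSettings,
    components_to_labels,
    segment_stack,
)
from .stats import correlation_clustermap, group_feature_tests
from .classify import combined_classify, repeated_cv_auc, train_linear_svm

__all__ = ["PipelineConfig", "run_pipeline", "subsample_ganglia", "stage_seeds"]

logger = logging.getLogger("mitoganglia")

SCHEMA_VERSION = 1

_STAGES = ("subsample", "stats", "cv", "spare")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive stable per-stage child seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


@dataclass
class StackEntry:
    """One ganglion's inputs: stack path plus mask or ROI and metadata."""

    ganglion_id: str
    stack: str
    subject_id: str = ""
    group: str = ""
    side: str = ""
    ganglion_mask: str | None = None
    roi: str | None = None
    bit_depth: int = 12
    clinical: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    manifest: list[StackEntry]
    geometry: VoxelGeometry
    output_dir: str
    seed: int = 0
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    n_perm: int = 100_000
    cv_repeats: int = 100
    cv_folds: int = 5
    q_score: float = 0.6
    q_volume: float = 0.4
    rule: str = "AND"
    subsample_n: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(p):
            return str((base / p).resolve()) if p and not Path(p).is_absolute() else p

        entries = []
        for e in raw["manifest"]:
            known = {f.name for f in dataclasses.fields(StackEntry)} - {"clinical"}
            entry = StackEntry(
                **{k: v for k, v in e.items() if k in known},
                clinical={k: v for k, v in e.items() if k not in known},
            )
            entry.stack = resolve(entry.stack)
            entry.ganglion_mask = resolve(entry.ganglion_mask)
            entry.roi = resolve(entry.roi)
            entries.append(entry)
        g = raw["geometry"]
        seg = SegmentationSettings(**raw.get("segmentation", {}))
        s = raw.get("stats", {})
        c = raw.get("classification", {})
        return cls(
            manifest=entries,
            geometry=VoxelGeometry(g["dx"], g["dy"], g.get("dz", 0.18)),
            output_dir=resolve(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            segmentation=seg,
            n_perm=int(s.get("n_perm", 100_000)),
            cv_repeats=int(c.get("repeats", 100)),
            cv_folds=int(c.get("folds", 5)),
            q_score=float(c.get("q_score", 0.6)),
            q_volume=float(c.get("q_volume", 0.4)),
            rule=str(c.get("rule", "AND")),
            subsample_n=raw.get("subsample", {}).get("n"),
        )

    def validate(self) -> None:
        """Fail fast: every referenced file must exist before any compute."""
        if not self.manifest:
            raise ValueError("empty manifest")
        for e in self.manifest:
            if not Path(e.stack).is_file():
                raise FileNotFoundError(f"{e.ganglion_id}: stack not found: {e.stack}")
            if e.ganglion_mask is None and e.roi is None:
                raise ValueError(f"{e.ganglion_id}: needs ganglion_mask or roi")
            for p in (e.ganglion_mask, e.roi):
                if p is not None and not Path(p).is_file():
                    raise FileNotFoundError(f"{e.ganglion_id}: missing input: {p}")


def subsample_ganglia(
    table: pd.DataFrame, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Random subsample of ``n`` ganglia keeping, when feasible, at least two
    ganglia per subject per colon side (seeded Mersenne-Twister draw)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(table):
        raise ValueError("n exceeds the number of ganglia")
    if n == len(table):
        return table.copy()
    rng = np.random.Generator(np.random.MT19937(seed))
    mandatory: list[int] = []
    for _, grp in table.groupby(["subject_id", "side"], sort=True):
        idx = grp.index.to_numpy()
        take = min(2, len(idx))
        mandatory.extend(rng.choice(idx, size=take, replace=False).tolist())
    if len(mandatory) > n:
        # constraint infeasible at this n: fall back to a uniform draw
        chosen = rng.choice(table.index.to_numpy(), size=n, replace=False)
    else:
        rest = np.array([i for i in table.index if i not in set(mandatory)])
        extra = rng.choice(rest, size=n - len(mandatory), replace=False) if len(mandatory) < n else []
        chosen = np.concatenate([np.array(mandatory, dtype=int), np.asarray(extra, dtype=int)])
    return table.loc[np.sort(chosen)].copy()


def _labels_to_components(labels: np.ndarray) -> list[MitoComponent]:
    comps = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        comps.append(MitoComponent(int(lab), np.argwhere(labels == lab)))
    return comps


def extract_features_for_entry(
    entry: StackEntry,
    geometry: VoxelGeometry,
    settings: SegmentationSettings,
    out_dir: Path | None = None,
) -> tuple[dict, pd.DataFrame, dict]:
    """Segment one stack and compute its feature-vector row.

    Returns ``(feature_row, per_object_table, segmentation_report_dict)``.
    """
    stack = mio.read_stack(entry.stack, geometry, bit_depth=entry.bit_depth)
    if stack.bit_depth == 12:
        stack = mio.adjust_to_16bit(stack)
    if entry.ganglion_mask:
        gmask = mio.read_mask(entry.ganglion_mask)
    else:
        roi = mio.read_roi_json(entry.roi)
        gmask = mio.rasterize_roi(roi, stack.shape)
    if gmask.shape != stack.shape:
        raise ValueError(f"{entry.ganglion_id}: ganglion mask shape mismatch")

    comps, report = segment_stack(stack, gmask, settings)
    logger.info(
        "%s: otsu=%.1f raw=%d small=%d large=%d outside=%d final=%d",
        entry.ganglion_id,
        report.otsu_threshold,
        report.n_components_raw,
        report.n_removed_small,
        report.n_removed_large,
        report.n_removed_outside,
        report.n_components_final,
    )
    shapes = [component_shape(c, geometry) for c in comps]
    gvol = ganglion_volume(gmask, geometry)
    meta = {
        "ganglion_id": entry.ganglion_id,
        "subject_id": entry.subject_id,
        "group": entry.group,
        "side": entry.side,
        **entry.clinical,
    }
    row = ganglion_features(shapes, gvol, meta)
    per_object = pd.DataFrame(
        [
            {
                "ganglion_id": entry.ganglion_id,
                "object_id": c.id,
                "volume_vox": s.volume_vox,
                "volume_um3": s.volume_um3,
                "surface_vox": s.surface_vox,
                "body_vox": s.body_vox,
                "skeleton_vox": s.skeleton_vox,
                "skeleton_length_um": s.skeleton_length_um,
                "node_count": s.node_count,
                "mean_node_degree": s.mean_node_degree,
            }
            for c, s in zip(comps, shapes)
        ]
    )
    if out_dir is not None:
        labels = components_to_labels(comps, stack.shape)
        import tifffile

        tifffile.imwrite(out_dir / f"{entry.ganglion_id}_labels.tif", labels, photometric="minisblack")
    return row, per_object, report.to_dict()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Writes ``features.csv``, ``objects.csv``, ``stats.json``,
    ``classify.json``, ``correlations.csv`` and ``run.log``. Any stage failure
    aborts with the stage name and the offending input in the message.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = stage_seeds(config.seed)
    try:
        logger.info("seed=%d stage_seeds=%s", config.seed, seeds)
        logger.info(
            "segmentation settings: gaussian %dpx sigma %.1f, background %dx%d, "
            "illumination %dx%d, brightness ratio %.2f, size filter [%d, %d], "
            "connectivity %d, otsu bins %d",
            config.segmentation.gaussian_size,
            config.segmentation.gaussian_sigma,
            config.segmentation.background_size,
            config.segmentation.background_size,
            config.segmentation.illumination_size,
            config.segmentation.illumination_size,
            config.segmentation.brightness_ratio,
            config.segmentation.min_voxels,
            config.segmentation.max_voxels,
            config.segmentation.connectivity,
            config.segmentation.otsu_bins,
        )

        rows, object_tables, reports = [], [], {}
        for entry in config.manifest:
            try:
                row, per_object, rep = extract_features_for_entry(
                    entry, config.geometry, config.segmentation, out
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage=segmentation input={entry.ganglion_id}: {exc}"
                ) from exc
            rows.append(row)
            object_tables.append(per_object)
            reports[entry.ganglion_id] = rep
        features = pd.DataFrame(rows)

        if config.subsample_n is not None:
            features = subsample_ganglia(
                features, config.subsample_n, seeds["subsample"]
            )
        mio.write_feature_table(features, out / "features.csv")
        objects = pd.concat([t for t in object_tables if len(t)], ignore_index=True) if any(
            len(t) for t in object_tables
        ) else pd.DataFrame()
        objects.to_csv(out / "objects.csv", index=False)

        stats_out: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                           "segmentation_reports": reports}
        groups = set(features["group"])
        feature_names = ["GanglionVolume"] + MITO_FEATURES
        group_sizes = features["group"].value_counts()
        can_test = {"patient", "control"} <= groups and (
            group_sizes.reindex(["patient", "control"]).fillna(0) >= 2
        ).all()
        if not can_test:
            stats_out["skipped"] = "need >= 2 ganglia in each of patient and control"
            logger.info("group tests skipped (groups: %s)", dict(group_sizes))
        if can_test:
            try:
                tests = group_feature_tests(
                    features, feature_names, n_perm=config.n_perm, seed=seeds["stats"]
                )
                stats_out["group_tests"] = tests.to_dict(orient="records")
            except Exception as exc:
                raise RuntimeError(f"stage=stats: {exc}") from exc
            numeric = features[feature_names].dropna(axis=1, how="all")
            if numeric.shape[1] >= 3 and len(features) >= 3:
                try:
                    cm = correlation_clustermap(features[list(numeric.columns)])
                    cm.correlations.to_csv(out / "correlations.csv")
                    stats_out["clustermap_order"] = cm.order
                except ValueError as exc:
                    logger.info("clustermap skipped: %s", exc)
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=1, default=float)

        cls_out: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed}
        counts = features["group"].value_counts()
        complete = features.dropna(subset=MITO_FEATURES)
        if (
            {"patient", "control"} <= groups
            and (complete["group"].value_counts().reindex(["patient", "control"]).fillna(0) >= config.cv_folds).all()
        ):
            try:
                X = complete[MITO_FEATURES].to_numpy()
                y = complete["group"].to_numpy()
                _, train_scores = train_linear_svm(X, y)
                cv = repeated_cv_auc(
                    X, y, n_repeats=config.cv_repeats, k=config.cv_folds,
                    seed=seeds["cv"],
                )
                clf, preds, confusion = combined_classify(
                    train_scores,
                    complete["GanglionVolume"].to_numpy(),
                    (y == "patient"),
                    q_score=config.q_score,
                    q_volume=config.q_volume,
                    rule=config.rule,
                )
                cls_out.update(
                    mean_cv_auc=cv.mean_auc,
                    repeat_aucs=list(map(float, cv.repeat_aucs)),
                    n_repeats=cv.n_repeats,
                    k=cv.k,
                    score_threshold=clf.score_threshold,
                    volume_threshold=clf.volume_threshold,
                    q_score=clf.q_score,
                    q_volume=clf.q_volume,
                    rule=clf.rule,
                    confusion=confusion.to_dict(),
                )
            except Exception as exc:
                raise RuntimeError(f"stage=classification: {exc}") from exc
        else:
            cls_out["skipped"] = "need both groups with >= k complete ganglia"
            logger.info("classification skipped (groups: %s)", dict(counts))
        with open(out / "classify.json", "w") as fh:
            json.dump(cls_out, fh, indent=1, default=float)
        logger.info("pipeline complete: %d ganglia", len(features))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
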