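"""End-to-end orchestration: training-set development, image quantification,
data assembly.  Config-file driven (no interactive prompts); every run is
registered in the experiment catalogue so outputs stay reachable and
reproducible.

The three flows are:

* :func:`run_training` — segment the training images, compute feature tables,
  train the Random Forest on the annotated cells, write the model plus
  classification overlays at each confidence threshold into a time-stamped
  iteration folder.
* :func:`run_quantification` — segment each test image with the iteration's
  parameters, classify with its model, background-correct the signal channel
  and produce per-cell quadrant and derived fluorescence measures plus class
  summaries.
* :func:`run_assembly` — concatenate per-cell tables across selected images
  into one compiled CSV and render summary plots.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import cell_classifier as cc
from . import fluor_quant as fq
from .geometry import ROI_KINDS, TissueFrame, assign_quadrants
from .image_io import (
    ExperimentCatalog,
    build_experiment_catalog,
    export_compiled_data,
    load_two_channel_image,
    timestamped_folder,
)
from .morphometrics import compute_feature_table, FEATURE_NAMES
from .segmentation import SegmentationParams, segment_image

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLDS = (0.5, 0.7, 0.9)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and image id."""


@dataclass
class TrainingIteration:
    """Reproducible record of one training-set iteration."""

    iteration_id: str
    folder: str
    segmentation: dict
    feature_subset: tuple[str, ...]
    class_names: tuple[str, ...]
    model_path: str
    annotation_path: str
    centers: dict[str, tuple[float, float]]
    pixel_size_um: float
    n_trees: int
    seed: int

    def save(self) -> Path:
        path = Path(self.folder) / "iteration.json"
        payload = asdict(self)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainingIteration":
        payload = json.loads(Path(path).read_text())
        payload["feature_subset"] = tuple(payload["feature_subset"])
        payload["class_names"] = tuple(payload["class_names"])
        payload["centers"] = {k: tuple(v) for k, v in payload["centers"].items()}
        return cls(**payload)

    def load_model(self) -> cc.ClassifierModel:
        return cc.ClassifierModel.load(self.model_path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _segmentation_params(config: dict) -> SegmentationParams:
    s = config.get("segmentation", {}) or {}
    crop = s.get("crop")
    return SegmentationParams(
        smoothing_variance_px=float(s.get("smoothing_variance_px", 1.0)),
        merge_depth_threshold=float(s.get("merge_depth_threshold", 10.0)),
        crop_region=tuple(crop) if crop else None,
    )


def _center_for(config: dict, image_id: str) -> tuple[float, float]:
    centers = config.get("centers", {}) or {}
    if image_id not in centers:
        raise PipelineError(f"[centers] no tissue center configured for image {image_id!r}")
    x, y = centers[image_id]
    return float(x), float(y)


def _stage(stage: str, image_id: str):
    """Context wrapper turning stage failures into PipelineError with context."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(f"[{stage}] image {image_id!r}: {exc}") from exc
            logger.info("stage %s on %s finished in %.2fs", stage, image_id, dt)
            return False

    return _Ctx()


def _process_image(record, config: dict, params: SegmentationParams):
    """Shared load → segment → features sequence for one catalogued image."""
    pixel_size = float(config["pixel_size_um"])
    with _stage("load", record.image_id):
        image = load_two_channel_image(record.source_path, pixel_size, record.metadata)
    with _stage("segment", record.image_id):
        seg = segment_image(image.reference, params)
        logger.info("image %s: %d cells segmented", record.image_id, seg.n_cells)
    with _stage("features", record.image_id):
        frame = TissueFrame(_center_for(config, record.image_id), pixel_size)
        table = compute_feature_table(seg, image.reference, frame)
    return image, seg, frame, table


def run_training(config: dict, catalog: ExperimentCatalog) -> TrainingIteration:
    """Training-set development: segment, featurise, annotate, train, record."""
    tr = config.get("training", {}) or {}
    image_ids = tr.get("images") or [r.image_id for r in catalog.records]
    annotations = pd.read_csv(tr["annotations"])
    features = tr.get("features", 18)
    if features == 18 or features == "18":
        subset = cc.DEFAULT_FEATURES_18
    else:
        subset = tuple(features)
    seed = int(tr.get("seed", 0))
    n_trees = int(tr.get("n_trees", 500))
    params = _segmentation_params(config)
    thresholds = tuple(config.get("confidence_thresholds", DEFAULT_CONFIDENCE_THRESHOLDS))
    plots = bool(config.get("plots", False))

    folder = timestamped_folder(catalog.output_folder, "iteration")
    iteration_id = folder.name
    tables: dict[str, pd.DataFrame] = {}
    staged = {}
    for image_id in image_ids:
        record = catalog.get(image_id)
        image, seg, frame, table = _process_image(record, config, params)
        tables[image_id] = table
        staged[image_id] = (image, seg, frame)
        table.to_csv(folder / f"{image_id}_features.csv")

    with _stage("train", ",".join(image_ids)):
        model = cc.train_random_forest(
            tables,
            annotations,
            feature_subset=subset,
            n_trees=n_trees,
            seed=seed,
            class_names=tr.get("classes"),
        )
    model.iteration_id = iteration_id
    model_path = folder / "model.joblib"
    model.save(model_path)
    pd.DataFrame(cc.rank_feature_importance(model), columns=["feature", "importance"]).to_csv(
        folder / "feature_importance.csv", index=False
    )

    for image_id in image_ids:
        image, seg, frame = staged[image_id]
        preds = cc.predict_with_confidence(model, tables[image_id])
        preds.to_csv(folder / f"{image_id}_predictions.csv", index=False)
        if plots:
            for thr in thresholds:
                render_classification_overlay(
                    image.reference,
                    seg.roic,
                    cc.filter_by_confidence(preds, thr),
                    tuple(model.class_names),
                    folder / f"{image_id}_classes_{int(thr * 100)}.png",
                )
        record = catalog.get(image_id)
        record.outputs[f"training_predictions_{iteration_id}"] = str(
            folder / f"{image_id}_predictions.csv"
        )
        record.training_iteration = iteration_id

    iteration = TrainingIteration(
        iteration_id=iteration_id,
        folder=str(folder),
        segmentation={
            "smoothing_variance_px": params.smoothing_variance_px,
            "merge_depth_threshold": params.merge_depth_threshold,
            "crop": list(params.crop_region) if params.crop_region else None,
        },
        feature_subset=model.feature_subset,
        class_names=tuple(model.class_names),
        model_path=str(model_path),
        annotation_path=str(tr["annotations"]),
        centers={i: _center_for(config, i) for i in image_ids},
        pixel_size_um=float(config["pixel_size_um"]),
        n_trees=n_trees,
        seed=seed,
    )
    iteration.save()
    catalog.save()
    return iteration


def quadrant_measures_wide(qm: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy quadrant measures to one row per cell.

    Column order is ROI-kind-major (C, L, W), then quadrant 1–4, then
    mean/std/size, e.g. ``C_q1_mean, C_q1_std, C_q1_size, C_q2_mean, ...``.
    """
    wide = qm.pivot_table(
        index="cell_id",
        columns=["roi_kind", "quadrant"],
        values=["mean", "std", "size"],
        sort=False,
        dropna=False,
    )
    cols = []
    for kind in ROI_KINDS:
        for q in fq.QUADRANTS:
            for stat in ("mean", "std", "size"):
                cols.append((stat, kind, q))
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    wide.columns = [f"{kind}_q{q}_{stat}" for stat, kind, q in wide.columns]
    return wide


def run_quantification(
    config: dict,
    catalog: ExperimentCatalog,
    iteration: TrainingIteration,
    image_ids: list[str] | None = None,
    threshold: float = 0.7,
) -> dict[str, pd.DataFrame]:
    """Quantify each test image with the iteration's parameters and model.

    Returns image_id → per-cell table (class, confidence, features, quadrant
    measures, derived measures); also writes each table as CSV and registers
    it in the catalogue under the ``cells`` output.
    """
    model = iteration.load_model()
    params = SegmentationParams(
        smoothing_variance_px=iteration.segmentation["smoothing_variance_px"],
        merge_depth_threshold=iteration.segmentation["merge_depth_threshold"],
        crop_region=tuple(iteration.segmentation["crop"])
        if iteration.segmentation.get("crop")
        else None,
    )
    image_ids = image_ids or [r.image_id for r in catalog.records]
    plots = bool(config.get("plots", False))
    folder = timestamped_folder(catalog.output_folder, "quantification")
    results: dict[str, pd.DataFrame] = {}
    for image_id in image_ids:
        record = catalog.get(image_id)
        image, seg, frame, table = _process_image(record, config, params)
        missing = [f for f in model.feature_subset if f not in table.columns]
        if missing:
            raise PipelineError(
                f"[classify] image {image_id!r}: model features absent from table: {missing}"
            )
        with _stage("classify", image_id):
            preds = cc.predict_with_confidence(model, table)
        with _stage("quantify", image_id):
            corrected = fq.background_correct(image.signal, seg.roic)
            quad = assign_quadrants(seg, frame)
            qm = fq.quantify_roi_quadrants(corrected, seg, quad)
            derived = fq.derive_measures(qm)
            summary = fq.summarize_by_class(derived, preds, threshold)
        cells = (
            preds.set_index("cell_id")
            .join(table)
            .join(quadrant_measures_wide(qm))
            .join(derived)
            .reset_index()
        )
        out_csv = folder / f"{image_id}_cells.csv"
        cells.to_csv(out_csv, index=False)
        summary.to_csv(folder / f"{image_id}_class_summary.csv")
        record.outputs["cells"] = str(out_csv)
        record.outputs["class_summary"] = str(folder / f"{image_id}_class_summary.csv")
        record.training_iteration = iteration.iteration_id
        if plots:
            render_segmentation_overlay(
                image.reference, seg.roic, folder / f"{image_id}_segmentation.png"
            )
            render_measure_heatmap(
                seg.roiw,
                derived["Wallsignal"],
                folder / f"{image_id}_wallsignal.png",
            )
        results[image_id] = cells
    catalog.save()
    return results


def run_assembly(
    catalog: ExperimentCatalog,
    factor_filter: dict | None = None,
    out_path: str | Path | None = None,
    plot_measure: str | None = None,
) -> pd.DataFrame:
    """Concatenate per-cell tables for selected images into one compiled CSV."""
    out_path = out_path or Path(catalog.output_folder) / "DataRawCompile.csv"
    compiled = export_compiled_data(catalog, factor_filter, out_path)
    if plot_measure is not None:
        g = compiled.groupby("class_label")[plot_measure]
        render_class_barplot(
            g.mean(),
            g.std(ddof=0),
            plot_measure,
            Path(out_path).with_suffix(f".{plot_measure}.png"),
        )
    return compiled


# ---------------------------------------------------------------------------
# Diagnostic renderers
# ---------------------------------------------------------------------------

def _random_cell_colors(n: int, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    colors = rng.uniform(0.15, 1.0, size=(n + 1, 3))
    colors[0] = 0.0
    return colors


def render_segmentation_overlay(reference: np.ndarray, roic: np.ndarray, path) -> None:
    """Random colour per cell over the counterstain channel."""
    colors = _random_cell_colors(int(roic.max()))
    rgb = colors[roic]
    ref = np.asarray(reference, dtype=float)
    ref = ref / ref.max() if ref.max() > 0 else ref
    blend = 0.55 * rgb + 0.45 * ref[..., None]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.clip(blend, 0, 1))
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_classification_overlay(
    reference: np.ndarray,
    roic: np.ndarray,
    preds: pd.DataFrame,
    class_names: tuple[str, ...],
    path,
) -> None:
    """Class-coloured cells (unclassified / filtered-out cells stay grey)."""
    cmap = plt.get_cmap("tab10")
    class_color = {c: cmap(i % 10)[:3] for i, c in enumerate(class_names)}
    lut = np.full((int(roic.max()) + 1, 3), 0.25)
    lut[0] = 0.0
    for _, row in preds.iterrows():
        lut[int(row["cell_id"])] = class_color[row["class_label"]]
    ref = np.asarray(reference, dtype=float)
    ref = ref / ref.max() if ref.max() > 0 else ref
    blend = 0.6 * lut[roic] + 0.4 * ref[..., None]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.clip(blend, 0, 1))
    ax.set_axis_off()
    handles = [plt.Line2D([], [], marker="s", ls="", color=class_color[c], label=c)
               for c in class_names]
    ax.legend(handles=handles, loc="lower right", fontsize=6)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_measure_heatmap(roi: np.ndarray, values: pd.Series, path) -> None:
    """Grey-scale heatmap of a per-cell measure painted over an ROI label map."""
    lut = np.zeros(int(roi.max()) + 1)
    finite = values[np.isfinite(values)]
    peak = finite.max() if len(finite) and finite.max() > 0 else 1.0
    for cid, v in values.items():
        if np.isfinite(v):
            lut[int(cid)] = v / peak
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(lut[roi], cmap="gray", vmin=0, vmax=1)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_class_barplot(means: pd.Series, stds: pd.Series, measure: str, path) -> None:
    """Per-class bar plot with standard-deviation error bars."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(means.index, means.to_numpy(), yerr=stds.to_numpy(), capsize=3)
    ax.set_ylabel(measure)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
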