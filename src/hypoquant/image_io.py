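"""Image loading, filename metadata, experiment catalogue and table export.

Input images are two-channel TIFFs: channel 0 is the cell-wall counterstain
(e.g. calcofluor white) used for segmentation, channel 1 the immunofluorescence
signal to be quantified.  Sample metadata travels in the filename as six
underscore-delimited tokens, e.g. ``C08R6_LM10_Col_21-day-old_Hyp_BR1``
(plate location, antibody, genotype, age, tissue, biological replicate).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

METADATA_FIELDS = ("plate_location", "antibody", "genotype", "age", "tissue", "replicate")

IMAGE_EXTENSIONS = {".tif", ".tiff"}


class MalformedNameError(ValueError):
    """Raised when a filename does not carry the six expected metadata tokens."""


class CatalogError(RuntimeError):
    """Raised for catalogue-level failures (empty folder, empty selection...)."""


@dataclass(frozen=True)
class SampleMetadata:
    """Six-token sample annotation parsed from an image filename."""

    plate_location: str
    antibody: str
    genotype: str
    age: str
    tissue: str
    replicate: str
    source_path: str = ""

    def __post_init__(self):
        for f in METADATA_FIELDS:
            if not getattr(self, f):
                raise ValueError(f"metadata token {f!r} must be non-empty")

    def format_name(self, ext: str = "") -> str:
        """Inverse of :func:`parse_image_filename` (extension optional)."""
        base = "_".join(getattr(self, f) for f in METADATA_FIELDS)
        return base + ext

    @property
    def image_id(self) -> str:
        return self.format_name()

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in METADATA_FIELDS}


@dataclass
class TwoChannelImage:
    """Reference (counterstain) + signal channel rasters with pixel size."""

    reference: np.ndarray
    signal: np.ndarray
    pixel_size_um: float
    metadata: SampleMetadata | None = None

    def __post_init__(self):
        self.reference = np.asarray(self.reference)
        self.signal = np.asarray(self.signal)
        if self.reference.shape != self.signal.shape:
            raise ValueError(
                f"channel shapes differ: {self.reference.shape} vs {self.signal.shape}"
            )
        if self.reference.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if (np.asarray(self.reference) < 0).any() or (np.asarray(self.signal) < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference.shape


def parse_image_filename(name: str) -> SampleMetadata:
    """Parse a six-token underscore-delimited basename into sample metadata.

    >>> parse_image_filename("C08R6_LM10_Col_21-day-old_Hyp_BR1").antibody
    'LM10'
    """
    if os.sep in name or "/" in name:
        raise MalformedNameError(f"{name!r} is not a basename")
    stem = name
    for ext in IMAGE_EXTENSIONS:
        if stem.lower().endswith(ext):
            stem = stem[: -len(ext)]
            break
    else:
        stem = os.path.splitext(stem)[0] if "." in stem else stem
    tokens = stem.split("_")
    if len(tokens) != len(METADATA_FIELDS):
        raise MalformedNameError(
            f"filename {name!r} has {len(tokens)} underscore-delimited tokens, "
            f"expected {len(METADATA_FIELDS)} "
            "(plate_antibody_genotype_age_tissue_replicate)"
        )
    return SampleMetadata(*tokens, source_path=name)


def load_two_channel_image(
    path: str | Path, pixel_size_um: float, metadata: SampleMetadata | None = None
) -> TwoChannelImage:
    """Read a 2-channel (or 2-page) TIFF; channel 0 → reference, 1 → signal."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # accept both channel-first (2, H, W) and channel-last (H, W, 2)
        if arr.shape[0] == 2:
            channels = [arr[0], arr[1]]
        elif arr.shape[-1] == 2:
            channels = [arr[..., 0], arr[..., 1]]
        else:
            n = arr.shape[0] if arr.shape[0] < arr.shape[-1] else arr.shape[-1]
            raise ValueError(f"{path}: expected 2 channels, found {n}")
    elif arr.ndim == 2:
        raise ValueError(f"{path}: expected 2 channels, found 1")
    else:
        raise ValueError(f"{path}: unsupported TIFF layout with shape {arr.shape}")
    if metadata is None:
        try:
            metadata = parse_image_filename(os.path.basename(str(path)))
        except MalformedNameError:
            metadata = None
    return TwoChannelImage(channels[0], channels[1], pixel_size_um, metadata)


def save_two_channel_image(path: str | Path, image: TwoChannelImage) -> None:
    """Write the two channels as a channel-first multi-page TIFF."""
    stack = np.stack([image.reference, image.signal])
    tifffile.imwrite(str(path), stack)


# ---------------------------------------------------------------------------
# Experiment catalogue ("ExperInfo")
# ---------------------------------------------------------------------------

@dataclass
class CatalogRecord:
    image_id: str
    metadata: SampleMetadata
    source_path: str
    outputs: dict = field(default_factory=dict)  # stage name -> path
    training_iteration: str | None = None


@dataclass
class ExperimentCatalog:
    """Registry of every image in an experiment and its per-stage outputs."""

    title: str
    output_folder: str
    records: list[CatalogRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.image_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise CatalogError("image ids must be unique")

    def add_record(self, record: CatalogRecord) -> None:
        if any(r.image_id == record.image_id for r in self.records):
            raise CatalogError(f"duplicate image id {record.image_id!r}")
        self.records.append(record)

    def get(self, image_id: str) -> CatalogRecord:
        for r in self.records:
            if r.image_id == image_id:
                return r
        raise KeyError(image_id)

    @property
    def path(self) -> Path:
        return Path(self.output_folder) / "catalog.json"

    def save(self) -> Path:
        payload = {
            "title": self.title,
            "output_folder": str(self.output_folder),
            "records": [
                {
                    "image_id": r.image_id,
                    "metadata": asdict(r.metadata),
                    "source_path": r.source_path,
                    "outputs": r.outputs,
                    "training_iteration": r.training_iteration,
                }
                for r in self.records
            ],
        }
        self.path.write_text(json.dumps(payload, indent=2))
        return self.path

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentCatalog":
        payload = json.loads(Path(path).read_text())
        records = [
            CatalogRecord(
                image_id=r["image_id"],
                metadata=SampleMetadata(**r["metadata"]),
                source_path=r["source_path"],
                outputs=r.get("outputs", {}),
                training_iteration=r.get("training_iteration"),
            )
            for r in payload["records"]
        ]
        return cls(payload["title"], payload["output_folder"], records)


def timestamped_folder(root: str | Path, title: str) -> Path:
    """Create ``<root>/<title>_<ISO-8601 timestamp>`` (never reuses a folder)."""
    root = Path(root)
    while True:
        stamp = datetime.now().strftime("%Y%m%dT%H%M%S.%f")
        folder = root / f"{title}_{stamp}"
        if not folder.exists():
            folder.mkdir(parents=True)
            return folder


def build_experiment_catalog(
    source_folder: str | Path, experiment_title: str, output_root: str | Path | None = None
) -> ExperimentCatalog:
    """Catalogue every parseable image in *source_folder*.

    Creates a fresh time-stamped output folder; files whose names do not carry
    the six metadata tokens are skipped with a warning.
    """
    source_folder = Path(source_folder)
    if not source_folder.is_dir():
        raise CatalogError(f"source folder {source_folder} does not exist")
    output_root = Path(output_root) if output_root is not None else source_folder.parent
    candidates = sorted(
        p for p in source_folder.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not candidates:
        raise CatalogError(f"no image files found in {source_folder}")
    folder = timestamped_folder(output_root, experiment_title)
    catalog = ExperimentCatalog(experiment_title, str(folder))
    for p in candidates:
        try:
            meta = parse_image_filename(p.name)
        except MalformedNameError as exc:
            logger.warning("skipping %s: %s", p.name, exc)
            continue
        catalog.add_record(CatalogRecord(meta.image_id, meta, str(p)))
    if not catalog.records:
        raise CatalogError(f"no parseable image filenames in {source_folder}")
    catalog.save()
    return catalog


def export_compiled_data(
    catalog: ExperimentCatalog,
    factor_filter: dict[str, str | list[str]] | None = None,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Concatenate per-cell result tables across selected images.

    *factor_filter* maps metadata factors (``antibody``, ``genotype``, ...) to
    an allowed token or list of tokens.  Each selected record must have a
    completed ``cells`` output (per-cell CSV from quantification).  Returns the
    compiled table; writes it to *out_path* when given.
    """
    factor_filter = factor_filter or {}
    for factor in factor_filter:
        if factor not in METADATA_FIELDS:
            raise ValueError(f"unknown factor {factor!r}; valid: {METADATA_FIELDS}")
    selected = []
    for rec in catalog.records:
        keep = True
        for factor, allowed in factor_filter.items():
            allowed = [allowed] if isinstance(allowed, str) else list(allowed)
            if getattr(rec.metadata, factor) not in allowed:
                keep = False
                break
        if keep:
            selected.append(rec)
    if not selected:
        raise CatalogError(f"filter {factor_filter!r} selects no images")
    frames = []
    for rec in selected:
        cells_path = rec.outputs.get("cells")
        if cells_path is None:
            raise CatalogError(f"image {rec.image_id!r} has no quantification output")
        df = pd.read_csv(cells_path)
        df.insert(0, "image_id", rec.image_id)
        for i, f in enumerate(METADATA_FIELDS):
            df.insert(1 + i, f, getattr(rec.metadata, f))
        frames.append(df)
    compiled = pd.concat(frames, ignore_index=True)
    if out_path is not None:
        compiled.to_csv(out_path, index=False)
    return compiled
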