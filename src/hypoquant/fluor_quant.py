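"""Quantification of the immunofluorescence channel per cell, ROI and quadrant.

The counterstain-derived label maps act as masks on the (background-corrected)
signal channel.  For every cell, each of the three ROI kinds (C = whole cell,
L = lumen, W = wall) is measured in each of the four radial quadrants; the
derived per-cell measures combine the quadrant statistics into polarity
ratios (periclinal / anticlinal), totals, means, and a punctateness score.

All standard deviations use the population (n) denominator.  Undefined
measures (zero denominators, empty ROIs) are flagged missing as NaN — the
cell row is kept so class summaries can use per-measure n.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geometry import ROI_KINDS, QuadrantMap
from .segmentation import CellSegmentation

logger = logging.getLogger(__name__)

QUADRANTS = (1, 2, 3, 4)
ANTICLINAL = (1, 2)
PERICLINAL = (3, 4)

#: Derived-measure export order.
DERIVED_MEASURES = (
    "LumenRPA",
    "WallRPA",
    "CellRPA",
    "LumenRPAmean",
    "WallRPAmean",
    "CellRPAmean",
    "Lumensignal",
    "Wallsignal",
    "Cellsignal",
    "Lumensignalmean",
    "Wallsignalmean",
    "PvD",
)


def background_correct(signal: np.ndarray, roic: np.ndarray) -> np.ndarray:
    """Subtract the median non-tissue intensity; clamp negatives to zero.

    Background = median of signal pixels outside every cell (ROIC label 0).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != roic.shape:
        raise ValueError("signal and ROIC shapes differ")
    outside = roic == 0
    if not outside.any():
        logger.warning("tissue fills the frame; background correction is a no-op")
        background = 0.0
    else:
        background = float(np.median(signal[outside]))
    return np.clip(signal - background, 0.0, None)


def quantify_roi_quadrants(
    signal: np.ndarray, seg: CellSegmentation, quad: QuadrantMap
) -> pd.DataFrame:
    """Mean / std / area of the signal for every (cell, ROI kind, quadrant).

    Returns a tidy frame with columns ``cell_id, roi_kind, quadrant, mean,
    std, size`` (size in µm²); empty quadrants have size 0 and NaN mean/std.
    Cells with an undefined radial axis are excluded.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != seg.roic.shape:
        raise ValueError("signal and segmentation shapes differ")
    from scipy import ndimage as ndi

    px_area = quad.frame.pixel_size_um**2
    records = []
    ids = [int(k) for k in seg.cell_ids if int(k) not in quad.undefined_cells]
    rois = {"C": seg.roic, "L": seg.roil, "W": seg.roiw}
    bboxes = ndi.find_objects(seg.roic)
    for k in ids:
        box = bboxes[k - 1]
        sig_box = signal[box]
        quad_box = quad.labels[box]
        for kind in ROI_KINDS:
            in_roi = rois[kind][box] == k
            for q in QUADRANTS:
                vals = sig_box[in_roi & (quad_box == q)]
                n = vals.size
                records.append(
                    {
                        "cell_id": k,
                        "roi_kind": kind,
                        "quadrant": q,
                        "mean": float(vals.mean()) if n else np.nan,
                        "std": float(vals.std(ddof=0)) if n else np.nan,
                        "size": n * px_area,
                    }
                )
    return pd.DataFrame.from_records(records)


def _pooled_stats(sub: pd.DataFrame) -> tuple[float, float, float]:
    """Pooled (mean, std, area) over the four quadrants from quadrant stats."""
    nz = sub[sub["size"] > 0]
    area = float(sub["size"].sum())
    if area == 0 or nz.empty:
        return np.nan, np.nan, area
    w = nz["size"].to_numpy()
    mu = nz["mean"].to_numpy()
    sd = nz["std"].to_numpy()
    pooled_mean = float((w * mu).sum() / w.sum())
    pooled_var = float((w * (sd**2 + mu**2)).sum() / w.sum() - pooled_mean**2)
    return pooled_mean, float(np.sqrt(max(pooled_var, 0.0))), area


def derive_measures(qm: pd.DataFrame) -> pd.DataFrame:
    """Per-cell derived fluorescence measures from the quadrant statistics.

    For each ROI kind: RPA = summed periclinal signal / summed anticlinal
    signal; RPAmean = (mean₃ + mean₄) / (mean₁ + mean₂); total signal =
    Σ_q mean_q·size_q; signal mean = total / area.  PvD (punctateness vs
    diffuseness) = coefficient of variation of the lumen pixel intensities.
    Empty quadrants contribute zero signal; zero denominators give NaN.
    """
    rows = {}
    for cell_id, cell_df in qm.groupby("cell_id"):
        row: dict[str, float] = {}
        totals: dict[str, float] = {}
        for kind, word in (("L", "Lumen"), ("W", "Wall"), ("C", "Cell")):
            sub = cell_df[cell_df["roi_kind"] == kind].set_index("quadrant")
            qsignal = {
                q: (sub.loc[q, "mean"] * sub.loc[q, "size"] if sub.loc[q, "size"] > 0 else 0.0)
                for q in QUADRANTS
            }
            peri = sum(qsignal[q] for q in PERICLINAL)
            anti = sum(qsignal[q] for q in ANTICLINAL)
            row[f"{word}RPA"] = peri / anti if anti > 0 else np.nan
            means = {q: (sub.loc[q, "mean"] if sub.loc[q, "size"] > 0 else 0.0) for q in QUADRANTS}
            anti_mean = means[1] + means[2]
            row[f"{word}RPAmean"] = (
                (means[3] + means[4]) / anti_mean if anti_mean > 0 else np.nan
            )
            pooled_mean, pooled_std, area = _pooled_stats(sub)
            total = float(sum(qsignal.values()))
            totals[kind] = total
            row[f"{word}signal"] = total
            if word in ("Lumen", "Wall"):
                row[f"{word}signalmean"] = total / area if area > 0 else np.nan
            if kind == "L":
                row["PvD"] = (
                    pooled_std / pooled_mean if pooled_mean and pooled_mean > 0 else np.nan
                )
        rows[cell_id] = {m: row.get(m, np.nan) for m in DERIVED_MEASURES}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(DERIVED_MEASURES))
    out.index.name = "cell_id"
    return out


def summarize_by_class(
    derived: pd.DataFrame,
    preds: pd.DataFrame,
    threshold: float = 0.0,
    relative: bool = False,
) -> pd.DataFrame:
    """Mean ± std of every derived measure per class, after confidence filtering.

    Cells below *threshold* confidence are dropped; classes with no retained
    cells are omitted (logged).  With ``relative=True`` each measure's class
    means are additionally divided by the maximum class mean (columns suffixed
    ``_rel``), the normalisation used for relative-intensity bar plots.
    """
    retained = preds[preds["confidence"] >= threshold]
    if retained.empty:
        raise ValueError(f"no cells retained at confidence threshold {threshold}")
    merged = derived.merge(retained[["cell_id", "class_label"]], on="cell_id", how="inner")
    if merged.empty:
        raise ValueError("predictions and derived measures share no cells")
    dropped = set(preds["class_label"].unique()) - set(merged["class_label"].unique())
    for c in sorted(dropped):
        logger.info("class %s has no retained cells at threshold %.2f", c, threshold)
    g = merged.groupby("class_label")
    out = {"n": g.size()}
    for m in DERIVED_MEASURES:
        out[f"{m}_mean"] = g[m].mean()
        out[f"{m}_std"] = g[m].std(ddof=0)
    summary = pd.DataFrame(out)
    summary.index.name = "class_label"
    if relative:
        for m in DERIVED_MEASURES:
            peak = summary[f"{m}_mean"].max()
            summary[f"{m}_rel"] = summary[f"{m}_mean"] / peak if peak and peak > 0 else np.nan
    return summary
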