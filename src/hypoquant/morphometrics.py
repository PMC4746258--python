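"""Per-cell morphometric features (the 22-feature vector used for classification).

Position features use two origins: ``m.cx``/``m.cy`` from the image top-left,
``Xnew``/``Ynew``/``radialV``/``angleV`` from the tissue centre.  Shape
features come from principal-component analysis of the cell's pixel
coordinates (axis length = 4·√eigenvalue, the full-axis convention that
recovers the true axes of a filled ellipse), a boundary-length perimeter
estimate, and border-to-centroid radius statistics.  Intensity features are
median/mean counterstain intensity over the whole cell and over its wall.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import perimeter as _perimeter_estimate

from .geometry import TissueFrame, polar_coordinates
from .segmentation import CellSegmentation

logger = logging.getLogger(__name__)

#: Canonical feature names and export order.
FEATURE_NAMES = (
    "m.cx",
    "m.cy",
    "Xnew",
    "Ynew",
    "radialV",
    "angleV",
    "m.majoraxes",
    "m.eccentricity",
    "m.theta",
    "s.area",
    "perimeter",
    "s.radius.mean",
    "s.radius.min",
    "s.radius.max",
    "extv",
    "inclV",
    "P2A",
    "MedianROIC",
    "MeanROIC",
    "m.theta.real",
    "MedianROIW",
    "MeanROIW",
)

#: Historical / misspelt aliases accepted on input.
FEATURE_ALIASES = {"m.eccenticity": "m.eccentricity"}


def canonical_feature_name(name: str) -> str:
    """Map accepted aliases to the canonical spelling; validate the name."""
    name = FEATURE_ALIASES.get(name, name)
    if name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {name!r}; valid names: {list(FEATURE_NAMES)}")
    return name


def _pca_axes(xs: np.ndarray, ys: np.ndarray):
    """Principal axes of a pixel cloud: (major, minor, unit e1), lengths = 4√λ."""
    coords = np.column_stack([xs, ys])
    cov = np.cov(coords, rowvar=False, ddof=0) if len(coords) > 1 else np.zeros((2, 2))
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    e1 = eigvecs[:, order[0]]
    major = 4.0 * float(np.sqrt(eigvals[0]))
    minor = 4.0 * float(np.sqrt(eigvals[1]))
    return major, minor, e1


def _acute_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Acute angle in [0, π/2] between two (undirected) vectors."""
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = abs(float(np.dot(v1, v2)) / (n1 * n2))
    return float(np.arccos(np.clip(c, 0.0, 1.0)))


def compute_features(
    cell_id: int,
    seg: CellSegmentation,
    reference: np.ndarray,
    frame: TissueFrame,
) -> dict[str, float]:
    """The 22-feature vector for one cell (lengths in µm, angles in radian)."""
    ps = frame.pixel_size_um
    mask = seg.roic == cell_id
    if not mask.any():
        raise KeyError(f"cell {cell_id} not present in segmentation")
    rows, cols = np.nonzero(mask)
    n_pix = rows.size
    xs = cols * ps
    ys = rows * ps
    mcx = float(xs.mean())
    mcy = float(ys.mean())
    centroid_px = (mcx / ps, mcy / ps)
    xnew, ynew, radialv, anglev = polar_coordinates(centroid_px, frame)

    degenerate = n_pix < 2
    if degenerate:
        logger.warning("cell %d is a single pixel; shape features degenerate", cell_id)
        major = minor = 0.0
        e1 = np.array([1.0, 0.0])
        eccentricity = 0.0
        theta = 0.0
    else:
        major, minor, e1 = _pca_axes(xs, ys)
        eccentricity = (
            float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2))) if major > 0 else 0.0
        )
        theta = float(np.arctan2(e1[1], e1[0]))
        if theta <= -np.pi / 2:
            theta += np.pi
        elif theta > np.pi / 2:
            theta -= np.pi

    area = n_pix * ps**2
    perim = float(_perimeter_estimate(mask, neighborhood=4)) * ps

    border = mask & ~ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1))
    brows, bcols = np.nonzero(border)
    if degenerate:
        r_mean = r_min = r_max = 0.0
    else:
        # +0.5 px: the object boundary lies half a pixel beyond border-pixel centres
        dists = np.hypot(bcols * ps - mcx, brows * ps - mcy) + 0.5 * ps
        r_mean, r_min, r_max = float(dists.mean()), float(dists.min()), float(dists.max())

    radial_vec = np.array([xnew, ynew])
    inclv = _acute_angle(radial_vec, e1) if not degenerate else 0.0
    theta_real = inclv  # angle to the first principal component, folded acute

    ref = np.asarray(reference, dtype=float)
    cell_vals = ref[mask]
    wall_mask = seg.roiw == cell_id
    if wall_mask.any():
        wall_vals = ref[wall_mask]
        med_w, mean_w = float(np.median(wall_vals)), float(wall_vals.mean())
    else:
        logger.warning("cell %d has an empty wall; ROIW intensity features set to 0", cell_id)
        med_w = mean_w = 0.0

    return {
        "m.cx": mcx,
        "m.cy": mcy,
        "Xnew": xnew,
        "Ynew": ynew,
        "radialV": radialv,
        "angleV": anglev,
        "m.majoraxes": major,
        "m.eccentricity": eccentricity,
        "m.theta": theta,
        "s.area": area,
        "perimeter": perim,
        "s.radius.mean": r_mean,
        "s.radius.min": r_min,
        "s.radius.max": r_max,
        "extv": major * minor,
        "inclV": inclv,
        "P2A": perim / area,
        "MedianROIC": float(np.median(cell_vals)),
        "MeanROIC": float(cell_vals.mean()),
        "m.theta.real": theta_real,
        "MedianROIW": med_w,
        "MeanROIW": mean_w,
    }


def compute_feature_table(
    seg: CellSegmentation, reference: np.ndarray, frame: TissueFrame
) -> pd.DataFrame:
    """One 22-feature row per ROIC cell, indexed by cell id."""
    ids = seg.cell_ids
    if ids.size == 0:
        raise ValueError("segmentation contains no cells")
    rows = {int(k): compute_features(int(k), seg, reference, frame) for k in ids}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    table.index.name = "cell_id"
    return table
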