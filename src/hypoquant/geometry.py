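"""Radial tissue frame and subdivision of every ROI into four quadrants.

A transverse section of a radially organised organ has a natural polar frame
around a (manually supplied) tissue centre.  Each cell is split into four 90°
sectors about its own centroid, oriented along the radial axis through the
tissue centre: quadrants 3 and 4 face outward / inward (periclinal, i.e.
tangential walls), quadrants 1 and 2 are the lateral sectors (anticlinal,
i.e. radial walls); 1 is the counter-clockwise side in array coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .segmentation import CellSegmentation

logger = logging.getLogger(__name__)

ROI_KINDS = ("C", "L", "W")

# sector half-width about the radial axis; boundary pixels (exactly 45°)
# resolve to the periclinal sector
_QUARTER = np.pi / 4


@dataclass(frozen=True)
class TissueFrame:
    """Manually selected tissue centre (x, y in pixels) plus pixel size."""

    center_xy: tuple[float, float]
    pixel_size_um: float

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


def polar_coordinates(
    centroid_xy: tuple[float, float], frame: TissueFrame
) -> tuple[float, float, float, float]:
    """Centre-origin Cartesian and polar coordinates of a cell centroid, in µm.

    Returns ``(Xnew, Ynew, radialV, angleV)`` with ``angleV`` in (−π, π] and
    defined as 0 when the centroid coincides with the tissue centre.
    """
    xnew = (centroid_xy[0] - frame.center_xy[0]) * frame.pixel_size_um
    ynew = (centroid_xy[1] - frame.center_xy[1]) * frame.pixel_size_um
    radial = float(np.hypot(xnew, ynew))
    angle = float(np.arctan2(ynew, xnew)) if radial > 0 else 0.0
    return float(xnew), float(ynew), radial, angle


@dataclass
class QuadrantMap:
    """Per-pixel quadrant labels (1–4) over the ROIC footprint.

    A pixel's quadrant depends only on its cell, so the same map serves ROIC,
    ROIL and ROIW (restricted to each ROI's footprint via :meth:`for_kind`).
    Cells whose centroid coincides with the tissue centre have no defined
    radial axis; they are listed in ``undefined_cells`` and carry quadrant 0.
    """

    labels: np.ndarray
    frame: TissueFrame
    undefined_cells: set[int] = field(default_factory=set)

    def for_kind(self, seg: CellSegmentation, kind: str) -> np.ndarray:
        roi = {"C": seg.roic, "L": seg.roil, "W": seg.roiw}[kind]
        return np.where(roi > 0, self.labels, 0)


def assign_quadrants(seg: CellSegmentation, frame: TissueFrame) -> QuadrantMap:
    """Classify every ROIC pixel into one of four radially oriented sectors.

    For a cell with centroid c, let u be the unit vector from the tissue
    centre through c.  A pixel p is classified by the signed angle φ between
    (p − c) and u:  |φ| ≤ 45° → quadrant 3 (outer periclinal); |φ| ≥ 135° →
    quadrant 4 (inner periclinal); otherwise φ > 0 → quadrant 1, φ < 0 →
    quadrant 2 (the two anticlinal sectors).
    """
    roic = seg.roic
    cx0, cy0 = frame.center_xy
    quad = np.zeros_like(roic, dtype=np.int8)
    undefined: set[int] = set()
    ids = seg.cell_ids
    if ids.size == 0:
        return QuadrantMap(quad, frame)
    centroids = ndi.center_of_mass(np.ones_like(roic), labels=roic, index=ids)
    for k, (cy, cx) in zip(ids, centroids):
        ux, uy = cx - cx0, cy - cy0
        if ux == 0 and uy == 0:
            logger.warning(
                "cell %d centroid coincides with the tissue centre; quadrants undefined", k
            )
            undefined.add(int(k))
            continue
        rows, cols = np.nonzero(roic == k)
        vx = cols - cx
        vy = rows - cy
        phi = np.arctan2(ux * vy - uy * vx, ux * vx + uy * vy)
        q = np.where(phi > 0, 1, 2).astype(np.int8)
        q[np.abs(phi) <= _QUARTER] = 3
        q[np.abs(phi) >= 3 * _QUARTER] = 4
        quad[rows, cols] = q
    return QuadrantMap(quad, frame, undefined)
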