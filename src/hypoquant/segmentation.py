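"""Counterstain-channel segmentation into ROIC / ROIL / ROIW label maps.

The counterstain channel shows bright cell walls around dark lumens.  The
pipeline is: Gaussian smoothing (variance 1 px² by default) → minima-seeded
watershed with dams on the walls → merging of shallow (over-segmented)
adjacent regions whose dam saliency is below a threshold (default 10 intensity
units) → per-cell Otsu thresholding to split each cell into lumen (ROIL) and
wall (ROIW = ROIC − ROIL).

Label conventions: 0 is background / watershed dam; cells are consecutive
positive integers shared across the three maps.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima
from skimage.segmentation import watershed, relabel_sequential

logger = logging.getLogger(__name__)

# 8-neighbourhood offsets used to find which regions a dam pixel touches
_NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SegmentationParams:
    """Tunable knobs of the counterstain segmentation."""

    smoothing_variance_px: float = 1.0
    merge_depth_threshold: float = 10.0
    crop_region: tuple[float, float, float, float] | None = None  # (x0, y0, x1, y1)

    def __post_init__(self):
        if self.smoothing_variance_px < 0:
            raise ValueError("smoothing_variance_px must be >= 0")
        if self.merge_depth_threshold < 0:
            raise ValueError("merge_depth_threshold must be >= 0")


@dataclass
class CellSegmentation:
    """Three aligned label maps: whole cell (ROIC), lumen (ROIL), wall (ROIW)."""

    roic: np.ndarray
    roil: np.ndarray
    roiw: np.ndarray

    def __post_init__(self):
        if not (self.roic.shape == self.roil.shape == self.roiw.shape):
            raise ValueError("ROIC/ROIL/ROIW shapes differ")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.roic)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    def validate(self) -> None:
        """Check the mutual-consistency invariants of the three maps."""
        if np.any((self.roil != 0) & (self.roil != self.roic)):
            raise ValueError("ROIL pixel outside its cell's ROIC")
        if np.any((self.roiw != 0) & (self.roiw != self.roic)):
            raise ValueError("ROIW pixel outside its cell's ROIC")
        inside = self.roic != 0
        wall_expected = np.where(inside & (self.roil == 0), self.roic, 0)
        if not np.array_equal(self.roiw, wall_expected):
            raise ValueError("ROIW is not the set difference ROIC − ROIL")


def smooth_reference(reference: np.ndarray, smoothing_variance_px: float = 1.0) -> np.ndarray:
    """Gaussian low-pass with the stated variance (σ = √variance), reflective borders."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty raster")
    if smoothing_variance_px < 0:
        raise ValueError("smoothing variance must be >= 0")
    if smoothing_variance_px == 0:
        return reference.copy()
    sigma = float(np.sqrt(smoothing_variance_px))
    return ndi.gaussian_filter(reference, sigma=sigma, mode="reflect")


def watershed_cells(smoothed: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Minima-seeded watershed on intensity, then shallow-region merging.

    Cells grow from dark lumens; dams (label 0) form on the bright walls.
    Returns a label map with consecutive positive integer cell ids.
    """
    params = params or SegmentationParams()
    smoothed = np.asarray(smoothed, dtype=float)
    minima = local_minima(smoothed, connectivity=1)
    markers, n_markers = ndi.label(minima, structure=ndi.generate_binary_structure(2, 1))
    if n_markers <= 1:
        logger.warning("image has a single regional minimum; producing one region")
        return np.ones_like(smoothed, dtype=np.int32)
    labels = watershed(smoothed, markers, connectivity=1, watershed_line=True)
    labels = labels.astype(np.int32)
    return merge_shallow_regions(labels, smoothed, params.merge_depth_threshold)


def _dam_adjacency(labels: np.ndarray):
    """For each dam pixel, the set of adjacent (8-connected) region labels.

    Returns (dam_rows, dam_cols, neighbour label array of shape (n_dam, 8);
    entries 0 where the neighbour is off-image or another dam pixel).
    """
    h, w = labels.shape
    rows, cols = np.nonzero(labels == 0)
    nb = np.zeros((rows.size, len(_NB8)), dtype=labels.dtype)
    for j, (dr, dc) in enumerate(_NB8):
        r = rows + dr
        c = cols + dc
        ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
        nb[ok, j] = labels[r[ok], c[ok]]
    return rows, cols, nb


def merge_shallow_regions(
    labels: np.ndarray, smoothed: np.ndarray, merge_depth_threshold: float
) -> np.ndarray:
    """Merge adjacent watershed regions whose dam saliency is below threshold.

    Saliency of an adjacent pair = (minimum intensity over their shared dam
    pixels) − max(region-A minimum, region-B minimum).  Pairs are merged
    iteratively, lowest saliency first, with saliencies recomputed after every
    merge; dam pixels left between two merged regions are absorbed into the
    merged cell.  Output labels are consecutive positive integers.
    """
    if labels.shape != smoothed.shape:
        raise ValueError("labels and smoothed raster shapes differ")
    labels = labels.astype(np.int32).copy()
    smoothed = np.asarray(smoothed, dtype=float)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size <= 1 or merge_depth_threshold <= 0:
        out, _, _ = relabel_sequential(labels)
        return out.astype(np.int32)

    region_min = dict(
        zip(ids.tolist(), ndi.minimum(smoothed, labels=labels, index=ids).tolist())
    )
    dam_rows, dam_cols, dam_nb = _dam_adjacency(labels)
    dam_vals = smoothed[dam_rows, dam_cols]
    dam_index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(dam_rows, dam_cols))}

    # union-find over labels
    parent: dict[int, int] = {int(i): int(i) for i in ids}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # edge bookkeeping: for each unordered root pair, dam minimum + dam pixel list
    from collections import defaultdict

    edge_dammin: dict[frozenset, float] = {}
    edge_pixels: dict[frozenset, list[int]] = defaultdict(list)
    for i in range(dam_rows.size):
        touching = np.unique(dam_nb[i])
        touching = touching[touching > 0]
        if touching.size < 2:
            continue
        v = dam_vals[i]
        for a_idx in range(touching.size):
            for b_idx in range(a_idx + 1, touching.size):
                key = frozenset((int(touching[a_idx]), int(touching[b_idx])))
                edge_pixels[key].append(i)
                if v < edge_dammin.get(key, np.inf):
                    edge_dammin[key] = float(v)

    neighbours: dict[int, set[int]] = defaultdict(set)
    for key in edge_dammin:
        a, b = tuple(key)
        neighbours[a].add(b)
        neighbours[b].add(a)

    def saliency(a: int, b: int) -> float:
        return edge_dammin[frozenset((a, b))] - max(region_min[a], region_min[b])

    heap: list[tuple[float, int, int]] = []
    for key in edge_dammin:
        a, b = tuple(key)
        heapq.heappush(heap, (saliency(a, b), min(a, b), max(a, b)))

    while heap:
        sal, a, b = heapq.heappop(heap)
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        key = frozenset((ra, rb))
        if key not in edge_dammin:
            continue
        cur = saliency(ra, rb)
        if cur != sal:
            # stale entry; a fresh one was (or is now) pushed with the current value
            heapq.heappush(heap, (cur, min(ra, rb), max(ra, rb)))
            continue
        if sal >= merge_depth_threshold:
            break
        # merge rb into ra
        keep, gone = (ra, rb) if ra < rb else (rb, ra)
        parent[gone] = keep
        region_min[keep] = min(region_min[keep], region_min[gone])
        pair_key = frozenset((keep, gone))
        pair_pix = edge_pixels.pop(pair_key)
        edge_dammin.pop(pair_key)
        neighbours[keep].discard(gone)
        neighbours[gone].discard(keep)
        # rewire edges of `gone` onto `keep`
        for c in list(neighbours[gone]):
            old = frozenset((gone, c))
            new = frozenset((keep, c))
            if new in edge_dammin:
                edge_dammin[new] = min(edge_dammin[new], edge_dammin[old])
                edge_pixels[new].extend(edge_pixels[old])
            else:
                edge_dammin[new] = edge_dammin[old]
                edge_pixels[new] = edge_pixels[old]
                neighbours[keep].add(c)
                neighbours[c].add(keep)
            del edge_dammin[old], edge_pixels[old]
            neighbours[c].discard(gone)
        neighbours.pop(gone, None)
        # absorb dam pixels now interior to the merged region (checking the
        # *current* label map: earlier merges/absorptions change adjacency)
        h, w = labels.shape

        def region_neighbours(r, c):
            touch = set()
            for dr, dc in _NB8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                    touch.add(find(int(labels[rr, cc])))
            return touch

        absorbed = []
        for i in pair_pix:
            r, c = int(dam_rows[i]), int(dam_cols[i])
            if labels[r, c] == 0 and region_neighbours(r, c) == {keep}:
                labels[r, c] = keep
                absorbed.append((r, c))
        # dam pixels adjacent to an absorbed pixel now also border `keep`:
        # extend the corresponding edges so later saliencies see them
        for r, c in absorbed:
            for dr, dc in _NB8:
                rr, cc = r + dr, c + dc
                j = dam_index.get((rr, cc))
                if j is None or labels[rr, cc] != 0:
                    continue
                for other in region_neighbours(rr, cc) - {keep}:
                    key2 = frozenset((keep, other))
                    edge_pixels.setdefault(key2, []).append(j)
                    old_min = edge_dammin.get(key2, np.inf)
                    if key2 not in edge_dammin:
                        neighbours[keep].add(other)
                        neighbours[other].add(keep)
                    if dam_vals[j] < old_min:
                        edge_dammin[key2] = float(dam_vals[j])
        # saliencies around `keep` may have changed (its minimum dropped,
        # and absorbed pixels may have exposed new or lower dams)
        for c in neighbours[keep]:
            heapq.heappush(heap, (saliency(keep, c), min(keep, c), max(keep, c)))

    # resolve union-find on the label map
    lut = np.arange(labels.max() + 1, dtype=np.int32)
    for i in ids:
        lut[i] = find(int(i))
    labels = lut[labels]
    out, _, _ = relabel_sequential(labels)
    return out.astype(np.int32)


def _otsu_threshold(values: np.ndarray, nbins: int = 256) -> float | None:
    """Otsu threshold over equal-width bins of the value range.

    Returns the bin edge maximising between-class variance, or ``None`` for a
    constant sample (no threshold exists).  Ties resolve to the lowest edge.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return None
    counts, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    counts = counts.astype(float)
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    centers = (edges[:-1] + edges[1:]) / 2
    mass = counts * centers
    m0 = np.cumsum(mass)[:-1]
    m1 = mass.sum() - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = m1 / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    cut = int(np.argmax(between))  # lowest-index tie-break
    return float(edges[cut + 1])


def extract_lumen(reference: np.ndarray, roic: np.ndarray) -> np.ndarray:
    """Per-cell Otsu thresholding of the reference channel: lumen = below threshold.

    Each cell's threshold is computed from its own pixel histogram (256
    equal-width bins of the cell's range); constant-intensity cells get an
    empty lumen (whole cell treated as wall).
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != roic.shape:
        raise ValueError("reference and ROIC shapes differ")
    ids = np.unique(roic)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("ROIC contains no cells")
    roil = np.zeros_like(roic)
    for k in ids:
        mask = roic == k
        thr = _otsu_threshold(reference[mask])
        if thr is None:
            continue
        roil[mask & (reference < thr)] = k
    return roil


def derive_wall(roic: np.ndarray, roil: np.ndarray) -> np.ndarray:
    """ROIW = per-cell set difference ROIC − ROIL."""
    if roic.shape != roil.shape:
        raise ValueError("ROIC and ROIL shapes differ")
    if np.any((roil != 0) & (roil != roic)):
        raise ValueError("ROIL pixel outside its cell's ROIC footprint")
    roiw = np.where((roic != 0) & (roil == 0), roic, 0).astype(roic.dtype)
    empty_wall = np.setdiff1d(np.unique(roic), np.unique(roiw))
    empty_wall = empty_wall[empty_wall > 0]
    if empty_wall.size:
        warnings.warn(f"cells with empty wall (lumen fills cell): {empty_wall.tolist()}")
    return roiw


def crop_restrict(
    seg: CellSegmentation, crop_region: tuple[float, float, float, float]
) -> CellSegmentation:
    """Keep only cells whose ROIC centroid lies inside the (x0, y0, x1, y1) rectangle.

    Retained cells keep their full pixel footprints (the rectangle selects
    cells, it does not clip them); ids are relabelled consecutively.
    """
    x0, y0, x1, y1 = crop_region
    h, w = seg.roic.shape
    if not (0 <= x0 <= x1 <= w and 0 <= y0 <= y1 <= h):
        raise ValueError(f"crop region {crop_region} outside image bounds {(w, h)}")
    ids = seg.cell_ids
    centroids = ndi.center_of_mass(np.ones_like(seg.roic), labels=seg.roic, index=ids)
    keep = [
        int(k)
        for k, (cy, cx) in zip(ids, centroids)
        if x0 <= cx <= x1 and y0 <= cy <= y1
    ]
    if not keep:
        raise ValueError("crop region retains no cells")
    lut = np.zeros(int(seg.roic.max()) + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        lut[old] = new
    return CellSegmentation(lut[seg.roic], lut[seg.roil], lut[seg.roiw])


def segment_image(
    reference: np.ndarray, params: SegmentationParams | None = None
) -> CellSegmentation:
    """Full counterstain segmentation: smooth → watershed+merge → lumen → wall."""
    params = params or SegmentationParams()
    smoothed = smooth_reference(reference, params.smoothing_variance_px)
    roic = watershed_cells(smoothed, params)
    roil = extract_lumen(smoothed, roic)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        roiw = derive_wall(roic, roil)
    seg = CellSegmentation(roic, roil, roiw)
    if params.crop_region is not None:
        seg = crop_restrict(seg, params.crop_region)
    return seg
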