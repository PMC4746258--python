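"""Ground-truthed synthetic two-channel images of radially organised tissue.

Emulates a transverse section of a plant organ (e.g. an Arabidopsis
hypocotyl): concentric rings of cells around a centre, each ring a distinct
cell-type class with its own cell size, wall thickness, counterstain
intensity and immunofluorescence amplitude.  Cell geometry is Voronoi-based
(seed points with blue-noise spacing, regions clipped to the ring annulus) —
enough to exercise watershed segmentation, morphometrics and classification,
with no pretension of biophysical realism (no cell-wall texture, no
point-spread function).

Channel 1 (reference): bright walls on cell boundaries, dark lumens, optional
additive Gaussian noise clipped at zero.  SNR is defined as wall mean / noise
standard deviation.  Channel 2 (signal): class-specific wall/lumen amplitudes
plus an optional constant background.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .image_io import SampleMetadata, TwoChannelImage

__all__ = [
    "RingSpec",
    "TissueSpec",
    "GroundTruth",
    "generate_radial_tissue",
    "generate_toy_fixtures",
    "default_tissue_spec",
    "segmentation_benchmark_spec",
    "iou_match_fraction",
    "majority_true_classes",
]


@dataclass(frozen=True)
class RingSpec:
    """One concentric ring of same-class cells."""

    class_name: str
    r_inner_um: float
    r_outer_um: float
    n_cells: int
    cell_area_um2: float | None = None  # None: annulus area / n_cells
    cell_area_cv: float = 0.25
    wall_thickness_px: int = 2
    wall_intensity: float = 60.0
    wall_noise_sd: float = 0.0
    lumen_intensity: float = 10.0
    lumen_noise_sd: float = 0.0
    signal_wall: float = 0.0
    signal_lumen: float = 0.0


@dataclass(frozen=True)
class TissueSpec:
    """Full recipe for one synthetic two-channel tissue image."""

    size_px: int
    pixel_size_um: float
    center_xy: tuple[float, float]
    rings: tuple[RingSpec, ...]
    seed: int
    signal_background: float = 0.0
    signal_noise_sd: float = 0.0

    def __post_init__(self):
        prev = 0.0
        for ring in self.rings:
            if ring.r_inner_um < prev:
                raise ValueError(f"rings overlap or are out of order at {ring.class_name!r}")
            if ring.r_outer_um <= ring.r_inner_um:
                raise ValueError(f"ring {ring.class_name!r} has non-positive width")
            prev = ring.r_outer_um
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(r.class_name for r in self.rings)


@dataclass
class GroundTruth:
    """True cell label map and per-cell class assignments for a generated image."""

    labels: np.ndarray
    classes: dict[int, str]
    ring_of: dict[int, int]
    centroids: dict[int, tuple[float, float]]
    spec: TissueSpec

    @property
    def n_cells(self) -> int:
        return len(self.classes)


def _place_ring_seeds(
    rng: np.random.Generator,
    ring: RingSpec,
    center_xy: tuple[float, float],
    pixel_size_um: float,
) -> list[tuple[float, float]]:
    """Jittered polar-lattice seed placement inside the ring annulus, in px.

    Cells are laid out in concentric rows (row count from the ring's mean
    cell size), with per-seed radial and angular jitter scaled by the ring's
    cell-size coefficient of variation — an even, blue-noise-like point set
    that always realises the target cell count exactly.
    """
    ri = ring.r_inner_um / pixel_size_um
    ro = ring.r_outer_um / pixel_size_um
    annulus_area = np.pi * (ro**2 - ri**2)
    if ring.cell_area_um2 is not None:
        requested = ring.n_cells * ring.cell_area_um2 / pixel_size_um**2
        if requested > annulus_area:
            raise ValueError(
                f"infeasible packing in ring {ring.class_name!r}: "
                f"{ring.n_cells} cells of {ring.cell_area_um2:.0f} µm² "
                "exceed the annulus area"
            )
    mean_area = annulus_area / ring.n_cells
    spacing = float(np.sqrt(mean_area))
    if spacing < 3.0:
        raise ValueError(
            f"infeasible packing in ring {ring.class_name!r}: "
            f"mean cell diameter below 3 px at this pixel size"
        )
    width = ro - ri
    n_rows = max(1, int(round(width / spacing)))
    row_edges = np.linspace(ri, ro, n_rows + 1)
    row_mid = (row_edges[:-1] + row_edges[1:]) / 2
    # cells per row proportional to row circumference
    weights = row_mid / row_mid.sum()
    counts = np.floor(weights * ring.n_cells).astype(int)
    remainder = ring.n_cells - counts.sum()
    order = np.argsort(-(weights * ring.n_cells - counts))
    counts[order[:remainder]] += 1
    cx, cy = center_xy
    jitter = 0.9 * ring.cell_area_cv  # jitter amplitude relative to lattice spacing
    placed: list[tuple[float, float]] = []
    row_width = width / n_rows
    for mid, count in zip(row_mid, counts):
        if count == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        for k in range(count):
            theta = phase + 2 * np.pi * k / count + rng.normal(0, jitter * np.pi / count)
            r = mid + rng.normal(0, jitter * row_width / 2)
            r = float(np.clip(r, ri + 0.25 * row_width, ro - 0.25 * row_width))
            placed.append((cx + r * np.cos(theta), cy + r * np.sin(theta)))
    return placed


def generate_radial_tissue(spec: TissueSpec) -> tuple[TwoChannelImage, GroundTruth]:
    """Render the two channels and the ground-truth label/class maps."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    cx, cy = spec.center_xy
    yy, xx = np.mgrid[0:n, 0:n]
    r_um = np.hypot(xx - cx, yy - cy) * spec.pixel_size_um

    ring_id = np.zeros((n, n), dtype=np.int8)  # 0 = outside tissue
    for i, ring in enumerate(spec.rings):
        ring_id[(r_um >= ring.r_inner_um) & (r_um < ring.r_outer_um)] = i + 1

    labels = np.zeros((n, n), dtype=np.int32)
    classes: dict[int, str] = {}
    ring_of: dict[int, int] = {}
    gid = 0
    for i, ring in enumerate(spec.rings):
        seeds = _place_ring_seeds(rng, ring, spec.center_xy, spec.pixel_size_um)
        mask = ring_id == i + 1
        rows, cols = np.nonzero(mask)
        tree = cKDTree(np.asarray(seeds))
        _, nearest = tree.query(np.column_stack([cols, rows]))
        labels[rows, cols] = gid + 1 + nearest
        for j in range(len(seeds)):
            classes[gid + 1 + j] = ring.class_name
            ring_of[gid + 1 + j] = i
        gid += len(seeds)

    # wall mask: pixels adjacent to a different label (or to the outside),
    # thickened per ring
    pad = np.pad(labels, 1, mode="edge")
    boundary = np.zeros((n, n), dtype=bool)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        boundary |= labels != pad[1 + dr : n + 1 + dr, 1 + dc : n + 1 + dc]
    boundary &= labels > 0
    wall = np.zeros((n, n), dtype=bool)
    for i, ring in enumerate(spec.rings):
        b = boundary & (ring_id == i + 1)
        it = max(0, ring.wall_thickness_px // 2)
        if it:
            b = ndi.binary_dilation(b, iterations=it) & (ring_id == i + 1)
        wall |= b

    ch1 = np.zeros((n, n), dtype=float)
    ch2 = np.full((n, n), float(spec.signal_background))
    sd1 = np.zeros((n, n), dtype=float)
    for i, ring in enumerate(spec.rings):
        in_ring = ring_id == i + 1
        lum = in_ring & ~wall
        wl = in_ring & wall
        ch1[lum] = ring.lumen_intensity
        ch1[wl] = ring.wall_intensity
        sd1[lum] = ring.lumen_noise_sd
        sd1[wl] = ring.wall_noise_sd
        ch2[lum] += ring.signal_lumen
        ch2[wl] += ring.signal_wall
    if np.any(sd1 > 0):
        ch1 = ch1 + rng.normal(0.0, 1.0, ch1.shape) * sd1
    if spec.signal_noise_sd > 0:
        ch2 = ch2 + rng.normal(0.0, spec.signal_noise_sd, ch2.shape)
    ch1 = np.clip(ch1, 0.0, None)
    ch2 = np.clip(ch2, 0.0, None)

    centroids = {}
    ids = np.array(sorted(classes))
    for k, (cyi, cxi) in zip(
        ids, ndi.center_of_mass(np.ones_like(labels), labels=labels, index=ids)
    ):
        centroids[int(k)] = (float(cxi), float(cyi))

    meta = SampleMetadata("SYN01", "LM10", "Col", "21-day-old", "Hyp", f"SR{spec.seed}")
    image = TwoChannelImage(ch1, ch2, spec.pixel_size_um, meta)
    return image, GroundTruth(labels, classes, ring_of, centroids, spec)


# ---------------------------------------------------------------------------
# Default study-condition specs
# ---------------------------------------------------------------------------

_DEFAULT_RINGS = (
    # class            r_in  r_out  n   wall_t  wall_I  lumen_I
    ("xylem-I",          0.0,  45.0, 40, 3,      70.0,   10.0),
    ("xylem-II",        45.0,  75.0, 45, 3,      80.0,    8.0),
    ("cambium",         75.0,  95.0, 55, 2,      50.0,   12.0),
    ("phloem",          95.0, 120.0, 50, 2,      60.0,   10.0),
    ("cortex",         120.0, 150.0, 45, 2,      45.0,   14.0),
    ("cork",           150.0, 170.0, 45, 2,      55.0,   10.0),
)


def default_tissue_spec(
    seed: int,
    snr: float | None = None,
    signal_class: str | None = "xylem-II",
    signal_amplitude: float = 120.0,
    signal_background: float = 5.0,
    radius_scale: float = 1.0,
) -> TissueSpec:
    """Six ringed cell-type classes on a 512×512 frame, 0.7 µm/px.

    Mimics the ringed organisation of a mature hypocotyl cross-section in
    topology only.  ``snr`` adds channel-1 Gaussian noise with sd =
    wall intensity / snr per ring (None = noiseless).  ``signal_class``
    receives a wall-restricted channel-2 amplitude (xylan-like labelling);
    ``radius_scale`` shifts all ring boundaries, emulating a genotype with
    displaced tissue-type boundaries.
    """
    rings = []
    for name, ri, ro, count, wt, wi, li in _DEFAULT_RINGS:
        noise = wi / snr if snr else 0.0
        rings.append(
            RingSpec(
                class_name=name,
                r_inner_um=ri * radius_scale,
                r_outer_um=ro * radius_scale,
                n_cells=count,
                wall_thickness_px=wt,
                wall_intensity=wi,
                wall_noise_sd=noise,
                lumen_intensity=li,
                lumen_noise_sd=noise,
                signal_wall=signal_amplitude if name == signal_class else 0.0,
                signal_lumen=0.0,
            )
        )
    return TissueSpec(
        size_px=512,
        pixel_size_um=0.7,
        center_xy=(256.0, 256.0),
        rings=tuple(rings),
        seed=seed,
        signal_background=signal_background,
        signal_noise_sd=2.0 if snr else 0.0,
    )


def segmentation_benchmark_spec(seed: int, snr: float | None = None) -> TissueSpec:
    """~150-cell, 4-ring variant of the default spec for segmentation benchmarks."""
    base = default_tissue_spec(seed, snr=snr, signal_class=None)
    keep = {"xylem-I": 35, "xylem-II": 40, "phloem": 40, "cortex": 35}
    rings = []
    prev_outer = 0.0
    for ring in base.rings:
        if ring.class_name in keep:
            rings.append(
                replace(
                    ring,
                    n_cells=keep[ring.class_name],
                    r_inner_um=prev_outer,
                )
            )
            prev_outer = ring.r_outer_um
    return replace(base, rings=tuple(rings))


# ---------------------------------------------------------------------------
# Ground-truth evaluation helpers
# ---------------------------------------------------------------------------

def _overlap_counts(a: np.ndarray, b: np.ndarray):
    """Joint pixel counts of two label maps as {(label_a, label_b): n}."""
    af = a.ravel().astype(np.int64)
    bf = b.ravel().astype(np.int64)
    width = bf.max() + 1
    joint = np.bincount(af * width + bf)
    nz = np.nonzero(joint)[0]
    return {(int(k // width), int(k % width)): int(joint[k]) for k in nz}


def iou_match_fraction(
    truth_labels: np.ndarray, roic: np.ndarray, iou_threshold: float = 0.7
) -> float:
    """Fraction of ground-truth cells matched one-to-one to a segmented cell
    with intersection-over-union at least *iou_threshold* (greedy, best first)."""
    joint = _overlap_counts(truth_labels, roic)
    area_t = np.bincount(truth_labels.ravel())
    area_s = np.bincount(roic.ravel())
    candidates = []
    for (t, s), n in joint.items():
        if t == 0 or s == 0:
            continue
        iou = n / (area_t[t] + area_s[s] - n)
        if iou >= iou_threshold:
            candidates.append((iou, t, s))
    used_t, used_s = set(), set()
    matched = 0
    for iou, t, s in sorted(candidates, reverse=True):
        if t in used_t or s in used_s:
            continue
        used_t.add(t)
        used_s.add(s)
        matched += 1
    n_truth = int((np.unique(truth_labels) > 0).sum())
    return matched / n_truth if n_truth else 0.0


def majority_true_classes(roic: np.ndarray, truth: GroundTruth) -> dict[int, str | None]:
    """Ground-truth class of each segmented cell by majority pixel overlap.

    Cells overlapping mostly background map to ``None``.
    """
    joint = _overlap_counts(roic, truth.labels)
    best: dict[int, tuple[int, int]] = {}
    for (s, t), n in joint.items():
        if s == 0:
            continue
        if n > best.get(s, (0, 0))[0]:
            best[s] = (n, t)
    return {s: (truth.classes.get(t) if t > 0 else None) for s, (_, t) in best.items()}


# ---------------------------------------------------------------------------
# Hand-specified toy fixtures with embedded expected outputs
# ---------------------------------------------------------------------------

def generate_toy_fixtures() -> dict[str, dict]:
    """Tiny deterministic rasters used as worked examples throughout the tests.

    Every fixture embeds its own expected outputs; nothing here is random.
    """
    fixtures: dict[str, dict] = {}

    # two dark basins split by a bright ridge: deep dam survives merging
    deep = np.full((16, 16), 10.0)
    deep[:, 8] = 200.0
    fixtures["two_basin_deep"] = {
        "raster": deep,
        "merge_threshold": 10.0,
        "expected_n_regions": 2,
        "expected_saliency": 190.0,
    }

    # same geometry, shallow ridge (saliency 5 < 10): regions merge
    shallow = np.full((16, 16), 10.0)
    shallow[:, 8] = 15.0
    fixtures["two_basin_shallow"] = {
        "raster": shallow,
        "merge_threshold": 10.0,
        "expected_n_regions": 1,
        "expected_saliency": 5.0,
    }

    # chain A–B–C with dam saliencies 4 and 6: everything merges at threshold 10
    chain = np.full((16, 16), 10.0)
    chain[:, 5] = 14.0
    chain[:, 10] = 16.0
    fixtures["three_chain"] = {
        "raster": chain,
        "merge_threshold": 10.0,
        "expected_n_regions": 1,
        "expected_saliencies": (4.0, 6.0),
    }

    # bimodal cell: bright 2-px wall around a dark interior; Otsu separates them
    bimodal = np.full((12, 12), 200.0)
    bimodal[2:-2, 2:-2] = 20.0
    roic = np.ones((12, 12), dtype=np.int32)
    lumen_mask = np.zeros((12, 12), dtype=bool)
    lumen_mask[2:-2, 2:-2] = True
    fixtures["bimodal_cell"] = {
        "reference": bimodal,
        "roic": roic,
        "modes": (20.0, 200.0),
        "expected_lumen_mask": lumen_mask,
    }

    # rectangles east of the tissue centre, major axis along / across the
    # radial direction: inclV ≈ 0 and ≈ π/2
    rect_radial = np.zeros((120, 120), dtype=np.int32)
    rect_radial[57:64, 80:101] = 1  # 7 rows × 21 cols, long axis = x = radial
    rect_tangential = np.zeros((120, 120), dtype=np.int32)
    rect_tangential[50:71, 87:94] = 1  # 21 rows × 7 cols, long axis ⟂ radial
    fixtures["rect_radial"] = {
        "roic": rect_radial,
        "center_xy": (60.0, 60.0),
        "expected_inclV": 0.0,
    }
    fixtures["rect_tangential"] = {
        "roic": rect_tangential,
        "center_xy": (60.0, 60.0),
        "expected_inclV": np.pi / 2,
    }

    # square cell east of centre with signal only east of its centroid
    # (quadrant 3); wall = 2-px frame, lumen = interior
    qroic = np.zeros((40, 40), dtype=np.int32)
    qroic[14:27, 24:37] = 1  # 13×13 cell, centroid (30, 20)
    qroil = np.zeros_like(qroic)
    qroil[16:25, 26:35] = 1
    qroiw = np.where((qroic == 1) & (qroil == 0), 1, 0).astype(np.int32)
    qsignal = np.zeros((40, 40), dtype=float)
    # narrow east wedge: dx ≥ 3, |dy| ≤ 2 from the centroid, all within ±45°
    qsignal[18:23, 33:37] = 50.0
    fixtures["quadrant_signal"] = {
        "roic": qroic,
        "roil": qroil,
        "roiw": qroiw,
        "signal": qsignal,
        "center_xy": (8.0, 20.0),
        "signal_value": 50.0,
        "expected_hot_quadrant": 3,
    }

    return fixtures
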