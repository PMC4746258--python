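# Methods

This note documents the models and numerical choices behind `hypoquant`, the
parameters that matter, what the synthetic data does and does not emulate,
and the package's known limitations.

## Segmentation model

The counterstain channel of a transverse section shows bright cell walls
around dark lumens, so cell detection is posed as watershed flooding of the
intensity landscape.

* **Smoothing.** Gaussian low-pass with variance 1 px² (σ = 1 px) by
  default, reflective boundary handling. The parameter is expressed as a
  variance (px²) rather than σ because that is how segmentation parameters
  are conventionally entered in this workflow; variance 0 disables
  smoothing.
* **Watershed.** Seeds are the regional minima of the smoothed image
  (4-connectivity); dams (label 0) form on intensity ridges, i.e. the walls.
  Seeding from minima rather than user markers keeps the step deterministic
  and parameter-free. The output is invariant to adding a constant to the
  image.
* **Merge rule.** Noise creates spurious minima and hence over-segmentation.
  For every adjacent region pair we compute a *dam saliency*: the minimum
  smoothed intensity over the shared dam pixels minus the higher of the two
  basin minima. Pairs with saliency below the merge threshold (default 10
  intensity units, appropriate for 8-bit-scaled data) are merged
  iteratively, lowest saliency first, with all saliencies recomputed after
  each merge; this lowest-first ordering makes the result independent of
  label order. Dam pixels left strictly between two merged basins are
  absorbed into the merged cell; dam spurs bordering a single region remain
  background. Region count is non-increasing in the threshold. Two readings
  of the merge criterion are possible — dam minimum versus first-flooded dam
  pixel; they coincide for the saddle pixel at which two basins first meet,
  and the dam-minimum form (classic waterfall saliency) is implemented.
* **Lumen/wall split.** Otsu's criterion is applied *per cell* over the
  cell's own histogram (256 equal-width bins of the cell's range; threshold
  at the bin edge maximising between-class variance, lowest edge on ties;
  lumen = pixels strictly below). A per-cell threshold adapts to local
  contrast differences that defeat a global one. Constant-intensity cells
  have no threshold and get an empty lumen (whole cell treated as wall, with
  a warning). ROIW is the exact set difference ROIC − ROIL, so
  |ROIL| + |ROIW| = |ROIC| always.
* **Cropping.** An optional rectangle restricts analysis by *centroid
  inclusion* (bounds inclusive): cells whose centroid falls inside keep
  their full footprint; others are dropped entirely. This avoids clipped
  partial cells at the crop border.
* **Dam exclusion bias.** Dam pixels belong to no cell, so walls shared by
  two cells lose a one-pixel line to background. This thins ROIW slightly
  and is the main reason segmented cells are marginally smaller than ground
  truth; it is accepted to keep cells strictly disjoint.

Intensities are processed as float64 regardless of input dtype.

## Radial frame and quadrants

The tissue centre is supplied by the user (config/CLI); automatic centre
detection is out of scope. For each cell, the radial unit vector u runs from
the tissue centre through the cell centroid, and each ROI pixel is
classified by its signed angle φ to u about the centroid: |φ| ≤ 45° → outer
periclinal quadrant 3; |φ| ≥ 135° → inner periclinal quadrant 4; otherwise
anticlinal quadrants 1 (counter-clockwise side, in array coordinates) and 2.
Sector boundaries at exactly ±45° resolve to the periclinal side. A pixel's
quadrant depends only on its cell, so ROIC, ROIL and ROIW agree wherever
they overlap. A cell whose centroid coincides with the tissue centre has no
radial axis; it is flagged and excluded from quadrant-based measures. The
quadrant numbering orientation is an arbitrary convention — only the
periclinal-versus-anticlinal contrast is biologically meaningful.

## Morphometric features

22 features per cell, lengths in µm (pixel size is mandatory), angles in
radians:

| group | features | notes |
|---|---|---|
| position | `m.cx`, `m.cy` (image origin), `Xnew`, `Ynew`, `radialV`, `angleV` (centre origin) | `angleV` ∈ (−π, π], defined 0 at the centre |
| shape (PCA) | `m.majoraxes`, `m.eccentricity`, `m.theta`, `extv` | axis length = 4·√eigenvalue of the pixel-coordinate covariance — the full-axis convention that recovers a filled ellipse's true axes; eccentricity = √(1 − minor²/major²); `m.theta` folded to (−π/2, π/2]; `extv` = major × minor |
| size/boundary | `s.area`, `perimeter`, `P2A`, `s.radius.mean/.min/.max` | perimeter via the weighted boundary-configuration estimator (√2 weight on diagonal steps); border-to-centroid radii carry a +0.5 px offset because the object boundary lies half a pixel beyond border-pixel centres; `P2A` is the plain perimeter/area ratio (µm⁻¹), despite its "circularity" nickname |
| radial orientation | `inclV`, `m.theta.real` | acute angle in [0, π/2] between the radial vector and the major axis / first principal component (numerically identical by construction; both kept for schema compatibility) |
| intensity | `MedianROIC`, `MeanROIC`, `MedianROIW`, `MeanROIW` | counterstain statistics over the whole cell and over the wall (the `…ROIW` names are authoritative; cells with an empty wall report 0 with a warning) |

`m.eccentricity` is the canonical spelling; the historical misspelling
`m.eccenticity` is accepted as an input alias. Single-pixel cells get zero
shape/radius features and a warning.

## Classifier

Breiman's Random Forest: bagged decision trees with √p random features per
split, built as a bagging ensemble over decision trees so every tree's
bootstrap sample is accessible. Defaults: 500 trees; the seed is mandatory
so runs are reproducible. Features enter **untransformed** — tree ensembles
are scale-invariant, and normalisation was deliberately rejected. The
default feature subset is 18 of the 22: all except the Cartesian
coordinates (`m.cx`, `m.cy`, `Xnew`, `Ynew`), which are uninformative in a
radially symmetric organ. A subset-selection helper supports iterative
reduction; `radialV`, `MedianROIW`, `MedianROIC` and `s.area` — consistently
the top-ranked features — are pre-listed as the seed of a five-feature set.

* **Confidence** = fraction of trees voting the winning class (ties resolve
  to the first class in sorted order), in (0, 1]. Filtering retains cells
  with confidence ≥ threshold; the retained sets at 90/70/50 % are nested by
  construction.
* **Importance** = out-of-bag permutation importance: per tree, the increase
  in misclassification on its out-of-bag samples when one feature column is
  permuted, averaged over trees. Impurity-based importances are also stored
  for comparison.

## Fluorescence quantification

Background is estimated once per image as the median signal intensity over
non-tissue pixels (ROIC = 0), subtracted everywhere, negatives clamped to
zero. For each (cell, ROI kind, quadrant): mean, standard deviation
(population, n denominator — documented choice) and area (µm²). Empty
quadrants have area 0 and missing mean/std.

Derived per-cell measures, per ROI kind:

* `…RPA` = summed periclinal signal / summed anticlinal signal
  (Σ mean·area over quadrants 3, 4 vs 1, 2);
* `…RPAmean` = (mean₃ + mean₄)/(mean₁ + mean₂) — the mean-intensity
  (area-independent) variant, which is why both exist;
* `…signal` = Σ_q mean_q·area_q (intensity·µm²; `Cellsignal` =
  `Lumensignal` + `Wallsignal` exactly);
* `…signalmean` = total / ROI area;
* `PvD` (punctateness vs diffuseness) = coefficient of variation
  (population std / mean) of the lumen pixel intensities: 0 for uniform
  signal, √(n−1) for a single bright pixel among n. The definition is
  isolated behind one function so alternatives (e.g. top-decile mass
  fraction) can be swapped.

Measures with a zero denominator are flagged missing (NaN), never zeroed,
and the cell row is kept; class summaries therefore use per-measure n.
Class summaries report mean ± population std per class after confidence
filtering, optionally rescaled by the maximum class mean for relative
bar plots. All means/stds/totals scale linearly with the signal channel;
the ratios RPA, RPAmean and PvD are scale-invariant; and no measure of a
cell depends on signal outside that cell's ROIC.

## Synthetic tissue

The generator emulates what the pipeline needs from a real section — not
its optics. Concentric rings of cells around a centre, one cell-type class
per ring, each with its own target cell count, cell-size CV, wall
thickness, counterstain wall/lumen intensities and immunolabel amplitudes.
Cell geometry is Voronoi: seeds are placed on a jittered polar lattice (row
count from the ring's mean cell size, jitter scaled by the size CV — an
even, blue-noise-like arrangement that always realises the target counts),
and each ring pixel joins its nearest same-ring seed. Channel 1 paints
walls on (thickened) region boundaries over dark lumens; channel 2 adds
class-specific wall/lumen amplitudes plus a constant background. Noise is
additive Gaussian clipped at zero; SNR is defined as wall mean / noise sd.
Everything is a pure function of the spec including its mandatory seed.

The default spec mirrors a mature hypocotyl's organisation in *topology
only*: six rings (xylem-I, xylem-II, cambium, phloem, cortex, cork) of
40–55 cells each on a 512×512 frame at 0.7 µm/px (within the typical
0.6–0.83 µm/px acquisition range), wall intensities 45–80 and lumens 8–14
on an 8-bit-like scale, with the immunolabel amplitude (120) confined to
xylem-II walls, emulating a xylan-type epitope. A four-ring, 150-cell
variant serves as the segmentation benchmark. These numbers are realistic
relative contrasts for counterstained sections, chosen once and fixed.

**What passing tests do not show:** the generator has no point-spread
function, no uneven illumination, no wall-texture variation, no torn or
folded tissue, and its cells are convex Voronoi polygons. Recovery rates on
it are an upper bound for real sections; the merge threshold and smoothing
variance will generally need per-experiment tuning on real data.

## Pipeline and reproducibility

All orchestration is config-file driven; there are no interactive prompts.
Every run writes into a fresh time-stamped folder
(`<title>_<ISO-8601 timestamp>`) and registers its outputs in a JSON
experiment catalogue, so each result file is reachable from the catalogue
and reruns never overwrite. A training iteration stores its segmentation
parameters, feature subset, class names, seed and model; re-running it
reproduces its predictions exactly, and the whole pipeline is byte-for-byte
reproducible for a fixed seed (timestamps live only in folder names).
Models are persisted with joblib at run time.

Problem sizes used by the test suite and `scripts/acceptance.py` — 150-cell
benchmarks for segmentation recovery, 280-cell six-ring images for
classification and quantification, 100–500-tree forests — were chosen as
the smallest sizes at which the ring structure is statistically meaningful
(≥ 40 cells per class).

## Known limitations

* 2-D only; no z-stacks or 3-D segmentation.
* Vendor formats (LSM) are not parsed; convert to 2-channel/2-page TIFF
  first (e.g. with Fiji's Bio-Formats exporter).
* The watershed excludes dam pixels from all cells (wall-thinning bias
  above).
* Tissue-centre selection is manual; badly placed centres distort
  `radialV`, `inclV` and the quadrant split.
* Confidence scores are vote fractions, not calibrated probabilities.
* Heavy reliance on `radialV` means a classifier trained on one genotype
  can misplace ring boundaries in a genotype with shifted tissue
  organisation; confidence filtering mitigates but does not remove this.
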