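# hypoquant

Automated segmentation, cell-type classification and per-cell fluorescence
quantification for two-channel confocal images of **radially organised plant
organ cross-sections** (e.g. Arabidopsis hypocotyls).

A typical input is a transverse section whose cell walls are counterstained
with calcofluor white (channel 1) and immunolabelled for a wall epitope such
as xylan/LM10 (channel 2).  `hypoquant` turns such an image into a per-cell
table: every cell's geometry, its cell-type class with a confidence score,
and the distribution of the immunofluorescence signal over its wall, lumen
and four radial quadrants.  It is aimed at plant developmental biologists who
need to phenotype many sections (mutant screens, antibody panels) without
tracing cells by hand.

## Method

1. **Segmentation** (channel 1).  Gaussian smoothing with variance 1 px²
   (σ = 1), then a minima-seeded watershed: cells flood from their dark
   lumens, dams form on the bright walls.  Over-segmentation is corrected by
   merging adjacent regions whose *dam saliency* — the minimum intensity on
   the shared dam minus the higher of the two basin minima — is below 10
   intensity units (lowest saliency first, recomputed after every merge).
   This yields ROIC (whole cell); per-cell Otsu thresholding of the cell's
   own histogram splits it into lumen ROIL and wall ROIW = ROIC − ROIL.
2. **Radial geometry.**  Around a user-supplied tissue centre, each cell is
   divided into four 90° sectors about its centroid, oriented along the
   radial axis: quadrants 3/4 are periclinal (outer/inner tangential walls),
   1/2 anticlinal (radial walls).
3. **Morphometrics.**  22 features per cell: position (image and
   centre-origin, polar), PCA axis lengths, eccentricity
   √(1 − minor²/major²), orientation, area, perimeter, border-radius
   statistics, incline angle to the radial axis, perimeter-to-area ratio,
   and median/mean counterstain intensity over ROIC and ROIW.
4. **Classification.**  A Random Forest (bagged trees, √p features per
   split, untransformed features) trained on user-annotated cells.  Each
   cell's *confidence* is the fraction of trees voting its winning class;
   results are filtered at 50/70/90 %.  Out-of-bag permutation importance
   ranks the features.
5. **Fluorescence quantification** (channel 2).  Median-background
   subtraction, then per (cell × {C, L, W} × quadrant) mean/std/area, and
   derived measures: periclinal/anticlinal polarity ratios (RPA), total and
   mean signals per ROI, and a punctateness score (PvD, the coefficient of
   variation of lumen pixels).  Per-class summaries with confidence
   filtering close the loop.

A built-in synthetic-tissue generator renders ground-truthed two-channel
images of concentric cell-type rings (Voronoi cell geometry, class-specific
size, wall thickness, intensities and noise) so the entire pipeline is
testable without microscopy data.

## Worked example

```python
import pandas as pd
import hypoquant as hq

# synthesise a ringed cross-section and segment its counterstain channel
spec = hq.default_tissue_spec(seed=11, snr=8)
image, truth = hq.generate_radial_tissue(spec)
seg = hq.segment_image(image.reference)
print(f"{seg.n_cells} cells segmented ({truth.n_cells} in the ground truth)")

# 22 morphometric features per cell, then a Random Forest on ground-truth labels
frame = hq.TissueFrame(spec.center_xy, spec.pixel_size_um)
table = hq.compute_feature_table(seg, image.reference, frame)
mapping = hq.majority_true_classes(seg.roic, truth)
annotations = pd.DataFrame(
    [{"cell_id": k, "class_label": mapping[k]} for k in table.index if mapping.get(k)]
)
model = hq.train_random_forest(table, annotations, n_trees=500, seed=7)
print("top features:", [f for f, _ in hq.rank_feature_importance(model)[:3]])
print(f"out-of-bag accuracy: {model.oob_score:.3f}")

# classify a second section and quantify its immunolabel channel
image2, truth2 = hq.generate_radial_tissue(hq.default_tissue_spec(seed=12, snr=8))
seg2 = hq.segment_image(image2.reference)
table2 = hq.compute_feature_table(seg2, image2.reference, frame)
preds = hq.predict_with_confidence(model, table2)
corrected = hq.background_correct(image2.signal, seg2.roic)
quad = hq.assign_quadrants(seg2, frame)
derived = hq.derive_measures(hq.quantify_roi_quadrants(corrected, seg2, quad))
summary = hq.summarize_by_class(derived, preds, threshold=0.7)
print(summary[["n", "Wallsignal_mean", "Lumensignal_mean"]].round(1))
```

prints

```
281 cells segmented (280 in the ground truth)
top features: ['radialV', 'MedianROIW', 'perimeter']
out-of-bag accuracy: 1.000
              n  Wallsignal_mean  Lumensignal_mean
class_label
cambium      55            131.6              69.5
cork         44             40.0             184.1
cortex       45             63.3             247.9
phloem       49             44.1             134.8
xylem-I      39             59.3              53.6
xylem-II     44           5713.4              95.3
```

The radial coordinate dominates the importance ranking, as expected for a
ring-organised tissue, and the wall-restricted immunolabel placed in the
xylem-II ring shows up as a ~40-fold wall-signal enrichment in that class
while lumen signal stays near background everywhere.

## Command line

```bash
hypoquant catalog  --source images/ --title myexperiment
hypoquant synth    --seed 5 --out demo/                      # ground-truthed test data
hypoquant segment  demo/SYN01_*.tif --pixel-size 0.7 --out seg/
hypoquant train    --config config.yaml --catalog <exp>/catalog.json
hypoquant quantify --config config.yaml --catalog <exp>/catalog.json \
                   --iteration <exp>/iteration_*/iteration.json --confidence 70
hypoquant assemble --catalog <exp>/catalog.json --filter antibody=LM10 --out compiled.csv
```

Image filenames carry six underscore-delimited metadata tokens
(`plate_antibody_genotype_age_tissue_replicate`, e.g.
`C08R6_LM10_Col_21-day-old_Hyp_BR1.tif`); the catalogue records them and the
`assemble` step filters on them.  The compiled per-cell CSV columns are:
image id and metadata, cell id, class and confidence, the 22 features, the
per-quadrant measures (ROI-kind-major C → L → W, quadrants 1–4, each
mean/std/size), then the derived measures.

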