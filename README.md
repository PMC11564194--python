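# dmvquant

Automated quantification of neonatal **deep medullary veins (DMVs)** on
susceptibility-weighted imaging (SWI) minimum-intensity-projection (MinIP)
slices.

Deep medullary veins drain the deep white matter toward the subependymal
veins; on SWI MinIP they appear as thin dark tubes (widths around
0.5–0.9 mm in neonates) on a brighter white-matter background. Their
number, calibre and tortuosity change with cerebral perfusion and
oxygenation, which makes them an in-vivo window on cerebral circulatory
regulation in newborns at hypoxic-ischemic risk. Manual readings of
dozens of sub-millimetre veins per slice are slow and unreliable;
`dmvquant` provides the full automated pipeline for researchers working
with such data:

- **Reconstruction** — slab MinIP from a 3D SWI volume: each output pixel
  is `min` over all slices whose center lies within ±t/2 of the slab
  center (e.g. 20 mm slabs every 1 mm, or a clinical 12 mm preset),
  linear window/level display mapping (default WW/WL = 240/200), and
  selection of the six analysis slices around a user-chosen reference
  slice (three superior, two inferior).
- **Segmentation** — a multi-scale Sato tubularity filter on the inverted
  slice, hysteresis thresholding, minimum-area filtering and an
  intensity-refinement step; any trained model can be dropped in through
  the `SegmenterContract` (slice in → same-shaped mask out). Pixelwise
  evaluation (accuracy, Dice) and ratio / k-fold dataset splitting are
  included.
- **Morphometry** — per vessel instance (8-connected component):
  - *width* `w = mean(2·EDT − 1) · Δ` over the centerline, where EDT is
    the Euclidean distance transform (exact on rasterized odd-width
    stripes);
  - *tortuosity* `τ = L_arc / L_chord ≥ 1`, arc length of the
    (smoothed) longest skeleton path over the endpoint distance;
  - per-slice bilateral counts about a midline column and per-subject
    vessel-weighted means;
  - ROI maximum-diameter measurement for the drainage veins
    (thalamostriate and anterior caudate veins): the widest vessel pixel
    inside the ROI wins.
- **Statistics** — tie-corrected Mann-Whitney U
  (`Z = (U − n₁n₂/2)/σ_ties`, exact enumeration for small groups),
  Spearman rank correlation, mean ± SD summaries, and cohort table
  builders with pairwise deletion of undetected veins.
- **Synthetic data** — a phantom generator drawing non-overlapping
  vessels from random splines with exact known width/tortuosity/count,
  and a cohort simulator with group-structured outcomes, so every stage
  is testable without clinical data.

## Worked example

```python
import numpy as np
from dmvquant import (PhantomSpec, generate_vessel_phantom, MinipSlice,
                      analyze_slice, mann_whitney, generate_cohort,
                      CohortSpec)

# a synthetic SWI-like slice with 12 vessels of known geometry
spec = PhantomSpec(image_shape=(320, 320), spacing_mm=0.2, n_vessels=12)
image, truth = generate_vessel_phantom(spec, seed=7)
s = MinipSlice(image=image, spacing_mm=(0.2, 0.2),
               slab_center_mm=0.0, slab_thickness_mm=20.0)
mask, summary = analyze_slice(s)       # segment + label + measure
print(f"vessels found: {summary.count_total} "
      f"(truth {len(truth.records)}); "
      f"L/R = {summary.count_left}/{summary.count_right}")
print(f"mean width:     {summary.mean_width_mm:.3f} mm "
      f"(truth {np.mean([r.width_mm for r in truth.records]):.3f} mm)")
print(f"mean tortuosity: {summary.mean_curvature:.3f} "
      f"(truth {np.mean([r.tortuosity for r in truth.records]):.3f})")

# a simulated cohort: term vs preterm DMV width, Mann-Whitney U
cohort = generate_cohort(CohortSpec(quota=True), seed=7)
term = cohort.loc[cohort.term == "term", "dmv_width_mm"]
pre = cohort.loc[cohort.term == "preterm", "dmv_width_mm"]
r = mann_whitney(term, pre, mode="normal")
print(f"term {term.mean():.3f} mm vs preterm {pre.mean():.3f} mm: "
      f"Z = {r.z:.2f}, p = {r.p_two_sided:.2g}")
```

prints

```
vessels found: 12 (truth 12); L/R = 7/5
mean width:     0.730 mm (truth 0.723 mm)
mean tortuosity: 1.074 (truth 1.074)
term 0.735 mm vs preterm 0.710 mm: Z = 3.21, p = 0.0013
```

i.e. the pipeline recovers the phantom's vessel count exactly, its mean
width and arc-to-chord tortuosity to within a few percent, and the
simulated term > preterm calibre difference is detected at p < 0.01.

A CLI mirrors the library:

```sh
dmvquant minip volume.nii.gz --slab-thickness 20 --slab-spacing 1 --window 240:200
dmvquant segment minip_out/minip_003.png --low 0.05 --high 0.15 --min-area 5
dmvquant quantify minip_out/*.png --out vessels.csv
dmvquant cohort-stats cohort.csv --factor term --outcomes dmv_count,dmv_width_mm
```

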