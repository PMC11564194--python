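# Methods

This note documents the measurement conventions, the synthetic-data
design, the numerical choices, and what the validation does and does not
establish.

## Geometry and reconstruction

A `Volume` is a (z, y, x) array with per-axis spacing; the z spacing is
the slice-center distance, i.e. slice thickness plus inter-slice gap
(1.5 mm + 0.3 mm = 1.8 mm for the neonatal SWI protocol the defaults
model; in-plane 0.703 mm = 180 mm FOV / 256 matrix).

**Slab MinIP.** Slab centers are placed every `slab_spacing_mm` such
that each slab lies fully inside the slice-center extent; each output
pixel is the minimum over member slices. Membership is the half-open
test `-t/2 ≤ z_i - c < t/2`: the slice exactly on the inferior face
belongs to the slab, the superior one does not, so abutting slabs never
double-count. A slab thicker than the whole volume raises a
`GeometryError` rather than silently projecting everything. Two common
parameterizations are shipped as constants: thick overlapping analysis
slabs (20 mm / 1 mm) and the clinical 12 mm reconstruction; both are
plain arguments.

**Windowing.** Display mapping is linear from
`[WL - WW/2, WL + WW/2]` to `[0, 255]` with clipping and
half-away-from-zero rounding (the window level maps to 128).
Intensities stay in native units until display; `MinipSlice` carries a
`window_applied` flag and refuses to window twice, since re-mapping an
8-bit image distorts intensities. The default detector operates on
whatever intensities the slice carries — windowing is monotone, and the
detector's thresholds are contrast-relative, so windowed and raw input
give near-identical masks.

**Analysis slices.** Six slices around a user-supplied reference index
(the slab showing the corpus callosum body): three superior, two
inferior. Which index direction is "superior" varies between exports,
so it is a parameter (`increasing` by default). Oblique reformatting to
the corpus callosum plane is out of scope; the input stack is assumed
axially consistent.

## Segmentation

The reference detector inverts the slice and takes the pixelwise maximum
of Sato tubularity responses at Gaussian scales `σ = r/(√2·Δ)` for
target radii r of 0.25–1.0 mm (covering the 0.49–0.93 mm neonatal DMV
width range), then applies hysteresis thresholding (defaults 0.05/0.15
relative to the response peak), removes components under 5 px, and
refines: the image is thresholded at the midpoint between the detected
vessels' lower-quartile intensity and the background median, and every
dark connected component touching a dilated detection seed is kept. The
refinement recovers vessel walls at image rather than filter resolution
(the raw tubularity mask over-fills by roughly one filter scale, Dice
~0.55 against phantom truth versus ~1.0 refined) and heals detections
that fragmented along one vessel. The lower quartile is used because
the detected mask drags in partial-volume halo pixels that would
inflate a plain mean.

Instances are 8-connected components (thin oblique vessels fragment
under 4-connectivity), ordered by raster scan. Vessels that cross or
touch form a single instance by design; the phantom generator keeps
vessels separated so instance counts have unambiguous truth. A trained
semantic-segmentation model can replace the whole detector through
`SegmenterContract`; training such a model, and any GPU inference, is
out of scope.

`split_dataset` apportions by largest remainder (900 at 5:2:2 →
500/200/200) and derives per-fold seeds from a `SeedSequence`, so k-fold
partitions are distinct but reproducible.

## Morphometry

**Centerline.** Skeletonize the instance, build the 8-connected graph
(edge weights 1 and √2), and take the longest geodesic path
(double-sweep Dijkstra, exact on trees — skeletons of thin vessels are
trees up to rare small loops). Side spurs are implicitly discarded by
the longest-path rule, which would otherwise inflate tortuosity.

**Width.** `w = mean(2·EDT − 1) · Δ` over centerline pixels, where EDT
is the distance to background in pixels. This convention is exact on
odd rasterized stripes (a 3-px stripe reads 3 px) and unbiased on 1-px
lines, unlike `2·EDT`, which overestimates by one pixel. Centerline
pixels within `ceil(max EDT)` steps of the path ends are excluded: at
the tips the distance transform sees the end caps, not the walls, and
would bias the mean low. If trimming would consume the whole path the
untrimmed mean is used.

**Tortuosity.** `τ = L_arc / L_chord` with τ = 1.0 for straight (and
single-pixel) instances. The raw 8-connected pixel chain overestimates
the length of oblique or curved paths by up to ~8% (staircase bias),
which would be fatal for a quantity whose dynamic range is 1.03–1.57;
the path coordinates are therefore smoothed with an endpoint-preserving
moving average (window 5 px, shrinking near the ends) before the arc
length is taken. Collinear paths stay collinear (axis-aligned and
diagonal straight lines read exactly 1.0), a rasterized quarter circle
reads within 3% of the analytic π/(2√2) ≈ 1.111, and the smoothing
shrinks a radius-R circular arc only by order (window/R)²/24 — well
under 0.1% at the radii of interest. Curvatures within 1e-9 of 1 are
snapped to exactly 1.0. A degenerate closed-loop path (chord 0) reports
infinite tortuosity rather than failing.

**Aggregation.** Per slice: instance count (after a minimum centerline
length filter, default 2 px), left/right counts by centerline-centroid
column against the midline (radiological convention by default:
image-left is the subject's right), and arithmetic means of width and
tortuosity; an empty slice reports count 0 and absent means — never
zeros. Per subject: mean of per-slice counts; width and tortuosity are
vessel-weighted across slices (equivalent to pooling all vessels), with
a slice-weighted option since either averaging order is defensible.

**Drainage veins (TSV/ACV).** `max_diameter_in_roi` returns the maximum
of `(2·EDT − 1)·Δ` over vessel pixels inside a user-supplied ROI — when
several veins cross the ROI the widest wins, matching how a reader
choosing "the widest visible vessel" behaves. An empty intersection is
an explicit not-detected result, not an exception, because undetected
veins are legitimately excluded from downstream statistics. The
measurement is deterministic, so the manual protocol of averaging three
repeated readings has no equivalent here. Automatic localization of
named veins is out of scope; ROIs are user-supplied.

## Statistics

Vein measurements are skewed, hence nonparametric tests throughout, all
two-sided.

**Mann-Whitney.** `U = #{x_i > y_j} + ties/2` (the first-sample U that
SPSS-style tables print beside Z), computed from midranks; `Z = (U −
n₁n₂/2)/σ` with the tie-corrected variance `σ² = (n₁n₂/12)[(n+1) −
Σ(t³−t)/(n(n−1))]`. The reported Z carries no continuity correction,
matching the convention of the statistical software whose output these
cohort tables mirror. Exact p-values come from full enumeration of the
`C(n, n₁)` group labelings of the pooled midranks (valid under ties;
the null U distribution is symmetric about n₁n₂/2 by exchangeability);
`auto` mode uses enumeration when both groups have ≤ 10 observations,
and forcing exact beyond group size 12 is refused on cost grounds. An
optional continuity flag applies the 0.5 correction to the
normal-approximation p only — with it, exact and approximate p agree
within 0.011 at every achievable U for n₁ = n₂ = 8; without it the gap
reaches 0.047, which is the price of reporting the conventional Z. If
every pooled value is tied the test is degenerate and reports U =
n₁n₂/2, Z = 0, p = 1.

**Spearman.** Pearson correlation of midranks with the t-approximation
p on n − 2 degrees of freedom (delegated to `scipy.stats.spearmanr`;
the test suite cross-checks against an explicit rank-Pearson
computation). Constant inputs are an error, not a NaN.

**Tables.** `compare_groups` requires exactly two non-empty factor
levels, drops absent outcome values pairwise (an undetected TSV/ACV is
excluded from that outcome only, never zero-filled), flags significance
at 0.05/0.01, and skips an all-absent outcome with a warning rather
than failing the whole table. No multiple-testing correction is applied
by default — each test is reported at its nominal level, as in the
cohort analyses this reproduces — with Holm adjustment available as an
option.

## Synthetic data

**Vessel phantoms.** Vessels are cubic Bézier curves: a chord of
6–14 mm oriented within ±30° of the image row axis, two interior
control points offset perpendicularly by uniform amounts scaled by
`tortuosity_level` (default 0.5, giving arc/chord ratios around
1.0–1.15 — the observed neonatal range). The true tortuosity is the
polyline arc/chord of the sampled curve, exact by construction; the
true width is drawn from N(0.73, 0.07²) mm clipped to [0.49, 0.93] mm.
Placement rejects any candidate whose surface comes within 1 mm of an
existing vessel (bounded retries, then a capacity error), so instance
counting has unambiguous truth. Hemisphere truth labels follow the same
radiological convention as the morphometry.

Rasterization draws a pixel when its center lies within a radius of the
densely resampled curve. The naive radius w/2 produces tubes that the
medial `2·EDT − 1` convention reads 0.5–1 px low (pixel-center
inclusion plus the integer-quantized distance transform, with an
orientation-dependent bias), so the radius is an empirically calibrated
monotone function of target width — a knot table inverted from the
measured width of tubes drawn over the generator's own curve
distribution, linearly interpolated. The calibration makes the drawn
width unbiased under the measurement convention; an independent check
(mean medial width over the plain morphological skeleton of the truth
mask) agrees with the recorded truth within a third of a pixel.

The background is a constant (default 200) plus a smooth Gaussian
random field (σ = image/8, amplitude 5) standing in for slow intensity
inhomogeneity; vessels are stamped at a constant dark intensity
(default 60) and Gaussian noise (sd 10) is added. Real SWI magnitude
noise is Rician, but at this background-to-noise ratio (20:1) the
Gaussian approximation is excellent; the noise model is a single
clearly-named parameter and can be swapped. What the phantom does *not*
emulate: anatomical background structure (ventricles, sulci, other
vessels), the point-spread blurring of real acquisition (phantom vessel
walls are hard edges), susceptibility blooming, and vessel crossings.
Passing the recovery tests therefore shows the geometry pipeline is
correct and well-calibrated, not that the classical detector matches a
trained model on clinical images.

**Cohorts.** Subject covariates are sampled at the observed cohort
composition (64.98% term, 78.55% high-risk, 52.7% male; 317 subjects by
default), either binomially or with exact largest-remainder quotas.
Outcomes are Gaussian per level of one stratifying factor (default term
status: count 13.23 ± 5.52 vs 11.04 ± 4.43, width 0.74 ± 0.07 vs
0.70 ± 0.07 mm, tortuosity 1.10 ± 0.06 vs 1.09 ± 0.07), with counts
rounded and clipped to 1–31; other covariates are independent of the
outcomes, so comparisons across them are null by construction — the
simulator reproduces one real effect axis, not the full covariance of a
clinical population. Drainage-vein calibres (TSV ~1.6 ± 0.35 mm, ACV
~1.23 ± 0.2 mm) share latent Gaussians with DMV count and width
(correlations ~0.1–0.28) and go missing at the observed ~1–3%
non-visualization rates (NaN, never zero).

## Problem sizes and determinism

Everything is a pure function of (spec, seed); NumPy `SeedSequence`
derives all internal streams. The validation runs use 20 random volumes
for the MinIP oracle, 100 random windows, 20 phantoms of 12 vessels at
0.2 mm spacing (320² px) for end-to-end recovery, full enumeration up
to group sizes 7×7 plus 10,000 Monte-Carlo null replicates (n = 30 per
arm) for the Mann-Whitney calibration, 1,000 tied samples for the
Spearman cross-check, and 100 simulated cohorts of 317 subjects for
effect-direction recovery — sizes chosen so the whole suite validates
every stage in well under a minute while keeping Monte-Carlo bands
tight (±0.7% on the type-I rate at α = 0.05).

## Known limitations

- The classical detector is a reference implementation of the segmenter
  contract, tuned for high-contrast dark tubes; clinical performance of
  any particular trained model is a property of that model, not of this
  package.
- Widths below ~2 px of spacing are reported at 1-px granularity; at
  the acquisition resolution of 0.703 mm/px neonatal DMVs are ~1 px
  wide, so sub-pixel width studies need finer reconstruction grids (the
  phantom supports any spacing).
- Vessels are quantified per 2D slice; no 3D tracking across slabs, no
  branch-point splitting of touching vessels, and no classification
  into named anatomical veins.
- 3D phantom generation is supported but lightly exercised; its
  calibration reuses the 2D width table.
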