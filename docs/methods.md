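# Methods

## The measurement model

Bright-blood short-axis CMR at end-diastole shows the LV blood pool bright,
myocardium dark, and air/lung background darker still. Trabeculae are dark
strands projecting from the endocardial wall into the pool. The quantity of
interest is the volume fraction of trabeculated myocardium,
TM% = 100·VT/(VT+VCZ). Per slice, the trabecular area At and compact area Ac
are converted to slab volumes by the slice interval (thickness + inter-slice
gap; 8 + 2 = 10 mm for the default acquisition), summed over the stack, and
thresholded at 27.4% (inclusive) for the LVNC label. Patient TM% is
volume-weighted, not a mean of slice percentages. Masses are volumes times a
myocardial density of 1.05 g/mL (configurable; the standard tissue value).

Slices that fail segmentation are skipped and reported; patient quantities
use the remaining slices with no interpolation. Every slice uses the same
interval (no half-interval at stack ends).

## Intensity handling

Scanners and patients differ wildly in absolute gray level, so every slice is
first windowed to [0, 1] by its 1st–99th percentile range. All thresholds
below are on this windowed scale.

## LV detection

Bright MSERs are computed on the max-tree of the smoothed (σ = 1 px),
windowed, 8-bit-quantized slice: a node is stable when its relative area
growth over a 5-gray-level descent is below 0.25 and a local minimum along
its root path; area bounds are 0.1–20% of the image. Two choices matter in
practice:

- **Bright floor.** Only nodes whose level-set threshold exceeds the slice
  Otsu level are kept. Without it, the component "everything above air"
  (pool + wall + RV as one region) is also maximally stable and, being
  large and round, can outscore the true pool.
- **Chain collapse.** Nested candidates along one ancestor chain keep only
  the most stable member, so a blood pool contributes one region instead of
  a ladder of level sets (the small bright core of a heavily trabeculated
  pool is rounder than the full pool and would otherwise win selection).

Selection score = circularity − 0.5·(centroid distance to image center /
half-diagonal), ties broken by larger area, then smaller centroid row, then
column. Circularity is 4πA/P² clipped to [0, 1] with **P the convex-hull
perimeter** of the region: a trabeculated pool is full of narrow recesses
that inflate its raw boundary length, and hull perimeter keeps the measure
about overall roundness rather than tortuosity (a rasterized disk still
scores ≥ 0.85 from radius 10 px).

## Endocardial hull and its refinement

The convex hull of the selected pool spans the trabecular recesses — the
standard convention for separating trabeculae (inside) from compact wall
(outside). Because the MSER region is extracted at its stability level on a
smoothed image, its hull overshoots the endocardial edge by a pixel or two;
a refinement pass re-thresholds the unsmoothed intensities inside the seed
hull (Otsu) and rebuilds the hull from the recovered pool. The refined hull
is then padded outward by 0.5 px (pixel-center → pixel-coverage convention)
and hull membership uses pixel centers, which together place the endocardial
boundary to sub-pixel accuracy. Residual misassignment is a sub-pixel band
at strand attachments worth ≲ 1.7 TM% points at 40% trabeculation in the
phantom studies below.

## External layer by radial ray casting

360 rays (1° sampling — chord error below a pixel for the radii involved)
walk outward from the hull boundary in 0.5 px steps, to reach
l = r·d_expand from the centroid, where r is the hull's equivalent-disk
radius floored by the coarse estimate n_pixels/3000 and d_expand defaults to
1.60. The local myocardium level is the median of the first samples beyond
the hull; the external point is the last sample before intensity drops below
half that level for two consecutive samples (a single-sample drop is noise).
A ray that instead rises clearly above the myocardium band (blend factor 0.3
toward the blood level — low enough to catch partial-volume grazes at the
RV's angular edges) has entered the RV and is bridged by angular
interpolation from its neighbors; a circular rolling-median pass (window 9°,
tolerance 3 px) re-bridges any ray that latched onto a remote edge. If more
than 20% of rays find no edge within reach, the slice fails with a hint to
raise d_expand. Ray results are assembled by index, so evaluation order —
serial or parallel — cannot change the contour.

## RV detection and tissue separation

The RV is the largest bright connected region, other than the pool, with at
least 25% of the LV cavity area that comes within 3 px of the external
contour — no assumption about which side it lies on. RV pixels are excluded
from the compact mask (the septal external layer is taken at the RV-facing
myocardial edge).

Inside the hull, Otsu splits dark trabeculae from blood; components under
4 px are dropped, as are components confined to within 2 px of the hull
boundary (partial-volume rim, not trabeculae). If the two Otsu classes
differ by less than 0.25 windowed units there is no genuine dark class — an
untrabeculated cavity — and the trabecular mask is empty rather than a split
of noise. Between hull and external contour, sub-blood pixels form the
compact wall; a second Otsu over those pixels separates myocardium from any
background swept in by the polygon rasterization at the epicardial edge
(again guarded by the 0.25 separation test, so a shell of pure myocardium is
kept whole).

## Fractal comparator

The border whose tortuosity FD measures is the outer boundary of the blood
pool with trabeculae excluded — the contour that trabecular recesses make
jagged. It is extracted by marching squares at the 0.5 level of the
hole-filled cavity mask, rasterized, and pruned of 1-px spurs so the result
is a closed 8-connected curve. (The filled union of cavity and trabeculae
would be convex and its boundary smooth; measuring that would erase exactly
the signal the method relies on.)

Box counting uses dyadic sizes s = 2, 4, 8, … up to a quarter of the
smaller image side, a single grid anchored at the array origin, and an
ordinary least-squares fit of log N(s) against log s (at least 4 sizes
required). Single-anchor dyadic counting carries a grid-phase sensitivity of
roughly ±0.03 in FD — visible when the same analytic curve is rasterized at
incommensurate sizes — which is why the scale-robustness check uses
grid-commensurate (power-of-two) raster doublings. On a depth-5 triadic Koch
curve (dimension log 4/log 3 ≈ 1.2619) the estimator lands within about
0.01–0.04 depending on raster base; a straight line measures 1.00.

Global FD is the arithmetic mean of present per-slice FDs (threshold 1.26,
inclusive); per-third maxima use 1.30. When the slice count is not divisible
by 3 the basal third takes the remainder first. Absent slices contribute
nothing; an empty third gets no maximum and a non-LVNC label.

## The phantom

Each slice renders, at 1 mm/px on a 224×224 grid (8 mm slices, 2 mm gap):
a blood-bright disk (cavity radius 26 mm), a dark compact annulus (wall
7 mm), n dark radial strands, and optionally a blood-bright crescent beyond
the annulus (radial extent 14 mm, angular half-width 50°) at any angle.
Intensities default to blood 800 / myocardium 300 / background 60 on a
12-bit scale with additive Gaussian noise (σ = 12), clipped and quantized so
file round trips are bit-exact. Identical spec and seed give bit-identical
stacks.

Strands are **wedges**: tangential width set at the endocardial attachment,
tapering linearly in arc toward the tip. Wedges keep the inter-strand blood
channels open at every radius — constant-width strands pinch the channels
near their tips and fragment the blood pool at heavy trabeculation, which no
segmentation could (or should) undo. Wedge and annulus areas are closed
form, so the generated trabecular fraction At/(At+Ac) is exact. Strand axes
carry a fixed angular offset (0.2399 rad) keeping them off the pixel-grid
diagonals, where thin-wedge rasterization is biased low.

The cross-section shrinks concentrically by 30% from base to apex (cavity,
wall, strands and RV all scale together, keeping the per-slice trabecular
fraction constant and areas closed-form); the resulting blood-pool area
trend is what slice-order normalization detects (Spearman |ρ| ≥ 0.6 decides
direction; anything weaker keeps the stored order and flags it).

`trabeculation_sweep` solves strand geometry for requested fractions:
strands deepen first at the base width, then widen at the packing limit
(blood channels never narrower than 3 mm, tips never shallower than 4 mm —
shallower strands are indistinguishable from partial-volume rim at this
resolution, and fewer strands are preferred for small targets for the same
reason). Achieved analytic fractions are exact to numerical precision.

What the phantom does **not** emulate: Rician MR noise (additive Gaussian is
enough to exercise the coarse-contrast thresholds), sinusoidal wall
undulation, papillary-muscle subclassification, partial-volume blur (edges
are hard), cine motion, coil-shading bias fields, and anatomy beyond the two
ventricles. Passing the recovery suites therefore shows the geometry and
bookkeeping are right under idealized contrast, not that the pipeline is
validated on patient images.

## Measured behavior (computed by the test suite and acceptance script)

Across generated trabecular fractions 10–40%, the full pipeline recovers
patient TM% within 2 percentage points (typical error well under 1 point;
the worst case, ≈1.7 points, is the strand-attachment band at 40%).
Segmenting a 9-slice stack takes on the order of a second per slice on one
CPU. Per-slice FD grows with trabecular fraction in the deepening regime
(0–30%); in the widening regime beyond, border length — hence FD —
plateaus, so monotonicity is asserted over 0–30%.

## Parallelism

Each slice is a pure function of its pixels and the configuration; the
worker pool maps over slices and assembles by index, so any worker count
reproduces the serial output bit for bit (asserted in tests). Throughput is
logged, never asserted.

## Known limitations

- The endocardial boundary is a convex hull: genuinely concave endocardial
  outlines (some apical slices) are spanned, overstating the cavity there.
- FD thresholds (1.26/1.30) were established for a specific border-extraction
  procedure elsewhere; here they are applied to this package's own
  trabeculated blood-pool border, which is a declared divergence.
- Inputs must be pre-selected end-diastole frames; no cine phase picking.
- Sub-pixel tissue assignment at strand attachments bounds TM% accuracy at
  coarse resolution (see above); at 0.5 mm/px the phantom errors halve.
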