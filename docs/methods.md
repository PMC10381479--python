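# Methods

This note records the model behind `sulcuseg`, the parameter choices that
matter, and the design decisions taken where more than one reasonable
convention existed.

## Problem setting and assumptions

The input is a 2-D B-mode cranial ultrasound frame (8-bit, conformed to
550×868 pixels) and, per groove, a manually drawn polygon that loosely
surrounds one sulcus. The method assumes:

* the sulcus appears *brighter* than surrounding tissue (true for
  echogenic sulci in transfontanelar imaging);
* the ROI polygon contains the whole structure of interest and not a
  second, larger bright structure (bone can defeat the largest-area rule
  if included);
* one groove per polygon — the output is a single connected component
  with a single closed outline.

Noise is treated as multiplicative speckle; no attempt is made to model
attenuation, shadowing, or anisotropic point-spread.

## The three methods

All methods crop the ROI's axis-aligned bounding window (half-open pixel
intervals, boundary vertices included) and min–max rescale the crop to
[0, 1]. A constant crop rescales to all zeros, so a structure-free ROI
yields an empty mask and a clean per-groove failure rather than an
exception.

**Local threshold.** Foreground iff intensity exceeds the local
Gaussian-weighted mean minus `offset`. Border neighborhoods are completed
by symmetric reflection; comparison is strict, so ties (e.g. a uniform
field) map to background. A disk closing then bridges thin dark cracks
inside the groove. Note closing joins *extended* structures separated by
a crack; it does not merge isolated dots, whose closing by a disk is the
identity.

**Sigmoid + threshold.** The logistic correction
O = 1/(1 + exp(gain·(cutoff − I))) is applied to the *full frame* before
cropping, then the threshold chain runs unchanged. Applying it globally
keeps the crop's local statistics unbiased by the window edges. With
`inv` the complement (negative correction) is returned.

**Snake (MorphACWE).** A binary level set is evolved for a fixed number
of iterations. Each step recomputes the mean intensity inside (c1) and
outside (c0) the front, flips border pixels toward the phase minimizing
the weighted Chan–Vese residual λ1(I−c1)² − λ2(I−c0)², and applies the
morphological curvature operator: alternating sup-inf / inf-sup filters
over the four 3×3 line structuring elements. The evolution is fully
deterministic. On a constant image the two phase means coincide and the
initialization is returned unchanged. Since the front may converge onto
the dark phase, the mask is inverted when foreground exceeds 50% of the
crop (strict inequality): a sulcus always occupies the minority of its
window.

## Structure selection

The candidate mask is hole-filled (enclosed "pepper" holes are
binarization artifacts, and the outline contract requires simply
connected regions), then: label 8-connected components (labels assigned
in raster-scan discovery order); drop regions with area < `min_area`
(cheap noise removal first); keep regions whose centroid passes a
boundary-inclusive point-in-polygon test against the ROI; select the
largest survivor (ties broken toward the lower label); clip to the
rasterized ROI. Clipping can sever a limb that was connected only
outside the polygon, so the largest remaining component is re-selected —
without this the single-component guarantee on the final mask would not
hold. An empty selection at any stage marks the groove `failed`, and the
original ROI polygon is echoed back as the contour so the user can still
edit vertices.

Eight-connectivity was chosen over 4-connectivity to avoid splitting
thin diagonal groove segments.

## Contour extraction

The outline is the pixel-edge boundary of the final mask: vertices on
the half-integer lattice, traced with interior-on-the-left orientation
and a left-turn preference that keeps diagonally touching pixels on a
single loop. Collinear runs are simplified, so a solid rectangle yields
exactly its four corners. The contract is that re-rasterizing the
polygon under the pixel-center rule reproduces the mask exactly; since
pixel centers (integers) never lie on the traced edges (half-integers),
the even-odd rasterization is exact. A clustering-based outline
(superpixels) would deliver the same boundary with added stochasticity,
which is why deterministic tracing is used instead. At a diagonal pinch
the loop touches itself at one vertex; masks with interior holes or
several components are rejected as a typed topology error.

## Parameters

| key | default | meaning / rationale |
| --- | --- | --- |
| `sigmoid.cutoff` | 0.5 | logistic midpoint (intensity mapped to 0.5); 0.4 is exposed as a noise-suppressing preset that darkens peri-sulcal speckle |
| `sigmoid.gain` | 10 | logistic slope; > 0 required |
| `threshold.block_size` | 27 px | neighborhood side; mid-range between separating grooves and fragmenting them |
| `threshold.method` | gaussian | Gaussian-weighted local mean (sigma = (block_size−1)/6) |
| `threshold.offset` | −0.15 | threshold = local mean + 0.15 on the rescaled crop. Calibrated on the default phantom battery: a zero margin marks roughly half the speckle background as foreground (any pixel above its local mean), which percolates under 8-connectivity into the groove; 0.15 maximizes Dice at every tested speckle level (0.1–0.6) and keeps degradation monotone in noise |
| `closing.radius` | 2 px | disk footprint; bridges cracks up to ~2 px |
| `regions.min_area` | 10 px | smallest structure worth keeping before the centroid test |
| `snake.iterations` | 35 | enough for convergence on two-level crops (mask change < 1% over 5 further steps) |
| `snake.smoothing` | 1 | curvature passes per step; higher rounds thin grooves away |
| `snake.lambda1/lambda2` | 1/1 | symmetric inside/outside weights |
| `snake.init` | checkerboard | period-5 checkerboard; `roi` seeds from the rasterized polygon |

Coordinate convention everywhere: 0-based, x = column, y = row, pixel
centers at integer coordinates; crop windows are half-open. Tables are
CSV (`groove,vertex,x,y`), with XLSX read/write behind the same schema.
RGB input is reduced to BT.601 luminance; the 550×868 conformance resize
is bilinear.

## Evaluation

Dice is computed from explicit TP/FP/FN counts. Two empty masks score
1 by convention (vacuous agreement), so an expert pair who both judged a
groove absent does not poison a mean; the report object states the
convention. `compare` accepts either two result lists (inter-expert
protocol) or results against ground-truth masks, and carries per-groove
timings.

## The phantom generator

Each phantom draws `n_grooves` (default 3) smooth cubic-spline curves
through 3–5 control points, one per horizontal band (curves confined to
the middle half of their band, so truth masks are disjoint and a dilated
ROI cannot reach a neighboring groove), thickened to 3 px at intensity
0.85 over a 0.15 background, blurred with a σ = 1 px Gaussian PSF, and
multiplied by log-normal speckle exp(N(0, σ_s²)), σ_s = 0.25 by default —
a standard first-order B-mode noise approximation. The ROI is the convex
hull of the truth mask dilated by 8 px; `roi_jitter` adds vertex noise to
emulate a sloppier manual outline. Everything is a pure function of the
spec and its seed.

What the phantoms do *not* emulate: anatomy (gyral geometry per
gestational week), depth-dependent attenuation, acoustic shadowing,
spatially correlated speckle, and neighboring bright bone. Passing the
phantom battery therefore shows the pipeline recovers bright curvilinear
structures under multiplicative noise at realistic contrast — not
clinical-grade accuracy on hospital data, which requires expert-annotated
frames.

On the default battery (20 phantoms, 3 grooves each, speckle 0.25) all
three methods reach mean Dice ≥ 0.8 against exact truth, with the
active contour slightly behind the threshold variants at low noise but
degrading most gracefully at high noise — consistent with its
initialization sensitivity and its robustness to unclear edges. The
residual error is concentrated in the blurred rim: the observed ridge is
wider than the 3-px truth support, bounding Dice well below 1 for any
intensity-based method.

## Problem sizes used in the test battery

Quantitative suites run on 256×256 phantoms: 20 seeds (7–26) at speckle
0.25 for recovery, 10 seeds per level of {0.1, 0.3, 0.6} for noise
monotonicity, 100 random grids ≤ 32×32 for the exact oracle
equivalences, and 100 seeded blobs ≤ 48×48 for the contour identity.

## Known limitations

* Bright non-sulcal structures (bone) inside the ROI win the
  largest-area rule; the tool relies on the clinician excluding them.
* The threshold margin is expressed on the rescaled crop, so its
  physical meaning depends on the crop's dynamic range; crops containing
  only noise still rescale noise to full range (mitigated by the margin
  and by `min_area`, and by the degenerate constant-crop rule).
* Contours are single simple polygons: branched sulci that genuinely
  split into several components must be annotated as separate grooves.
* Timing fields measure wall-clock on the running machine and are not
  comparable across hardware.
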