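# sulcuseg

Semi-automatic, ROI-guided segmentation of cerebral sulci (grooves) in
neonatal cranial ultrasound.

During the third trimester the cortex folds rapidly, and the depth and
shape of individual sulci — imaged through the open fontanelle as bright
curvilinear structures on dark, speckle-noised tissue — are markers of
brain maturation in preterm infants. Fully manual outlining of each
groove is slow and reader-dependent; fully automatic segmentation is
unreliable in B-mode speckle. `sulcuseg` implements the middle road: a
clinician draws a rough polygon (the ROI) around one groove, and the
tool isolates the bright structure inside it, returning a binary mask
and an ordered, editable contour.

It is a library plus a small CLI, intended for researchers building
image-analysis pipelines for cranial ultrasound and for anyone needing a
tested reference implementation of this class of ROI-guided method.

## Method

Three interchangeable segmentation methods share one scaffold. For a
frame $I$ and ROI polygon $P$:

1. **Crop** the axis-aligned bounding window of $P$ and stretch contrast,
   $I' = (I - \min I)/(\max I - \min I)$.
2. **Binarize** —
   * *Threshold*: pixelwise local adaptive threshold, foreground iff
     $I'(x) > \mu_B(x) - \text{offset}$, where $\mu_B$ is the
     Gaussian-weighted mean over a `block_size` neighborhood; then
     morphological closing (dilation ∘ erosion, disk footprint) to bridge
     dark cracks.
   * *Sigmoid + Threshold*: same, after first applying the logistic
     contrast correction $O = 1/(1 + e^{\,\mathrm{gain}\,(\mathrm{cutoff} - I)})$
     to the full frame.
   * *Snake*: morphological active contours without edges (MorphACWE) —
     a binary level set evolved by the Chan–Vese data term (inside/outside
     mean intensities) alternated with morphological curvature smoothing;
     the mask is inverted if foreground exceeds half the crop, since a
     sulcus is always the minority phase.
3. **Select** the structure: label 8-connected components, drop those with
   area < `min_area`, keep those whose centroid lies inside $P$, take the
   largest survivor, and clip it to the rasterized polygon.
4. **Report**: transpose the mask back to full-frame coordinates and trace
   its pixel-edge boundary into a closed polygon whose (boundary-inclusive)
   rasterization reproduces the mask exactly. Individual vertices can then
   be edited and the result exported as a `groove,vertex,x,y` table.

Agreement between segmentations $S$ and $GT$ is scored with the
Sørensen–Dice coefficient
$\mathrm{DSC} = 2|S \cap GT| / (|S| + |GT|) = 2TP/(2TP+FP+FN)$.

Because clinical frames cannot be redistributed, the package ships a
seeded phantom generator (`sulcuseg.synthetic`): smooth bright curves on
a dark background with Gaussian blur and multiplicative log-normal
speckle, with exact ground-truth masks and auto-generated ROIs. All
quantitative tests run against these phantoms.

## Worked example

```python
from sulcuseg import (MethodConfig, PhantomSpec, compare,
                      generate_phantom, segment_all)

img, pairs = generate_phantom(PhantomSpec(seed=7))      # 256x256, 3 grooves
truth = {roi.groove_label: mask for mask, roi in pairs}
for method in ("threshold", "sigmoid_threshold", "snake"):
    results = segment_all(img, [roi for _, roi in pairs],
                          MethodConfig(method=method))
    report = compare(results, truth)
    per = ", ".join(f"{g.groove_label}={g.dsc:.3f}" for g in report.per_groove)
    print(f"{method:18s} mean DSC {report.mean_dsc:.3f}  ({per})")
```

prints

```
threshold          mean DSC 0.907  (groove1=0.901, groove2=0.918, groove3=0.902)
sigmoid_threshold  mean DSC 0.907  (groove1=0.899, groove2=0.916, groove3=0.906)
snake              mean DSC 0.912  (groove1=0.903, groove2=0.932, groove3=0.899)
```

Each number is the Dice overlap between the method's mask and the
phantom's exact groove support: ≈ 0.9 means the recovered structure
matches the true groove up to its blurred, speckled rim.

The same flow from the shell, exercising the file formats:

```sh
sulcuseg phantom --out data --n 1 --seed 7 --speckle 0.25
sulcuseg run  --image data/image_000.png --roi data/rois_000.csv \
              --method threshold --out pred.csv
sulcuseg eval --pred pred.csv --truth data/truth_000.csv \
              --image data/image_000.png --report report.csv
# -> groove1: ok (0.014 s) ... mean DSC 0.90687 over 3 grooves
```

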