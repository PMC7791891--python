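# Methods

This note records the models, conventions and numerical choices behind the
package, the reasoning where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Data model and rasterization

Coordinates are 0-based; pixel (i, j) occupies the half-open square
[j, j+1) × [i, i+1) in continuous pixel units, so its center is
(j + 0.5, i + 0.5). A pixel belongs to a cell iff its center lies strictly
inside the cell polygon. This convention is unambiguous (centers of a label
map's pixels can never fall on a polygon whose vertices lie on the integer
grid) and makes the polygon → label-map → polygon round-trip exact, which
the suite verifies pixel-for-pixel on random cohorts.

Polygons are the canonical instance representation: adjacent cells in
hand-drawn outlines may overlap, which a label map cannot encode. Label-map
export therefore has a strict mode (error listing colliding ids) and a
precedence mode (contested pixels go to the higher-confidence instance,
ties to the lower id). Manual instances carry confidence exactly 1.0 so a
single confidence-filtering path serves manual and predicted cohorts alike.

IOU is computed on rasters, not polygon geometry, because the matching
criterion operates on segmentation pixels; the implementation intersects
bounding boxes only, which keeps per-frame matching cheap.

## Matching and metrics

A prediction can match only a same-class truth cell at IOU ≥ θ = 0.25;
predictions survive filtering only with confidence strictly above τ = 0.3.
The assignment is the maximum-cardinality one-to-one matching, with total
IOU maximized among maximum-cardinality solutions. It is solved as a linear
assignment with weight C + IOU on admissible pairs, where C exceeds any
achievable total IOU, making cardinality lexicographically dominant. This
choice (rather than greedy matching) makes the result order-independent and
lets an exhaustive enumeration oracle check it exactly, which the suite
does on a thousand random crowded frames.

True negatives do not exist for instance detection, so "specificity" is
operationalized as the positive predictive value TP/(TP+FP) over a class's
predictions — the only per-class, cell-level quantity consistent with false
positives inflating a class's apparent prevalence. Every metrics file
carries this definition. Counts are pooled over frames before ratios are
formed (micro-averaging); a class absent from both sides is reported with
n = 0 and NaN ratios rather than dropped or zeroed. Overall rows report
both cell-weighted averages (sensitivity weighted by truth cells,
specificity by predictions, IOU by matched pairs) and class-unweighted
means, since published summaries are ambiguous between the two.

## Synthetic tissue model

Each frame (default 1024² px) is populated with Poisson(cells_per_frame)
cells placed by cluster-then-scatter: cluster centers uniform in a margin
box, each cell displaced from a random cluster by an isotropic Gaussian
(default 4 clusters, 12 µm spread). The margin is a conservative
cell-radius bound (three geometric SDs above the class median area, capped
at a quarter frame), and placement is rejection-sampled into it so no
boundary clamping distorts the spatial statistics.

A cell is a star-shaped polygon: an ellipse with axis ratio U[0.6, 1] and
uniform orientation whose radius is modulated by a random harmonic of
orders 2–4 normalized to the class's irregularity amplitude (< 1, keeping
the polygon simple), rescaled to an area drawn from the class's log-normal
distribution. Lymphocytes (T and B cells) get low irregularity (0.08);
dendritic cells, which are visibly more amorphous in tissue, get 0.25–0.30.
Default median areas (80 µm² T, 110/95 µm² mDC/pDC, 70 µm² B at fresh-frozen
scale, geometric SD 1.4–1.5) are plausible for lymphocytes and DCs in 2-D
confocal sections and are shared across the cohort presets, so preset
cohorts differ by density, mixture, pixel size and shrinkage only.

Cohort presets mirror the three study conditions: fresh-frozen double-stain
(0.1413 µm pixels, 21.5 cells/frame), FFPE double-stain (0.1058 µm, 44.7
cells/frame) and FFPE single-stain (0.1058 µm, 31.0 cells/frame, five
classes), with class mixtures renormalized from the published manual count
tables.

**Shrinkage.** Formalin fixation contracts tissue; the model is a single
linear factor s ∈ (0, 1] multiplying cell linear size *and every position
about the frame center*. Scaling positions wholesale (not just
within-cluster displacements) was a deliberate choice: contraction acts on
the tissue, and it makes every intercellular distance scale exactly by s,
so mean area scales by s², perimeter and nearest-DC distance by s — closed
forms the pipeline recovers within sampling error. With s = 1 the
configuration reproduces the unshrunk cohort exactly under the same seed;
rejection acceptance depends only on unshrunk draws, so the random stream
is identical at every s and cohorts pair cell-for-cell.

**Degradation.** Each truth cell is detected independently with its class's
detect_prob; detected cells get a confusion-sampled class (row-stochastic
matrix; identity by default), a jittered outline (Gaussian translation of
SD jitter × equivalent radius plus a clipped isotropic rescale; jitter = 0
leaves the outline bit-identical so matched IOU is exactly 1), and a
confidence from Beta(8, 2) when correctly classified or Beta(2, 2)
otherwise — unimodal confidences above and straddling the 0.3 filter,
respectively. Poisson(fp_rate) false positives per frame and class borrow
the outline of a random truth cell of that class (empirical size
distribution) at a uniform position; a 3-µm disk is the fallback when a
class has no exemplar. Measured sensitivity converges to
detect_prob × confusion-diagonal, which the suite verifies at n ≥ 2,000.

Random streams are split per frame from the master seed
(`SeedSequence.spawn`), so growing a cohort never reshuffles earlier frames.

**What the simulator does not model.** No fluorescence intensities,
spectral bleed-through, autofluorescence or staining variability —
degradation acts on instances directly, with error rates as knobs rather
than consequences of image quality. Cell shapes are star-shaped, so
extreme dendritic morphology (long thin processes) is under-represented;
false positives are spatially uniform rather than correlated with tissue
structure; detection errors are independent across cells, with no
density-dependent failure in crowded regions. Passing tests therefore
establish that the *measurement pipeline* is correct and calibrated — not
that any particular detector achieves these error rates on real images.

## Morphometry and distances

Area is the set-pixel count times the pixel area. Perimeter is the length
of the level-0.5 iso-contour of the 3×3-box anti-aliased mask: contouring
the raw binary mask overestimates a digital disk's perimeter by ~5% (and
pixel-edge counting by up to 4/π), while the anti-aliased contour is
accurate to well under 1% at cell scales and never undercuts the
isoperimetric bound perimeter ≥ π·d_eq, which is asserted (with a 1e-6
discretization tolerance) as a record invariant. A golden test pins the
estimator (10×10 px square → 36.6253…). All features are computed in pixel
units and multiplied by the pixel size at the end, so unit scaling is exact
to machine precision.

T-cell-to-DC distance defaults to centroid-to-centroid (raster centroids):
published work rarely states the reference point, and centroids are stable
for amorphous DCs whose dendrites dominate a boundary-based measure. A
boundary mode (minimum outline distance, 0 for overlapping cells) is
provided, and every output records the mode. Distance targets are DC
classes only — in a two-marker-panel frame the single stained DC type, in
the five-class panel {mDC, pDC}; B cells are never targets. T cells in
DC-free frames are skipped and logged, not zero-filled. Border-touching
cells are flagged (possible truncation bias) but not excluded.

## Statistics

KS comparisons use the two-sample statistic D = sup |ECDF₁ − ECDF₂| with
asymptotic p-values (effective n = n₁n₂/(n₁+n₂)), appropriate at the
sample sizes the pipeline produces; an exact option exists and results with
fewer than 5 observations on a side carry a small-sample flag. The suite
verifies D against brute-force ECDF evaluation exactly and the 5% type-I
rate within ±1.5% at n = 200. No multiple-testing correction is applied;
reports state the number of tests run. Percent change of means is
100·(m_ref − m_cmp)/m_ref, positive for reductions.

Population tables round half-up at printed precision (1 decimal for
cells/image, 2 for percentages), with the total derived from the class
counts so percentages always sum to 100 within rounding. Dataset splits
shuffle frames by seed and apportion partition sizes by largest remainder,
so each size differs from its exact share by less than one frame; the
split is at the image level (frames from one biopsy can land in different
partitions — intentional when the goal is isolating preparation effects
from patient effects, but a caveat for generalization claims).

## Problem sizes and determinism

The shipped verification uses cohorts of 120–200 frames (≈5,000–7,200
cells, ≥2,000 per class where a class-level recovery is asserted), 1,000
random frames for the matcher oracle, and 500/2,000 replicates for the KS
checks — sizes at which every 3-standard-error band is a few percent wide
while the whole suite runs in minutes on one core. All stochastic stages
consume `numpy` Generators seeded from explicit integers; identical
configurations and seeds reproduce cohorts byte-for-byte through the file
writers (provenance manifests carry the only timestamps).

## Known limitations

- The degradation model's jitter → IOU relationship is empirical; the
  simulator exposes the knob rather than asserting a particular IOU
  distribution.
- Evaluation is single-threshold (θ = 0.25), matching the protocol it
  implements; no COCO-style multi-threshold averaging.
- Features are 2-D; out-of-plane structure (dendrites crossing the imaging
  plane) is not modeled.
- Published population tables contain a few cells inconsistent with their
  own totals under any fixed rounding rule; the table builder is
  self-consistent (counts → total → percentages) and the discrepant cells
  are documented where they matter.
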