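# Methods

This note documents the models, conventions and numerical choices behind
`vertemorph`, in the spirit of a statistical-software methods appendix.

## Coordinate conventions

All coordinates are image pixels, 0-based, origin at the top-left, x
rightward and y downward (cranial → caudal). The anterior side of the
spine is configurable (`anterior_side`, default `"left"`), since lateral
radiographs can be acquired in either laterality; landmark sets are
always serialized by name (AU, AL, CU, CL, PU, PL), never by position,
to make anterior/posterior swaps impossible to introduce silently.
Physical pixel spacing is carried as metadata only — every reported
ratio is unit-free.

## Stage 1: detection and curve filtering

Any callable `image → [InstanceMask]` can serve as the detector; the
reference backend is a deterministic global Otsu threshold followed by
connected-component labeling (components below `min_area` = 64 px are
dropped). It is adequate for phantoms, where bone is brighter than
background; a trained instance-segmentation network slots into the same
interface for clinical images. Each mask is reduced to its center of
gravity, the **unweighted** arithmetic mean of foreground pixel
coordinates — the binary mask, not the intensity, defines the center.

The spinal curve is fitted as `x = f(y)` with y the independent
variable: a vertically running spine is single-valued in y but not in x.
RANSAC draws minimal samples of size `degree + 1` for each degree
1..min(4, n−1) (`n_iter` = 500 per degree, which is exhaustive in
practice for the ≤ 20 centers of one radiograph; duplicate samples are
skipped). Each sample model's consensus set is refit by least squares
and candidates compete on (more inliers, then lower degree, then lower
sum of squared inlier residuals); inlier flags are recomputed against
the refit model, so every flagged inlier's residual is ≤ the threshold
by construction. The fit is deterministic for a fixed seed, and
`enumerate_spinal_curve` provides the exhaustive counterpart used to
verify that the randomized search reaches the optimum.

**Residual threshold.** "Deviating significantly from the curve" needs a
number; the default is 0.5 × the median nearest-neighbor spacing of the
detected centers, computed per image. This is scale-free across image
resolutions: a center must sit more than half a typical inter-vertebral
spacing off the curve to be discarded. It is a declared package default,
exposed in `RunConfig`.

**Crops.** Retained centers are cropped to `side` = 224 px square
windows (configurable). The window origin is `round(center) − side//2`
per axis, so the rounded center lands on crop pixel (112, 112); the
crop→image transform is an exact integer translation and round-trips
losslessly. Out-of-image regions are padded with the image median (a
background proxy) and recorded per edge.

## Stage 2: landmarks and morphometry

Landmark backends are callables `(crop, window) → LandmarkSet` in crop
coordinates; outputs are contract-checked (six finite points inside the
crop). The shipped oracle backend looks up the ground-truth vertebra
nearest the window center and perturbs its landmarks with seeded
zero-mean Gaussian noise. The noise is drawn as `noise_sd × z` with z
standard normal from one generator, so runs at different noise levels
under the same seed are **paired by common random numbers** — realized
mean absolute errors then scale exactly linearly with the SD, which is
what makes the noise-degradation experiments sharp at modest sample
sizes. Regression targets are crop-frame pixels (not normalized to
[0, 1]); a small ridge-regression backend is included as optional
trainable scaffolding.

Heights are Euclidean distances between paired landmarks; ratios are
C/A, C/P, A/P. **Collapse percent** is defined as
`100·(1 − min(A/P, C/P))`, floored at 0: wedge deformity depresses A/P
and biconcave depresses C/P, both measurable within a single vertebra
against its own posterior height. Crush deformity (posterior loss) is
invisible to within-vertebra ratios; `posterior_collapse_percent`
compares P against the mean of adjacent vertebrae and is off the default
path. QM bins are half-open — [0,20), [20,25), [25,40), [40,∞) — so a
collapse of exactly 25% grades `25-40` and exactly 40% grades `>40`;
this convention is asserted prominently because the printed bin labels
overlap at their edges. The algorithm-vs-reference discrepancy flag
triggers at |Δratio| ≥ 0.2, inclusive (with a 1e-9-relative guard so a
difference that is exactly the threshold up to float representation
still flags).

## Evaluation statistics

* **Matching.** Predictions are matched to reference vertebrae greedily
  in increasing center-distance order, one-to-one, within a radius
  τ = `tau_factor` (default 0.5) × the local reference vertebral height.
  Sensitivity = TP / reference count, precision = TP / (TP + FP), FP
  rate = FP / images; zero denominators yield explicit undefined
  markers, and percentages are rounded to one decimal only at the
  reporting surface.
* **Landmark errors** are |Δx| and |Δy| as percentages of the reference
  vertebra's width (mean of the upper and lower edge spans) and height
  (mean of the anterior and posterior heights). The width/height
  definition affects the percentages, not the coordinates, and is
  documented here because "width and height" admits several readings.
* **Correlation.** Shapiro–Wilk on both series; Pearson iff both
  p ≥ α = 0.05, Spearman otherwise. Spearman p-values use the
  large-sample t approximation, switching to an exact rank-permutation
  test below n = 10. Constant series return an undefined marker rather
  than raising.
* **Bland–Altman.** Differences are oriented algorithm − reference;
  MD ± 1.96 × sample SD (ddof = 1) defines the LOA, within which ~95% of
  normally distributed differences fall. Subgroup rows (per QM bin)
  count coverage against the single **global** LOA, so growing
  measurement error in severely collapsed vertebrae shows up as falling
  subgroup coverage. Proportional bias is the simple linear regression
  of the difference on the pair mean (slope, p, R²); zero-variance
  differences collapse the LOA to [MD, MD] with the trend undefined.

## The phantom generator

The phantom emulates exactly the geometry the pipeline consumes: a
vertical column of brighter-than-background vertebral bodies whose
centers lie on a degree-≤ 4 polynomial midline, rendered as filled
hexagons through their own six landmarks (so truth landmarks and truth
masks agree by construction), with Gaussian edge smoothing (σ = 0.8 px),
additive Gaussian noise, and optional bright curvilinear confuser
strokes mimicking the main false-detection sources (diaphragm edge,
posterior airway wall, rib overlap — the first two placed off the
spinal column so only the curve filter can reject them, the rib
deliberately crossing a vertebral margin as a merged-component stress
case).

Defaults: 14 vertebrae (T4–L5) in an 880 × 420 px frame, base size
64 × 34 px growing 3% per caudal level (lumbar vertebrae are larger than
thoracic), 10 px inter-vertebral gap, bone/background gray levels
40000/12000 on a 16-bit scale, noise SD 200. Deformity severity s maps
onto landmark geometry so that the defining ratio reduction equals s —
wedge: A/P = 1 − s (tilted upper endplate, C = (A+P)/2 follows);
biconcave: C/P = 1 − s (symmetric central dip); crush: all heights
scaled by 1 − s, leaving within-vertebra ratios at 1 exactly as in real
crush fractures. This mapping is the package's own construction — it
makes requested severity and recovered QM collapse coincide by
definition, which is what a ground-truth generator should do, but it is
a geometric idealization, not a biomechanical model.

What the phantom does **not** emulate: exposure physics, soft-tissue and
trabecular texture, posterior elements (pedicles, processes), rotation/
projection foreshortening, or scoliotic multi-curve spines. Passing
phantom tests therefore demonstrates that the pipeline's geometry,
bookkeeping and statistics are correct, and that curve-based
false-positive rejection works when confusers are off-column; it says
nothing about detector or landmark accuracy on clinical radiographs,
which is entirely a property of the trained backends plugged in.

## Problem sizes and determinism

The test and acceptance workloads use one to a few 14-vertebra phantoms,
10⁴-sample agreement simulations, and 200-trial RANSAC-vs-enumeration
comparisons — sizes at which every check is sharp while the whole suite
runs in well under a minute. Every stochastic component (phantom noise,
RANSAC sampling, oracle landmark noise, simulations) draws from an
explicit seed; identical inputs and seeds reproduce outputs
bit-identically, and CLI outputs embed a provenance block (tool version,
config hash, seed).

## Known limitations

* The reference detector assumes bright-on-dark, non-touching vertebrae;
  overlapping structures merge components (the rib confuser exercises
  this) and must be handled by a learned backend on real data.
* Greedy distance matching is not guaranteed to equal the maximum-
  cardinality assignment in adversarial geometries, though it does on
  well-separated spines (property-tested against exhaustive
  enumeration on small random configurations).
* Crush severity is not reflected in the default collapse percent (by
  design of the within-vertebra definition); use the adjacent-posterior
  mode for crush-focused studies.
* Vertebral level labels come from the truth/reference annotations, not
  from image content.
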