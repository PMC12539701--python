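# Methods

This note documents the models, conventions and design choices behind
`pollentrace`: what each stage computes, which parameters matter, what the
synthetic data generator does and does not emulate, and the numerical
conventions fixed where the underlying method is silent.

## Segmentation

The pollen region is separated from the acquisition template by texture,
not color. For each pixel we take the gray level `0.299R + 0.587G +
0.114B` (the Y row of the RGB→XYZ matrix used later, so gray and luminance
are one convention), quantize to 256 uniform levels on [0,1] (by rounding
to the nearest of 256 levels), and compute the base-2 Shannon entropy of
the level histogram inside a circular patch of radius 5 px (pixels whose
center distance is ≤ radius; patches are truncated, not padded, at image
borders). The computation is delegated to `skimage.filters.rank.entropy`,
whose bit units and truncated-border behavior are verified against a
brute-force patch-counting oracle in the test suite. The entropy map is
thresholded by Otsu's criterion: values are binned into 256 uniform bins
between their minimum and maximum, the between-class variance is maximized
over all splits leaving both classes nonempty, and ties go to the lowest
level. Inputs whose values collapse into a single bin raise a
degenerate-input error rather than returning an arbitrary threshold.

**Shadow removal.** Cast shadows hug grain borders and are as locally
"busy" as the grains, so they survive entropy thresholding — but they are
nearly achromatic. For every masked pixel we compute the distance to the
gray diagonal of the RGB cube, `d(P) = ‖U × P‖/‖U‖`, `U = [1,1,1]`
(equivalently the Euclidean distance from P to the line R=G=B, zero for
grays and homogeneous of degree one). Let σ be the standard deviation of
`d` over masked pixels only (computed on [0,1]-scaled RGB). The default
rule `remove_low` drops masked pixels with `d < σ`. The opposite reading —
keeping only the near-gray pixels — is available as `keep_low`, but it
discards exactly the chromatic grain pixels the rest of the pipeline
needs, so it is not the default. If σ = 0 (all masked pixels the same
color) the mask is returned unchanged. The refined mask is always a subset
of the input mask; no morphological post-processing is applied.

## Color spaces

Two full spaces and their chroma-only projections are supported.

* **HSV**: V = max(R,G,B); C = V − min(R,G,B); S = C/V (0 when C = 0);
  H = atan2(√3(G−B), 2R−G−B) folded into [0, 2π), with H = 0 for
  achromatic pixels. The two-argument arctangent is used deliberately: a
  single-argument arctan of the same ratio is quadrant-ambiguous and
  cannot produce the full hue circle. H and S are invariant to uniform
  intensity scaling of RGB, which is the motivation for this space.
* **CIE L\*u\*v\***: XYZ is the fixed linear map with rows
  (0.607, 0.174, 0.200), (0.299, 0.587, 0.114), (0, 0.066, 1.116); then
  with y = Y/Y₀ (Y₀ = 1 for RGB in [0,1]):
  L = 116·y^⅓ − 16 for y > 0.008856, else 903.3·y (the two branches agree
  to ~7·10⁻⁴ at the branch point); u\* = 13L(4X/D − u₀) and
  v\* = 13L(6Y/D − v₀) with D = X + 15Y + 3Z, u₀ = 0.19793943,
  v₀ = 0.46831096. When D = 0 (black) both chroma terms are defined as 0.
  Note an internal inconsistency in this parameterization: the constant
  v₀ is the CIE-1976 white-point value for the v′ = 9Y/D chromaticity,
  while the v\* formula uses 6Y/D. The package implements 6Y/D by default
  (`v_prime="as_printed"`) and offers `v_prime="cie1976"` for the
  self-consistent 9Y/D variant; the choice shifts v\* by a fixed offset
  per lightness and does not affect classification in practice.
* **Representations**: `hsv` (H,S,V), `luv` (L,u\*,v\*), `hs`, `uv` —
  dimensions 3, 3, 2, 2. Hue is fed to k-means as a plain coordinate; its
  circularity is *not* unwrapped, a known artifact of the `hsv`/`hs`
  representations (a hue near 2π and one near 0 are far apart to the
  quantizer). The chroma-only `uv` representation, which wins model
  selection, is unaffected.

No sRGB gamma linearization or chromatic adaptation is applied; 8-bit
images are divided by 255 at load and every downstream formula assumes
[0,1] inputs.

## Color codebooks and features

A k-color codebook is fit by mini-batch k-means (k-means++ seeding, batch
4096, 100 iterations, 3 initializations, fixed random state; these values
are not derivable from the method description and are fixed for
reproducibility) on pixels pooled from segmented images, up to
`max_per_image = 4000` per image (uniform, seeded). By default only
*training-split* pixels are pooled (`codebook_scope="train_only"`);
pooling all images (`"all"`) is available but leaks test pixels into the
representation. Centroids are sorted lexicographically before storage so a
codebook is canonical regardless of cluster numbering. `k = 1` falls back
to the closed form (the centroid is the pixel mean). Each image is then
the k-vector of *relative* frequencies (counts divided by masked-pixel
count, so images with different masked areas are comparable) of
nearest-centroid assignments under Euclidean distance, ties to the lowest
centroid index. The admissible range k ∈ [16, 35] mirrors the species
counts reported per sample by palynological analysis — one codebook color
per putative floral source — and is enforced on the pipeline
configuration; the codebook type itself accepts any k ≥ 1 so the
closed-form and sweep cases remain expressible. A separate codebook is fit
for every (representation, k) combination requested.

## Classifier selection

The default grid crosses three families — polynomial-kernel SVMs (degrees
4–10, C = 0.91, coef0 = 1.3, `gamma="scale"`), random forests (50/100/200
trees) and MLPs (one or two hidden layers from {32, 64, 128}; kept small
because this family underperforms substantially) — with the four
representations and the configured k values. Features enter the
classifiers raw: codebook frequencies already live in [0,1] and are not
re-standardized. Class imbalance is handled only by stratification and by
the weighted-F1 selection criterion; no resampling or class weights.
Stratified 10-fold cross-validation (shuffled, seeded; every class must
have ≥ 10 members) scores each spec by mean weighted F1; a fold whose
training part degenerates to one class scores 0 with a warning. Exact ties
are broken toward fewer effective parameters (SVM degree, tree count, total
hidden units), then lexicographically, so selection is order-invariant.
The winner is refit on the full training split.

## Evaluation

All metrics derive from the multiclass confusion matrix with explicit
zero-division conventions: a never-predicted class has precision 0, and
F1 = 0 when precision = recall = 0. Balanced accuracy is the plain mean of
per-class recalls (no chance adjustment). Weighted recall and precision
weight per-class values by true class counts (weighted recall therefore
equals accuracy). Municipality rollup maps both label vectors through the
producer→municipality table before computing metrics; because the mapping
is a function, rollup accuracy is never below producer accuracy. The
temporal table computes these metrics independently within each sampling
visit. Test-retest reliability r₁₂ is the Pearson correlation between
per-producer F1 vectors computed separately on the acquisition-round-1 and
round-2 test subsets; a constant F1 vector in either round raises an
explicit undefined-correlation error instead of silently reporting 0.

## The synthetic data generator

The generator emulates the *statistical* structure the pipeline relies on,
not light-box optics:

* **Palettes.** All producers share a pool of `palette_size` (default 24)
  chromatic base colors drawn with saturation 0.45–0.9 and value
  0.35–0.95, spread over hue — no pool color sits near the gray axis.
  One shared Dirichlet(2) weight vector represents the regional flora;
  producer p's weights are shifted toward a producer-specific
  Dirichlet(0.5) mode by `min(separation · u_p, 1)` with a distinctiveness
  factor `u_p ~ U(0.5, 1.5)`. Heterogeneous distinctiveness reflects field
  observations that some producers are markedly harder to identify than
  others; it is also what gives test-retest reliability something stable
  to measure. At `separation = 0` every producer has identical weights and
  classification collapses to chance by construction.
* **Visit drift.** Each visit v tilts all weights by `w · exp(δ·g_v)`
  (renormalized) with a standard-normal direction `g_v` derived from the
  dataset seed and the visit only, and scale δ = `visit_drift` (default
  0.08). The tilt is deliberately *global* — shared by all producers — so
  it models a seasonal shift of the pollen spectrum without leaking
  producer identity through drift directions.
* **Rendering.** A gray template at `background_gray = 0.78` gets a
  per-image illumination offset and horizontal ramp (±`illumination_jitter
  = 0.02`) and per-pixel noise (σ = 0.002). Elliptical grains with radii
  4–7 px are stamped at uniform positions, rejecting any center that falls
  inside an existing grain, until the grain-pixel fraction reaches
  `coverage = 0.30`. Each grain draws its color from the visit-tilted
  mixture plus per-grain noise (σ = 0.02) and per-pixel achromatic texture
  noise (σ = 0.025, which makes the pollen region locally heterogeneous
  the way a real spread of small pellets is). Each grain casts a darker
  achromatic arc (a partial ring, 2.5 px wide, on the image's common
  shadow side) at depth `shadow_strength = 0.35` — these sit on the RGB
  diagonal and are exactly what the shadow-removal rule eliminates.
* **Dataset layout.** Defaults mirror the field study's design: 20
  producers paired into 10 municipalities, 4 visits, ~14 samples per
  producer-visit, 4 images per sample (two acquisition rounds of two
  images). Per producer, whole samples are assigned to the test split,
  spread round-robin across visits, topped up with a half-sample when
  needed so the training fraction is within one image of 2/3; test images
  are always split evenly between the two rounds. Ground-truth grain
  masks, shadow masks and palettes are saved alongside the images.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: real grain texture and shape, specular
reflections, camera optics and white-balance drift, inter-sample clumping,
and any color calibration against a reference mark. Results on synthetic
data demonstrate that the pipeline recovers producer identity *when the
mixture-of-colors model holds*; they do not certify field accuracy.

## Desk-scale study conditions

Tests and the acceptance script run a desk-scale condition: 10 producers in
5 municipalities, 4 visits × 3 samples × 4 images (480 images of 256×256;
320 train / 160 test), `uv` representation, k = 32, SVM degrees {4, 6}.
Problem sizes were chosen so the whole suite runs comfortably on a laptop
CPU. The `separation = 0.28` default defines "moderate" difficulty: high
enough that a polynomial SVM recovers producers far above chance, low
enough that per-producer F1 varies — a regime where reliability is
informative (at saturation every F1 is 1.0 and r₁₂ is undefined; near
chance it is noise). With 8 test images per producer and round, per-round
F1 estimates are coarse, so r₁₂ at desk scale is itself noisy; the
acceptance script therefore averages r₁₂ over three generator seeds.

## Known limitations

* Hue circularity is not handled for `hsv`/`hs` codebooks (see above).
* σ for the shadow rule is estimated from masked pixels of one image; very
  sparsely masked images give unstable σ.
* The r₁₂ estimate degrades when classification saturates; the undefined
  case is raised, not imputed.
* `predict_manifest` recomputes histograms from *all* masked pixels while
  the training pipeline caps them at `max_hist_pixels = 25000` per image;
  for images below the cap (every configuration used here) the two paths
  are identical.
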