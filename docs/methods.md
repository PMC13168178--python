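# Methods

This note records the modelling choices in dermfeat, the defaults and
their rationale, and the known limitations. Module-level docstrings give
the per-function contracts; this document covers the decisions that span
modules.

## Synthetic data model

The package is developed and validated entirely on synthetic data with
known ground truth.

**Lesions** (`dermfeat.synth.generate_lesion`). A lesion is an ellipse
(base radius *r*, aspect ratio *q*) whose boundary radius is modulated
sinusoidally: ρ(θ) = ρ_ellipse(θ)·(1 + A·sin(fθ + φ)) with amplitude *A*
and frequency *f*. The amplitude is the single knob for border
irregularity, which makes monotonicity of the border feature testable.
An asymmetry ratio shifts pigment density toward one half of the lesion.
Pigment is drawn from six clinically named colors (white, red, light
brown, dark brown, blue-gray, black) with per-pixel jitter; the
background is uniform skin whose color is generated from an individual
typology angle (ITA) through the Lab relation L = 50 + b·tan(ITA), with
the b channel kept inside the sRGB gamut. Optional hair strokes are dark
anti-aliased curves. The generator record stores every parameter plus the
derived center, semi-axes, diameter and phase, so feature extractors can
be checked against ground truth rather than against themselves.

**Feature tables** (`generate_feature_table`). Balanced binary labels;
informative columns receive a mean shift of `effect_size` for the
positive class; redundant columns are noisy copies of informative parents
with a target correlation (noise σ = √(1/ρ² − 1)); noise columns are
independent standard normals. The returned mask marks the informative
columns, which is what the selection-recovery tests assert against.

Generator defaults are the study conditions. They were fixed before the
evaluation suite was run and are not tuned to test outcomes.

## Preprocessing

- Images are float32 RGB in [0, 1]; masks are uint8 in {0, 1} (PNG 0/255
  on disk). Bilinear resize for images, nearest-neighbor (re-binarized)
  for masks.
- **Dull razor** hair removal: grayscale → morphological blackhat with a
  17×17 cross structuring element → fixed threshold 10 (0–255 scale) →
  1-px dilation of the hair mask → biharmonic inpainting. A hairless image
  is a fixed point (empty blackhat mask).
- **Splits** are stratified 70/10/20 with integer target sizes
  (`round(f·n)`), so 1000 records give exactly 700/100/200. When the
  validation split is smaller than the number of classes (only possible at
  the minimum dataset size of 10), that stage falls back to a seeded
  unstratified draw; the test split is always stratified.
- **Augmentation** up-samples the minority class to parity. Each copy
  independently applies rotation (uniform ±45°) with probability 0.7,
  zoom (0.8–1.2) with probability 0.3 and horizontal flip with
  probability 0.3; image and mask receive the same transform (bilinear
  vs nearest-neighbor order). Applied to the train split only; the
  applied transform is recorded on each copy. The rotation/zoom/flip
  probabilities are part of the method; the magnitude ranges are
  configuration defaults.

## Serrated-contour border irregularity

Pipeline per mask: Moore boundary tracing of the largest component
(counter-clockwise) → direct least-squares ellipse fit → contour points
within 1 px of the ellipse, grouped into contiguous runs, one
representative angle per run → circular mean μΘ of the run angles →
radial rays from the ellipse center stepped by μΘ → farthest contour
crossing per ray → serrated polygon → ΔA = A_contour − A_serrated
(signed, shoelace areas).

Edge-case policy for the step angle:

- If ≥90 % of contour points lie on the ellipse (a nearly exact ellipse,
  where crossing runs are arbitrary), a fixed 10° step is used.
- If the circular-mean resultant is < 0.1 (crossings balanced around the
  circle, mean direction meaningless) or μΘ falls outside (0, 120°], the
  step falls back to the mean angular gap 360°/n_runs, clipped to
  [1°, 120°].

The ray fan is anchored at the crossing run farthest from the ellipse
center — a landmark that co-rotates with the lesion — which makes ΔA
invariant to translations and rotations of the mask (verified within 2 %
under translation and 90° rotation). With a fan anchored at a fixed image
axis the sampled polygon would depend on the lesion's orientation.

Auxiliary descriptors computed on the same mask: box-counting fractal
dimension of the boundary, Zernike moment magnitudes to radial order 8
(on the circumscribing unit disk), circularity 4πA/P² with the Crofton
perimeter (clipped at 1.05 to absorb discretization overshoot), solidity,
convexity and ellipse eccentricity. A k-means (k = 2) step over these
rows, seeded deterministically by the rows with smallest and largest
|ΔA|, labels lesions regular/irregular.

## Remaining handcrafted features

- **Asymmetry**: for 9 orientations (20° steps over [0°, 180°)), rotate
  the mask, draw chords parallel to the reference axis through the
  ellipse-fit centroid, fit a line to the chord midpoints and take the
  mean squared vertical residual; μ_dE is the mean over orientations and
  the lesion is flagged asymmetric above a threshold of 5 (pixel² units).
  Mirror-invariant within 1 %.
- **Colors**: six axis-aligned RGB boxes; a color counts as present when
  it covers ≥5 % of lesion pixels. The red box is kept exactly as
  specified (R < 0.8, G < 0.2, B < 0.2) even though it overlaps black; a
  `corrected_red` flag switches to a non-overlapping red box (R ≥ 0.55)
  for callers who want disjoint counts. The default stays faithful to the
  published box.
- **Diameter**: the longest chord between contour points whose angular
  separation about the centroid is 180° ± 2°; the tolerance widens to 5°
  with a warning when no antipodal pair exists at 2°.
- **Texture**: grey-level co-occurrence matrix at 64 levels, distance 1,
  angles {0°, 45°, 90°, 135°}, symmetrized and normalized, restricted to
  lesion pixels. Conventions for degenerate cases: zero variance gives
  correlation 1 (a constant patch is perfectly correlated); energy is
  √ASM.
- **Fitzpatrick**: a skin patch is located by a two-stage quadrant search
  minimizing lesion overlap (rejected above 50 % overlap); ITA =
  arctan((L−50)/b)·180/π from mean Lab values (±90° when |b| < 1e−6);
  classes I–VI at thresholds 50/25/0/−25/−50.

The final handcrafted vector has 11 named columns (asymmetry,
border_delta_area, n_colors, diameter_px, fitzpatrick, and six GLCM
statistics) plus diagnostic fields. Per-feature failures are flagged in
the row rather than raised, so one degenerate lesion cannot abort a batch.

## Dual-stream network

Shallow stream: stride-1 7×7 stem (64) → residual squeeze-excite (RSE)
blocks 64/64/128 → CBAM. Deep stream: stride-2 stem (64) → stride-2 RSE
blocks 128/256/512/1024 → CBAM. Each RSE block is conv-BN-GeLU ×2 with an
SE gate (reduction 16) and a residual add through a 1×1 projection when
shapes change. Both streams are globally average-pooled, concatenated,
and passed through a 2048-unit GeLU dense layer (the deep feature tap),
dropout 0.3, and a single logit. The pinned 299×299 configuration has
22,569,879 trainable parameters (22.57 M); the count is invariant to
input size and batch content and is recomputed from the built model by
`scripts/acceptance.py`.

The stack runs on a small reverse-mode autograd engine (im2col
convolution, erf-based GeLU, batch norm composed from primitives in train
mode and applied in closed form from running statistics in eval mode,
numerically stable binary cross-entropy on logits, Adam). Feature
extraction runs the network in eval mode; untrained (seeded) weights are
a valid extractor configuration for pipeline tests, and a training loop
with early stopping and best-weight restoration is provided.

## Feature selection

**SAMI.** Each feature is a token embedded as its standardized sample
vector. Seeded orthogonal projections give Q, K, V (d_k = min(64, n));
attention logits QKᵀ/√d_k are biased by the pairwise
mutual-information matrix and row-softmaxed; the score of feature *i* is
‖O_i‖₂ · MI(f_i, y). The kept k is chosen from a grid by stratified
5-fold cross-validated MLP accuracy, ties resolved toward smaller k.

**Mutual information** uses 10 equal-frequency bins and the plug-in
joint-histogram estimator (nats); it requires ≥10 observations and
returns 0 with a warning for constant inputs.

**Fusion** concatenates the SAMI-selected handcrafted columns with the
2048 deep columns, z-scored using train-split statistics only, with
provenance recorded per column.

**OFS.** Relevance R_i = σ(α·MI_i + β·var_i − γ·maxcorr_i) with the three
statistics min-max normalized once on the train split. Each iteration
proposes a (α, β, γ, k) configuration, trains the MLP on the top-k
columns, and updates the weights by δ ← clip(δ + η·ΔAcc·Δδ, 0, 1) with
η = 0.01; search stops after 15 iterations without validation
improvement and reports the test accuracy of the best configuration.

## Classifier and metrics

MLP 128/64/32 with ReLU, batch norm and dropout 0.3, Adam (lr 0.01,
batch 32), early stopping on validation accuracy. Metrics treat zero
denominators as 0 with a warning (e.g. precision with no positive
predictions); weighted recall equals accuracy by construction, which the
tests assert as a cross-check.

## Limitations

- Synthetic lesions are radial-function shapes; the geometry code is not
  exercised on self-intersecting or multi-lobed real-world boundaries
  beyond what the generator produces.
- The numpy network is CPU-bound: a forward pass of two 299×299 images
  takes tens of seconds, so full-resolution training is impractical here;
  training behavior is validated at small input sizes.
- The naive Otsu fallback mask is a stand-in for a segmentation model and
  is flagged as such.
- ΔA rotation invariance holds to within discretization error (~2 %);
  exact invariance is impossible on a pixel grid.
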