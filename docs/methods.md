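# Methods

`tntdetect` implements an automated pipeline for detecting, segmenting and
counting tunneling nanotubes (TNTs) in 2D phase-contrast micrographs of
adherent cell cultures, and for reporting the TNT-to-cell ratio
(TCR = n_TNTs / n_cells, usually reported ×100 as TNTs per 100 cells).
This note records the model assumptions, the parameters that matter, and
the design choices made where the design was genuinely open.

## The pipeline

1. **Shading correction** (stitched acquisitions only). A multiplicative
   flat field is estimated per tile and divided out. The estimator is a
   robust order-2 bivariate polynomial: an L1 (iteratively reweighted) fit
   converges to the median surface — the smooth background, which is the
   majority phase of a 30–40%-confluent culture — followed by a
   least-squares pass on MAD-selected inliers. The global image mean is
   preserved. This is a deliberately simple single-image surrogate for
   multi-image flat-field tools; only removal of the tile-edge shadows
   matters downstream. It assumes tiles are large relative to cells (true
   for 1388×1040 px tiles and ~100 px cells); on tiles only 2–3 cell
   diameters wide the background-majority assumption degrades.

2. **Label correction.** Manual TNT annotations are polylines that
   under-cover the true TNT width. The chain: deblur a copy with
   Richardson–Lucy (RL) deconvolution using a truncated-Gaussian PSF of
   7×7 px and σ = 20 (normalized to sum 1 — at this σ the PSF is nearly
   uniform on its support); subtract the deblurred copy from the original
   to isolate fine detail; represent the signed difference 128-centered in
   8 bits; binarize; ink the visible TNTs full-width in black on a
   duplicate; XOR the two binaries. The XOR output is exactly the inked
   pixels that carried detail: a pixel-accurate TNT mask.

   *RL iteration count.* The iteration count is a free parameter with two
   regimes. A single iteration acts as an unsharp mask: thin bright
   structures leave a strong, localized positive residual. Many iterations
   of the near-uniform PSF behave as an ill-conditioned inverse filter:
   ringing develops around every cell rim and, measured on phantoms,
   swamps the TNT signal (≈25% of TNT pixels recoverable at any threshold
   after 30 iterations, vs 97–100% after one). The label chain therefore
   defaults to `iterations=1`; the general deblurring utility keeps a
   configurable default of 30.

   *Binarization.* The default `robust` method smooths the signed residual
   with a Gaussian (σ = 1 px, exploiting the spatial coherence of a line
   against iid sensor noise) and thresholds at median + 3·1.4826·MAD, with
   a floor of half a gray level. Polarity: bright-structure pixels become
   white, which is what makes ink-black-then-XOR capture them. Otsu and
   fixed thresholds are selectable; Otsu's bimodal assumption is dominated
   by the much stronger cell-rim response and misses most TNT pixels.

3. **Hierarchical patch classification.** The image is scanned with a
   512 px sliding window (stride 10 at the published operating point;
   desk-scale runs use 64), each window labelled positive iff it holds at
   least `min_tnt_pixels` labelled pixels (default 50 at the 512 scale,
   half that at 256) *and* their centroid falls in the central square
   covering `center_fraction` = 0.5 of the window side — so a TNT cut by a
   window edge does not create a positive. Positive coarse windows are
   re-scanned at 256 px. The centroid-in-central-square test is the
   cheapest monotone formalization of "pixels located closer to the
   center"; both constants are configurable. Fine windows reuse the coarse
   stride. Training sets are balanced to 1:1 positives:negatives by
   subsampling negatives.

4. **Models.** Two learned components, each in two tiers. The
   transfer-learning tier (`vgg16_pretrained` classifier backbone,
   `resnet_pretrained` U-Net encoder) requires a deep-learning runtime
   with ImageNet weights and raises a clear error when unavailable. The
   self-contained tier runs on an in-package numpy layer library
   (convolutions via im2col, hand-written backward passes, Adam) and is
   the default:

   - *Classifier* (`small_cnn`): average-pool the patch to a 64 px working
     resolution, three conv/ReLU/maxpool stages (8, 16, 16 channels), then
     the dense head 512/170/70 with 60% dropout between each pair of dense
     layers and a sigmoid output. Decision threshold 0.5.
   - *Segmenter* (`small_encoder`): U-Net of depth 2, base 8 channels.
     Each encoder level applies two 3×3 conv+ReLU and a 2×2 maxpool,
     doubling channels; the decoder mirrors with nearest-neighbour 2×
     upsampling followed by a 2×2 convolution halving the channels, skip
     concatenation, and two 3×3 conv+ReLU. Skips are gated by additive
     attention (1×1 convs θ, φ into an intermediate space, ReLU, 1×1 ψ,
     sigmoid; the skip is multiplied by the resulting map). The network is
     fully convolutional: it trains on 64 px crops and predicts 256 px
     patches.

   *Loss.* `w_bce·BCE + w_dice·(1 − Dice) + w_ac·AC`, defaults (1, 1, 1).
   Dice is the smoothed soft form (2Σpt + 1)/(Σp + Σt + 1). The
   active-contour term is the boundary-length energy Σ√(∇p² + ε) (on a
   rasterized region this approximates its perimeter) plus the
   inside/outside region energies Σp(t−c₁)² + Σ(1−p)(t−c₂)² with c₁ = 1,
   c₂ = 0 for binary targets, normalized per pixel. Optimizer: Adam,
   lr 10⁻³. All training is deterministic under the configured seed.

5. **Counting.** Per-patch probability maps are rescaled to 8-bit heatmaps
   by round(p·255), stitched by pixel-wise max (mean available) with
   uncovered pixels at 0, and thresholded at ≥ 235 (i.e. p ≥ 0.9216). The
   binary mask is outlined by the morphological gradient (dilation −
   erosion, elliptical 5×5 structuring element); external contours of the
   gradient image (holes filled so each structure yields one outline) are
   measured by the shoelace polygon area and counted as TNTs when the
   area lies in [400, 2500] px — 44.89–280.56 µm² at 0.335 µm/px (the
   resolution follows from 6.7 µm camera pixels behind a 20× objective).
   Fragmented predictions remain fragmented, reproducing the known
   multiple-counting behavior of this stage; an optional gap-closing
   morphological closing (disk radius 3) is available and off by default.
   Cells are counted by the Cellpose adapter when that package is
   installed, otherwise by the built-in blob counter (Gaussian smooth,
   Otsu, morphological closing, hole filling, distance-transform watershed
   with regional-maximum markers, minimum area 200 px).

6. **Evaluation.** Predictions are matched one-to-one to true lines
   greedily: a prediction is a true positive when ≥ 30% of its pixels lie
   within 5 px of a not-yet-matched true line (both constants exposed;
   they formalize an adjudication that was manual in the original
   protocol). Precision = TP/(TP+FP), recall = TP/(TP+FN),
   f1 = 2PR/(P+R); undefined ratios report 0 with a flag. Expert
   consensus: marks from different annotators whose polyline midpoints lie
   within 10 px (single linkage) are one candidate structure; with four
   experts, ≥ 3 votes accept, exactly 2 flag for joint review, ≤ 1 reject;
   for other panel sizes, strict majority accepts and exactly half flags.
   Inter-rater agreement uses two-rater Cohen's κ (κ ≡ 1 when both raters
   are constant and identical); TCR comparisons use the pooled
   two-sample t-test (Welch optional); human-vs-model counts across image
   sets use fixed two-way ANOVA without replication, right-tailed F.
   These statistics are implemented from their closed forms and verified
   against scipy/statsmodels/scikit-learn in the test suite.

## The synthetic phantom

No public image set accompanies the method, so the package generates
phantoms with exact ground truth. The phantom stylizes what the pipeline
actually exploits, not the optics of phase contrast: cells are
non-overlapping bright-rimmed ellipses (rim 0.92, interior 0.30 on a 0.45
background, 8-bit) at sub-confluent density; TNTs are straight-to-angular
polylines (a single optional midpoint bend ≤ 0.15·length; never
sinusoidal) connecting two cell boundaries, drawn at intensity 0.70 —
between background and rim — with integer widths ≤ 3 px (< 1 µm at
0.335 µm/px) and a base tapered to ≤ 2 px within 3 px of the cell.
Rasterization is exact: a pixel is set iff its center lies within
width/2 of the polyline. Optional confounders: iid Gaussian sensor noise
(default sd 0.03 of full scale), a smooth multiplicative illumination
ramp, per-tile quadratic edge-darkening shadows, and full-frame scratches
of width 1–2 px deliberately confusable with TNTs. Simulated experts miss
each true line with a configured probability, jitter vertices, and add
Poisson-distributed spurious lines.

What the phantom does *not* emulate — halo artifacts, cell debris,
out-of-focus TNTs fading into background, touching/overlapping cells,
gondola bulges — bounds what passing tests show: they demonstrate that
the mechanism (label chain → windows → models → counting → TCR) is
implemented correctly and can be trained to high accuracy when the
structures are visible, not that the published detection rates on real
MSTO-211H micrographs are reproduced.

## Desk-scale end-to-end condition

The end-to-end demonstration (tests and `scripts/acceptance.py`) runs on a
768×768 phantom with 20 cells and TNT lengths 30–60 µm at high contrast
(noise sd 0.02, no scratches/tiles/gradient), stride 64, the
self-contained model tier (classifier 40 epochs at lr 10⁻³; segmenter 120
epochs on 96 crops of 64 px), and gap closing enabled in the counting
stage. Two of these sizes are consequences of the counting band, not
taste: a line much shorter than ~20 µm has a gradient-outline area below
the 400 px floor and is uncountable by construction, and a 70 µm line
with the label-chain halo reaches ~2470 px, leaving no margin under the
2500 px ceiling — hence 30–60 µm. Gap closing is enabled because
thresholded heatmaps of thin lines fragment, and fragments fall below the
area floor; this is the labeled extension of the counting stage, with the
published behavior (fragmentation kept) remaining the library default.
The repo bar for this condition is precision ≥ 0.8 and recall ≥ 0.8
against phantom truth.

## Numerical choices and degenerate inputs

- Heatmap threshold comparison is ≥ (235 itself counts).
- Probabilities are clipped to [10⁻⁷, 1−10⁻⁷] inside BCE.
- The AC length term uses forward differences with ε = 10⁻⁸ under the
  square root.
- Contour extraction pads the gradient image by one pixel so structures
  touching the border still yield closed polygons.
- TCR is undefined at zero cells and raises; TCR×100 is rounded to two
  decimals in reports, full precision kept internally.
- A featureless (constant) detail image binarizes to all-black.
- One global integer seed expands to per-component seeds through
  `np.random.SeedSequence(seed, spawn_key=(component_index,))` with a
  fixed component table (`tntdetect.config.SEED_COMPONENTS`); every
  derived seed is < 2³¹.

## Known limitations

- The self-contained models are desk-scale: they overfit a single phantom
  per run and carry no claim of generalization across images.
- The flat-field surrogate is per-tile and single-image; it does not
  reproduce multi-image flat-field estimation numerically.
- Contour "area" is the shoelace area of the external outline of the
  gradient image (the outline of a dilated structure), not the pixel area
  of the structure itself; the published band 400–2500 px is interpreted
  in that sense, which the ~45–280 µm² gloss supports.
- The consensus matcher clusters by polyline midpoint only; two distinct
  collinear structures with coincident midpoints would merge.
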