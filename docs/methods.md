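# Methods

## The localization model

`entroloc` treats optic disc (OD) localization as a texture-search problem.
The working assumption is anatomical: the disc is where the central retinal
vessels and nerve fibre bundles converge, so a window over the disc sees a
brightness distribution spread over many grey levels, while windows over
the retinal background (smooth shading plus a few thin vessels) see a
concentrated one. Shannon entropy of the 256-bin brightness histogram,

    H(R) = - Σ_j p(j) log2 p(j),   p(j) = counts[j] / |R|,

measures exactly this spread, in bits, with 0 ≤ H ≤ 8 for 8-bit data.
Empty bins contribute nothing (0·log 0 = 0); accumulation is in double
precision and entropies are compared exactly, with ties broken toward the
smallest row-major grid label so every search is deterministic.

All scoring runs on the green channel of the RGB photograph, which carries
the strongest disc/background and vessel/background contrast of the three
planes; no enhancement or denoising precedes it.

## The two-stage search

1. **Coarse stage.** The green plane is split into a `rows × cols`
   (default 3 × 3) grid of disjoint patches covering the image exactly;
   when the image dimensions are not divisible, the last row/column band
   absorbs the remainder. The patch with maximal entropy is the candidate.
   With a typical fundus framing, a 3 × 3 patch is roughly disc-sized,
   which is what makes a single patch able to "capture" the disc.
2. **Refinement region.** The candidate patch is grown by half of each
   neighbouring patch's extent on every side where a neighbour exists,
   clipped to the image. This guarantees the region still contains the
   disc when the disc straddles a patch boundary. For an interior winner
   this doubles the linear size of the search area.
3. **Fine stage.** The refined region is covered by a `k × k` lattice
   (default k = 5, sensible range 4–6) of equal windows of the stage-1
   patch size, laid out endpoints-flush: window (i, j) sits at offset
   `round(i·(H_parent − h_window)/(k − 1))`, so the first window touches
   the top-left corner and the last the bottom-right, with neighbours
   overlapping whenever the stride is below the window size. The entropy
   argmax over the lattice is the final window; its floor-midpoint pixel
   is reported as the OD centre (sub-pixel precision would be spurious
   here). The search is exactly two stages deep; no further recursion is
   performed.

Coordinates are 0-based `(row, col)` with rows increasing downward, and
every rectangle is half-open `[top, bottom) × [left, right)`.

Degenerate inputs are handled deterministically rather than rejected: a
uniform image yields all-zero entropies and the tie-break chain selects the
top-left window at both stages, flagged by `candidate_entropy ==
mean_rest_entropy == 0`. Images smaller than the coarse grid are a
validation error. A batch run isolates per-file failures (unreadable or
malformed images) without aborting the remaining files.

## Synthetic fundus generator

`entroloc.synth` produces seeded images that emulate the *statistical*
structure the algorithm relies on, not photographic appearance:

- a circular camera aperture (radius 0.62 × the short image side, so the
  field-of-view circle is cropped by the frame except for small dark
  corners, as in clinical photographs) filled with a reddish background;
  the green plane carries a gentle linear shading ramp (peak-to-peak 12
  levels, random direction) plus σ = 1.5 pixel noise, keeping background
  patches at low entropy;
- a near-black exterior outside the aperture;
- 5–15 dark curvilinear vessels drawn as quadratic Bézier strokes that
  start just inside the disc and radiate isotropically outward to the
  aperture rim, 1–3 px wide (width skewed toward 1 px, matching
  capillary-scale vessels at 256-px resolution), darkening the green
  plane by 40 levels;
- one bright disc of radius 32 px (1/8 of the short side, the relative
  disc size of a narrow-field ~30° camera) at a centre sampled uniformly
  over the retina interior, kept at least `radius + 8 px` clear of the
  aperture rim and fully inside the frame; its interior carries Gaussian
  texture (base 160, σ = 60, clipped to [0, 255]) plus the crossing
  vessel roots, spreading its histogram across most of the brightness
  range.

Every image is a pure function of `(seed, params)`; a suite of n images
uses seeds `base_seed … base_seed + n − 1` and writes a
`filename, center_row, center_col, radius` ground-truth CSV.

Two vessel-geometry choices matter and were made deliberately. Strokes
radiate *from the disc*, so vascular density is highest in the disc's own
neighbourhood — the convergence structure the method exploits; aiming
strokes at the aperture rim instead would concentrate vessel pixels in
patches far from the disc and invert the intended entropy ordering.
Stroke widths favour 1 px because thick strokes make the per-patch vessel
pixel count noisy enough to perturb the entropy ranking between the two
patches sharing a boundary-straddling disc.

What the generator does **not** emulate: realistic colour and vessel
branching, the macula, illumination artefacts, pathology (exudates,
haemorrhages — which can themselves be high-entropy distractors), camera
noise statistics, or inter-image scale variation. Passing tests on this
data therefore demonstrate correctness of the algorithm and its
implementation under the method's own texture assumption; they do not
predict accuracy on clinical images, where that assumption can be
violated.

## Evaluation

A predicted centre is correct when its Euclidean distance to the true
centre is at most a criterion distance — by default the image's own true
disc radius (the conventional choice in the OD-localization literature),
optionally a fixed pixel threshold. The boundary is inclusive. Accuracy
is `100 · n_correct / n_images`. Predictions and truth are matched by file
basename; a prediction without a matching truth row is an error that lists
the offending names. Tightening the criterion can only lower accuracy.

## Problem sizes and defaults

The shipped test suite and the acceptance script work at 256 × 256 with
100-image suites, where the full generate–localize–score cycle takes a few
seconds on one CPU; the algorithm itself is resolution-independent and the
generator accepts any size ≥ 96 × 96 with disc radius ≤ 1/8 of the short
side. Key defaults: 3 × 3 coarse grid, k = 5 fine lattice (the middle of
the sensible 4–6 range), 16-bit rasters rescaled by `v // 257`, marker
square side `max(5, 2% of the short side)`.

## Known limitations

- A large bright high-texture lesion can out-score the disc; the method
  has no anatomical prior beyond texture richness.
- When the disc straddles a coarse patch boundary almost exactly, either
  neighbouring patch may win stage 1; the refinement region contains the
  disc in both cases, so the final centre is typically still recovered,
  but the coarse winner is then not guaranteed to contain the true
  centre.
- Entropy is computed per whole window; there is no multi-resolution
  pyramid, rotation handling, or non-rectangular windowing.
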