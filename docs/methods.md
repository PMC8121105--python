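# Methods

## The random-location null model

Let the monolayer occupy M pixels, of which T(r), B(r) and S(r) are TRI,
BI and BODY at junction radius r (T + B + S = M for every r). The null
hypothesis is that a diapedesis event picks a monolayer pixel uniformly
at random, so category counts for n events are multinomial with
p = (T, B, S)/M. Nothing in the test depends on cell biology beyond this
areal-frequency assumption; everything biological enters through the
geometry of the junction network and the choice of r.

r is a modelling parameter, not a measurement: junctions are geometric
curves and points with no inherent thickness, and r expresses how close
an event must be to count as junctional. Because no single r is
privileged, all results are reported over a sweep (default 0.5–6.0 µm in
0.5 µm steps; 6 µm is the largest radius considered before the
tricellular fraction stops being a minority share, and events with a
diapedesis pore of ~5 µm diameter are plausibly junctional within that
distance).

### Category map

The dilation is realised as a thresholded exact Euclidean distance
transform on pixel centres, in physical units (`scipy.ndimage.
distance_transform_edt` with `sampling=pixel_size`), with the priority
TRI > BI > BODY applied by painting BI first and TRI last. Compared with
iterated morphological discs this is rotation-consistent,
pixel-size-aware, and matched pixel-for-pixel by a brute-force
nearest-feature computation, which the test suite verifies on rasters up
to 512×512 at radii 0–6 µm. Frequencies are computed over in-monolayer
pixels only — a cell can only transmigrate where there is endothelium.
Whether off-monolayer pixels should enter the denominator is genuinely
ambiguous for images whose field extends beyond the monolayer, so a
`denominator` switch (`monolayer`/`image`) exposes the alternative; it
rescales all three frequencies by a common factor.

### Statistics

* Global test: Monte-Carlo exact multinomial goodness-of-fit. Outcomes
  are ordered by multinomial likelihood; p = (1 + #{simulated outcome at
  most as likely}) / (n_mc + 1). The add-one form keeps p ≥ 1/(n_mc+1)
  and makes the test exact-level; a likelihood tolerance of 1e-9 counts
  equal-probability outcomes as ties. Chi-square is available for
  comparison but is not the default: event counts in this assay are
  typically a few tens, where the asymptotics are unreliable.
* Per-category follow-up: two-sided exact binomial tests (scipy
  `binomtest`), Benjamini–Hochberg adjustment across the three
  categories, Wilson 95% intervals (stable at small n), and enrichment
  ratios observed/expected. A category with null probability 0 and a
  positive count gets likelihood −∞ and is always rejected.
* Events landing off the monolayer are reported as unclassifiable and
  excluded from counts rather than snapped to the nearest monolayer
  pixel, which would manufacture junctional events.

Calibration and power are verified by simulation: under uniform
placement the global test rejects at 3.8–6.0% at the 5% level (500
replicates of n = 100); with a 60% tricellular composition against a
null of p_TRI ≈ 0.2 (radius 6 µm), the BH-adjusted tricellular binomial
test has power ≈ 0.98 at n = 26.

## Junction extraction

The boundary mask (pixels whose 4-neighbourhood holds ≥2 distinct
nonzero labels; label/0 rim interfaces excluded) is thinned with
scikit-image's skeletonization, and the skeleton graph is built
directly:

* **Branch pixels** are found by crossing number — the number of
  connected runs of skeleton pixels around the 8-neighbour ring — not by
  a raw ≥3-neighbour count, which misfires along diagonal staircases.
  Fully filled 2×2 skeleton blocks (left by thinning where two lines
  cross at a diagonal) are also branch pixels, since their members see
  their neighbours as a single run.
* Branch pixels are clustered 8-connectedly into **nodes**; the
  remaining skeleton is decomposed into **paths** with a connectivity
  that cuts diagonal adjacencies whose bridging pixel is a branch pixel
  (otherwise two arms meeting diagonally across a single-pixel node
  would fuse into one path).
* **Spurs** — endpoint-terminated paths shorter than 2 µm that do not
  touch the image border — are pruned and degrees recomputed, iterating
  to a fixed point. 2 µm removes rasterization whiskers while being
  shorter than any plausible junction arm; the value is configurable and
  logged.
* Node positions are refined to the least-squares intersection of the
  incident arm lines (first six pixels of each arm), clamped to a 2.5 px
  shift. Thinning a 2-px band displaces branch points by up to ~2 px
  where arms meet at shallow angles; the arm-intersection estimate
  recovers the true meeting point to ~1 px. Tricellular *membership*
  (which pixels seed the TRI dilation) still uses the raw node pixels.
* **Tricellular** = nodes of degree ≥ 3 (three *or more* cells meeting —
  rare 4-cell points are still tricellular junctions biologically) whose
  centroid lies off the outermost 2-px frame; branch points created by
  cells cut at the field edge are artifacts. **Bicellular** = all path
  pixels; endpoint pixels and pruned spurs are excluded, and pixels of
  frame-excluded or sub-degree-3 nodes are kept as bicellular so no
  junction signal is lost.

An independent route reads junctions straight off the label map: a pixel
corner is tricellular when its 2×2 block contains ≥3 distinct labels; a
pixel is bicellular when its closed 4-neighbourhood holds exactly two.
On clean rasterized tessellations both routes recover ≥95% (in practice
≥98%) of ground-truth vertices within 2 px with no spurious detections
farther than 2 px, and they agree with each other at the same tolerance
— the cross-validation that substitutes for the original assay's
by-eye check.

## Segmentation

The classical stage turns a fluorescence stack into a label map: mean
z-projection; rolling-ball background subtraction (default radius 20 px,
the standard choice for thin junctional signal); Gaussian smoothing;
Otsu (or fixed) thresholding of the boundary signal; one watershed seed
per connected component of the sub-threshold region (components smaller
than `seed_min_distance`² px are noise and dropped); watershed with the
smoothed intensity as elevation. Cell interiors are minimum plateaus of
the boundary elevation, so component seeding is the plateau-safe reading
of "local minima separated by a minimum distance" and is robust exactly
where peak-style seeding over-segments. On noise-free renders the
segmentation reproduces the generating tessellation's cell count and
adjacency graph exactly; at 20% ridge-amplitude noise boundary recall
and precision stay ≥ 0.9 within 2 px. A neural segmenter is deliberately
not included — any external label TIFF can be substituted, and the
null-model analysis only needs a faithful label map.

## Synthetic data generator

The generator emulates a confluent, flow-elongated endothelial monolayer
with a fluorescent junction marker:

* **Geometry**: seed points uniform in the domain, three rounds of Lloyd
  relaxation (clipped Voronoi via mirror reflection across the domain
  edges, which makes the cells tile the rectangle exactly), then
  anisotropic scaling along x by the elongation factor. This yields
  convex-ish, size-regular cells without modelling biology; 50 cells on
  200×200 µm gives ~800 µm² cells, a generic epithelial/endothelial
  scale. A regular hexagonal tiling (Voronoi of a triangular lattice) is
  available as the analytically tractable extreme.
* **Rendering**: shared edges drawn as 3-px ridges (thin enough to mimic
  junctional signal, thick enough to survive skeletonization), Gaussian
  blur (0.5 µm), unit peak, multiplicative linear illumination gradient,
  additive Gaussian noise independent per z-plane. Defaults (noise sd
  0.1–0.2 of ridge peak, 10% gradient, 3 planes) are a moderately noisy
  but workable acquisition.
* **Events**: `uniform` draws pixels uniformly over the monolayer — the
  null itself; `category_probs` draws a category then a pixel within it.
  Events are stored as continuous µm coordinates jittered within the
  generating pixel, so classification at the same radius recovers the
  generating category exactly; they are snapped to pixels only when
  classified. Presets encode the observed compositions: 60% tricellular
  of all events, or 60% of paracellular events (the source wording
  supports both readings; neither is asserted as *the* truth, and the
  10% transcellular share in the paracellular-split preset is a chosen
  plumbing value, not a measurement). A ~40% tricellular live-imaging
  preset is also provided.

What the generator does **not** emulate: curved junction paths between
vertices are near-straight here; real junctional signal varies in
intensity along junctions and VE-cadherin remodels; cells at inflamed
barriers lose size regularity; there is no crawling, no flow, no
time axis. Passing tests therefore demonstrate correctness of the
geometry/statistics machinery on idealized monolayers, not segmentation
robustness on real microscopy.

## Numerical choices and degenerate inputs

* Coordinates: 0-based (row, col); physical position of a pixel =
  (index + 0.5) × pixel_size; all public inputs/outputs in µm.
* Rasterization assigns each pixel the cell containing its centre,
  computed as nearest Voronoi generator in the pre-elongation metric
  (exact for this geometry, no scan-conversion error).
* Radius 0 reproduces the raw junction pixels exactly (EDT distance at a
  feature pixel is 0); a radius beyond the image diagonal makes every
  monolayer pixel TRI through the priority rule.
* A pixel belonging to both a tri cluster and the bi candidate set is
  tri — consistent with the global priority rule.
* Empty masks skeletonize to empty; a uniform image raises "no cells
  detected"; an empty event table, an empty monolayer, radii < 0 and
  probabilities not summing to 1 are rejected with explicit errors.
* All randomness flows through `numpy.random.default_rng` seeds;
  every generator and test is bit-reproducible for a fixed seed, and the
  CLI records seeds in its manifests.

## Problem sizes

Verification runs use 50-cell monolayers at 0.5 µm/px (400×400 px),
brute-force oracle comparisons at up to 512×512, and 500-replicate
simulations for calibration and power — sizes at which every oracle is
computable exactly while still exercising thousands of junctions across
the seeded repeats.

## Known limitations

* The junction radius r is not an estimate of junctional cleft
  thickness; no such estimate is attempted.
* Tricellular and bicellular zones are treated as uniform-affinity
  regions; any within-category spatial preference is invisible to the
  multinomial reduction.
* The label-map route reports junction positions on the pixel-corner
  grid; sub-pixel localization is out of scope.
* Events are endpoints only; duration, crawling and directionality are
  not modelled.
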