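# Methods

This note documents the models, estimators and numerical choices behind
`fibrilmorph`, in the spirit of a methods appendix: what each stage
assumes, which parameters matter, and what validation on synthetic data
does and does not establish.

## Synthetic data model

The generator emulates stained TEM cross-sections of developing tendon:
dark, near-circular fibril profiles on a lighter background.

* **Geometry.** Disk diameters are drawn i.i.d. from a 1–3 component
  normal mixture truncated at zero (non-positive draws are redrawn —
  diameters are physical lengths). Disks are placed by random sequential
  adsorption (RSA): candidate centres are sampled uniformly and accepted
  only if the surface-to-surface distance to every accepted disk is at
  least `min_gap_nm`; each disk gets a fixed attempt budget (400) and is
  skipped when it expires, with a warning. Larger disks are attempted
  first, which raises attainable packing fractions. RSA produces the
  amorphous, hard-exclusion-zone packing that real fibril fields show.
  With `allow_touching` the gap constraint is replaced by a cap on
  overlap (10% of the smaller radius), producing the touching pairs the
  watershed stage must split.
* **Rendering.** A pixel belongs to a disk when its centre does
  (consequently a disk's pixel area converges to πr² as the pixel size
  shrinks — verified at two resolutions). Fibrils are dark (grey 60) on
  a light background (200) by convention; an `invert` flag covers the
  opposite convention. Optional cell occlusions are smooth random blobs
  (circle with a low-order Fourier radial perturbation) stored as
  polygons so the masking stage can be exercised with a known mask area.
  Additive Gaussian noise of configurable sd completes the image.
* **Time series.** `timepoint_mixture(day)` encodes the developmental
  schedule used throughout validation: one population before day 8
  (mean 50 + 2·day nm, sd 8), two from day 8 (70/140 nm, sds 8/12), three
  from day 14 (60/120/200 nm, sds 8/12/20, equal weights).
* **Growth curve.** Real animal-mass data are not bundled;
  `generate_growth_curve` provides a Gompertz stand-in
  `m(t) = M·exp(log(m₀/M)·e^(−rt))` with defaults m₀ = 1.5 g, M = 30 g,
  r = 0.08 day⁻¹ — a realistic laboratory-mouse trajectory (birth mass,
  adult mass, most growth inside the first eight weeks). All
  expansion-metric identities are invariant to rescaling this curve, so
  its exact shape never enters the validated quantities.

What the generator does **not** emulate: stain granularity, knife marks,
section-thickness artefacts, non-circular fibril profiles and spatially
correlated noise. Passing tests therefore demonstrate correctness of the
measurement chain on geometrically faithful inputs, not robustness to
every real-microscopy artefact.

## Segmentation

* **Adaptive threshold.** The image is tiled (`tile_size_px`, default
  64 px); per tile, Otsu's split is computed and refined to the midpoint
  of the two class means (one Ridler–Calvard step). The refinement
  matters: with well-separated classes the between-class variance is
  flat across the whole intensity valley, so the raw Otsu value can hug
  one class and interpolation between tiles may then cross into
  foreground intensities. A tile is deemed bimodal only if the split
  explains ≥ 80% of its intensity variance (a unimodal Gaussian tops out
  near 64%, a uniform ramp at 75%); other tiles inherit the threshold of
  the nearest bimodal tile. Tile thresholds are bilinearly interpolated
  between tile centres, which makes the detected set invariant to linear
  illumination/stain gradients (verified exactly on noise-free fields).
* **Splitting.** With watershed enabled, markers are local maxima of the
  Euclidean distance transform smoothed with a Gaussian
  (`smooth_sigma_px`, default 2) within a square footprint
  (`watershed_footprint_px`, default 21 px ≈ one fibril diameter at
  4 nm/px — scale it with fibril size); regions grow by watershed on the
  inverted distance map. The smoothing suppresses plateau artefacts of
  the distance transform that would otherwise over-split single disks.
* **Filtering.** Per-object morphological opening
  (`opening_radius_px`), then removal of objects outside
  [`min_area_nm2`, `max_area_nm2`] or with solidity (area over
  convex-hull area) below `min_solidity` (default 0.85 —
  "highly irregular" operationalised for near-circular profiles).
  Surviving objects touching the image border are classed `border`;
  they carry valid areas (used by the area fraction) but are excluded
  from diameter and spatial statistics, where clipping would bias the
  result. Per-day parameter overrides are supported in the pipeline
  config because magnification and fibril size change across a series.

## Morphometry

* **Perimeter** uses the 4-direction Crofton estimator. The choice is
  load-bearing for circularity: naive pixel-edge counting overestimates
  a digitised circle's perimeter by up to ~27%, which would push C for
  true circles down to ~0.6. With Crofton, digitised disks measure
  C = 1.00 ± 0.02; the invariant `C ≤ 1.05` is asserted on synthetic
  fields.
* **MFD** is the minimum caliper width, computed exactly on the convex
  hull of the object's pixel-corner points (the minimal width of a convex
  polygon is attained flush against one of its edges). Pixel corners
  rather than centres: a 10-px-wide square must measure 10 px, not 9.
  For a digitised disk the MFD sits ~1% inside the continuous diameter.
* **Centroids** are means of pixel centres, reported in nm with x right,
  y down, origin at the top-left image corner.

## Diameter-distribution modality

* **Mixture fits.** k = 1 is the closed-form MLE. k = 2, 3 use EM with
  one quantile-based initialisation plus 9 random restarts (seeded,
  deterministic), a variance floor of (10⁻³·sample sd)² against
  component collapse, and a monotonicity guard — a decreasing
  log-likelihood aborts the run. Components are reported sorted by mean
  so per-day peak traces are stable. The implementation is independent
  of scikit-learn's `GaussianMixture`, which serves as a cross-check
  oracle in the test suite (means agree within 2 nm, per-point
  log-likelihood within 5×10⁻³ on trimodal samples).
* **KDE reference.** Gaussian kernel, Scott's-rule bandwidth
  (`n^(−1/5)`·sample sd), 512-point grid on [0, 1.1·max]. Both rule and
  grid are fixed so R² values are reproducible.
* **R² definition.** The fitted density is convolved with the KDE's
  kernel (bandwidth² added to each component variance) before residuals
  against the KDE are formed; SS_tot uses the KDE mean. Without this the
  comparison is dominated by smoothing bias: on trimodal samples of
  n = 2000 the Scott bandwidth (~13 nm) is larger than the narrowest
  component sd, and even the *true* density scores R² ≈ 0.36. With both
  curves equally smoothed, a correctly parameterised fit scores ≥ 0.999
  while an under-parameterised one falls to 0.1–0.7, giving the 0.98
  threshold a sharp decision boundary. R² may be negative for very poor
  fits.
* **Modality call.** Per day, the smallest k with R² ≥ threshold
  (default 0.98, exposed as a parameter since the "number of peaks" is
  ultimately a modelling convention); if no k qualifies, the
  best-scoring k is reported. Transition days are the first days the
  call reaches 2 and 3.

## Packing statistics

* **Alpha shape.** Built directly from the Delaunay triangulation:
  triangles with circumradius ≤ 1/α form the alpha complex; the
  perimeter is the set of complex edges used by exactly one kept
  triangle. With α unset, the circumradius threshold is chosen
  automatically (binary search over the sorted circumradii) as the
  smallest value for which the complex is one connected region
  containing every point — the most concave hull that does not
  fragment the field.
* **Pruning.** Every Delaunay edge incident to a perimeter vertex is
  excluded from the statistics (outer vertices acquire artificially long
  edges), and triangles containing any perimeter vertex are likewise
  excluded from the angle sample. On a perfect triangular lattice the
  kept edges all equal the lattice spacing and every kept angle is 60°
  to machine precision.
* **Gaps.** For each kept edge, the distance from each endpoint's
  centroid to its own fibril boundary is measured by intersecting the
  edge ray with the traced outline (sub-pixel iso-contour); the gap is
  the edge length minus both. If an outline is missing or the ray
  misses it (non-star-shaped object), the equivalent-circle radius
  √(A/π) is substituted and the edge flagged. The gap ratio divides by
  the mean MFD of the two fibrils. Negative gaps are possible when
  segmented boundaries overlap and are retained (flagged) rather than
  clipped.
* **RDF.** Mean count of other centres in annuli [r, r + dr) (default
  dr = 10 nm), averaged over reference centres at least `r_max` from the
  window boundary — interior-reference restriction is a simple unbiased
  edge correction. Distances are rounded at 10⁻⁹ nm so exact lattice
  distances do not straddle a bin edge. Counts are also reported
  normalised to g(r) by the ideal-gas expectation ρ·π((r+dr)² − r²); on
  Poisson fields g ≈ 1 with per-bin fluctuations of 0.02–0.07 at
  n = 2000 (pair counts are correlated between reference points, so the
  noise is larger than a naive Poisson estimate).

## Expansion metrics

ϕ sums interior *and* border fibril areas over the usable (non-cell)
area, so it is invariant to the pixel scale. Densities count all
detected fibrils per μm² of usable area. `N(t) = n(t)·m(t)^(2/3)`
normalised at the first observed day; masses are interpolated with a
monotone PCHIP so interpolation never overshoots the tabulated curve,
and the normalisation absorbs any proportionality constant (verified by
round-trip construction). The m^(2/3) exponent assumes constant tissue
mass density (mass ∝ volume ∝ L³, cross-sectional area ∝ L²); that
assumption is inherited, not tested. Time-course fits use nonlinear
least squares with data-driven starts — the plateau from late-time
means, timescales from a coarse grid spanning the observation window,
and (for the double exponential) amplitudes from the conditional linear
least-squares solution at fixed timescales — polishing each start and
keeping the best residual sum of squares. Noiseless model data are
recovered to ≤ 10⁻⁴ in every parameter; constant series degenerate
gracefully to A = mean, M ≈ 0.

## Pipeline and reproducibility

A single YAML config drives synthetic generation → segmentation →
morphometry → mixture fits → spatial statistics → expansion metrics.
All randomness (generation, EM restarts) descends from one root seed via
`numpy.random.SeedSequence` spawning, so reruns are numerically
identical. Stages communicate through files (per-image fibril CSVs,
per-day JSONs, summary CSV), and the run log records versions, seeds and
parameters. Validation problem sizes — 1024² px fields of 200 disks,
21-day series with 2000 diameters per day, 20 recovery replicates —
were chosen as the smallest sizes at which the statistical claims under
test (exact interior recall, ±2% watershed counts, <5 nm mean recovery,
exact transition calls) are comfortably separated from their failure
modes.

## Known limitations

* The watershed footprint must be rescaled when fibril pixel diameters
  differ greatly from ~40 px; a footprint far below the fibril radius
  over-splits, far above merges touching pairs.
* The adaptive threshold assumes locally bimodal tiles; images that are
  foreground-free everywhere yield an empty segmentation with a warning
  rather than an estimate.
* Circularity values depend on the perimeter estimator; comparisons with
  other pipelines should check which estimator they use before comparing
  absolute C values.
* The alpha-shape auto-selection targets connectivity, not visual
  concavity; strongly non-convex fields may need a manual α.
* Gap measurement assumes outlines are star-shaped around their
  centroid; the equivalent-circle fallback is flagged per edge.
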