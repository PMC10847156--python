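# fibrilmorph

Quantitative morphometry of collagen fibrils in transmission-electron-microscopy
(TEM) cross-sections of developing tendon.

In early postnatal tendon, collagen fibrils appear in cross-section as
near-circular dark disks. As the animal grows, the distribution of fibril
diameters changes from a single narrow population to two and then three
populations, the fibril area fraction rises to a plateau, and the packing
stays amorphous with a roughly constant gap between neighbouring fibrils.
`fibrilmorph` provides the full analysis chain needed to measure these
phenomena from segmented images — and a ground-truthed synthetic image
generator so every stage can be validated without microscopy data. It is
aimed at matrix-biology and bio-image-analysis groups quantifying fibril
populations across a developmental time series.

## What it computes

* **Segmentation** — tiled adaptive threshold (per-tile Otsu refined to the
  class-mean midpoint, bilinearly interpolated between tile centres so
  uneven stain or illumination cancels), distance-transform watershed to
  split touching fibrils, morphological smoothing, and size/shape/border
  filtering. Fibrils touching the image border go to a separate *border*
  class: they count towards area fractions but not diameter or spatial
  statistics.
* **Morphometry** — per fibril: area `A`, Crofton perimeter `P`, centroid,
  minimum Feret diameter (MFD; rotating calipers on the pixel-corner convex
  hull) and circularity `C = 4πA/P²` (1 for a perfect circle).
* **Diameter modality** — maximum-likelihood EM fits of 1–3 component
  normal mixtures `Σᵢ wᵢ N(μᵢ, σᵢ²)` to MFD samples, scored against a
  Gaussian KDE by a coefficient of determination; the modality of each day
  is the smallest k whose fit reaches `R² ≥ 0.98`, which pinpoints the days
  a second and a third fibril population emerge.
* **Packing** — Delaunay triangulation of fibril centroids with alpha-shape
  perimeter pruning (removes artificially long outer edges), edge lengths,
  triangle angles (all 60° for a hexagonal array), interfibrillar gaps
  measured by ray-casting along each edge, gap/MFD ratios, and the radial
  distribution function (RDF, `dr = 10 nm` by default) with
  interior-reference edge correction.
* **Matrix expansion** — fibril area fraction `ϕ = A_f/(A_T − A_c)`, number
  density `n(t)` (μm⁻²), and the relative fibril number
  `N(t) ∝ n(t)·m(t)^(2/3)` (normalised to 1 at the first day), where `m(t)`
  is the animal growth curve; saturating `f(t) = A + M(1 − e^(−t/T))` and
  double-exponential `g(t) = A + M₁e^(−t/T₁) + M₂e^(−t/T₂)` time-course
  fits.

## Worked example

`examples/02_diameter_modality.py` samples diameters for 21 synthetic
postnatal days — the generator introduces a second population at day 8 and
a third at day 14 — fits the three mixture models per day and calls each
day's modality (output abridged to the days around the transitions):

```
day  modality  R2(k=1)  R2(k=2)  R2(k=3)
  1         1    0.998    0.998    1.000
  7         1    0.997    0.999    0.999
  8         2    0.175    1.000    1.000
 13         2    0.146    1.000    1.000
 14         3    0.350    0.666    1.000
 21         3    0.418    0.656    1.000

first bimodal day:  8
first trimodal day: 14
```

A fit with too few components cannot reproduce the extra modes of the KDE,
so its R² collapses the day a new population appears; the transition days
are recovered exactly. The other examples cover segmentation against
ground truth (`01`), packing statistics (`03`, hexagonal lattice vs RSA
field), expansion metrics (`04`) and a full config-driven pipeline run
(`05`). A thin CLI wraps the same functions:

```sh
fibrilmorph run-all --config config.yaml
fibrilmorph synth --out field.tif --day 14 --seed 1
```

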