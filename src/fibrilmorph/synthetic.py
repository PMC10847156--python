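"""Ground-truthed synthetic inputs for the fibril-morphometry pipeline.

TEM cross-sections of developing tendon show fields of near-circular dark
fibrils on a lighter background, sometimes partly occluded by tendon
cells. The generator here emulates that geometry — disks with diameters
drawn from a 1-3 component normal mixture, packed by random sequential
adsorption (RSA) with a hard minimum surface-to-surface gap, optional
touching, optional smooth cell-shaped occlusions, additive Gaussian
noise — and records the exact ground truth (centres, diameters, mixture
component, cell polygons) so every downstream stage can be validated.

Also provides the measurement-level generators used as oracles:
mixture-distributed diameter samples, perfect hexagonal (triangular)
lattices of centroids, and a Gompertz animal growth curve standing in for
published mouse mass data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from fibrilmorph.distributions import MixtureParams

__all__ = [
    "SyntheticImageSpec", "GroundTruth", "GrowthCurve",
    "generate_fibril_image", "sample_mfd", "hexagonal_lattice",
    "generate_growth_curve", "timepoint_mixture",
]


class DegenerateGeometryError(RuntimeError):
    """Raised when fewer than a workable number of disks can be placed."""


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic fibril image.

    Attributes
    ----------
    width_px, height_px : image size in pixels.
    nm_per_px : physical pixel scale.
    diameter_mixture : normal mixture the true diameters are drawn from (nm).
    min_gap_nm : minimum surface-to-surface separation between disks.
    target_count : number of disks the packer attempts to place.
    cell_fraction : approximate fraction of the image covered by cell
        occlusions (0 disables cells).
    noise_sd : sd of additive Gaussian pixel noise (grey levels).
    allow_touching : permit contact / slight overlap between disks
        (up to ``max_overlap_frac`` of the smaller radius). Required for
        ``min_gap_nm = 0``.
    seed : RNG seed; generation is deterministic given the spec.
    foreground, background : grey levels of fibrils and background
        (fibrils dark by convention; set ``invert`` for the opposite).
    """

    width_px: int = 1024
    height_px: int = 1024
    nm_per_px: float = 4.0
    diameter_mixture: MixtureParams = field(
        default_factory=lambda: MixtureParams([150.0], [20.0**2], [1.0]))
    min_gap_nm: float = 30.0
    target_count: int = 200
    cell_fraction: float = 0.0
    noise_sd: float = 0.0
    allow_touching: bool = False
    seed: int = 0
    foreground: int = 60
    background: int = 200
    cell_gray: int = 140
    invert: bool = False
    max_overlap_frac: float = 0.1
    attempts_per_disk: int = 400

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        if self.min_gap_nm < 0 or self.noise_sd < 0:
            raise ValueError("min_gap_nm and noise_sd must be non-negative")
        if self.target_count <= 0:
            raise ValueError("target_count must be positive")
        if not (0 <= self.cell_fraction < 1):
            raise ValueError("cell_fraction must lie in [0, 1)")
        if self.min_gap_nm == 0 and not self.allow_touching:
            raise ValueError("min_gap_nm = 0 requires allow_touching=True")


@dataclass
class GroundTruth:
    """Exact geometry behind a synthetic image.

    Coordinates are in nm with x rightwards and y downwards, the origin at
    the top-left image corner (pixel (row, col) spans
    [col, col+1) x [row, row+1) in pixel units).
    """

    centroids_nm: np.ndarray  # (n, 2) x, y
    diameters_nm: np.ndarray  # (n,)
    components: np.ndarray  # (n,) mixture component index of each disk
    cell_polygons: list[Polygon] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.diameters_nm.size

    def interior_mask(self, width_nm: float, height_nm: float) -> np.ndarray:
        """Boolean mask of disks lying fully inside the image (continuous
        geometry; see ``interior_mask_raster`` for the pixel-exact rule)."""
        r = self.diameters_nm / 2
        x, y = self.centroids_nm[:, 0], self.centroids_nm[:, 1]
        return (x - r >= 0) & (y - r >= 0) & (x + r <= width_nm) & (y + r <= height_nm)

    def interior_mask_raster(self, nm_per_px: float, width_px: int,
                             height_px: int) -> np.ndarray:
        """Disks whose rasterisation does not touch the image border.

        A rasterised disk covers a pixel iff the pixel centre lies within
        the disk, so a disk is border-class exactly when some pixel
        centre of the outermost pixel rows/columns is within its radius.
        This matches the segmentation stage's border test pixel for
        pixel, which the continuous test cannot (tangency is ambiguous
        within one pixel).
        """
        s = nm_per_px
        cx, cy = self.centroids_nm[:, 0], self.centroids_nm[:, 1]
        r = self.diameters_nm / 2

        def hits_line(c_perp, c_par, line_perp, n_par):
            # nearest pixel centre on the border line to each disk centre
            grid = np.clip(np.round((c_par - 0.5 * s) / s), 0, n_par - 1)
            near_par = (grid + 0.5) * s
            d = np.hypot(c_perp - line_perp, c_par - near_par)
            return d <= r

        touches = (hits_line(cx, cy, 0.5 * s, height_px)
                   | hits_line(cx, cy, (width_px - 0.5) * s, height_px)
                   | hits_line(cy, cx, 0.5 * s, width_px)
                   | hits_line(cy, cx, (height_px - 0.5) * s, width_px))
        return ~touches

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_nm": self.centroids_nm[:, 0],
            "y_nm": self.centroids_nm[:, 1],
            "diameter_nm": self.diameters_nm,
            "component": self.components,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_mfd(mixture: MixtureParams, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw n i.i.d. diameters (nm) from a weighted normal mixture,
    truncated at zero by redrawing non-positive values."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = rng.choice(mixture.k, size=n, p=mixture.weights)
    out = rng.normal(mixture.means[comp], mixture.sds[comp])
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mixture.means[comp[bad]], mixture.sds[comp[bad]])
        bad = out <= 0
    return out


def _cell_blob(rng: np.random.Generator, centre: np.ndarray, radius_nm: float,
               n_vertices: int = 64, n_harmonics: int = 4, roughness: float = 0.25) -> Polygon:
    """Smooth random blob: circle with a low-order Fourier radial perturbation."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full_like(theta, 1.0)
    for h in range(1, n_harmonics + 1):
        amp = roughness * rng.uniform(0, 1) / h
        r += amp * np.cos(h * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.3, None) * radius_nm
    pts = centre + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Polygon(pts)


def _make_cells(rng: np.random.Generator, spec: SyntheticImageSpec) -> list[Polygon]:
    w_nm = spec.width_px * spec.nm_per_px
    h_nm = spec.height_px * spec.nm_per_px
    target_area = spec.cell_fraction * w_nm * h_nm
    frame = Polygon([(0, 0), (w_nm, 0), (w_nm, h_nm), (0, h_nm)])
    cells: list[Polygon] = []
    covered = 0.0
    for _ in range(64):
        if covered >= target_area:
            break
        radius = 0.5 * math.sqrt(target_area / math.pi) * rng.uniform(0.7, 1.3)
        centre = rng.uniform([0, 0], [w_nm, h_nm])
        blob = _cell_blob(rng, centre, radius).intersection(frame)
        if blob.is_empty or blob.area == 0:
            continue
        cells.append(blob)
        covered += blob.area
    return cells


def _rasterize_polygons(polys: list[Polygon], spec: SyntheticImageSpec) -> np.ndarray:
    """Binary raster of polygons: a pixel is inside if its centre is."""
    mask = np.zeros((spec.height_px, spec.width_px), bool)
    s = spec.nm_per_px
    for poly in polys:
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(minx / s) - 1, 0)
        c1 = min(int(maxx / s) + 2, spec.width_px)
        r0 = max(int(miny / s) - 1, 0)
        r1 = min(int(maxy / s) + 2, spec.height_px)
        if c1 <= c0 or r1 <= r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        xs = (cols + 0.5) * s
        ys = (rows + 0.5) * s
        from shapely import points, contains
        inside = contains(poly, points(np.column_stack([xs.ravel(), ys.ravel()])))
        mask[r0:r1, c0:c1] |= inside.reshape(rows.shape)
    return mask


def _rsa_pack(rng: np.random.Generator, spec: SyntheticImageSpec,
              diameters: np.ndarray, cells: list[Polygon]) -> tuple[np.ndarray, np.ndarray]:
    """Random sequential adsorption of disks with a hard minimum gap.

    Returns (centres_nm (m,2), indices of the diameters placed). Larger
    disks are attempted first — standard for RSA, improves attainable
    packing fractions.
    """
    w_nm = spec.width_px * spec.nm_per_px
    h_nm = spec.height_px * spec.nm_per_px
    order = np.argsort(diameters)[::-1]
    placed_xy: list[np.ndarray] = []
    placed_r: list[float] = []
    placed_idx: list[int] = []
    for idx in order:
        r = diameters[idx] / 2
        ok = False
        for _ in range(spec.attempts_per_disk):
            xy = rng.uniform([0.0, 0.0], [w_nm, h_nm])
            if placed_xy:
                d = np.linalg.norm(np.asarray(placed_xy) - xy, axis=1)
                rr = np.asarray(placed_r)
                if spec.allow_touching:
                    limit = (rr + r) - spec.max_overlap_frac * np.minimum(rr, r)
                else:
                    limit = rr + r + spec.min_gap_nm
                if np.any(d < limit):
                    continue
            if cells:
                p = Point(xy)
                if any(c.distance(p) < r for c in cells):
                    continue
            ok = True
            break
        if ok:
            placed_xy.append(xy)
            placed_r.append(r)
            placed_idx.append(idx)
    if not placed_xy:
        return np.empty((0, 2)), np.empty(0, int)
    return np.asarray(placed_xy), np.asarray(placed_idx)


def _rasterize_disks(centres_nm: np.ndarray, radii_nm: np.ndarray,
                     spec: SyntheticImageSpec) -> np.ndarray:
    mask = np.zeros((spec.height_px, spec.width_px), bool)
    s = spec.nm_per_px
    for (x, y), r in zip(centres_nm, radii_nm):
        c0 = max(int((x - r) / s) - 1, 0)
        c1 = min(int((x + r) / s) + 2, spec.width_px)
        r0 = max(int((y - r) / s) - 1, 0)
        r1 = min(int((y + r) / s) + 2, spec.height_px)
        if c1 <= c0 or r1 <= r0:
            continue
        cols = (np.arange(c0, c1) + 0.5) * s - x
        rows = (np.arange(r0, r1) + 0.5) * s - y
        inside = rows[:, None] ** 2 + cols[None, :] ** 2 <= r * r
        mask[r0:r1, c0:c1] |= inside
    return mask


def generate_fibril_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic TEM-like field of fibril cross-sections.

    Disks with mixture-drawn diameters are packed by RSA honouring
    ``min_gap_nm`` (unless touching is allowed), optionally avoiding
    cell-shaped occlusions, rasterised (a pixel belongs to a disk when its
    centre does), and degraded with additive Gaussian noise. Returns the
    8-bit grayscale image and the exact :class:`GroundTruth`.

    Raises :class:`DegenerateGeometryError` when fewer than
    ``min(3, target_count)`` disks could be placed.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _make_cells(rng, spec) if spec.cell_fraction > 0 else []
    # Draw diameters with component labels kept (sample_mfd hides them).
    comp = rng.choice(spec.diameter_mixture.k, size=spec.target_count,
                      p=spec.diameter_mixture.weights)
    diameters = rng.normal(spec.diameter_mixture.means[comp],
                           spec.diameter_mixture.sds[comp])
    bad = diameters <= 0
    while np.any(bad):
        diameters[bad] = rng.normal(spec.diameter_mixture.means[comp[bad]],
                                    spec.diameter_mixture.sds[comp[bad]])
        bad = diameters <= 0

    centres, placed_idx = _rsa_pack(rng, spec, diameters, cells)
    if placed_idx.size < min(3, spec.target_count):
        raise DegenerateGeometryError(
            f"only {placed_idx.size} of {spec.target_count} disks placeable; "
            "geometry too crowded for the requested gap")
    if placed_idx.size < spec.target_count:
        warnings.warn(f"placed {placed_idx.size}/{spec.target_count} disks "
                      "before exhausting the attempt budget")
    diam = diameters[placed_idx]
    truth = GroundTruth(centroids_nm=centres, diameters_nm=diam,
                        components=comp[placed_idx], cell_polygons=cells)

    img = np.full((spec.height_px, spec.width_px), float(spec.background))
    disk_mask = _rasterize_disks(centres, diam / 2, spec)
    img[disk_mask] = spec.foreground
    if cells:
        cell_mask = _rasterize_polygons(cells, spec)
        img[cell_mask] = spec.cell_gray
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    if spec.invert:
        img = 255.0 - img
    return np.clip(np.round(img), 0, 255).astype(np.uint8), truth


def hexagonal_lattice(spacing_nm: float, rows: int, cols: int) -> np.ndarray:
    """(rows*cols, 2) points of a triangular lattice with nearest-neighbour
    distance exactly ``spacing_nm``; odd rows are offset by half a spacing."""
    if rows < 3 or cols < 3:
        raise ValueError("rows and cols must both be >= 3")
    if spacing_nm <= 0:
        raise ValueError("spacing_nm must be positive")
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = (c + 0.5 * (r % 2)) * spacing_nm
    y = r * spacing_nm * math.sqrt(3) / 2
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


@dataclass(frozen=True)
class GrowthCurve:
    """Animal mass over postnatal time: ordered (day, mass in g) pairs.

    ``mass_at`` interpolates with a monotone piecewise-cubic (PCHIP), so
    interpolated masses never overshoot the tabulated values.
    """

    days: np.ndarray
    mass_g: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, float))
        object.__setattr__(self, "mass_g", np.asarray(self.mass_g, float))
        if self.days.size == 0:
            raise ValueError("growth curve needs at least one day")
        if self.days.size != self.mass_g.size:
            raise ValueError("days and masses must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.mass_g <= 0):
            raise ValueError("masses must be positive")

    def mass_at(self, days) -> np.ndarray:
        from scipy.interpolate import PchipInterpolator
        if self.days.size == 1:
            return np.full_like(np.asarray(days, float), self.mass_g[0])
        return PchipInterpolator(self.days, self.mass_g)(np.asarray(days, float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "mass_g": self.mass_g})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GrowthCurve":
        df = pd.read_csv(path)
        return cls(df["day"].to_numpy(), df["mass_g"].to_numpy())


def generate_growth_curve(mass_at_birth_g: float = 1.5, adult_mass_g: float = 30.0,
                          rate: float = 0.08, days=None) -> GrowthCurve:
    """Gompertz growth curve m(t) = M exp(log(m0/M) exp(-rate t)).

    A smooth, saturating stand-in for a laboratory-mouse mass curve:
    m(0) = mass at birth, m(inf) = adult mass, strictly increasing.
    Defaults approximate a C57BL/6 mouse (birth ~1.5 g, adult ~30 g,
    most growth within the first ~8 weeks).
    """
    if not (0 < mass_at_birth_g < adult_mass_g):
        raise ValueError("require 0 < mass_at_birth_g < adult_mass_g")
    if days is None:
        days = np.arange(0, 57, dtype=float)
    days = np.asarray(days, float)
    if days.size == 0:
        raise ValueError("day list must be non-empty")
    log_ratio = math.log(mass_at_birth_g / adult_mass_g)
    mass = adult_mass_g * np.exp(log_ratio * np.exp(-rate * days))
    return GrowthCurve(days=days, mass_g=mass)


def timepoint_mixture(day: float) -> MixtureParams:
    """Diameter mixture emulating the developmental time series.

    Unimodal before day 8 (a single narrow population that grows slowly),
    bimodal from day 8 (a second, larger population appears), trimodal
    from day 14 (a third population; components at 60/120/200 nm with sds
    8/12/20 nm). Used by the pipeline's synthetic mode and by the
    modality-transition validation.
    """
    if day < 8:
        mu = 50.0 + 2.0 * day
        return MixtureParams([mu], [8.0**2], [1.0])
    if day < 14:
        return MixtureParams([70.0, 140.0], [8.0**2, 12.0**2], [0.5, 0.5])
    return MixtureParams([60.0, 120.0, 200.0], [8.0**2, 12.0**2, 20.0**2],
                         [1 / 3, 1 / 3, 1 / 3])
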