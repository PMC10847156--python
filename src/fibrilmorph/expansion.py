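"""Matrix-expansion metrics across a developmental time series.

Three per-day quantities track how the tendon matrix grows:

* fibril area fraction, phi = Af / (AT - Ac), where Af is the total
  fibril area (interior and border fibrils alike), AT the whole image
  area and Ac the masked cell area;
* fibril number density n(t) in fibrils per square micron of usable
  (non-cell) area;
* relative fibril number N(t) proportional to n(t) * m(t)^(2/3), where
  m(t) is the animal mass: assuming constant tissue mass density, mass is
  proportional to volume ~ L^3 while a cross-section scales as L^2, so
  m^(2/3) proxies the lateral expansion of the tissue cross-section.
  The proportionality constant is unknown, so N is normalised to 1 at
  the first observed day.

Time courses are summarised with two standard saturating models fitted by
nonlinear least squares: f(t) = A + M (1 - exp(-t/T)) and
g(t) = A + M1 exp(-t/T1) + M2 exp(-t/T2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from fibrilmorph.morphometry import FibrilRecord
from fibrilmorph.synthetic import GrowthCurve

__all__ = ["AreaFractionResult", "CurveFitResult", "area_fraction",
           "number_density", "relative_fibril_number", "fit_timecourse",
           "summarize_timeseries"]


@dataclass
class AreaFractionResult:
    """Fibril area fraction of one image (all areas in nm^2)."""

    Af: float
    AT: float
    Ac: float

    @property
    def phi(self) -> float:
        return self.Af / (self.AT - self.Ac)


def area_fraction(records: list[FibrilRecord], image_area_nm2: float,
                  cell_area_nm2: float = 0.0) -> AreaFractionResult:
    """phi = Af / (AT - Ac). Border-class fibrils count towards Af."""
    if image_area_nm2 <= cell_area_nm2:
        raise ValueError("whole-image area must exceed the masked cell area")
    af = float(sum(r.area_nm2 for r in records))
    return AreaFractionResult(Af=af, AT=float(image_area_nm2), Ac=float(cell_area_nm2))


def number_density(records: list[FibrilRecord], image_area_nm2: float,
                   cell_area_nm2: float = 0.0) -> float:
    """Fibrils per square micron of usable (non-cell) area; all detected
    fibrils count, border-class included."""
    if image_area_nm2 <= cell_area_nm2:
        raise ValueError("whole-image area must exceed the masked cell area")
    usable_um2 = (image_area_nm2 - cell_area_nm2) / 1e6
    return len(records) / usable_um2


def relative_fibril_number(days, density_um2, growth_curve: GrowthCurve) -> np.ndarray:
    """N(t) = n(t) m(t)^(2/3), normalised so the first day equals 1.

    Masses are interpolated monotonically from the growth curve onto the
    requested days; the first day must lie within the curve's support.
    """
    days = np.asarray(days, float)
    n = np.asarray(density_um2, float)
    if days.size != n.size or days.size == 0:
        raise ValueError("days and densities must be equal-length and non-empty")
    if days[0] < growth_curve.days[0] or days[0] > growth_curve.days[-1]:
        raise ValueError(f"no mass available for the first day ({days[0]})")
    mass = growth_curve.mass_at(days)
    raw = n * mass ** (2.0 / 3.0)
    if raw[0] == 0:
        raise ValueError("density at the first day is zero; cannot normalise")
    return raw / raw[0]


@dataclass
class CurveFitResult:
    """Nonlinear least-squares fit of a saturating time-course model."""

    model: str  # "single_saturating" or "double_exponential"
    params: dict[str, float]
    rss: float
    stderr: dict[str, float]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        p = self.params
        if self.model == "single_saturating":
            return p["A"] + p["M"] * (1.0 - np.exp(-t / p["T"]))
        return (p["A"] + p["M1"] * np.exp(-t / p["T1"])
                + p["M2"] * np.exp(-t / p["T2"]))


def _f_single(t, A, M, T):
    return A + M * (1.0 - np.exp(-t / T))


def _g_double(t, A, M1, T1, M2, T2):
    return A + M1 * np.exp(-t / T1) + M2 * np.exp(-t / T2)


def _amplitudes_given_T(t, y, T1, T2):
    """g(t) is linear in (A, M1, M2) once the timescales are fixed."""
    X = np.column_stack([np.ones_like(t), np.exp(-t / T1), np.exp(-t / T2)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_timecourse(t, y, model: str = "single_saturating") -> CurveFitResult:
    """Fit a saturating single-exponential or a double-exponential model.

    Initial values come from data heuristics (plateau from the late-time
    mean, timescales from a coarse grid, amplitudes from the conditional
    linear least-squares solution); several starts are polished with
    ``scipy.optimize.curve_fit`` and the best residual sum of squares is
    kept. Deterministic given the data. Raises ``RuntimeError`` when no
    start converges.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n_par = 3 if model == "single_saturating" else 5
    if t.size != y.size or t.size < n_par + 2:
        raise ValueError(f"need at least {n_par + 2} points for {model}")
    span = float(t.max() - t.min()) or 1.0
    t_grid = span * np.array([0.05, 0.15, 0.35, 0.7, 1.5])

    best = None
    if model == "single_saturating":
        names = ("A", "M", "T")
        A0 = float(y[np.argmin(t)])
        M0 = float(np.mean(y[t >= np.quantile(t, 0.7)]) - A0)
        for T0 in t_grid:
            try:
                popt, pcov = curve_fit(_f_single, t, y, p0=[A0, M0, T0],
                                       bounds=([-np.inf, -np.inf, 1e-12],
                                               [np.inf, np.inf, np.inf]),
                                       maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((y - _f_single(t, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss, pcov)
    elif model == "double_exponential":
        names = ("A", "M1", "T1", "M2", "T2")
        for i, T1 in enumerate(t_grid):
            for T2 in t_grid[i + 1:]:
                (A0, M10, M20), _ = _amplitudes_given_T(t, y, T1, T2)
                try:
                    popt, pcov = curve_fit(
                        _g_double, t, y, p0=[A0, M10, T1, M20, T2],
                        bounds=([-np.inf, -np.inf, 1e-12, -np.inf, 1e-12],
                                [np.inf] * 5),
                        maxfev=40000)
                except RuntimeError:
                    continue
                rss = float(np.sum((y - _g_double(t, *popt)) ** 2))
                if best is None or rss < best[1]:
                    best = (popt, rss, pcov)
    else:
        raise ValueError(f"unknown model {model!r}")

    if best is None:
        raise RuntimeError(f"{model} fit failed to converge from any start")
    popt, rss, pcov = best
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    params = dict(zip(names, map(float, popt)))
    if model == "double_exponential" and params["T1"] > params["T2"]:
        # canonical ordering: fast component first
        params = {"A": params["A"], "M1": params["M2"], "T1": params["T2"],
                  "M2": params["M1"], "T2": params["T1"]}
        se = se[[0, 3, 4, 1, 2]]
    return CurveFitResult(model=model, params=params, rss=rss,
                          stderr=dict(zip(names, map(float, se))))


def summarize_timeseries(per_image: pd.DataFrame,
                         growth_curve: GrowthCurve | None = None) -> pd.DataFrame:
    """Per-day aggregates from a per-image table.

    ``per_image`` needs columns day, n_fibrils, fibril_area_nm2,
    image_area_nm2, cell_area_nm2, phi. Counts and areas are pooled
    across all images of a day (density and phi from the pooled totals);
    per-image phi/density standard deviations are reported alongside.
    With a growth curve, the relative fibril number N(t) is appended.
    """
    rows = []
    for day, grp in per_image.groupby("day"):
        usable = (grp.image_area_nm2 - grp.cell_area_nm2).sum()
        phi_img = grp.phi
        dens_img = grp.n_fibrils / ((grp.image_area_nm2 - grp.cell_area_nm2) / 1e6)
        rows.append({
            "day": day,
            "n_images": len(grp),
            "n_fibrils": int(grp.n_fibrils.sum()),
            "phi": grp.fibril_area_nm2.sum() / usable,
            "phi_sd": float(phi_img.std(ddof=1)) if len(grp) > 1 else 0.0,
            "density_um2": grp.n_fibrils.sum() / (usable / 1e6),
            "density_sd": float(dens_img.std(ddof=1)) if len(grp) > 1 else 0.0,
        })
    out = pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
    if growth_curve is not None:
        out["relative_fibril_number"] = relative_fibril_number(
            out.day.to_numpy(), out.density_um2.to_numpy(), growth_curve)
    return out
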