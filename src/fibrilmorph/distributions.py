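"""Modality analysis of fibril-diameter distributions.

During early postnatal development the distribution of tendon-fibril
minimum Feret diameters (MFDs) changes from unimodal to bimodal and then
trimodal. This module fits 1-, 2- and 3-component normal mixtures to MFD
samples by maximum-likelihood EM, scores each fit against a Gaussian
kernel density estimate (KDE) via a coefficient of determination, and
calls the modality of each day in a time series as the smallest number of
components whose fit reaches an R-squared threshold (0.98 by default).

R-squared is computed between the *kernel-smoothed* fitted density (each
fitted component's variance inflated by the squared KDE bandwidth, i.e.
the fitted density convolved with the KDE's Gaussian kernel) and the KDE
itself. Both curves then carry the same smoothing bias, so a fit with the
correct number of components scores near 1 regardless of bandwidth, while
an under-parameterised fit cannot reproduce the extra modes and scores
far lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "MixtureParams", "MixtureFit", "KDEProfile", "ModalitySeries",
    "fit_mixture", "kde", "r_squared", "modality_transition", "mfd_range",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of a k-component (k = 1..3) normal mixture of diameters.

    Means are in nm, variances in nm^2, weights dimensionless summing to 1.
    Zero variances are permitted (used by the synthetic generator for
    degenerate draws); fitted parameters always have strictly positive
    variances.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.atleast_1d(np.asarray(self.means, float)))
        object.__setattr__(self, "variances", np.atleast_1d(np.asarray(self.variances, float)))
        object.__setattr__(self, "weights", np.atleast_1d(np.asarray(self.weights, float)))
        k = self.means.size
        if not (1 <= k <= 3):
            raise ValueError(f"mixture must have 1-3 components, got {k}")
        if self.variances.size != k or self.weights.size != k:
            raise ValueError("means, variances and weights must have equal length")
        if np.any(self.variances < 0):
            raise ValueError("variances must be non-negative")
        if np.any(self.weights <= 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")

    @property
    def k(self) -> int:
        return self.means.size

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(self.variances)

    def mean(self) -> float:
        """Mixture mean, sum_i w_i mu_i."""
        return float(np.sum(self.weights * self.means))

    def pdf(self, x: np.ndarray, extra_var: float = 0.0) -> np.ndarray:
        """Mixture density; `extra_var` adds variance to every component
        (convolution with a Gaussian kernel of that variance)."""
        x = np.asarray(x, float)
        v = self.variances + extra_var
        if np.any(v <= 0):
            raise ValueError("pdf undefined for zero-variance component")
        s = np.sqrt(v)
        z = (x[..., None] - self.means) / s
        return np.sum(self.weights * np.exp(-0.5 * z * z) / (s * _SQRT_2PI), axis=-1)

    def sorted_by_mean(self) -> "MixtureParams":
        order = np.argsort(self.means)
        return MixtureParams(self.means[order], self.variances[order], self.weights[order])


@dataclass
class KDEProfile:
    """Gaussian KDE of an MFD sample on a uniform grid.

    Bandwidth follows Scott's rule (n**(-1/5) times the sample sd); the
    grid spans [0, 1.1 * max(sample)] with a fixed point count so that
    R-squared values are reproducible.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class MixtureFit:
    """A fitted normal mixture with its goodness-of-fit metadata."""

    params: MixtureParams
    log_likelihood: float
    converged: bool
    n_iter: int
    peak_locations: np.ndarray = field(default_factory=lambda: np.empty(0))
    r2_vs_kde: float | None = None

    @property
    def k(self) -> int:
        return self.params.k


def _log_likelihood(x: np.ndarray, means, variances, weights) -> float:
    s = np.sqrt(variances)
    z = (x[:, None] - means) / s
    dens = weights * np.exp(-0.5 * z * z) / (s * _SQRT_2PI)
    return float(np.sum(np.log(np.maximum(dens.sum(axis=1), 1e-300))))


def _em(x: np.ndarray, means, variances, weights, var_floor: float,
        max_iter: int, tol: float):
    """Vectorised 1-D EM. Returns (means, variances, weights, ll, n_iter,
    converged). The log-likelihood is monotone non-decreasing across
    iterations; a decrease beyond round-off aborts loudly."""
    ll_old = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        s = np.sqrt(variances)
        z = (x[:, None] - means) / s
        dens = weights * np.exp(-0.5 * z * z) / (s * _SQRT_2PI)
        total = np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)
        resp = dens / total
        ll = float(np.sum(np.log(total)))
        if ll < ll_old - 1e-8 * max(1.0, abs(ll_old)):
            raise RuntimeError(f"EM log-likelihood decreased: {ll_old} -> {ll}")
        if ll - ll_old < tol * max(1.0, abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
    return means, variances, weights, ll_old, n_iter, converged


def _initial_params(x: np.ndarray, k: int, restart: int, rng: np.random.Generator):
    """Quantile-based means for the first restart, random data picks after."""
    if restart == 0:
        q = (2 * np.arange(k) + 1) / (2 * k)
        means = np.quantile(x, q)
    else:
        means = rng.choice(x, size=k, replace=False)
    v0 = max(x.var() / k**2, 1e-6)
    return means.astype(float), np.full(k, v0), np.full(k, 1.0 / k)


def fit_mixture(mfds, k: int, seed: int = 0, n_restarts: int = 10,
                max_iter: int = 500, tol: float = 1e-10) -> MixtureFit:
    """Maximum-likelihood fit of a k-component normal mixture to an MFD
    sample.

    k = 1 is solved in closed form (sample mean, population variance).
    k = 2 or 3 uses EM with one quantile-based and `n_restarts - 1`
    random initialisations; the restart with the best log-likelihood is
    kept. Deterministic for a fixed seed. Components are ordered by
    ascending mean so peak traces are stable across a time series.

    Raises ``ValueError`` for samples smaller than ``10 * k`` and
    ``RuntimeError`` when every restart collapses.
    """
    x = np.asarray(mfds, float).ravel()
    if not (1 <= k <= 3):
        raise ValueError("k must be 1, 2 or 3")
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} observations for k={k}, got {x.size}")

    if k == 1:
        mu = x.mean()
        var = max(x.var(), 1e-12)
        params = MixtureParams([mu], [var], [1.0])
        ll = _log_likelihood(x, params.means, params.variances, params.weights)
        fit = MixtureFit(params, ll, converged=True, n_iter=0)
        fit.peak_locations = _pdf_peaks(params, x)
        return fit

    rng = np.random.default_rng(seed)
    var_floor = max((1e-3 * x.std()) ** 2, 1e-12)
    best = None
    for restart in range(n_restarts):
        means, variances, weights = _initial_params(x, k, restart, rng)
        try:
            m, v, w, ll, n_iter, conv = _em(x, means, variances, weights,
                                            var_floor, max_iter, tol)
        except (FloatingPointError, RuntimeError):
            continue
        if np.any(v <= var_floor * (1 + 1e-9)) and not conv:
            continue  # collapsed onto a point mass without converging
        if best is None or ll > best[3]:
            best = (m, v, w, ll, n_iter, conv)
    if best is None:
        raise RuntimeError(f"all {n_restarts} EM restarts collapsed for k={k}")
    m, v, w, ll, n_iter, conv = best
    w = w / w.sum()
    params = MixtureParams(m, v, w).sorted_by_mean()
    fit = MixtureFit(params, ll, converged=conv, n_iter=n_iter)
    fit.peak_locations = _pdf_peaks(params, x)
    return fit


def _pdf_peaks(params: MixtureParams, x: np.ndarray, n_grid: int = 2048) -> np.ndarray:
    """Local maxima of the mixture PDF (at most k)."""
    lo = min(x.min(), params.means.min()) - 4 * params.sds.max()
    hi = max(x.max(), params.means.max()) + 4 * params.sds.max()
    g = np.linspace(lo, hi, n_grid)
    p = params.pdf(g)
    interior = (p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:])
    return g[1:-1][interior]


def kde(mfds, n_grid: int = 512, bw_method: str | float = "scott") -> KDEProfile:
    """Gaussian-kernel density estimate of an MFD sample.

    The grid spans [0, 1.1 * max(sample)] with ``n_grid`` uniform points;
    the returned bandwidth is the kernel standard deviation in nm.
    """
    x = np.asarray(mfds, float).ravel()
    if x.size < 5:
        raise ValueError(f"KDE needs at least 5 observations, got {x.size}")
    est = gaussian_kde(x, bw_method=bw_method)
    bandwidth = float(est.factor * x.std(ddof=1))
    grid = np.linspace(0.0, float(x.max()) * 1.1, n_grid)
    density = est(grid)
    return KDEProfile(grid=grid, density=density, bandwidth=bandwidth)


def r_squared(fit: MixtureFit, ref: KDEProfile) -> float:
    """Coefficient of determination of a mixture fit against a KDE.

    The fitted density is first convolved with the KDE's Gaussian kernel
    (variance bandwidth^2 added to each component) so both curves share
    the same smoothing; residuals are taken on the KDE grid and SS_tot
    uses the KDE mean. May be negative for very poor fits. The value is
    stored on ``fit.r2_vs_kde`` as a side effect.
    """
    pdf = fit.params.pdf(ref.grid, extra_var=ref.bandwidth**2)
    ss_res = float(np.sum((pdf - ref.density) ** 2))
    ss_tot = float(np.sum((ref.density - ref.density.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant KDE: R-squared undefined (SS_tot = 0)")
    r2 = 1.0 - ss_res / ss_tot
    fit.r2_vs_kde = r2
    return r2


@dataclass
class ModalitySeries:
    """Per-day modality calls and peak-location traces for a time series."""

    days: np.ndarray
    modality: np.ndarray  # smallest k with R^2 >= threshold, per day
    r2: dict[int, np.ndarray]  # k -> per-day R^2
    bimodal_peaks: list[np.ndarray]  # per-day peak locations of the k=2 fit
    trimodal_peaks: list[np.ndarray]  # per-day peak locations of the k=3 fit
    threshold: float

    def transition_day(self, modality: int) -> float | None:
        """First day at which the called modality reaches `modality`."""
        hit = np.nonzero(self.modality >= modality)[0]
        return float(self.days[hit[0]]) if hit.size else None


def modality_transition(fits_by_day: dict[float, dict[int, MixtureFit]],
                        kde_by_day: dict[float, KDEProfile],
                        r2_threshold: float = 0.98) -> ModalitySeries:
    """Call per-day modality as the smallest k whose fit reaches the
    R-squared threshold against that day's KDE.

    `fits_by_day` maps day -> {k: MixtureFit} and must contain k = 1, 2, 3
    for every day. If no k reaches the threshold the day is called with
    the best-scoring k. Also returns the bimodal and trimodal
    peak-location traces used to visualise when populations separate.
    """
    days = np.array(sorted(fits_by_day))
    if days.size < 2:
        raise ValueError("need fits for at least 2 days")
    ks = (1, 2, 3)
    r2 = {k: np.empty(days.size) for k in ks}
    modality = np.empty(days.size, dtype=int)
    bi_peaks, tri_peaks = [], []
    for i, day in enumerate(days):
        fits = fits_by_day[day]
        missing = [k for k in ks if k not in fits]
        if missing:
            raise ValueError(f"day {day}: missing fits for k={missing}")
        for k in ks:
            r2[k][i] = (fits[k].r2_vs_kde if fits[k].r2_vs_kde is not None
                        else r_squared(fits[k], kde_by_day[day]))
        passing = [k for k in ks if r2[k][i] >= r2_threshold]
        modality[i] = min(passing) if passing else max(ks, key=lambda k: r2[k][i])
        bi_peaks.append(fits[2].peak_locations)
        tri_peaks.append(fits[3].peak_locations)
    return ModalitySeries(days=days, modality=modality, r2=r2,
                          bimodal_peaks=bi_peaks, trimodal_peaks=tri_peaks,
                          threshold=r2_threshold)


def mfd_range(mfds) -> tuple[float, float, float]:
    """(min, max, max - min) of an MFD sample, in nm."""
    x = np.asarray(mfds, float).ravel()
    if x.size == 0:
        raise ValueError("empty MFD sample")
    lo, hi = float(x.min()), float(x.max())
    return lo, hi, hi - lo
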