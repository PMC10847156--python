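"""End-to-end orchestration from a declarative YAML config.

A run executes synthetic generation (optional) -> segmentation ->
morphometry -> distribution fitting -> spatial statistics -> expansion
metrics, writing a results tree of CSV/JSON files plus a machine-readable
run log. All randomness flows from one root seed split per stage and
image, so a rerun with the same config is byte-identical. Segmentation
parameters may be overridden per postnatal day, mirroring how analysis
settings are adapted across a developmental time series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

import fibrilmorph
from fibrilmorph import distributions as dist
from fibrilmorph import expansion as expn
from fibrilmorph import morphometry as morph
from fibrilmorph import spatial as spat
from fibrilmorph.distributions import MixtureParams
from fibrilmorph.segmentation import SegmentationParams, segment
from fibrilmorph.synthetic import (GrowthCurve, SyntheticImageSpec,
                                   generate_fibril_image,
                                   generate_growth_curve, timepoint_mixture)

__all__ = ["RunConfig", "load_config", "validate_config", "run"]


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_config`` for the YAML form)."""

    output_dir: str = "results"
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    per_day_overrides: dict[float, dict] = field(default_factory=dict)
    r2_threshold: float = 0.98
    n_restarts: int = 10
    alpha: float | None = None
    rdf_dr_nm: float = 10.0
    rdf_r_max_nm: float = 600.0
    growth_curve_path: str | None = None
    manifest_path: str | None = None
    synthetic: dict | None = None

    def seg_params_for(self, day: float) -> SegmentationParams:
        override = self.per_day_overrides.get(day, {})
        return replace(self.segmentation, **override) if override else self.segmentation


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seg = SegmentationParams(**raw.pop("segmentation", {}))
    overrides = {float(k): v for k, v in raw.pop("per_day_overrides", {}).items()}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(segmentation=seg, per_day_overrides=overrides, **raw)


def validate_config(config: RunConfig) -> list[str]:
    """All violations found in a config, without running anything."""
    problems: list[str] = []
    try:
        SegmentationParams(**asdict(config.segmentation))
    except ValueError as err:
        problems.append(f"segmentation: {err}")
    for day, override in config.per_day_overrides.items():
        try:
            replace(config.segmentation, **override)
        except (ValueError, TypeError) as err:
            problems.append(f"per-day override for day {day}: {err}")
    if config.alpha is not None and config.alpha <= 0:
        problems.append("alpha must be positive")
    if config.rdf_dr_nm <= 0:
        problems.append("rdf_dr_nm must be positive")
    if config.rdf_r_max_nm <= config.rdf_dr_nm:
        problems.append("rdf_r_max_nm must exceed rdf_dr_nm")
    if not (0 < config.r2_threshold <= 1) and config.r2_threshold != -np.inf:
        problems.append("r2_threshold should lie in (0, 1]")
    for label, path in (("growth_curve_path", config.growth_curve_path),
                        ("manifest_path", config.manifest_path)):
        if path is not None and not Path(path).exists():
            problems.append(f"{label}: no such file {path}")
    if config.manifest_path is None and config.synthetic is None:
        problems.append("config needs either a manifest or a synthetic block")
    if config.synthetic is not None:
        if not config.synthetic.get("days"):
            problems.append("synthetic block needs a non-empty 'days' list")
    if config.manifest_path is not None:
        try:
            manifest = pd.read_csv(config.manifest_path)
            for col in ("image", "day", "nm_per_px"):
                if col not in manifest.columns:
                    problems.append(f"manifest lacks required column '{col}'")
            if "image" in manifest.columns:
                for img in manifest.image:
                    if not Path(img).exists():
                        problems.append(f"manifest references missing image {img}")
        except Exception as err:  # unparseable manifest
            problems.append(f"manifest unreadable: {err}")
    return problems


def _generate_synthetic(config: RunConfig, outdir: Path,
                        rng_seeds: list[int]) -> pd.DataFrame:
    synth = config.synthetic
    days = synth["days"]
    per_day = int(synth.get("images_per_day", 1))
    base = dict(synth.get("image", {}))
    rows = []
    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    seed_iter = iter(rng_seeds)
    for day in days:
        for i in range(per_day):
            spec_kwargs = dict(base)
            if "diameter_mixture" in spec_kwargs:
                m = spec_kwargs["diameter_mixture"]
                spec_kwargs["diameter_mixture"] = MixtureParams(
                    m["means"], m["variances"], m["weights"])
            else:
                spec_kwargs["diameter_mixture"] = timepoint_mixture(day)
            spec = SyntheticImageSpec(seed=next(seed_iter), **spec_kwargs)
            image, truth = generate_fibril_image(spec)
            stem = f"day{day:g}_img{i}"
            tifffile.imwrite(img_dir / f"{stem}.tif", image)
            truth.to_csv(img_dir / f"{stem}_truth.csv")
            rows.append({"image": str(img_dir / f"{stem}.tif"), "day": day,
                         "nm_per_px": spec.nm_per_px, "mask": ""})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def run(config: RunConfig, seed: int | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    The results tree holds per-image fibril CSVs, per-day mixture-fit
    JSONs, spatial-statistics CSVs, a per-day summary CSV with expansion
    metrics and time-course fits, and ``run_log.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4096)]

    if config.synthetic is not None:
        manifest = _generate_synthetic(config, outdir, child_seeds[:2048])
    else:
        manifest = pd.read_csv(config.manifest_path)
        for img in manifest.image:
            if not Path(img).exists():
                raise FileNotFoundError(f"manifest references missing image {img}")

    fibril_dir = outdir / "fibrils"
    fibril_dir.mkdir(exist_ok=True)
    per_image_rows = []
    records_by_day: dict[float, list] = {}
    first_image_records: dict[float, list] = {}
    for _, row in manifest.iterrows():
        image = tifffile.imread(row.image)
        nm_per_px = float(row.nm_per_px)
        mask = None
        if "mask" in manifest.columns and isinstance(row["mask"], str) and row["mask"]:
            import imageio.v3 as iio
            mask = iio.imread(row["mask"]).astype(bool)
        params = config.seg_params_for(float(row.day))
        try:
            labels, ac = segment(image, params, nm_per_px, mask)
        except Exception as err:
            raise RuntimeError(f"segmentation failed on {row.image}: {err}") from err
        records = morph.measure(labels, nm_per_px)
        stem = Path(row.image).stem
        morph.records_to_dataframe(records).to_csv(fibril_dir / f"{stem}.csv", index=False)
        at = image.shape[0] * image.shape[1] * nm_per_px**2
        afr = expn.area_fraction(records, at, ac)
        per_image_rows.append({
            "image": row.image, "day": float(row.day),
            "n_fibrils": len(records), "fibril_area_nm2": afr.Af,
            "image_area_nm2": at, "cell_area_nm2": ac, "phi": afr.phi,
        })
        day = float(row.day)
        records_by_day.setdefault(day, []).extend(
            r for r in records if not r.border)
        if day not in first_image_records:
            first_image_records[day] = [r for r in records if not r.border]

    per_image = pd.DataFrame(per_image_rows)
    per_image.to_csv(outdir / "per_image.csv", index=False)

    # per-day mixture fits and modality
    fits_by_day: dict[float, dict[int, dist.MixtureFit]] = {}
    kde_by_day: dict[float, dist.KDEProfile] = {}
    day_json = {}
    for di, (day, recs) in enumerate(sorted(records_by_day.items())):
        mfds = np.array([r.mfd_nm for r in recs])
        if mfds.size < 30:
            warnings.warn(f"day {day}: too few fibrils ({mfds.size}) for mixture fits")
            continue
        profile = dist.kde(mfds)
        kde_by_day[day] = profile
        fits = {}
        for k in (1, 2, 3):
            fit = dist.fit_mixture(mfds, k, seed=child_seeds[2048 + 3 * di + k - 1],
                                   n_restarts=config.n_restarts)
            dist.r_squared(fit, profile)
            fits[k] = fit
        fits_by_day[day] = fits
        lo, hi, rng_ = dist.mfd_range(mfds)
        day_json[day] = {
            "n_fibrils": int(mfds.size),
            "mfd_min_nm": lo, "mfd_max_nm": hi, "mfd_range_nm": rng_,
            "fits": {k: {
                "means_nm": f.params.means.tolist(),
                "variances_nm2": f.params.variances.tolist(),
                "weights": f.params.weights.tolist(),
                "log_likelihood": f.log_likelihood,
                "r2_vs_kde": f.r2_vs_kde,
                "peaks_nm": f.peak_locations.tolist(),
                "converged": bool(f.converged),
            } for k, f in fits.items()},
        }
    modality = None
    if len(fits_by_day) >= 2:
        modality = dist.modality_transition(fits_by_day, kde_by_day,
                                            config.r2_threshold)
        for i, day in enumerate(modality.days):
            day_json[float(day)]["modality"] = int(modality.modality[i])
    with open(outdir / "distribution_fits.json", "w") as fh:
        json.dump({str(d): v for d, v in day_json.items()}, fh, indent=1)

    # spatial statistics on the first image of each day
    spatial_rows = []
    rdf_rows = []
    for day, recs in sorted(first_image_records.items()):
        if len(recs) < 10:
            continue
        pts = np.array([r.centroid_nm for r in recs])
        try:
            tri = spat.triangulate_and_prune(pts, config.alpha)
        except ValueError as err:
            warnings.warn(f"day {day}: spatial statistics skipped ({err})")
            continue
        if tri.edges.size:
            spat.interfibrillar_gaps(tri, recs)
            for e, (i, j) in enumerate(tri.edges):
                spatial_rows.append({
                    "day": day, "v1": int(i), "v2": int(j),
                    "edge_length_nm": tri.edge_lengths[e],
                    "gap_nm": tri.gaps_nm[e], "gap_ratio": tri.gap_ratios[e],
                })
        try:
            profile = spat.rdf(pts, config.rdf_dr_nm, config.rdf_r_max_nm)
            for r, c, g in zip(profile.r, profile.counts, profile.g):
                rdf_rows.append({"day": day, "r_nm": r, "count": c, "g": g})
        except ValueError as err:
            warnings.warn(f"day {day}: RDF skipped ({err})")
    pd.DataFrame(spatial_rows).to_csv(outdir / "edges.csv", index=False)
    pd.DataFrame(rdf_rows).to_csv(outdir / "rdf.csv", index=False)

    # expansion metrics and time-course fits
    growth = (GrowthCurve.from_csv(config.growth_curve_path)
              if config.growth_curve_path else generate_growth_curve())
    summary = expn.summarize_timeseries(per_image, growth)
    summary.to_csv(outdir / "summary.csv", index=False)
    fit_json = {}
    if len(summary) >= 5:
        for col in ("phi", "density_um2"):
            fit = expn.fit_timecourse(summary.day, summary[col], "single_saturating")
            fit_json[col] = {"model": fit.model, "params": fit.params, "rss": fit.rss}
    if len(summary) >= 7:
        fit = expn.fit_timecourse(summary.day, summary.relative_fibril_number,
                                  "double_exponential")
        fit_json["relative_fibril_number"] = {
            "model": fit.model, "params": fit.params, "rss": fit.rss}
    with open(outdir / "timecourse_fits.json", "w") as fh:
        json.dump(fit_json, fh, indent=1)

    log = {
        "fibrilmorph_version": fibrilmorph.__version__,
        "root_seed": root_seed,
        "n_images": len(manifest),
        "days": sorted(records_by_day),
        "segmentation": asdict(config.segmentation),
        "per_day_overrides": config.per_day_overrides,
        "r2_threshold": config.r2_threshold,
        "modality_transitions": None if modality is None else {
            "bimodal_day": modality.transition_day(2),
            "trimodal_day": modality.transition_day(3)},
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return outdir
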