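"""End-to-end pipeline: simulate -> features -> fit -> spatial -> map -> land use.

A :class:`PipelineConfig` (constructible from a YAML file; unknown keys
are rejected) drives the stages in order and a JSON manifest records
package version, seeds, row counts, skipped-day logs and SHA-256
checksums of every output, so reruns with the same configuration are
verifiably identical for the deterministic stages.

Dates are ISO-8601 throughout; the 2000-to-2000-hours measurement day is
labelled by its end date.  Missing values are written as empty CSV
fields, never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, gridio, landuse, mapping, met, spatial, synth, temporal

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""
    out_dir: str = "endoair_out"
    simulate: bool = True
    n_days: int = 240
    start_date: str = "2002-04-01"
    seed: int = 0
    # input paths (required when simulate is disabled)
    met_path: str | None = None
    conc_path: str | None = None
    sites_path: str | None = None
    landcover_path: str | None = None
    cafos_path: str | None = None
    # analysis parameters
    central_site: str = "CENTRAL"
    analyte: str = "endotoxin"
    season: str = "dry"
    outlier_threshold: float = 20.0
    cv_folds: int = 5
    grid_spacing: float = 0.25
    map_width: float = 50.0
    map_height: float = 60.0
    idw_power: float = 2.0
    min_sites_map: int = 6
    min_sites_cv: int = 4
    buffer_radii: tuple = (10.0, 20.0)
    lur_categories: tuple = ("cropland", "pasture", "grassland", "forest",
                             "park", "school", "cafo")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            missing = [name for name in ("met_path", "conc_path", "sites_path")
                       if getattr(self, name) is None]
            if missing:
                raise ValueError(
                    f"simulate disabled but inputs not configured: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {},
                "config": dataclasses.asdict(config)}

    # ---- stage: simulate (or load) -------------------------------------
    if config.simulate:
        ds = synth.simulate_dataset(n_days=config.n_days,
                                    start_date=config.start_date,
                                    seed=config.seed)
        paths = synth.write_dataset(ds, out / "data")
        met_df, conc, sites = ds.met, ds.conc, ds.landscape.sites
        landscape = ds.landscape
        manifest["stages"]["simulate"] = {
            "n_days": config.n_days, "files": paths,
            "n_conc_rows": int(len(conc)),
        }
    else:
        met_df = met.read_met(config.met_path)
        conc = pd.read_csv(config.conc_path, parse_dates=["date"])
        sites = pd.read_csv(config.sites_path)
        landscape = None
        if config.landcover_path and config.cafos_path:
            grid, x0, y0, cell = gridio.read_asc(config.landcover_path)
            landscape = synth.Landscape(
                grid=grid.astype(int), cell_km=cell,
                width=grid.shape[1] * cell, height=grid.shape[0] * cell,
                cafos=synth.read_cafos(config.cafos_path), sites=sites)
        manifest["stages"]["load"] = {"n_conc_rows": int(len(conc))}

    # ---- stage: features ------------------------------------------------
    features = met.daily_features(met_df)
    feat_path = out / "met_features.csv"
    met.write_features(features, feat_path)
    manifest["stages"]["features"] = {
        "n_days": int(len(features)),
        "n_missing_recirc": int(features["recirc12"].isna().sum()),
        "file": str(feat_path),
    }

    # ---- stage: temporal fit -------------------------------------------
    model = temporal.EndotoxinLagModel.from_dataframe(
        conc, config.central_site, features, analyte=config.analyte,
        outlier_threshold=config.outlier_threshold)
    fit = model.fit()
    fit_path = out / "temporal_fit.csv"
    fit.to_frame().to_csv(fit_path, index_label="term")
    (out / "temporal_fit.txt").write_text(
        fit.to_frame().to_string() + "\n"
        + f"n = {fit.nobs}, imputed = {fit.n_imputed}, dropped = {model.n_dropped}\n"
        + f"R^2 = {fit.rsquared:.4f}, adj R^2 = {fit.rsquared_adj:.4f}\n")
    manifest["stages"]["fit_temporal"] = {
        "n_obs": fit.nobs, "n_imputed": fit.n_imputed,
        "n_dropped": model.n_dropped,
        "r_squared": fit.rsquared, "adj_r_squared": fit.rsquared_adj,
        "file": str(fit_path),
    }

    # ---- stage: spatial statistics -------------------------------------
    snap = spatial.snapshot(conc, config.analyte, config.season)
    pair_rows = []
    for site in snap.columns:
        if site == config.central_site:
            continue
        ps = spatial.pair_regression(snap, config.central_site, site)
        if ps is not None:
            pair_rows.append(dataclasses.asdict(ps))
    pd.DataFrame(pair_rows).to_csv(out / "pairstats.csv", index=False)
    cv, cv_summary = spatial.daily_cv(snap, min_sites=config.min_sites_cv)
    cv.rename("cv").to_csv(out / "cv_daily.csv", index_label="date")
    snapshots = {a: spatial.snapshot(conc, a, config.season)
                 for a in synth.ANALYTES}
    corr = spatial.spatial_correlation(snapshots, config.central_site)
    corr.to_csv(out / "correlation_table.csv", index_label="site")
    manifest["stages"]["spatial_stats"] = {
        "n_pairs": len(pair_rows), "cv_summary": cv_summary,
        "files": [str(out / n) for n in
                  ("pairstats.csv", "cv_daily.csv", "correlation_table.csv")],
    }

    # ---- stage: mapping -------------------------------------------------
    center = (sites.loc[sites["class"] == "central", ["x_km", "y_km"]]
              .iloc[0].to_numpy() if "class" in sites else
              sites[["x_km", "y_km"]].mean().to_numpy())
    grid = mapping.GridSpec.centered(center[0], center[1],
                                     width=config.map_width,
                                     height=config.map_height,
                                     spacing=config.grid_spacing,
                                     analyte=config.analyte)
    avg_map, daily_maps, used = mapping.map_period(
        snap, sites, grid, power=config.idw_power,
        min_sites=config.min_sites_map)
    avg_map.write_asc(out / f"{config.analyte}_{config.season}_avg.asc")
    avg_map.to_frame().to_csv(out / f"{config.analyte}_{config.season}_avg.csv",
                              index=False)
    loo = mapping.loo_validate(snap, sites, power=config.idw_power,
                               min_sites=config.min_sites_map)
    loo.records.to_csv(out / "loo_report.csv", index=False)
    manifest["stages"]["map"] = {
        "n_days_mapped": len(daily_maps),
        "n_days_skipped": int(len(snap) - len(daily_maps)),
        "loo_mean_bias_pct": loo.mean_bias_pct,
        "loo_mean_abs_error_pct": loo.mean_abs_error_pct,
        "loo_r2": loo.r2,
    }

    # ---- stage: land-use regression ------------------------------------
    if landscape is not None:
        buffers = landuse.buffer_table(landscape, sites,
                                       radii=config.buffer_radii)
        buffers.to_csv(out / "buffers.csv", index=False)
        averages = landuse.period_average(snap, min_sites=config.min_sites_map)
        lur_rows = []
        for cat in config.lur_categories:
            for radius in config.buffer_radii:
                res = landuse.lur_daily(snap, buffers, cat, radius)
                try:
                    avg_r2, avg_slope = landuse.lur_average(
                        averages, buffers, cat, radius)
                except ValueError:
                    avg_r2, avg_slope = float("nan"), float("nan")
                lur_rows.append({
                    "category": cat, "radius_km": radius,
                    "mean_daily_r2": res.mean_r2, "n_days": res.n_days,
                    "slope_sign": res.slope_sign,
                    "period_avg_r2": avg_r2, "period_avg_slope": avg_slope,
                })
        pd.DataFrame(lur_rows).to_csv(out / "lur_results.csv", index=False)
        manifest["stages"]["landuse"] = {
            "n_regressions": len(lur_rows),
            "files": [str(out / "buffers.csv"), str(out / "lur_results.csv")],
        }
    else:
        log.warning("no landscape inputs; land-use stage skipped")
        manifest["stages"]["landuse"] = {"skipped": "no landscape inputs"}

    # ---- manifest -------------------------------------------------------
    checksums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(out))] = _sha256(p)
    manifest["checksums"] = checksums
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
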