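"""Seeded synthetic study data: meteorology, landscape, and concentrations.

The generator emulates the statistical structure of a multi-year ambient
monitoring campaign in a flat agricultural valley: a May–October dry
season with low relative humidity and multi-day stagnation episodes
(light winds whose direction reverses diurnally, as under summertime
inversions); a central-site daily endotoxin series driven by a lagged
nonlinear model of yesterday's concentration, humidity, recirculation
and evening wind speed; satellite sites whose mean endotoxin is elevated
in proportion to the agricultural land area within 20 km; and three
co-pollutants whose cross-site correlation ordering is
PM2.5 > EC > PMc > endotoxin (PM2.5 regional, EC with an urban-core
gradient, PMc sharing endotoxin's spatial driver, PM10 = PM2.5 + PMc
identically).

All randomness flows from explicit integer seeds via
``numpy.random.default_rng``; the same seed reproduces the data
bit-for-bit.

Wind directions use the meteorological from-which convention (degrees
clockwise from north); coordinates are local planar kilometres with the
origin at the domain's southwest corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import gridio
from .landuse import raster_buffer_areas
from .met import daily_features
from .seasons import DRY_MONTHS

#: land-cover category codes for the landscape raster
CATEGORIES = {
    "cropland": 1,
    "pasture": 2,
    "grassland": 3,
    "forest": 4,
    "urban": 5,
    "park": 6,
    "school": 7,
}

ANALYTES = ("endotoxin", "pm25", "pm10", "pmc", "ec")

#: default coefficients of the daily endotoxin model (EU/m^3 scale):
#: intercept, E(t-1), E(t-1)^3, RH, RH^2, 12-hr recirculation index,
#: wind speed at 2000 hours day t-1, and its square.
DEFAULT_TEMPORAL_COEFFS = {
    "intercept": 2.822,
    "lag": 0.6901,
    "lag_cubed": -0.0084,
    "mean_rh": -0.0122,
    "mean_rh_sq": -0.0010,
    "recirc12": 1.4705,
    "ws_2000_prev": -0.1618,
    "ws_2000_prev_sq": -0.0211,
}


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape and monitoring network."""
    width: float = 50.0          # km
    height: float = 60.0         # km
    cell_km: float = 0.25        # land-cover raster resolution
    n_schools: int = 10
    n_residences: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0 or self.cell_km <= 0:
            raise ValueError("domain dimensions and cell size must be positive")
        if self.n_schools + self.n_residences + 1 <= 0 or self.n_schools < 0 \
                or self.n_residences < 0:
            raise ValueError("site counts must be non-negative")


@dataclass
class Landscape:
    """Generated landscape: category raster, CAFO polygons, site table."""
    grid: np.ndarray             # (ny, nx) integer codes, row 0 at south edge
    cell_km: float
    width: float
    height: float
    cafos: list                  # shapely Polygons (planar km)
    sites: pd.DataFrame          # columns id, x_km, y_km, class
    categories: dict = field(default_factory=lambda: dict(CATEGORIES))

    @property
    def center(self) -> tuple[float, float]:
        return self.width / 2.0, self.height / 2.0


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside generated data, for recovery tests."""
    coeffs: dict = field(default_factory=lambda: dict(DEFAULT_TEMPORAL_COEFFS))
    noise_sd: float = 1.0            # EU/m^3, daily innovation of the central series
    endo_site_sd: float = 1.2        # EU/m^3, site-level endotoxin noise
    offset_per_km2: float = 0.005    # EU/m^3 added per km^2 of 20-km agricultural area
    offset_radius_km: float = 20.0
    missing_rate: float = 0.03       # independent Bernoulli per site-day-analyte
    outlier_value: float = 25.0      # EU/m^3, single forced outlier day at the center
    outlier_date: str | None = None  # ISO date; default: 61st day of the series
    gap_date: str | None = None      # forced singleton missing day; default: 41st day
    site_offsets: dict = field(default_factory=dict)  # filled by the generator

    def __post_init__(self):
        if self.noise_sd < 0 or self.endo_site_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.offset_per_km2 < 0:
            raise ValueError("site offsets must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# meteorology
# ---------------------------------------------------------------------------

def gen_met(n_days: int, start_date="2002-01-01", seed: int = 0,
            stagnation_rate: float = 0.35, rh_dry: float = 22.0,
            rh_sd: float = 4.5, rh_phi: float = 0.3, rh_april: float = 33.0,
            ws_mean: float = 1.4, ws_sd: float = 0.25,
            season_mode: str = "calendar") -> pd.DataFrame:
    """Generate an hourly meteorology series of ``24*n_days`` records.

    Dry-season days (May–October) have low mean relative humidity and,
    at roughly ``stagnation_rate`` of days, belong to multi-day
    stagnation episodes: wind speeds below ~1.5 m/s with a diurnally
    reversing direction (northwesterly by day, southeasterly drainage at
    night).  Other days carry a steady ~3 m/s northwesterly flow.
    Wet-season humidity is high, so generated endotoxin collapses toward
    zero outside the dry season, as observed in the field.

    Returns a DataFrame with columns ``timestamp, ws, wd, rh, temp`` and
    a boolean ``stagnant`` flag (generator metadata; downstream feature
    extraction ignores it).
    """
    if n_days < 2:
        raise ValueError("n_days must be at least 2")
    rng = np.random.default_rng(seed)
    days = pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D")
    months = days.month.to_numpy()
    if season_mode == "calendar":
        dry = np.isin(months, list(DRY_MONTHS))
    elif season_mode == "dry":
        # perpetual dry-season regime regardless of calendar month, for
        # simulations of an uninterrupted run of dry-season days
        dry = np.ones(n_days, dtype=bool)
    else:
        raise ValueError("season_mode must be 'calendar' or 'dry'")

    # stagnation episodes: dry-season only, 2-4 day runs; each episode has
    # its own nocturnal flow-reversal angle (full reversal = strongest
    # recirculation), so the recirculation index varies continuously
    stagnant_day = np.zeros(n_days, dtype=bool)
    reversal = np.zeros(n_days)
    d = 0
    while d < n_days:
        if dry[d] and not stagnant_day[d] and rng.random() < stagnation_rate / 3.0:
            run = int(rng.integers(2, 5))
            ang = rng.uniform(120.0, 180.0)
            stagnant_day[d:d + run] = dry[d:d + run]
            reversal[d:d + run] = np.where(dry[d:d + run], ang, 0.0)
            d += run
        else:
            d += 1

    # daily-mean RH: dry-season base low (valley summer), a mild within-
    # season cycle (May/Oct damper than July/August), and AR(1) day-to-day
    # persistence so humid spells last several days
    rh_base = np.where(dry, rh_dry, np.where(months == 4, rh_april, 70.0))
    if season_mode == "calendar":
        # mild within-dry-season humidity cycle (May/Oct damper than July);
        # omitted in perpetual-dry mode, which models homogeneous conditions
        month_rh = {5: 3.0, 6: 1.0, 7: -2.0, 8: -2.0, 9: 1.0, 10: 3.0}
        rh_base = rh_base + np.vectorize(lambda m: month_rh.get(m, 0.0))(months)
    dev = np.empty(n_days)
    innov = rng.normal(0.0, rh_sd * np.sqrt(1 - rh_phi ** 2), n_days)
    prev = 0.0
    for i in range(n_days):
        prev = rh_phi * prev + innov[i]
        dev[i] = prev
    rh_day = rh_base + dev
    temp_base = np.where(dry, 26.0, np.where(months == 4, 18.0, 11.0))
    temp_day = temp_base + rng.normal(0.0, 3.0, n_days)

    hours = np.arange(24)
    diurnal_rh = 12.0 * np.cos(2 * np.pi * (hours - 5) / 24.0)     # max near dawn
    diurnal_t = 8.0 * np.cos(2 * np.pi * (hours - 15) / 24.0)      # max mid-afternoon

    rh = np.clip(rh_day[:, None] + diurnal_rh[None, :]
                 + rng.normal(0.0, 2.0, (n_days, 24)), 0.0, 100.0)
    temp = temp_day[:, None] + diurnal_t[None, :] + rng.normal(0.0, 1.0, (n_days, 24))

    speed_base = np.where(stagnant_day,
                          np.clip(rng.normal(0.8, 0.2, n_days), 0.25, None),
                          np.clip(rng.normal(ws_mean, ws_sd, n_days), 0.8, None))
    diurnal_ws = 0.5 * np.cos(2 * np.pi * (hours - 15) / 24.0)  # afternoon peak
    ws = np.clip(speed_base[:, None] + diurnal_ws[None, :]
                 + rng.normal(0.0, 0.25, (n_days, 24)), 0.05, None)

    daytime = (hours >= 8) & (hours < 20)
    wd_steady = 315.0 + rng.normal(0.0, 20.0, (n_days, 24))
    wd_stag = (315.0 - np.where(daytime[None, :], 0.0, reversal[:, None])
               + rng.normal(0.0, 15.0, (n_days, 24)))
    wd = np.where(stagnant_day[:, None], wd_stag, wd_steady) % 360.0

    ts = pd.date_range(days[0], periods=24 * n_days, freq="h")
    return pd.DataFrame({
        "timestamp": ts,
        "ws": ws.ravel(),
        "wd": wd.ravel(),
        "rh": rh.ravel(),
        "temp": temp.ravel(),
        "stagnant": np.repeat(stagnant_day, 24),
    })


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def gen_landscape(config: LandscapeConfig | None = None) -> Landscape:
    """Generate the land-cover raster, CAFO polygons, and site table.

    Agricultural categories (cropland, pasture) are concentrated west
    and south of a central urban block; grassland and forest occupy the
    north and northeast; CAFO rectangles sit in the agricultural west
    and southwest.  Sites: one central monitor in the urban core,
    ``n_schools`` schools scattered through the urban area, and
    ``n_residences`` residences over the wider domain, the first of
    which is pinned to the far west so the network spans the
    agricultural gradient.
    """
    if config is None:
        config = LandscapeConfig()
    if config.n_schools + config.n_residences + 1 < 1:
        raise ValueError("at least one site is required")
    rng = np.random.default_rng(config.seed)
    W, H, cell = config.width, config.height, config.cell_km
    nx = int(np.ceil(W / cell))
    ny = int(np.ceil(H / cell))
    cx, cy = W / 2.0, H / 2.0

    xc = (np.arange(nx) + 0.5) * cell
    yc = (np.arange(ny) + 0.5) * cell
    X, Y = np.meshgrid(xc, yc)

    # agriculture on three sides (west, south, east); native vegetation
    # (grassland/forest) to the north and northeast
    grid = np.full((ny, nx), CATEGORIES["grassland"], dtype=np.int16)
    grid[(X < cx - 8) | (Y < cy - 18)] = CATEGORIES["cropland"]        # west + south
    grid[(X > cx + 14) & (Y < cy + 6)] = CATEGORIES["cropland"]        # east
    grid[(X < cx - 10) & (Y < cy - 8)] = CATEGORIES["pasture"]         # southwest
    grid[(X > cx + 10) & (Y > cy + 10)] = CATEGORIES["forest"]         # northeast
    urban = (np.abs(X - cx) < 8) & (np.abs(Y - cy) < 8)
    grid[urban] = CATEGORIES["urban"]

    # speckle noise among the open-land categories
    open_land = np.isin(grid, [CATEGORIES["cropland"], CATEGORIES["pasture"],
                               CATEGORIES["grassland"]])
    speckle = open_land & (rng.random(grid.shape) < 0.08)
    grid[speckle] = rng.choice(
        [CATEGORIES["cropland"], CATEGORIES["pasture"], CATEGORIES["grassland"]],
        size=int(speckle.sum()))

    # a few urban parks (small blocks inside the urban core)
    for _ in range(8):
        px = cx + rng.uniform(-7, 7)
        py = cy + rng.uniform(-7, 7)
        j, i = int(px / cell), int(py / cell)
        grid[max(i - 1, 0):i + 1, max(j - 1, 0):j + 1] = CATEGORIES["park"]

    # CAFO rectangles in the agricultural west / southwest
    cafo_rects = [(3.0, 34.0, 5.5, 36.5), (6.0, 14.0, 8.5, 16.5),
                  (11.0, 6.0, 13.5, 8.5), (8.0, 24.0, 10.0, 26.0)]
    cafos = [Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
             for x0, y0, x1, y1 in cafo_rects]

    # sites: central, schools in/near the urban core, residences domain-wide
    rows = [("CENTRAL", cx, cy, "central")]
    for k in range(config.n_schools):
        ang = 2 * np.pi * k / max(config.n_schools, 1) + rng.uniform(-0.2, 0.2)
        r = rng.uniform(2.0, 7.0)
        sx, sy = cx + r * np.cos(ang), cy + r * np.sin(ang)
        rows.append((f"SCH{k + 1:02d}", sx, sy, "school"))
        j, i = int(sx / cell), int(sy / cell)
        grid[i, j] = CATEGORIES["school"]
    for k in range(config.n_residences):
        if k == 0:
            rx, ry = 7.0, cy - 4.0   # westernmost residence, deep in cropland
        else:
            # residences sit in the urban fringe and the agricultural belt
            # (west/south/east); the northern native-vegetation zone is
            # outside the study circle
            rx = rng.uniform(8.0, W - 5.0)
            ry = rng.uniform(8.0, cy + 8.0)
        rows.append((f"RES{k + 1:02d}", rx, ry, "residence"))
    sites = pd.DataFrame(rows, columns=["id", "x_km", "y_km", "class"])

    return Landscape(grid=grid, cell_km=cell, width=W, height=H,
                     cafos=cafos, sites=sites)


# ---------------------------------------------------------------------------
# concentrations
# ---------------------------------------------------------------------------

def simulate_endotoxin_series(features: pd.DataFrame, coeffs: dict,
                              noise_sd: float, rng: np.random.Generator,
                              init: float = 2.0) -> pd.Series:
    """Simulate the central-site daily endotoxin series from the lag model.

    E(t) = max(0, b0 + b1 E(t-1) + b2 E(t-1)^3 + b3 RH + b4 RH^2
                 + b5 R12 + b6 WS + b7 WS^2 + eps),  eps ~ N(0, noise_sd).

    Missing covariates are filled with their column means for the
    purposes of generation (the generated record itself carries no
    missingness; that is injected separately).
    """
    f = features.copy()
    f = f.fillna(f.mean())
    met_part = (coeffs["intercept"]
                + coeffs["mean_rh"] * f["mean_rh"].to_numpy()
                + coeffs["mean_rh_sq"] * f["mean_rh_sq"].to_numpy()
                + coeffs["recirc12"] * f["recirc12"].to_numpy()
                + coeffs["ws_2000_prev"] * f["ws_2000_prev"].to_numpy()
                + coeffs["ws_2000_prev_sq"] * f["ws_2000_prev_sq"].to_numpy())
    n = len(f)
    eps = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    values = np.empty(n)
    prev = init
    b1, b2 = coeffs["lag"], coeffs["lag_cubed"]
    for t in range(n):
        values[t] = max(0.0, met_part[t] + b1 * prev + b2 * prev ** 3 + eps[t])
        prev = values[t]
    return pd.Series(values, index=f.index, name="endotoxin")


def _agricultural_offsets(landscape: Landscape, truth: SyntheticTruth) -> pd.Series:
    """Per-site endotoxin offsets, linear in 20-km agricultural buffer area.

    Offset_i = offset_per_km2 * (ag_i - min_j ag_j) where ag is the
    cropland + pasture area within ``offset_radius_km``: exactly linear
    in the 20-km agricultural area and >= 0, with the least-agricultural
    site at zero.  Concentration generation applies offsets *relative to
    the central site* (offset_i - offset_central), so the central series
    follows the temporal model exactly while the cross-site mean surface
    remains linear in agricultural area.
    """
    ag = {}
    for _, s in landscape.sites.iterrows():
        areas = raster_buffer_areas(landscape, s["x_km"], s["y_km"],
                                    truth.offset_radius_km)
        ag[s["id"]] = areas["cropland"] + areas["pasture"]
    ag = pd.Series(ag)
    return truth.offset_per_km2 * (ag - ag.min())


def gen_concentrations(features: pd.DataFrame, landscape: Landscape,
                       truth: SyntheticTruth | None = None, seed: int = 0,
                       dates=None) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the multi-site daily concentration table for all analytes.

    Returns ``(conc, truth)`` where ``conc`` is a long DataFrame with
    columns ``site, date, analyte, value`` (NaN = missing) and ``truth``
    is the input truth with the realised per-site offsets recorded.

    Spatial structure, by analyte:

    * endotoxin — central series from the lag model; other sites add an
      agricultural-land offset plus site noise (most heterogeneous);
    * pm25 — regional AR(1) field with small site noise (most homogeneous);
    * ec — common daily driver scaled by an urban-core proximity gradient;
    * pmc — shares the endotoxin spatial driver plus its own regional term;
    * pm10 — pm25 + pmc, identically.
    """
    if truth is None:
        truth = SyntheticTruth()
    if dates is not None:
        dates = pd.DatetimeIndex(dates)
        if not dates.isin(features.index).all():
            raise ValueError("requested dates not covered by the met features")
        features = features.loc[dates]
    rng = np.random.default_rng(seed)
    idx = features.index
    n = len(idx)
    if n == 0:
        raise ValueError("met features cover no days")
    sites = landscape.sites
    m = len(sites)
    cxy = np.array(landscape.center)
    dist_center = np.hypot(sites["x_km"].to_numpy() - cxy[0],
                           sites["y_km"].to_numpy() - cxy[1])

    offsets = _agricultural_offsets(landscape, truth)
    truth.site_offsets = {k: float(v) for k, v in offsets.items()}
    central_col = int(np.flatnonzero(sites["class"].to_numpy() == "central")[0])
    central_id = sites["id"].iloc[central_col]
    # offsets enter relative to the central reference so the central series
    # follows the temporal model exactly
    delta = (offsets - offsets[central_id]).loc[sites["id"]].to_numpy()

    e0 = simulate_endotoxin_series(features, truth.coeffs, truth.noise_sd, rng)
    e0v = e0.to_numpy()

    # endotoxin per site (days x sites); central column = base series exactly
    endo = np.clip(e0v[:, None] + delta[None, :]
                   + rng.normal(0.0, truth.endo_site_sd, (n, m)), 0.0, None)
    endo[:, central_col] = np.clip(e0v, 0.0, None)

    def ar1(mean, phi, sd):
        x = np.empty(n)
        prev = mean
        innov = rng.normal(0.0, sd, n)
        for t in range(n):
            prev = mean + phi * (prev - mean) + innov[t]
            x[t] = prev
        return x

    # pm25: regional field, high cross-site correlation
    p_reg = np.clip(ar1(9.0, 0.6, 2.2), 1.0, None)
    pm25 = np.clip(p_reg[:, None] + rng.normal(0.0, 0.4, (n, m)), 0.3, None)

    # pmc: shares endotoxin's spatial driver plus a regional term
    c_reg = ar1(0.0, 0.5, 1.3)
    pmc = np.clip(2.0 + 1.2 * endo + c_reg[:, None]
                  + rng.normal(0.0, 1.2, (n, m)), 0.2, None)

    # ec: common driver scaled by urban-core proximity
    a_reg = ar1(0.0, 0.5, 0.4)
    gain = 0.4 + 1.6 * np.exp(-dist_center / 10.0)
    ec = np.clip(gain[None, :] * np.clip(0.8 + a_reg, 0.1, None)[:, None]
                 + rng.normal(0.0, 0.15, (n, m)), 0.02, None)

    pm10 = pm25 + pmc

    # missingness: independent Bernoulli per site-day for each measured channel
    miss = {a: rng.random((n, m)) < truth.missing_rate
            for a in ("endotoxin", "pm25", "pmc", "ec")}
    miss["pm10"] = miss["pm25"] | miss["pmc"]

    # forced singleton gap and outlier day on the central endotoxin series
    gap_date = pd.Timestamp(truth.gap_date) if truth.gap_date else idx[min(40, n - 1)]
    out_date = pd.Timestamp(truth.outlier_date) if truth.outlier_date else idx[min(60, n - 1)]
    values = {"endotoxin": endo, "pm25": pm25, "pm10": pm10, "pmc": pmc, "ec": ec}
    if gap_date in idx:
        g = idx.get_loc(gap_date)
        miss["endotoxin"][g, central_col] = True
        for nb in (g - 1, g + 1):           # keep it a singleton gap
            if 0 <= nb < n:
                miss["endotoxin"][nb, central_col] = False
    if out_date in idx:
        o = idx.get_loc(out_date)
        values["endotoxin"][o, central_col] = truth.outlier_value
        miss["endotoxin"][o, central_col] = False

    frames = []
    site_ids = sites["id"].to_numpy()
    for analyte in ANALYTES:
        vals = values[analyte].copy()
        vals[miss[analyte]] = np.nan
        frame = pd.DataFrame(vals, index=idx, columns=site_ids)
        long = frame.stack(future_stack=True).rename("value").reset_index()
        long.columns = ["date", "site", "value"]
        long["analyte"] = analyte
        frames.append(long[["site", "date", "analyte", "value"]])
    conc = pd.concat(frames, ignore_index=True)
    return conc, truth


# ---------------------------------------------------------------------------
# bundled dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    met: pd.DataFrame
    features: pd.DataFrame
    landscape: Landscape
    conc: pd.DataFrame
    truth: SyntheticTruth
    seed: int


def simulate_dataset(n_days: int = 240, start_date="2002-04-01", seed: int = 0,
                     config: LandscapeConfig | None = None,
                     truth: SyntheticTruth | None = None) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic study dataset."""
    if config is None:
        config = LandscapeConfig(seed=seed)
    met = gen_met(n_days, start_date=start_date, seed=seed)
    features = daily_features(met).dropna(how="all")
    landscape = gen_landscape(config)
    conc, truth = gen_concentrations(features, landscape, truth=truth,
                                     seed=seed + 1, dates=None)
    return SyntheticDataset(met=met, features=features, landscape=landscape,
                            conc=conc, truth=truth, seed=seed)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write the dataset as delimited text files; returns {name: path}.

    Files: sites.csv, met_hourly.csv, conc_daily.csv, met_features.csv,
    landcover.asc, cafos.csv, truth.json.  Missing values are empty CSV
    fields.
    """
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["sites"] = outdir / "sites.csv"
    ds.landscape.sites.to_csv(paths["sites"], index=False)

    paths["met_hourly"] = outdir / "met_hourly.csv"
    ds.met[["timestamp", "ws", "wd", "rh", "temp"]].to_csv(paths["met_hourly"], index=False)

    paths["met_features"] = outdir / "met_features.csv"
    ds.features.to_csv(paths["met_features"], index_label="date")

    paths["conc_daily"] = outdir / "conc_daily.csv"
    ds.conc.to_csv(paths["conc_daily"], index=False)

    paths["landcover"] = outdir / "landcover.asc"
    gridio.write_asc(paths["landcover"], ds.landscape.grid.astype(float),
                     0.0, 0.0, ds.landscape.cell_km, nodata=-1)

    paths["cafos"] = outdir / "cafos.csv"
    rows = []
    for k, poly in enumerate(ds.landscape.cafos):
        for j, (x, y) in enumerate(poly.exterior.coords[:-1]):
            rows.append((f"CAFO{k + 1:02d}", j, x, y))
    pd.DataFrame(rows, columns=["cafo", "vertex", "x_km", "y_km"]).to_csv(
        paths["cafos"], index=False)

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(ds.truth), fh, indent=2, default=str)

    return {k: str(v) for k, v in paths.items()}


def read_cafos(path) -> list:
    """Read CAFO polygons back from cafos.csv."""
    df = pd.read_csv(path)
    polys = []
    for _, grp in df.groupby("cafo", sort=True):
        grp = grp.sort_values("vertex")
        polys.append(Polygon(list(zip(grp["x_km"], grp["y_km"]))))
    return polys
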