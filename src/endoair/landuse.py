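"""Land-use buffer areas and buffer regressions.

Monitoring sites in the study design sit inside an urban core surrounded
by agricultural land, and site-to-site differences in ambient endotoxin
are hypothesised to track the amount of agricultural activity nearby.
This module measures the area of each land-cover category within circular
buffers (10 km and 20 km by default) of each site and regresses daily or
period-average concentrations on those areas, one category at a time.

Raster categories use the cell-centre-in-circle rule (count of cell
centres inside the circle times the cell area), which converges to the
exact geometric area as the cell size shrinks.  CAFO source polygons are
intersected with the buffer circle exactly (shapely).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point

log = logging.getLogger(__name__)


def raster_buffer_areas(landscape, x: float, y: float, radius: float) -> dict:
    """Area (km^2) of each raster land-cover category within ``radius`` of (x, y).

    ``landscape`` needs attributes ``grid`` (2-D integer category codes,
    row 0 at the south edge), ``cell_km``, ``width``, ``height`` and
    ``categories`` (name -> code).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0 <= x <= landscape.width and 0 <= y <= landscape.height):
        raise ValueError(f"site ({x}, {y}) lies outside the landscape domain")
    cell = landscape.cell_km
    grid = landscape.grid
    ny, nx = grid.shape
    j0 = max(0, int((x - radius) / cell))
    j1 = min(nx, int(np.ceil((x + radius) / cell)))
    i0 = max(0, int((y - radius) / cell))
    i1 = min(ny, int(np.ceil((y + radius) / cell)))
    areas = {name: 0.0 for name in landscape.categories}
    if j1 <= j0 or i1 <= i0:
        return areas
    xc = (np.arange(j0, j1) + 0.5) * cell
    yc = (np.arange(i0, i1) + 0.5) * cell
    dx2 = (xc - x) ** 2
    dy2 = (yc - y) ** 2
    inside = (dy2[:, None] + dx2[None, :]) <= radius ** 2
    sub = grid[i0:i1, j0:j1]
    cell_area = cell * cell
    for name, code in landscape.categories.items():
        areas[name] = float(np.count_nonzero(inside & (sub == code))) * cell_area
    return areas


def cafo_buffer_area(cafos, x: float, y: float, radius: float) -> float:
    """Exact intersection area (km^2) of CAFO polygons with the buffer circle."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    circle = Point(x, y).buffer(radius, quad_segs=128)
    return float(sum(circle.intersection(poly).area for poly in cafos))


def buffer_area(landscape, x: float, y: float, radius: float) -> dict:
    """All category areas (raster categories plus 'cafo') within the buffer."""
    areas = raster_buffer_areas(landscape, x, y, radius)
    areas["cafo"] = cafo_buffer_area(landscape.cafos, x, y, radius)
    return areas


def buffer_table(landscape, sites: pd.DataFrame | None = None,
                 radii=(10.0, 20.0)) -> pd.DataFrame:
    """Long table of per-site, per-radius, per-category buffer areas.

    Columns: site, radius_km, category, area_km2.
    """
    if sites is None:
        sites = landscape.sites
    rows = []
    for _, s in sites.iterrows():
        for radius in radii:
            for cat, area in buffer_area(landscape, s["x_km"], s["y_km"], radius).items():
                rows.append((s["id"], radius, cat, area))
    return pd.DataFrame(rows, columns=["site", "radius_km", "category", "area_km2"])


def aggregate_categories(buffers: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Append summed-category rows, e.g. {"agriculture": ["cropland", "pasture"]}.

    Returns the buffer table with one extra category per group, usable as
    a regression predictor like any raw category.
    """
    frames = [buffers]
    for name, members in groups.items():
        agg = (buffers[buffers["category"].isin(members)]
               .groupby(["site", "radius_km"], as_index=False)["area_km2"].sum())
        agg["category"] = name
        frames.append(agg[["site", "radius_km", "category", "area_km2"]])
    return pd.concat(frames, ignore_index=True)


def _predictor(buffers: pd.DataFrame, category: str, radius: float) -> pd.Series:
    sel = buffers[(buffers["category"] == category)
                  & (np.isclose(buffers["radius_km"], radius))]
    if sel.empty:
        raise ValueError(f"no buffer areas for category {category!r} at {radius} km")
    return sel.set_index("site")["area_km2"]


@dataclass
class LurResult:
    """Single-category land-use regression summary."""
    category: str
    radius_km: float
    r2_by_day: pd.Series        # per qualifying day
    mean_r2: float
    slope_sign: int             # modal sign of the daily slopes
    n_days: int
    skipped: list = field(default_factory=list)


def lur_daily(snapshot: pd.DataFrame, buffers: pd.DataFrame, category: str,
              radius: float, min_sites: int = 3) -> LurResult:
    """Regress each day's site concentrations on one category's buffer area.

    ``snapshot`` is a dates x sites concentration matrix.  Days with
    fewer than ``min_sites`` sites present, or with a constant predictor
    across the present sites, are skipped and logged.
    """
    areas = _predictor(buffers, category, radius)
    r2s, slopes, skipped = {}, [], []
    for day, row in snapshot.iterrows():
        vals = row.dropna()
        vals = vals[vals.index.isin(areas.index)]
        if len(vals) < min_sites:
            skipped.append((day, "too few sites"))
            continue
        x = areas.loc[vals.index].to_numpy()
        if np.ptp(x) == 0:
            skipped.append((day, "constant predictor"))
            continue
        res = stats.linregress(x, vals.to_numpy())
        r2s[day] = res.rvalue ** 2
        slopes.append(np.sign(res.slope))
    r2_series = pd.Series(r2s, dtype=float)
    for day, why in skipped:
        log.debug("lur_daily skipped %s: %s", day, why)
    sign = int(pd.Series(slopes).mode().iloc[0]) if slopes else 0
    mean_r2 = float(r2_series.mean()) if len(r2_series) else np.nan
    return LurResult(category, radius, r2_series, mean_r2, sign, len(r2_series), skipped)


def lur_average(averages: pd.Series, buffers: pd.DataFrame, category: str,
                radius: float) -> tuple[float, float]:
    """Regress period-average site concentrations on one category's area.

    Returns (r2, slope).  Raises on fewer than 3 sites; returns
    (nan, nan) with a log entry for a degenerate (constant or all-zero)
    predictor.
    """
    averages = averages.dropna()
    if len(averages) < 3:
        raise ValueError("need period averages for at least 3 sites")
    areas = _predictor(buffers, category, radius)
    common = averages.index.intersection(areas.index)
    if len(common) < 3:
        raise ValueError("need at least 3 sites with both averages and buffer areas")
    x = areas.loc[common].to_numpy()
    if np.ptp(x) == 0:
        log.warning("lur_average skipped %s@%gkm: constant predictor", category, radius)
        return np.nan, np.nan
    res = stats.linregress(x, averages.loc[common].to_numpy())
    return float(res.rvalue ** 2), float(res.slope)


def period_average(snapshot: pd.DataFrame, min_sites: int = 6) -> pd.Series:
    """Per-site mean concentration over days with >= min_sites sites present.

    Mirrors the mapping day filter, so averages describe the same day set
    as the period-average concentration maps.
    """
    counts = snapshot.notna().sum(axis=1)
    qualifying = snapshot.loc[counts >= min_sites]
    return qualifying.mean(axis=0)
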