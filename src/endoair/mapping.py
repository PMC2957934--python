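"""Daily concentration surfaces by inverse-distance weighting (IDW).

Multi-site daily concentrations are interpolated onto a regular planar
grid (default 0.25-km spacing spanning a 50 x 60 km domain centred on
the central monitor).  Mapping is performed day by day *before* temporal
averaging, and period-average maps are node-wise means of the daily
maps.  Accuracy is assessed by leave-one-out cross-validation: each
site-day observation is predicted from the remaining sites with the
same interpolator.

The interpolated value at a node is the convex combination
``sum(w_i z_i) / sum(w_i)`` with ``w_i = d_i**(-power)``; a node within
the snap distance of a site takes that site's value exactly, so the
surface interpolates the stations and its extrema never exceed the
input extrema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import gridio

log = logging.getLogger(__name__)

DEFAULT_SPACING = 0.25   # km
DEFAULT_POWER = 2.0
DEFAULT_MIN_SITES = 6
SNAP_KM = 0.001          # 1 m


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid: origin at the southwest node, node-registered."""
    origin_x: float
    origin_y: float
    spacing: float = DEFAULT_SPACING
    nx: int = 201
    ny: int = 241
    analyte: str | None = None

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must contain at least one node")

    @classmethod
    def centered(cls, center_x: float, center_y: float, width: float = 50.0,
                 height: float = 60.0, spacing: float = DEFAULT_SPACING,
                 analyte: str | None = None) -> "GridSpec":
        nx = int(round(width / spacing)) + 1
        ny = int(round(height / spacing)) + 1
        return cls(center_x - width / 2.0, center_y - height / 2.0,
                   spacing, nx, ny, analyte)

    def node_coords(self):
        """(X, Y) meshgrids of node coordinates, row 0 at the south edge."""
        x = self.origin_x + self.spacing * np.arange(self.nx)
        y = self.origin_y + self.spacing * np.arange(self.ny)
        return np.meshgrid(x, y)


@dataclass
class GridMap:
    """A concentration surface on a GridSpec, daily or time-averaged."""
    spec: GridSpec
    values: np.ndarray          # (ny, nx), row 0 at the south edge
    label: str                  # date or averaging-period label
    n_contributing: int         # sites (daily map) or days (average map)

    def write_asc(self, path) -> None:
        gridio.write_asc(path, self.values, self.spec.origin_x,
                         self.spec.origin_y, self.spec.spacing)

    def to_frame(self) -> pd.DataFrame:
        """Flat (x, y, value) form."""
        X, Y = self.spec.node_coords()
        return pd.DataFrame({"x_km": X.ravel(), "y_km": Y.ravel(),
                             "value": self.values.ravel()})


def idw(site_xy: np.ndarray, site_values: np.ndarray, target_xy: np.ndarray,
        power: float = DEFAULT_POWER, snap: float = SNAP_KM) -> np.ndarray:
    """Inverse-distance-weighted interpolation at arbitrary target points.

    All stations contribute; targets within ``snap`` of a station take
    that station's value exactly.
    """
    site_xy = np.asarray(site_xy, dtype=float)
    vals = np.asarray(site_values, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    d = np.hypot(target_xy[:, None, 0] - site_xy[None, :, 0],
                 target_xy[:, None, 1] - site_xy[None, :, 1])
    near = d <= snap
    d = np.maximum(d, snap)
    w = d ** (-power)
    out = (w * vals[None, :]).sum(axis=1) / w.sum(axis=1)
    hit = near.any(axis=1)
    if hit.any():
        out[hit] = vals[np.argmax(near[hit], axis=1)]
    return out


def map_day(day_values: pd.Series, sites: pd.DataFrame, grid: GridSpec,
            power: float = DEFAULT_POWER, min_sites: int = DEFAULT_MIN_SITES,
            snap: float = SNAP_KM) -> GridMap | None:
    """IDW surface for one day; None (logged) if too few sites report.

    ``day_values`` is indexed by site id; ``sites`` has columns
    ``id, x_km, y_km``.
    """
    vals = day_values.dropna()
    if len(vals) < min_sites:
        log.info("map_day %s skipped: %d sites < %d", day_values.name,
                 len(vals), min_sites)
        return None
    coords = sites.set_index("id").loc[vals.index, ["x_km", "y_km"]].to_numpy()
    X, Y = grid.node_coords()
    targets = np.column_stack([X.ravel(), Y.ravel()])
    surface = idw(coords, vals.to_numpy(), targets, power=power, snap=snap)
    name = day_values.name
    try:
        label = str(pd.Timestamp(name).date())
    except (TypeError, ValueError):
        label = str(name) if name is not None else ""
    return GridMap(grid, surface.reshape(grid.ny, grid.nx), label, len(vals))


def average_maps(maps: list[GridMap], label: str = "average") -> GridMap:
    """Node-wise arithmetic mean of daily maps on an identical GridSpec."""
    if not maps:
        raise ValueError("need at least one daily map")
    spec = maps[0].spec
    for m in maps[1:]:
        if replace(m.spec, analyte=spec.analyte) != spec:
            raise ValueError("maps are on mismatched grid specifications")
    stack = np.stack([m.values for m in maps])
    return GridMap(spec, stack.mean(axis=0), label, len(maps))


def map_period(snap_matrix: pd.DataFrame, sites: pd.DataFrame, grid: GridSpec,
               power: float = DEFAULT_POWER, min_sites: int = DEFAULT_MIN_SITES,
               label: str = "period-average"):
    """Map every qualifying day, then time-average (mapping before averaging).

    Returns ``(average_map, daily_maps, used_dates)``.
    """
    daily, used = [], []
    for day, row in snap_matrix.iterrows():
        m = map_day(row, sites, grid, power=power, min_sites=min_sites)
        if m is not None:
            daily.append(m)
            used.append(day)
    if not daily:
        raise ValueError("no day passed the site-count filter")
    return average_maps(daily, label=label), daily, used


@dataclass
class LooReport:
    """Leave-one-out validation of the daily mapping.

    ``records`` columns: site, date, observed, predicted, pct_error
    (100*(pred-obs)/obs; NaN where observed == 0).  Aggregates: mean
    signed bias (%), mean absolute error (%), and r^2 of predicted vs
    observed; zero-observation records are excluded from the percentage
    aggregates and counted in ``n_zero_obs``.
    """
    records: pd.DataFrame
    mean_bias_pct: float
    mean_abs_error_pct: float
    r2: float
    n_zero_obs: int


def loo_validate(snap_matrix: pd.DataFrame, sites: pd.DataFrame,
                 power: float = DEFAULT_POWER, min_sites: int = DEFAULT_MIN_SITES,
                 snap: float = SNAP_KM) -> LooReport:
    """Predict each site-day from the remaining sites by the same IDW."""
    coords_all = sites.set_index("id")[["x_km", "y_km"]]
    rows = []
    for day, row in snap_matrix.iterrows():
        vals = row.dropna()
        if len(vals) < min_sites:
            continue
        coords = coords_all.loc[vals.index].to_numpy()
        v = vals.to_numpy()
        for i, site in enumerate(vals.index):
            keep = np.arange(len(v)) != i
            pred = idw(coords[keep], v[keep], coords[i:i + 1],
                       power=power, snap=snap)[0]
            rows.append((site, day, v[i], pred))
    records = pd.DataFrame(rows, columns=["site", "date", "observed", "predicted"])
    if records.empty:
        raise ValueError("no qualifying day for leave-one-out validation")
    nonzero = records["observed"] != 0
    pct = np.where(nonzero,
                   100.0 * (records["predicted"] - records["observed"])
                   / records["observed"].where(nonzero), np.nan)
    records["pct_error"] = pct
    obs = records["observed"].to_numpy()
    pred = records["predicted"].to_numpy()
    if np.ptp(obs) > 0 and np.ptp(pred) > 0:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        r2 = np.nan
    valid = records["pct_error"].dropna()
    return LooReport(records,
                     float(valid.mean()) if len(valid) else np.nan,
                     float(valid.abs().mean()) if len(valid) else np.nan,
                     r2, int((~nonzero).sum()))


def tertile_maps(snap_matrix: pd.DataFrame, sites: pd.DataFrame, central: str,
                 grid: GridSpec, power: float = DEFAULT_POWER,
                 min_sites: int = DEFAULT_MIN_SITES) -> dict:
    """Average maps for low/mid/high tertiles of the central site's days.

    Qualifying days (site-count filter) are ranked by the central site's
    concentration, ties to the lower tertile; days where the central
    site is missing are excluded and logged.  Tertile day counts differ
    by at most one (low gets any extra).
    """
    qualifying = []
    for day, row in snap_matrix.iterrows():
        if row.notna().sum() < min_sites:
            continue
        if pd.isna(row.get(central, np.nan)):
            log.info("tertile_maps: central missing on %s, day excluded", day)
            continue
        qualifying.append((day, row[central]))
    if len(qualifying) < 3:
        raise ValueError("need at least 3 qualifying days for tertiles")
    qualifying.sort(key=lambda t: (t[1], t[0]))  # stable: ties to lower tertile
    days_sorted = [d for d, _ in qualifying]
    splits = np.array_split(np.arange(len(days_sorted)), 3)
    out = {}
    for name, idx in zip(("low", "mid", "high"), splits):
        maps = [map_day(snap_matrix.loc[days_sorted[i]], sites, grid,
                        power=power, min_sites=min_sites) for i in idx]
        out[name] = average_maps([m for m in maps if m is not None],
                                 label=f"{name}-tertile")
    return out
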