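"""Daily meteorological covariates from hourly wind and humidity records.

The central quantity is the 12-hr air-recirculation index, a wind-run /
net-transport factor: over a window of hourly wind vectors ``V_i`` with
``dt = 1 h``, the scalar wind run is ``S = sum |V_i| dt`` and the net
transport is ``L = |sum V_i dt|``; the index is ``R = 1 - L/S``.  R is 0
for straight-line flow and 1 when transport cancels completely, so larger
values mean more recirculating (stagnant) air.

A measurement day *t* spans 2000 hours of day t-1 to 2000 hours of day t
(the endotoxin sampler's collection window) and is labelled by its end
date.  The daily recirculation covariate is the mean of six overlapping
12-hr windows: 1200–2400 day t-1, 1600 day t-1 – 0400 day t, 2000 day t-1
– 0800 day t, 2400 day t-1 – 1200 day t, 0400–1600 day t, and 0800–2000
day t.  Hourly intervals are half-open and labelled by their start hour,
so "2400 hours day t-1" coincides with "0000 hours day t".

Wind directions follow the meteorological convention: degrees clockwise
from north, reporting the direction the wind blows *from*.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: minimum present hours for a 12-hr recirculation window to be valid (75%)
MIN_WINDOW_HOURS = 9
#: minimum present hours for the 24-hr RH average to be valid (75%)
MIN_RH_HOURS = 18

FEATURE_COLUMNS = ["mean_rh", "mean_rh_sq", "recirc12", "ws_2000_prev", "ws_2000_prev_sq"]

# 12-hr window start offsets in hours relative to 0000 of day t
_WINDOW_STARTS = (-12, -8, -4, 0, 4, 8)


def wind_to_vector(speed, direction):
    """Convert (speed, from-direction) into (u, v) transport components.

    The returned vector points where the air is going:
    ``u = -speed*sin(dir)``, ``v = -speed*cos(dir)``, so a north wind
    (direction 0) gives (0, -speed).

    Parameters
    ----------
    speed : float or array, m/s, must be >= 0 (NaN allowed)
    direction : float or array, degrees in [0, 360)
    """
    speed = np.asarray(speed, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if np.any(speed[~np.isnan(speed)] < 0):
        raise ValueError("wind speed must be non-negative")
    rad = np.deg2rad(direction)
    u = -speed * np.sin(rad)
    v = -speed * np.cos(rad)
    return u, v


def recirculation_index(u, v, min_hours: int = MIN_WINDOW_HOURS) -> float:
    """Recirculation factor R = 1 - L/S for a window of hourly (u, v).

    NaN pairs are treated as missing hours; the sums run over present
    hours only.  Returns NaN when fewer than ``min_hours`` hours are
    present or when the wind run S is zero (dead calm).

    Raises
    ------
    ValueError
        If the window is empty.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if u.size == 0:
        raise ValueError("empty wind window")
    if u.shape != v.shape:
        raise ValueError("u and v must have the same length")
    ok = ~(np.isnan(u) | np.isnan(v))
    n_ok = int(ok.sum())
    if n_ok < min_hours:
        log.debug("recirculation window invalid: %d/%d hours present", n_ok, u.size)
        return np.nan
    uu, vv = u[ok], v[ok]
    speeds = np.hypot(uu, vv)
    S = speeds.sum()
    if S == 0.0:
        log.debug("recirculation window undefined: zero wind run")
        return np.nan
    L = np.hypot(uu.sum(), vv.sum())
    return 1.0 - L / S


def _hourly_arrays(met: pd.DataFrame):
    """Reindex hourly records onto a continuous hourly grid; return arrays."""
    ts = pd.DatetimeIndex(met["timestamp"])
    if not ts.is_monotonic_increasing or ts.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")
    full = pd.date_range(ts[0].floor("h"), ts[-1].floor("h"), freq="h")
    df = met.set_index(ts).reindex(full)
    u, v = wind_to_vector(df["ws"].to_numpy(), df["wd"].to_numpy())
    return full, u, v, df["rh"].to_numpy(dtype=float), df["ws"].to_numpy(dtype=float)


def _cum(x: np.ndarray) -> np.ndarray:
    """Cumulative sum over present values with a leading zero."""
    out = np.zeros(x.size + 1)
    np.cumsum(np.where(np.isnan(x), 0.0, x), out=out[1:])
    return out


def daily_features(met: pd.DataFrame, dates=None,
                   min_window_hours: int = MIN_WINDOW_HOURS,
                   min_rh_hours: int = MIN_RH_HOURS) -> pd.DataFrame:
    """Compute the daily model covariates for every coverable day.

    Parameters
    ----------
    met : DataFrame with columns ``timestamp, ws, wd, rh`` (hourly).
    dates : optional sequence of day labels to restrict to.

    Returns
    -------
    DataFrame indexed by date with columns ``mean_rh``, ``mean_rh_sq``,
    ``recirc12``, ``ws_2000_prev``, ``ws_2000_prev_sq``.  A day's
    ``recirc12`` is missing if any of its six 12-hr windows is invalid
    (fewer than ``min_window_hours`` present hours, or zero wind run):
    averaging only the windier windows would bias the index toward calm
    conditions.  ``mean_rh`` averages the 24 sampling-window hours (2000
    day t-1 to 2000 day t) and tolerates up to 25% missing hours.
    ``ws_2000_prev`` is the single 2000-hours reading of day t-1.
    """
    full, u, v, rh, ws = _hourly_arrays(met)
    n = full.size
    speed = np.hypot(u, v)

    cu, cv, cs = _cum(u), _cum(v), _cum(speed)
    cn = _cum((~np.isnan(speed)).astype(float))
    crh, crn = _cum(rh), _cum((~np.isnan(rh)).astype(float))

    # index of hour 0000 for each candidate day t: need 1200 t-1 .. 2000 t
    day0 = full[0].normalize()
    all_days = pd.date_range(day0, full[-1].normalize(), freq="D")
    rows = {}
    for day in all_days:
        i0 = int((day - full[0]) / pd.Timedelta(hours=1))
        if i0 - 12 < 0 or i0 + 20 > n:
            continue  # hourly coverage 1200 t-1 .. 2000 t unavailable
        # six 12-hr recirculation windows
        r_vals = []
        for off in _WINDOW_STARTS:
            a, b = i0 + off, i0 + off + 12
            cnt = cn[b] - cn[a]
            if cnt < min_window_hours:
                r_vals.append(np.nan)
                continue
            S = cs[b] - cs[a]
            if S == 0.0:
                r_vals.append(np.nan)
                continue
            L = np.hypot(cu[b] - cu[a], cv[b] - cv[a])
            r_vals.append(1.0 - L / S)
        r_vals = np.asarray(r_vals)
        recirc12 = np.nan if np.isnan(r_vals).any() else float(r_vals.mean())

        # 24-hr RH over the sampling window 2000 t-1 .. 2000 t
        a, b = i0 - 4, i0 + 20
        rh_cnt = crn[b] - crn[a]
        mean_rh = (crh[b] - crh[a]) / rh_cnt if rh_cnt >= min_rh_hours else np.nan

        ws_prev = ws[i0 - 4]  # 2000 hours of day t-1
        rows[day] = (mean_rh, mean_rh ** 2, recirc12, ws_prev, ws_prev ** 2)

    feats = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_COLUMNS)
    feats.index.name = "date"
    if dates is not None:
        feats = feats.reindex(pd.DatetimeIndex(dates))
    return feats


def daily_recirc12(date, met: pd.DataFrame, min_window_hours: int = MIN_WINDOW_HOURS) -> float:
    """Mean of the six 12-hr recirculation indices for measurement day ``date``."""
    feats = daily_features(met, min_window_hours=min_window_hours)
    day = pd.Timestamp(date).normalize()
    if day not in feats.index:
        log.warning("no hourly coverage for day %s", day.date())
        return np.nan
    return float(feats.loc[day, "recirc12"])


def read_met(path) -> pd.DataFrame:
    """Read an hourly meteorology CSV (timestamp, ws, wd, rh, temp)."""
    return pd.read_csv(path, parse_dates=["timestamp"])


def write_features(feats: pd.DataFrame, path) -> None:
    feats.to_csv(path, index_label="date")
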