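"""Between-site agreement and spatial heterogeneity statistics.

Given a sites x days concentration matrix for one analyte and season,
this module computes pairwise site regressions, coefficients of
divergence (COD), daily spatial coefficients of variation (CV), and the
spatial Pearson correlation table between a central monitor and the rest
of the network.

The COD between two sites over p valid paired days is

    COD = sqrt( (1/p) * sum_i ((x_i - y_i) / (x_i + y_i))^2 )

which is 0 for identical series and approaches 1 for maximally divergent
ones.  For series in constant ratio r it reduces to |r - 1| / (r + 1):
a site running 33% higher than another gives COD 0.14, one 133% higher
gives 0.40.

The daily spatial CV is the across-site standard deviation divided by
the across-site mean, computed only on days with enough reporting sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seasons import season_mask

log = logging.getLogger(__name__)

#: concentration substituted for zeros before log transforms (the field
#: blank level, EU/m^3)
ZERO_SUBSTITUTE = 0.01


def snapshot(conc: pd.DataFrame, analyte: str, season: str | None = None) -> pd.DataFrame:
    """Dates x sites value matrix for one analyte, season-filtered.

    ``season``: 'dry' (May–Oct), 'wet' (Nov–Mar; April in neither) or
    None for all days.
    """
    sel = conc[conc["analyte"] == analyte]
    if sel.empty:
        raise ValueError(f"no rows for analyte {analyte!r}")
    mat = sel.pivot_table(index="date", columns="site", values="value",
                          aggfunc="first", dropna=False)
    mat.index = pd.DatetimeIndex(mat.index)
    mat = mat.sort_index()
    mask = season_mask(mat.index, season)
    return mat.loc[mask.to_numpy()]


@dataclass
class PairStats:
    """Agreement statistics for one site pair."""
    x_site: str
    y_site: str
    n: int
    slope: float
    intercept: float
    r2: float
    cod: float


def pair_regression(snap: pd.DataFrame, x_site: str, y_site: str,
                    min_pairs: int = 3) -> PairStats | None:
    """OLS of y-site on x-site over shared days, with r^2 and COD.

    Returns None (logged) with fewer than ``min_pairs`` paired days or a
    degenerate (constant) predictor.
    """
    pair = snap[[x_site, y_site]].dropna()
    if len(pair) < min_pairs:
        log.warning("pair %s~%s: only %d paired days", y_site, x_site, len(pair))
        return None
    x = pair[x_site].to_numpy()
    y = pair[y_site].to_numpy()
    if np.ptp(x) == 0:
        log.warning("pair %s~%s: constant predictor", y_site, x_site)
        return None
    res = stats.linregress(x, y)
    return PairStats(x_site, y_site, len(pair), float(res.slope),
                     float(res.intercept), float(res.rvalue ** 2),
                     cod(snap, x_site, y_site))


def cod(snap: pd.DataFrame, x_site: str, y_site: str) -> float:
    """Coefficient of divergence between two sites' daily series.

    Paired days where both values are zero contribute no term (0/0);
    days where exactly one value is zero contribute a term of 1.
    Returns NaN when no valid paired day exists.
    """
    pair = snap[[x_site, y_site]].dropna()
    x = pair[x_site].to_numpy(dtype=float)
    y = pair[y_site].to_numpy(dtype=float)
    denom = x + y
    valid = denom > 0
    if not valid.any():
        log.warning("cod %s~%s: no valid paired days", x_site, y_site)
        return np.nan
    terms = ((x[valid] - y[valid]) / denom[valid]) ** 2
    return float(np.sqrt(terms.mean()))


def cod_for_ratio(r: float) -> float:
    """COD of two series in constant ratio r: |r - 1| / (r + 1)."""
    if r <= 0:
        raise ValueError("ratio must be positive")
    return abs(r - 1.0) / (r + 1.0)


def ratio_for_cod(c: float) -> float:
    """Inverse of :func:`cod_for_ratio` on [0, 1): r = (1 + c) / (1 - c)."""
    if not 0 <= c < 1:
        raise ValueError("COD must be in [0, 1)")
    return (1.0 + c) / (1.0 - c)


def daily_cv(snap: pd.DataFrame, min_sites: int = 4, ddof: int = 1):
    """Per-day spatial CV (across-site SD / mean) and its summary.

    Days with fewer than ``min_sites`` reporting sites are skipped; days
    whose across-site mean is zero are undefined and skipped with a log
    entry.  ``ddof=1`` uses the sample standard deviation (switchable).

    Returns ``(cv_series, summary_dict)`` with summary keys
    ``median, min, max, n_days``.
    """
    if min_sites < 2:
        raise ValueError("min_sites must be at least 2")
    out = {}
    for day, row in snap.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if len(vals) < min_sites:
            continue
        mean = vals.mean()
        if mean == 0:
            log.warning("daily_cv: zero mean on %s", day)
            continue
        out[day] = vals.std(ddof=ddof) / mean
    cv = pd.Series(out, dtype=float)
    summary = {
        "median": float(cv.median()) if len(cv) else np.nan,
        "min": float(cv.min()) if len(cv) else np.nan,
        "max": float(cv.max()) if len(cv) else np.nan,
        "n_days": len(cv),
    }
    return cv, summary


def classify_correlation(r: float) -> str:
    """Band label from r^2: high (>= 0.8), moderate (0.5–0.8), poor (< 0.5)."""
    r2 = r * r
    if r2 >= 0.8:
        return "high"
    if r2 >= 0.5:
        return "moderate"
    return "poor"


def spatial_correlation(snapshots: dict, central: str,
                        min_pairs: int = 3) -> pd.DataFrame:
    """Pearson correlation of each site with the central site, per analyte.

    ``snapshots`` maps analyte name -> dates x sites matrix.  Returns a
    sites x analytes table with an ``Average`` row (mean over sites);
    degenerate (constant) or short series give NaN entries.
    """
    table = {}
    for analyte, snap in snapshots.items():
        if central not in snap.columns:
            raise ValueError(f"central site {central!r} absent from {analyte} snapshot")
        col = {}
        for site in snap.columns:
            if site == central:
                continue
            pair = snap[[central, site]].dropna()
            if len(pair) < min_pairs:
                col[site] = np.nan
                continue
            a = pair[central].to_numpy()
            b = pair[site].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                log.warning("spatial_correlation %s/%s: degenerate series", analyte, site)
                col[site] = np.nan
                continue
            col[site] = float(stats.pearsonr(a, b).statistic)
        table[analyte] = col
    df = pd.DataFrame(table)
    df.loc["Average"] = df.mean(axis=0)
    return df


def geometric_mean(values, zero_substitute: float = ZERO_SUBSTITUTE) -> float:
    """Geometric mean with zeros replaced by the field-blank level."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size == 0:
        return np.nan
    v = np.where(v <= 0, zero_substitute, v)
    return float(np.exp(np.mean(np.log(v))))


def monthly_summary(series: pd.Series) -> pd.DataFrame:
    """Monthly distribution table: geometric mean, median, quartiles, extremes."""
    s = pd.Series(series).dropna()
    s.index = pd.DatetimeIndex(s.index)
    groups = s.groupby(s.index.month)
    rows = {}
    for month, vals in groups:
        rows[month] = {
            "geometric_mean": geometric_mean(vals),
            "median": float(vals.median()),
            "maximum": float(vals.max()),
            "p75": float(vals.quantile(0.75)),
            "p25": float(vals.quantile(0.25)),
            "minimum": float(vals.min()),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "month"
    return out
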