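"""Daily endotoxin concentration model: a lagged nonlinear OLS fit.

The model describes the daily mean endotoxin concentration E(t) at a
monitoring site during the dry season (May–October) as

    E(t) = b0 + b1 E(t-1) + b2 E(t-1)^3 + b3 RH(t) + b4 RH(t)^2
         + b5 R12(t) + b6 WS(t-1) + b7 WS(t-1)^2 + eps(t)

where RH is the 24-hr mean relative humidity over the sampling window,
R12 the 12-hr recirculation index (mean of six overlapping windows), and
WS the wind speed at 2000 hours of the previous day.  A single lag of
the response removes the serial correlation in the daily series; the
meteorological terms capture the association of stagnation and dry air
with elevated endotoxin.

The module follows the statsmodels idiom: build an
:class:`EndotoxinLagModel` from a daily series plus meteorological
features, call :meth:`~EndotoxinLagModel.fit` to obtain an
:class:`EndotoxinLagResults` with coefficients, standard errors,
R-squared and residual diagnostics.  Model selection over a candidate
term library uses cross-validated deletion / substitution / addition
moves, a cross-validation surrogate for data-adaptive selection
algorithms of that family.

Before fitting, series are imputed: values above an outlier threshold
(default 20 EU/m^3) are set missing, and any missing day whose two
calendar neighbours are present is replaced by the neighbour mean;
longer gaps stay missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.stattools import acf as _acf

from .seasons import DRY_MONTHS

log = logging.getLogger(__name__)

#: transforms available to the model, keyed by term name; each maps
#: (lagged response, features frame) -> column.  Unknown term names fall
#: back to identity columns of the features frame, which is how extra
#: candidate covariates enter model selection.
TERM_TRANSFORMS = {
    "intercept": lambda lag, f: pd.Series(1.0, index=f.index),
    "lag": lambda lag, f: lag,
    "lag_cubed": lambda lag, f: lag ** 3,
    "mean_rh": lambda lag, f: f["mean_rh"],
    "mean_rh_sq": lambda lag, f: f["mean_rh"] ** 2,
    "recirc12": lambda lag, f: f["recirc12"],
    "ws_2000_prev": lambda lag, f: f["ws_2000_prev"],
    "ws_2000_prev_sq": lambda lag, f: f["ws_2000_prev"] ** 2,
}

DEFAULT_TERMS = tuple(TERM_TRANSFORMS)


@dataclass(frozen=True)
class TemporalModelSpec:
    """Term list (fixed transforms) and season restriction of the model."""
    terms: tuple = DEFAULT_TERMS
    months: frozenset = frozenset(DRY_MONTHS)

    def __post_init__(self):
        if len(self.terms) == 0:
            raise ValueError("spec must contain at least one term")


def impute_series(series: pd.Series, outlier_threshold: float = 20.0):
    """Outlier removal followed by singleton-gap imputation.

    Values above ``outlier_threshold`` are set missing; then every
    missing day preceded *and* followed by a present calendar day is
    replaced by the mean of those two neighbours.  Longer gaps remain
    missing.  Present, non-outlier values are never altered.

    Returns ``(imputed, log)`` where ``imputed`` is reindexed onto the
    full daily calendar and ``log`` lists ``(date, rule)`` entries with
    rule in {"outlier", "singleton"}.
    """
    if outlier_threshold <= 0:
        raise ValueError("outlier threshold must be positive")
    if series.empty:
        raise ValueError("series is empty")
    s = series.copy()
    s.index = pd.DatetimeIndex(s.index)
    s = s.reindex(pd.date_range(s.index.min(), s.index.max(), freq="D"))
    entries = []
    outliers = s > outlier_threshold
    for date in s.index[outliers]:
        entries.append((date, "outlier"))
    s[outliers] = np.nan
    present = s.notna().to_numpy()
    vals = s.to_numpy(dtype=float)
    missing = np.flatnonzero(~present)
    for i in missing:
        if 0 < i < len(vals) - 1 and present[i - 1] and present[i + 1]:
            vals[i] = 0.5 * (vals[i - 1] + vals[i + 1])
            entries.append((s.index[i], "singleton"))
    out = pd.Series(vals, index=s.index, name=series.name)
    return out, entries


def _term_column(name: str, lag: pd.Series, features: pd.DataFrame) -> pd.Series:
    if name in TERM_TRANSFORMS:
        return TERM_TRANSFORMS[name](lag, features)
    if name in features.columns:
        return features[name]
    raise KeyError(f"unknown model term {name!r}")


def build_design(series: pd.Series, features: pd.DataFrame,
                 spec: TemporalModelSpec | None = None):
    """Assemble the response and covariate matrix for the season-restricted fit.

    The lagged response is built on the full calendar *before* the season
    filter is applied to the response rows, so the first dry-season day
    may use the preceding April value as its lag.  Rows with any missing
    entry are dropped and counted.

    Returns ``(y, X, n_dropped)`` with matching date indexes.
    """
    if spec is None:
        spec = TemporalModelSpec()
    s = series.copy()
    s.index = pd.DatetimeIndex(s.index)
    full = pd.date_range(s.index.min(), s.index.max(), freq="D")
    s = s.reindex(full)
    feats = features.reindex(full)
    lag = s.shift(1)
    in_season = pd.Series(full.month.isin(list(spec.months)), index=full)
    cols = {name: _term_column(name, lag, feats) for name in spec.terms}
    design = pd.DataFrame(cols, index=full)
    design["__y__"] = s
    design = design.loc[in_season]
    n_season = len(design)
    design = design.dropna()
    if design.empty:
        raise ValueError("no usable rows after season filter and missingness drop")
    y = design.pop("__y__")
    return y, design, n_season - len(design)


class EndotoxinLagModel:
    """Lagged daily-concentration model bound to one site's data.

    Parameters
    ----------
    series : pd.Series
        Daily concentrations indexed by date (EU/m^3 for endotoxin).
    features : pd.DataFrame
        Daily meteorological covariates (see :mod:`endoair.met`).
    spec : TemporalModelSpec, optional
        Term list; defaults to the full eight-term model.
    outlier_threshold : float
        Concentrations above this are treated as outliers and imputed.
    impute : bool
        Apply the imputation rule before building the design (default).
    """

    def __init__(self, series: pd.Series, features: pd.DataFrame,
                 spec: TemporalModelSpec | None = None,
                 outlier_threshold: float = 20.0, impute: bool = True):
        self.spec = spec if spec is not None else TemporalModelSpec()
        if impute:
            series, self.imputation_log = impute_series(series, outlier_threshold)
        else:
            self.imputation_log = []
        self.series = series
        self.features = features
        self.endog, self.exog, self.n_dropped = build_design(series, features, self.spec)

    @classmethod
    def from_dataframe(cls, conc: pd.DataFrame, site: str, features: pd.DataFrame,
                       analyte: str = "endotoxin", **kwargs) -> "EndotoxinLagModel":
        """Build from a long concentration table (site, date, analyte, value)."""
        sel = conc[(conc["site"] == site) & (conc["analyte"] == analyte)]
        if sel.empty:
            raise ValueError(f"no rows for site {site!r}, analyte {analyte!r}")
        series = sel.set_index(pd.DatetimeIndex(sel["date"]))["value"].sort_index()
        return cls(series, features, **kwargs)

    def fit(self, robust: bool = False) -> "EndotoxinLagResults":
        """Ordinary least squares fit; robust=True switches to HC1 errors."""
        X = self.exog.to_numpy(dtype=float)
        if X.shape[0] <= X.shape[1]:
            raise ValueError("fewer rows than model terms")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_terms(self.exog)
            raise ValueError(f"rank-deficient design; collinear terms: {bad}")
        res = sm.OLS(self.endog.to_numpy(), X).fit(
            cov_type="HC1" if robust else "nonrobust")
        return EndotoxinLagResults(self, res)


def _collinear_terms(exog: pd.DataFrame) -> list:
    """Name the columns whose removal restores full rank."""
    bad = []
    X = exog.to_numpy(dtype=float)
    full = np.linalg.matrix_rank(X)
    for i, name in enumerate(exog.columns):
        if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == full:
            bad.append(name)
    return bad


class EndotoxinLagResults:
    """Fit results: coefficients, uncertainties, diagnostics.

    Attributes mirror statsmodels results, with term-named pandas
    indexes: ``params``, ``bse``, ``pvalues``, ``rsquared``,
    ``rsquared_adj``, ``nobs``, ``resid`` (date-indexed), plus
    ``n_imputed`` from the imputation stage.
    """

    def __init__(self, model: EndotoxinLagModel, sm_results):
        self.model = model
        self._sm = sm_results
        names = list(model.exog.columns)
        self.params = pd.Series(sm_results.params, index=names)
        self.bse = pd.Series(sm_results.bse, index=names)
        self.pvalues = pd.Series(sm_results.pvalues, index=names)
        self.rsquared = float(sm_results.rsquared)
        self.rsquared_adj = float(sm_results.rsquared_adj)
        self.nobs = int(sm_results.nobs)
        self.n_imputed = len(model.imputation_log)
        self.resid = pd.Series(sm_results.resid, index=model.endog.index)

    def summary(self):
        """statsmodels-style summary table with term names."""
        return self._sm.summary(xname=list(self.params.index))

    def check_autocorrelation(self, nlags: int = 10) -> "AutocorrelationCheck":
        return check_autocorrelation(self.resid, nlags=nlags)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, p) as a DataFrame."""
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "p": self.pvalues})


@dataclass
class AutocorrelationCheck:
    """Residual autocorrelations at lags 1..K with a white-noise verdict.

    ``acf`` carries the per-lag values and ``bound`` the marginal 95%
    band +/-1.96/sqrt(n) for plotting; ``ok`` is an omnibus Ljung-Box
    verdict at the 5% level over all K lags (testing each lag against
    the marginal band would falsely flag ~40% of genuinely white series
    at K = 10).
    """
    acf: pd.Series
    bound: float                  # +/- 1.96 / sqrt(n), per-lag band
    lb_pvalue: float              # Ljung-Box p at lag K
    ok: bool                      # lb_pvalue >= 0.05


def check_autocorrelation(resid: pd.Series, nlags: int = 10) -> AutocorrelationCheck:
    """Lag-1..K residual autocorrelations with a Ljung-Box whiteness flag."""
    r = pd.Series(resid).dropna()
    n = len(r)
    if n < 10:
        raise ValueError("need at least 10 residuals")
    if np.std(r.to_numpy()) == 0:
        raise ValueError("autocorrelation undefined for constant residuals")
    vals = _acf(r.to_numpy(), nlags=nlags, fft=True)[1:]
    bound = 1.96 / np.sqrt(n)
    series = pd.Series(vals, index=pd.RangeIndex(1, nlags + 1, name="lag"))
    lb = acorr_ljungbox(r.to_numpy(), lags=[nlags])
    p = float(lb["lb_pvalue"].iloc[0])
    return AutocorrelationCheck(series, bound, p, bool(p >= 0.05))


# ---------------------------------------------------------------------------
# cross-validated move-based model selection
# ---------------------------------------------------------------------------

def _cv_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Contiguous time-ordered blocks; the seed rotates the block offset."""
    offset = int(np.random.default_rng(seed).integers(0, n))
    return (((np.arange(n) + offset) % n) * folds) // n


def _cv_loss(y: np.ndarray, X: np.ndarray, cols: list, fold_id: np.ndarray,
             folds: int) -> float:
    sse = 0.0
    Xs = X[:, cols]
    for k in range(folds):
        test = fold_id == k
        train = ~test
        beta, *_ = np.linalg.lstsq(Xs[train], y[train], rcond=None)
        err = y[test] - Xs[test] @ beta
        sse += float(err @ err)
    return sse / len(y)


def select_model_cv(series: pd.Series, features: pd.DataFrame, candidates,
                    folds: int = 5, seed: int = 0, start=("intercept",),
                    min_rel_improve: float = 0.01,
                    months=frozenset(DRY_MONTHS)):
    """Greedy deletion / substitution / addition search under V-fold CV loss.

    Starting from ``start`` (default intercept-only), each step evaluates
    every single-term deletion, addition of an unused candidate, and
    substitution of an included term by an unused one, and accepts the
    move with the lowest V-fold cross-validated squared-error loss if it
    improves on the current loss by at least ``min_rel_improve``
    (relative).  Folds are contiguous blocks of the time-ordered rows
    (rotated by the seed), so validation respects the serial dependence
    of daily data.

    Returns ``(spec, trace)``; the trace lists (move, terms, cv_loss)
    per accepted step, with the starting state first.
    """
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("candidate library is empty")
    start = [t for t in start if t in candidates] or [candidates[0]]
    full_spec = TemporalModelSpec(terms=tuple(candidates), months=frozenset(months))
    y, X, _ = build_design(series, features, full_spec)
    yv = y.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    n = len(yv)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    fold_id = _cv_folds(n, folds, seed)
    index = {t: i for i, t in enumerate(candidates)}

    current = list(start)
    loss = _cv_loss(yv, Xv, [index[t] for t in current], fold_id, folds)
    trace = [("start", tuple(current), loss)]
    while True:
        moves = []
        unused = [t for t in candidates if t not in current]
        if len(current) > 1:
            for t in current:
                moves.append(("delete", [u for u in current if u != t]))
        for t in unused:
            moves.append(("add", current + [t]))
        for t in current:
            for u in unused:
                moves.append(("substitute", [u if v == t else v for v in current]))
        scored = [(move, terms,
                   _cv_loss(yv, Xv, [index[t] for t in terms], fold_id, folds))
                  for move, terms in moves]
        if not scored:
            break
        best_loss = min(s[2] for s in scored)
        # near-ties resolved toward parsimony: among moves within the
        # acceptance margin of the best CV loss, take the smallest spec
        # (a deletion beats a comparable substitution that would smuggle
        # in a spurious term on fold noise)
        near = [s for s in scored if s[2] <= best_loss * (1.0 + min_rel_improve)]
        best = min(near, key=lambda s: (len(s[1]), s[2]))
        if best[2] >= loss * (1.0 - min_rel_improve):
            break
        _, current, loss = best
        trace.append((best[0], tuple(current), loss))
    order = [t for t in candidates if t in current]
    return TemporalModelSpec(terms=tuple(order), months=frozenset(months)), trace


def transfer_fit(spec: TemporalModelSpec, series: pd.Series,
                 features: pd.DataFrame, outlier_threshold: float = 20.0,
                 impute: bool = True, robust: bool = False) -> EndotoxinLagResults:
    """Refit the same variable forms on another site's data.

    All coefficients, including the intercept, are re-estimated; only
    the transforms carry over, so comparing adjusted R-squared across
    sites asks whether the same physical variables explain daily
    variation elsewhere.
    """
    model = EndotoxinLagModel(series, features, spec=spec,
                              outlier_threshold=outlier_threshold, impute=impute)
    return model.fit(robust=robust)
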