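"""Imputation, design assembly, OLS fitting, selection, and transfer."""

import numpy as np
import pandas as pd
import pytest

import endoair as ea
from endoair.temporal import (DEFAULT_TERMS, EndotoxinLagModel,
                              TemporalModelSpec, build_design,
                              check_autocorrelation, impute_series,
                              select_model_cv, transfer_fit)


def _series(values, start="2002-06-01"):
    return pd.Series(values, index=pd.date_range(start, periods=len(values)),
                     dtype=float)


class TestImputeSeries:
    def test_singleton_gap_filled_with_neighbour_mean(self):
        out, log = impute_series(_series([2, np.nan, 4]))
        assert out.iloc[1] == pytest.approx(3.0)
        assert log == [(out.index[1], "singleton")]

    def test_longer_gaps_left_missing(self):
        out, log = impute_series(_series([2, np.nan, np.nan, 4]))
        assert np.isnan(out.iloc[1]) and np.isnan(out.iloc[2])
        assert log == []

    def test_outlier_flagged_then_imputed(self):
        out, log = impute_series(_series([3, 25, 4]), outlier_threshold=20.0)
        assert out.iloc[1] == pytest.approx(3.5)
        rules = {rule for _, rule in log}
        assert rules == {"outlier", "singleton"}

    def test_present_values_never_altered(self):
        vals = [1.0, 2.5, np.nan, 4.0, 19.9]
        out, _ = impute_series(_series(vals))
        for i in (0, 1, 3, 4):
            assert out.iloc[i] == vals[i]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            impute_series(_series([1.0]), outlier_threshold=0.0)


def _features(index, rh=30.0, r12=0.1, ws=1.5):
    return pd.DataFrame({"mean_rh": rh, "mean_rh_sq": rh ** 2, "recirc12": r12,
                         "ws_2000_prev": ws, "ws_2000_prev_sq": ws ** 2},
                        index=index)


class TestBuildDesign:
    def test_lag_transforms_and_season_restriction(self):
        idx = pd.date_range("2002-04-28", periods=10)
        s = pd.Series([1, 2, 2, 3, 2, np.nan, 2, 4, 3, 2], index=idx, dtype=float)
        y, X, dropped = build_design(s, _features(idx))
        # May rows only; row for the NaN day and the day lacking a lag drop out
        assert (y.index.month == 5).all()
        # lag for May 1 comes from April 30
        assert X.loc["2002-05-01", "lag"] == pytest.approx(2.0)
        assert X.loc["2002-05-05", "lag_cubed"] == pytest.approx(8.0)
        # manual count: May rows are days 3..9 (7 rows); the NaN response row
        # and its successor (missing lag) drop -> 5 usable rows
        assert len(y) == 5
        assert dropped == 2

    def test_november_day_excluded(self):
        idx = pd.date_range("2002-10-29", periods=6)
        s = pd.Series(np.arange(6.0), index=idx)
        y, X, _ = build_design(s, _features(idx))
        assert not (y.index.month == 11).any()

    def test_empty_design_rejected(self):
        idx = pd.date_range("2002-01-01", periods=8)  # wet season only
        s = pd.Series(np.ones(8), index=idx)
        with pytest.raises(ValueError):
            build_design(s, _features(idx))


class TestFit:
    def _simulated(self, seed=5, n_days=400):
        met = ea.gen_met(n_days, "2002-05-01", seed=seed, season_mode="dry")
        f = ea.daily_features(met)
        s = ea.simulate_endotoxin_series(f, ea.DEFAULT_TEMPORAL_COEFFS, 1.0,
                                         np.random.default_rng(seed + 1))
        return s, f

    def test_noiseless_coefficients_recovered_exactly(self):
        met = ea.gen_met(300, "2002-05-01", seed=2, season_mode="dry")
        f = ea.daily_features(met)
        s = ea.simulate_endotoxin_series(f, ea.DEFAULT_TEMPORAL_COEFFS, 0.0,
                                         np.random.default_rng(0))
        spec = TemporalModelSpec(months=frozenset(range(1, 13)))
        fit = EndotoxinLagModel(s, f, spec=spec, impute=False).fit()
        for name, truth in ea.DEFAULT_TEMPORAL_COEFFS.items():
            assert fit.params[name] == pytest.approx(truth, rel=1e-6, abs=1e-9)
        assert fit.rsquared > 0.999999

    def test_noisy_estimates_within_three_se_of_truth(self):
        s, f = self._simulated(seed=11)
        spec = TemporalModelSpec(months=frozenset(range(1, 13)))
        fit = EndotoxinLagModel(s, f, spec=spec, impute=False).fit()
        for name, truth in ea.DEFAULT_TEMPORAL_COEFFS.items():
            assert abs(fit.params[name] - truth) < 3 * fit.bse[name]

    def test_residuals_orthogonal_to_design(self):
        s, f = self._simulated(seed=3)
        spec = TemporalModelSpec(months=frozenset(range(1, 13)))
        model = EndotoxinLagModel(s, f, spec=spec, impute=False)
        fit = model.fit()
        X = model.exog.to_numpy()
        inner = X.T @ fit.resid.to_numpy()
        scale = np.abs(X).sum(axis=0) * fit.resid.abs().max()
        assert (np.abs(inner) < 1e-6 * np.maximum(scale, 1.0)).all()
        assert abs(fit.resid.mean()) < 1e-8 * fit.resid.std()

    def test_constant_response_gives_zero_slopes(self):
        idx = pd.date_range("2002-05-01", periods=40)
        f = _features(idx)
        f["mean_rh"] = np.random.default_rng(0).uniform(20, 40, len(idx))
        f["mean_rh_sq"] = f["mean_rh"] ** 2
        s = pd.Series(2.0, index=idx)
        spec = TemporalModelSpec(terms=("intercept", "mean_rh"))
        fit = EndotoxinLagModel(s, f, spec=spec, impute=False).fit()
        assert fit.params["mean_rh"] == pytest.approx(0.0, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(2.0)

    def test_rank_deficient_design_names_collinear_terms(self):
        idx = pd.date_range("2002-05-01", periods=60)
        f = _features(idx)
        s = pd.Series(np.random.default_rng(1).uniform(1, 3, 60), index=idx)
        # constant features make rh collinear with the intercept
        spec = TemporalModelSpec(terms=("intercept", "mean_rh"))
        with pytest.raises(ValueError, match="collinear"):
            EndotoxinLagModel(s, f, spec=spec, impute=False).fit()

    def test_summary_and_frame_report(self):
        s, f = self._simulated(seed=9, n_days=300)
        spec = TemporalModelSpec(months=frozenset(range(1, 13)))
        fit = EndotoxinLagModel(s, f, spec=spec, impute=False).fit()
        assert "recirc12" in str(fit.summary())
        frame = fit.to_frame()
        assert list(frame.columns) == ["estimate", "se", "p"]
        assert 0.0 <= fit.rsquared <= 1.0
        assert fit.nobs == len(fit.resid)


class TestAutocorrelation:
    def test_white_noise_usually_clean(self):
        flags = []
        for seed in range(20):
            resid = pd.Series(np.random.default_rng(seed).normal(0, 1, 500))
            flags.append(check_autocorrelation(resid).ok)
        assert np.mean(flags) >= 0.9

    def test_ar1_residuals_flagged(self):
        rng = np.random.default_rng(0)
        x = np.empty(500)
        prev = 0.0
        for t in range(500):
            prev = 0.8 * prev + rng.normal()
            x[t] = prev
        chk = check_autocorrelation(pd.Series(x))
        assert not chk.ok
        assert chk.acf.loc[1] > chk.bound

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            check_autocorrelation(pd.Series(np.ones(100)))
        with pytest.raises(ValueError):
            check_autocorrelation(pd.Series(np.arange(5.0)))


class TestSelection:
    def _data(self, seed, n_days=500, n_noise=5):
        met = ea.gen_met(n_days, "2002-05-01", seed=seed, season_mode="dry")
        f = ea.daily_features(met)
        rng = np.random.default_rng(seed + 1000)
        s = ea.simulate_endotoxin_series(f, ea.DEFAULT_TEMPORAL_COEFFS, 1.0, rng)
        for k in range(n_noise):
            f[f"noise{k}"] = rng.normal(0, 1, len(f))
        return s, f

    def test_intercept_only_library(self):
        s, f = self._data(0)
        spec, trace = select_model_cv(s, f, ["intercept"], seed=0,
                                      months=frozenset(range(1, 13)))
        assert spec.terms == ("intercept",)
        assert len(trace) == 1

    def test_selected_loss_never_worse_than_start(self):
        s, f = self._data(1)
        cands = list(DEFAULT_TERMS) + [f"noise{k}" for k in range(5)]
        _, trace = select_model_cv(s, f, cands, seed=1, start=DEFAULT_TERMS,
                                   months=frozenset(range(1, 13)))
        assert trace[-1][2] <= trace[0][2]

    def test_pure_noise_covariates_usually_excluded(self):
        hits = 0
        reps = 20
        for r in range(reps):
            s, f = self._data(300 + r)
            cands = list(DEFAULT_TERMS) + [f"noise{k}" for k in range(5)]
            spec, _ = select_model_cv(s, f, cands, seed=r, start=DEFAULT_TERMS,
                                      months=frozenset(range(1, 13)))
            hits += not any(t.startswith("noise") for t in spec.terms)
        assert hits / reps >= 0.8

    def test_empty_library_rejected(self):
        s, f = self._data(2)
        with pytest.raises(ValueError):
            select_model_cv(s, f, [], seed=0)


class TestTransfer:
    def _site_pair(self, seed=4, offset=2.0):
        met = ea.gen_met(500, "2002-05-01", seed=seed, season_mode="dry")
        f = ea.daily_features(met)
        rng = np.random.default_rng(seed + 1)
        s1 = ea.simulate_endotoxin_series(f, ea.DEFAULT_TEMPORAL_COEFFS, 1.0, rng)
        s2 = s1 + offset
        return s1, s2, f

    def test_same_site_twice_identical(self):
        s1, _, f = self._site_pair()
        spec = TemporalModelSpec(months=frozenset(range(1, 13)))
        a = transfer_fit(spec, s1, f, impute=False)
        b = transfer_fit(spec, s1, f, impute=False)
        pd.testing.assert_series_equal(a.params, b.params)

    def test_constant_offset_moves_intercept_not_slopes(self):
        # for a purely linear lag model (no cubic), a site running c higher
        # shifts the refit intercept by exactly c*(1 - b1); slopes carry over
        met = ea.gen_met(500, "2002-05-01", seed=4, season_mode="dry")
        f = ea.daily_features(met)
        coeffs = dict(ea.DEFAULT_TEMPORAL_COEFFS, lag_cubed=0.0, intercept=1.6)
        s1 = ea.simulate_endotoxin_series(f, coeffs, 1.0,
                                          np.random.default_rng(5))
        s2 = s1 + 2.0
        spec = TemporalModelSpec(
            terms=tuple(t for t in DEFAULT_TERMS if t != "lag_cubed"),
            months=frozenset(range(1, 13)))
        f1 = transfer_fit(spec, s1, f, impute=False)
        f2 = transfer_fit(spec, s2, f, impute=False)
        shift = f2.params["intercept"] - f1.params["intercept"]
        assert shift == pytest.approx(2.0 * (1 - f1.params["lag"]), rel=1e-6)
        for slope in ("lag", "recirc12", "ws_2000_prev", "mean_rh"):
            assert f2.params[slope] == pytest.approx(f1.params[slope], abs=1e-9)

    def test_transfer_fit_quality_comparable(self):
        # two sites from the same generating process: adjusted R^2 close
        met = ea.gen_met(500, "2002-05-01", seed=8, season_mode="dry")
        f = ea.daily_features(met)
        s1 = ea.simulate_endotoxin_series(f, ea.DEFAULT_TEMPORAL_COEFFS, 1.0,
                                          np.random.default_rng(1))
        s2 = ea.simulate_endotoxin_series(f, ea.DEFAULT_TEMPORAL_COEFFS, 1.0,
                                          np.random.default_rng(2))
        spec = TemporalModelSpec(months=frozenset(range(1, 13)))
        r1 = transfer_fit(spec, s1, f, impute=False)
        r2 = transfer_fit(spec, s2, f, impute=False)
        assert abs(r1.rsquared_adj - r2.rsquared_adj) < 0.1


class TestFromDataFrame:
    def test_imputation_feeds_the_fit(self, dataset):
        model = EndotoxinLagModel.from_dataframe(dataset.conc, "CENTRAL",
                                                 dataset.features)
        fit = model.fit()
        assert fit.n_imputed >= 2  # the forced outlier + singleton gap at least
        assert fit.nobs > 50
        assert (model.endog.index.month >= 5).all()
        assert (model.endog.index.month <= 10).all()

    def test_unknown_site_rejected(self, dataset):
        with pytest.raises(ValueError):
            EndotoxinLagModel.from_dataframe(dataset.conc, "NOPE", dataset.features)
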