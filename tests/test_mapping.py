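"""IDW surfaces, period averaging, leave-one-out validation, tertile maps."""

import numpy as np
import pandas as pd
import pytest

import endoair as ea
from endoair.mapping import (GridSpec, average_maps, idw, loo_validate,
                             map_day, map_period, tertile_maps)


def _toy_sites(coords):
    return pd.DataFrame([(f"S{i}", x, y) for i, (x, y) in enumerate(coords)],
                        columns=["id", "x_km", "y_km"])


def _toy_snap(values_by_day, site_ids, start="2002-06-01"):
    idx = pd.date_range(start, periods=len(values_by_day))
    return pd.DataFrame(values_by_day, index=idx, columns=site_ids)


SIX = [(0, 0), (10, 0), (0, 10), (10, 10), (5, 9), (9, 5)]


class TestGridSpec:
    def test_default_domain_dimensions(self):
        g = GridSpec.centered(25.0, 30.0)
        assert (g.nx, g.ny) == (201, 241)
        assert g.spacing == 0.25
        X, Y = g.node_coords()
        assert X.min() == pytest.approx(0.0)
        assert Y.max() == pytest.approx(60.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 0, spacing=0.0)
        with pytest.raises(ValueError):
            GridSpec(0, 0, nx=0)


class TestIdw:
    def test_exact_interpolation_at_stations(self):
        xy = np.array(SIX, dtype=float)
        vals = np.arange(1.0, 7.0)
        out = idw(xy, vals, xy)
        assert np.allclose(out, vals)

    def test_bounded_by_input_extrema(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 10, (8, 2))
        vals = rng.uniform(1, 9, 8)
        targets = rng.uniform(-2, 12, (500, 2))
        out = idw(xy, vals, targets)
        assert np.isfinite(out).all()
        assert (out >= vals.min() - 1e-12).all()
        assert (out <= vals.max() + 1e-12).all()

    def test_equidistant_node_near_mean_of_near_pair(self):
        # node equidistant from stations with values 2 and 4; other stations
        # 100x farther contribute less than their inverse-square weight share
        xy = np.array([(4, 5), (6, 5), (500, 500), (-500, 500),
                       (500, -500), (-500, -500)], dtype=float)
        vals = np.array([2.0, 4.0, 9.0, 9.0, 9.0, 9.0])
        out = idw(xy, vals, np.array([[5.0, 5.0]]))[0]
        w_far = 4 * (1 / 700.0 ** 2)
        w_near = 2 * 1.0
        bound = (9.0 - 3.0) * w_far / (w_near + w_far)
        assert abs(out - 3.0) <= bound + 1e-12


class TestMapDay:
    def test_uniform_input_gives_uniform_surface(self):
        sites = _toy_sites(SIX)
        snap = _toy_snap([[4.0] * 6], sites["id"])
        grid = GridSpec(0, 0, spacing=1.0, nx=11, ny=11)
        m = map_day(snap.iloc[0], sites, grid)
        assert np.allclose(m.values, 4.0)
        assert m.n_contributing == 6

    def test_node_at_station_takes_station_value(self):
        sites = _toy_sites(SIX)
        snap = _toy_snap([[1, 2, 3, 4, 5, 6]], sites["id"])
        grid = GridSpec(0, 0, spacing=1.0, nx=11, ny=11)
        m = map_day(snap.iloc[0], sites, grid)
        assert m.values[0, 0] == pytest.approx(1.0)     # site at (0, 0)
        assert m.values[0, 10] == pytest.approx(2.0)    # site at (10, 0)
        assert m.values[9, 5] == pytest.approx(5.0)     # site at (5, 9)

    def test_too_few_sites_skipped(self):
        sites = _toy_sites(SIX)
        vals = [4.0] * 6
        vals[0] = np.nan
        snap = _toy_snap([vals], sites["id"])
        grid = GridSpec(0, 0, spacing=1.0, nx=11, ny=11)
        assert map_day(snap.iloc[0], sites, grid, min_sites=6) is None
        assert map_day(snap.iloc[0], sites, grid, min_sites=5) is not None


class TestAverageMaps:
    def test_single_map_identity_and_pairwise_mean(self):
        sites = _toy_sites(SIX)
        snap = _toy_snap([[1, 2, 3, 4, 5, 6], [3, 4, 5, 6, 7, 8]], sites["id"])
        grid = GridSpec(0, 0, spacing=1.0, nx=11, ny=11)
        m1 = map_day(snap.iloc[0], sites, grid)
        m2 = map_day(snap.iloc[1], sites, grid)
        assert np.allclose(average_maps([m1]).values, m1.values)
        avg = average_maps([m1, m2])
        assert np.allclose(avg.values, (m1.values + m2.values) / 2)
        assert avg.n_contributing == 2

    def test_mismatched_grids_rejected(self):
        sites = _toy_sites(SIX)
        snap = _toy_snap([[1, 2, 3, 4, 5, 6]], sites["id"])
        g1 = GridSpec(0, 0, spacing=1.0, nx=11, ny=11)
        g2 = GridSpec(0, 0, spacing=0.5, nx=11, ny=11)
        with pytest.raises(ValueError):
            average_maps([map_day(snap.iloc[0], sites, g1),
                          map_day(snap.iloc[0], sites, g2)])

    def test_idw_linearity_constant_station_set(self):
        # mapping-then-averaging equals averaging-then-mapping
        rng = np.random.default_rng(4)
        sites = _toy_sites(SIX)
        snap = _toy_snap(rng.uniform(1, 6, (9, 6)), sites["id"])
        grid = GridSpec(0, 0, spacing=1.0, nx=11, ny=11)
        avg, daily, used = map_period(snap, sites, grid)
        direct = map_day(snap.mean(axis=0).rename(snap.index[0]), sites, grid)
        assert np.max(np.abs(avg.values - direct.values)) < 1e-10

    def test_leave_one_day_out_stability(self, dry_snapshot, sites):
        grid = GridSpec(5, 10, spacing=5.0, nx=9, ny=9)
        avg, daily, used = map_period(dry_snapshot, sites, grid)
        n = len(daily)
        drop = daily[n // 2]
        rest = average_maps([m for m in daily if m is not drop])
        day_range = np.ptp(drop.values)
        assert np.max(np.abs(avg.values - rest.values)) <= day_range / n + 1e-9


class TestLooValidate:
    def test_constant_field_has_zero_error(self):
        sites = _toy_sites(SIX)
        snap = _toy_snap([[5.0] * 6] * 3, sites["id"])
        rep = loo_validate(snap, sites)
        assert rep.mean_bias_pct == pytest.approx(0.0, abs=1e-10)
        assert rep.mean_abs_error_pct == pytest.approx(0.0, abs=1e-10)

    def test_colocated_twin_predicted_exactly(self):
        coords = SIX + [(0.0, 0.0)]  # S6 co-located with S0
        sites = _toy_sites(coords)
        snap = _toy_snap([[1, 2, 3, 4, 5, 6, 1.0]], sites["id"])
        rep = loo_validate(snap, sites, min_sites=7)
        rec = rep.records
        err = rec.loc[rec["site"] == "S6", "pct_error"].iloc[0]
        assert abs(err) < 1e-9

    def test_zero_observation_excluded_from_percent_aggregates(self):
        sites = _toy_sites(SIX)
        snap = _toy_snap([[0.0, 2, 3, 4, 5, 6]], sites["id"])
        rep = loo_validate(snap, sites)
        assert rep.n_zero_obs == 1
        assert rep.records["pct_error"].isna().sum() == 1

    def test_regional_analyte_maps_more_accurately(self, dataset, sites):
        endo = ea.snapshot(dataset.conc, "endotoxin", "dry")
        pm25 = ea.snapshot(dataset.conc, "pm25", "dry")
        r_e = loo_validate(endo, sites)
        r_p = loo_validate(pm25, sites)
        assert r_p.mean_abs_error_pct < r_e.mean_abs_error_pct


class TestTertileMaps:
    def test_three_days_one_per_tertile(self):
        sites = _toy_sites(SIX)
        snap = _toy_snap([[1.0] * 6, [2.0] * 6, [3.0] * 6], sites["id"])
        grid = GridSpec(0, 0, spacing=2.0, nx=6, ny=6)
        maps = tertile_maps(snap, sites, "S0", grid)
        assert set(maps) == {"low", "mid", "high"}
        assert all(m.n_contributing == 1 for m in maps.values())
        assert np.allclose(maps["low"].values, 1.0)
        assert np.allclose(maps["high"].values, 3.0)

    def test_identical_days_give_identical_maps(self):
        sites = _toy_sites(SIX)
        snap = _toy_snap([[1, 2, 3, 4, 5, 6]] * 6, sites["id"])
        grid = GridSpec(0, 0, spacing=2.0, nx=6, ny=6)
        maps = tertile_maps(snap, sites, "S0", grid)
        assert np.allclose(maps["low"].values, maps["high"].values)

    def test_22_day_partition_sizes(self):
        rng = np.random.default_rng(9)
        sites = _toy_sites(SIX)
        snap = _toy_snap(rng.uniform(1, 6, (22, 6)), sites["id"])
        grid = GridSpec(0, 0, spacing=2.0, nx=6, ny=6)
        maps = tertile_maps(snap, sites, "S0", grid)
        counts = sorted(m.n_contributing for m in maps.values())
        assert sum(counts) == 22
        assert counts[-1] - counts[0] <= 1

    def test_central_missing_day_excluded(self):
        sites = _toy_sites(SIX)
        vals = np.ones((4, 6))
        vals[1, 0] = np.nan  # central missing but 5 others present
        snap = _toy_snap(vals, sites["id"])
        grid = GridSpec(0, 0, spacing=2.0, nx=6, ny=6)
        maps = tertile_maps(snap, sites, "S0", grid, min_sites=5)
        assert sum(m.n_contributing for m in maps.values()) == 3
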