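"""Puff-kernel physics, hotspot filtering/sampling and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from peathaze import (
    ConcentrationField,
    DispersionParams,
    Grid,
    calibrate,
    classify_peat,
    filter_hotspots,
    hotspot_density,
    mean_plume_per_class,
    puff_field,
    puff_snapshot,
    sample_hotspots,
    scale_up,
)
from peathaze.dispersion import mass_fraction_remaining, peat_class_from_code
from peathaze.synthetic import _default_peat_map

NO_LOSS = dict(dry_deposition_velocity_ms=0.0, wet_scavenging_rate_s=0.0)


# --------------------------------------------------------------------------
# filtering, classification, sampling


class TestFilterHotspots:
    def _table(self, confs):
        return pd.DataFrame({"id": range(len(confs)), "confidence": confs})

    def test_retention_band_is_inclusive_at_80(self):
        out = filter_hotspots(self._table([79, 80, 95, 100, 50]), 80)
        assert list(out["confidence"]) == [80, 95, 100]
        assert list(out["id"]) == [1, 2, 3]  # order preserved

    def test_min_zero_is_identity(self):
        t = self._table([3, 50, 99])
        assert filter_hotspots(t, 0).equals(t)

    def test_min_above_100_empties(self):
        assert len(filter_hotspots(self._table([100, 80]), 101)) == 0

    def test_missing_confidence_is_schema_error(self):
        with pytest.raises(KeyError):
            filter_hotspots(pd.DataFrame({"id": [1]}), 80)


def test_depth_codes_map_to_peat_classes():
    peat = _default_peat_map((60.0, 40.0))
    # points placed inside each depth rectangle: D2 -> shallow, D4 -> deep
    d2 = {"x_km": 0.4 * 60, "y_km": 0.2 * 40}
    d4 = {"x_km": 0.8 * 60, "y_km": 0.2 * 40}
    off = {"x_km": 1.0, "y_km": 39.0}
    assert classify_peat(d2, peat) == "shallow"
    assert classify_peat(d4, peat) == "deep"
    assert classify_peat(off, peat) is None
    assert peat_class_from_code("D1") == "shallow"
    assert peat_class_from_code("D3") == "deep"
    assert peat_class_from_code(None) is None


class TestSampleHotspots:
    def _records(self, n_deep, n_shallow, year=2015):
        n = n_deep + n_shallow
        return pd.DataFrame({
            "id": range(n),
            "peat_class": ["deep"] * n_deep + ["shallow"] * n_shallow,
            "datetime": pd.Timestamp(f"{year}-08-01"),
        })

    def test_balanced_sample_of_100_per_class(self):
        out = sample_hotspots(self._records(150, 150), 100, 2015, seed=3)
        assert (out["peat_class"] == "deep").sum() == 100
        assert (out["peat_class"] == "shallow").sum() == 100
        assert out["id"].is_unique

    def test_short_class_takes_all_with_warning(self):
        with pytest.warns(UserWarning, match="only 5 shallow"):
            out = sample_hotspots(self._records(150, 5), 100, 2015, seed=3)
        assert (out["peat_class"] == "shallow").sum() == 5

    def test_same_seed_same_ids(self):
        r = self._records(80, 80)
        a = sample_hotspots(r, 30, 2015, seed=9)
        b = sample_hotspots(r, 30, 2015, seed=9)
        assert list(a["id"]) == list(b["id"])

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            sample_hotspots(self._records(5, 5), 0, 2015)


# --------------------------------------------------------------------------
# puff kernel


def test_zero_wind_no_loss_field_is_radially_symmetric(plume_grid, calm_params):
    p = DispersionParams(n_puffs=4, dt_sample_h=0.5, **NO_LOSS)
    f = puff_field((0.0, 0.0), (0.0, 0.0), p, plume_grid).values
    for flipped in (f[::-1, :], f[:, ::-1], f.T):
        assert np.max(np.abs(f - flipped)) <= 1e-9 * f.max()


def test_puff_mass_conserved_without_deposition():
    # single puff, light wind, wide grid; snapshot integrals stay within
    # 0.5% of the released mass at all probe times
    grid = Grid.centered(100.0)
    p = DispersionParams(n_puffs=1, release_duration_h=1.0, **NO_LOSS)
    released = p.emission_rate * 3600.0
    for t_h in (2.0, 6.0, 12.0, 24.0):
        f = puff_snapshot((0.0, 0.0), (0.1, 0.05), p, grid, t_h * 3600.0)
        assert f.total_mass(p.plume_layer_top_m) == pytest.approx(released, rel=5e-3)


def test_deposition_decay_matches_numerical_integration_oracle():
    p = DispersionParams()  # v_d = 0.001 m/s, H = 100 m, Lambda = 8e-5 /s
    lam = p.dry_deposition_velocity_ms / p.plume_layer_top_m + p.wet_scavenging_rate_s
    ode = solve_ivp(lambda t, m: -lam * m, (0.0, 3600.0), [1.0],
                    rtol=1e-12, atol=1e-14)
    oracle = float(ode.y[0, -1])
    assert oracle == pytest.approx(0.7232502423798424, rel=1e-9)
    assert mass_fraction_remaining(3600.0, p) == pytest.approx(oracle, rel=1e-6)
    # and the gridded snapshot loses exactly that mass fraction
    grid = Grid.centered(60.0)
    t = 3600.0 + 1800.0  # 1 h after the (mid-interval) single release
    p1 = DispersionParams(n_puffs=1, release_duration_h=1.0)
    f = puff_snapshot((0.0, 0.0), (0.0, 0.0), p1, grid, t)
    released = p1.emission_rate * 3600.0
    assert f.total_mass(p1.plume_layer_top_m) / released == pytest.approx(
        mass_fraction_remaining(3600.0, p1), rel=5e-3
    )


def test_puff_field_matches_brute_force_oracle(plume_grid):
    """Direct unoptimised per-cell summation at 20 random cells."""
    p = DispersionParams(n_puffs=6, dt_sample_h=2.0)
    hotspot, wind, mix = (2.0, -3.0), (1.1, 0.7), 900.0
    f = puff_field(hotspot, wind, p, plume_grid, mixing_height_m=mix)
    rng = np.random.default_rng(5)
    rows = rng.integers(0, plume_grid.ny, 20)
    cols = rng.integers(0, plume_grid.nx, 20)
    dur = p.release_duration_h * 3600.0
    t_rel = [(i + 0.5) * dur / p.n_puffs for i in range(p.n_puffs)]
    mass = p.emission_rate * dur / p.n_puffs
    lam = p.dry_deposition_velocity_ms / p.plume_layer_top_m + p.wet_scavenging_rate_s
    n_steps = int(round(p.averaging_period_h / p.dt_sample_h))
    for r, c in zip(rows, cols):
        xm = plume_grid.x[c] * 1000.0
        ym = plume_grid.y[r] * 1000.0
        total = 0.0
        for j in range(n_steps):
            t = (j + 0.5) * p.dt_sample_h * 3600.0
            for tr in t_rel:
                a = t - tr
                if a <= 0:
                    continue
                cx = hotspot[0] * 1000.0 + wind[0] * a
                cy = hotspot[1] * 1000.0 + wind[1] * a
                s2 = 2.0 * p.horizontal_diffusivity_m2s * a + p.sigma0_m**2
                r2 = (xm - cx) ** 2 + (ym - cy) ** 2
                total += (
                    mass * np.exp(-lam * a)
                    / (2.0 * np.pi * s2 * p.plume_layer_top_m)
                    * np.exp(-r2 / (2.0 * s2))
                )
        expected = total / n_steps
        assert f.values[r, c] == pytest.approx(expected, rel=1e-10)


def test_hotspot_outside_grid_and_zero_mixing_height_rejected(plume_grid, calm_params):
    with pytest.raises(ValueError, match="outside"):
        puff_field((999.0, 0.0), (0.0, 0.0), calm_params, plume_grid)
    with pytest.raises(ValueError, match="mixing height"):
        puff_field((0.0, 0.0), (0.0, 0.0), calm_params, plume_grid, mixing_height_m=0.0)


# --------------------------------------------------------------------------
# averaging, scale-up, calibration


def _met_for(dates, u=0.5, v=0.0):
    d = pd.to_datetime(pd.Series(dates)).dt.normalize().unique()
    return pd.DataFrame({
        "date": d, "u_ms": u, "v_ms": v, "mixing_height_m": 1000.0,
    })


def test_mean_plume_single_hotspot_is_identity(plume_grid, calm_params):
    recs = pd.DataFrame({
        "x_km": [3.0], "y_km": [4.0],
        "datetime": [pd.Timestamp("2015-08-01 10:00")],
        "peat_class": ["deep"],
    })
    met = _met_for(recs["datetime"])
    out = mean_plume_per_class(recs, met, calm_params, plume_grid, classes=("deep",))
    direct = puff_field((0.0, 0.0), (0.5, 0.0), calm_params, plume_grid)
    np.testing.assert_allclose(out["deep"].values, direct.values, rtol=1e-12)


def test_mean_plume_two_identical_hotspots_equals_either(plume_grid, calm_params):
    recs = pd.DataFrame({
        "x_km": [3.0, 40.0], "y_km": [4.0, 20.0],
        "datetime": pd.to_datetime(["2015-08-01 10:00", "2015-08-01 22:00"]),
        "peat_class": ["deep", "deep"],
    })
    met = _met_for(recs["datetime"])
    out = mean_plume_per_class(recs, met, calm_params, plume_grid, classes=("deep",))
    direct = puff_field((0.0, 0.0), (0.5, 0.0), calm_params, plume_grid)
    np.testing.assert_allclose(out["deep"].values, direct.values, rtol=1e-12)


def test_mean_plume_empty_class_names_the_class(plume_grid, calm_params):
    recs = pd.DataFrame({
        "x_km": [3.0], "y_km": [4.0],
        "datetime": [pd.Timestamp("2015-08-01")],
        "peat_class": ["deep"],
    })
    with pytest.raises(ValueError, match="shallow"):
        mean_plume_per_class(recs, _met_for(recs["datetime"]), calm_params, plume_grid)


class TestScaleUp:
    def _inputs(self):
        full = Grid.from_extent(40.0, 30.0)
        plume = Grid.centered(5.0)
        pv = np.zeros((plume.ny, plume.nx))
        pv[plume.ny // 2, plume.nx // 2] = 1.0
        mean_fields = {
            "deep": ConcentrationField(plume, pv),
            "shallow": ConcentrationField(plume, pv),
        }
        recs = pd.DataFrame({"x_km": [10.2, 30.5], "y_km": [10.5, 20.1]})
        dens = {
            "deep": hotspot_density(recs, full),
            "shallow": hotspot_density(recs, full),
        }
        return mean_fields, dens

    def test_zero_counts_give_zero_field(self):
        mf, dens = self._inputs()
        out = scale_up(mf, {"deep": 0, "shallow": 0}, dens)
        assert not out.values.any()

    def test_linear_in_counts(self):
        mf, dens = self._inputs()
        a = scale_up(mf, {"deep": 50, "shallow": 40}, dens)
        b = scale_up(mf, {"deep": 100, "shallow": 80}, dens)
        np.testing.assert_allclose(b.values, 2.0 * a.values, rtol=1e-9, atol=1e-12)

    def test_deep_exceeding_shallow_by_8pct_shows_in_contributions(self):
        mf, dens = self._inputs()
        deep_only = scale_up(mf, {"deep": 108, "shallow": 0}, dens)
        shallow_only = scale_up(mf, {"deep": 0, "shallow": 100}, dens)
        assert deep_only.values.sum() == pytest.approx(
            1.08 * shallow_only.values.sum(), rel=1e-9
        )

    def test_negative_count_rejected(self):
        mf, dens = self._inputs()
        with pytest.raises(ValueError):
            scale_up(mf, {"deep": -1, "shallow": 0}, dens)


class TestCalibrate:
    def _field(self, station_value=10.0):
        g = Grid.from_extent(10.0, 10.0)
        vals = np.linspace(1, 2, g.ny * g.nx).reshape(g.ny, g.nx)
        r, c = g.index_of(5.0, 5.0)
        vals[r, c] = station_value
        return ConcentrationField(g, vals)

    def test_observed_65_over_modeled_10_scales_by_6_5(self):
        out = calibrate(self._field(10.0), 65.0, (5.0, 5.0))
        assert out.value_at(5.0, 5.0) == pytest.approx(65.0)
        np.testing.assert_allclose(out.values, 6.5 * self._field(10.0).values)

    def test_matching_observation_is_identity(self):
        f = self._field(10.0)
        out = calibrate(f, 10.0, (5.0, 5.0))
        np.testing.assert_allclose(out.values, f.values)

    def test_idempotent(self):
        once = calibrate(self._field(10.0), 65.0, (5.0, 5.0))
        twice = calibrate(once, 65.0, (5.0, 5.0))
        np.testing.assert_allclose(twice.values, once.values)

    def test_zero_modeled_station_value_is_an_error(self):
        g = Grid.from_extent(10.0, 10.0)
        f = ConcentrationField(g, np.zeros((g.ny, g.nx)))
        with pytest.raises(ValueError, match="calibration"):
            calibrate(f, 65.0, (5.0, 5.0))


def test_calibrated_field_invariant_to_emission_rate(plume_grid):
    """Scale-up + calibrate commute with rescaling the emission rate."""
    full = Grid.from_extent(40.0, 30.0)
    recs = pd.DataFrame({
        "x_km": [10.0, 22.0], "y_km": [12.0, 18.0],
        "datetime": pd.to_datetime(["2015-08-01", "2015-08-02"]),
        "peat_class": ["deep", "shallow"],
    })
    met = _met_for(recs["datetime"])
    dens = {c: hotspot_density(recs[recs["peat_class"] == c], full)
            for c in ("deep", "shallow")}
    results = []
    for rate in (1.0, 7.3):
        p = DispersionParams(emission_rate=rate, n_puffs=4, dt_sample_h=2.0)
        mf = mean_plume_per_class(recs, met, p, Grid.centered(20.0))
        raw = scale_up(mf, {"deep": 30, "shallow": 25}, dens)
        results.append(calibrate(raw, 42.0, (20.0, 15.0)).values)
    np.testing.assert_allclose(results[0], results[1], rtol=1e-9)
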