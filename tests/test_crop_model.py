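import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from cassava_gsua import crop_model as cm
from cassava_gsua.weather import SiteProfile, WeatherSeries

CONSTANTS = cm.SpeciesConstants()


def constant_weather(tmean=28.0, srad=17.0, rain=8.0, days=400, diurnal=10.0):
    """Constant-forcing series for closed-form phenology oracles."""
    dates = pd.date_range("2000-01-01", periods=days)
    frame = pd.DataFrame(
        {
            "date": dates,
            "tmax": tmean + diurnal / 2,
            "tmin": tmean - diurnal / 2,
            "srad": srad,
            "rain": rain,
        }
    )
    site = SiteProfile("const", 0, 0, 0, tmean, srad, rain * 365)
    return WeatherSeries(site, frame)


@pytest.fixture(scope="module")
def soil():
    from cassava_gsua.soil_water import load_soil_profile

    return load_soil_profile("warm")


@pytest.fixture(scope="module")
def unlimited():
    return cm.Management(water_limited=False)


def run_const(gsp_overrides, soil, mgmt, tmean=28.0, **weather_kw):
    from cassava_gsua.gsp import default_gsp_values

    g = default_gsp_values()
    g.update(gsp_overrides)
    wx = constant_weather(tmean=tmean, **weather_kw)
    return cm.simulate_season(
        cm.GSPSet(**g), wx, soil, mgmt, start_index=mgmt.preplant_days
    )


class TestBranching:
    def test_first_branch_day_closed_form(self, soil, unlimited):
        """Constant tmean 28, branching base 13 => 15 degC-day/day; first
        branch on day ceil(764/15) = 51."""
        out = run_const({"B01ND": 764.0, "TBLSZ": 14.0}, soil, unlimited, tmean=28.0)
        assert out.day_first_branch == math.ceil(764.0 / 15.0) == 51

    def test_second_branch_threshold_is_b01nd_plus_b12nd(self, soil, unlimited):
        b01, b12 = 450.0, 300.0
        out = run_const({"B01ND": b01, "B12ND": b12, "TBLSZ": 14.0}, soil, unlimited)
        assert out.day_first_branch == math.ceil(b01 / 15.0)
        assert out.day_second_branch == math.ceil((b01 + b12) / 15.0)

    def test_no_branching_when_threshold_unreachable(self, soil, unlimited):
        out = run_const({"B01ND": 1e6}, soil, unlimited)
        # censored at season length
        assert out.day_first_branch == 300.0
        assert out.day_second_branch == 300.0


class TestLeafAppearance:
    def test_identity_scaling_at_lnslp_one(self):
        age = np.array([0.0, 500.0, 2000.0])
        ref = CONSTANTS.appearance_r0 / (1 + age / CONSTANTS.appearance_halflife)
        np.testing.assert_allclose(cm.leaf_appearance_rate(age, 1.0), ref)

    def test_proportionality(self):
        hi = cm.leaf_appearance_rate(700.0, 1.3)
        lo = cm.leaf_appearance_rate(700.0, 0.7)
        assert hi / lo == pytest.approx(1.3 / 0.7)

    def test_non_increasing_in_age(self):
        ages = np.linspace(0, 5000, 200)
        rates = cm.leaf_appearance_rate(ages, 1.0)
        assert np.all(np.diff(rates) <= 0)
        assert np.all(rates > 0)

    def test_rejects_negative_age(self):
        with pytest.raises(ValueError):
            cm.leaf_appearance_rate(-1.0, 1.0)


class TestPotentialLeafSize:
    def test_peak_value_at_900(self):
        assert cm.potential_leaf_size(900.0, 500.0) == pytest.approx(500.0)

    def test_origin_fraction(self):
        assert cm.potential_leaf_size(0.0, 500.0) == pytest.approx(
            CONSTANTS.leaf_size_f0 * 500.0
        )

    def test_declines_past_peak(self):
        assert cm.potential_leaf_size(1200.0, 500.0) < 500.0

    def test_continuous_at_peak(self):
        eps = 1e-6
        below = cm.potential_leaf_size(900.0 - eps, 500.0)
        above = cm.potential_leaf_size(900.0 + eps, 500.0)
        assert below == pytest.approx(above, abs=1e-3)


class TestNodeGrowth:
    def test_integral_converges_to_nodwt(self):
        nodwt = 8.5
        total, _ = integrate.quad(
            lambda t: cm.node_growth_rate(t, 50.0, nodwt), 0, 5000, limit=300
        )
        assert total == pytest.approx(nodwt, rel=0.01)

    def test_rate_non_negative(self):
        ages = np.linspace(0, 4000, 100)
        assert np.all(np.asarray(cm.node_growth_rate(ages, 0.0, 5.0)) >= 0)

    def test_mass_scale_equivariance(self):
        m1 = cm.node_mass_potential(400.0, 20.0, 5.0)
        m2 = cm.node_mass_potential(400.0, 20.0, 10.0)
        assert m2 == pytest.approx(2.0 * m1)

    def test_mass_zero_at_age_zero(self):
        assert cm.node_mass_potential(0.0, 10.0, 7.0) == pytest.approx(0.0)


class TestAssimilation:
    def test_zero_canopy(self):
        assert cm.daily_assimilation(20.0, 0.0, 2.0, 0.8) == 0.0

    def test_full_interception_asymptote(self):
        a = cm.daily_assimilation(20.0, 50.0, 2.0, 0.8)
        assert a == pytest.approx(0.5 * 20.0 * 2.0, rel=1e-6)

    def test_half_interception_at_ln2(self):
        kcan, lai = 0.7, math.log(2) / 0.7
        a = cm.daily_assimilation(20.0, lai, 2.0, kcan)
        assert a == pytest.approx(0.5 * 0.5 * 20.0 * 2.0)


class TestDemandAndAllocation:
    def test_no_growth_no_demand(self):
        leaf, stem, fib = cm.compute_demand(0.0, 0.0, 250.0, 0.2)
        assert (leaf, stem, fib) == (0.0, 0.0, 0.0)

    def test_fibrous_is_ten_percent(self):
        leaf, stem, fib = cm.compute_demand(100.0, 3.0, 250.0, 0.2)
        assert fib == pytest.approx(0.10 * (leaf + stem))

    def test_petiole_fraction_split(self):
        lpefr = 0.22
        leaf, _, _ = cm.compute_demand(100.0, 0.0, 250.0, lpefr)
        lamina = 100.0 / 250.0
        assert lamina / leaf == pytest.approx(1.0 - lpefr)

    def test_allocation_supply_equals_demand(self):
        leaf, stem, fib, storage = cm.allocate_spillover(6.0, 3.0, 2.0, 1.0)
        assert (leaf, stem, fib, storage) == (3.0, 2.0, 1.0, 0.0)

    def test_allocation_surplus_to_storage(self):
        *_, storage = cm.allocate_spillover(9.0, 3.0, 2.0, 1.0)
        assert storage == pytest.approx(3.0)

    def test_allocation_deficit_scales_proportionally(self):
        leaf, stem, fib, storage = cm.allocate_spillover(3.6, 3.0, 2.0, 1.0)
        assert leaf == pytest.approx(0.6 * 3.0)
        assert stem == pytest.approx(0.6 * 2.0)
        assert fib == pytest.approx(0.6 * 1.0)
        assert storage == 0.0

    def test_allocation_rejects_negative(self):
        with pytest.raises(ValueError):
            cm.allocate_spillover(-1.0, 1.0, 1.0, 1.0)


class TestSenescence:
    def test_infinite_llifa_keeps_canopy(self, soil, unlimited):
        keep = run_const({"LLIFA": 1e6}, soil, unlimited)
        drop = run_const({"LLIFA": 200.0}, soil, unlimited)
        assert keep.max_lai >= drop.max_lai
        # senesced leaf mass is retained in aboveground biomass, so totals
        # respond through canopy feedback only
        assert keep.aboveground_biomass > 0 and drop.aboveground_biomass > 0


class TestSimulateSeason:
    def test_parue_monotonicity(self, soil, unlimited):
        base = run_const({}, soil, unlimited)
        double = run_const({"PARUE": 2.0 * 1.4}, soil, unlimited)
        assert double.aboveground_biomass > base.aboveground_biomass

    def test_unlimited_equals_rainfed_when_rain_rich(self, soil):
        rainfed = cm.Management(water_limited=True)
        unlimited = cm.Management(water_limited=False)
        a = run_const({}, soil, rainfed, rain=15.0)
        b = run_const({}, soil, unlimited, rain=15.0)
        assert a.as_tuple() == pytest.approx(b.as_tuple())

    def test_daily_mass_balance_from_trace(self, soil, gsp_set):
        wx = constant_weather(rain=6.0)
        mgmt = cm.Management(water_limited=True)
        out, trace = cm.simulate_season(
            gsp_set, wx, soil, mgmt, trace=True, start_index=mgmt.preplant_days
        )
        pools = (
            trace[["lamina_mass", "petiole_mass", "stem_mass", "fibrous_mass", "storage_mass"]]
            .sum(axis=1)
            .to_numpy()
        )
        delta = np.diff(np.concatenate([[0.0], pools]))
        supply = trace["supply"].to_numpy()
        np.testing.assert_allclose(delta, supply, rtol=1e-9, atol=1e-12)

    def test_season_total_conservation(self, soil, gsp_set, warm_weather):
        raw = cm.simulate_batch(
            {k: np.array([v]) for k, v in gsp_set.as_dict().items()},
            warm_weather,
            soil,
            cm.Management(water_limited=True),
            year=2000,
        )
        assert raw["_total_mass"][0] == pytest.approx(raw["_cum_supply"][0], rel=1e-9)

    def test_deterministic(self, soil, gsp_set, warm_weather):
        mgmt = cm.Management()
        a = cm.simulate_season(gsp_set, warm_weather, soil, mgmt, year=2000)
        b = cm.simulate_season(gsp_set, warm_weather, soil, mgmt, year=2000)
        assert a == b

    def test_short_weather_rejected(self, soil, gsp_set):
        wx = constant_weather(days=100)
        with pytest.raises(ValueError, match="window"):
            cm.simulate_season(gsp_set, wx, soil, cm.Management(), start_index=30)

    def test_outputs_non_negative(self, soil, gsp_set, warm_weather):
        out = cm.simulate_season(gsp_set, warm_weather, soil, cm.Management(), year=2000)
        assert all(v >= 0 for v in out.as_tuple())

    def test_storage_zero_on_supply_limited_days(self, soil, gsp_set):
        wx = constant_weather(rain=6.0)
        mgmt = cm.Management(water_limited=False)
        _, trace = cm.simulate_season(
            gsp_set, wx, soil, mgmt, trace=True, start_index=mgmt.preplant_days
        )
        limited = trace["demand"] > trace["supply"] + 1e-12
        storage_growth = np.diff(np.concatenate([[0.0], trace["storage_mass"].to_numpy()]))
        assert np.all(storage_growth[limited.to_numpy()] == 0.0)

    def test_batch_matches_scalar_runs(self, soil, warm_weather, gsp_defaults):
        """A 3-row batch reproduces three independent scalar runs."""
        rows = []
        for parue in (1.0, 1.4, 1.9):
            g = dict(gsp_defaults)
            g["PARUE"] = parue
            rows.append(g)
        batch = {k: np.array([r[k] for r in rows]) for k in rows[0]}
        mgmt = cm.Management(water_limited=True)
        raw = cm.simulate_batch(batch, warm_weather, soil, mgmt, year=2000)
        for i, g in enumerate(rows):
            out = cm.simulate_season(cm.GSPSet(**g), warm_weather, soil, mgmt, year=2000)
            for j, name in enumerate(cm.OUTPUT_NAMES):
                assert raw[name][i] == pytest.approx(getattr(out, name), rel=1e-12), name


class TestDirectionalClaims:
    """Monotonicity spot-checks at 5 parameter levels (no water stress)."""

    def test_laxs_increases_max_lai(self, soil, unlimited):
        levels = [220.0, 280.0, 340.0, 400.0, 460.0]
        lai = [run_const({"LAXS": v}, soil, unlimited).max_lai for v in levels]
        assert all(b >= a for a, b in zip(lai, lai[1:]))

    def test_parue_increases_biomass(self, soil, unlimited):
        levels = [0.8, 1.1, 1.4, 1.7, 2.0]
        bm = [run_const({"PARUE": v}, soil, unlimited).aboveground_biomass for v in levels]
        assert all(b >= a for a, b in zip(bm, bm[1:]))

    def test_tblsz_decreases_max_lai_cool(self, soil_cool, unlimited):
        levels = [11.0, 12.5, 14.0, 15.5, 17.0]
        lai = [
            run_const({"TBLSZ": v}, soil_cool, unlimited, tmean=18.0).max_lai
            for v in levels
        ]
        assert all(b <= a for a, b in zip(lai, lai[1:]))

    def test_nodwt_range_runs_and_conserves(self, soil, unlimited, gsp_defaults):
        """Across the NODWT support the model must run and conserve mass;
        the biomass response may legitimately peak (non-monotonic)."""
        wx = constant_weather()
        for nodwt in (1.0, 4.0, 8.0, 12.0, 16.0):
            g = dict(gsp_defaults)
            g["NODWT"] = nodwt
            raw = cm.simulate_batch(
                {k: np.array([v]) for k, v in g.items()}, wx, soil, unlimited,
                start_index=unlimited.preplant_days,
            )
            assert raw["_total_mass"][0] == pytest.approx(raw["_cum_supply"][0], rel=1e-9)
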