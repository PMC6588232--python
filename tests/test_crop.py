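"""Crop model: phenology against the closed-form oracle, stress and sterility
responses, growth behaviour, and yield arithmetic."""

import math

import numpy as np
import pytest

from paddysim.crop import (
    DVS_MATURITY,
    CropState,
    cold_sterility,
    develop,
    drought_stress_index,
    grow,
    nursery_development,
    phase_durations_days,
    phase_mean_stress,
    photoperiod_factor,
    sow_direct,
    spikelet_number,
    thermal_time,
    transplant,
    yield_t_ha,
)
from paddysim.soil import SoilWaterState

REF_TAVG = 28.0
REF_DAYLENGTH = 13.0


def days_to_maturity(cultivar, state=None, tavg=REF_TAVG, daylength=REF_DAYLENGTH, limit=400):
    state = state or sow_direct(cultivar)
    for day in range(1, limit + 1):
        state = develop(state, cultivar, tavg, daylength)
        if state.dvs >= DVS_MATURITY:
            return day
    return math.inf


def closed_form_duration(cultivar, tavg=REF_TAVG, daylength=REF_DAYLENGTH):
    """Independent hand formula: sum over phases of dvs-span / (rate *
    dev_scale * degree-days * photoperiod factor)."""
    tt = min(tavg - 8.0, 22.0)
    pf = max(0.0, 1.0 - cultivar.ppse * min(1.5, max(0.0, daylength - cultivar.mopp)))
    spans_rates = [
        (0.40, cultivar.dvr_juvenile, 1.0),
        (0.25, cultivar.dvr_photoperiod, pf),
        (0.35, cultivar.dvr_panicle, 1.0),
        (1.00, cultivar.dvr_reproductive, 1.0),
    ]
    return sum(span / (rate * cultivar.dev_scale * tt * f) for span, rate, f in spans_rates)


class TestPhenology:
    def test_rated_durations_recovered_at_reference_forcing(self, mtu, arize):
        assert abs(days_to_maturity(mtu) - 150) <= 3
        assert abs(days_to_maturity(arize) - 125) <= 3

    def test_daily_stepping_matches_closed_form(self, mtu, arize):
        for cv in (mtu, arize):
            for tavg, dl in [(28.0, 13.0), (25.0, 12.0), (30.0, 13.5)]:
                expected = closed_form_duration(cv, tavg, dl)
                assert abs(days_to_maturity(cv, tavg=tavg, daylength=dl) - expected) <= 1.5

    def test_phase_durations_sum_equals_closed_form(self, mtu):
        assert sum(phase_durations_days(mtu)) == pytest.approx(closed_form_duration(mtu))

    def test_short_duration_hybrid_always_earlier(self, mtu, arize, weather_10y):
        for year in weather_10y.years[:5]:
            arr = weather_10y.year_arrays(year)
            tavg = (arr["tmax"] + arr["tmin"]) / 2
            states = {cv.name: sow_direct(cv) for cv in (mtu, arize)}
            anthesis, maturity = {}, {}
            for i in range(120, len(tavg)):  # both sown 1 May
                for cv in (mtu, arize):
                    s = states[cv.name]
                    if s.dvs >= DVS_MATURITY:
                        continue
                    prev = s.dvs
                    s = develop(s, cv, float(tavg[i]), float(arr["daylength"][i]))
                    states[cv.name] = s
                    if prev < 1.0 <= s.dvs:
                        anthesis[cv.name] = i
                    if s.dvs >= DVS_MATURITY:
                        maturity[cv.name] = i
            assert anthesis["Arize6129"] < anthesis["MTU7029"]
            assert maturity["Arize6129"] < maturity["MTU7029"]

    def test_photoperiod_factor_shape(self, mtu):
        assert photoperiod_factor(mtu, mtu.mopp - 1.0) == 1.0
        assert photoperiod_factor(mtu, mtu.mopp) == 1.0
        f13 = photoperiod_factor(mtu, 13.0)
        f14 = photoperiod_factor(mtu, 14.0)
        assert 0.0 < f14 <= f13 < 1.0

    def test_thermal_time_piecewise(self):
        assert thermal_time(5.0) == 0.0
        assert thermal_time(28.0) == pytest.approx(20.0)
        assert thermal_time(30.0) == pytest.approx(22.0)
        assert thermal_time(36.0) == pytest.approx(11.0)
        assert thermal_time(45.0) == 0.0

    def test_dvs_never_decreases(self, mtu, weather_10y):
        arr = weather_10y.year_arrays(weather_10y.years[0])
        tavg = (arr["tmax"] + arr["tmin"]) / 2
        state = sow_direct(mtu)
        prev = 0.0
        for i in range(150, 300):
            state = develop(state, mtu, float(tavg[i]), float(arr["daylength"][i]))
            assert state.dvs >= prev
            prev = state.dvs


class TestDroughtStress:
    def test_ponded_field_unstressed(self, profile, mtu):
        soil = SoilWaterState(theta=[l.dul for l in profile.layers], pond=30.0)
        assert drought_stress_index(sow_direct(mtu), soil, profile) == 1.0

    def test_lower_limit_is_maximum_stress(self, profile, mtu):
        soil = SoilWaterState(theta=[l.ll for l in profile.layers])
        assert drought_stress_index(sow_direct(mtu), soil, profile) == 0.0

    def test_half_critical_fraction(self, uniform_profile, mtu):
        # FAW = 0.25 uniformly, f_crit = 0.5 -> lstrs = 0.5
        theta = [l.ll + 0.25 * (l.dul - l.ll) for l in uniform_profile.layers]
        soil = SoilWaterState(theta=theta)
        crop = sow_direct(mtu)
        crop.root_depth_cm = 60.0
        assert drought_stress_index(crop, soil, uniform_profile) == pytest.approx(0.5)


class TestColdSterility:
    def test_warm_window_is_fertile(self):
        assert cold_sterility([28.0] * 20, 28.0) == 0.0
        assert cold_sterility([30.0] * 20, 28.0) == 0.0

    def test_cold_window_is_sterile(self):
        # tavg 20 for 20 days at cttmax 28: 160 cooling degree days
        assert cold_sterility([20.0] * 20, 28.0) >= 0.9

    def test_full_length_22_degree_window(self):
        assert cold_sterility([22.0] * 20, 28.0) >= 0.9

    def test_monotone_in_threshold(self):
        series = [21.0] * 15
        assert cold_sterility(series, 28.0) >= cold_sterility(series, 22.0)

    def test_empty_window(self):
        assert cold_sterility([], 28.0) == 0.0


class TestGrowth:
    def test_full_stress_stops_growth(self, mtu):
        state = sow_direct(mtu)
        state.lai = 2.0
        grown = grow(state, mtu, 20.0, lstrs=0.0)
        assert grown.biomass_shoot == state.biomass_shoot

    def test_gain_linear_in_radiation_at_closed_canopy(self, mtu):
        state = sow_direct(mtu)
        state.lai = 50.0  # interception ~ 1
        g1 = grow(state.copy(), mtu, 10.0, 1.0).biomass_shoot - state.biomass_shoot
        g2 = grow(state.copy(), mtu, 20.0, 1.0).biomass_shoot - state.biomass_shoot
        assert g2 == pytest.approx(2.0 * g1, rel=1e-9)

    def test_hybrid_partitions_more_to_panicle(self, mtu, arize):
        for cv, other in [(arize, mtu)]:
            s_a, s_b = sow_direct(cv), sow_direct(other)
            for s, c in ((s_a, cv), (s_b, other)):
                s.dvs = s.dvs_at_last_grow = 1.1
                s.lai = 4.0
                s.biomass_shoot = 8000.0
            g_a = grow(s_a, cv, 18.0, 1.0)
            g_b = grow(s_b, other, 18.0, 1.0)
            assert g_a.biomass_panicle > g_b.biomass_panicle

    def test_severe_stress_senesces_canopy(self, mtu):
        state = sow_direct(mtu)
        state.lai = 2.0
        stressed = state
        for _ in range(20):
            stressed = grow(stressed, mtu, 18.0, lstrs=0.0)
        assert stressed.lai < 0.8 * state.lai


class TestYield:
    def test_full_sterility_zero_yield(self, mtu):
        state = CropState(dvs=2.0, sterility=1.0, panicle_phase_growth=4000.0,
                          biomass_panicle=5000.0)
        assert yield_t_ha(state, mtu) == 0.0

    def test_source_limited_yield_equals_panicle_biomass(self, mtu):
        state = CropState(dvs=2.0, panicle_phase_growth=50000.0, biomass_panicle=3000.0)
        assert yield_t_ha(state, mtu) == pytest.approx(3.0)

    def test_spikelet_arithmetic(self, mtu):
        state = CropState(panicle_phase_growth=2000.0)  # 200 g m-2
        assert spikelet_number(state, mtu) == pytest.approx(12800.0)

    def test_dead_crop_yields_nothing(self, mtu):
        state = CropState(dvs=2.0, panicle_phase_growth=4000.0, biomass_panicle=5000.0,
                          alive=False)
        assert yield_t_ha(state, mtu) == 0.0


class TestTransplanting:
    def test_recommended_age_no_penalty(self, mtu):
        assert transplant(mtu, 30.0).growth_penalty == 1.0

    def test_oldest_observed_seedling_penalty(self, mtu):
        assert transplant(mtu, 79.0).growth_penalty == pytest.approx(0.51)

    def test_penalty_floor(self, mtu):
        assert transplant(mtu, 120.0).growth_penalty == 0.5

    def test_too_young_rejected(self, mtu):
        with pytest.raises(ValueError):
            transplant(mtu, 10.0)

    def test_dsr_matures_8_to_10_days_before_transplanted(self, mtu):
        # both sown the same day; the transplanted crop spends 30 d in the
        # nursery, then pauses for the transplanting shock
        dsr_days = days_to_maturity(mtu)
        nursery_dvs = nursery_development(mtu, 30, REF_TAVG, REF_DAYLENGTH)
        tr_state = transplant(mtu, 30.0, nursery_dvs=nursery_dvs)
        tr_days = 30 + days_to_maturity(mtu, state=tr_state)
        assert 8 <= tr_days - dsr_days <= 10

    def test_nursery_credit_capped_at_panicle_initiation(self, mtu):
        assert nursery_development(mtu, 200) == pytest.approx(0.65)


class TestPhaseMeanStress:
    def test_constant_unstressed(self):
        veg, rep = phase_mean_stress([1.0] * 10, np.linspace(0.1, 2.0, 10))
        assert veg == 1.0 and rep == 1.0

    def test_piecewise_constant(self):
        dvs = np.concatenate([np.linspace(0.1, 0.99, 5), np.linspace(1.0, 2.0, 5)])
        lstrs = np.array([1.0] * 5 + [0.4] * 5)
        veg, rep = phase_mean_stress(lstrs, dvs)
        assert veg == pytest.approx(1.0) and rep == pytest.approx(0.4)

    def test_empty_phase_flagged(self):
        veg, rep = phase_mean_stress([0.9, 0.8], [0.2, 0.3])
        assert veg == pytest.approx(0.85) and math.isnan(rep)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            phase_mean_stress([1.0, 1.0], [0.5])
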