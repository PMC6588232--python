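"""Soil water balance: PAWC arithmetic, pond/percolation behaviour, two-stage
evaporation against an independent oracle, and daily mass conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paddysim.soil import (
    SoilLayer,
    SoilProfile,
    SoilWaterState,
    fraction_of_field_capacity,
    irrigation_to_saturation_plus_pond,
    pawc,
    potential_evapotranspiration,
    puddle,
    step_water_balance,
)


def saturated_state(profile, pond=0.0, puddled=False):
    return SoilWaterState(
        theta=[layer.sat for layer in profile.layers], pond=pond, puddled=puddled
    )


def dul_state(profile):
    return SoilWaterState(theta=[layer.dul for layer in profile.layers])


class TestPawc:
    def test_patna_0_60_matches_printed_value(self, profile):
        assert pawc(profile, 60.0) == pytest.approx(93.0, abs=1e-9)
        assert abs(pawc(profile, 60.0) - 92.0) <= 1.0 + 1e-9

    def test_patna_0_150_matches_printed_value(self, profile):
        assert pawc(profile, 150.0) == pytest.approx(234.0, abs=1e-9)
        assert abs(pawc(profile, 150.0) - 235.0) <= 1.0 + 1e-9

    def test_additive_over_depth(self, profile):
        assert pawc(profile, 150.0) == pytest.approx(
            pawc(profile, 60.0)
            + sum(
                (l.dul - l.ll) * l.thickness_mm
                for l in profile.layers
                if l.top_depth >= 60.0
            )
        )

    def test_degenerate_profile_near_zero(self):
        layers = (SoilLayer(0, 60, ll=0.2, dul=0.2 + 1e-9, sat=0.4),)
        assert pawc(SoilProfile(layers=layers), 60.0) == pytest.approx(0.0, abs=1e-6)

    def test_non_boundary_depth_rejected(self, profile):
        with pytest.raises(ValueError):
            pawc(profile, 45.0)
        with pytest.raises(ValueError):
            pawc(profile, 200.0)


class TestStepWaterBalance:
    def test_quiescent_day_at_dul_changes_nothing(self, profile):
        state = dul_state(profile)
        new, fluxes = step_water_balance(state, profile, 0.0, 0.0, 0.0)
        assert new.theta == pytest.approx(state.theta)
        assert fluxes["drainage"] == 0.0 and fluxes["evaporation"] == 0.0

    def test_saturated_puddled_pond_drains_exactly_3mm(self, profile):
        state = saturated_state(profile, pond=60.0, puddled=True)
        _, fluxes = step_water_balance(state, profile, 0.0, 0.0, 0.0)
        assert fluxes["drainage"] == pytest.approx(3.0, abs=1e-9)

    def test_saturated_nonpuddled_drains_exactly_12mm(self, profile):
        state = saturated_state(profile, pond=60.0, puddled=False)
        _, fluxes = step_water_balance(state, profile, 0.0, 0.0, 0.0)
        assert fluxes["drainage"] == pytest.approx(12.0, abs=1e-9)

    def test_dry_down_matches_independent_two_stage_oracle(self):
        # independent recursion of the two-stage model: stage 1 at the
        # potential rate until U accumulates, then cona * (sqrt(t+1) - sqrt(t));
        # thick top layer so extractable water does not run out in 30 days
        profile = SoilProfile(
            layers=(SoilLayer(0, 30, ll=0.10, dul=0.30, sat=0.40),
                    SoilLayer(30, 60, ll=0.10, dul=0.30, sat=0.40))
        )
        pe = 6.0
        u, cona = profile.u_stage1, profile.cona_stage2
        expected, cum1, cum2 = [], 0.0, 0.0
        for _ in range(30):
            if cum1 < u:
                es = min(pe, u - cum1)
                cum1 += es
            else:
                t_prev = (cum2 / cona) ** 2
                es = min(pe, cona * math.sqrt(t_prev + 1.0) - cum2)
                cum2 += es
            expected.append(es)

        state = dul_state(profile)
        simulated = []
        for _ in range(30):
            state, fluxes = step_water_balance(state, profile, 0.0, 0.0, pe)
            simulated.append(fluxes["evaporation"])
        assert sum(simulated) == pytest.approx(sum(expected), abs=0.1)
        np.testing.assert_allclose(simulated, expected, atol=0.1)

    def test_evaporation_suppressed_under_pond(self, profile):
        state = saturated_state(profile, pond=40.0)
        new, fluxes = step_water_balance(state, profile, 0.0, 0.0, 5.0)
        assert fluxes["evaporation"] == pytest.approx(5.0)  # pond at potential
        assert new.pond < state.pond

    def test_rain_rewinds_evaporation_stages(self, profile):
        state = dul_state(profile)
        for _ in range(6):
            state, _ = step_water_balance(state, profile, 0.0, 0.0, 5.0)
        dried = state.cum_evap_stage1 + state.cum_evap_stage2
        state, _ = step_water_balance(state, profile, 15.0, 0.0, 0.0)
        assert state.cum_evap_stage1 + state.cum_evap_stage2 < dried

    def test_puddled_drains_no_faster_than_nonpuddled(self, profile):
        rng = np.random.default_rng(42)
        rains = rng.gamma(0.5, 20.0, 120)
        cum = {}
        for puddled in (False, True):
            state = saturated_state(profile, pond=30.0, puddled=puddled)
            total = 0.0
            for rain in rains:
                state, fluxes = step_water_balance(state, profile, float(rain), 0.0, 4.0)
                total += fluxes["drainage"]
            cum[puddled] = total
        assert cum[True] <= cum[False]

    def test_negative_inputs_rejected(self, profile):
        with pytest.raises(ValueError):
            step_water_balance(dul_state(profile), profile, -1.0, 0.0, 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        rain=st.floats(0, 120),
        irrigation=st.floats(0, 80),
        pe=st.floats(0, 9),
        demand=st.floats(0, 8),
        wetness=st.floats(0, 1),
        pond=st.floats(0, 80),
    )
    def test_conservation_and_bounds(self, rain, irrigation, pe, demand, wetness, pond):
        from paddysim import load_soil_profile

        profile = load_soil_profile()
        theta = [l.ll + wetness * (l.sat - l.ll) for l in profile.layers]
        state = SoilWaterState(theta=theta, pond=pond, puddled=wetness > 0.5)
        new, fluxes = step_water_balance(state, profile, rain, irrigation, pe, demand, 45.0)
        assert abs(fluxes["balance_error"]) < 1e-6
        for th, layer in zip(new.theta, profile.layers):
            assert layer.ll - 1e-9 <= th <= layer.sat + 1e-9
        assert new.pond >= 0.0
        assert fluxes["drainage"] <= (3.0 if state.puddled else 12.0) + 1e-9


class TestQueries:
    def test_fraction_at_field_capacity_is_one(self, profile):
        state = dul_state(profile)
        assert fraction_of_field_capacity(state, profile, 15.0) == pytest.approx(1.0)

    def test_fraction_proportional(self, profile):
        state = SoilWaterState(theta=[0.5 * l.dul for l in profile.layers])
        assert fraction_of_field_capacity(state, profile, 60.0) == pytest.approx(0.5)

    def test_top_layer_printed_value(self, profile):
        state = dul_state(profile)
        state.theta[0] = 0.120
        assert fraction_of_field_capacity(state, profile, 15.0) == pytest.approx(0.60)

    def test_irrigation_depth_saturated_plus_extra(self, profile):
        state = saturated_state(profile)
        assert irrigation_to_saturation_plus_pond(state, profile, 30.0, 50.0) == pytest.approx(50.0)

    def test_irrigation_depth_from_dul_matches_table_arithmetic(self, profile):
        state = dul_state(profile)
        # (0.390-0.200)*150 + (0.410-0.210)*150 + 50
        assert irrigation_to_saturation_plus_pond(state, profile, 30.0, 50.0) == pytest.approx(
            108.5
        )

    def test_irrigation_depth_from_ll_closed_form(self, profile):
        state = SoilWaterState(theta=[l.ll for l in profile.layers])
        expected = sum((l.sat - l.ll) * l.thickness_mm for l in profile.layers[:2])
        assert irrigation_to_saturation_plus_pond(state, profile, 30.0, 0.0) == pytest.approx(
            expected
        )


class TestPuddle:
    def test_puddling_sets_flag_and_slows_drainage(self, profile):
        state = saturated_state(profile, pond=20.0)
        new = puddle(state, profile)
        assert new.puddled
        _, fluxes = step_water_balance(new, profile, 0.0, 0.0, 0.0)
        assert fluxes["drainage"] <= 3.0 + 1e-9

    def test_idempotent(self, profile):
        state = puddle(saturated_state(profile, pond=20.0), profile)
        again = puddle(state, profile)
        assert again.puddled and again.theta == state.theta

    def test_dry_field_rejected(self, profile):
        with pytest.raises(ValueError):
            puddle(dul_state(profile), profile)


def test_potential_et_reasonable_range():
    # humid-tropics daily ET: a few mm, increasing with radiation and warmth
    low = potential_evapotranspiration(10.0, 20.0)
    high = potential_evapotranspiration(24.0, 35.0)
    assert 0.5 < low < high < 9.0
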