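"""Event-driven management rules and the daily season loop.

Encodes the establishment triggers, irrigation policies, mortality rules and
harvest rules of the four simulation experiments:

* transplanted rice on fixed nursery dates under full alternate-wetting-and-
  drying (AWD) irrigation;
* farmer-practice transplanted rice (fTR): nursery sown on the first 50 mm /
  3-day rainfall event in a 15 May - 15 Aug window, transplanted once
  seedlings are at least 21 days old and rain has ponded more than 50 mm on
  the bunded field, rainfed thereafter — plus its single-factor improvements
  (medium-duration hybrid, drought-index-triggered supplemental irrigation,
  30-day "appropriate aged" seedlings);
* rainfed direct-seeded rice (DSR) sown when the 0-15 cm layer sits at
  40-80% of field capacity for three consecutive days, with post-sowing
  inundation mortality;
* irrigated DSR with pre-sowing irrigation and drought-index-triggered
  supplemental irrigation.

Daily event order (fixed by design): irrigation decided from yesterday's
end-of-day state -> water balance -> crop development and growth -> trigger
evaluation on today's end-of-day state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import crop as cr
from . import soil as so

__all__ = [
    "Scenario",
    "SeasonResult",
    "simulate_season",
    "ftr_nursery_trigger",
    "ftr_transplant_trigger",
    "dsr_sowing_trigger",
    "ponding_mortality",
    "awd_topup",
    "harvest_rule",
    "PONDING_MORTALITY_TABLE",
]

# establishment / irrigation rule constants
NURSERY_RAIN_TRIGGER = 50.0  # mm over 3 consecutive days
NURSERY_RAIN_WINDOW = 3
TRANSPLANT_MIN_AGE = 21  # days
TRANSPLANT_POND_TRIGGER = 50.0  # mm, strict ">"
AWD_POND_TARGET = 50.0  # mm maintained for the first 15 days
AWD_FLOOD_DAYS = 15
AWD_DRY_DAYS = 2  # irrigate two days after ponded water disappears
LSTRS_IRRIGATION_THRESHOLD = 0.8  # strict "<"
IRRIGATION_DEPTH_CM = 30.0  # saturate the top two layers ...
IRRIGATION_EXTRA_POND = 50.0  # ... plus 50 mm of surface water
DSR_FC_BAND = (0.40, 0.80)  # fraction of field capacity in 0-15 cm
DSR_FC_DEPTH = 15.0
DSR_FC_DAYS = 3
DSR_MORTALITY_WINDOW = 5  # days after sowing
HARVEST_DELAY = 8  # days after physiological maturity
IRRIGATION_CUTOFF_DAYS = 7  # cease irrigation one week before maturity
DROUGHT_KILL_DAYS = 15  # days of total stress that kill a vegetative crop
DROUGHT_KILL_LSTRS = 0.05

# plant-density multiplier by number of ponded days in the first five days
# after DSR sowing (15/40/75% reduction; five days means crop failure)
PONDING_MORTALITY_TABLE = {0: 1.0, 1: 1.0, 2: 0.85, 3: 0.60, 4: 0.25}


@dataclass
class Scenario:
    """A declarative management rule set for one cropping system."""

    name: str
    method: str  # 'transplanted' | 'dsr'
    cultivar_name: str = "MTU7029"
    establishment: str = "ftr_trigger"
    # 'fixed_nursery' | 'ftr_trigger' | 'onset_transplant' | 'moisture_window'
    sowing_window: tuple = ((5, 15), (8, 15))
    nursery_date: tuple | None = None  # (month, day) for 'fixed_nursery'
    irrigation_policy: str = "none"
    # 'none' | 'full_awd' | 'lstrs_triggered' | 'dsr_irrigated'
    seedling_policy: str = "farmer_nursery"  # or 'fixed_age_30'
    hills_m2: float = 33.0
    seedlings_per_hill: float = 2.0
    plants_m2: float = 150.0
    row_spacing_cm: float = 20.0
    presow_irrigation: bool = False
    transplant_deadline: tuple = (9, 30)
    n_fertilizer: float = 150.0  # kg N ha-1, recorded only (N non-limiting)
    n_split: tuple = ((0, 0.5), (21, 0.5))  # (days after establishment, share)

    def __post_init__(self):
        if self.method not in ("transplanted", "dsr"):
            raise ValueError(f"unknown method {self.method!r}")
        if _doy(self.sowing_window[0]) >= _doy(self.sowing_window[1]):
            raise ValueError("sowing window start must precede its end")
        if self.method == "transplanted" and self.establishment == "moisture_window":
            raise ValueError("moisture_window establishment is a DSR rule")

    @property
    def transplant_density(self):
        return self.hills_m2 * self.seedlings_per_hill


@dataclass
class SeasonResult:
    """Per-year outcome of one scenario."""

    year: int
    scenario: str
    nursery_doy: int | None = None
    establish_doy: int | None = None  # transplanting or DSR sowing day of year
    seedling_age: float | None = None
    yield_t_ha: float = 0.0
    irrigation_events: int = 0
    irrigation_total: float = 0.0
    lstrs_veg_mean: float = math.nan
    lstrs_rep_mean: float = math.nan
    sterility: float = math.nan
    maturity_doy: int | None = None
    harvest_doy: int | None = None
    failure_mode: str = "none"
    monsoon_rain: float = 0.0


def _doy(month_day, year=2001):
    """Day of year of a (month, day) pair in a non-leap reference year."""
    month, day = month_day
    cum = (0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334)
    return cum[month - 1] + day


# ---------------------------------------------------------------------------
# standalone rule operations (pure functions over series)
# ---------------------------------------------------------------------------

def ftr_nursery_trigger(rain, doy, window=((5, 15), (8, 15))):
    """First day-of-year in the window whose trailing 3-day rainfall total is
    at least 50 mm; None if the condition is never met."""
    rain = np.asarray(rain, dtype=float)
    doy = np.asarray(doy)
    csum = np.convolve(rain, np.ones(NURSERY_RAIN_WINDOW), mode="full")[: len(rain)]
    ok = (csum >= NURSERY_RAIN_TRIGGER) & (doy >= _doy(window[0])) & (doy <= _doy(window[1]))
    idx = np.flatnonzero(ok)
    return int(doy[idx[0]]) if len(idx) else None


def ftr_transplant_trigger(pond, doy, nursery_doy, deadline_doy=273):
    """First day with seedlings at least 21 days old and end-of-day ponding
    strictly above 50 mm; None if not met by the deadline."""
    if nursery_doy is None:
        return None
    pond = np.asarray(pond, dtype=float)
    doy = np.asarray(doy)
    ok = (
        (doy >= nursery_doy + TRANSPLANT_MIN_AGE)
        & (doy <= deadline_doy)
        & (pond > TRANSPLANT_POND_TRIGGER)
    )
    idx = np.flatnonzero(ok)
    return int(doy[idx[0]]) if len(idx) else None


def dsr_sowing_trigger(fc_fraction, doy, window=((5, 1), (8, 31))):
    """First day completing three consecutive days with the 0-15 cm moisture
    fraction of field capacity inside [0.40, 0.80]; None if never met."""
    frac = np.asarray(fc_fraction, dtype=float)
    doy = np.asarray(doy)
    lo, hi = DSR_FC_BAND
    in_band = (frac >= lo) & (frac <= hi)
    run = 0
    for i in range(len(frac)):
        run = run + 1 if in_band[i] else 0
        if run >= DSR_FC_DAYS and _doy(window[0]) <= doy[i] <= _doy(window[1]):
            return int(doy[i])
    return None


def ponding_mortality(ponded_days, density):
    """Apply the DSR seedling-mortality rule for ponding within the first
    five days after sowing; returns (surviving density, failed flag)."""
    if ponded_days >= DSR_MORTALITY_WINDOW:
        return 0.0, True
    return density * PONDING_MORTALITY_TABLE[int(ponded_days)], False


def awd_topup(pond, target=AWD_POND_TARGET):
    """Daily top-up (mm) that restores the pond to the AWD target depth."""
    return max(0.0, target - pond)


def harvest_rule(maturity_doy):
    """Harvest eight days after physiological maturity (grain dry-down)."""
    return None if maturity_doy is None else maturity_doy + HARVEST_DELAY


# ---------------------------------------------------------------------------
# the daily season loop
# ---------------------------------------------------------------------------

def _irrigation_cease_dvs(cultivar):
    """DVS beyond which irrigation stops: one week of reference development
    short of maturity."""
    daily = cultivar.dvr_reproductive * cultivar.dev_scale * 20.0
    return cr.DVS_MATURITY - IRRIGATION_CUTOFF_DAYS * daily


def simulate_season(scenario, year_forcing, profile, cultivar, gp=cr.DEFAULT_GROWTH,
                    year=0):
    """Run one scenario over one calendar year of forcing.

    ``year_forcing`` is the dict of numpy arrays from
    :meth:`paddysim.weather.WeatherSeries.year_arrays`.
    """
    doys = year_forcing["doy"]
    n_days = len(doys)
    tmax = year_forcing["tmax"]
    tmin = year_forcing["tmin"]
    rain = year_forcing["rain"]
    srad = year_forcing["srad"]
    daylength = year_forcing["daylength"]
    tavg = (tmax + tmin) / 2.0

    result = SeasonResult(year=year, scenario=scenario.name)
    result.monsoon_rain = float(rain[(doys >= 152) & (doys <= 273)].sum())

    soil = so.SoilWaterState.initial(profile)
    crop = None
    cease_dvs = _irrigation_cease_dvs(cultivar)

    window_start = _doy(scenario.sowing_window[0])
    window_end = _doy(scenario.sowing_window[1])
    deadline = _doy(scenario.transplant_deadline)
    fixed_nursery_doy = (
        _doy(scenario.nursery_date) if scenario.nursery_date is not None else None
    )

    nursery_doy = None
    nursery_dvs = 0.0
    establish_doy = None
    flood_doy = None  # fixed-date systems: flood and puddle one day before transplanting
    transplant_doy = None
    irrigation_tomorrow = 0.0
    band_run = 0
    dry_pond_days = 0
    ponded_days = 0
    mortality_applied = scenario.method != "dsr"
    drought_days = 0
    presow_done = not (scenario.method == "dsr" and scenario.presow_irrigation)
    lstrs_series = []
    dvs_series = []

    for i in range(n_days):
        doy = int(doys[i])
        t_mean = float(tavg[i])
        pet = so.potential_evapotranspiration(float(srad[i]), t_mean)

        irrigation = irrigation_tomorrow
        irrigation_tomorrow = 0.0
        if irrigation > 0.0:
            result.irrigation_events += 1
            result.irrigation_total += irrigation

        # canopy partition of potential evaporation
        if crop is not None and crop.alive:
            cover = 1.0 - math.exp(-gp.k_extinction * crop.lai)
            transp_demand = pet * cover
            pe_surface = pet * (1.0 - cover)
            root_depth = crop.root_depth_cm
        else:
            transp_demand = 0.0
            pe_surface = pet
            root_depth = 0.0

        soil, fluxes = so.step_water_balance(
            soil, profile, float(rain[i]), irrigation, pe_surface, transp_demand, root_depth
        )
        pond_peak = fluxes["pond_peak"]

        # fixed-date establishment: flood water arrived today -> puddle;
        # transplant the day after puddling
        if flood_doy is not None and doy == flood_doy and soil.pond > 0.0:
            soil = so.puddle(soil, profile)
        if transplant_doy is not None and doy == transplant_doy and crop is None:
            crop = cr.transplant(
                cultivar, 30.0, scenario.transplant_density, nursery_dvs, gp=gp
            )
            establish_doy = doy
            result.seedling_age = 30.0

        # nursery development (transplanted systems, sown nursery): seedlings
        # develop continuously, capped at panicle initiation
        if scenario.method == "transplanted" and nursery_doy is not None and crop is None:
            tt_day = cr.thermal_time(t_mean, gp)
            if nursery_dvs < cr.DVS_JUVENILE_END:
                nursery_dvs += cultivar.dvr_juvenile * cultivar.dev_scale * tt_day
            else:
                nursery_dvs += (
                    cultivar.dvr_photoperiod
                    * cultivar.dev_scale
                    * tt_day
                    * cr.photoperiod_factor(cultivar, float(daylength[i]))
                )
            nursery_dvs = min(nursery_dvs, cr.DVS_PHOTOPERIOD_END)

        # crop development and growth
        if crop is not None and crop.alive and establish_doy is not None and doy > establish_doy:
            lstrs = cr.drought_stress_index(crop, soil, profile, gp=gp)
            crop = cr.develop(crop, cultivar, t_mean, float(daylength[i]), gp)
            crop = cr.grow(crop, cultivar, float(srad[i]), lstrs, t_mean, gp)
            lstrs_series.append(lstrs)
            dvs_series.append(crop.dvs)

            # DSR inundation mortality over the first five days after sowing
            if not mortality_applied:
                days_since = doy - establish_doy
                if days_since <= DSR_MORTALITY_WINDOW and soil.pond > 0.0:
                    ponded_days += 1
                if days_since >= DSR_MORTALITY_WINDOW or ponded_days >= DSR_MORTALITY_WINDOW:
                    density, failed = ponding_mortality(ponded_days, crop.density)
                    mortality_applied = True
                    if failed:
                        crop = cr.kill(crop)
                        result.failure_mode = "inundation_kill"
                    else:
                        crop.density = density

            # drought kill during the vegetative phase: a long spell of total
            # stress, or a canopy senesced to nothing, is unrecoverable
            if crop.alive and crop.dvs < cr.DVS_ANTHESIS:
                if lstrs < DROUGHT_KILL_LSTRS:
                    drought_days += 1
                else:
                    drought_days = 0
                canopy_collapsed = (
                    doy - establish_doy > 20 and crop.lai < 0.02
                )
                if drought_days >= DROUGHT_KILL_DAYS or canopy_collapsed:
                    crop = cr.kill(crop)
                    result.failure_mode = "drought_kill"

            if crop.mature:
                result.maturity_doy = doy
                break

        # ---- end-of-day trigger evaluation (sets tomorrow's actions) ----
        if scenario.method == "transplanted":
            if scenario.establishment == "fixed_nursery":
                if nursery_doy is None and doy >= fixed_nursery_doy:
                    nursery_doy = fixed_nursery_doy
                    result.nursery_doy = nursery_doy
                    flood_doy = nursery_doy + 29
                    transplant_doy = nursery_doy + 30
                if flood_doy is not None and doy == flood_doy - 1:
                    irrigation_tomorrow = so.irrigation_to_saturation_plus_pond(
                        soil, profile, IRRIGATION_DEPTH_CM, IRRIGATION_EXTRA_POND
                    )
            elif scenario.establishment == "ftr_trigger":
                if nursery_doy is None and window_start <= doy <= window_end:
                    if i >= 2 and rain[i] + rain[i - 1] + rain[i - 2] >= NURSERY_RAIN_TRIGGER:
                        nursery_doy = doy
                        result.nursery_doy = doy
                elif (
                    nursery_doy is not None
                    and crop is None
                    and doy >= nursery_doy + TRANSPLANT_MIN_AGE
                    and doy <= deadline
                    and pond_peak > TRANSPLANT_POND_TRIGGER
                    and soil.pond > 0.0
                ):
                    soil = so.puddle(soil, profile)
                    age = float(doy - nursery_doy)
                    crop = cr.transplant(
                        cultivar, age, scenario.transplant_density, nursery_dvs, gp=gp
                    )
                    establish_doy = doy
                    result.seedling_age = age
            elif scenario.establishment == "onset_transplant":
                if (
                    crop is None
                    and window_start <= doy <= deadline
                    and pond_peak > TRANSPLANT_POND_TRIGGER
                    and soil.pond > 0.0
                ):
                    soil = so.puddle(soil, profile)
                    crop = cr.transplant(cultivar, 30.0, scenario.transplant_density, gp=gp)
                    establish_doy = doy
                    result.nursery_doy = doy - 30
                    result.seedling_age = 30.0
            # irrigation policies (post-transplant)
            if crop is not None and crop.alive and establish_doy is not None:
                if scenario.irrigation_policy == "full_awd" and crop.dvs < cease_dvs:
                    if doy - establish_doy < AWD_FLOOD_DAYS:
                        irrigation_tomorrow = awd_topup(soil.pond)
                    else:
                        dry_pond_days = dry_pond_days + 1 if soil.pond <= 0.0 else 0
                        if dry_pond_days >= AWD_DRY_DAYS:
                            irrigation_tomorrow = so.irrigation_to_saturation_plus_pond(
                                soil, profile, IRRIGATION_DEPTH_CM, IRRIGATION_EXTRA_POND
                            )
                            dry_pond_days = 0
                elif scenario.irrigation_policy == "lstrs_triggered" and crop.dvs < cease_dvs:
                    lstrs_now = cr.drought_stress_index(crop, soil, profile, gp=gp)
                    if lstrs_now < LSTRS_IRRIGATION_THRESHOLD:
                        irrigation_tomorrow = so.irrigation_to_saturation_plus_pond(
                            soil, profile, IRRIGATION_DEPTH_CM, IRRIGATION_EXTRA_POND
                        )
        else:  # DSR
            if crop is None:
                if not presow_done and doy >= window_start:
                    frac = so.fraction_of_field_capacity(soil, profile, DSR_FC_DEPTH)
                    if frac < DSR_FC_BAND[0]:
                        top = profile.layers[0]
                        irrigation_tomorrow = max(
                            0.0, (top.dul - soil.theta[0]) * top.thickness_mm
                        )
                    presow_done = True
                if window_start <= doy <= window_end:
                    frac = so.fraction_of_field_capacity(soil, profile, DSR_FC_DEPTH)
                    band_run = band_run + 1 if DSR_FC_BAND[0] <= frac <= DSR_FC_BAND[1] else 0
                    if band_run >= DSR_FC_DAYS:
                        crop = cr.sow_direct(cultivar, scenario.plants_m2, gp=gp)
                        establish_doy = doy
            elif (
                crop.alive
                and scenario.irrigation_policy == "dsr_irrigated"
                and doy - establish_doy > DSR_MORTALITY_WINDOW
                and crop.dvs < cease_dvs
            ):
                lstrs_now = cr.drought_stress_index(crop, soil, profile, gp=gp)
                if lstrs_now < LSTRS_IRRIGATION_THRESHOLD:
                    irrigation_tomorrow = so.irrigation_to_saturation_plus_pond(
                        soil, profile, IRRIGATION_DEPTH_CM, IRRIGATION_EXTRA_POND
                    )

    # ---- season wrap-up ----
    result.establish_doy = establish_doy
    if establish_doy is None:
        result.failure_mode = "not_established"
        result.yield_t_ha = 0.0
    elif crop is not None and not crop.alive:
        result.yield_t_ha = 0.0
    elif result.maturity_doy is None:
        # season ended before physiological maturity; a crop well into grain
        # fill is harvested with whatever has filled, otherwise it is lost
        if crop.dvs >= 1.2:
            result.yield_t_ha = cr.yield_t_ha(crop, cultivar, gp)
            result.sterility = crop.sterility
            if result.yield_t_ha <= 0.0 or crop.sterility >= 0.98:
                result.failure_mode = "cold_kill"
        else:
            result.failure_mode = "cold_kill"
            result.yield_t_ha = 0.0
    else:
        result.yield_t_ha = cr.yield_t_ha(crop, cultivar, gp)
        result.sterility = crop.sterility
        result.harvest_doy = harvest_rule(result.maturity_doy)
        if crop.sterility >= 0.98:
            result.failure_mode = "cold_kill"
    if lstrs_series:
        result.lstrs_veg_mean, result.lstrs_rep_mean = cr.phase_mean_stress(
            lstrs_series, dvs_series
        )
    return result
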