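"""Multi-year simulation experiments and their preset plans.

An :class:`ExperimentPlan` is a factor grid of management scenarios run over
every year of a weather series; years are treated as independent replicates
(the soil is re-initialized each 1 January), and non-established years are
recorded as zero-yield rows and included in all distributional summaries.

The four shipped presets are the core simulation experiments:

1. transplanting-date response — 16 weekly nursery dates (1 May .. 14 Aug,
   transplanted 30 days later) x 2 cultivars under full AWD irrigation;
2. farmer-practice transplanted rice (fTR) and its single-factor
   improvements (medium-duration hybrid, supplemental irrigation, both
   combined, 30-day "appropriate aged" seedlings);
3. rainfed direct-seeded rice over a 1 May - 31 Aug moisture-triggered
   sowing window, for both cultivars;
4. irrigated DSR over ten weekly sowing-window start dates S1-S10
   (1 May .. 3 Jul), for both cultivars.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import crop as cr
from .io import load_cultivars, load_soil_profile
from .management import Scenario, simulate_season
from .weather import MonsoonGeneratorParams, WeatherSeries, generate_weather

__all__ = [
    "ExperimentPlan",
    "run_experiment",
    "experiment1_preset",
    "experiment2_presets",
    "experiment3_preset",
    "experiment4_preset",
]

RESULT_COLUMNS = [
    "scenario",
    "year",
    "nursery_doy",
    "establish_doy",
    "seedling_age",
    "yield_t_ha",
    "irrigation_events",
    "irrigation_total",
    "lstrs_veg_mean",
    "lstrs_rep_mean",
    "sterility",
    "maturity_doy",
    "harvest_doy",
    "failure_mode",
    "monsoon_rain",
]


@dataclass
class ExperimentPlan:
    """A named list of scenarios plus the weather to run them over."""

    name: str
    scenarios: list
    weather: WeatherSeries | None = None
    generator_params: MonsoonGeneratorParams | None = None
    n_years: int = 44
    seed: int = 0

    def resolve_weather(self):
        if self.weather is not None:
            return self.weather
        return generate_weather(
            self.generator_params or MonsoonGeneratorParams(), self.n_years, self.seed
        )


def run_experiment(plan, profile=None, cultivars=None, gp=cr.DEFAULT_GROWTH):
    """Run every scenario over every year; returns one row per scenario-year."""
    profile = profile or load_soil_profile()
    cultivars = cultivars or load_cultivars()
    weather = plan.resolve_weather()
    years = weather.years
    if not years:
        raise ValueError("weather series covers no years")
    for scen in plan.scenarios:
        if scen.cultivar_name not in cultivars:
            raise ValueError(f"scenario {scen.name}: unknown cultivar {scen.cultivar_name}")
    rows = []
    for year in years:
        forcing = weather.year_arrays(year)
        for scen in plan.scenarios:
            res = simulate_season(
                scen, forcing, profile, cultivars[scen.cultivar_name], gp=gp, year=year
            )
            rows.append(
                {
                    "scenario": res.scenario,
                    "year": res.year,
                    "nursery_doy": res.nursery_doy,
                    "establish_doy": res.establish_doy,
                    "seedling_age": res.seedling_age,
                    "yield_t_ha": res.yield_t_ha,
                    "irrigation_events": res.irrigation_events,
                    "irrigation_total": res.irrigation_total,
                    "lstrs_veg_mean": res.lstrs_veg_mean,
                    "lstrs_rep_mean": res.lstrs_rep_mean,
                    "sterility": res.sterility,
                    "maturity_doy": res.maturity_doy,
                    "harvest_doy": res.harvest_doy,
                    "failure_mode": res.failure_mode,
                    "monsoon_rain": res.monsoon_rain,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _weekly_dates(start_month, start_day, count):
    """(month, day) pairs at 7-day intervals in a non-leap calendar."""
    lengths = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
    cum = [0]
    for n in lengths:
        cum.append(cum[-1] + n)
    doy = cum[start_month - 1] + start_day
    out = []
    for _ in range(count):
        month = next(m for m in range(12) if cum[m] < doy <= cum[m + 1])
        out.append((month + 1, doy - cum[month]))
        doy += 7
    return out


# 16 weekly nursery dates, 1 May .. 14 Aug (transplanting 31 May .. 14 Sep)
EXPERIMENT1_NURSERY_DATES = _weekly_dates(5, 1, 16)

# S1-S10 irrigated-DSR sowing-window start dates, 1 May .. 3 Jul
EXPERIMENT4_WINDOW_STARTS = _weekly_dates(5, 1, 10)


def experiment1_preset(cultivars=("MTU7029", "Arize6129"), **plan_kwargs):
    """Transplanting-date response under full AWD irrigation."""
    scenarios = [
        Scenario(
            name=f"{cv}_T{i + 1}",
            method="transplanted",
            cultivar_name=cv,
            establishment="fixed_nursery",
            nursery_date=date,
            sowing_window=((5, 1), (8, 15)),
            irrigation_policy="full_awd",
        )
        for cv in cultivars
        for i, date in enumerate(EXPERIMENT1_NURSERY_DATES)
    ]
    return ExperimentPlan(name="transplanting_dates", scenarios=scenarios, **plan_kwargs)


def experiment2_presets(**plan_kwargs):
    """fTR and its single-factor improvements (the five compared systems)."""
    base = dict(
        method="transplanted",
        establishment="ftr_trigger",
        sowing_window=((5, 15), (8, 15)),
    )
    scenarios = [
        Scenario(name="fTR", cultivar_name="MTU7029", irrigation_policy="none", **base),
        Scenario(
            name="fTR_short_duration",
            cultivar_name="Arize6129",
            irrigation_policy="none",
            **base,
        ),
        Scenario(
            name="fTR_supplemental_irrigation",
            cultivar_name="MTU7029",
            irrigation_policy="lstrs_triggered",
            **base,
        ),
        Scenario(
            name="fTR_irrigation_short_duration",
            cultivar_name="Arize6129",
            irrigation_policy="lstrs_triggered",
            **base,
        ),
        Scenario(
            name="fTR_appropriate_seedling",
            method="transplanted",
            cultivar_name="MTU7029",
            establishment="onset_transplant",
            sowing_window=((5, 15), (9, 15)),
            irrigation_policy="none",
            seedling_policy="fixed_age_30",
        ),
    ]
    return ExperimentPlan(name="ftr_interventions", scenarios=scenarios, **plan_kwargs)


def experiment3_preset(cultivars=("MTU7029", "Arize6129"), **plan_kwargs):
    """Rainfed DSR with the soil-moisture sowing trigger."""
    scenarios = [
        Scenario(
            name=f"rainfed_DSR_{cv}",
            method="dsr",
            cultivar_name=cv,
            establishment="moisture_window",
            sowing_window=((5, 1), (8, 31)),
            irrigation_policy="none",
        )
        for cv in cultivars
    ]
    return ExperimentPlan(name="rainfed_dsr", scenarios=scenarios, **plan_kwargs)


def experiment4_preset(cultivars=("MTU7029", "Arize6129"), **plan_kwargs):
    """Irrigated DSR over the S1-S10 sowing-window start dates."""
    scenarios = [
        Scenario(
            name=f"irrigated_DSR_{cv}_S{i + 1}",
            method="dsr",
            cultivar_name=cv,
            establishment="moisture_window",
            sowing_window=(start, (8, 31)),
            irrigation_policy="dsr_irrigated",
            presow_irrigation=True,
        )
        for cv in cultivars
        for i, start in enumerate(EXPERIMENT4_WINDOW_STARTS)
    ]
    return ExperimentPlan(name="irrigated_dsr", scenarios=scenarios, **plan_kwargs)
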