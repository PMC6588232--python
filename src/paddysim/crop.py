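"""Simplified process-based rice crop model.

Phenology is thermal-time driven on the continuous development-stage (DVS)
scale — 0 at establishment, 1 at anthesis, 2 at physiological maturity — with
four phases (juvenile, photoperiod-sensitive, panicle development,
reproductive) whose per-degree-day rates come from the cultivar's genetic
coefficients.  Photoperiod sensitivity delays the second phase when daylength
exceeds the cultivar optimum.  Biomass accumulates by radiation-use
efficiency on intercepted PAR, modulated by the leaf-rolling drought stress
index ``lstrs`` (1 = no stress, 0 = maximum stress), and is partitioned to a
panicle pool after anthesis; grain yield is the minimum of the spikelet sink
(spikelet number x grain mass, discounted by cold-induced sterility) and the
panicle source.  Cold sterility accumulates as cooling degree days below the
threshold ``cttmax`` (28 degC) during the flowering-sensitive window.

The engine is a deliberately minimal surrogate for a full cropping-system
model: it preserves the behaviours the management-rule analysis depends on
(date responses, stress responses, cultivar duration contrasts) rather than
any particular host model's internal equations.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Cultivar",
    "CropState",
    "GrowthParams",
    "thermal_time",
    "photoperiod_factor",
    "phase_durations_days",
    "calibrate_dev_scale",
    "develop",
    "grow",
    "drought_stress_index",
    "cold_sterility",
    "sterility_from_cdd",
    "yield_t_ha",
    "transplant",
    "sow_direct",
    "phase_mean_stress",
]

# DVS phase boundaries (ORYZA convention)
DVS_JUVENILE_END = 0.40
DVS_PHOTOPERIOD_END = 0.65
DVS_ANTHESIS = 1.00
DVS_MATURITY = 2.00

# cold-sterility window on the DVS scale (flowering-sensitive period)
STERILITY_WINDOW = (0.96, 1.20)

PHOTOPERIOD_EXCESS_CAP = 1.5  # h; see photoperiod_factor


@dataclass(frozen=True)
class GrowthParams:
    """Surrogate growth-engine constants (documented defaults, config-tunable)."""

    t_base: float = 8.0  # degC, development/growth base
    t_opt: float = 30.0  # degC, thermal-time optimum
    t_ceiling: float = 42.0  # degC, upper cutoff
    rue: float = 2.2  # g DM per MJ intercepted PAR (pre-anthesis)
    par_fraction: float = 0.5  # PAR share of global radiation
    k_extinction: float = 0.5
    sla: float = 0.025  # m2 leaf per g leaf
    leaf_fraction: float = 0.5  # share of shoot growth to leaf pre-anthesis
    lai_rgr: float = 0.0090  # relative LAI growth per degC d in the exponential stage
    lai_exponential_until: float = 1.0
    lai_max: float = 7.0
    grain_mass: float = 2.5e-5  # kg per grain (25 mg)
    f_crit: float = 0.5  # available-water fraction at stress onset
    shock_days: float = 9.0  # transplanting shock pause
    reserve_fraction: float = 0.25  # translocatable share of anthesis shoot biomass
    sterility_c0: float = 20.0  # cooling degree days tolerated before sterility
    sterility_c1: float = 100.0  # cooling degree days from onset to full sterility
    stress_senescence_lstrs: float = 0.2  # below this, drought kills leaf area
    stress_senescence_rate: float = 0.95  # daily LAI survival at lstrs = 0
    root_growth_cm_d: float = 1.0
    root_depth_max_cm: float = 60.0


DEFAULT_GROWTH = GrowthParams()


@dataclass(frozen=True)
class Cultivar:
    """Genetic coefficients of a rice cultivar.

    Development rates are per degree-day within each phenological phase;
    ``ppse`` is the photoperiod sensitivity (h-1) and ``mopp`` the maximum
    optimum photoperiod (h); ``spgf`` the spikelet growth factor (spikelets
    per kg of growth during panicle development); ``panicle_partition`` the
    fractions of shoot dry matter partitioned to panicles at development
    stages 1.0, 1.2 and 2.5; ``cttmax`` the cooling-degree-day threshold
    temperature for spikelet sterility.  ``dev_scale`` is the surrogate's
    calibration scalar fixing the rated crop duration (see
    :func:`calibrate_dev_scale`).
    """

    name: str
    dvr_juvenile: float
    dvr_photoperiod: float
    dvr_panicle: float
    dvr_reproductive: float
    ppse: float
    mopp: float
    spgf: float
    panicle_partition: tuple
    cttmax: float = 28.0
    duration_days: float = 150.0
    dev_scale: float = 1.0

    def __post_init__(self):
        rates = (
            self.dvr_juvenile,
            self.dvr_photoperiod,
            self.dvr_panicle,
            self.dvr_reproductive,
        )
        if any(r <= 0 for r in rates):
            raise ValueError("development rates must be positive")
        p = self.panicle_partition
        if len(p) != 3 or any(not 0.0 <= x <= 1.0 for x in p) or not (p[0] <= p[1] <= p[2] + 1e-12):
            raise ValueError("panicle partition fractions must be non-decreasing in [0, 1]")


@dataclass
class CropState:
    """Daily crop state (biomass pools in kg ha-1, LAI in m2 m-2)."""

    dvs: float = 0.0
    biomass_shoot: float = 0.0
    biomass_panicle: float = 0.0
    lai: float = 0.0
    density: float = 150.0
    ref_density: float = 150.0
    spikelets: float = 0.0
    sterility: float = 0.0
    lstrs: float = 1.0
    seedling_age: float = 0.0
    alive: bool = True
    root_depth_cm: float = 5.0
    shock_days_left: float = 0.0
    growth_penalty: float = 1.0
    growth_paused: bool = False
    # internal bookkeeping
    cdd: float = 0.0
    panicle_phase_growth: float = 0.0  # kg ha-1 shoot growth over DVS 0.65-1.00
    reserve_pool: float = 0.0
    reserve_remaining: float = 0.0
    lai_at_anthesis: float = 0.0
    dvs_at_last_grow: float = 0.0

    @property
    def phase(self):
        if self.dvs < DVS_JUVENILE_END:
            return "juvenile"
        if self.dvs < DVS_PHOTOPERIOD_END:
            return "photoperiod"
        if self.dvs < DVS_ANTHESIS:
            return "panicle"
        return "reproductive"

    @property
    def mature(self):
        return self.dvs >= DVS_MATURITY

    def copy(self):
        return copy.copy(self)


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

def thermal_time(tavg, gp=DEFAULT_GROWTH):
    """Effective degree days: linear from base to optimum, declining to the ceiling."""
    if tavg <= gp.t_base:
        return 0.0
    if tavg <= gp.t_opt:
        return tavg - gp.t_base
    if tavg >= gp.t_ceiling:
        return 0.0
    return (gp.t_opt - gp.t_base) * (gp.t_ceiling - tavg) / (gp.t_ceiling - gp.t_opt)


def photoperiod_factor(cultivar, daylength):
    """Development-rate multiplier in the photoperiod-sensitive phase.

    Rice is a short-day plant: daylength above the maximum optimum
    photoperiod slows development by ``ppse`` per excess hour.  The response
    saturates at :data:`PHOTOPERIOD_EXCESS_CAP` hours of excess so that
    strongly sensitive cultivars are delayed but never stalled.
    """
    excess = min(PHOTOPERIOD_EXCESS_CAP, max(0.0, daylength - cultivar.mopp))
    return max(0.0, 1.0 - cultivar.ppse * excess)


def _phase_rates(cultivar):
    return (
        cultivar.dvr_juvenile,
        cultivar.dvr_photoperiod,
        cultivar.dvr_panicle,
        cultivar.dvr_reproductive,
    )


_PHASE_SPANS = (
    DVS_JUVENILE_END,
    DVS_PHOTOPERIOD_END - DVS_JUVENILE_END,
    DVS_ANTHESIS - DVS_PHOTOPERIOD_END,
    DVS_MATURITY - DVS_ANTHESIS,
)


def phase_durations_days(cultivar, tavg=28.0, daylength=13.0, gp=DEFAULT_GROWTH):
    """Closed-form phase durations (days) under constant forcing.

    Duration of each phase is its DVS span divided by
    rate * dev_scale * thermal_time (times the photoperiod factor in the
    photoperiod-sensitive phase).
    """
    tt = thermal_time(tavg, gp)
    if tt <= 0:
        return (math.inf,) * 4
    pf = photoperiod_factor(cultivar, daylength)
    durations = []
    for span, rate, factor in zip(_PHASE_SPANS, _phase_rates(cultivar), (1.0, pf, 1.0, 1.0)):
        daily = rate * cultivar.dev_scale * tt * factor
        durations.append(span / daily if daily > 0 else math.inf)
    return tuple(durations)


def calibrate_dev_scale(cultivar, target_days=None, ref_tavg=28.0, ref_daylength=13.0):
    """Return the cultivar with ``dev_scale`` solving
    sum(phase durations) == rated duration at the reference forcing
    (constant 28 degC, 13.0 h photoperiod — the Patna rice-season daylength).
    """
    target = target_days if target_days is not None else cultivar.duration_days
    unit = replace(cultivar, dev_scale=1.0)
    raw_days = sum(phase_durations_days(unit, ref_tavg, ref_daylength))
    return replace(cultivar, dev_scale=raw_days / target)


def develop(state, cultivar, tavg, daylength, gp=DEFAULT_GROWTH):
    """Advance development one day; accumulates cooling degree days in the
    flowering-sensitive window and updates sterility."""
    if not state.alive:
        return state
    s = state.copy()
    if s.shock_days_left > 0:
        s.shock_days_left -= 1
        s.growth_paused = True
        return s
    s.growth_paused = False
    tt = thermal_time(tavg, gp)
    rates = _phase_rates(cultivar)
    if s.dvs < DVS_JUVENILE_END:
        rate = rates[0]
        pf = 1.0
    elif s.dvs < DVS_PHOTOPERIOD_END:
        rate = rates[1]
        pf = photoperiod_factor(cultivar, daylength)
    elif s.dvs < DVS_ANTHESIS:
        rate = rates[2]
        pf = 1.0
    else:
        rate = rates[3]
        pf = 1.0
    lo, hi = STERILITY_WINDOW
    if lo <= s.dvs < hi:
        s.cdd += max(0.0, cultivar.cttmax - tavg)
        s.sterility = sterility_from_cdd(s.cdd, gp)
    s.dvs = min(DVS_MATURITY, s.dvs + rate * cultivar.dev_scale * tt * pf)
    s.root_depth_cm = min(gp.root_depth_max_cm, s.root_depth_cm + gp.root_growth_cm_d)
    return s


# ---------------------------------------------------------------------------
# stress
# ---------------------------------------------------------------------------

def drought_stress_index(state, soil_state, profile, root_depth=None, gp=DEFAULT_GROWTH):
    """Leaf-rolling drought stress index ``lstrs`` in [0, 1].

    The fraction of available water (theta - LL)/(DUL - LL), depth-weighted
    over the root zone, relative to the stress-onset fraction ``f_crit``;
    1 under standing water, 0 at the lower limit of extraction.
    """
    if soil_state.pond > 0.0:
        return 1.0
    depth = root_depth if root_depth is not None else state.root_depth_cm
    depth = max(depth, profile.layers[0].bottom_depth)
    total = 0.0
    weight = 0.0
    for theta, layer in zip(soil_state.theta, profile.layers):
        if layer.top_depth >= depth:
            break
        thick = min(layer.bottom_depth, depth) - layer.top_depth
        faw = (theta - layer.ll) / (layer.dul - layer.ll)
        total += max(0.0, faw) * thick
        weight += thick
    faw = total / weight
    return min(1.0, max(0.0, faw / gp.f_crit))


def sterility_from_cdd(cdd, gp=DEFAULT_GROWTH):
    """Spikelet sterility fraction, linear in cooling degree days between
    the tolerance c0 and saturation c0 + c1."""
    return min(1.0, max(0.0, (cdd - gp.sterility_c0) / gp.sterility_c1))


def cold_sterility(t_series, cttmax=28.0, gp=DEFAULT_GROWTH):
    """Sterility from a daily mean-temperature series over the sensitive window."""
    t = np.asarray(t_series, dtype=float)
    if t.size == 0:
        return 0.0
    cdd = float(np.maximum(0.0, cttmax - t).sum())
    return sterility_from_cdd(cdd, gp)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _partition_fraction(cultivar, dvs):
    p1, p2, p3 = cultivar.panicle_partition
    return float(np.interp(dvs, [DVS_ANTHESIS, 1.2, 2.5], [p1, p2, p3]))


def grow(state, cultivar, srad, lstrs, tavg=28.0, gp=DEFAULT_GROWTH):
    """One day of biomass growth at the given radiation and stress level."""
    if not state.alive:
        return state
    s = state.copy()
    s.lstrs = lstrs
    if s.growth_paused:
        s.dvs_at_last_grow = s.dvs
        return s
    density_factor = min(1.0, math.sqrt(s.density / s.ref_density)) if s.ref_density > 0 else 1.0
    intercepted = gp.par_fraction * srad * (1.0 - math.exp(-gp.k_extinction * s.lai))
    gain_g_m2 = gp.rue * intercepted * lstrs * density_factor * s.growth_penalty
    gain = gain_g_m2 * 10.0  # kg ha-1
    s.biomass_shoot += gain

    if s.dvs < DVS_ANTHESIS:
        if s.lai < gp.lai_exponential_until:
            tt = thermal_time(tavg, gp)
            s.lai *= math.exp(gp.lai_rgr * tt * lstrs)
        else:
            s.lai += gp.sla * gp.leaf_fraction * gain_g_m2
        if lstrs < gp.stress_senescence_lstrs:
            # severe leaf-rolling stress kills leaf area; a later shower does
            # not resurrect a desiccated canopy
            s.lai *= gp.stress_senescence_rate + (1.0 - gp.stress_senescence_rate) * (
                lstrs / gp.stress_senescence_lstrs
            )
        s.lai = min(s.lai, gp.lai_max)
        if s.dvs >= DVS_PHOTOPERIOD_END:
            s.panicle_phase_growth += gain
    else:
        if s.reserve_pool == 0.0 and s.dvs_at_last_grow < DVS_ANTHESIS:
            # anthesis today: freeze the translocatable reserve and peak LAI
            s.reserve_pool = gp.reserve_fraction * s.biomass_shoot
            s.reserve_remaining = s.reserve_pool
            s.lai_at_anthesis = s.lai
        s.biomass_panicle += _partition_fraction(cultivar, s.dvs) * gain
        # stem-reserve translocation in proportion to reproductive progress
        ddvs = max(0.0, s.dvs - max(s.dvs_at_last_grow, DVS_ANTHESIS))
        transfer = min(s.reserve_remaining, s.reserve_pool * ddvs / (DVS_MATURITY - DVS_ANTHESIS))
        s.biomass_panicle += transfer
        s.reserve_remaining -= transfer
        # senescence
        frac = (s.dvs - DVS_ANTHESIS) / (DVS_MATURITY - DVS_ANTHESIS)
        s.lai = s.lai_at_anthesis * max(0.15, 1.0 - 0.85 * frac)
    s.dvs_at_last_grow = s.dvs
    return s


def yield_t_ha(state, cultivar, gp=DEFAULT_GROWTH):
    """Grain yield (t ha-1) at maturity: min of spikelet sink and panicle source."""
    if not state.alive:
        return 0.0
    growth_kg_m2 = state.panicle_phase_growth / 1e4
    spikelets_m2 = cultivar.spgf * growth_kg_m2
    sink_t_ha = spikelets_m2 * (1.0 - state.sterility) * gp.grain_mass * 10.0
    source_t_ha = state.biomass_panicle / 1000.0
    return max(0.0, min(sink_t_ha, source_t_ha))


def spikelet_number(state, cultivar):
    """Spikelets per m2 formed from panicle-phase shoot growth."""
    return cultivar.spgf * state.panicle_phase_growth / 1e4


# ---------------------------------------------------------------------------
# establishment
# ---------------------------------------------------------------------------

def nursery_development(cultivar, seedling_age, tavg=28.0, daylength=13.0):
    """Development-stage credit a seedling of the given age carries to the
    main field: juvenile then photoperiod-phase accrual at nursery forcing,
    capped at panicle initiation."""
    dvs = 0.0
    tt = thermal_time(tavg)
    for _ in range(int(seedling_age)):
        if dvs < DVS_JUVENILE_END:
            dvs += cultivar.dvr_juvenile * cultivar.dev_scale * tt
        else:
            dvs += (
                cultivar.dvr_photoperiod
                * cultivar.dev_scale
                * tt
                * photoperiod_factor(cultivar, daylength)
            )
        if dvs >= DVS_PHOTOPERIOD_END:
            return DVS_PHOTOPERIOD_END
    return dvs


def transplant(cultivar, seedling_age, density=66.0, nursery_dvs=None,
               seedling_mass_g=0.3, gp=DEFAULT_GROWTH):
    """Initialize a transplanted main-field crop.

    Seedlings carry nursery development credit (capped at the juvenile phase
    end) and suffer a transplanting shock: a growth-and-development pause of
    ``gp.shock_days`` plus, for seedlings older than 30 days, a linear
    old-seedling growth penalty capped at 50%.
    """
    if seedling_age < 15:
        raise ValueError("seedlings younger than 15 days cannot be transplanted")
    if nursery_dvs is None:
        nursery_dvs = nursery_development(cultivar, seedling_age)
    # seedlings develop continuously in the nursery; credit is capped at
    # panicle initiation (older seedlings are penalized, not rejuvenated)
    nursery_dvs = min(nursery_dvs, DVS_PHOTOPERIOD_END)
    penalty = 1.0
    if seedling_age > 30:
        penalty = max(0.5, 1.0 - 0.01 * (seedling_age - 30.0))
    biomass = seedling_mass_g * density * 10.0  # kg ha-1
    lai = gp.sla * gp.leaf_fraction * seedling_mass_g * density
    return CropState(
        dvs=nursery_dvs,
        biomass_shoot=biomass,
        lai=lai,
        density=density,
        ref_density=66.0,
        seedling_age=seedling_age,
        root_depth_cm=10.0,
        shock_days_left=gp.shock_days,
        growth_penalty=penalty,
        dvs_at_last_grow=nursery_dvs,
    )


def sow_direct(cultivar, density=150.0, seed_mass_g=0.03, gp=DEFAULT_GROWTH):
    """Initialize a direct-seeded crop (no nursery credit, no shock)."""
    biomass = seed_mass_g * density * 10.0
    lai = gp.sla * gp.leaf_fraction * seed_mass_g * density
    return CropState(
        dvs=0.0,
        biomass_shoot=biomass,
        lai=max(lai, 0.01),
        density=density,
        ref_density=density,
        root_depth_cm=5.0,
    )


def kill(state):
    s = state.copy()
    s.alive = False
    return s


# ---------------------------------------------------------------------------
# seasonal stress summary
# ---------------------------------------------------------------------------

def phase_mean_stress(lstrs_series, dvs_series):
    """Mean lstrs over the vegetative (DVS < 1) and reproductive (1 <= DVS <= 2)
    periods; NaN for an empty phase."""
    lstrs = np.asarray(lstrs_series, dtype=float)
    dvs = np.asarray(dvs_series, dtype=float)
    if lstrs.shape != dvs.shape:
        raise ValueError("series must be aligned")
    veg = lstrs[dvs < DVS_ANTHESIS]
    rep = lstrs[(dvs >= DVS_ANTHESIS) & (dvs <= DVS_MATURITY)]
    veg_mean = float(veg.mean()) if veg.size else math.nan
    rep_mean = float(rep.mean()) if rep.size else math.nan
    return veg_mean, rep_mean
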