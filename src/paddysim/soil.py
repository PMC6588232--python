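"""Layered daily soil-water balance with pond dynamics for puddled and
direct-seeded rice fields.

The profile is a cascading bucket: rain and irrigation enter a surface pond,
the pond infiltrates top-down up to saturation, water above the drained upper
limit (DUL, identified with field capacity) cascades to the layer below, and
drainage out of the profile bottom is capped at the saturated percolation
rate ks — 12 mm d-1 for non-puddled soil and 3 mm d-1 once the field has been
puddled.  Soil evaporation follows the two-stage (Ritchie) model with a
stage-1 limit U and stage-2 coefficient cona; a standing pond evaporates at
the potential rate instead.  Water is conserved daily to 1e-6 mm.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SoilWaterState",
    "pawc",
    "step_water_balance",
    "fraction_of_field_capacity",
    "irrigation_to_saturation_plus_pond",
    "puddle",
    "potential_evapotranspiration",
]


@dataclass(frozen=True)
class SoilLayer:
    """One soil layer; depths in cm, water contents volumetric (cm3 cm-3)."""

    top_depth: float
    bottom_depth: float
    ll: float
    dul: float
    sat: float
    bd: float = 1.3
    ph: float = 7.0

    def __post_init__(self):
        if not (0.0 < self.ll < self.dul < self.sat < 1.0):
            raise ValueError(
                f"layer {self.top_depth}-{self.bottom_depth} cm needs 0 < LL < DUL < SAT < 1"
            )
        if self.bottom_depth <= self.top_depth:
            raise ValueError("layer bottom must be below top")

    @property
    def thickness_mm(self):
        return (self.bottom_depth - self.top_depth) * 10.0


@dataclass(frozen=True)
class SoilProfile:
    """Ordered contiguous layers plus the scalar hydraulic parameters."""

    layers: tuple
    ks_puddled: float = 3.0
    ks_nonpuddled: float = 12.0
    u_stage1: float = 12.0
    cona_stage2: float = 3.0
    bund_height: float = 100.0
    # surface horizon that wets freely from the pond; percolation across and
    # below its base is rate-limited by ks, which is what lets rain pond on
    # a bunded field before the deep profile is saturated
    intake_depth_cm: float = 15.0

    def __post_init__(self):
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise ValueError("profile needs at least one layer")
        if layers[0].top_depth != 0.0:
            raise ValueError("profile must start at 0 cm")
        for upper, lower in zip(layers, layers[1:]):
            if not math.isclose(upper.bottom_depth, lower.top_depth):
                raise ValueError("layers must be contiguous")

    @property
    def depth_cm(self):
        return self.layers[-1].bottom_depth

    def boundary_index(self, to_depth):
        """Index one past the layer whose bottom is ``to_depth`` (must be a boundary)."""
        for i, layer in enumerate(self.layers):
            if math.isclose(layer.bottom_depth, to_depth):
                return i + 1
        raise ValueError(f"{to_depth} cm is not a layer boundary of this profile")


@dataclass
class SoilWaterState:
    """Evolving water state: per-layer volumetric content plus surface pond (mm)."""

    theta: list
    pond: float = 0.0
    puddled: bool = False
    cum_evap_stage1: float = 0.0
    cum_evap_stage2: float = 0.0
    cum_drainage: float = 0.0
    cum_runoff: float = 0.0
    cum_irrigation: float = 0.0

    @classmethod
    def initial(cls, profile, wet_below_cm=30.0, dry_fraction=0.7):
        """1-January initial state: DUL below ``wet_below_cm``, 0.7*DUL above."""
        theta = [
            layer.dul if layer.top_depth >= wet_below_cm else max(layer.ll, dry_fraction * layer.dul)
            for layer in profile.layers
        ]
        return cls(theta=theta)

    def copy(self):
        return copy.deepcopy(self)

    def storage_mm(self, profile):
        return sum(t * layer.thickness_mm for t, layer in zip(self.theta, profile.layers))


def load_default_profile():
    """The packaged Patna silty-loam profile (see ``paddysim/data``)."""
    from .io import load_soil_profile

    return load_soil_profile()


# ---------------------------------------------------------------------------
# static queries
# ---------------------------------------------------------------------------

def pawc(profile, to_depth):
    """Plant-available water capacity, sum of (DUL - LL) * thickness, in mm."""
    n = profile.boundary_index(to_depth)
    return sum(
        (layer.dul - layer.ll) * layer.thickness_mm for layer in profile.layers[:n]
    )


def fraction_of_field_capacity(state, profile, to_depth):
    """Depth-weighted mean of theta/DUL over [0, to_depth] cm."""
    if to_depth > profile.depth_cm:
        raise ValueError("to_depth beyond profile")
    total = 0.0
    weight = 0.0
    for theta, layer in zip(state.theta, profile.layers):
        if layer.top_depth >= to_depth:
            break
        thick = min(layer.bottom_depth, to_depth) - layer.top_depth
        total += (theta / layer.dul) * thick
        weight += thick
    return total / weight


def irrigation_to_saturation_plus_pond(state, profile, to_depth, extra_pond):
    """Water depth (mm) needed to saturate layers above ``to_depth`` and add
    ``extra_pond`` mm of surface water."""
    n = profile.boundary_index(to_depth)
    deficit = sum(
        max(0.0, layer.sat - theta) * layer.thickness_mm
        for theta, layer in zip(state.theta[:n], profile.layers[:n])
    )
    return deficit + extra_pond


def puddle(state, profile):
    """Puddle a flooded field: percolation drops to ks_puddled. Idempotent."""
    if state.pond <= 0.0:
        raise ValueError("cannot puddle a field without standing water")
    new = state.copy()
    new.puddled = True
    return new


# ---------------------------------------------------------------------------
# potential evapotranspiration (radiation-driven surrogate)
# ---------------------------------------------------------------------------

def potential_evapotranspiration(srad, tavg, alpha=1.26):
    """Priestley-Taylor-style potential ET (mm d-1) from solar radiation and
    mean temperature.  Net radiation is approximated as 0.75*srad minus a
    2 MJ m-2 d-1 longwave loss; latent heat 2.45 MJ kg-1."""
    es = 0.6108 * math.exp(17.27 * tavg / (tavg + 237.3))
    delta = 4098.0 * es / (tavg + 237.3) ** 2
    gamma = 0.0665
    rn = max(0.0, 0.75 * srad - 2.0)
    return max(0.0, alpha * (delta / (delta + gamma)) * rn / 2.45)


# ---------------------------------------------------------------------------
# the daily step
# ---------------------------------------------------------------------------

def step_water_balance(
    state,
    profile,
    rain,
    irrigation,
    potential_evap,
    transpiration_demand=0.0,
    root_depth=0.0,
):
    """Advance the water balance one day; returns ``(new_state, fluxes)``.

    Daily order of operations: rain and irrigation join the pond; the pond
    infiltrates top-down to saturation; pond above the bund runs off;
    gravity water cascades down and bottom drainage is capped at ks; the
    pond refills freed pore space; evaporation is taken from the pond at the
    potential rate or from the top layer by the two-stage model; transpiration
    is extracted over the root zone weighted by available water.
    """
    if min(rain, irrigation, potential_evap, transpiration_demand, root_depth) < 0:
        raise ValueError("water-balance inputs must be non-negative")

    s = state.copy()
    layers = profile.layers
    n = len(layers)
    thick = [l.thickness_mm for l in layers]
    w = [t * th for t, th in zip(s.theta, thick)]  # mm per layer
    storage0 = sum(w) + state.pond

    pond = s.pond + rain + irrigation
    ks = profile.ks_puddled if s.puddled else profile.ks_nonpuddled

    def infiltrate(pond):
        # the pond wets the surface intake horizon freely, up to saturation
        for i in range(n):
            if layers[i].top_depth >= profile.intake_depth_cm:
                break
            room = layers[i].sat * thick[i] - w[i]
            take = min(pond, max(0.0, room))
            w[i] += take
            pond -= take
            if pond <= 0.0:
                break
        return pond

    w0_before = w[0]
    pond = infiltrate(pond)
    # infiltration into the surface layer winds the two-stage evaporation
    # counters back (stage 2 first), the standard partial-rewetting rule
    infil_top = w[0] - w0_before
    if infil_top > 0.0:
        from_stage2 = min(infil_top, s.cum_evap_stage2)
        s.cum_evap_stage2 -= from_stage2
        s.cum_evap_stage1 = max(0.0, s.cum_evap_stage1 - (infil_top - from_stage2))

    runoff = max(0.0, pond - profile.bund_height)
    pond -= runoff
    pond_peak = pond  # ponding observable during the day, before the day's losses

    # gravity cascade: excess above DUL moves down; flux across and below the
    # intake-horizon base is capped at ks, as is outflow from the profile
    for i in range(n - 1):
        excess = max(0.0, w[i] - layers[i].dul * thick[i])
        room = max(0.0, layers[i + 1].sat * thick[i + 1] - w[i + 1])
        move = min(excess, room)
        if layers[i + 1].top_depth >= profile.intake_depth_cm:
            move = min(move, ks)
        w[i] -= move
        w[i + 1] += move
    drainage = min(ks, max(0.0, w[-1] - layers[-1].dul * thick[-1]))
    w[-1] -= drainage

    pond = infiltrate(pond)

    # evaporation
    evaporation = 0.0
    if pond > 0.0:
        evaporation = min(pond, potential_evap)
        pond -= evaporation
        s.cum_evap_stage1 = 0.0
        s.cum_evap_stage2 = 0.0
    else:
        avail = max(0.0, w[0] - layers[0].ll * thick[0])
        if s.cum_evap_stage1 < profile.u_stage1:
            es = min(potential_evap, profile.u_stage1 - s.cum_evap_stage1)
            es = min(es, avail)
            s.cum_evap_stage1 += es
        else:
            cona = profile.cona_stage2
            t_prev = (s.cum_evap_stage2 / cona) ** 2
            es = cona * math.sqrt(t_prev + 1.0) - s.cum_evap_stage2
            es = min(es, potential_evap, avail)
            s.cum_evap_stage2 += es
        evaporation = es
        w[0] -= es

    # transpiration over the root zone, weighted by available water
    transpiration = 0.0
    if transpiration_demand > 0.0 and root_depth > 0.0:
        avail = []
        for i in range(n):
            if layers[i].top_depth >= root_depth:
                avail.append(0.0)
                continue
            frac = (min(layers[i].bottom_depth, root_depth) - layers[i].top_depth) / (
                layers[i].bottom_depth - layers[i].top_depth
            )
            avail.append(max(0.0, w[i] - layers[i].ll * thick[i]) * frac)
        total_avail = sum(avail)
        if pond > 0.0:
            take = min(pond, transpiration_demand)
            pond -= take
            transpiration += take
        remaining = transpiration_demand - transpiration
        if remaining > 0.0 and total_avail > 0.0:
            t_soil = min(remaining, total_avail)
            for i in range(n):
                if avail[i] > 0.0:
                    w[i] -= t_soil * avail[i] / total_avail
            transpiration += t_soil

    # rewetting resets the evaporation stage counters
    if pond > 0.0 or w[0] >= layers[0].dul * thick[0] - 1e-9:
        s.cum_evap_stage1 = 0.0
        s.cum_evap_stage2 = 0.0

    s.theta = [wi / th for wi, th in zip(w, thick)]
    s.pond = pond
    s.cum_drainage += drainage
    s.cum_runoff += runoff
    s.cum_irrigation += irrigation

    storage1 = sum(w) + pond
    balance = storage1 - storage0 - (
        rain + irrigation - runoff - drainage - evaporation - transpiration
    )
    fluxes = {
        "rain": rain,
        "irrigation": irrigation,
        "pond_peak": pond_peak,
        "runoff": runoff,
        "drainage": drainage,
        "evaporation": evaporation,
        "transpiration": transpiration,
        "balance_error": balance,
    }
    if abs(balance) > 1e-6:
        raise AssertionError(f"water balance violated by {balance:.3e} mm")
    return s, fluxes
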