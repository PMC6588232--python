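"""Loaders for the packaged soil and cultivar fixtures and user config files."""

from __future__ import annotations

from importlib import resources

import yaml

from .crop import Cultivar, GrowthParams, calibrate_dev_scale
from .soil import SoilLayer, SoilProfile

__all__ = [
    "load_soil_profile",
    "load_cultivar",
    "load_cultivars",
    "load_growth_params",
]


def _packaged(name):
    return resources.files("paddysim.data").joinpath(name)


def load_soil_profile(path=None):
    """Load a layered soil profile from YAML (default: the Patna silty loam)."""
    source = open(path) if path else _packaged("patna_silty_loam.yaml").open()
    with source as fh:
        cfg = yaml.safe_load(fh)
    layers = tuple(SoilLayer(**layer) for layer in cfg["layers"])
    scalars = {
        k: float(cfg[k])
        for k in ("ks_puddled", "ks_nonpuddled", "u_stage1", "cona_stage2", "bund_height")
        if k in cfg
    }
    return SoilProfile(layers=layers, **scalars)


def _build_cultivar(name, spec):
    cv = Cultivar(
        name=name,
        dvr_juvenile=float(spec["dvr_juvenile"]),
        dvr_photoperiod=float(spec["dvr_photoperiod"]),
        dvr_panicle=float(spec["dvr_panicle"]),
        dvr_reproductive=float(spec["dvr_reproductive"]),
        ppse=float(spec["ppse"]),
        mopp=float(spec["mopp"]),
        spgf=float(spec["spgf"]),
        panicle_partition=tuple(float(x) for x in spec["panicle_partition"]),
        cttmax=float(spec.get("cttmax", 28.0)),
        duration_days=float(spec.get("duration_days", 150.0)),
    )
    return calibrate_dev_scale(cv)


def load_cultivars(path=None):
    """All packaged cultivars, duration-calibrated, as a name -> Cultivar dict."""
    source = open(path) if path else _packaged("cultivars.yaml").open()
    with source as fh:
        cfg = yaml.safe_load(fh)
    return {name: _build_cultivar(name, spec) for name, spec in cfg["cultivars"].items()}


def load_cultivar(name, path=None):
    cultivars = load_cultivars(path)
    try:
        return cultivars[name]
    except KeyError:
        raise KeyError(f"unknown cultivar {name!r}; have {sorted(cultivars)}") from None


def load_growth_params(path=None):
    """Surrogate growth-engine constants from the cultivar config file."""
    source = open(path) if path else _packaged("cultivars.yaml").open()
    with source as fh:
        cfg = yaml.safe_load(fh)
    spec = cfg.get("surrogate", {})
    return GrowthParams(**{k: float(v) for k, v in spec.items()})
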