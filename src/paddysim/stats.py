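"""Model-evaluation metrics, risk summaries, and water productivity."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "rmse",
    "normalized_rmse",
    "water_productivity",
    "RiskSummary",
    "summarize",
    "summarize_results",
    "anova_lsd",
]

PERCENTILES = (5, 10, 25, 50, 75, 90, 95)


def _paired(simulated, observed):
    s = np.asarray(simulated, dtype=float)
    o = np.asarray(observed, dtype=float)
    if s.shape != o.shape:
        raise ValueError("simulated and observed series must have equal length")
    if s.size == 0:
        raise ValueError("empty series")
    return s, o


def rmse(simulated, observed):
    """Root mean square error, sqrt(mean((S_i - O_i)^2))."""
    s, o = _paired(simulated, observed)
    return float(np.sqrt(np.mean((s - o) ** 2)))


def normalized_rmse(simulated, observed):
    """RMSE as a percent of the observed mean."""
    s, o = _paired(simulated, observed)
    mean_obs = float(np.mean(o))
    if mean_obs == 0.0:
        raise ZeroDivisionError("normalized RMSE undefined for zero observed mean")
    return 100.0 * rmse(s, o) / mean_obs


def water_productivity(grain_yield, irrigation_total):
    """Irrigation water productivity WP_I = grain yield (kg ha-1) / irrigation
    (mm); NaN (undefined, excluded from means) for rainfed zero-irrigation
    seasons."""
    if irrigation_total < 0 or grain_yield < 0:
        raise ValueError("yield and irrigation must be non-negative")
    if irrigation_total == 0.0:
        return math.nan
    return grain_yield / irrigation_total


@dataclass(frozen=True)
class RiskSummary:
    """Distributional summary of a per-year outcome across replicate years."""

    median: float
    sd: float
    percentiles: dict
    fraction_exceeding: dict
    n_years: int


def summarize(values, thresholds=()):
    """Median, sample SD, the standard risk percentiles (linear interpolation),
    and the fraction of years strictly exceeding each threshold."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    pct = {p: float(np.percentile(v, p)) for p in PERCENTILES}
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    frac = {t: float(np.mean(v > t)) for t in thresholds}
    return RiskSummary(
        median=pct[50], sd=sd, percentiles=pct, fraction_exceeding=frac, n_years=int(v.size)
    )


def anova_lsd(groups, alpha=0.05):
    """One-way ANOVA with Fisher's least significant difference.

    ``groups`` maps scenario name -> per-year values (equal counts, years as
    replicates).  Returns (table, lsd): a pairwise DataFrame with mean
    differences and significance flags at the 1 - alpha confidence level,
    and the LSD value t_(1-alpha/2, df_error) * sqrt(2 * MSE / n).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    n = arrays[0].size
    if n < 2:
        raise ValueError("need at least two replicates per group")
    if any(a.size != n for a in arrays):
        raise ValueError("groups must have equal replicate counts")
    k = len(arrays)
    grand = np.mean(np.concatenate(arrays))
    ss_treat = n * sum((a.mean() - grand) ** 2 for a in arrays)
    ss_error = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_error = k * (n - 1)
    mse = ss_error / df_error
    f_value = (ss_treat / (k - 1)) / mse if mse > 0 else math.inf
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df_error)
    lsd = t_crit * math.sqrt(2.0 * mse / n)
    rows = []
    for a_name, b_name in itertools.combinations(names, 2):
        diff = float(np.mean(groups[a_name]) - np.mean(groups[b_name]))
        rows.append(
            {
                "group_a": a_name,
                "group_b": b_name,
                "mean_difference": diff,
                "significant": abs(diff) > lsd,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs.update({"lsd": lsd, "mse": mse, "f_value": f_value, "df_error": df_error})
    return table, lsd


def summarize_results(results, by="scenario", value="yield_t_ha", thresholds=(1.0,)):
    """Risk summaries of a results table, one row per scenario.

    Mirrors the headline reporting convention: median and SD of yield with
    fallow years included, median irrigation events with their range, median
    reproductive-phase drought stress with the count of stressed years.
    """
    rows = []
    for name, g in results.groupby(by):
        summ = summarize(g[value].to_numpy(), thresholds)
        rep = g["lstrs_rep_mean"].to_numpy(dtype=float)
        rep = rep[~np.isnan(rep)]
        irr = g["irrigation_events"].to_numpy(dtype=float)
        rows.append(
            {
                by: name,
                "n_years": summ.n_years,
                "median_yield_t_ha": summ.median,
                "sd_yield_t_ha": summ.sd,
                "p10_yield": summ.percentiles[10],
                "p90_yield": summ.percentiles[90],
                "median_irrigation_events": float(np.median(irr)),
                "irrigation_events_min": float(irr.min()),
                "irrigation_events_max": float(irr.max()),
                "median_lstrs_grain_fill": float(np.median(rep)) if rep.size else math.nan,
                "years_lstrs_below_0.8": int((rep < 0.8).sum()),
                "fraction_yield_above_1t": summ.fraction_exceeding.get(1.0, math.nan),
                "n_not_established": int((g["failure_mode"] == "not_established").sum()),
            }
        )
    return pd.DataFrame(rows)
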