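"""Generate the synthetic multi-year Patna weather record used by the other
analysis scripts, and report how its climatology compares with the target
statistics (mean annual rainfall 1130 mm, 85-90% of it in June-September,
monsoon onset around 18 June, cool Dec-Jan, hot May-Jun)."""

import pathlib

import numpy as np

from paddysim import generate_weather, monsoon_onset, write_weather

YEARS = 100
SEED = 20190601

out_dir = pathlib.Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

series = generate_weather(n_years=YEARS, seed=SEED)
write_weather(series, out_dir / "weather_synthetic.csv")

df = series.df
ann = df.groupby(df["date"].dt.year)["rain"].sum()
jjas = df[df["date"].dt.month.isin([6, 7, 8, 9])]
share = jjas.groupby(jjas["date"].dt.year)["rain"].sum() / ann
onsets = [o for o in (monsoon_onset(series, y) for y in series.years) if o is not None]
monthly = df.groupby(df["date"].dt.month)[["tmax", "tmin", "rain", "srad"]].mean()
monthly.to_csv(out_dir / "weather_monthly_climatology.csv", float_format="%.2f")

print(f"{YEARS} synthetic years written to results/weather_synthetic.csv")
print(f"annual rainfall: mean {ann.mean():.0f} mm, range {ann.min():.0f}-{ann.max():.0f} mm")
print(f"Jun-Sep share of annual rain: {share.mean():.1%}")
print(f"rain-trigger monsoon onset: mean DOY {np.mean(onsets):.0f} "
      f"(18 June = DOY 169), sd {np.std(onsets):.0f} d")
print(f"December-January mean tmin: {monthly.loc[[12, 1], 'tmin'].mean():.1f} degC; "
      f"May-June mean tmax: {monthly.loc[[5, 6], 'tmax'].mean():.1f} degC")
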