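# Methods

`paddysim` couples a layered soil-water balance, a minimal process-based
rice crop model, and an event-driven management rule engine, run day by day
over multi-year synthetic monsoon weather. Years are independent
replicates: the soil is re-initialized every 1 January (drained upper limit
below 30 cm, 70 % of it above), and each scenario-year produces one row of
outcomes (yield, establishment dates, irrigation, stress indices, failure
mode). This note records the model equations, the defaults and why they
hold, and what the synthetic setting can and cannot show.

## Weather generation

The generator emulates the Patna (25.59 °N) climatology that drives the
management rules rather than any particular historical record.

* **Monsoon onset** is drawn per year from a normal distribution,
  mean day-of-year 169 (18 June), SD 10 d, truncated to 15 May – 31 July.
  The onset itself is a three-day burst (gamma, shape 2, scale 12 mm),
  which is what makes the 50 mm / 3-day nursery trigger track onset.
* **Rainfall occurrence** is a first-order two-state Markov chain with
  per-month baseline probabilities outside the monsoon, and a monsoon
  regime from onset through 30 September that alternates between
  persistent *active* spells (mean ≈ 17 d; P(wet|dry) = 0.60,
  P(wet|wet) = 0.78) and *break* spells (mean ≈ 5 d; scattered light
  showers). Breaks are essential structure: they create the mid-season
  and terminal drought spells the irrigation rules respond to.
* **Rainfall amounts** on wet days are gamma-distributed; the active-
  monsoon distribution (shape 0.32, scale 49 mm) is deliberately
  heavy-tailed so that the multi-day heavy spells that pond a bunded
  field occur at a realistic frequency. The calibration targets were the
  site's documented statistics: long-run mean annual rainfall 1130 mm
  (achieved: 1128–1145 mm across seeds at 1000 years), 85–90 % of rain in
  June–September (achieved ≈ 88 %), annual range ≈ 630–1740 mm, and the
  rule outcomes reported for the historical record (establishment in
  ~90 % of years, transplanting median DOY ≈ 214, DSR sowing median
  ≈ 1 June).
* **Temperature and sunshine** follow two-harmonic annual cycles fitted to
  Patna monthly normals (December–January minima < 10 °C, ~40 °C May–June
  maxima), with wet-day depression of tmax and sunshine and Gaussian
  daily noise; tmax ≥ tmin + 1 is enforced. Solar radiation comes from
  sunshine hours through the Angstrom–Prescott relation
  `Rs = Ra (a + b n/N)` with the standard astronomical closed forms for
  extraterrestrial radiation and day length (solar constant
  0.0820 MJ m⁻² min⁻¹). Coefficients default to (a, b) = (0.25, 0.50);
  the optional latitude regression is a = 0.29 cos(latitude), b = 0.52.
* **Seeding**: one master seed; year *i* uses the substream
  `SeedSequence((seed, i))`, so extending a run never perturbs earlier
  years.

## Soil water

Six layers (0–150 cm) carry the silty-loam hydraulic constants (LL, DUL,
SAT, BD, pH per layer). Daily order of operations: rain and irrigation
join the surface pond; the pond wets the 0–15 cm surface horizon freely up
to saturation; pond above the 100 mm bund runs off; water above DUL
cascades downward with the flux across and below the surface-horizon base
capped at the saturated percolation rate ks (12 mm d⁻¹, or 3 mm d⁻¹ once
the field is puddled), as is outflow from the profile bottom; the pond
refills freed pore space; evaporation and transpiration are removed;
closure is checked to 10⁻⁶ mm every day.

Rationale for the rate-limited percolation: with an unlimited cascading
bucket a bunded field can never pond (all rain drains through the 150 cm
profile), whereas ponding against a slowly-percolating plow pan is
precisely the hydrology that puddled rice exploits. The 15 cm horizon
corresponds to the tillage layer above the pan.

Soil evaporation follows the two-stage model: stage 1 at the potential
rate until the cumulative 12 mm (*U*) since last rewetting, then stage 2
along the cona·√t curve (*cona* = 3 mm d⁻⁰·⁵). Infiltration into the top
layer winds the stage counters back (stage 2 first) — the standard partial
rewetting rule; a pond or a top layer at DUL resets them fully, and a
standing pond evaporates at the potential rate instead. Potential
evapotranspiration is a Priestley–Taylor-style radiation-driven estimate
(α = 1.26, net radiation ≈ 0.75·Rs − 2 MJ m⁻² d⁻¹), partitioned between
soil/pond evaporation and transpiration by canopy cover 1 − exp(−k·LAI).
The drying floor is LL everywhere (no air-dry stage); transpiration is
extracted over the root zone weighted by available water.

## Crop model

The crop engine is a deliberately minimal surrogate: it preserves the
behaviours the rule analysis depends on (date responses, stress responses,
cultivar duration contrasts) without reproducing any host model's internal
equations.

**Phenology.** Development stage (DVS) advances each day by
`rate_phase × dev_scale × TT × photoperiod factor`, with phase boundaries
at DVS 0.40 (juvenile → photoperiod-sensitive), 0.65 (→ panicle
development; anthesis at 1.00, maturity at 2.00). Effective degree days TT
rise linearly from a base of 8 °C to an optimum of 30 °C and fall to zero
at 42 °C. In the photoperiod-sensitive phase the rate is multiplied by
`max(0, 1 − ppse·min(1.5, daylength − mopp))`: rice is a short-day plant,
and the 1.5 h saturation of the excess keeps strongly sensitive cultivars
delayed but never stalled (without it the hybrid's large ppse can stretch
its photoperiod phase until the long-duration cultivar overtakes it, which
no field ranking supports). Each cultivar carries a single calibration
scalar `dev_scale`, solved in closed form so that the phase durations sum
to the rated 150 d (MTU7029) / 125 d (Arize6129) at the reference forcing
of constant 28 °C and 13.0 h photoperiod — the site's rice-season
daylength. One shared scalar cannot fit both durations (the cultivars'
raw phase-duration sums differ by < 2 %), so the scalar is per-cultivar.

**Growth.** Daily gain = RUE × intercepted PAR × lstrs × density factor ×
old-seedling penalty, with RUE 2.2 g MJ⁻¹ of intercepted
photosynthetically active radiation (PAR = 0.5 × global), extinction
k = 0.5, and density factor √(density/reference). LAI grows exponentially
(relative rate 0.009 per °Cd) until LAI 1, then with new leaf mass
(SLA 0.025 m² g⁻¹, leaf fraction 0.5); it senesces linearly after anthesis
and is destroyed at up to 5 % per day while lstrs < 0.2 — severe leaf
rolling kills canopy that a later shower cannot resurrect, which is what
turns long early-season dry spells into real stand failures. After
anthesis, shoot gain is partitioned to the panicle by the cultivar's
partition fractions (interpolated over DVS 1.0/1.2/2.5), and a stem
reserve equal to 25 % of anthesis shoot biomass is translocated to the
panicle in proportion to reproductive progress; without translocation a
30-day grain-fill of current assimilate alone cannot reach the 6–7 t ha⁻¹
scale that irrigated rice attains here.

**Stress and sterility.** The drought index is
`lstrs = clip(FAW / 0.5, 0, 1)` with FAW the depth-weighted available
water fraction over the root zone (1 under a pond); 1 means no stress.
Cooling degree days below `cttmax` = 28 °C accumulate while DVS is in the
flowering-sensitive window 0.96–1.20, and sterility is
`clip((CDD − 20)/100, 0, 1)`: a window at 28 °C gives 0, a 20-day window
at 22 °C gives 1. Yield = min(spikelet sink, panicle biomass), with
spikelets = spikelet growth factor × shoot growth during panicle
development and a 25 mg grain; sink is discounted by sterility; a dead
crop yields zero.

**Establishment.** Transplants carry nursery development credit —
seedlings develop continuously in the nursery (juvenile then
photoperiod-phase rates), capped at panicle initiation (DVS 0.65) — and
suffer a 9-day growth-and-development pause (transplanting shock; this is
why a direct-seeded crop matures ~9 d faster from the same sowing date)
plus, beyond age 30 d, a growth penalty `max(0.5, 1 − 0.01(age − 30))`.
Direct seeding starts from seed mass at 150 plants m⁻² with no shock.

## Management rules

Daily event order (fixed): irrigation decided from yesterday's end-of-day
state → water balance → crop development and growth → trigger evaluation
on today's state. "Three consecutive days" windows are trailing and
inclusive. One exception to end-of-day reading: the transplanting trigger
compares the day's **peak** ponding (after rain infiltration, before that
day's percolation and evaporation) against the strict 50 mm threshold,
because standing water during the day is what the decision observes.

* Fixed-date transplanted systems flood to saturate 0–30 cm plus 50 mm of
  pond one day before transplanting, puddle, and transplant 30-day
  seedlings at 33 hills m⁻² × 2 seedlings.
* AWD: maintain a 50 mm pond daily for the first 15 days, then re-irrigate
  (0–30 cm to saturation + 50 mm) after two consecutive pond-free days;
  irrigation ceases one reference week before maturity (in DVS terms).
* Farmer practice: nursery on the first ≥ 50 mm / 3-day rain in
  15 May – 15 Aug; transplant at age ≥ 21 d on the first > 50 mm ponding
  (puddling then, from rainwater); rainfed; fallow if never met by
  30 September. The fertilizer schedule is recorded but inert
  (N non-limiting).
* Supplemental irrigation: whenever end-of-day lstrs < 0.8 (strict),
  apply 0–30 cm-to-saturation + 50 mm, one event per application.
* DSR: sow when the 0–15 cm layer is at 40–80 % of field capacity
  (θ/DUL, depth-weighted) three days running within the window; ponded
  days among the first five after sowing reduce the stand by the
  15/40/75 % schedule, five ponded days kill the crop (no re-sowing).
  Irrigated DSR adds a pre-sowing irrigation (top layer to DUL) if the
  window opens below 40 %, and the lstrs rule from day 6.
* Death rules: 15 consecutive days of lstrs < 0.05 before anthesis, or a
  canopy senesced below LAI 0.02, kills the crop (drought); a crop that
  has not reached mid grain fill (DVS 1.2) by 31 December is lost to cold,
  while one beyond DVS 1.2 is harvested with whatever grain has filled.
  Harvest is otherwise 8 days after physiological maturity.

## Statistics

Risk summaries report the median, the sample (n−1) SD, percentiles
{5, 10, 25, 50, 75, 90, 95} with linear interpolation, and
fraction-of-years strictly exceeding thresholds; fallow years enter all
summaries as zero-yield rows. Irrigation water productivity is
WP_I = grain yield (kg ha⁻¹) / irrigation (mm), undefined (and excluded
from means) for rainfed years. Scenario contrasts use one-way ANOVA with
years as replicates and Fisher's LSD at 95 %
(t₀.₉₇₅,df·√(2·MSE/n)). Model-evaluation metrics (RMSE and normalized
RMSE) are provided for users with observations to compare against.

## Problem sizes

The shipped analysis drivers use 100 synthetic years per experiment; the
acceptance checks use 1000 years for the rainfall climatology, 500 years
for the risk-pattern ensembles, and 200 for the water-productivity
contrast — large enough that the medians and orderings they assert are
stable across seeds.

## Known limitations

* Nitrogen is non-limiting everywhere. The consequence is visible in the
  farmer-practice intervention ladder: irrigated good years reach the same
  ~6.5–7 t ha⁻¹ climatic potential as the fixed-date experiment, so the
  interannual SD of the irrigated systems is dominated by the gap between
  fallow years and that potential, and irrigation does not reduce the SD
  below rainfed farmer practice here even though it roughly doubles the
  median. Under a fertilizer cap the irrigated distribution would compress
  from above and the variance reduction would be stronger.
* The surrogate crop engine has no tillering dynamics, no aeration-deficit
  or pest/weed stress, and a single-pool canopy; cultivar contrasts ride
  entirely on the genetic coefficients.
* The weather generator has no interannual teleconnection structure (ENSO
  and the like): years are exchangeable, so decadal clustering of drought
  is absent.
* Relative humidity and wind are not generated (the evapotranspiration
  surrogate does not use them).
* Passing the synthetic-weather tests shows the rules and models behave
  correctly under the stated climatology; it does not validate yields
  against field observations, which would require the historical record
  and trial data.
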