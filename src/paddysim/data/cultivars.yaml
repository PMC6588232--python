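# Genetic coefficients of the two rice cultivars used in the simulations:
# MTU7029 (long duration, 150 d) and Arize6129 (medium duration hybrid,
# 125 d).  Development rates are per degree-day; ppse photoperiod
# sensitivity (h-1); mopp maximum optimum photoperiod (h); spgf spikelet
# growth factor (no kg-1); panicle_partition the shoot-to-panicle fractions
# at development stages 1.0, 1.2 and 2.5; cttmax the cooling-degree-day
# threshold temperature (degC) for spikelet sterility.
#
# The surrogate section holds the growth-engine constants that are not
# cultivar genetics (see paddysim.crop.GrowthParams for meanings/units).
cultivars:
  MTU7029:
    dvr_juvenile: 0.000593
    dvr_photoperiod: 0.000596
    dvr_panicle: 0.000550
    dvr_reproductive: 0.002050
    ppse: 0.2
    mopp: 11.2
    spgf: 64000
    panicle_partition: [0.3, 0.6, 0.6]
    cttmax: 28.0
    duration_days: 150
  Arize6129:
    dvr_juvenile: 0.000700
    dvr_photoperiod: 0.000400
    dvr_panicle: 0.000700
    dvr_reproductive: 0.002050
    ppse: 0.3
    mopp: 11.4
    spgf: 64900
    panicle_partition: [0.5, 1.0, 1.0]
    cttmax: 28.0
    duration_days: 125
surrogate:
  t_base: 8.0
  t_opt: 30.0
  t_ceiling: 42.0
  rue: 2.2
  par_fraction: 0.5
  k_extinction: 0.5
  sla: 0.025
  leaf_fraction: 0.5
  lai_rgr: 0.0090
  grain_mass: 2.5e-5
  f_crit: 0.5
  shock_days: 9
  reserve_fraction: 0.25
  sterility_c0: 20.0
  sterility_c1: 100.0
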