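# Silty loam soil of the ICAR-RCER Patna field site used in the simulations.
# Per-layer values: depths in cm; LL, DUL, SAT volumetric (cm3 cm-3);
# BD g cm-3.  Scalars: stage-1 evaporation limit U (mm), stage-2 coefficient
# cona (mm d^-0.5), saturated percolation ks (mm d-1) for puddled and
# non-puddled soil, bund height (mm).
name: patna_silty_loam
layers:
  - {top_depth: 0,   bottom_depth: 15,  ll: 0.050, dul: 0.200, sat: 0.390, bd: 1.190, ph: 6.7}
  - {top_depth: 15,  bottom_depth: 30,  ll: 0.060, dul: 0.210, sat: 0.410, bd: 1.230, ph: 7.0}
  - {top_depth: 30,  bottom_depth: 60,  ll: 0.070, dul: 0.230, sat: 0.380, bd: 1.300, ph: 7.3}
  - {top_depth: 60,  bottom_depth: 90,  ll: 0.100, dul: 0.240, sat: 0.380, bd: 1.350, ph: 7.6}
  - {top_depth: 90,  bottom_depth: 120, ll: 0.080, dul: 0.250, sat: 0.360, bd: 1.300, ph: 7.7}
  - {top_depth: 120, bottom_depth: 150, ll: 0.120, dul: 0.280, sat: 0.360, bd: 1.320, ph: 7.8}
u_stage1: 12.0
cona_stage2: 3.0
ks_puddled: 3.0
ks_nonpuddled: 12.0
bund_height: 100.0
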