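# Default minute-scale osmotic-stress kinetics for the mannitol map series.
#
# Per-pixel expected carotenoid amplitude follows
#   A(t) = A0 * (floor + (1 - floor) * 2^(-t / half_life(conc)))
# with t in minutes after treatment.  Half-lives decrease with mannitol
# concentration; the defaults place the 50%-of-pre-treatment threshold
# crossing of the map mean at the 5-min sampled timepoint for 250 mM and the
# 15-min timepoint for 100 mM (150 mM also crosses at 15 min on the sampled
# grid).  spatial_sd is the lognormal coefficient of variation of the
# persistent per-pixel carotenoid content across the mapped area.
half_life_min:
  100: 11.0
  150: 7.0
  250: 3.5
floor: 0.1
spatial_sd: 0.08
timepoints_min: [0, 5, 15, 30, 45]
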