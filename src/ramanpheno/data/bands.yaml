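# Quantification band table.  Amplitude = maximum preprocessed intensity in
# center +/- half_window (cm-1).  The 1157 cm-1 carotenoid band is the
# default quantification band; 1524 cm-1 is the intrinsically strongest
# carotenoid band but is excluded from degradation statistics because it is
# overlapped by the anthocyanin band.
default: carotenoid_1157
bands:
  carotenoid_1007: {center: 1007.0, half_window: 10.0}
  carotenoid_1157: {center: 1157.0, half_window: 10.0}
  carotenoid_1524: {center: 1524.0, half_window: 10.0}
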