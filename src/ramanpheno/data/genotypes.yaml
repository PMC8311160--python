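# Default generative profiles for the six tissue/genotype fixtures.
#
# Band amplitudes are arbitrary units chosen for realistic signal-to-noise;
# the carotenoid triplet sits at 1007 / 1157 / 1524 cm-1 (Lorentzian HWHM in
# cm-1), the anthocyanin band at 1530 cm-1 overlaps the 1524 carotenoid band,
# chlorophyll bands appear in green tissue only.  Drought degradation
# fractions are the day-0 -> day-7 relative losses of carotenoid band
# amplitude; controls do not degrade.  Near-isogenic lines (lox2, lox4) share
# the recurrent parent B73's initial amplitudes.  "B73-dark" is the
# dark-grown, chlorophyll-less (white) tissue fixture: lower carotenoid
# content and no degradation under osmotic stress.
grid:
  min: 400.0
  max: 1800.0
  step: 1.0
profiles:
  B73:
    tissue: green
    bands:
      - {label: carotenoid,  center: 1007.0, hwhm: 5.0,  amplitude: 0.45}
      - {label: carotenoid,  center: 1157.0, hwhm: 6.0,  amplitude: 1.00}
      - {label: carotenoid,  center: 1524.0, hwhm: 7.0,  amplitude: 1.25}
      - {label: chlorophyll, center: 1326.0, hwhm: 10.0, amplitude: 0.30}
      - {label: chlorophyll, center: 1440.0, hwhm: 12.0, amplitude: 0.25}
      - {label: anthocyanin, center: 1530.0, hwhm: 4.0,  amplitude: 0.25}
    degradation: {control: 0.0, drought: 0.06}
    amplitude_cv: 0.05
    gain_cv: 0.05
    additive_noise_frac: 0.01
    background:
      poly: [1.5, 0.4, -0.25, 0.15]
      fluorescence: {height: 2.0, center: 1250.0, sigma: 450.0}
  CML176:
    tissue: green
    bands:
      - {label: carotenoid,  center: 1007.0, hwhm: 5.0,  amplitude: 0.315}
      - {label: carotenoid,  center: 1157.0, hwhm: 6.0,  amplitude: 0.70}
      - {label: carotenoid,  center: 1524.0, hwhm: 7.0,  amplitude: 0.875}
      - {label: chlorophyll, center: 1326.0, hwhm: 10.0, amplitude: 0.30}
      - {label: chlorophyll, center: 1440.0, hwhm: 12.0, amplitude: 0.25}
      - {label: anthocyanin, center: 1530.0, hwhm: 4.0,  amplitude: 0.175}
    degradation: {control: 0.0, drought: 0.22}
    amplitude_cv: 0.05
    gain_cv: 0.05
    additive_noise_frac: 0.01
    background:
      poly: [1.5, 0.4, -0.25, 0.15]
      fluorescence: {height: 2.0, center: 1250.0, sigma: 450.0}
  OH28:
    tissue: green
    bands:
      - {label: carotenoid,  center: 1007.0, hwhm: 5.0,  amplitude: 0.3825}
      - {label: carotenoid,  center: 1157.0, hwhm: 6.0,  amplitude: 0.85}
      - {label: carotenoid,  center: 1524.0, hwhm: 7.0,  amplitude: 1.0625}
      - {label: chlorophyll, center: 1326.0, hwhm: 10.0, amplitude: 0.30}
      - {label: chlorophyll, center: 1440.0, hwhm: 12.0, amplitude: 0.25}
      - {label: anthocyanin, center: 1530.0, hwhm: 4.0,  amplitude: 0.2125}
    degradation: {control: 0.0, drought: 0.20}
    amplitude_cv: 0.05
    gain_cv: 0.05
    additive_noise_frac: 0.01
    background:
      poly: [1.5, 0.4, -0.25, 0.15]
      fluorescence: {height: 2.0, center: 1250.0, sigma: 450.0}
  lox2:
    tissue: green
    bands:
      - {label: carotenoid,  center: 1007.0, hwhm: 5.0,  amplitude: 0.45}
      - {label: carotenoid,  center: 1157.0, hwhm: 6.0,  amplitude: 1.00}
      - {label: carotenoid,  center: 1524.0, hwhm: 7.0,  amplitude: 1.25}
      - {label: chlorophyll, center: 1326.0, hwhm: 10.0, amplitude: 0.30}
      - {label: chlorophyll, center: 1440.0, hwhm: 12.0, amplitude: 0.25}
      - {label: anthocyanin, center: 1530.0, hwhm: 4.0,  amplitude: 0.25}
    degradation: {control: 0.0, drought: 0.10}
    amplitude_cv: 0.05
    gain_cv: 0.05
    additive_noise_frac: 0.01
    background:
      poly: [1.5, 0.4, -0.25, 0.15]
      fluorescence: {height: 2.0, center: 1250.0, sigma: 450.0}
  lox4:
    tissue: green
    bands:
      - {label: carotenoid,  center: 1007.0, hwhm: 5.0,  amplitude: 0.45}
      - {label: carotenoid,  center: 1157.0, hwhm: 6.0,  amplitude: 1.00}
      - {label: carotenoid,  center: 1524.0, hwhm: 7.0,  amplitude: 1.25}
      - {label: chlorophyll, center: 1326.0, hwhm: 10.0, amplitude: 0.30}
      - {label: chlorophyll, center: 1440.0, hwhm: 12.0, amplitude: 0.25}
      - {label: anthocyanin, center: 1530.0, hwhm: 4.0,  amplitude: 0.25}
    degradation: {control: 0.0, drought: 0.03}
    amplitude_cv: 0.05
    gain_cv: 0.05
    additive_noise_frac: 0.01
    background:
      poly: [1.5, 0.4, -0.25, 0.15]
      fluorescence: {height: 2.0, center: 1250.0, sigma: 450.0}
  B73-dark:
    tissue: white
    bands:
      - {label: carotenoid,  center: 1007.0, hwhm: 5.0,  amplitude: 0.1575}
      - {label: carotenoid,  center: 1157.0, hwhm: 6.0,  amplitude: 0.35}
      - {label: carotenoid,  center: 1524.0, hwhm: 7.0,  amplitude: 0.4375}
      - {label: anthocyanin, center: 1530.0, hwhm: 4.0,  amplitude: 0.0875}
    degradation: {control: 0.0, drought: 0.0}
    amplitude_cv: 0.05
    gain_cv: 0.05
    additive_noise_frac: 0.01
    background:
      poly: [0.8, 0.2, -0.12, 0.08]
      fluorescence: {height: 1.0, center: 1250.0, sigma: 450.0}
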