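# Methods

## The measurement model

A leaf Raman spectrum under 532 nm excitation is modelled as

```
I(ν) = g · [ B(ν) + s·C(ν) + b·H(ν) + F(ν) ] + ε(ν)
```

- `ν` — Raman shift on a fixed grid, 400–1800 cm⁻¹ at 1 cm⁻¹ steps (the
  band positions discussed all lie in 1000–1550 cm⁻¹; the grid is a package
  choice, not a measured instrument property).
- `B(ν)` — smooth autofluorescence background: a cubic polynomial plus one
  broad Gaussian (σ = 450 cm⁻¹), peaking at roughly twice the tallest Raman
  band.  Real leaf fluorescence is often far stronger; the default keeps the
  bands clearly measurable while still exercising the baseline-removal
  stage (see *Limitations*).
- `C(ν)` — the carotenoid band triplet: Lorentzians at 1007, 1157,
  1524 cm⁻¹ with HWHM 5/6/7 cm⁻¹ and genotype-specific amplitudes
  (relative pattern 0.45 : 1.00 : 1.25).  `s` is the carotenoid content
  scale — the quantity that degrades under stress.
- `H(ν)` — the anthocyanin band at 1530 cm⁻¹ (HWHM 4 cm⁻¹), overlapping
  the 1524 cm⁻¹ carotenoid line; this overlap is why degradation statistics
  use 1157 cm⁻¹ even though 1524 cm⁻¹ is intrinsically strongest.
- `F(ν)` — chlorophyll bands (1326, 1440 cm⁻¹) in green tissue; absent in
  dark-grown (white, etioplast-only) tissue, which also carries ~35 % of the
  green carotenoid amplitude and does not degrade under osmotic stress.
- noise: per-spectrum lognormal carotenoid-content variation
  (`amplitude_cv`, default 5 %), per-spectrum lognormal gain drift
  (`gain_cv`, default 5 %; this is what unit-vector normalization removes),
  and additive Gaussian detector noise (`additive_noise_frac`, default 1 %
  of the tallest band).

## Degradation dynamics

**Day scale (drought).**  In a stressed arm the expected carotenoid scale
falls linearly, `s(d) = 1 − r·d/7`, so the day-0→day-7 relative-change
statistic recovers the genotype parameter `r` exactly in expectation; `r`
is a two-point relative change, not a rate constant, which is why the decay
is linear rather than exponential.  Controls have `r = 0`.

As carotenoids degrade, the generator grows the anthocyanin band so that
the total Raman band energy `‖s·C + b·H + F‖²` is conserved (the amplitude
`b(s)` solves a quadratic in the band-shape inner products).  Anthocyanin
accumulation is a documented companion response to osmotic stress; here it
additionally serves identifiability: the unit-vector-normalized 1157 cm⁻¹
amplitude is then proportional to true carotenoid content, so the
normalized pipeline can recover `r` without a separate intensity reference.
Without this energy balance, normalization would make the measured rate a
strongly biased function of the carotenoid share of total spectral energy.

**Minute scale (mannitol).**  Per-pixel expected amplitude follows
`A(t) = A0 · [φ + (1−φ)·2^(−t/τ(c))]` with degradation floor `φ = 0.1` and
half-lives `τ = 11 / 7 / 3.5 min` at 100 / 150 / 250 mM.  Strict
proportionality of rate to concentration is not imposed; the half-lives are
calibrated so that the 50 %-of-pre-treatment crossing of the map mean falls
at the observed sampled timepoints (5 min at 250 mM, 15 min at 100 mM; the
interpolated 150 mM series also crosses at the 15-min sample) with ≥ 10 %
margin over map-mean sampling noise.  Note that a floor of 0.1 forces
half-lives shorter than the nominal crossing times: with `τ = 5` the 5-min
mean would be `0.1 + 0.9/2 = 0.55 > 0.5`.  Per-pixel carotenoid content is
lognormal (CV 8 %) and persistent across the timepoints of a series, as the
same tissue area is re-mapped.

## The analysis pipeline

1. **Baseline (modified polyfit).**  Least-squares polynomial fit of order
   7 (configurable 3–11; 5–9 is conventional for leaf autofluorescence),
   clamp every point above the fit to the fit, refit; stop when successive
   fits differ by < 1e-6 × (max−min) of the raw trace or after the
   iteration budget (default 100).  Non-convergence sets a flag in the
   result metadata rather than raising: on noisy spectra the clamped trace
   keeps creeping at the noise scale and the 1e-6 criterion is rarely
   reached, while the fit is already stable to ~1e-4 — the flag is
   informational.  Fits use a Chebyshev basis on a scaled domain for
   conditioning (values identical to a power-basis fit).
2. **Savitzky–Golay** — window 15, order 3, mirror-padded edges (order 3
   preserves band shape at this window; parameters echoed into metadata).
3. **Unit-vector normalization** over the full analysis grid (the
   conventional whole-spectrum variant).
4. **Band amplitude** = maximum intensity in center ± 10 cm⁻¹ — robust to
   a few cm⁻¹ of center jitter; "peak height" is deliberately not a fitted
   parameter.
5. **Aggregation ladder** — the spectra of each plant × day cell are
   averaged **on the raw scale first**, then the mean spectrum is
   preprocessed and quantified (the study protocol analyses mean spectra
   averaged over leaf regions).  Averaging first also matters numerically:
   the clamped baseline rides the *lower envelope* of noise, so
   preprocessing individual noisy spectra depresses amplitudes by ~2 noise
   SD and the recovered rate by ~0.7 points at default noise; averaging
   twelve spectra first reduces this to < 0.2 points.  The per-spectrum
   variant remains available (`average_first=False`).  Plant amplitudes are
   averaged per replicate, the rate is computed per replicate, and results
   are reported as mean ± SE over the n = 3 replicate experiments (SE over
   replicates, not plants).
6. **Group comparison** — classical one-way ANOVA (F from between/within
   mean squares, p from the F distribution, α = 0.05; no multiple-testing
   correction — one omnibus test per experiment).  A Bartlett test is
   provided as an optional variance-homogeneity diagnostic.
7. **Maps** — per-pixel preprocessing applies baseline removal and
   smoothing but **no normalization**: images compare absolute band heights
   across pixels and timepoints, which per-pixel unit-norm would erase.
   Whether to baseline-correct map pixels at all is a config choice
   (`preprocess_matrix(..., normalize=False)` is the map default; raw peak
   height can be had by quantifying unprocessed spectra).  The
   threshold-crossing readout reports the first *sampled* timepoint at
   which the map mean ≤ fraction × pre-treatment mean; the 50 % default is
   a config parameter, not a hard-coded constant.

## Accuracy of the recovered rate

The chain is mildly nonlinear (envelope baseline, windowed max, norm
coupling), so the recovered rate is not *exactly* the generator's `r`:

- zero noise: systematic transfer ≈ −0.2 points at the steepest default
  fraction (r = 22 %), dominated by the polynomial envelope's slightly
  different absorption of the shrinking carotenoid vs. growing anthocyanin
  bands, plus Savitzky–Golay band-energy transfer;
- default noise, full design: per-arm SE ≈ 0.1 points (seed-to-seed SD
  ≈ 0.15); mean error over 20 seeds ≈ −0.3 points at r = 22 % and
  proportionally less at smaller r.

Band widths and the background shape were chosen, together with the
energy-balance mechanism, to keep this transfer error an order of magnitude
inside the ±2-point recovery band used by the study-level checks; broader
anthocyanin bands (HWHM ≳ 10 cm⁻¹) or a sharper fluorescence hump
(σ ≈ 300 cm⁻¹, poorly captured by an order-7 polynomial) each add multiple
points of systematic error.

## Problem sizes

Default test and acceptance runs simulate full-replication arms (1440
spectra per genotype arm: 3 × 5 × 12 × 8 days) and 6-timepoint 80-point map
series; preprocessing is vectorized across spectra sharing a grid (one
pseudo-inverse per grid/order), so a full arm processes in ~1 s and the
complete acceptance script in a few seconds on one CPU.

## What the generator does and does not emulate

Emulated: band positions/overlaps, autofluorescence background, linear
day-scale and exponential minute-scale degradation, green vs. dark-grown
tissue contrast, replicate/plant/spectrum replication structure, laser-gain
drift, detector noise, spatial heterogeneity of maps.

Not emulated: physically calibrated Raman cross-sections and absolute
intensities (all amplitudes are arbitrary units; the study reports no
absolute y-axis values), cosmic rays, wavenumber miscalibration,
plant-level random effects beyond spectrum-level noise, day-to-day
instrument drift, senescence gradients within leaves, and fluorescence
many-fold stronger than the Raman bands.  Passing tests therefore
demonstrate correctness of the pipeline's algorithms and estimator under a
plausible signal model — not robustness to every artifact of real leaf
spectra.

## Degenerate inputs and tie-breaks

- Baseline fitting requires ≥ order+2 points; an all-zero trace is its own
  (zero) baseline.
- Savitzky–Golay requires a uniform grid (the error instructs resampling)
  and a window no longer than the spectrum.
- Unit normalization of a zero spectrum is an error.
- `strongest_band` breaks exact amplitude ties toward the lower
  wavenumber.
- `degradation_rate` requires A(day 0) > 0 and both endpoint days; negative
  rates (amplitude gain) are legal and reported as such.
- A map series without a pre-treatment map cannot be normalized to
  pre-treatment and is rejected.
- Water-control series (`mannitol:0`) and white tissue never decay.
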