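# Methods

This note documents the models behind `rcfdose`: what is simulated, the
defaults and why, the numerical choices, and what the synthetic
experiments can and cannot say about real film dosimetry.

## Film response

The forward dose→signal model is

```
netOD(D) = a·D / (1 + b·D) + c·D
```

a saturating rational term plus a small linear tail, strictly
increasing for `a > 0, c ≥ 0` and zero at zero dose.  Defaults:

| channel       | a [netOD/Gy] | b [1/Gy] | c [netOD/Gy] |
|---------------|--------------|----------|--------------|
| `scanner_red` | 0.115        | 0.08     | 0.004        |
| `led_green`   | 0.090        | 0.06     | 0.003        |

chosen so the red channel reaches netOD ≈ 0.6 at 8 Gy, typical of EBT3
film read on a flatbed scanner, with the green LED channel somewhat
less sensitive.  The functional form is a modelling convenience: real
calibration is always *learned* by the inverse pipeline from (dose,
reading) samples, never copied from these parameters, so forward model
and calibrator share no information beyond the data.

Calibration itself is a degree-5 least-squares polynomial (the standard
protocol choice), fitted as signal(dose) and inverted by bracketed root
finding (Brent, 1e-9 Gy tolerance) on its monotone branch.  Inverting
whole maps uses a 4096-point monotone interpolation grid instead
(error well below 1 mGy over an 8 Gy range).

**Monotonicity guard.**  A quintic can oscillate.  A fit is rejected as
uninvertible when its counter-directional excursion exceeds 0.5 % of
the fitted span.  The threshold is deliberately not zero: fits through
noisy averaged ADC counts routinely carry a sub-0.5 % ripple within the
last few tens of mGy of the range, which is harmless for bracketed
inversion (the dose ambiguity is bounded by the ripple's width), while
a material oscillation — the failure the guard exists for — is orders
of magnitude larger.

## Sources and fields

The X-ray tube output follows `Dose(mGy) = A·(SSD − D′)^(−p)` per unit
calibration time with `A = 138251 mGy·mm^p`, `p = 2.003`; distances are
in mm and exposure-time scaling is linear (constant dose rate).  The
offset `D′` is recovered from two (SSD, dose-rate) pairs by solving the
linear equation `(SSD₁ − D′)/(SSD₂ − D′) = (rate₂/rate₁)^(1/p)`; the
solution must lie below both SSDs.  The Cs-137 source is a constant
4.05 Gy/min dose rate with a homogeneous field.

Field inhomogeneity is a multiplicative relative field with mean
exactly 1: a smooth quadratic surface whose maximum sits at a
configurable fractional offset from the film centre (emulating an
off-axis beam-intensity displacement) plus seeded Gaussian texture (5 %
of the surface amplitude), affinely rescaled so the maximum %dispersion
about the mean equals the target — 20 % for the X-ray preset, 4 % for
Cs-137.  Because the mean is exactly 1, the film-mean dose of an
open-field irradiation equals the nominal dose for every seed.

## Spectrum and step attenuation

The tube spectrum is Kramers bremsstrahlung, photon weights
∝ `(kVp − E)/E` on a 1 keV grid from 5 keV to the tube potential,
attenuated by `exp(−μ_Al(E)·t)`.  Characteristic tungsten lines are
neglected (the K series lies at ~59–67 keV, above the 60 kVp operating
point).  Two filtration terms contribute: the external filter (1.3 mm
Al default) and an *effective inherent filtration* (1.2 mm Al-equivalent
default) standing in for the anode self-absorption and exit window that
the bare Kramers form ignores.  The inherent-filtration default was set
by matching the model's step-wedge dose ratios to published Monte Carlo
transport results for this tube class — the usual way semi-empirical
spectrum models are anchored (cf. half-value-layer matching); it is a
model-construction calibration, not a fit to this package's own tests.

Attenuation under a step of thickness `t` is spectrum-weighted
Beer–Lambert transmission.  The quantity of interest is a **dose**
ratio, so the fluence is weighted by the dose response of a
water-equivalent detector, `r(E) = E·μen/ρ(E)` (water):

```
ratio = Σ w(E)·r(E) / Σ w(E)·r(E)·exp(−μ(E)·t)   ≥ 1
```

`transmission_ratio` itself defaults to a flat weighting (a pure
photon-fluence ratio); the beam-level helper `step_dose_ratio` applies
the dose weighting and is what the irradiation simulator uses.
Mass attenuation coefficients for Al and PMMA (and μen/ρ for water) are
bundled on a 5–100 keV grid of standard reference values and
interpolated log-log.  With the defaults the model reproduces published
Monte Carlo step-dose ratios to within about ±10 % (PMMA 10 mm +9 %,
Al 3 mm −6 %, Al 6 mm +2 %) — adequate for a stand-in that ignores
scatter build-up, geometry and the true semi-empirical spectrum shape,
and documented as such rather than claimed exact.

## Photodetector-array device

Geometry: 5 rows × 10 columns of 5 mm-diameter photoresistors at 6 mm
pitch; film experiments use the top two rows (the film sizes involved
cover only those), the full array remains addressable.  The film sees
the array mirrored left-right: device column `c` reads film column
`n_cols − 1 − c`; the mapping is an involution.

Signal chain per LDR:

1. **Aperture** — mean transmission `10^(−netOD)` over the circular
   footprint, with partially covered pixels weighted by their covered
   area fraction (5×5 subgrid), so the average converges to the true
   aperture integral regardless of map resolution.  Footprints clipped
   by the film edge carry a boundary flag.
2. **LED drive** — 3×3 green LEDs, 0–3 V in 256 integer steps; the
   local illumination over an LDR is the bilinear interpolation of the
   drive levels at its position (equal levels give an exactly uniform
   field, the default).
3. **Photoresistor** — `R = R₀·light^(−γ)` with `R₀ = 10 kΩ`,
   `γ = 0.8` (the stated behaviour is inverse proportionality; the
   exponent is configurable), floored at `light = 1e-6` in darkness.
4. **Divider + amplifier** — `V = gain·(Vs·Rf/(Rf + R) − offset)`,
   clamped at 0 V: a fixed, strictly monotone map wherever the channel
   is not clamped dark.  Gain and offset are set by a two-point span
   calibration so films from 0 to 10 Gy cover the ADC range: the
   unirradiated film maps to 88 % of full scale and the 10 Gy film to
   6 %.  The upper point deliberately leaves headroom because channels
   with a +10 % manufacturing gain factor would otherwise clip against
   the ADC ceiling and their calibration curves would flatten and
   become uninvertible.
5. **ADC** — 12-bit quantization `floor(4096·V/Vref)` clamped to
   0–4095 (4096 codes), read `reads_per_ldr` times (default 16) with
   multiplicative Gaussian glitch noise per read (σ = 1 %), the codes
   averaged.  Two array positions (#19, #20 by default) carry 5× the
   noise, emulating channels with anomalous error of unexplained
   origin; they are flagged in every frame and excluded from headline
   means, never silently dropped.

Manufacturing spread is a per-LDR multiplicative voltage gain factor,
uniform ±10 % (seeded, reference LDR pinned at 1).  Because the spread
is a pure scalar on the output, per-LDR calibration curves collapse
exactly onto the reference curve under one scalar conversion factor per
LDR — the design the inverse pipeline assumes.

## Inverse pipeline

**Scanner branch.**  Exposed/unexposed scan pairs (or ready netOD maps)
→ per-pixel netOD → dose via the inverted calibration.  Non-positive or
saturated pixels are masked and counted; netOD outside the calibrated
interval is clamped to the nearest end and counted as out-of-range.
ROI statistics (mean ± sd) use a millimetre rectangle, clipped to the
film with a flag.

**Array branch.**  One degree-5 count(dose) fit per LDR (counts must
fall with dose), then one least-squares scalar per LDR collapsing its
curve onto the reference LDR's over a 256-point common dose grid;
the reference factor is exactly 1.  `adc_to_dose` multiplies counts by
the factors and inverts the reference curve; counts outside the
calibrated interval yield NaN with a per-LDR flag rather than an error.
Curves are fitted first and normalized after (the alternative order —
normalize raw counts, then fit once — is equally defensible; fitting
first keeps per-LDR residual diagnostics).

**Staircase analysis.**  Background subtraction uses a companion film
irradiated at the same nominal dose without the phantom, and is
performed in OD space: the background's OD variation about its mean is
subtracted from the measured map before conversion to dose (for dose
maps and per-LDR doses the equivalent relative-field division is used).
Subtracting in dose space is deliberately rejected: the calibration is
non-linear, so field inhomogeneity must be removed on the signal side.
Films are split into equal horizontal bands (1 or 3 zones:
top/middle/bottom) and per-step averages use the central 60 % of each
step's width to stay off the penumbra.  Note the OD-space correction is
itself only exact for small field perturbations; at 20 % dispersion the
recovered step ratios shift by a few percent from the constructed ones
— the same systematic the physical procedure carries.

**Orientation detection.**  For each candidate orientation (steps
advancing along x for `R`, along y for `R+90`) the expected per-LDR
dose is predicted from the phantom geometry and the step ratios; the
candidate minimizing the summed absolute mismatch over usable LDRs
wins.  Ties within 5 % and symmetric/absent phantoms return
"undetermined".

## Synthetic experiments and their scale

The packaged end-to-end runs use: scanner calibration at 9 doses
0.2–8 Gy on 50×50 mm films at 0.2 mm pitch with a 40×40 mm ROI; array
calibration at 11 doses 0.2–4 Gy (Cs-137) or 0.2–8 Gy (cross-method) on
60×12 mm films covering the top two rows; OD read noise σ = 0.003.
The denser array grid reflects that twenty independent quintic fits on
noisy averaged counts need more support than a single fit on ROI-mean
netOD.  The 0.2 mm synthetic pitch (versus 0.02 mm for a 1200 dpi scan)
keeps the circular apertures well resolved (~490 pixels each) at a
fraction of the memory; results are insensitive to the pitch because
aperture averages are coverage-weighted.

## What the synthetic data does not capture

* No photon transport: no scatter build-up behind steps, no penumbra
  from finite focal spot, no heel effect beyond the smooth-surface
  field model.  Step ratios are narrow-beam, dose-response-weighted
  Beer–Lambert values.
* No post-irradiation darkening kinetics (measurements are assumed at a
  fixed development time) and no multi-channel (RGB triplet) dosimetry.
* Film noise is Gaussian in OD and spatially white; real film has
  structured granularity and batch-to-batch response variation.
* The LDR spread model is a pure output gain; real photoresistors also
  vary in γ and dark resistance, which scalar conversion factors would
  only approximately absorb.
* Electrical detail (multiplexer timing, amplifier bandwidth,
  temperature drift) is out of scope; the per-read glitch noise stands
  in for all of it.

Passing tests therefore demonstrate the *consistency and correctness of
the analysis chain* under a realistic noise budget — not the absolute
accuracy of any physical device.

## Degenerate inputs and tie-breaks

A zero dispersion target returns an exactly flat field; zero-dose films
have netOD 0 by construction; `adc_quantize` clamps rather than errors
(saturation is the contract); an empty usable-LDR set in orientation detection
returns "undetermined" rather than guessing.  All stochastic draws in a
simulated artifact derive from one integer seed via spawned
sub-sequences, so artifacts are reproducible individually and jointly.
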