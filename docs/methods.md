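# Methods

`oxisim` simulates what a reflectance pulse oximeter measures on fingers of
different skin pigmentation, and quantifies how far pigmentation pushes the
device's calibration away from the transmittance-mode calibration it was
likely derived from. This note documents the model, its parameters, the
numerical choices, and what the simulations can and cannot show.

## The physical model

### Geometry

The finger is a stack of plane-parallel slabs: epidermis (0.15 mm), four
dermal sublayers (0.30 mm each), subcutaneous fat (2.0 mm) and muscle
(7.0 mm), with an optional bone cylinder (radius 2 mm, axis 7 mm deep,
perpendicular to the source-detector axis). Coordinates: origin at the
photon entry point, z positive into the tissue, all lengths in mm. An LED
is modelled as a pencil beam at the origin; the photodetector is a disc on
the surface whose centre is 3 mm from the source along +x — a separation
known to give good-quality finger PPG signals. All tissue layers share
n = 1.4 against ambient n = 1.0, so the only refractive mismatch is the
skin surface.

The default pipeline omits the bone: at a 3 mm source-detector separation
in reflectance mode the detected photons overwhelmingly turn around within
the first one or two millimetres, and test runs with and without the
cylinder agree within sampling error. The cylinder is retained in the
geometry (exact ray-cylinder intersection) for experiments at larger
separations; its refractive index is treated as matched to the host slab,
since the Fresnel step at a deep, rarely-reached interface has no
measurable effect on surface reflectance at this separation.

### Absorption

Layer absorption is composed from chromophore volume fractions:

* **Epidermis** — `mu_a = vmel*mu_mel + vw*mu_w + (1-vmel-vw)*mu_base`,
  with the melanosome power law `mu_mel = 6.6e10 * lambda^-3.33` and the
  pigment-free baseline `mu_base = 7.84e7 * lambda^-3.255` (mm^-1, lambda
  in nm). The residual weight on the baseline follows the standard
  tissue-optics convention of closing the volume budget. The melanosome
  fractions 2.55%, 15.5% and 30.5% define the light, moderate and dark
  presets (Fitzpatrick-scale anchors); they are the only field in which
  the three shipped presets differ.
* **Dermal sublayers** — arterial and venous whole blood at their own
  saturations plus water and baseline:
  `[satA*muaHbO2 + (1-satA)*muaHHb]*vA + [satV*muaHbO2 + (1-satV)*muaHHb]*vV
  + vw*mu_w + (1-vA-vV-vw)*mu_base`. Venous saturation is tied to arterial
  saturation by a fixed 10-point offset, `satV = satA - 0.10`.
* **Fat, muscle, bone** — fixed literature absorption per wavelength.

Whole-blood HbO2/HHb and water absorption at 660 and 940 nm ship as an
editable CSV (`chromophore_spectra.csv`), derived from the standard
compiled molar extinction spectra at 150 g/L haemoglobin. No spectral
value is hard-coded in logic; wavelength lookup is exact by default
(`interpolate=True` enables log-log interpolation for sweeps).

### The cardiac pulse

Systole is modelled as a doubling of each dermal sublayer's diastolic
blood volume; arterial and venous compartments start equal and each
double, which is the unambiguous reading of "equally distributed" for the
shipped presets. Scattering is phase-invariant; only blood-bearing layers
change between phases.

### Transport

Standard weighted photon-packet Monte Carlo (hop / drop / spin):
exponential free paths `-ln(xi)/mu_t`, absorption handled by weight
multiplication with the single-scattering albedo, Henyey-Greenstein
deflection (inverse-CDF sampling; the isotropic limit g=0 is handled
exactly), uniform azimuth, unpolarised Fresnel reflection / Snell
refraction at index mismatches with total internal reflection beyond the
critical angle, and exact geometric splitting of steps at layer and
cylinder boundaries (the residual optical depth is carried into the next
medium). Launch deducts the normal-incidence specular loss (2.78% for
1.0/1.4). Packets below weight 1e-4 play roulette with survival
probability 0.1 and 10x reweighting, which is unbiased.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| vmel (light/moderate/dark) | 0.0255 / 0.155 / 0.305 | — | skin-type anchors |
| satA grid | 0.70–1.00 step 0.05 | — | hypoxaemia-to-normal range |
| satV | satA − 0.10 | — | fixed arteriovenous offset |
| dermal blood vA=vV per sublayer | 0.002/0.005/0.010/0.020 | — | perfusion increasing with depth |
| dermal/epidermal water | 0.65 / 0.20 | — | literature tissue water content |
| source-detector separation | 3.0 | mm | high-quality finger PPG geometry |
| detector radius | 1.0 | mm | typical PD active area (~3 mm^2) |
| detected-packet target | 1e5 (desk), 1e6 (paper scale) | packets | precision vs runtime |
| roulette threshold / survival | 1e-4 / 0.1 | — | standard unbiased termination |
| lateral cutoff | 15 | mm | finger half-width; see below |

Scattering spectra (mu_s, g per wavelength and layer) live entirely in the
preset YAML files, with reduced scattering around 2.4 mm^-1 (dermis,
660 nm) falling to ~1.5 mm^-1 at 940 nm and anisotropy 0.7–0.8 — mid-range
literature values for skin, fat and muscle. Layer constants are
literature-derived defaults, not fitted quantities; swapping in other
published sets only requires editing the YAML.

## From reflectance to calibration curves

For each (skin, wavelength, phase, satA) the engine runs until the
detected-packet target is reached and reports reflectance =
detected weight / launched weight. Per saturation:

* `DC_lambda = R_diastole`, `AC_lambda = R_diastole - R_systole` (systolic
  blood influx absorbs more light, so AC >= 0). The choice of the
  diastolic reading as the DC baseline is a convention; `dc_mode="mean"`
  switches to the two-phase mean, which changes R by well under 1% at
  these pulse amplitudes.
* perfusion index `PI = AC/DC`; ratio of ratios `R = PI_660 / PI_940`.

Calibration curves `SaO2 = a - b*R` are ordinary least squares of SaO2 on
R (statsmodels under the hood; estimates, standard errors and residuals
are reported). The reference-equation fixture `table2_curves.json` ships
six simulated transmittance/reflectance curves for the three skin types
plus the commercial algorithm `SpO2 = 110 - 25*R`; the commercial row is
for comparison plots only.

**Bias analysis.** The light-skin transmittance curve (which closely
matches the commercial algorithm) is inverted on the healthy range
SaO2 = 95, 96, ..., 100% — a 1% step reproduces the fixture's published
summary statistics exactly, pinning down the grid — and the resulting R
values are substituted into each skin type's transmittance and reflectance
curves; bias is transmittance minus reflectance prediction, summarised by
its RMSE.

**Correction factors.** For each darker skin type, both its reflectance
curve and the light-skin reflectance curve are inverted on the full 70–100
(step 5) grid, and the factor is the mean of `R_light / R_target`.
Multiplying a darker skin type's measured R by this factor maps it onto
the light-skin calibration. On the shipped fixture this yields 2.17 (dark)
and 1.22 (moderate). The factor is overridable by explicit value, because
the mean-ratio construction is one of several defensible conventions (the
endpoint ratios range from 1.86 to 2.33 for dark skin: a single multiplier
cannot make the curves coincide everywhere, which is also visible in the
corrected curves' residual spread).

## Numerical and variance choices

* **Ring (azimuthally averaged) detection tally.** The pencil-beam
  problem is rotationally symmetric about the source axis, so a packet
  exiting at radial distance r contributes its weight times the fraction
  of the circle of radius r covered by the detector disc. This has
  exactly the expectation of the literal point-in-disc tally (the two are
  compared in the test suite) at roughly an order of magnitude lower
  variance per launched packet. `tally="disc"` selects the literal tally.
  The detected-packet count in ring mode counts packets exiting within
  the annulus that overlaps the detector.
* **Lateral cutoff 15 mm.** Packets wandering further than a finger
  half-width from the source are terminated and tallied separately (and
  folded into the absorbed ledger). Their potential later contribution to
  a detector 3 mm from the source is bounded by the attenuation of a
  >24 mm return path (<1e-3 of the signal) while their simulation cost is
  unbounded.
* **Energy ledger.** specular + diffuse reflected + transmitted +
  absorbed = launched, exactly to float rounding on every run: roulette
  kills/amplifications and lateral terminations are folded into the
  absorbed tally, keeping the invariant checkable per run rather than
  only in expectation.
* **Determinism.** A run is a pure function of (stack, detector,
  settings, seed). The RNG is an inline xorshift128+ stream seeded via
  splitmix64; per-combination child seeds are SHA-256 hashes of
  (base seed, skin, wavelength, phase, satA), so extending a grid never
  changes existing results. Execution is single-threaded.
* **Degenerate inputs.** mu_t = 0 propagates straight to the next
  boundary; a vacuum layer with horizontal flight is terminated into the
  lateral tally; xi ~ U(0,1] in the step sampler so a zero step is
  possible but log(0) is not.
* **Problem sizes.** Routine runs and the shipped analyses use the
  desk-scale target of 1e5 detected packets per combination (the full
  three-skin grid is 84 transport runs); `--detected 1000000` reproduces
  the paper-scale stop criterion when more precision is wanted. At desk
  scale the ratio-of-ratios of a single combination carries a relative
  standard error of roughly 1–3%, dominated by the AC differences.

## What the simulations show, and what they do not

At desk scale the model reproduces two qualitative effects of
pigmentation robustly: 660 nm reflectance is strictly ordered light >
moderate > dark at every grid point (melanin absorbs red light), and the
ratio of ratios falls with SaO2 on every preset (deoxyhaemoglobin's red
absorption drives the red pulsatile signal), yielding fitted calibration
curves with the field's familiar negative R-coefficient.

Two further effects reported for pigmented skin — a steeper calibration
slope and a compressed R range for dark skin — do **not** emerge from
this model class, and the corresponding acceptance-suite checks document
that as a negative result. The reason is structural: melanin is confined
to a thin epidermis that contains no pulsatile blood, so its attenuation
multiplies systolic and diastolic reflectance almost equally and cancels
in PI = AC/DC. The residual path-selection effect even has the opposite
sign (epidermal absorption preferentially kills shallow, multi-crossing
photon paths, biasing the detected ensemble toward deeper, more
blood-sensitive paths). Reproducing a strong dark-skin R compression
evidently requires a different allocation of the optical constants than
the literature stand-ins shipped here; and at the desk-scale packet
budget the per-point R carries a 7–15% relative standard error, so
single-fit slope and range comparisons between presets are
noise-dominated in any case.

The model does not reproduce any particular published calibration's
coefficients, because those depend on the exact layer optical constants
(thicknesses, mu_s, g, blood fractions) of the source model. The
closed-form bias/RMSE and correction-factor analyses, by contrast, are
exact functions of the shipped curve fixture and are reproduced to four
decimals.

Known limitations: slab geometry (no curved finger surface, nail or
vessel-resolved vasculature); no motion artifact, ambient light or
time-resolved waveform synthesis; bilirubin and dyshaemoglobins are not
modelled; the bone cylinder ignores its refractive mismatch; spectra are
fixed at two wavelengths unless interpolation is enabled.
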