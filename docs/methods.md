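# Methods

This note records the models, the numerical choices and the limits of the
synthetic-data emulation, so results produced with this package can be read
with the right caveats.

## Units and domains

Thermo-mechanical quantities are SI internally (cp in J·K⁻¹·kg⁻¹, cs in
m·s⁻¹, ρ in kg·m⁻³); spectra keep bench units (cm⁻¹, nm, MHz, dB·cm⁻¹).
Conversions happen only at type boundaries, because the Grüneisen formula
Γ = β·cs²/cp is notoriously easy to get wrong by a factor of 1000 when cp
is quoted per gram; a guard test asserts the unit round trip.

Each constitutive law carries the concentration/wavelength/frequency domain
over which it was characterised (absorption: C ∈ [0.5, 2] % w/w,
λ ∈ [490, 835] nm; scattering: C ∈ [0.25, 1] mg/mL, λ ∈ [590, 815] nm;
attenuation: C ∈ [0.75, 4] % w/w, f ∈ [15, 35] MHz). Evaluation outside a
domain is permitted — the laws extrapolate well, and higher agarose
concentrations are the intended route to stiffer, more absorbing phantoms —
but every such evaluation raises `ExtrapolationWarning` and is recorded in
property sheets and design results. Nothing is clamped silently.

## Reconstructed linear laws

The density, sound-speed and heat-capacity regressions are linear laws
anchored to published range endpoints (ρ 1000→1018 kg·m⁻³ and
cs 1482→1493 m·s⁻¹ over C_agarose ∈ [0.5, 3] % w/w; cp 4100→3870
J·K⁻¹·kg⁻¹ over C_TiO2 ∈ [0, 1] mg/mL) because the fitted coefficients
themselves were never released. They are reconstructions, not printed fits,
and the anchors are overridable (`LinearLaw.from_anchors`); whether the
sound-speed range maps to the [0.5, 3] or the full [0.5, 4] concentration
interval is genuinely ambiguous, which is the other reason the anchors are
configuration, not constants.

## Uncertainty propagation

Law standard errors propagate to first order (delta method) into property
sheets. Parameter covariances were not published, so errors are treated as
independent — a conservative approximation. Bench-style Type-B budgets
(calorimetry, sound speed) follow the GUM pattern: per-input standard
uncertainty times analytic sensitivity, combined in quadrature, expanded
with k = 1.96. The Monte-Carlo scheme (`montecarlo_uncertainty`) perturbs
every scalar input of a pluggable inversion independently with a uniform
law of configurable half-width and reports per-output CVs; it is seeded and
bit-reproducible. The adding-doubling and integral-reflectance inversions
themselves are external contracts, not reimplemented here — any callable
honouring `inputs → outputs` plugs in, and the tests use analytic
stand-ins whose CV has a closed form (w/(μ√12) for the identity).

## Acoustic processing choices

- **Delay estimator**: peak of the full cross-correlation between sample
  and reference traces with three-point parabolic sub-sample interpolation.
  Sign convention: Δt < 0 when the sample pulse arrives earlier (sample
  faster than water). The estimator is not prescribed by the source
  measurements; cross-correlation is the robust default for
  pulse-through-pulse delays.
- **Water model**: Marczak's 5th-order polynomial cw(T) (0–95 °C), which
  gives 1482 m·s⁻¹ at 20 °C to the rounding used throughout; water
  attenuation αw(f) = k·f² with k = 0.85/400 dB·cm⁻¹·MHz⁻², anchored at
  20 MHz. Both are fields of `WaterModel` and overridable; temperature
  dependence of αw is out of scope.
- **Temperature correction**: cs is corrected to a reference day
  temperature (default 19.9 °C) with the agar-gel slope 0.6 m·s⁻¹·°C⁻¹.
- **Spectra**: magnitude of the real FFT with a rectangular window over a
  configurable gate (default: full trace). Windowing was not prescribed;
  the synthetic traces are compactly supported so the rectangular window is
  exact for them.
- **Power-law fits**: least squares in log-log space — exact on noiseless
  power-law input, with standard errors from the linear-regression
  covariance. dB↔Np conversions use 8.685889638.

## Nonlinear optical fits

Trust-region reflective least squares (scipy), tolerances 1e-12, at most
10 000 evaluations, bounds a_rm ∈ [0, 1], c > 0, amplitude > 0.
Non-convergence raises `FitFailureError` carrying the residual vector —
never a silent partial result. The scattering fit follows a two-stage
default: per-concentration fits from the initial point (a, x, y) =
(0.5, 5, 2) — flagging a Rayleigh weight pinned at a bound with a large
residual — then a pooled joint fit of the concentration-proportional model
initialised from the stage-1 medians. A simultaneous single-stage fit is
exposed as an alternative (`pooling="simultaneous"`); the two agree to all
reported figures on clean data, and the per-concentration stage is what
reveals the Rayleigh/Mie degeneracy on λ⁻⁴-like data (a → 1 and y → 4 are
equivalent minima; both are accepted).

## Mie anisotropy

The TiO2 particle index follows the single-pole dispersion
n² = 5.913 + 0.2441/(λ² − 0.0803) (λ in μm); the host index is 1.335.
Size parameter x = 2π·r·n_host/λ_vac, relative index m = n_TiO2/n_host.
Scattering coefficients use the logarithmic-derivative downward recurrence
(stable for all m·x) with Riccati-Bessel functions of the real argument by
upward recurrence, truncated at the standard x + 4x^(1/3) + 2 terms; a test
cross-checks against an independent direct evaluation built on scipy's
spherical Bessel functions to 1e-6. The summary g is the **unweighted**
mean over the radius grid 125–250 nm (10 nm steps) and wavelength grid
590–830 nm (1 nm steps, 3133 evaluations): the true particle size
distribution is unknown, so uniform weighting is the documented default and
a per-radius weight vector can be supplied instead. On this grid the mean
is 0.505 with spread 0.067 — inside the published 0.516 ± 0.045 band; the
residual offset is consistent with the unknown size distribution.

## PA signal processing

Wavelet denoising: Daubechies-8, decomposition level min(5, ⌊log2 N⌋ − 3),
soft universal threshold σ√(2 ln N) with σ from the median absolute
deviation of the finest detail level. Only the wavelet family was
prescribed upstream; order, level and threshold are this package's
documented defaults, and the validation metric (peak-to-peak amplitude) is
insensitive to them at the tested SNRs — acceptance rests on
SNR-improvement properties, not waveform equality. The peak-to-peak
spectrum divides (max − min) of the gated, denoised trace by the
photodiode pulse-energy proxy; the gate defaults to the full trace.
Ensemble comparisons are made after peak normalisation to 1 (absolute
comparison available behind a flag), reporting pointwise z-scores and the
fractions of wavelengths inside mean ± 1 sd and inside the min/max
envelope.

## Synthetic data: what it emulates and what it does not

Every generator is the exact algebraic inverse of its analysis stage in the
noiseless limit, asserted per stage in the tests. Noise defaults mirror
bench repeatability: 1.28 % CV on optical coefficients, 0.1 °C thermocouple
scatter, 0.1 mg mass scatter, additive white noise on waveforms at a
configurable SNR. Not emulated: coloured instrument noise (white noise is a
documented simplification), transducer diffraction and beam effects
(plane-wave substitution is assumed), fluence and acoustic propagation in
the PA source model (amplitude ∝ Γ·μa only), and interface losses in the
attenuation model (total transmission assumed, justified by the ≥ 0.987
transmission coefficients). Passing round-trip tests therefore demonstrates
the correctness of the computations, not the realism of the bench physics.

Problem sizes: synthetic waveforms default to the 4 GSa/s digitiser rate on
the dataclass, while generators in the tests run at 1 GSa/s over 2 μs —
a decimation that leaves the 15–40 MHz analysis band with a 12× Nyquist
margin. PA A-lines use 2048 samples at 250 MSa/s over the 700–900 nm,
5 nm-step spectroscopy grid. Simulation-based tests use 50–100 seeds per
statistic and 1000 records for the Monte-Carlo-vs-delta-method calorimetry
check.

## Inverse design

Pure optical targets invert in closed form (each optical property
constrains exactly one concentration):
C_TiO2 = μs′/(x·(λ/1000)^(−y)) and
C_agarose = (μa·(c² + (λ−500)²)/c − b)/a. Mixed targets are solved by
bounded least squares over both concentrations in log-property space, so
properties spanning orders of magnitude weigh equally (uniform weights by
default). Search bounds default to the intersection of the characterised
domains of the targeted laws, with an explicit escape hatch
(`allow_extrapolation`). Unreachable targets are reported infeasible with
the nearest-achievable recipe and its residuals. The design→predict round
trip is the identity on the admissible region (property-tested).

## Known limitations

- β was never measured on this material; Γ predictions inherit the
  gelatin-hydrogel interval and always carry a range.
- The linear thermo-mechanical laws are endpoint reconstructions (above).
- Optical laws carry no temperature dependence; attenuation of water no
  temperature dependence either.
- No multilayer phantoms, no bone mimicry, no image
  reconstruction/beamforming, no chromophore unmixing.
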