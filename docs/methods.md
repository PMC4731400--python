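# Methods

This note documents the models, the numerical choices, the synthetic
data generator, and the limits of what the test suite demonstrates.

## Forward models

**Time-resolved reflectance.** We use the dipole (image-source) solution
of the diffusion equation for a homogeneous semi-infinite medium. The
isotropic source sits at depth z₀ = 1/μs′; the extrapolated boundary
places the negative image at −(z₀ + 2z_b) with z_b = 2AD, where
A(n) = (1 + R_eff)/(1 − R_eff) and R_eff follows the Groenhuis/Egan
polynomial in the relative refractive index. The diffusion coefficient
is D = 1/(3μs′), i.e. absorption-independent — the convention under
which absorption factorizes exactly as exp(−μa·v·t), which the tests
exploit. A zero-boundary variant (z_b = 0) is selectable through
`MediumConfig(boundary="zero")`. Defaults: tissue n = 1.4, exterior
n = 1.0, the ubiquitous soft-tissue convention. Units are cm, ns, cm⁻¹
throughout; source-detector separations are accepted in mm because that
is how probes are specified.

The late-time log-slope of R(ρ,t) tends to −μa·v only asymptotically:
the t^(−5/2) prefactor contributes −2.5/t to the slope, which at t = 4 ns
is still ~25–30% of μa·v for μa ≈ 0.1 cm⁻¹. The corresponding test
therefore checks the slope on an 80–100 ns window, where the prefactor
term is below 1.5%.

**Correlation diffusion.** The electric-field autocorrelation of the
same half-space geometry is the difference of two Green's functions with
decay wavenumber K²(τ) = 3μs′μa + 6μs′²k₀²·BFI·τ, i.e. Brownian
scatterer dynamics ⟨Δr²(τ)⟩ = 6·BFI·τ with the blood flow index
BFI ≡ αD_b fitted as a single parameter. The intensity autocorrelation
follows from the Siegert relation g₂ = 1 + β|g₁|².

Both forward models are verified against independently coded 50-digit
(mpmath) evaluations on 100-point parameter sweeps at relative error
< 10⁻⁸.

## TRS fitting

The forward model is evaluated on the TCSPC grid, convolved with the
unit-sum measured IRF (linear discrete convolution truncated to the grid
length), scaled by a free amplitude, and compared to the counts inside
the fit window — first bin ≥ 80% of peak on the rising edge to the last
bin ≥ 1% of peak on the tail (inclusive thresholds; the first bin
attaining the maximum is the peak). Residuals carry Poisson weights
√max(counts, 1). Because the amplitude is free and the weights scale
with the data, the fit is invariant under rescaling the curve, so no
separate normalization step is needed.

The optimizer is bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) over (μa, μs′, log-amplitude),
bounds μa ∈ [0.01, 1], μs′ ∈ [1, 30] cm⁻¹, with a three-point
multi-start fallback when the first solve does not converge.
Non-convergence sets a flag, never raises. Curves with fewer than 10⁴
total counts, or fits with reduced χ² > 10, are flagged excluded — an
auditable stand-in for the manual low-SNR exclusion such protocols
apply.

An optional time-shift parameter between IRF and DTOF (bounded ±3 bins)
is available for instruments with uncertain delay calibration, but it is
off by default: the shift is nearly degenerate with μs′ at TCSPC noise
levels (with it free, μs′ errors at 10⁶ counts reach ~13%; with it
fixed, they stay below ~2%). On simulated data the grids are aligned by
construction, and on real data a separate delay calibration is the
better remedy.

## Chromophore decomposition

Extinction coefficients ship as a versioned CSV (`data/extinction_nir.csv`):
a Prahl-style compilation for oxy-/deoxyhemoglobin (cm⁻¹·M⁻¹, log-10
basis, converted by ln 10) and Hale & Querry-interpolated pure-water
absorption. The water term (fixed fraction, default 0.78) is subtracted
and the 3-equation/2-unknown system solved by unweighted ordinary least
squares; the residual norm is reported. Negative fitted concentrations
are flagged and reported unclipped, for auditability. Whether the
original analyses solved the overdetermined system by least squares or
by a wavelength pair is not documented anywhere we know of; least
squares is the natural choice and is what we test. Published THC/StO₂
anchors are checked at ±5%, the spread attributable to extinction
compilations; a sensitivity test confirms that moving the assumed water
fraction by ±5 percentage points moves THC by well under 10%.

## DCS fitting

g₂ curves are fitted by 1 + β·g₁(τ; BFI)² over lags in 10⁻⁷–10⁻² s,
truncated where g₂ − 1 falls below 1% of the plateau β (noise floor),
with uniform weights. BFI is optimized on a log scale (it spans decades);
β is fitted jointly by default or can be fixed from the early-lag
plateau. The optical properties entering g₁ come from the TRS fit at
785 nm — no spectral interpolation is needed since the DCS laser sits at
a TRS wavelength. Plateau values below 1.05 raise a low-coherence flag.
Per-channel fits (the instrument records four) are averaged after
dropping non-converged channels; weights default to equal because the
exports carry no per-channel photon counts.

## Synthetic data

The generator emulates the study conditions, not an arbitrary
instrument:

* **IRFs** — exGaussian (Gaussian ⊗ exponential tail, tail constant 25%
  of the width) with FWHM 400/350/450 ps at 690/785/830 nm on 10 ps
  bins, iteratively rescaled so the realized FWHM matches within 2%.
* **DTOFs** — Poisson draws around the IRF-convolved forward curve,
  default 10⁶ total counts at ρ = 25 mm.
* **g₂ curves** — noiseless Siegert curve plus zero-mean Gaussian noise
  with a Koppel-type variance: for each lag, with multi-tau bin width
  δ(τ) and n = (count rate)·δ photons per bin,
  var ∝ (δ/T)[β²(1+e^(−2Γτ)) + 2β(1+e^(−2Γτ))/n + (1+βe^(−Γτ))/n²],
  Γ the effective 1/e decay rate, T the integration time (7 s default),
  count rate 100 kHz per channel — noise falls as 1/T and grows with
  lag-bin sparseness, matching the qualitative behavior of hardware
  correlators.
* **Cohorts** — 22 subjects (10 F / 12 M) with gender-specific
  demographics and tissue dimensions; six probe locations per subject
  with location means and SDs equal to the healthy-population tables
  (THC 100.9–144.8 μM, StO₂ 63.8–68.4%, BFI (7.8–16.0)×10⁻⁹ cm²/s);
  a per-subject random intercept (ICC 0.4 of each location variance, a
  typical repeated-measures share); BMI slopes (−2 μM, −0.25%,
  −0.2×10⁻⁹ cm²/s per kg/m², centered at BMI 23.5 so location means are
  preserved); moment-matched lognormal BFI at the three locations where
  right-skew was observed; and an optional nodule template (THC
  210.8 μM, BFI 45.5×10⁻⁹ cm²/s, StO₂ 72%, μs′ scaled by 0.73 on the
  left-lobe locations of the first four subjects). Truth is
  parameterized at the hemodynamics level and mapped to μa triplets
  through the same extinction table the decomposition uses, so
  absorption-level and concentration-level truths are consistent by
  construction. All generators are bit-reproducible given (config, seed);
  stages draw from named CRC-keyed substreams of one root seed.

What the generator does **not** emulate: layered tissue (the superficial
thickness values are metadata only — the forward model is homogeneous),
probe-pressure and contact artifacts, physiological drift between
repeat placements (we generate one record per subject × location, which
is also how repeats are aggregated before modelling), afterpulsing or
background counts in the TCSPC histograms, and inter-channel speckle
correlations. Passing recovery tests therefore demonstrate correctness
of the inference chain under the stated noise models, not robustness to
every artifact of clinical data.

## Statistics

Mixed models use `statsmodels` MixedLM (random intercept per subject),
ML estimation, and a χ² likelihood-ratio test of the fixed effect
against the intercept-only null; fitted level means (intercept + level
coefficients) are reported next to raw means. Degenerate designs (one
subject, failed or non-finite fits) fall back to raw means with a
`singular` flag. Calibration was verified by simulation: the organ-test
type-I error at n = 22 sits at ~5% over 1000 null cohorts. The
"bootstrapping" robustness check is implemented as leave-one-subject-out
refits (flagging exclusions that cross p = 0.05) plus an optional
subject-level bootstrap, which reproduces the reported single-subject
exclusion behavior. No multiple-comparison correction is applied, by
design. Percent contrasts are reported as 100·(mean_a/mean_b − 1)
rounded to integer percent.

## Problem sizes

The acceptance studies use 100 seeded TRS recoveries, 3×20 DCS
recoveries, 1000 null + 100 alternative cohorts for the mixed-model
calibration, and one full 22-subject raw-curve round trip — sizes at
which every Monte-Carlo margin in the assertions is several estimated
standard errors wide while the whole suite stays fast on a single CPU.

## Known limitations

* Homogeneous semi-infinite geometry only; thyroid sits under
  2–12 mm of superficial tissue, so real measurements carry partial
  volume effects the model cannot separate (a two-layer model would).
* The extinction compilation is one of several in circulation; absolute
  THC/StO₂ carry a few-percent compilation uncertainty, which is why the
  published anchors are checked at ±5%.
* The g₂ noise model is a variance model, not a photon-level speckle
  simulation; correlations between lags are not reproduced.
* β and BFI are jointly identifiable on clean data but trade off under
  heavy noise; fixing β from the plateau is available when needed.
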