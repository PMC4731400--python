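# thyrodos

Hybrid **time-resolved spectroscopy (TRS)** + **diffuse correlation
spectroscopy (DCS)** analysis of thyroid and neck-muscle tissue, as a
tested Python library: forward photon-diffusion models, inverse fitting
for optical properties and blood flow, hemoglobin decomposition, and the
mixed-effects statistical layer for multi-subject cohorts — plus a
synthetic-data generator that emulates the whole measurement protocol so
every stage is testable without instrument data.

It is written for researchers in biomedical optics who want a
transparent, scriptable reference implementation of the standard
near-infrared tissue characterization chain in reflectance geometry.

## The models

**TRS.** A picosecond laser pulse injected at the tissue surface spreads
diffusively; the histogram of photon arrival times (DTOF) at a
source-detector separation ρ is modelled by the semi-infinite
homogeneous diffusion solution with an extrapolated boundary,

```
R(ρ, t) = (4πDv)^(-3/2) t^(-5/2) exp(-μa v t - ρ²/(4Dvt))
          × ½ [ z₀ e^(-z₀²/4Dvt) + (z₀+2z_b) e^(-(z₀+2z_b)²/4Dvt) ],
```

with D = 1/(3μs′), z₀ = 1/μs′, z_b = 2AD, v = c/n. The model is
convolved with the measured instrument response function (IRF) and
fitted to the curve from 80% of the peak on the rising edge to 1% on the
tail, with Poisson weights, yielding the absorption and reduced
scattering coefficients (μa, μs′) at 690, 785 and 830 nm.

**Chromophores.** The three absorption coefficients are a linear mixture
μa(λ) = Σᵢ εᵢ(λ)cᵢ of oxy- and deoxyhemoglobin plus a fixed 78% water
fraction (lipid neglected); ordinary least squares on the 3×2 system
gives the concentrations, hence THC = c_HbO2 + c_Hb and
StO₂ = 100·c_HbO2/THC.

**DCS.** Moving red blood cells decorrelate coherent diffused light. The
measured intensity autocorrelation g₂(τ) = 1 + β·g₁(τ)² (Siegert
relation) is fitted by the semi-infinite correlation-diffusion solution
with Brownian dynamics, decay wavenumber K²(τ) = 3μs′μa + 6μs′²k₀²·BFI·τ,
using the TRS-fitted μa and μs′ at 785 nm — which is what makes the
fitted blood flow index (BFI, cm²/s) an absolute quantity.

**Statistics.** Cohort data (one record per subject × probe location) is
analyzed with linear mixed-effects models: per-subject random intercept,
one fixed effect at a time (organ, side, location, BMI, …), and a
likelihood-ratio test against the intercept-only null at p < 0.05, with
Shapiro–Wilk/Q-Q normality checks, leave-one-subject-out and
subject-bootstrap robustness analysis, and Welch t-tests for
demographics.

## Worked example

```python
from thyrodos import decompose

res = decompose((0.28, 0.27, 0.31))   # thyroid organ-average mu_a, 1/cm
print(round(res.thc, 1), round(res.sto2, 1))
```

prints `137.6 66.7`: a tissue absorbing 0.28/0.27/0.31 cm⁻¹ at
690/785/830 nm carries 137.6 μM of total hemoglobin at 66.7% oxygen
saturation. The `examples/` directory has one narrative script per
capability:

* `decompose_organ_triplets.py` — absorption triplets → THC/StO₂ for
  thyroid and muscle;
* `fit_single_placement.py` — simulate and refit one probe placement
  (three DTOFs + one g₂ curve) end to end;
* `population_analysis.py` — a 22-subject synthetic cohort through the
  mixed-effects layer, with the influence analysis;
* `nodule_case.py` — the nodule template pushed through the whole
  raw-curve pipeline.

A thin CLI mirrors the stages (`thyrodos cohort-sim`, `fit-trs`,
`fit-dcs`, `decompose`, `analyze`, …); run `thyrodos --help`.

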