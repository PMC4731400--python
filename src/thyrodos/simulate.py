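"""Synthetic measurement and cohort generation.

Everything the analysis pipeline consumes can be generated here: TCSPC
histograms (DTOFs) with their instrument response functions, intensity
autocorrelation curves, and full multi-subject cohorts with the
repeated-measures structure of a bilateral thyroid/neck-muscle protocol
(six probe locations per subject, a per-subject random intercept, a BMI
covariate, location-specific right-skew in the blood flow index, and an
optional nodule template).

Default parameter values are the healthy-population means and standard
deviations of the study the generator emulates: THC 101-145 uM, StO2
64-68%, BFI (8-16)e-9 cm^2/s across the six locations; mu_s' 6.5-9.2
1/cm across wavelengths; 22 subjects (10 F / 12 M) with gender-specific
demographics; IRF widths 400/350/450 ps at 690/785/830 nm.

All generators are bit-reproducible given (config, seed); independent
stages draw from named substreams of the root seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromophores import concentrations_from_hemodynamics, forward_mu_a, load_extinction_table
from .dcs import AutocorrelationCurve
from .forward import DCSModelParams, MediumConfig, OpticalProperties, dcs_g1, siegert, tr_reflectance
from .stats import LOCATIONS
from .trs import IRF, DTOFCurve


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class InstrumentConfig:
    """Acquisition parameters of the hybrid TRS/DCS instrument."""

    wavelengths_nm: tuple = (690.0, 785.0, 830.0)
    pulse_widths_ps: tuple = (400.0, 350.0, 450.0)
    rep_rate_hz: float = 50e6
    sd_separations_mm: tuple = (13.0, 25.0)
    trs_acq_time_s: float = 21.0
    dcs_acq_time_s: float = 7.0
    bin_width_ns: float = 0.01
    n_bins: int = 1000

    def __post_init__(self) -> None:
        span = self.bin_width_ns * self.n_bins
        if span > 1e9 / self.rep_rate_hz:
            raise ValueError("histogram span exceeds the laser repetition period")

    @property
    def time_axis_ns(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_ns

    def pulse_width(self, wavelength_nm: float) -> float:
        return self.pulse_widths_ps[self.wavelengths_nm.index(wavelength_nm)]


def generate_irf(
    width_ps: float,
    time_axis_ns: np.ndarray,
    wavelength_nm: float = 785.0,
    shape: str = "exgaussian",
    t0_ns: float = 1.0,
    tail_fraction: float = 0.25,
) -> IRF:
    """Unit-area instrument response with a given FWHM.

    Shapes: ``exgaussian`` (Gaussian convolved with an exponential tail,
    the typical TCSPC response), ``gaussian``, or ``delta`` (single
    bin).  The width parameter is iteratively rescaled so the measured
    FWHM matches ``width_ps`` within 2% on the given grid.
    """
    if width_ps <= 0 and shape != "delta":
        raise ValueError("width must be positive")
    t = np.asarray(time_axis_ns, dtype=float)
    dt = t[1] - t[0]
    if shape == "delta":
        counts = np.zeros_like(t)
        counts[int(round(t0_ns / dt))] = 1.0
        return IRF(t, counts, wavelength_nm, nominal_width_ps=0.0)
    if dt * 1000.0 > width_ps / 3.0:
        import warnings

        warnings.warn("time axis too coarse for the requested IRF width", stacklevel=2)

    width_ns = width_ps / 1000.0
    tau = tail_fraction * width_ns if shape == "exgaussian" else 0.0

    def build(sigma):
        g = np.exp(-0.5 * ((t - t0_ns) / sigma) ** 2)
        if tau > 0:
            kernel_t = np.arange(0, 6 * tau + dt, dt)
            kernel = np.exp(-kernel_t / tau)
            g = np.convolve(g, kernel)[: len(t)]
        return g / g.sum()

    def fwhm(y):
        half = y.max() / 2.0
        above = np.nonzero(y >= half)[0]
        i0, i1 = above[0], above[-1]
        # linear interpolation at both crossings
        left = t[i0] if i0 == 0 else np.interp(half, [y[i0 - 1], y[i0]], [t[i0 - 1], t[i0]])
        right = t[i1] if i1 == len(t) - 1 else np.interp(
            half, [y[i1 + 1], y[i1]], [t[i1 + 1], t[i1]]
        )
        return right - left

    sigma = width_ns / 2.3548
    y = build(sigma)
    for _ in range(8):
        w = fwhm(y)
        if abs(w - width_ns) / width_ns < 0.005:
            break
        sigma *= width_ns / w
        y = build(sigma)
    return IRF(t, y, wavelength_nm, nominal_width_ps=width_ps)


def simulate_dtof(
    props: OpticalProperties,
    rho_mm: float,
    irf: IRF,
    total_counts: float,
    medium: MediumConfig | None = None,
    seed: int = 0,
    noise: bool = True,
) -> DTOFCurve:
    """Poisson-noised TCSPC histogram of the IRF-convolved diffusion model.

    With ``noise=False`` the expected-counts curve (convolved model
    scaled to ``total_counts``) is returned exactly.
    """
    from .trs import convolve_irf

    medium = medium or MediumConfig()
    t = irf.time_bins_ns
    theory = np.zeros_like(t)
    pos = t > 0
    theory[pos] = tr_reflectance(props, rho_mm, t[pos], medium)
    expected = convolve_irf(theory, irf)
    expected = expected * (total_counts / expected.sum())
    if noise:
        rng = substream(seed, "dtof")
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DTOFCurve(t, counts, irf.wavelength_nm, rho_mm)


def default_taus(n_per_decade: int = 20) -> np.ndarray:
    """Log-spaced correlator lags from 100 ns to 10 ms."""
    return np.geomspace(1e-7, 1e-2, int(5 * n_per_decade) + 1)


def simulate_g2(
    params: DCSModelParams,
    props: OpticalProperties,
    rho_mm: float,
    taus_s: np.ndarray | None = None,
    integration_time_s: float = 7.0,
    medium: MediumConfig | None = None,
    seed: int = 0,
    count_rate_hz: float = 100e3,
    channel_id: int = 1,
) -> AutocorrelationCurve:
    """Intensity autocorrelation with correlator (Koppel-type) noise.

    The noiseless curve is 1 + beta * g1(tau)^2.  Zero-mean Gaussian
    noise is added with a variance built from the classic correlator
    statistics: for each lag, with local bin width delta(tau) (the
    multi-tau spacing) and n = count_rate * delta photons per bin,

        var(tau) = delta / T * [ beta^2 (1 + e^(-2 G tau))
                                 + 2 beta (1 + e^(-2 G tau)) / n
                                 + (1 + beta e^(-G tau)) / n^2 ],

    where T is the integration time and G the effective decay rate of
    g1.  Variance falls as 1/T and rises with lag-bin sparseness;
    ``integration_time_s=np.inf`` returns the noiseless curve.
    """
    medium = medium or MediumConfig()
    if integration_time_s <= 0:
        raise ValueError("integration_time must be positive")
    taus = default_taus() if taus_s is None else np.asarray(taus_s, dtype=float)
    g1 = dcs_g1(props, params, rho_mm, taus, medium)
    g2 = siegert(g1, params.beta)
    if np.isfinite(integration_time_s):
        # effective 1/e decay rate of g1
        idx = np.searchsorted(-g1, -np.exp(-1.0))
        tau_e = taus[min(idx, len(taus) - 1)]
        gamma = 1.0 / tau_e
        delta = np.gradient(taus)
        n_ph = np.maximum(count_rate_hz * delta, 1e-12)
        decay = np.exp(-2.0 * gamma * taus)
        var = (delta / integration_time_s) * (
            params.beta**2 * (1.0 + decay)
            + 2.0 * params.beta * (1.0 + decay) / n_ph
            + (1.0 + params.beta * np.exp(-gamma * taus)) / n_ph**2
        )
        rng = substream(seed, f"g2-ch{channel_id}")
        g2 = g2 + rng.normal(0.0, np.sqrt(var))
    return AutocorrelationCurve(
        taus, g2, channel_id=channel_id, rho_mm=rho_mm,
        wavelength_nm=params.wavelength_nm,
        integration_time_s=float(min(integration_time_s, 1e12)),
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: per-location (mean, sd) of the hemodynamic variables; BFI in cm^2/s
HEMODYNAMIC_DEFAULTS = {
    "muscle_right": {"THC": (100.9, 13.7), "StO2": (63.8, 3.8), "BFI": (8.1e-9, 4.3e-9)},
    "gland1_right": {"THC": (144.8, 21.4), "StO2": (67.4, 3.1), "BFI": (13.7e-9, 4.5e-9)},
    "gland2_right": {"THC": (134.7, 18.0), "StO2": (68.4, 2.7), "BFI": (14.7e-9, 6.1e-9)},
    "gland2_left": {"THC": (131.9, 22.2), "StO2": (67.5, 2.2), "BFI": (16.0e-9, 8.8e-9)},
    "gland1_left": {"THC": (136.5, 26.8), "StO2": (66.6, 3.0), "BFI": (15.4e-9, 7.3e-9)},
    "muscle_left": {"THC": (105.7, 17.8), "StO2": (65.9, 3.4), "BFI": (7.8e-9, 1.8e-9)},
}

#: per-location (mean, sd) reduced scattering at 690/785/830 nm, 1/cm
SCATTERING_DEFAULTS = {
    "muscle_right": ((9.1, 0.9), (8.1, 1.0), (7.3, 0.9)),
    "gland1_right": ((9.2, 1.1), (7.9, 1.3), (7.4, 1.1)),
    "gland2_right": ((8.6, 1.2), (7.4, 1.3), (6.9, 1.1)),
    "gland2_left": ((8.1, 1.2), (7.0, 1.3), (6.5, 1.2)),
    "gland1_left": ((8.8, 1.1), (7.6, 1.3), (7.2, 1.2)),
    "muscle_left": ((9.1, 0.9), (8.0, 0.9), (7.3, 0.9)),
}

#: locations whose BFI is drawn from a moment-matched lognormal
LOGNORMAL_BFI_LOCATIONS = ("gland2_right", "gland2_left", "muscle_left")

#: gender-specific demographics: (mean, sd) per variable
DEMOGRAPHICS_DEFAULTS = {
    "F": {"age": (31, 4), "weight": (60, 11), "height": (164, 6),
          "HR": (75, 13), "SaO2": (98, 1),
          "BP_sys_before": (114, 9), "BP_sys_after": (119, 10),
          "BP_dia_before": (69, 9), "BP_dia_after": (70, 4)},
    "M": {"age": (32, 5), "weight": (77, 9), "height": (177, 5),
          "HR": (71, 14), "SaO2": (98, 1),
          "BP_sys_before": (133, 14), "BP_sys_after": (132, 12),
          "BP_dia_before": (79, 8), "BP_dia_after": (78, 11)},
}

#: gender-specific tissue dimensions per organ: (STT, TT) as (mean, sd), mm
TISSUE_DIMENSION_DEFAULTS = {
    "muscle": {"F": ((2.9, 0.8), (6.8, 1.7)), "M": ((3.0, 0.8), (8.1, 1.8))},
    "thyroid": {"F": ((6.5, 2.0), (10.4, 2.8)), "M": ((8.7, 2.0), (13.7, 4.5))},
}


@dataclass(frozen=True)
class NoduleTemplate:
    """Hemodynamic signature of a vascularized thyroid nodule.

    Affected locations get elevated THC and BFI, mildly elevated StO2
    and depressed scattering, mirroring the contrast a large
    hypervascular nodule produces against nodule-free thyroid tissue.
    """

    locations: tuple = ("gland1_left", "gland2_left")
    n_subjects: int = 4
    thc_mean: float = 210.8  # uM
    bfi_mean: float = 45.5e-9  # cm^2/s
    sto2_mean: float = 72.0  # %
    mu_s_scale: float = 0.73  # multiplies the healthy mu_s' means

    def __post_init__(self) -> None:
        if any(loc.startswith("muscle") for loc in self.locations):
            raise ValueError("nodule template cannot target a muscle location")


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters of the synthetic cohort."""

    n_subjects: int = 22
    n_female: int = 10
    hemodynamics: dict = field(default_factory=lambda: HEMODYNAMIC_DEFAULTS)
    scattering: dict = field(default_factory=lambda: SCATTERING_DEFAULTS)
    lognormal_bfi_locations: tuple = LOGNORMAL_BFI_LOCATIONS
    icc: float = 0.4  # fraction of variance between subjects
    bmi_slopes: dict = field(default_factory=lambda: {
        "THC": -2.0,       # uM per kg/m^2
        "StO2": -0.25,     # % per kg/m^2
        "BFI": -0.2e-9,    # cm^2/s per kg/m^2
    })
    bmi_reference: float = 23.5
    sd_separation_mm: float = 25.0
    nodule: NoduleTemplate | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not 0 <= self.icc < 1:
            raise ValueError("icc must be in [0, 1)")
        for loc, entry in self.hemodynamics.items():
            for var, (m, s) in entry.items():
                if m <= 0 or s < 0:
                    raise ValueError(f"invalid (mean, sd) for {var} at {loc}")

    def null(self) -> "CohortConfig":
        """Copy with all location differences removed (organ-effect null)."""
        grand = {
            var: float(np.mean([e[var][0] for e in self.hemodynamics.values()]))
            for var in ("THC", "StO2", "BFI")
        }
        sds = {
            var: float(np.mean([e[var][1] for e in self.hemodynamics.values()]))
            for var in ("THC", "StO2", "BFI")
        }
        hemo = {loc: {var: (grand[var], sds[var]) for var in grand}
                for loc in self.hemodynamics}
        return replace(self, hemodynamics=hemo, lognormal_bfi_locations=(), nodule=None)


@dataclass(frozen=True)
class CohortData:
    subjects: pd.DataFrame
    measurements: pd.DataFrame
    curves: dict | None = None


def _organ_side(location: str):
    organ = "muscle" if location.startswith("muscle") else "thyroid"
    side = "right" if location.endswith("right") else "left"
    return organ, side


def _draw_subjects(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_f = min(config.n_female, config.n_subjects)
    genders = ["F"] * n_f + ["M"] * (config.n_subjects - n_f)
    for i, g in enumerate(genders, start=1):
        d = DEMOGRAPHICS_DEFAULTS[g]
        weight = max(rng.normal(*d["weight"]), 35.0)
        height = max(rng.normal(*d["height"]), 140.0)
        row = {
            "subject_id": i,
            "gender": g,
            "age": max(rng.normal(*d["age"]), 18.0),
            "weight": weight,
            "height": height,
            "BMI": weight / (height / 100.0) ** 2,
        }
        for var in ("HR", "SaO2", "BP_sys_before", "BP_sys_after",
                    "BP_dia_before", "BP_dia_after"):
            row[var] = rng.normal(*d[var])
        row["SaO2"] = min(row["SaO2"], 100.0)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    with_curves: bool = False,
    instrument: InstrumentConfig | None = None,
    medium: MediumConfig | None = None,
    total_counts: float = 1e6,
) -> CohortData:
    """Generate a full synthetic cohort (one record per subject x location).

    Each hemodynamic value is mean_location + subject random intercept +
    BMI slope * (BMI - reference) + residual; BFI residual draws are
    moment-matched lognormal at the configured right-skewed locations.
    The mu_a triplet of each record is derived from its THC/StO2 through
    the extinction table, so concentration-level and absorption-level
    truths are mutually consistent.  With ``with_curves=True`` the
    underlying DTOF (per wavelength) and g2 curves are also emitted, so
    the whole pipeline can run end to end from raw curves.
    """
    config = config or CohortConfig()
    instrument = instrument or InstrumentConfig()
    medium = medium or MediumConfig()
    table = load_extinction_table()

    subjects = _draw_subjects(config, substream(seed, "subjects"))
    rng = substream(seed, "measurements")

    nodule_subjects: set = set()
    if config.nodule is not None:
        nodule_subjects = set(subjects["subject_id"].iloc[: config.nodule.n_subjects])

    # one standard-normal subject effect per response, shared across locations
    u = {var: rng.standard_normal(config.n_subjects) for var in ("THC", "StO2", "BFI")}
    u_mus = rng.standard_normal(config.n_subjects)

    records = []
    curves: dict = {}
    irfs = None
    if with_curves:
        irfs = {
            wl: generate_irf(instrument.pulse_width(wl), instrument.time_axis_ns, wl)
            for wl in instrument.wavelengths_nm
        }

    for si, subj in subjects.iterrows():
        sid = int(subj["subject_id"])
        bmi_dev = subj["BMI"] - config.bmi_reference
        for location in config.hemodynamics:
            organ, side = _organ_side(location)
            entry = dict(config.hemodynamics[location])
            mus_means = [m for m, _ in config.scattering[location]]
            mus_sds = [s for _, s in config.scattering[location]]
            nodule_here = (
                config.nodule is not None
                and sid in nodule_subjects
                and location in config.nodule.locations
            )
            if nodule_here:
                entry = {
                    "THC": (config.nodule.thc_mean, entry["THC"][1]),
                    "StO2": (config.nodule.sto2_mean, entry["StO2"][1]),
                    "BFI": (config.nodule.bfi_mean, entry["BFI"][1]),
                }
                mus_means = [m * config.nodule.mu_s_scale for m in mus_means]

            values = {}
            for var, (mean, sd) in entry.items():
                slope = config.bmi_slopes.get(var, 0.0)
                sd_subj = np.sqrt(max(config.icc * sd**2 - slope**2 * 13.0, 0.0))
                sd_res = np.sqrt(max((1.0 - config.icc) * sd**2, 0.0))
                center = mean + u[var][si] * sd_subj + slope * bmi_dev
                lognormal = (
                    var == "BFI" and location in config.lognormal_bfi_locations
                )
                if lognormal and center > 0 and sd_res > 0:
                    s2 = np.log1p((sd_res / center) ** 2)
                    val = rng.lognormal(np.log(center) - s2 / 2.0, np.sqrt(s2))
                else:
                    val = center + rng.normal(0.0, sd_res)
                values[var] = val
            values["THC"] = max(values["THC"], 5.0)
            values["StO2"] = float(np.clip(values["StO2"], 1.0, 99.0))
            values["BFI"] = max(values["BFI"], 1e-10)

            mus = [
                max(m + u_mus[si] * np.sqrt(config.icc) * s
                    + rng.normal(0.0, np.sqrt(1 - config.icc) * s), 1.5)
                for m, s in zip(mus_means, mus_sds)
            ]
            c_hbo2, c_hb = concentrations_from_hemodynamics(values["THC"], values["StO2"])
            mu_a = forward_mu_a(c_hbo2, c_hb, table)

            dims = TISSUE_DIMENSION_DEFAULTS[organ][subj["gender"]]
            stt = max(rng.normal(*dims[0]), 0.5)
            tt = max(rng.normal(*dims[1]), 1.0)

            rec = {
                "subject_id": sid,
                "organ": organ,
                "side": side,
                "location": location,
                "sd_separation": config.sd_separation_mm,
                "THC": values["THC"],
                "StO2": values["StO2"],
                "BFI": values["BFI"],
                "mu_a_690": mu_a[0], "mu_a_785": mu_a[1], "mu_a_830": mu_a[2],
                "mu_s_690": mus[0], "mu_s_785": mus[1], "mu_s_830": mus[2],
                "STT": stt, "TT": tt, "TTD": stt + tt,
                "nodule_index": int(nodule_here),
            }
            records.append(rec)

            if with_curves:
                placement = {"dtofs": {}, "irfs": irfs, "g2": None}
                for k, wl in enumerate(instrument.wavelengths_nm):
                    props = OpticalProperties(wl, mu_a[k], mus[k])
                    placement["dtofs"][wl] = simulate_dtof(
                        props, config.sd_separation_mm, irfs[wl], total_counts,
                        medium, seed=int(rng.integers(2**31)),
                    )
                props785 = OpticalProperties(785.0, mu_a[1], mus[1])
                placement["g2"] = simulate_g2(
                    DCSModelParams(bfi=values["BFI"], beta=0.5),
                    props785, config.sd_separation_mm,
                    integration_time_s=instrument.dcs_acq_time_s,
                    medium=medium, seed=int(rng.integers(2**31)),
                )
                curves[(sid, location)] = placement

    measurements = pd.DataFrame(records)
    return CohortData(subjects, measurements, curves if with_curves else None)
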