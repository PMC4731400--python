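"""Closed-form photon-diffusion forward models for a semi-infinite medium.

Two observables are modelled for reflectance-geometry measurements on
tissue: the time-resolved diffuse reflectance R(rho, t) measured by
time-resolved spectroscopy (TRS), and the normalized electric-field
autocorrelation g1(tau) measured by diffuse correlation spectroscopy
(DCS).  Both use the homogeneous semi-infinite diffusion solution with
an extrapolated (or, optionally, zero) boundary condition.

Units are fixed package-wide: lengths in cm, time-of-flight in ns,
correlation lags in s, mu_a and mu_s' in 1/cm, BFI in cm^2/s.
Source-detector separations are passed in mm at the API surface (the
convention of the instrument) and converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: speed of light in vacuum, cm/ns
C_VACUUM_CM_NS = 29.9792458


class EvaluationError(FloatingPointError):
    """Raised when a forward-model evaluation over- or underflows."""


@dataclass(frozen=True)
class MediumConfig:
    """Optical boundary configuration of the probed half-space.

    Parameters
    ----------
    n_tissue : float
        Refractive index of the tissue half-space (soft-tissue default 1.4).
    n_exterior : float
        Refractive index of the exterior (air, 1.0).
    boundary : {"extrapolated", "zero"}
        Boundary condition of the diffusion solution.  The extrapolated
        boundary places the negative image source at ``-(z0 + 2*zb)`` with
        ``zb = 2*A*D``; the zero boundary sets the fluence to zero at the
        physical surface.
    """

    n_tissue: float = 1.4
    n_exterior: float = 1.0
    boundary: str = "extrapolated"

    def __post_init__(self) -> None:
        if self.n_tissue < 1 or self.n_exterior < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.boundary not in ("extrapolated", "zero"):
            raise ValueError(f"unknown boundary condition {self.boundary!r}")

    @property
    def speed(self) -> float:
        """Speed of light in the medium, cm/ns."""
        return C_VACUUM_CM_NS / self.n_tissue

    @property
    def boundary_coefficient(self) -> float:
        """Internal-reflection parameter A(n) of the extrapolated boundary.

        Uses the Groenhuis/Egan polynomial for the effective Fresnel
        reflection coefficient as a function of the relative refractive
        index n = n_tissue / n_exterior.
        """
        n = self.n_tissue / self.n_exterior
        r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
        return (1.0 + r_eff) / (1.0 - r_eff)


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering at one wavelength."""

    wavelength_nm: float
    mu_a: float  # 1/cm
    mu_s_prime: float  # 1/cm

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ValueError("mu_a and mu_s_prime must be positive")
        if self.mu_s_prime / self.mu_a < 10:
            warnings.warn(
                "mu_s'/mu_a < 10: diffusion approximation may be inaccurate",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DCSModelParams:
    """Dynamical parameters of the correlation-diffusion model.

    ``bfi`` is the blood flow index (effective Brownian diffusion
    coefficient of the moving scatterers, cm^2/s; tissue values are of
    order 1e-9).  ``beta`` is the coherence factor — the g2 intercept
    above 1 set by the detection optics.
    """

    bfi: float
    beta: float = 0.5
    wavelength_nm: float = 785.0

    def __post_init__(self) -> None:
        if self.bfi < 0:
            raise ValueError("bfi must be >= 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")


def _geometry(props: OpticalProperties, medium: MediumConfig):
    """Return (D, z0, zb) in cm for the dipole image construction."""
    D = 1.0 / (3.0 * props.mu_s_prime)
    z0 = 1.0 / props.mu_s_prime
    if medium.boundary == "extrapolated":
        zb = 2.0 * medium.boundary_coefficient * D
    else:
        zb = 0.0
    return D, z0, zb


def tr_reflectance(
    props: OpticalProperties,
    rho_mm: float,
    times_ns: np.ndarray,
    medium: MediumConfig | None = None,
) -> np.ndarray:
    """Time-resolved diffuse reflectance of a semi-infinite medium.

    Evaluates the dipole (image-source) solution of the diffusion
    equation for a short pulse injected at depth z0 = 1/mu_s', detected
    at surface distance ``rho_mm``:

        R(rho, t) = (4 pi D v)^(-3/2) t^(-5/2)
                    * exp(-mu_a v t - rho^2 / (4 D v t)) / 2
                    * [ z0 exp(-z0^2/(4Dvt)) + (z0+2 zb) exp(-(z0+2zb)^2/(4Dvt)) ]

    The overall scale is arbitrary (the measured amplitude is fitted
    separately); the shape in t carries the information on mu_a and
    mu_s'.  Absorption factorizes: increasing mu_a by ``d`` multiplies
    the whole curve by exp(-d v t).

    Parameters
    ----------
    rho_mm : float
        Source-detector separation in mm (>0).
    times_ns : array
        Strictly positive times of flight in ns.

    Returns
    -------
    ndarray of reflectance values (arbitrary scale), finite and >= 0.
    """
    medium = medium or MediumConfig()
    t = np.asarray(times_ns, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    if rho_mm <= 0:
        raise ValueError("rho must be positive")
    rho = rho_mm / 10.0
    v = medium.speed
    D, z0, zb = _geometry(props, medium)

    with np.errstate(over="raise", divide="raise", invalid="raise"):
        try:
            four_dvt = 4.0 * D * v * t
            common = (
                (4.0 * np.pi * D * v) ** -1.5
                * t**-2.5
                * np.exp(-props.mu_a * v * t - rho**2 / four_dvt)
            )
            if medium.boundary == "extrapolated":
                z1 = z0 + 2.0 * zb
                dipole = 0.5 * (
                    z0 * np.exp(-(z0**2) / four_dvt)
                    + z1 * np.exp(-(z1**2) / four_dvt)
                )
            else:
                dipole = z0 * np.exp(-(z0**2) / four_dvt)
            out = common * dipole
        except FloatingPointError as exc:  # pragma: no cover - extreme params
            raise EvaluationError(f"reflectance evaluation failed: {exc}") from exc
    if not np.all(np.isfinite(out)):
        raise EvaluationError("non-finite reflectance values")
    return out


def dcs_g1(
    props: OpticalProperties,
    params: DCSModelParams,
    rho_mm: float,
    taus_s: np.ndarray,
    medium: MediumConfig | None = None,
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) of the semi-infinite medium.

    Solves the correlation-diffusion equation with Brownian scatterer
    dynamics, mean-square displacement <dr^2(tau)> = 6 * BFI * tau, so
    the decay wavenumber is

        K(tau)^2 = 3 mu_s' mu_a + 6 mu_s'^2 k0^2 * BFI * tau,

    with k0 = 2 pi n / lambda the optical wavenumber in the medium.  The
    unnormalized correlation is the difference of the two image-source
    Green's functions; g1 is normalized so g1(0) = 1.
    """
    medium = medium or MediumConfig()
    taus = np.asarray(taus_s, dtype=float)
    if np.any(taus < 0):
        raise ValueError("taus must be >= 0")
    rho = rho_mm / 10.0
    D, z0, zb = _geometry(props, medium)
    lam_cm = params.wavelength_nm * 1e-7
    k0 = 2.0 * np.pi * medium.n_tissue / lam_cm
    r1 = np.hypot(rho, z0)
    r2 = np.hypot(rho, z0 + 2.0 * zb)

    def _G1(tau):
        K = np.sqrt(
            3.0 * props.mu_s_prime * props.mu_a
            + 6.0 * props.mu_s_prime**2 * k0**2 * params.bfi * tau
        )
        return np.exp(-K * r1) / r1 - np.exp(-K * r2) / r2

    g1 = _G1(taus) / _G1(0.0)
    # guard against roundoff pushing the normalized value past 1
    return np.clip(g1, 0.0, 1.0)


def siegert(g1_values: np.ndarray, beta: float) -> np.ndarray:
    """Intensity autocorrelation from the field autocorrelation.

    g2(tau) = 1 + beta * g1(tau)^2.  ``beta`` in (0, 1].
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    g1 = np.asarray(g1_values, dtype=float)
    if np.any((g1 < 0) | (g1 > 1)):
        raise ValueError("g1 values must lie in [0, 1]")
    return 1.0 + beta * g1**2
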