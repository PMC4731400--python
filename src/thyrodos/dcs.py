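"""Diffuse correlation spectroscopy (DCS) autocorrelation fitting.

Measured intensity autocorrelations g2(tau) from each detector channel
are fitted by the Siegert-transformed semi-infinite correlation-
diffusion solution, 1 + beta * g1(tau; BFI)^2, yielding the blood flow
index BFI and the coherence factor beta.  The absorption and reduced
scattering coefficients entering g1 are taken from the TRS fit at the
DCS wavelength (785 nm), which is what makes the recovered BFI an
absolute quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .forward import DCSModelParams, MediumConfig, OpticalProperties, dcs_g1

#: default tau fit window, s
TAU_WINDOW = (1e-7, 1e-2)
#: noise-floor rule: drop lags where g2 - 1 < NOISE_FLOOR_FRAC * beta_hat
NOISE_FLOOR_FRAC = 0.01


@dataclass(frozen=True)
class AutocorrelationCurve:
    """One correlator channel's (tau, g2) samples."""

    taus_s: np.ndarray
    g2: np.ndarray
    channel_id: int = 1
    rho_mm: float = 25.0
    wavelength_nm: float = 785.0
    integration_time_s: float = 7.0

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus_s, dtype=float)
        g2 = np.asarray(self.g2, dtype=float)
        if taus.shape != g2.shape or taus.ndim != 1:
            raise ValueError("taus and g2 must be equal-length 1-D arrays")
        if np.any(taus <= 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be positive and strictly increasing")
        if not np.all(np.isfinite(g2)):
            raise ValueError("g2 must be finite")
        object.__setattr__(self, "taus_s", taus)
        object.__setattr__(self, "g2", g2)


@dataclass(frozen=True)
class DCSFitResult:
    bfi: float  # cm^2/s
    beta: float
    fit_range: tuple  # (tau_min, tau_max) actually used, s
    residual_norm: float
    converged: bool
    low_coherence: bool = False
    n_points: int = 0


def _plateau_beta(curve: AutocorrelationCurve) -> float:
    """Early-lag estimate of beta from the g2 plateau."""
    k = min(5, len(curve.g2))
    return float(np.mean(curve.g2[:k]) - 1.0)


def fit_g2(
    curve: AutocorrelationCurve,
    props: OpticalProperties,
    medium: MediumConfig | None = None,
    init: DCSModelParams | None = None,
    fit_beta: bool = True,
    tau_window: tuple = TAU_WINDOW,
) -> DCSFitResult:
    """Fit BFI (and beta) to one g2 curve by bounded least squares.

    The fit uses lags inside ``tau_window`` and above the noise floor
    (g2 - 1 >= 0.01 * plateau beta).  BFI is optimized on a log scale;
    beta is either fitted jointly (default) or fixed from the early-lag
    plateau.  Uniform weighting.
    """
    medium = medium or MediumConfig()
    beta_hat = _plateau_beta(curve)
    low_coherence = beta_hat < 0.05  # plateau below 1.05

    mask = (curve.taus_s >= tau_window[0]) & (curve.taus_s <= tau_window[1])
    floor = NOISE_FLOOR_FRAC * max(beta_hat, 1e-3)
    above = curve.g2 - 1.0 >= floor
    # keep everything up to the last lag still above the noise floor so a
    # noisy dip does not truncate the decay prematurely
    if above.any():
        mask &= np.arange(len(mask)) <= np.nonzero(above)[0][-1]
    taus = curve.taus_s[mask]
    data = curve.g2[mask]
    if len(taus) < 5:
        return DCSFitResult(
            bfi=np.nan, beta=np.nan, fit_range=(np.nan, np.nan),
            residual_norm=np.inf, converged=False,
            low_coherence=low_coherence,
        )

    init = init or DCSModelParams(
        bfi=1e-8, beta=min(max(beta_hat, 0.05), 1.0),
        wavelength_nm=curve.wavelength_nm,
    )

    def model(log_bfi, beta):
        params = DCSModelParams(
            bfi=float(np.exp(log_bfi)), beta=beta,
            wavelength_nm=curve.wavelength_nm,
        )
        g1 = dcs_g1(props, params, curve.rho_mm, taus, medium)
        return 1.0 + beta * g1**2

    if fit_beta:
        def residuals(x):
            return model(x[0], x[1]) - data
        x0 = np.array([np.log(init.bfi), init.beta])
        bounds = ([np.log(1e-12), 1e-3], [np.log(1e-5), 1.0])
    else:
        beta_fixed = init.beta
        def residuals(x):
            return model(x[0], beta_fixed) - data
        x0 = np.array([np.log(init.bfi)])
        bounds = ([np.log(1e-12)], [np.log(1e-5)])

    try:
        sol = least_squares(residuals, x0, bounds=bounds, method="trf",
                            xtol=1e-12, ftol=1e-12, max_nfev=400)
    except Exception:
        return DCSFitResult(
            bfi=np.nan, beta=np.nan, fit_range=(float(taus[0]), float(taus[-1])),
            residual_norm=np.inf, converged=False, low_coherence=low_coherence,
            n_points=len(taus),
        )
    bfi = float(np.exp(sol.x[0]))
    beta = float(sol.x[1]) if fit_beta else float(init.beta)
    return DCSFitResult(
        bfi=bfi,
        beta=beta,
        fit_range=(float(taus[0]), float(taus[-1])),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0),
        low_coherence=low_coherence,
        n_points=len(taus),
    )


def average_channels(fits, weights=None) -> DCSFitResult:
    """Aggregate per-channel fits into one placement-level result.

    Non-converged channels are excluded; BFI and beta are averaged over
    the remaining channels with the given weights (default: equal).
    Raises ``ValueError`` when no channel converged (placement-level
    missing value).
    """
    fits = list(fits)
    if weights is None:
        weights = [1.0] * len(fits)
    kept = [(f, w) for f, w in zip(fits, weights) if f.converged]
    if not kept:
        raise ValueError("no converged channels: placement-level missing value")
    ws = np.array([w for _, w in kept], dtype=float)
    ws = ws / ws.sum()
    bfi = float(np.sum(ws * [f.bfi for f, _ in kept]))
    beta = float(np.sum(ws * [f.beta for f, _ in kept]))
    return DCSFitResult(
        bfi=bfi,
        beta=beta,
        fit_range=kept[0][0].fit_range,
        residual_norm=float(np.mean([f.residual_norm for f, _ in kept])),
        converged=True,
        n_points=int(np.sum([f.n_points for f, _ in kept])),
    )
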