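"""Chromophore decomposition of multi-wavelength absorption.

The absorption coefficient of tissue at wavelength lambda is a linear
mixture of its chromophores,

    mu_a(lambda) = ln(10) * [eps_HbO2(lambda) c_HbO2 + eps_Hb(lambda) c_Hb]
                   + f_water * mu_a_water(lambda),

with the hemoglobin extinction coefficients tabulated on a log-10 basis
(cm^-1 M^-1) and concentrations in mol/L.  At the three instrument
wavelengths (690, 785, 830 nm), with the tissue water fraction fixed at
78% and lipid neglected, the two hemoglobin concentrations are the
solution of an overdetermined 3x2 linear system, solved by ordinary
least squares.  Total hemoglobin concentration THC = c_HbO2 + c_Hb and
oxygen saturation StO2 = 100 * c_HbO2 / THC follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

LN10 = float(np.log(10.0))

#: required instrument wavelengths, nm
WAVELENGTHS = (690.0, 785.0, 830.0)

DEFAULT_WATER_FRACTION = 0.78


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction/absorption basis spectra at the instrument wavelengths.

    ``log10_basis`` declares whether the hemoglobin extinction values
    require the ln(10) conversion to natural-log absorption (the usual
    convention of the published compilations).
    """

    wavelengths_nm: tuple
    eps_hbo2: tuple  # cm^-1 M^-1
    eps_hb: tuple  # cm^-1 M^-1
    mu_a_water: tuple  # cm^-1, pure water
    log10_basis: bool = True
    source_citation: str = ""

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        if not (len(self.eps_hbo2) == len(self.eps_hb) == len(self.mu_a_water) == n):
            raise ValueError("all columns must have the same length")
        if any(e <= 0 for e in self.eps_hbo2 + self.eps_hb + self.mu_a_water):
            raise ValueError("extinction/absorption values must be positive")
        missing = set(WAVELENGTHS) - set(self.wavelengths_nm)
        if missing:
            raise ValueError(f"table missing required wavelengths: {sorted(missing)}")

    def row(self, wavelength_nm: float):
        """(eps_hbo2, eps_hb, mu_a_water) at one wavelength."""
        try:
            i = self.wavelengths_nm.index(wavelength_nm)
        except ValueError as exc:
            raise KeyError(f"wavelength {wavelength_nm} nm not in table") from exc
        return self.eps_hbo2[i], self.eps_hb[i], self.mu_a_water[i]

    def design_matrix(self, wavelengths=WAVELENGTHS) -> np.ndarray:
        """Hemoglobin design matrix mapping (c_HbO2, c_Hb) in uM to mu_a in 1/cm."""
        scale = (LN10 if self.log10_basis else 1.0) * 1e-6
        return np.array(
            [[self.row(w)[0] * scale, self.row(w)[1] * scale] for w in wavelengths]
        )

    def water_mu_a(self, wavelengths=WAVELENGTHS) -> np.ndarray:
        return np.array([self.row(w)[2] for w in wavelengths])


def load_extinction_table(path=None) -> ExtinctionTable:
    """Load an extinction table from CSV (default: the shipped compilation).

    Expected columns: wavelength_nm, eps_hbo2, eps_hb, mu_a_water.  A
    comment line ``# basis=log10`` (or ``basis=natural``) declares the
    extinction basis.
    """
    if path is None:
        ref = resources.files("thyrodos.data") / "extinction_nir.csv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    log10_basis = True
    rows = []
    header = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "basis=natural" in line:
                log10_basis = False
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            required = {"wavelength_nm", "eps_hbo2", "eps_hb", "mu_a_water"}
            if not required <= set(header):
                raise ValueError(f"extinction CSV missing columns {required - set(header)}")
            continue
        rows.append(dict(zip(header, (float(x) for x in line.split(",")))))
    return ExtinctionTable(
        wavelengths_nm=tuple(r["wavelength_nm"] for r in rows),
        eps_hbo2=tuple(r["eps_hbo2"] for r in rows),
        eps_hb=tuple(r["eps_hb"] for r in rows),
        mu_a_water=tuple(r["mu_a_water"] for r in rows),
        log10_basis=log10_basis,
        source_citation="shipped NIR compilation",
    )


@dataclass(frozen=True)
class ChromophoreResult:
    """Hemoglobin decomposition of one mu_a triplet."""

    c_hbo2: float  # uM
    c_hb: float  # uM
    water_fraction: float
    residual_norm: float  # 1/cm, norm of the 3-wavelength residual
    negative_concentration: bool = False

    @property
    def thc(self) -> float:
        """Total hemoglobin concentration, uM."""
        return self.c_hbo2 + self.c_hb

    @property
    def sto2(self) -> float:
        """Hemoglobin oxygen saturation, percent."""
        if self.thc == 0:
            return float("nan")
        return 100.0 * self.c_hbo2 / self.thc


def decompose(
    mu_a_triplet,
    table: ExtinctionTable | None = None,
    water_fraction: float = DEFAULT_WATER_FRACTION,
) -> ChromophoreResult:
    """Hemoglobin concentrations and StO2 from a 690/785/830 nm mu_a triplet.

    The fixed water contribution is subtracted, then the 3x2 linear
    system is solved by ordinary least squares.  Negative fitted
    concentrations are reported unclipped with a warning flag.
    """
    table = table or load_extinction_table()
    mu_a = np.asarray(mu_a_triplet, dtype=float)
    if mu_a.shape != (3,):
        raise ValueError("expected a mu_a triplet at 690/785/830 nm")
    if np.any(mu_a <= 0):
        raise ValueError("mu_a values must be positive")
    if not 0 <= water_fraction <= 1:
        raise ValueError("water_fraction must be in [0, 1]")

    b = mu_a - water_fraction * table.water_mu_a()
    if np.any(b < 0):
        warnings.warn(
            "water-corrected mu_a negative at some wavelength; clipping to 0",
            stacklevel=2,
        )
        b = np.clip(b, 0.0, None)
    A = table.design_matrix()
    if np.linalg.cond(A) > 1e8:
        raise ValueError("extinction matrix is singular or near-singular")
    c, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.linalg.norm(A @ c - b))
    negative = bool(np.any(c < 0))
    if negative:
        warnings.warn("negative fitted hemoglobin concentration", stacklevel=2)
    return ChromophoreResult(
        c_hbo2=float(c[0]),
        c_hb=float(c[1]),
        water_fraction=water_fraction,
        residual_norm=residual,
        negative_concentration=negative,
    )


def forward_mu_a(
    c_hbo2_um: float,
    c_hb_um: float,
    table: ExtinctionTable | None = None,
    water_fraction: float = DEFAULT_WATER_FRACTION,
) -> np.ndarray:
    """mu_a triplet at 690/785/830 nm from hemoglobin concentrations (uM)."""
    table = table or load_extinction_table()
    if c_hbo2_um < 0 or c_hb_um < 0:
        raise ValueError("concentrations must be non-negative")
    A = table.design_matrix()
    return A @ np.array([c_hbo2_um, c_hb_um]) + water_fraction * table.water_mu_a()


def concentrations_from_hemodynamics(thc_um: float, sto2_pct: float):
    """(c_HbO2, c_Hb) in uM from THC (uM) and StO2 (%)."""
    if thc_um < 0 or not 0 <= sto2_pct <= 100:
        raise ValueError("need THC >= 0 and StO2 in [0, 100]")
    c_hbo2 = thc_um * sto2_pct / 100.0
    return c_hbo2, thc_um - c_hbo2
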