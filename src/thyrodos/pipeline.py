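"""End-to-end processing: raw curves -> fits -> hemodynamics -> statistics.

`process_cohort` turns the raw DTOF and g2 curves of a cohort into a
fitted measurement table (per-wavelength optical properties, THC, StO2,
BFI per placement), using the TRS-fitted optical properties at 785 nm
in the DCS fit.  `analyze_cohort` runs the statistical layer on any
measurement table: per-location summaries, organ/side/location/covariate
mixed-model contrasts, and the nodule-index contrast when present.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .chromophores import ExtinctionTable, decompose, load_extinction_table
from .dcs import fit_g2
from .forward import DCSModelParams, MediumConfig, OpticalProperties
from .stats import (
    EffectEstimate,
    lme_contrast,
    normality_check,
    percent_contrast,
    summarize_population,
)
from .trs import fit_dtof


def process_placement(
    dtofs: dict,
    irfs: dict,
    g2_curve,
    medium: MediumConfig | None = None,
    table: ExtinctionTable | None = None,
) -> dict:
    """Fit one probe placement: three DTOFs plus one g2 curve.

    Returns the fitted per-wavelength optical properties, the
    chromophore decomposition and the BFI, with an ``excluded`` flag if
    any TRS fit failed the SNR/quality rules.
    """
    medium = medium or MediumConfig()
    table = table or load_extinction_table()
    out: dict = {"excluded": False}
    mu_a = []
    props785 = None
    for wl in sorted(dtofs):
        res = fit_dtof(dtofs[wl], irfs[wl], medium)
        if res.excluded or not res.converged:
            out["excluded"] = True
            return out
        key = f"{int(wl)}"
        out[f"mu_a_{key}"] = res.props.mu_a
        out[f"mu_s_{key}"] = res.props.mu_s_prime
        mu_a.append(res.props.mu_a)
        if int(wl) == 785:
            props785 = res.props

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chrom = decompose(mu_a, table)
    out["THC"] = chrom.thc
    out["StO2"] = chrom.sto2

    if g2_curve is not None and props785 is not None:
        dcs_res = fit_g2(g2_curve, props785, medium)
        out["BFI"] = dcs_res.bfi if dcs_res.converged else np.nan
        out["beta"] = dcs_res.beta
    return out


def process_cohort(cohort, medium: MediumConfig | None = None) -> pd.DataFrame:
    """Fit every placement of a cohort generated with raw curves.

    Returns a measurement table shaped like the generator's truth table
    (same keys), but with THC/StO2/BFI and optical properties obtained
    by fitting the raw curves rather than copied from the truth.
    """
    if cohort.curves is None:
        raise ValueError("cohort was generated without raw curves")
    medium = medium or MediumConfig()
    table = load_extinction_table()
    rows = []
    truth = cohort.measurements.set_index(["subject_id", "location"])
    for (sid, location), placement in cohort.curves.items():
        fitted = process_placement(
            placement["dtofs"], placement["irfs"], placement["g2"], medium, table
        )
        if fitted.pop("excluded"):
            continue
        meta = truth.loc[(sid, location)]
        row = {
            "subject_id": sid,
            "location": location,
            "organ": meta["organ"],
            "side": meta["side"],
            "sd_separation": meta["sd_separation"],
            "STT": meta["STT"], "TT": meta["TT"], "TTD": meta["TTD"],
            "nodule_index": meta["nodule_index"],
        }
        row.update(fitted)
        rows.append(row)
    return pd.DataFrame(rows)


DEFAULT_CONTRASTS = (
    ("THC", "organ"), ("StO2", "organ"), ("BFI", "organ"),
    ("THC", "location"), ("StO2", "location"),
    ("THC", "side"), ("StO2", "side"),
)


def analyze_cohort(
    measurements: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
    contrasts=DEFAULT_CONTRASTS,
) -> dict:
    """Statistical report for a measurement table.

    Contents: the per-location summary table, normality checks per
    location for BFI, the requested mixed-model contrasts, organ->muscle
    percent contrasts for THC and BFI, BMI contrasts when subject data
    is provided, and the nodule-index contrast when any record has
    nodule_index = 1.
    """
    report: dict = {}
    summary = summarize_population(measurements)
    report["summary"] = summary

    report["normality"] = {
        loc: normality_check(grp["BFI"].dropna())
        for loc, grp in measurements.groupby("location")
        if grp["BFI"].notna().sum() >= 3
    }

    effects = {}
    for response, effect in contrasts:
        if effect in measurements.columns and response in measurements.columns:
            effects[(response, effect)] = lme_contrast(measurements, response, effect)
    report["effects"] = effects

    pc = {}
    for var in ("THC", "BFI"):
        for side in ("right", "left"):
            for gland in ("gland1", "gland2"):
                a, b = f"{gland}_{side}", f"muscle_{side}"
                if a in summary.index and b in summary.index:
                    pc[(var, a, b)] = percent_contrast(summary, a, b, var)
    report["percent_contrasts"] = pc

    if subjects is not None:
        merged = measurements.merge(
            subjects[["subject_id", "BMI", "age"]], on="subject_id"
        )
        for cov in ("BMI", "age"):
            for response in ("THC", "StO2", "BFI"):
                effects[(response, cov)] = lme_contrast(merged, response, cov)

    if "nodule_index" in measurements.columns and measurements["nodule_index"].any():
        thyroid = measurements[measurements["organ"] == "thyroid"]
        report["nodule_effect"] = {
            response: lme_contrast(thyroid, response, "nodule_index")
            for response in ("THC", "BFI")
        }
    return report


def format_report(report: dict) -> str:
    """Plain-text rendering of an `analyze_cohort` report."""
    lines = ["Per-location summary (mean +/- SD):"]
    summary = report["summary"]
    for loc in summary.index:
        thc_m = summary.loc[loc, ("THC", "mean")]
        thc_s = summary.loc[loc, ("THC", "sd")]
        sto2_m = summary.loc[loc, ("StO2", "mean")]
        sto2_s = summary.loc[loc, ("StO2", "sd")]
        bfi_m = summary.loc[loc, ("BFI", "mean")] * 1e9
        bfi_s = summary.loc[loc, ("BFI", "sd")] * 1e9
        lines.append(
            f"  {loc:14s} THC {thc_m:6.1f} +/- {thc_s:4.1f} uM   "
            f"StO2 {sto2_m:4.1f} +/- {sto2_s:3.1f} %   "
            f"BFI ({bfi_m:4.1f} +/- {bfi_s:4.1f})e-9 cm^2/s"
        )
    lines.append("")
    lines.append("Organ and covariate contrasts (LME, random subject intercept):")
    for (response, effect), est in report["effects"].items():
        status = "significant" if est.significant else "n.s."
        lines.append(f"  {response} ~ {effect}: p = {est.p_value:.2g} ({status})")
    if "nodule_effect" in report:
        lines.append("")
        lines.append("Nodule-index contrast (thyroid records):")
        for response, est in report["nodule_effect"].items():
            lines.append(
                f"  {response}: levels {est.level_estimates}, p = {est.p_value:.2g}"
            )
    lines.append("")
    lines.append("Percent contrasts vs ipsilateral muscle:")
    for (var, a, b), val in report["percent_contrasts"].items():
        lines.append(f"  {var} {a} vs {b}: {val:+d}%")
    return "\n".join(lines)
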