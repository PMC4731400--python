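"""Population-level statistics for the hemodynamic cohort.

The unit of analysis is one probe placement (subject x organ x side x
location) with its fitted hemodynamics (THC, StO2, BFI) and optical
properties, joined to subject metadata.  Repeated-measures structure is
handled with linear mixed-effects models: a random intercept per
subject, one fixed effect under investigation at a time, and a
likelihood-ratio test against the intercept-only null model at the 0.05
level.  Significant findings are stress-tested by leave-one-subject-out
refits and an optional subject-level bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: protocol measurement locations, in probe-scan order
LOCATIONS = (
    "muscle_right",
    "gland1_right",
    "gland2_right",
    "gland2_left",
    "gland1_left",
    "muscle_left",
)

#: variables summarized in the population tables
SUMMARY_VARIABLES = (
    "mu_a_690", "mu_a_785", "mu_a_830",
    "mu_s_690", "mu_s_785", "mu_s_830",
    "THC", "StO2", "BFI",
)

ALPHA = 0.05


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    is_normal: bool | None  # None when degenerate
    qq_correlation: float
    degenerate: bool = False


def normality_check(values, alpha: float = ALPHA) -> NormalityResult:
    """Shapiro-Wilk test with a quantile-quantile cross-check.

    Returns the W statistic, its p-value, a normality flag at ``alpha``
    and the correlation coefficient of the normal Q-Q plot.  Constant
    input is degenerate: the flag is None.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("need at least 3 finite values")
    if np.ptp(x) == 0:
        return NormalityResult(np.nan, np.nan, None, np.nan, degenerate=True)
    w, p = sps.shapiro(x)
    (_, _), (_, _, r) = sps.probplot(x, dist="norm")
    return NormalityResult(float(w), float(p), bool(p >= alpha), float(r))


@dataclass(frozen=True)
class EffectEstimate:
    """One mixed-model contrast: response ~ fixed_effect + (1 | subject)."""

    response: str
    fixed_effect: str
    level_estimates: dict
    p_value: float
    significant: bool
    singular: bool = False
    n_subjects: int = 0
    n_records: int = 0


def _design(df: pd.DataFrame, fixed_effect: str):
    """(exog with intercept, level names) for one fixed effect."""
    col = df[fixed_effect]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"fixed effect {fixed_effect!r} has < 2 levels")
        dummies = np.column_stack(
            [(col.astype(str) == lv).astype(float) for lv in levels[1:]]
        )
        exog = np.column_stack([np.ones(len(df)), dummies])
        return exog, levels
    exog = np.column_stack([np.ones(len(df)), col.to_numpy(dtype=float)])
    return exog, None


def lme_contrast(
    records: pd.DataFrame, response: str, fixed_effect: str,
    subject_col: str = "subject_id", alpha: float = ALPHA,
) -> EffectEstimate:
    """Random-intercept LME contrast with a likelihood-ratio p-value.

    Fits ``response ~ fixed_effect`` with a per-subject random intercept
    (ML) and compares it to the intercept-only null model by a
    chi-square likelihood-ratio test.  Categorical effects return the
    fitted mean of each level; continuous effects return the slope.
    Designs that cannot support the random effect (a single subject, or
    a failed/singular fit) are flagged ``singular`` and fall back to
    reporting raw level means with p = NaN.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = records.dropna(subset=[response, fixed_effect, subject_col])
    n_subjects = df[subject_col].nunique()
    exog, levels = _design(df, fixed_effect)
    endog = df[response].to_numpy(dtype=float)
    groups = df[subject_col].to_numpy()

    def _fallback():
        if levels is not None:
            est = {lv: float(df.loc[df[fixed_effect].astype(str) == lv, response].mean())
                   for lv in levels}
        else:
            est = {"slope": float(np.polyfit(exog[:, 1], endog, 1)[0])}
        return EffectEstimate(response, fixed_effect, est, float("nan"), False,
                              singular=True, n_subjects=n_subjects, n_records=len(df))

    if n_subjects < 2:
        return _fallback()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = MixedLM(endog, exog, groups).fit(reml=False)
            null = MixedLM(endog, exog[:, :1], groups).fit(reml=False)
    except Exception:
        return _fallback()
    if not (np.isfinite(full.llf) and np.isfinite(null.llf)):
        return _fallback()

    lr = max(2.0 * (full.llf - null.llf), 0.0)
    df_diff = exog.shape[1] - 1
    p = float(sps.chi2.sf(lr, df_diff))

    coefs = np.asarray(full.fe_params)
    if levels is not None:
        est = {levels[0]: float(coefs[0])}
        est.update({lv: float(coefs[0] + coefs[i]) for i, lv in enumerate(levels[1:], 1)})
    else:
        est = {"intercept": float(coefs[0]), "slope": float(coefs[1])}
    return EffectEstimate(
        response, fixed_effect, est, p, bool(p < alpha),
        n_subjects=n_subjects, n_records=len(df),
    )


@dataclass(frozen=True)
class InfluenceReport:
    """Leave-one-subject-out (and optional bootstrap) robustness check."""

    baseline_p: float
    leave_one_out: pd.DataFrame  # excluded_subject, p_value, flips_significance
    bootstrap_significant_fraction: float | None = None
    skipped: tuple = ()


def influence_analysis(
    records: pd.DataFrame, response: str, fixed_effect: str,
    subject_col: str = "subject_id", n_boot: int = 0, seed: int = 0,
    alpha: float = ALPHA,
) -> InfluenceReport:
    """Check which subjects a significant contrast hinges on.

    Refits the contrast with each subject excluded in turn and flags
    exclusions that move the p-value across ``alpha``.  With ``n_boot``
    > 0, additionally resamples subjects with replacement and reports
    the fraction of bootstrap cohorts in which the contrast stays
    significant.
    """
    baseline = lme_contrast(records, response, fixed_effect, subject_col, alpha)
    subjects = sorted(records[subject_col].unique())
    rows, skipped = [], []
    for sid in subjects:
        sub = records[records[subject_col] != sid]
        if sub[subject_col].nunique() < 2 or sub[fixed_effect].nunique() < 2:
            skipped.append(sid)
            continue
        est = lme_contrast(sub, response, fixed_effect, subject_col, alpha)
        rows.append({
            "excluded_subject": sid,
            "p_value": est.p_value,
            "flips_significance": bool(est.significant != baseline.significant),
        })
    loo = pd.DataFrame(rows, columns=["excluded_subject", "p_value", "flips_significance"])

    boot_frac = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_boot):
            chosen = rng.choice(subjects, size=len(subjects), replace=True)
            parts = []
            for new_id, sid in enumerate(chosen):
                part = records[records[subject_col] == sid].copy()
                part[subject_col] = f"boot_{new_id}"
                parts.append(part)
            est = lme_contrast(pd.concat(parts), response, fixed_effect, subject_col, alpha)
            hits += bool(est.significant)
        boot_frac = hits / n_boot
    return InfluenceReport(baseline.p_value, loo, boot_frac, tuple(skipped))


def summarize_population(records: pd.DataFrame) -> pd.DataFrame:
    """Per-location mean +/- SD table for the optical and hemodynamic variables.

    Rows follow the protocol location order; columns are a (variable,
    statistic) MultiIndex with statistics ``mean``, ``sd`` and ``n``.
    Cells with a single record report SD as NaN.
    """
    cols = [v for v in SUMMARY_VARIABLES if v in records.columns]
    grouped = records.groupby("location")[cols]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    n = grouped.count()
    out = pd.concat({"mean": mean, "sd": sd, "n": n}, axis=1)
    out = out.swaplevel(axis=1).sort_index(axis=1)
    order = [loc for loc in LOCATIONS if loc in out.index]
    extra = [loc for loc in out.index if loc not in LOCATIONS]
    return out.loc[order + extra]


def percent_contrast(
    summary: pd.DataFrame, location_a: str, location_b: str, variable: str,
) -> int:
    """Percent increase of ``variable`` at location_a over location_b.

    100 * (mean_a / mean_b - 1), rounded to the nearest integer percent
    (the convention of the reported contrasts).
    """
    mean_a = summary.loc[location_a, (variable, "mean")]
    mean_b = summary.loc[location_b, (variable, "mean")]
    if mean_b == 0 or not np.isfinite(mean_b):
        raise ValueError("zero or undefined denominator mean")
    return int(round(100.0 * (mean_a / mean_b - 1.0)))


def demographic_ttests(subjects: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Two-tailed Welch t-tests between genders for demographic variables."""
    if variables is None:
        variables = [c for c in subjects.columns
                     if c not in ("subject_id", "gender")
                     and np.issubdtype(subjects[c].dtype, np.number)]
    f = subjects[subjects["gender"] == "F"]
    m = subjects[subjects["gender"] == "M"]
    rows = []
    for var in variables:
        t, p = sps.ttest_ind(f[var].dropna(), m[var].dropna(), equal_var=False)
        rows.append({"variable": var, "t": float(t), "p_value": float(p),
                     "significant": bool(p < ALPHA)})
    return pd.DataFrame(rows)
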