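"""Epidemiological layer: stress quartiles, odds ratios, geometric-mean
ratios, and sub-cohort representativeness tests.

The perceived-stress questionnaire (PSQ) total score is the mean of the 20
item scores (each 1-4).  Scores below the first quartile define the low-
stress group, above the third quartile the high-stress group, everything
else (including exact ties with a cutpoint) medium.  Persistent wheeze is
the binary endpoint; raw odds ratios come from 2x2 tables with Wald
intervals, adjusted ones from maximum-likelihood logistic regression, and
multiplicative effects on positive outcomes (methylation, expression,
biomarkers) from OLS on the log scale, reported as ratios of geometric
means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ValidationError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ORResult:
    comparison: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    model_covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class MeanRatioResult:
    comparison: str
    mean_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model_covariates: tuple[str, ...] = ()


# ----------------------------------------------------------- categorizing ----

def categorize_stress(scores, convention: str = "linear"):
    """Assign low/medium/high stress categories by score quartiles.

    Q1/Q3 use linear interpolation between order statistics by default
    (``convention="nearest"`` switches to the nearest-rank rule).  Strictly
    below Q1 is low, strictly above Q3 is high; ties with a cutpoint land in
    medium.  Returns (categories array, (Q1, Q3)).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValidationError("need at least 4 scores to form quartiles")
    method = {"linear": "linear", "nearest": "closest_observation"}[convention]
    q1, q3 = np.quantile(scores, [0.25, 0.75], method=method)
    if np.all(scores == scores[0]):
        warnings.warn("all stress scores identical; every subject is 'medium'")
    cats = np.where(scores < q1, "low", np.where(scores > q3, "high", "medium"))
    return cats.astype(object), (float(q1), float(q3))


# ------------------------------------------------------------ odds ratios ----

def odds_ratio_from_counts(a: float, b: float, c: float, d: float,
                           comparison: str = "exposed vs reference",
                           continuity: bool = False) -> ORResult:
    """2x2 odds ratio with Wald 95% CI.

    a/b: cases/non-cases among exposed; c/d: cases/non-cases in the
    reference group.  ``continuity=True`` adds 0.5 to every cell (use when a
    cell is zero).
    """
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        raise ValidationError(
            "zero cell in the 2x2 table; pass continuity=True for the "
            "0.5-corrected estimate")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = math.log(or_) / se
    return ORResult(
        comparison=comparison,
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - Z_95 * se),
        ci_high=math.exp(math.log(or_) + Z_95 * se),
        p_value=2 * stats.norm.sf(abs(z)),
        adjusted=False,
    )


def contingency_or(table: pd.DataFrame, outcome: str, exposure: str,
                   exposure_level: str, reference: str,
                   continuity: bool = False) -> ORResult:
    """Raw odds ratio for one exposure level against a reference level."""
    exp_rows = table[exposure] == exposure_level
    ref_rows = table[exposure] == reference
    y = table[outcome].astype(int)
    a = int((exp_rows & (y == 1)).sum())
    b = int((exp_rows & (y == 0)).sum())
    c = int((ref_rows & (y == 1)).sum())
    d = int((ref_rows & (y == 0)).sum())
    return odds_ratio_from_counts(
        a, b, c, d, comparison=f"{exposure_level} vs {reference}",
        continuity=continuity)


def _design_matrix(table: pd.DataFrame, exposure: str, reference: str,
                   covariates: list[str]):
    """Intercept + exposure dummies (reference dropped) + covariates
    (object/categorical covariates dummy-coded, first level dropped)."""
    levels = [l for l in pd.unique(table[exposure]) if l != reference]
    levels.sort()
    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    for lvl in levels:
        X[f"{exposure}[{lvl}]"] = (table[exposure] == lvl).astype(float)
    for cov in covariates:
        col = table[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = col.astype(float)
    return X, levels


def logistic_adjusted_or(table: pd.DataFrame, outcome: str, exposure: str,
                         covariates: list[str] | None = None,
                         reference: str = "low") -> list[ORResult]:
    """Adjusted odds ratios from a maximum-likelihood logistic fit.

    One ORResult per non-reference exposure level; Wald CIs from the
    observed information.  With an empty covariate list this reproduces the
    2x2 table odds ratios exactly (saturated model).
    """
    covariates = list(covariates or [])
    X, levels = _design_matrix(table, exposure, reference, covariates)
    y = table[outcome].astype(float).to_numpy()
    try:
        fit = sm.Logit(y, X.to_numpy()).fit(disp=0, tol=1e-10, maxiter=200)
    except Exception as exc:
        raise ValidationError(
            f"logistic fit failed (separation or non-convergence) for "
            f"exposure={exposure!r}, covariates={covariates}: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValidationError(
            f"logistic fit did not converge for exposure={exposure!r}")
    names = list(X.columns)
    out = []
    for lvl in levels:
        j = names.index(f"{exposure}[{lvl}]")
        b, se = fit.params[j], fit.bse[j]
        out.append(ORResult(
            comparison=f"{lvl} vs {reference}",
            odds_ratio=math.exp(b),
            ci_low=math.exp(b - Z_95 * se),
            ci_high=math.exp(b + Z_95 * se),
            p_value=float(fit.pvalues[j]),
            adjusted=bool(covariates),
            model_covariates=tuple(covariates),
        ))
    return out


# ------------------------------------------------------------ mean ratios ----

def adjusted_mean_ratio(table: pd.DataFrame, outcome: str, exposure: str,
                        covariates: list[str] | None = None,
                        level: str = "high", reference: str = "low") -> MeanRatioResult:
    """Ratio of geometric means for one exposure contrast, optionally
    adjusted: OLS on ln(outcome), MR = exp(level coefficient)."""
    covariates = list(covariates or [])
    vals = table[outcome].to_numpy(dtype=float)
    bad = np.nonzero(~(vals > 0))[0]
    if bad.size:
        ids = table.iloc[bad].get("subject_id", pd.Series(bad)).tolist()[:10]
        raise ValidationError(
            f"outcome {outcome!r} must be strictly positive before the log "
            f"transform; offending subjects: {ids}")
    X, levels = _design_matrix(table, exposure, reference, covariates)
    fit = sm.OLS(np.log(vals), X.to_numpy()).fit()
    names = list(X.columns)
    if f"{exposure}[{level}]" not in names:
        raise ValidationError(f"exposure level {level!r} absent from the table")
    j = names.index(f"{exposure}[{level}]")
    b, se = fit.params[j], fit.bse[j]
    return MeanRatioResult(
        comparison=f"{level} vs {reference}",
        mean_ratio=math.exp(b),
        ci_low=math.exp(b - Z_95 * se),
        ci_high=math.exp(b + Z_95 * se),
        p_value=float(fit.pvalues[j]),
        model_covariates=tuple(covariates),
    )


# ------------------------------------------------------ representativeness ----

def representativeness_chisq(sub: pd.DataFrame, full: pd.DataFrame,
                             field: str) -> tuple[float, float]:
    """Pearson chi-square comparing a categorical field's distribution in a
    sub-cohort against the full cohort.  Returns (statistic, p)."""
    cats = sorted(set(sub[field].dropna()) | set(full[field].dropna()))
    if len(cats) < 2:
        raise ValidationError(f"field {field!r} has fewer than 2 categories")
    obs = np.array([
        [int((sub[field] == c).sum()) for c in cats],
        [int((full[field] == c).sum()) for c in cats],
    ])
    expected = stats.contingency.expected_freq(obs)
    if (expected < 1).any():
        warnings.warn(f"expected cell count < 1 for field {field!r}; "
                      "chi-square approximation is unreliable")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)
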