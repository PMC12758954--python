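"""Fixed-effects analysis of the group-level simulation table.

Two ordinary-least-squares models are fitted to the per-group responses
(mean PSI or CV of PSI), excluding the degenerate completely synchronous
family:

* a one-way model, ``response ~ family``, testing whether the
  parturition-date distribution affects the response; and
* a nested model, ``response ~ family + duration(family) + size(family)``,
  testing season-duration and group-size effects within each family.

Both designs are balanced (every family carries the same duration x size
grid), so the OLS F statistics coincide with those of a maximum-likelihood
fixed-effects fit, sequential and marginal sums of squares agree, and the
least-squares means equal the arithmetic means of each factor level.
Confidence intervals use the central t quantile with the residual degrees
of freedom and the pooled residual mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "EffectTestResult",
    "LSMeanEstimate",
    "fit_distribution_model",
    "fit_nested_model",
    "residual_summary",
]


@dataclass(frozen=True)
class EffectTestResult:
    """F-test of one fixed effect."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class LSMeanEstimate:
    """Least-squares mean of one factor level with its 95% CI.

    On a balanced design the LS-mean equals the arithmetic mean of the
    response over the level's groups.
    """

    factor: str
    level: tuple
    estimate: float
    ci_low: float
    ci_high: float
    n: int


_RESPONSES = ("mean_psi", "cv_psi_percent")


def _f_and_p(an: pd.DataFrame, term: str, fit) -> tuple[float, float]:
    """F and p for one anova table row.

    A response that is constant (or exactly explained, leaving only float
    dust in a sum of squares) would otherwise yield a ratio of rounding
    errors; such terms are reported as F = 0, p = 1 when the term's share
    of variance is negligible relative to the response scale, and as an
    infinite F when the residual is the negligible part.
    """
    y = np.asarray(fit.model.endog)
    scale = float(np.mean(y**2)) + np.finfo(float).tiny
    eps = 1e-20 * y.size * scale
    ss_term = float(an.loc[term, "sum_sq"])
    ss_resid = float(an.loc["Residual", "sum_sq"])
    if ss_term <= eps:
        return 0.0, 1.0
    if ss_resid <= eps:
        return float("inf"), 0.0
    return float(an.loc[term, "F"]), float(an.loc[term, "PR(>F)"])


def _prepare(table: pd.DataFrame, response: str) -> pd.DataFrame:
    if response not in table.columns:
        raise ValueError(
            f"response {response!r} not in table; expected one of {_RESPONSES}"
        )
    df = table[table["family"] != "synchronous"].copy()
    if df["family"].nunique() < 2:
        raise ValueError("need at least two distribution families")
    return df


def _ls_means(
    df: pd.DataFrame,
    by: list[str],
    response: str,
    mse: float,
    df_den: int,
    alpha: float = 0.05,
) -> list[LSMeanEstimate]:
    tcrit = st.t.ppf(1 - alpha / 2, df_den) if df_den > 0 else np.nan
    out = []
    for level, sub in df.groupby(by, sort=True):
        est = float(sub[response].mean())
        half = tcrit * np.sqrt(mse / len(sub))
        out.append(
            LSMeanEstimate(
                factor="*".join(by),
                level=level if isinstance(level, tuple) else (level,),
                estimate=est,
                ci_low=est - half,
                ci_high=est + half,
                n=len(sub),
            )
        )
    return out


def fit_distribution_model(
    table: pd.DataFrame, response: str = "mean_psi"
) -> tuple[EffectTestResult, list[LSMeanEstimate]]:
    """One-way fixed-effects model: does the date distribution affect the
    response?

    Returns the family F-test (df = L-1, N-L) and per-family LS-means with
    95% CIs based on the residual mean square.
    """
    df = _prepare(table, response)
    counts = df.groupby("family").size()
    if (counts < 2).any():
        raise ValueError("every family needs at least two groups")
    fit = smf.ols(f"{response} ~ C(family)", data=df).fit()
    an = sm.stats.anova_lm(fit, typ=1)
    df_den = int(fit.df_resid)
    mse = float(fit.mse_resid)
    F, p = _f_and_p(an, "C(family)", fit)
    test = EffectTestResult(
        effect="family",
        F=F,
        df_num=int(an.loc["C(family)", "df"]),
        df_den=df_den,
        p=p,
    )
    return test, _ls_means(df, ["family"], response, mse, df_den)


def _check_balanced(df: pd.DataFrame) -> None:
    cell_counts = df.groupby(["family", "duration", "size"]).size()
    if cell_counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every family x duration x size cell must "
            "hold the same number of groups"
        )
    grids = df.groupby("family").apply(
        lambda g: frozenset(zip(g["duration"], g["size"])),
        include_groups=False,
    )
    if grids.nunique() != 1:
        raise ValueError(
            "unbalanced design: families carry different duration x size grids"
        )


def fit_nested_model(
    table: pd.DataFrame, response: str = "mean_psi"
) -> tuple[dict[str, EffectTestResult], dict[str, list[LSMeanEstimate]]]:
    """Nested fixed-effects model with duration and size nested in family.

    Fits ``response ~ family + family:duration + family:size`` and returns
    F-tests for the two nested effects against the residual mean square,
    plus nested LS-means per family x duration and family x size.  For the
    default study design (4 families, 5 durations, 8 sizes, one group per
    cell) the nested tests carry df (16, 112) and (28, 112).
    """
    df = _prepare(table, response)
    _check_balanced(df)
    fit = smf.ols(
        f"{response} ~ C(family) + C(family):C(duration) + C(family):C(size)",
        data=df,
    ).fit()
    an = sm.stats.anova_lm(fit, typ=1)
    df_den = int(fit.df_resid)
    mse = float(fit.mse_resid)
    tests = {}
    for term, name in [
        ("C(family):C(duration)", "duration(family)"),
        ("C(family):C(size)", "size(family)"),
    ]:
        F, p = _f_and_p(an, term, fit)
        tests[name] = EffectTestResult(
            effect=name,
            F=F,
            df_num=int(an.loc[term, "df"]),
            df_den=df_den,
            p=p,
        )
    lsmeans = {
        "duration(family)": _ls_means(
            df, ["family", "duration"], response, mse, df_den
        ),
        "size(family)": _ls_means(
            df, ["family", "size"], response, mse, df_den
        ),
    }
    return tests, lsmeans


def residual_summary(fit) -> dict:
    """Programmatic residual diagnostics: skewness, excess kurtosis, and a
    per-family residual-variance table.  Advisory only."""
    resid = np.asarray(fit.resid)
    data = fit.model.data.frame
    var = float(resid.var(ddof=1)) if resid.size > 1 else 0.0
    # exact fits leave only float dust in the residuals; report shape
    # statistics as 0 rather than amplifying cancellation noise
    degenerate = var <= 1e-24
    out = {
        "skewness": 0.0 if degenerate else float(st.skew(resid)),
        "kurtosis_excess": 0.0 if degenerate else float(st.kurtosis(resid)),
        "resid_var": var,
    }
    if "family" in data.columns:
        var_by = (
            pd.Series(resid, index=data.index)
            .groupby(data["family"])
            .var(ddof=1)
        )
        out["resid_var_by_family"] = var_by.to_dict()
    return out
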