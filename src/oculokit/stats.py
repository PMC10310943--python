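"""Group statistics: demographics tests, normality-gated correlations with
disease severity, MANCOVA with ANCOVA post-hocs, and Benjamini–Hochberg FDR
control applied per parameter family (fixation / pro-saccade /
anti-saccade), matching how clinical eye-tracking tables are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests

from .types import (
    ANTISACCADE_PARAMETERS,
    FIXATION_PARAMETERS,
    PROSACCADE_PARAMETERS,
)

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "MancovaTermResult",
    "welch_t",
    "chi2_2x2",
    "bh_adjust",
    "correlate_with_severity",
    "mancova",
    "ancova_posthoc",
    "analyze_table",
]

PARAMETER_FAMILIES = {
    "fixation": list(FIXATION_PARAMETERS),
    "prosaccade": list(PROSACCADE_PARAMETERS),
    "antisaccade": list(ANTISACCADE_PARAMETERS),
}


@dataclass
class CorrelationResult:
    parameter: str
    method: str  # pearson | spearman
    coefficient: float
    p_raw: float
    p_adjusted: float = float("nan")
    n: int = 0


@dataclass
class GroupComparisonResult:
    parameter: str
    f_statistic: float
    df: tuple[int, int]
    p_raw: float
    p_adjusted: float = float("nan")
    adjusted_mean_pd: float = float("nan")
    adjusted_mean_hc: float = float("nan")
    percent_difference: float = float("nan")


@dataclass
class MancovaTermResult:
    term: str
    pillai: float
    f_statistic: float
    df: tuple[float, float]
    p: float


def welch_t(mean1, sd1, n1, mean2, sd2, n2):
    """Two-sample Welch t test from summary statistics.

    Returns (t, Welch–Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_t needs n >= 2 per group")
    if sd1 <= 0 and sd2 <= 0:
        raise ValueError("welch_t undefined with zero variance in both groups")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    se2 = sd1**2 / n1 + sd2**2 / n2
    df = se2**2 / (
        (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def chi2_2x2(table):
    """Pearson chi-square on a 2x2 contingency table (no continuity
    correction). Returns (chi2, df=1, p)."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("chi2_2x2 needs a non-negative 2x2 table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("chi2_2x2 undefined with a zero marginal")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_with_severity(
    values, severity, alpha_normality: float = 0.05
) -> CorrelationResult:
    """Correlation of one parameter with severity, Shapiro–Wilk gated.

    Pearson's r when both variables pass Shapiro–Wilk at
    ``alpha_normality``; Spearman's rho (average ranks for ties) otherwise.
    Incomplete pairs are dropped.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(severity, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    normal = (
        sps.shapiro(x).pvalue > alpha_normality
        and sps.shapiro(y).pvalue > alpha_normality
    )
    if normal:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult("", method, float(r), float(p), n=int(x.size))


def _design_frame(
    table: pd.DataFrame, response_cols: list[str]
) -> pd.DataFrame:
    """Complete-case frame with numeric group/sex codings."""
    df = table.copy()
    df["group_pd"] = (df["group"] == "PD").astype(float)
    df["sex_m"] = (df["sex"] == "M").astype(float)
    cols = response_cols + ["group_pd", "age", "sex_m"]
    df = df[cols].dropna()
    return df


def mancova(
    table: pd.DataFrame, response_cols: list[str]
) -> list[MancovaTermResult]:
    """Multivariate ANCOVA of the responses on group with age and sex
    covariates (design: intercept + group + age + sex).

    Reports Pillai's trace with its standard F approximation for each
    model term, on complete cases only.
    """
    df = _design_frame(table, response_cols)
    n = len(df)
    if n <= 4 + len(response_cols):
        raise ValueError("too few complete cases for the MANCOVA design")
    for col in ("group_pd", "age", "sex_m"):
        if df[col].nunique() < 2:
            raise ValueError(f"design column '{col}' is constant (rank-deficient design)")
    endog = df[response_cols].to_numpy()
    exog = sm.add_constant(df[["group_pd", "age", "sex_m"]].to_numpy())
    if len(response_cols) == 1:
        # one response: each 1-df term test reduces to the univariate F;
        # Pillai's trace is then F / (F + df_den)
        fit = sm.OLS(endog[:, 0], exog).fit()
        out = []
        for term, idx in (("group", 1), ("age", 2), ("sex", 3)):
            f_stat = float(fit.tvalues[idx] ** 2)
            df_den = float(fit.df_resid)
            out.append(
                MancovaTermResult(
                    term=term,
                    pillai=f_stat / (f_stat + df_den),
                    f_statistic=f_stat,
                    df=(1.0, df_den),
                    p=float(sps.f.sf(f_stat, 1.0, df_den)),
                )
            )
        return out
    mv = MANOVA(endog, exog)
    res = mv.mv_test(
        hypotheses=[
            ("group", np.array([[0.0, 1.0, 0.0, 0.0]])),
            ("age", np.array([[0.0, 0.0, 1.0, 0.0]])),
            ("sex", np.array([[0.0, 0.0, 0.0, 1.0]])),
        ]
    )
    out = []
    for term in ("group", "age", "sex"):
        stat = res.results[term]["stat"]
        row = stat.loc["Pillai's trace"]
        out.append(
            MancovaTermResult(
                term=term,
                pillai=float(row["Value"]),
                f_statistic=float(row["F Value"]),
                df=(float(row["Num DF"]), float(row["Den DF"])),
                p=float(row["Pr > F"]),
            )
        )
    return out


def ancova_posthoc(table: pd.DataFrame, response_col: str) -> GroupComparisonResult:
    """Univariate ANCOVA post-hoc for one parameter.

    F test for the group term with age and sex as covariates (type III;
    identical to type II here since the model has no interactions), plus
    covariate-adjusted group means evaluated at the covariate averages and
    the percent difference (PD − HC)/HC × 100.
    """
    df = _design_frame(table, [response_col])
    if len(df) < 6:
        raise ValueError("too few complete cases for ANCOVA")
    y = df[response_col].to_numpy()
    X = sm.add_constant(df[["group_pd", "age", "sex_m"]].to_numpy())
    fit = sm.OLS(y, X).fit()
    # partial F for the group coefficient == squared t in this 1-df case
    t_group = fit.tvalues[1]
    f_stat = float(t_group**2)
    df_num, df_den = 1, int(fit.df_resid)
    p = float(sps.f.sf(f_stat, df_num, df_den))
    age_bar, sex_bar = df["age"].mean(), df["sex_m"].mean()
    b = fit.params
    mean_hc = float(b[0] + b[2] * age_bar + b[3] * sex_bar)
    mean_pd = float(mean_hc + b[1])
    pct = (mean_pd - mean_hc) / mean_hc * 100.0 if mean_hc != 0 else float("nan")
    return GroupComparisonResult(
        parameter=response_col,
        f_statistic=f_stat,
        df=(df_num, df_den),
        p_raw=p,
        adjusted_mean_pd=mean_pd,
        adjusted_mean_hc=mean_hc,
        percent_difference=pct,
    )


def analyze_table(
    table: pd.DataFrame, alpha_normality: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full statistical layer over a subject parameter table.

    Returns (correlations, group_comparisons, mancova_terms) DataFrames.
    Correlations with the severity score use PD subjects (the group with
    scores); BH adjustment is applied within each parameter family, as is
    conventional for per-table reporting.
    """
    corr_rows, comp_rows, manc_rows = [], [], []
    pd_rows = table[table["group"] == "PD"]
    for family, names in PARAMETER_FAMILIES.items():
        usable = [
            n for n in names if table[n].notna().sum() >= 6 and table[n].nunique() > 2
        ]
        fam_corr = []
        for name in usable:
            sub = pd_rows[[name, "updrs3"]].dropna()
            try:
                res = correlate_with_severity(
                    sub[name], sub["updrs3"], alpha_normality
                )
                res.parameter = name
            except ValueError:
                continue
            fam_corr.append(res)
        if fam_corr:
            adj = bh_adjust([r.p_raw for r in fam_corr])
            for r, a in zip(fam_corr, adj):
                r.p_adjusted = float(a)
                corr_rows.append(
                    dict(
                        family=family,
                        parameter=r.parameter,
                        method=r.method,
                        coefficient=r.coefficient,
                        p_raw=r.p_raw,
                        p_adjusted=r.p_adjusted,
                        n=r.n,
                    )
                )
        fam_comp = []
        for name in usable:
            try:
                fam_comp.append(ancova_posthoc(table, name))
            except ValueError:
                continue
        if fam_comp:
            adj = bh_adjust([r.p_raw for r in fam_comp])
            for r, a in zip(fam_comp, adj):
                r.p_adjusted = float(a)
                comp_rows.append(
                    dict(
                        family=family,
                        parameter=r.parameter,
                        f_statistic=r.f_statistic,
                        df_num=r.df[0],
                        df_den=r.df[1],
                        p_raw=r.p_raw,
                        p_adjusted=r.p_adjusted,
                        adjusted_mean_pd=r.adjusted_mean_pd,
                        adjusted_mean_hc=r.adjusted_mean_hc,
                        percent_difference=r.percent_difference,
                    )
                )
        if usable:
            try:
                for term in mancova(table, usable):
                    manc_rows.append(
                        dict(
                            family=family,
                            term=term.term,
                            pillai=term.pillai,
                            f_statistic=term.f_statistic,
                            df_num=term.df[0],
                            df_den=term.df[1],
                            p=term.p,
                        )
                    )
            except ValueError:
                pass
    return pd.DataFrame(corr_rows), pd.DataFrame(comp_rows), pd.DataFrame(manc_rows)
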