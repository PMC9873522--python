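"""Scalar statistics for demographics, coupling and clinical correlations.

Conventions match mainstream clinical-statistics software: the one-sample
normality check is the Kolmogorov-Smirnov statistic against a normal with
estimated parameters, with Lilliefors-corrected p; the 2x2 chi-square is the
Pearson statistic WITHOUT continuity correction; t-tests are pooled-variance,
two-sided; the Mann-Whitney test is exact for small untied samples and uses
the tie/continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ks_normality",
    "two_sample_t",
    "two_sample_t_summary",
    "mann_whitney",
    "chi_square_2x2",
    "clinical_correlation",
    "demographics_table",
]


def ks_normality(sample, alpha: float = 0.05) -> dict:
    """KS test against a normal with mean/SD estimated from the sample.

    p is Lilliefors-corrected (parameters estimated from data);
    pass = p > alpha.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("normality test needs n >= 4")
    if x.std(ddof=1) == 0:
        raise ValueError("normality test undefined for zero-variance sample")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return {"statistic": float(stat), "p": float(p), "pass": bool(p > alpha)}


def two_sample_t(sample_a, sample_b) -> dict:
    """Unpaired pooled-variance two-sided t-test; df = n_a + n_b - 2."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": int(df), "p": float(p)}


def two_sample_t_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> dict:
    """Pooled-variance t-test from group summaries (mean, SD, n)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0 or (sd_a == 0 and sd_b == 0):
        raise ValueError("invalid summary SDs")
    res = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return {"t": float(res.statistic), "df": int(n_a + n_b - 2), "p": float(res.pvalue)}


def mann_whitney(sample_a, sample_b) -> dict:
    """Two-sided Mann-Whitney U.

    Exact enumeration when n_a + n_b <= 16 and no ties; otherwise the normal
    approximation with tie and continuity corrections.  U is reported for the
    first sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 16 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def chi_square_2x2(table) -> dict:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def clinical_correlation(cluster_means, clinical_scores) -> dict:
    """Pearson correlation between cluster means and a clinical variable."""
    x = np.asarray(cluster_means, dtype=float)
    y = np.asarray(clinical_scores, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must be paired")
    if x.size < 4:
        raise ValueError("correlation needs n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}


def demographics_table(participants: pd.DataFrame, group_col: str = "group",
                       patient_label: str = "patient", alpha: float = 0.05) -> pd.DataFrame:
    """Group-comparison table for sex (chi-square) and continuous covariates.

    Continuous variables take the t-test when both groups pass the normality
    check, Mann-Whitney otherwise — the same gate used for the coupling
    comparison.
    """
    pat = participants[participants[group_col] == patient_label]
    ctl = participants[participants[group_col] != patient_label]
    rows = []
    if "sex" in participants:
        tab = [
            [(pat["sex"] == 0).sum(), (pat["sex"] == 1).sum()],
            [(ctl["sex"] == 0).sum(), (ctl["sex"] == 1).sum()],
        ]
        res = chi_square_2x2(tab)
        rows.append({
            "variable": "sex", "test": "chi2", "statistic": res["chi2"],
            "p": res["p"],
            "patient": f"{tab[0][0]}/{tab[0][1]}", "control": f"{tab[1][0]}/{tab[1][1]}",
        })
    for col in ("age", "education"):
        if col not in participants:
            continue
        a, b = pat[col].to_numpy(float), ctl[col].to_numpy(float)
        normal = (
            a.size >= 4 and b.size >= 4
            and ks_normality(a, alpha)["pass"] and ks_normality(b, alpha)["pass"]
        )
        if normal:
            res = two_sample_t(a, b)
            test, stat = "t", res["t"]
        else:
            res = mann_whitney(a, b)
            test, stat = "mann-whitney", res["U"]
        rows.append({
            "variable": col, "test": test, "statistic": stat, "p": res["p"],
            "patient": f"{a.mean():.2f} +/- {a.std(ddof=1):.2f}",
            "control": f"{b.mean():.2f} +/- {b.std(ddof=1):.2f}",
        })
    return pd.DataFrame(rows)
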