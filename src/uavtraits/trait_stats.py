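"""Descriptive and group statistics for stage-wise trait samples.

The coefficient of variation is computed conditionally on normality: the
Shapiro-Wilk test gates the denominator.  When the test does not reject
normality (p > 0.05) the CV uses the mean, CV = 100 * SD / mean; when it
rejects (p <= 0.05) the distribution's center is better represented by the
median and CV = 100 * SD / median.  Skewness is the adjusted Fisher-Pearson
sample skewness and kurtosis is excess kurtosis, both bias-corrected, so a
normal sample reports values near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def conditional_cv(sd: float, mean: float, median: float, sw_p: float) -> float:
    """CV (%) under the Shapiro-Wilk-gated rule: mean basis iff p > 0.05."""
    denom = mean if sw_p > 0.05 else median
    if denom == 0:
        return float("nan")
    return 100.0 * sd / denom


@dataclass
class StageSummary:
    """One trait x stage row of the descriptive-statistics table."""

    trait: str
    stage: str
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    q1: float
    q2: float
    q3: float
    skewness: float
    kurtosis: float
    sw_p: float
    cv: float
    cv_basis: str  # "mean" | "median"


def describe_trait_stage(
    values, trait: str = "", stage: str = ""
) -> StageSummary:
    """Descriptive statistics of one trait sample at one growth stage."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 finite observations")
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if sd == 0:
        sw_p, skew, kurt = 1.0, 0.0, 0.0
    else:
        sw_p = float(stats.shapiro(x).pvalue)
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    basis = "mean" if sw_p > 0.05 else "median"
    cv = 0.0 if sd == 0 else conditional_cv(sd, mean, float(q2), sw_p)
    return StageSummary(
        trait=trait, stage=stage, n=n, mean=mean, sd=sd,
        minimum=float(x.min()), maximum=float(x.max()),
        q1=float(q1), q2=float(q2), q3=float(q3),
        skewness=skew, kurtosis=kurt, sw_p=sw_p, cv=float(cv), cv_basis=basis,
    )


def summary_table(table: pd.DataFrame, traits=("ph", "ndvi", "cc")) -> pd.DataFrame:
    """Stage x trait descriptive summary of a long-form trait table."""
    rows = []
    for stage, grp in table.groupby("stage"):
        for trait in traits:
            vals = grp[trait].dropna()
            if len(vals) >= 3:
                rows.append(vars(describe_trait_stage(vals, trait=trait, stage=stage)))
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame, stage: str, traits=("ph", "ndvi", "cc")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-tailed p between traits at one stage."""
    sub = table.loc[table["stage"] == stage, list(traits)].dropna()
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 complete records at stage {stage}")
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(sub.iloc[:, i], sub.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(traits)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def group_f_statistics(
    table: pd.DataFrame, trait: str, group_col: str = "group"
) -> tuple[pd.DataFrame, str]:
    """One-way F across genetic-background groups per stage, plus the
    stage order sorted ascending by F (where group differences are weakest
    first), formatted like "S4-S3-S1-S2"."""
    rows = []
    for stage, grp in table.groupby("stage"):
        sub = grp[[group_col, trait]].dropna()
        samples = [g[trait].to_numpy() for _, g in sub.groupby(group_col) if len(g) >= 2]
        if len(samples) < 2:
            continue
        f, p = stats.f_oneway(*samples)
        rows.append({"stage": stage, "F": float(f), "p": float(p)})
    if not rows:
        raise ValueError(f"no stage has >= 2 groups with >= 2 members for {trait}")
    df = pd.DataFrame(rows).sort_values("stage").reset_index(drop=True)
    order = "-".join(df.sort_values("F")["stage"])
    return df, order


def sort_stages_by_f(f_by_stage: dict) -> str:
    """Ascending-F stage label, e.g. {'S1': 8.5, ...} -> 'S4-S3-S1-S2'."""
    return "-".join(sorted(f_by_stage, key=f_by_stage.get))
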