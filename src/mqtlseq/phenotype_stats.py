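"""Trait summaries and genetic-inheritance statistics for RIL phenotype tables.

Broad-sense heritability is computed on an entry-mean basis from the expected
mean squares of a balanced genotype x environment ANOVA with replication:

    sigma2_e  = MS_error
    sigma2_ge = (MS_GxE - MS_error) / R
    sigma2_g  = (MS_G - MS_GxE) / (E * R)
    H2        = sigma2_g / (sigma2_g + sigma2_ge / E + sigma2_e / (E * R))

Negative variance-component estimates are truncated at zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TraitSummary:
    mean: float
    sd: float
    min: float
    max: float
    cv_percent: float
    n: int


@dataclass
class HeritabilityResult:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    h2_percent: float
    n_env: int
    n_rep: int
    truncated: bool = False


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV% = 100 * sd / mean, rounded to one decimal."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return round(100.0 * sd / mean, 1)


def summarize_trait(
    phenotypes: pd.DataFrame, group: str | None = None
) -> TraitSummary | dict[str, TraitSummary]:
    """Mean, sample SD, range and CV% of dtf, optionally per group column."""
    if group is not None:
        return {
            key: summarize_trait(sub)
            for key, sub in phenotypes.groupby(group, sort=True)
        }
    x = phenotypes["dtf"].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return TraitSummary(
        mean=mean,
        sd=sd,
        min=float(np.min(x)),
        max=float(np.max(x)),
        cv_percent=coefficient_of_variation(mean, sd),
        n=int(x.size),
    )


def _check_balanced(df: pd.DataFrame) -> tuple[int, int, int]:
    counts = df.groupby(["individual", "environment"])["dtf"].count()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design (unequal cell counts); analyse environments "
            "separately or balance replicates"
        )
    n_g = df["individual"].nunique()
    n_env = df["environment"].nunique()
    n_rep = int(counts.iloc[0])
    if len(df) != n_g * n_env * n_rep:
        raise ValueError("missing genotype x environment cells")
    return n_g, n_env, n_rep


def gxe_anova(phenotypes: pd.DataFrame, include_parents: bool = False) -> pd.DataFrame:
    """Two-factor fixed-effects ANOVA (genotype, environment, interaction).

    Requires a balanced replicated table; returns the statsmodels ANOVA table
    with rows G, E, GxE and Residual (sum_sq, df, F, PR(>F)).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = phenotypes
    if not include_parents and "population" in df.columns:
        df = df[df["population"] != "parent"]
    _check_balanced(df)
    model = ols("dtf ~ C(individual) * C(environment)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        index={
            "C(individual)": "G",
            "C(environment)": "E",
            "C(individual):C(environment)": "GxE",
        }
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]
    return table


def broad_sense_heritability(
    phenotypes: pd.DataFrame, include_parents: bool = False
) -> HeritabilityResult:
    """Entry-mean broad-sense heritability from the G x E ANOVA mean squares.

    With a single environment the GxE term is absent and
    H2 = sigma2_g / (sigma2_g + sigma2_e / R).
    """
    df = phenotypes
    if not include_parents and "population" in df.columns:
        df = df[df["population"] != "parent"]
    n_g, n_env, n_rep = _check_balanced(df)
    if n_g < 2 or (n_env < 2 and n_rep < 2):
        raise ValueError("need >=2 genotypes and >=2 environments or replicates")

    if n_env == 1:
        grand = df["dtf"].mean()
        means = df.groupby("individual")["dtf"].agg(["mean", "count"])
        ss_g = float((means["count"] * (means["mean"] - grand) ** 2).sum())
        ms_g = ss_g / (n_g - 1)
        resid = df["dtf"] - df.groupby("individual")["dtf"].transform("mean")
        ms_e = float((resid**2).sum() / (n_g * (n_rep - 1)))
        sigma2_e = ms_e
        sigma2_g = (ms_g - ms_e) / n_rep
        sigma2_ge = 0.0
    else:
        table = gxe_anova(df, include_parents=True)
        ms_g = table.loc["G", "mean_sq"]
        ms_ge = table.loc["GxE", "mean_sq"]
        ms_e = table.loc["Residual", "mean_sq"]
        sigma2_e = float(ms_e)
        sigma2_ge = float((ms_ge - ms_e) / n_rep)
        sigma2_g = float((ms_g - ms_ge) / (n_env * n_rep))

    truncated = sigma2_g < 0 or sigma2_ge < 0 or sigma2_e < 0
    sigma2_g = max(sigma2_g, 0.0)
    sigma2_ge = max(sigma2_ge, 0.0)
    sigma2_e = max(sigma2_e, 0.0)
    denom = sigma2_g + sigma2_ge / n_env + sigma2_e / (n_env * n_rep)
    h2 = 100.0 * sigma2_g / denom if denom > 0 else 0.0
    return HeritabilityResult(
        sigma2_g, sigma2_ge, sigma2_e, h2, n_env, n_rep, truncated
    )


def transgressive_segregation(
    phenotypes: pd.DataFrame,
    parent_early: str = "parent_early",
    parent_late: str = "parent_late",
    k_sd: float = 2.0,
) -> tuple[int, int, bool]:
    """Counts of RIL entry means beyond each parental mean +/- k_sd * SD.

    Returns (n_below_early_bound, n_above_late_bound, bidirectional_flag).
    """
    df = phenotypes
    means = df.groupby("individual")["dtf"].mean()
    sds = df.groupby("individual")["dtf"].std(ddof=1).fillna(0.0)
    for p in (parent_early, parent_late):
        if p not in means.index:
            raise ValueError(f"parent {p!r} absent from phenotype table")
    lo = means[parent_early] - k_sd * sds[parent_early]
    hi = means[parent_late] + k_sd * sds[parent_late]
    ril = means.drop(index=[parent_early, parent_late])
    below = int((ril < lo).sum())
    above = int((ril > hi).sum())
    return below, above, below > 0 and above > 0
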