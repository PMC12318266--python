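"""Genotype–phenotype association statistics.

Works on two kinds of input: aggregate genotype-by-outcome count tables (one
row per T-allele dosage 0/1/2 with columns ``n`` and ``cases``, the shape of
a published cohort characteristics table) and individual-level cohort tables
with dosage, phenotypes and covariates. Provides per-genotype prevalences
with a chi-squared test, the crude allele-counting odds ratio with a Woolf
confidence interval, per-allele logistic/linear regression (grouped logistic
on aggregate tables; covariate-adjusted on individual data), a one-way ANOVA
reconstructed from per-group summary statistics, and a Bonferroni-thresholded
multi-biomarker scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssocResult",
    "genotype_prevalence",
    "allelic_or",
    "per_allele_regression",
    "phewas_scan",
    "anova_from_summary",
]


def _check_count_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"dosage", "n", "cases"}
    if not required <= set(table.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    t = table.sort_values("dosage").reset_index(drop=True)
    if sorted(t["dosage"]) != [0, 1, 2]:
        raise ValueError("dosages must be exactly {0, 1, 2}")
    if (t["cases"] > t["n"]).any() or (t["cases"] < 0).any():
        raise ValueError("cases must lie in [0, n] per genotype")
    return t


def genotype_prevalence(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-genotype case percentage (one decimal) and 2x3 chi-squared p."""
    t = _check_count_table(table)
    if (t["n"] <= 0).any():
        raise ValueError("every genotype needs n > 0")
    out = t.copy()
    out["percent"] = np.round(100.0 * out["cases"] / out["n"], 1)
    contingency = np.vstack([t["cases"], t["n"] - t["cases"]])
    p = float(stats.chi2_contingency(contingency, correction=False).pvalue)
    return out, p


def allelic_or(table: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Crude per-T-allele odds ratio from an aggregate table.

    Genotype counts are collapsed to allele counts (dosage-weighted); the
    odds ratio is (case T x control C) / (case C x control T) with a Woolf
    95% CI; zero cells get the Haldane–Anscombe +0.5 correction.
    """
    t = _check_count_table(table)
    cases, controls = t["cases"].to_numpy(float), (t["n"] - t["cases"]).to_numpy(float)
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("degenerate table: no cases or no controls")
    d = t["dosage"].to_numpy(float)
    cell = np.array([
        float((d * cases).sum()),          # case T alleles
        float(((2 - d) * cases).sum()),    # case C alleles
        float((d * controls).sum()),       # control T alleles
        float(((2 - d) * controls).sum()),  # control C alleles
    ])
    if np.any(cell == 0):
        cell = cell + 0.5
    case_t, case_c, ctrl_t, ctrl_c = cell
    or_ = (case_t * ctrl_c) / (case_c * ctrl_t)
    se = float(np.sqrt((1 / cell).sum()))
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return float(or_), (float(lo), float(hi))


@dataclass
class AssocResult:
    """Per-allele association estimate for one phenotype."""

    phenotype: str
    effect: float                # log-odds (binary) or slope (continuous)
    se: float
    p: float
    conf_int: tuple[float, float]
    kind: str                    # 'logistic' | 'linear' | 'grouped-logistic'
    n: int
    significant: bool | None = None

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.effect)) if "logistic" in self.kind else None


def per_allele_regression(data: pd.DataFrame, phenotype: str = "case",
                          covariates: tuple[str, ...] = ()) -> AssocResult:
    """Per-T-allele effect on a phenotype.

    Individual-level tables get a maximum-likelihood logistic fit (binary
    phenotype) or least-squares linear fit (continuous), optionally adjusted
    for covariates. A table with ``n``/``cases`` columns is treated as an
    aggregate genotype count table and fitted by grouped logistic regression
    on dosage alone (covariates are unavailable for aggregates).
    """
    if {"n", "cases"} <= set(data.columns):
        t = _check_count_table(data)
        if covariates:
            raise ValueError("covariate adjustment needs individual-level data")
        endog = np.column_stack([t["cases"], t["n"] - t["cases"]])
        exog = sm.add_constant(t["dosage"].to_numpy(float))
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        kind, n = "grouped-logistic", int(t["n"].sum())
    else:
        if "dosage" not in data.columns:
            raise ValueError("individual-level table needs a 'dosage' column")
        cols = ["dosage", *covariates]
        exog = sm.add_constant(data[cols].to_numpy(float))
        y = data[phenotype].to_numpy(float)
        binary = set(np.unique(y)) <= {0.0, 1.0}
        if binary:
            try:
                fit = sm.Logit(y, exog).fit(disp=False)
            except Exception as err:  # includes perfect separation
                raise ValueError(
                    f"logistic fit failed for {phenotype!r} (possible "
                    f"separation): {err}") from err
            kind = "logistic"
        else:
            fit = sm.OLS(y, exog).fit()
            kind = "linear"
        n = len(data)
    ci = fit.conf_int()
    ci = np.asarray(ci)
    return AssocResult(phenotype=phenotype, effect=float(fit.params[1]),
                       se=float(fit.bse[1]), p=float(fit.pvalues[1]),
                       conf_int=(float(ci[1, 0]), float(ci[1, 1])),
                       kind=kind, n=n)


def phewas_scan(cohort: pd.DataFrame, biomarkers: list[str],
                covariates: tuple[str, ...] = (), alpha: float = 0.05
                ) -> tuple[pd.DataFrame, float]:
    """Per-allele regression for each biomarker with a Bonferroni threshold.

    Returns (results ranked by p, threshold = alpha / m); ``significant``
    flags p strictly below the threshold.
    """
    m = len(biomarkers)
    if m == 0:
        raise ValueError("no biomarkers to scan")
    threshold = alpha / m
    rows = []
    for b in biomarkers:
        res = per_allele_regression(cohort, phenotype=b, covariates=covariates)
        rows.append({"phenotype": b, "beta": res.effect, "se": res.se,
                     "p": res.p, "kind": res.kind})
    df = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    df["significant"] = df["p"] < threshold
    return df, threshold


def anova_from_summary(ns, means, sds) -> tuple[float, float]:
    """One-way ANOVA F and p reconstructed from per-group n, mean and SD.

    Exact for the usual sample-SD convention (ddof = 1), so a continuous
    cohort-characteristics row (e.g. HbA1c by genotype) can be tested from
    its printed summaries.
    """
    ns = np.asarray(ns, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if len(ns) < 2:
        raise ValueError("need at least two groups")
    grand = np.sum(ns * means) / ns.sum()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    df_b, df_w = len(ns) - 1, int(ns.sum()) - len(ns)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(stats.f.sf(F, df_b, df_w))
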