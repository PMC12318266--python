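"""Genotype differential expression, the HEP2/HEP1 ratio slope, and the
metabolite volcano filter.

Within a hepatocyte cluster, genes expressed (nonzero) in more than 10% of
cells of both genotypes are tested by an equal-variance two-sample t-test on
normalized expression, with Benjamini–Hochberg FDR control; a gene passes at
FDR < 0.05. The ratio-slope statistic regresses each gene's knockout
HEP2/HEP1 log-ratio on its control log-ratio — a slope below 1 means the
transcriptional distinction between the two hepatocyte populations is
attenuated in the knockout. Metabolites are called significantly altered when
-log10(p) > 1.3 and |log2 fold change| > 1 (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import _dense

__all__ = [
    "bh_adjust",
    "de_within_cluster",
    "SlopeResult",
    "ratio_slope",
    "volcano_filter",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_within_cluster(norm: ad.AnnData, clusters, cluster_id,
                      genotype_key: str = "genotype", min_frac: float = 0.10,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Differential expression between genotypes within one cluster.

    Genes whose expressed fraction (nonzero normalized expression, i.e.
    nonzero count) exceeds ``min_frac`` in BOTH genotypes are tested by an
    equal-variance two-sample t-test; BH adjustment runs over the tested
    genes; ``passed`` requires FDR < ``alpha``.
    """
    clusters = np.asarray(clusters)
    in_cluster = clusters == cluster_id
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster_id!r} is empty")
    geno = norm.obs[genotype_key].astype(str).values[in_cluster]
    levels = sorted(set(geno))
    if len(levels) != 2:
        raise ValueError(f"cluster {cluster_id!r} must contain exactly two "
                         f"genotypes, found {levels}")
    g0, g1 = levels
    X = _dense(norm.X)[in_cluster]
    A, B = X[geno == g0], X[geno == g1]
    frac0 = (A > 0).mean(axis=0)
    frac1 = (B > 0).mean(axis=0)
    res = pd.DataFrame({
        "cluster": cluster_id,
        f"mean_{g0}": A.mean(axis=0), f"mean_{g1}": B.mean(axis=0),
        f"frac_{g0}": frac0, f"frac_{g1}": frac1,
    }, index=norm.var_names)
    tested = (frac0 > min_frac) & (frac1 > min_frac)
    t = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    if tested.any():
        tt = stats.ttest_ind(A[:, tested], B[:, tested], axis=0, equal_var=True)
        tstat, pval = np.asarray(tt.statistic), np.asarray(tt.pvalue)
        # identical samples give 0/0 -> no evidence of a difference
        same = ~np.isfinite(tstat)
        tstat[same], pval[same] = 0.0, 1.0
        t[tested], p[tested] = tstat, pval
    res["t"], res["p"] = t, p
    fdr = np.full(X.shape[1], np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p[tested])
    res["fdr"] = fdr
    res["tested"] = tested
    res["passed"] = tested & (fdr < alpha)
    return res


@dataclass
class SlopeResult:
    slope: float
    intercept: float
    conf_int: tuple[float, float]
    n_genes: int


def ratio_slope(norm: ad.AnnData, clusters, hep1_id, hep2_id,
                genes: list[str] | None = None, genotype_key: str = "genotype",
                con_label: str = "CON", ko_label: str = "KO",
                eps: float = 1e-9) -> SlopeResult:
    """OLS slope of the knockout HEP2/HEP1 log-ratio on the control one.

    Per gene and genotype, ratio = log2((mean in HEP2 + eps)/(mean in HEP1 +
    eps)) over that genotype's cells; the knockout ratios are regressed on the
    control ratios with an intercept.
    """
    clusters = np.asarray(clusters)
    X = _dense(norm.X)
    geno = norm.obs[genotype_key].astype(str).values
    if genes is None:
        gene_idx = np.arange(norm.n_vars)
    else:
        gene_idx = np.asarray([norm.var_names.get_loc(g) for g in genes])
    if len(gene_idx) < 3:
        raise ValueError("need at least 3 genes for the ratio slope")

    def log_ratio(label: str) -> np.ndarray:
        m1 = X[(clusters == hep1_id) & (geno == label)][:, gene_idx].mean(axis=0)
        m2 = X[(clusters == hep2_id) & (geno == label)][:, gene_idx].mean(axis=0)
        return np.log2((m2 + eps) / (m1 + eps))

    r_con, r_ko = log_ratio(con_label), log_ratio(ko_label)
    fit = sm.OLS(r_ko, sm.add_constant(r_con)).fit()
    ci = fit.conf_int(alpha=0.05)
    return SlopeResult(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                       conf_int=(float(ci[1, 0]), float(ci[1, 1])),
                       n_genes=len(gene_idx))


def volcano_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Significance filter for metabolite tables (name, category, p, log2fc).

    Keeps rows with -log10(p) > 1.3 AND |log2fc| > 1.0 (both strict) and
    returns the significant subset plus per-category proportions (summing to
    1 over the significant subset).
    """
    required = {"name", "category", "p", "log2fc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metabolite table missing columns: {sorted(missing)}")
    if table["category"].isna().any() or (table["category"].astype(str) == "").any():
        raise ValueError("every metabolite needs a non-empty category")
    p = table["p"].astype(float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    keep = (-np.log10(p) > 1.3) & (table["log2fc"].abs() > 1.0)
    sig = table[keep].copy()
    if len(sig):
        proportions = sig["category"].value_counts(normalize=True)
    else:
        proportions = pd.Series(dtype=float)
    return sig, proportions
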