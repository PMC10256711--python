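"""Replication of reference eQTLs in village data.

Reference (SNP, gene) pairs are first filtered to those testable in the
pool: the SNP must have at least two distinct dosages across the pooled
lines, and the gene must show a significant line contribution to its
expression variance.  Effects are then estimated per condition (uni-culture
vs village) by ordinary least squares of per-(line, site) mean expression
on effect-allele dosage, and compared to the reference by sign concordance
(1-df chi-squared goodness of fit against 50:50) and by Spearman
correlation of effect sizes between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, spearmanr


@dataclass
class EqtlResult:
    snp: str
    gene: str
    condition: str
    beta: float
    se: float
    p: float
    concordant: bool | None = None  # vs reference sign; beta == 0 is discordant


def filter_testable(reference: pd.DataFrame, genotypes: pd.DataFrame,
                    significant_genes: set[str]) -> pd.DataFrame:
    """Keep (snp, gene) pairs with polymorphic dosage and a significant
    line-variance gene.  Reference SNPs absent from the genotype table are
    dropped (logged in the returned frame's attrs)."""
    if genotypes.empty:
        raise ValueError("empty genotype table")
    keep, dropped_missing = [], []
    for _, row in reference.iterrows():
        snp, gene = row["snp"], row["gene"]
        if snp not in genotypes.columns:
            dropped_missing.append(snp)
            continue
        dosages = genotypes[snp].to_numpy()
        if len(np.unique(dosages)) < 2:
            continue
        if gene not in significant_genes:
            continue
        keep.append(row)
    out = pd.DataFrame(keep, columns=reference.columns).reset_index(drop=True)
    out.attrs["dropped_missing_snps"] = dropped_missing
    return out


def fit_eqtl(sample_means: pd.DataFrame, genotypes: pd.DataFrame,
             snp: str, gene: str, condition: str,
             covariates: list[str] | None = None,
             reference_beta: float | None = None) -> EqtlResult:
    """OLS of per-(line, site) mean expression on effect-allele dosage.

    ``sample_means`` must carry columns line, expression (for ``gene``),
    plus any covariates; one row per (line, site) sample in the given
    condition.
    """
    if len(sample_means) < 3:
        raise ValueError("need >=3 (line, site) observations")
    dosage = genotypes.loc[sample_means["line"], snp].to_numpy(float)
    if len(np.unique(dosage)) < 2:
        raise ValueError(f"SNP {snp} is monomorphic in these samples")
    cols = [np.ones(len(sample_means)), dosage]
    names = ["intercept", "dosage"]
    for cov in covariates or []:
        col = sample_means[cov]
        if col.dtype == object:
            for lvl, dummy in pd.get_dummies(col, drop_first=True).items():
                cols.append(dummy.to_numpy(float))
                names.append(f"{cov}[{lvl}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design (columns: {names})")
    y = sample_means["expression"].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[1])
    concordant = None
    if reference_beta is not None:
        concordant = bool(np.sign(beta) == np.sign(reference_beta) and beta != 0)
    return EqtlResult(snp=snp, gene=gene, condition=condition, beta=beta,
                      se=float(fit.bse[1]), p=float(fit.pvalues[1]),
                      concordant=concordant)


def concordance_test(results: list[EqtlResult],
                     reference: pd.DataFrame | None = None) -> dict:
    """Sign-concordance chi-squared test against a 50:50 null.

    chi2 = (c - n/2)^2/(n/2) + (d - n/2)^2/(n/2) on 1 df, where c/d are the
    concordant/discordant counts.  An effect of exactly zero counts as
    discordant.
    """
    if not results:
        raise ValueError("no eQTL results to test")
    if reference is not None:
        ref_sign = {(r["snp"], r["gene"]): np.sign(r["beta"])
                    for _, r in reference.iterrows()}
        for r in results:
            s = ref_sign.get((r.snp, r.gene))
            if s is not None:
                r.concordant = bool(np.sign(r.beta) == s and r.beta != 0)
    flags = [r.concordant for r in results if r.concordant is not None]
    if not flags:
        raise ValueError("no results with a reference sign")
    n = len(flags)
    c = sum(flags)
    d = n - c
    expected = n / 2.0
    stat = (c - expected) ** 2 / expected + (d - expected) ** 2 / expected
    return {
        "n": n,
        "concordant": c,
        "discordant": d,
        "concordance_pct": 100.0 * c / n,
        "chi2": float(stat),
        "p": float(chi2.sf(stat, 1)),
    }


def uni_village_correlation(beta_uni: np.ndarray,
                            beta_village: np.ndarray) -> tuple[float, float]:
    """Two-sided Spearman correlation between paired condition effect sizes."""
    beta_uni = np.asarray(beta_uni, float)
    beta_village = np.asarray(beta_village, float)
    if beta_uni.shape != beta_village.shape or beta_uni.size < 3:
        raise ValueError("need >=3 paired effect sizes")
    res = spearmanr(beta_uni, beta_village)
    return float(res.statistic), float(res.pvalue)
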