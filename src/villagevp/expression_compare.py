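"""Transcriptome-profile correlations and uni- vs village differential expression.

Profiles are per-sample mean expression vectors over genes; all unordered
sample pairs are compared with a two-sided Spearman rank correlation and
labelled by which covariates the two samples share, so the distribution of
correlations can be contrasted between, e.g., replicate pairs and
different-line pairs.

Differential expression between uni-culture and village cells uses a
likelihood-ratio test between logistic regressions of condition on
expression (plus covariates) versus covariates alone, after filtering genes
expressed (count > 0) in fewer than 10% of cells, with Bonferroni
correction over the tests actually performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr


def profile_correlations(norm_expr: np.ndarray, metadata: pd.DataFrame,
                         sample_definition: list[str]
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Spearman correlations of per-sample mean expression profiles.

    ``norm_expr`` is genes x cells aligned to ``metadata`` rows.  A sample is
    one combination of the ``sample_definition`` covariates.  Returns the
    pair table (with ``shares_<cov>`` flags and rho; constant profiles give
    missing rho) and the median rho per shared covariate.
    """
    norm_expr = np.atleast_2d(np.asarray(norm_expr, float))
    if norm_expr.shape[0] < 3:
        raise ValueError("need >=3 genes")
    keys = metadata[sample_definition].astype(str).agg("|".join, axis=1)
    samples = sorted(keys.unique())
    if len(samples) < 2:
        raise ValueError("need >=2 samples")
    profiles = {}
    attrs = {}
    for s in samples:
        mask = (keys == s).to_numpy()
        profiles[s] = norm_expr[:, mask].mean(axis=1)
        attrs[s] = metadata.loc[mask, sample_definition].iloc[0]
    rows = []
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            if np.std(profiles[a]) == 0 or np.std(profiles[b]) == 0:
                rho = np.nan
            else:
                rho = spearmanr(profiles[a], profiles[b]).statistic
            row = {"sample_a": a, "sample_b": b, "rho": rho}
            for cov in sample_definition:
                row[f"shares_{cov}"] = bool(attrs[a][cov] == attrs[b][cov])
            rows.append(row)
    pairs = pd.DataFrame(rows)
    medians = pd.Series({
        cov: pairs.loc[pairs[f"shares_{cov}"], "rho"].median()
        for cov in sample_definition})
    return pairs, medians


@dataclass
class DEResult:
    gene: str
    p: float
    p_bonferroni: float
    tested: bool
    flag: str = ""


def logistic_de(norm_expr: np.ndarray, group: np.ndarray,
                covariates: pd.DataFrame | None = None,
                genes: list[str] | None = None,
                min_expr_frac: float = 0.10) -> list[DEResult]:
    """Uni- vs village differential expression via logistic-regression LRT.

    ``group`` is a binary condition vector (0/1 or two labels).  Genes
    expressed (value > 0) in fewer than ``min_expr_frac`` of cells are
    skipped.  Bonferroni multiplies by the number of tests performed.
    Perfect separation falls back to a ridge-penalized fit, flagged.
    """
    norm_expr = np.atleast_2d(np.asarray(norm_expr, float))
    n_genes, n = norm_expr.shape
    if genes is None:
        genes = [f"gene{j}" for j in range(n_genes)]
    g = pd.Series(group)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError("group must be binary")
    y = (g == levels[1]).to_numpy(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("each group needs >=2 cells")
    base_cols = [np.ones(n)]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or str(col.dtype) == "category":
                dummies = pd.get_dummies(col, drop_first=True)
                base_cols.extend(dummies[c2].to_numpy(float) for c2 in dummies)
            else:
                base_cols.append(col.to_numpy(float))
    X0 = np.column_stack(base_cols)
    ll0 = _logit_loglik(y, X0)

    results = []
    tested = []
    for j in range(n_genes):
        x = norm_expr[j]
        if (x > 0).mean() < min_expr_frac:
            results.append(DEResult(gene=genes[j], p=np.nan, p_bonferroni=np.nan,
                                    tested=False, flag="below_expression_filter"))
            continue
        X1 = np.column_stack([X0, x])
        flag = ""
        try:
            ll1 = _logit_loglik(y, X1)
        except (np.linalg.LinAlgError, ValueError):
            ll1, flag = _logit_loglik(y, X1, ridge=1e-4), "penalized_fit"
        if not np.isfinite(ll1) or ll1 < ll0 - 1e-6:
            ll1, flag = _logit_loglik(y, X1, ridge=1e-4), "penalized_fit"
        from scipy.stats import chi2
        stat = max(0.0, 2.0 * (ll1 - ll0))
        p = float(chi2.sf(stat, 1))
        results.append(DEResult(gene=genes[j], p=p, p_bonferroni=np.nan,
                                tested=True, flag=flag))
        tested.append(results[-1])
    m = len(tested)
    for r in tested:
        r.p_bonferroni = min(1.0, m * r.p)
    return results


def _logit_loglik(y: np.ndarray, X: np.ndarray, ridge: float = 0.0) -> float:
    if ridge > 0:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        fit = model.fit_regularized(alpha=ridge, L1_wt=0.0)
        eta = X @ fit.params
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    with np.errstate(all="ignore"):
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    return float(fit.llf)
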