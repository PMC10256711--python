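"""Per-gene variance decomposition and significance testing.

Each gene's normalized expression is fit with a linear mixed model in which
categorical covariates (line, village status, site, replicate,
cryopreservation, and their pairwise interactions) enter as random
intercepts and continuous covariates (pseudotime) enter as fixed effects.
The intra-class correlation attributes variance to each covariate:

    ICC_var = 100 * sigma2_var / sum_i sigma2_i

with the sum running over every component including the residual.  For a
continuous covariate the attributed component is the empirical variance of
its fitted contribution across cells.

Covariate significance is a likelihood-ratio test between maximum-likelihood
refits of the model with and without the covariate; variance components
tested at their boundary use the 50:50 chi2_0:chi2_1 mixture reference.
Line x pseudotime ("dynamic") effects are random per-line slopes tested
against a common-slope model, gated on both line and pseudotime being
significant contributors, with Benjamini-Hochberg FDR across gated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMFit, RandomTerm, VarianceComponentModel, lrt_pvalue

#: covariate sets matching the three experimental designs
MODEL_SPECS = {
    "fresh": {"random": ["line", "village", "site", "replicate"], "continuous": []},
    "cryopreserved": {"random": ["line", "village", "cryopreservation", "replicate"],
                      "continuous": []},
    "eighteen_line": {"random": ["line", "passage"], "continuous": []},
    "dynamic": {"random": ["line"], "continuous": ["pseudotime"]},
}


@dataclass
class VarianceComponents:
    gene: str
    components: dict[str, float]  # covariate -> sigma^2, includes "residual"
    fitted: bool
    beta: np.ndarray | None = None


@dataclass
class CovariateTest:
    gene: str
    covariate: str
    lrt: float
    p: float
    q: float | None = None


@dataclass
class DynamicEffect:
    gene: str
    interaction_var: float
    lrt: float
    p: float
    q: float | None = None
    slopes: dict[str, float] = field(default_factory=dict)  # per-line total slope


def _build_terms(design: pd.DataFrame, random_terms: list[str]) -> list[RandomTerm]:
    terms = []
    for name in random_terms:
        if ":" in name:
            a, b = name.split(":", 1)
            labels = design[a].astype(str) + "|" + design[b].astype(str)
        else:
            labels = design[name]
        if pd.Series(labels).nunique() < 2:
            raise ValueError(f"covariate {name!r} is constant across cells")
        terms.append(RandomTerm.from_labels(name, labels))
    return terms


def _build_X(design: pd.DataFrame, continuous_terms: list[str],
             n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for name in continuous_terms:
        x = design[name].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"continuous covariate {name!r} is constant")
        cols.append(x)
    return np.column_stack(cols)


def build_model(design: pd.DataFrame, random_terms: list[str],
                continuous_terms: list[str] = ()) -> VarianceComponentModel:
    """Assemble the reusable design for per-gene fits."""
    n = len(design)
    X = _build_X(design, list(continuous_terms), n)
    terms = _build_terms(design, list(random_terms))
    model = VarianceComponentModel(X, terms)
    model.continuous_terms = list(continuous_terms)  # type: ignore[attr-defined]
    return model


def fit_gene_lmm(y: np.ndarray, design: pd.DataFrame,
                 random_terms: list[str],
                 continuous_terms: list[str] = (),
                 gene: str = "", model: VarianceComponentModel | None = None
                 ) -> VarianceComponents:
    """REML variance components for one gene.

    Continuous terms contribute var(x_j * beta_j) across cells; the residual
    component is always present.  Non-convergence is flagged with components
    set to NaN.
    """
    y = np.asarray(y, float)
    if np.isnan(y).any():
        raise ValueError("y contains NaN")
    if model is None:
        model = build_model(design, random_terms, continuous_terms)
    fit = model.fit(y, reml=True)
    if not fit.converged:
        comps = {t.name: np.nan for t in model.terms}
        comps.update({name: np.nan for name in continuous_terms})
        comps["residual"] = np.nan
        return VarianceComponents(gene=gene, components=comps, fitted=False)
    comps = dict(fit.variance_components)
    for j, name in enumerate(getattr(model, "continuous_terms", continuous_terms)):
        contrib = model.X[:, 1 + j] * fit.beta[1 + j]
        comps[name] = float(np.var(contrib))
    comps["residual"] = fit.residual_variance
    return VarianceComponents(gene=gene, components=comps, fitted=True,
                              beta=fit.beta)


def icc(components: VarianceComponents | dict[str, float]) -> dict[str, float]:
    """Intra-class correlation (percent) for every component incl. residual."""
    comps = components.components if isinstance(components, VarianceComponents) else components
    if "residual" not in comps:
        raise ValueError("components must include 'residual'")
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("all variance components are zero")
    return {k: 100.0 * v / total for k, v in comps.items()}


def test_covariate(y: np.ndarray, design: pd.DataFrame,
                   full_terms: list[str], dropped_term: str,
                   continuous_terms: list[str] = (),
                   boundary: bool | None = None,
                   gene: str = "",
                   models: tuple | None = None) -> CovariateTest:
    """LRT (ML refits) for one covariate's contribution to one gene.

    ``dropped_term`` may be a random term (boundary-corrected mixture
    reference by default) or a continuous term (plain chi-squared, 1 df).
    """
    continuous_terms = list(continuous_terms)
    is_random = dropped_term in full_terms
    if not is_random and dropped_term not in continuous_terms:
        raise ValueError(f"{dropped_term!r} not in model terms")
    if models is None:
        full = build_model(design, full_terms, continuous_terms)
        if is_random:
            reduced = build_model(design,
                                  [t for t in full_terms if t != dropped_term],
                                  continuous_terms)
        else:
            reduced = build_model(design, full_terms,
                                  [t for t in continuous_terms if t != dropped_term])
    else:
        full, reduced = models
    fit_full = full.fit(y, reml=False)
    fit_red = reduced.fit(y, reml=False)
    if not (fit_full.converged and fit_red.converged):
        return CovariateTest(gene=gene, covariate=dropped_term,
                             lrt=np.nan, p=np.nan)
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
    if boundary is None:
        boundary = is_random
    p = lrt_pvalue(stat, boundary=boundary)
    return CovariateTest(gene=gene, covariate=dropped_term, lrt=stat, p=p)


def test_interaction(y: np.ndarray, design: pd.DataFrame,
                     term_a: str, term_b: str,
                     base_terms: list[str] | None = None,
                     gene: str = "") -> CovariateTest:
    """LRT for the ``term_a:term_b`` random interaction on top of main effects."""
    base = list(base_terms) if base_terms is not None else [term_a, term_b]
    inter = f"{term_a}:{term_b}"
    return test_covariate(y, design, base + [inter], inter, gene=gene)


def bh_adjust(tests: list[CovariateTest | DynamicEffect]) -> None:
    """Benjamini-Hochberg q-values in place, over tests with finite p."""
    ps = np.array([t.p for t in tests], float)
    ok = np.isfinite(ps)
    if ok.sum() == 0:
        return
    q = np.full_like(ps, np.nan)
    q[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    for t, qi in zip(tests, q):
        t.q = float(qi) if np.isfinite(qi) else None


def dynamic_effects(expr: np.ndarray, design: pd.DataFrame,
                    line_col: str = "line", pt_col: str = "pseudotime",
                    genes: list[str] | None = None,
                    gate_fdr: float = 0.05) -> list[DynamicEffect]:
    """Line x pseudotime interaction tests for genes passing the gate.

    The gate requires both the line term (random intercept, boundary LRT)
    and the pseudotime term to be significant contributors at BH-FDR <
    ``gate_fdr`` across all genes; the pseudotime gate compares the model
    with per-line slopes against the no-pseudotime model, so genes whose
    line-specific slopes cancel in the average are still gated in.

    Gated genes are then tested for slope heterogeneity: per-line slopes
    enter as fixed effects and are compared with the common-slope model by
    a chi-squared LRT on n_lines - 1 df.  (With the two or three lines of a
    village, a random-slope variance is essentially unidentified and its
    boundary LRT is severely conservative; fixed per-line slopes keep the
    null p-value uniform.)  A second BH correction runs over the gated set,
    and per-line slope estimates are reported.
    """
    expr = np.atleast_2d(np.asarray(expr, float))
    n_genes, n = expr.shape
    if genes is None:
        genes = [f"gene{j}" for j in range(n_genes)]
    pt = design[pt_col].to_numpy(float)
    if np.ptp(pt) == 0:
        raise ValueError("pseudotime is constant")
    lines = design[line_col].astype(str)
    codes, line_levels = pd.factorize(lines)
    L = len(line_levels)
    if L < 2:
        raise ValueError("need >=2 lines")

    # shared designs: random line intercept throughout
    line_term = [RandomTerm.from_labels(line_col, lines)]
    X0 = np.ones((n, 1))
    X_common = np.column_stack([np.ones(n), pt])
    # per-line slopes: common slope + deviations for lines 2..L
    devs = np.zeros((n, L - 1))
    for k in range(1, L):
        devs[codes == k, k - 1] = pt[codes == k]
    X_slopes = np.column_stack([X_common, devs])
    m_null = VarianceComponentModel(X0, line_term)
    m_common = VarianceComponentModel(X_common, line_term)
    m_slopes = VarianceComponentModel(X_slopes, line_term)
    m_noline = VarianceComponentModel(X_common, [])

    from scipy.stats import chi2

    line_tests, pt_tests = [], []
    for j in range(n_genes):
        y = expr[j]
        f_common = m_common.fit(y, reml=False)
        f_noline = m_noline.fit(y, reml=False)
        f_slopes = m_slopes.fit(y, reml=False)
        f_null = m_null.fit(y, reml=False)
        stat_line = max(0.0, 2.0 * (f_common.loglik - f_noline.loglik))
        line_tests.append(CovariateTest(
            gene=genes[j], covariate=line_col, lrt=stat_line,
            p=lrt_pvalue(stat_line, boundary=True)))
        stat_pt = max(0.0, 2.0 * (f_slopes.loglik - f_null.loglik))
        pt_tests.append(CovariateTest(
            gene=genes[j], covariate=pt_col, lrt=stat_pt,
            p=float(chi2.sf(stat_pt, L))))
    bh_adjust(line_tests)
    bh_adjust(pt_tests)

    effects = []
    for j in range(n_genes):
        ql, qp = line_tests[j].q, pt_tests[j].q
        if ql is None or qp is None or ql >= gate_fdr or qp >= gate_fdr:
            continue
        y = expr[j]
        fit_full = m_slopes.fit(y, reml=False)
        fit_red = m_common.fit(y, reml=False)
        if not (fit_full.converged and fit_red.converged):
            effects.append(DynamicEffect(gene=genes[j], interaction_var=np.nan,
                                         lrt=np.nan, p=np.nan))
            continue
        stat = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
        p = float(chi2.sf(stat, L - 1))
        common = float(fit_full.beta[1])
        dev_coef = np.concatenate([[0.0], fit_full.beta[2:2 + L - 1]])
        slope_contrib = dev_coef[codes] * pt
        slopes = {lv: common + float(d) for lv, d in zip(line_levels, dev_coef)}
        effects.append(DynamicEffect(
            gene=genes[j], interaction_var=float(np.var(slope_contrib)),
            lrt=stat, p=p, slopes=slopes))
    bh_adjust(effects)
    return effects


def decompose_all(expr: np.ndarray, design: pd.DataFrame,
                  random_terms: list[str], continuous_terms: list[str] = (),
                  genes: list[str] | None = None,
                  compute_tests: bool = True) -> pd.DataFrame:
    """Tidy per-gene variance decomposition table.

    Returns one row per gene x component with sigma^2, ICC %, and (when
    ``compute_tests``) the covariate LRT p and BH-FDR q computed across
    genes per covariate.  Genes whose fit fails are flagged, not dropped.
    """
    expr = np.atleast_2d(np.asarray(expr, float))
    n_genes = expr.shape[0]
    if genes is None:
        genes = [f"gene{j}" for j in range(n_genes)]
    continuous_terms = list(continuous_terms)
    model = build_model(design, random_terms, continuous_terms)
    test_models = {}
    if compute_tests:
        full_ml = model
        for term in random_terms:
            test_models[term] = (
                full_ml, build_model(design,
                                     [t for t in random_terms if t != term],
                                     continuous_terms))
        for term in continuous_terms:
            test_models[term] = (
                full_ml, build_model(design, random_terms,
                                     [t for t in continuous_terms if t != term]))

    rows = []
    tests_per_term: dict[str, list[CovariateTest]] = {t: [] for t in test_models}
    for j in range(n_genes):
        y = expr[j]
        if np.var(y) == 0:
            rows.append({"gene": genes[j], "component": "residual",
                         "sigma2": np.nan, "icc_pct": np.nan, "fitted": False,
                         "note": "zero variance"})
            for term in test_models:
                tests_per_term[term].append(CovariateTest(
                    gene=genes[j], covariate=term, lrt=np.nan, p=np.nan))
            continue
        vc = fit_gene_lmm(y, design, random_terms, continuous_terms,
                          gene=genes[j], model=model)
        iccs = icc(vc) if vc.fitted else {k: np.nan for k in vc.components}
        for comp, s2 in vc.components.items():
            rows.append({"gene": genes[j], "component": comp, "sigma2": s2,
                         "icc_pct": iccs[comp], "fitted": vc.fitted, "note": ""})
        for term, models in test_models.items():
            tests_per_term[term].append(test_covariate(
                y, design, random_terms, term, continuous_terms,
                gene=genes[j], models=models))
    table = pd.DataFrame(rows)
    if compute_tests:
        for term, tests in tests_per_term.items():
            bh_adjust(tests)
            tmap_p = {t.gene: t.p for t in tests}
            tmap_q = {t.gene: t.q for t in tests}
            sel = table["component"] == term
            table.loc[sel, "p"] = table.loc[sel, "gene"].map(tmap_p)
            table.loc[sel, "q"] = table.loc[sel, "gene"].map(tmap_q)
    return table
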