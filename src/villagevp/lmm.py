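"""Variance-components linear mixed model solver.

Fits models of the form

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, s2_e I)

by REML (component estimation) or ML (likelihood-ratio tests), with each
variance bounded at zero.  The marginal covariance V = Z G Z' + s2_e I is
handled on the q x q scale via the Woodbury identity, so a likelihood
evaluation costs O(q^3) after a one-off O(n q^2) setup shared across all
response vectors on the same design — the property that makes per-gene
genome-wide fits cheap.

Random terms are arbitrary real design matrices: categorical covariates
enter as one-hot indicator blocks (random intercepts), and a random-slope
term is an indicator block scaled by a continuous covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class RandomTerm:
    name: str
    Z: np.ndarray  # n x q_k

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomTerm":
        """Random-intercept block from a categorical label vector."""
        codes, levels = pd.factorize(np.asarray(labels))
        if len(levels) < 2:
            raise ValueError(f"random term {name!r} has <2 levels")
        Z = np.zeros((len(codes), len(levels)))
        Z[np.arange(len(codes)), codes] = 1.0
        return cls(name=name, Z=Z)

    @classmethod
    def slopes(cls, name: str, labels, x) -> "RandomTerm":
        """Per-level random slopes on continuous covariate ``x``."""
        term = cls.from_labels(name, labels)
        return cls(name=name, Z=term.Z * np.asarray(x, float)[:, None])


@dataclass
class LMMFit:
    variance_components: dict[str, float]  # per random term
    residual_variance: float
    beta: np.ndarray
    loglik: float  # log-likelihood (ML) or restricted log-likelihood (REML)
    reml: bool
    converged: bool
    n: int
    ranef: dict[str, np.ndarray] = field(default_factory=dict)  # BLUPs


class VarianceComponentModel:
    """A fixed design (X, random terms) reusable across many responses."""

    def __init__(self, X: np.ndarray, terms: list[RandomTerm]):
        X = np.atleast_2d(np.asarray(X, float))
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.X = X
        self.terms = list(terms)
        self.n, self.p = X.shape
        if self.terms:
            self.Z = np.hstack([t.Z for t in self.terms])
        else:
            self.Z = np.zeros((self.n, 0))
        self.q = self.Z.shape[1]
        self._block = np.concatenate(
            [np.full(t.Z.shape[1], i) for i, t in enumerate(self.terms)]
        ) if self.terms else np.zeros(0, int)
        # shared cross-products
        self.ZtZ = self.Z.T @ self.Z
        self.ZtX = self.Z.T @ self.X
        self.XtX = self.X.T @ self.X
        if np.linalg.matrix_rank(self.XtX) < self.p:
            raise ValueError("fixed-effect design X is rank deficient")

    # -- likelihood machinery ------------------------------------------------

    def _crit(self, theta: np.ndarray, y_stats, reml: bool) -> float:
        """-2 log (restricted) likelihood at variance vector theta."""
        yty, Zty, Xty = y_stats
        n, p, q = self.n, self.p, self.q
        s2 = theta[:-1]
        se2 = theta[-1]
        if se2 <= 0:
            return np.inf
        w = np.sqrt(np.maximum(s2[self._block], 0.0)) if q else np.zeros(0)
        M = se2 * np.eye(q) + (w[:, None] * self.ZtZ) * w[None, :]
        try:
            cf = sla.cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf
        logdetM = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdetV = (n - q) * np.log(se2) + logdetM
        ty = w * Zty
        TX = w[:, None] * self.ZtX
        Mi_ty = sla.cho_solve(cf, ty, check_finite=False)
        Mi_TX = sla.cho_solve(cf, TX, check_finite=False)
        XtViX = (self.XtX - TX.T @ Mi_TX) / se2
        XtViy = (Xty - TX.T @ Mi_ty) / se2
        ytViy = (yty - ty @ Mi_ty) / se2
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf
        r = ytViy - beta @ XtViy
        if reml:
            sign, logdetXVX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return np.inf
            return (n - p) * _LOG2PI + logdetV + logdetXVX + r
        return n * _LOG2PI + logdetV + r

    def _beta_and_blups(self, theta, y, y_stats):
        yty, Zty, Xty = y_stats
        q = self.q
        s2, se2 = theta[:-1], theta[-1]
        w = np.sqrt(np.maximum(s2[self._block], 0.0)) if q else np.zeros(0)
        M = se2 * np.eye(q) + (w[:, None] * self.ZtZ) * w[None, :]
        cf = sla.cho_factor(M, lower=True, check_finite=False)
        ty = w * Zty
        TX = w[:, None] * self.ZtX
        Mi_ty = sla.cho_solve(cf, ty, check_finite=False)
        Mi_TX = sla.cho_solve(cf, TX, check_finite=False)
        XtViX = (self.XtX - TX.T @ Mi_TX) / se2
        XtViy = (Xty - TX.T @ Mi_ty) / se2
        beta = np.linalg.solve(XtViX, XtViy)
        # u_hat = G Z' V^{-1} (y - X beta); Woodbury gives
        # Z'V^{-1}e = (Z'e - ZtZ W M^{-1} W Z'e) / se2
        Zte = Zty - self.ZtX @ beta
        Mi_te = sla.cho_solve(cf, w * Zte, check_finite=False)
        ZtVie = (Zte - (self.ZtZ * w[None, :]) @ Mi_te) / se2
        u = s2[self._block] * ZtVie if q else np.zeros(0)
        ranef = {}
        start = 0
        for t in self.terms:
            k = t.Z.shape[1]
            ranef[t.name] = u[start:start + k]
            start += k
        return beta, ranef

    # -- fitting -------------------------------------------------------------

    def fit(self, y: np.ndarray, reml: bool = True) -> LMMFit:
        y = np.asarray(y, float)
        if y.shape != (self.n,):
            raise ValueError(f"y has shape {y.shape}, expected ({self.n},)")
        if not np.isfinite(y).all():
            raise ValueError("y contains NaN or infinite values")
        vy = float(np.var(y))
        if vy <= 0:
            raise ValueError("y has zero variance")
        y_stats = (float(y @ y), self.Z.T @ y, self.X.T @ y)
        K = len(self.terms)
        bounds = [(0.0, None)] * K + [(vy * 1e-9, None)]
        starts = [
            np.full(K + 1, vy / (K + 1.0)),
            np.concatenate([np.full(K, 0.05 * vy), [0.95 * vy]]),
        ]
        best = None
        for x0 in starts:
            res = minimize(
                self._crit, x0, args=(y_stats, reml), method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9,
                         "eps": max(vy, 1e-3) * 1e-7},
            )
            if best is None or res.fun < best.fun:
                best = res
        if not best.success:
            # L-BFGS-B occasionally reports line-search failure near the
            # boundary; a simplex polish from its iterate recovers it
            res = minimize(
                self._crit, np.maximum(best.x, 0.0), args=(y_stats, reml),
                method="Nelder-Mead",
                options={"maxiter": 800, "xatol": 1e-10, "fatol": 1e-12})
            if res.fun <= best.fun or res.success:
                best = res
        theta = np.maximum(best.x, 0.0)
        theta[-1] = max(theta[-1], vy * 1e-9)
        beta, ranef = self._beta_and_blups(theta, y, y_stats)
        return LMMFit(
            variance_components={t.name: float(theta[i]) for i, t in enumerate(self.terms)},
            residual_variance=float(theta[-1]),
            beta=beta,
            loglik=-0.5 * float(best.fun),
            reml=reml,
            converged=bool(best.success and np.isfinite(best.fun)),
            n=self.n,
            ranef=ranef,
        )


def lrt_pvalue(stat: float, boundary: bool = True, df: int = 1) -> float:
    """P-value for a likelihood-ratio statistic.

    For a single variance component tested at its boundary the asymptotic
    null is the 50:50 mixture chi2_0 : chi2_1, so p = 0.5 * P(chi2_1 > T)
    for T > 0 and 1 at T = 0.  With ``boundary=False`` a plain chi2_df
    reference is used (fixed-effect drops).
    """
    from scipy.stats import chi2

    stat = max(float(stat), 0.0)
    if not boundary:
        return float(chi2.sf(stat, df))
    if stat == 0.0:
        return 1.0
    return float(0.5 * chi2.sf(stat, 1))
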