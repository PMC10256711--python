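"""Line proportions, growth rates, and their correlation.

Line proportions per sample come straight from retained consensus
assignments; growth rates are log-linear least-squares fits of cell counts
(or confluency) against time in days, the minimal estimator consistent with
exponential growth; and the two are related by a two-sided Spearman rank
correlation, mirroring the observation that faster-growing lines come to
dominate a pooled culture over passages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


def line_proportions(assignments: pd.DataFrame, sample_col: str = "sample",
                     line_col: str = "line",
                     replicate_col: str | None = None) -> pd.DataFrame:
    """Per-sample line proportions from retained cells.

    When ``replicate_col`` is given, the SE column is the standard error of
    the per-replicate proportions (SD / sqrt(r)); otherwise SE is missing.
    """
    if "status" in assignments.columns:
        assignments = assignments[assignments["status"] == "retained"]
    counts = assignments.groupby([sample_col, line_col], observed=True).size()
    if counts.empty:
        raise ValueError("no retained cells")
    totals = counts.groupby(level=0).sum()
    for sample, total in totals.items():
        if total == 0:
            raise ValueError(f"sample {sample!r} has 0 retained cells")
    rows = []
    for (sample, line), c in counts.items():
        se = np.nan
        if replicate_col is not None:
            sub = assignments[assignments[sample_col] == sample]
            per_rep = (
                sub.groupby(replicate_col, observed=True)[line_col]
                .apply(lambda s, l=line: (s == l).mean()))
            if len(per_rep) > 1:
                se = float(per_rep.std(ddof=1) / np.sqrt(len(per_rep)))
        rows.append({"sample": sample, "line": line,
                     "proportion": c / totals[sample], "se": se})
    out = pd.DataFrame(rows)
    sums = out.groupby("sample")["proportion"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    return out


@dataclass
class GrowthFit:
    line: str
    rate: float  # per-day exponential growth rate
    intercept: float
    r_squared: float


def growth_rate_fit(timepoints: np.ndarray, measurements: np.ndarray,
                    line: str = "") -> GrowthFit:
    """Exponential growth rate from log-linear least squares.

    Fits log(measurement) = intercept + rate * t; the slope is the per-day
    rate (ln 2 / rate is the doubling time).
    """
    t = np.asarray(timepoints, float)
    m = np.asarray(measurements, float)
    if t.size != m.size or t.size < 2:
        raise ValueError("need >=2 paired timepoints")
    if (m <= 0).any():
        raise ValueError("measurements must be positive")
    logm = np.log(m)
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, logm, rcond=None)
    fitted = A @ coef
    ss_res = float(np.sum((logm - fitted) ** 2))
    ss_tot = float(np.sum((logm - logm.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return GrowthFit(line=line, rate=float(coef[1]),
                     intercept=float(coef[0]), r_squared=r2)


def proportion_growth_correlation(rates: pd.Series,
                                  proportions: pd.Series) -> tuple[float, float]:
    """Two-sided Spearman correlation of growth rate vs line proportion.

    Both series are indexed by line; only shared lines are used.
    """
    shared = rates.index.intersection(proportions.index)
    if len(shared) < 3:
        raise ValueError("need >=3 lines")
    res = spearmanr(rates.loc[shared], proportions.loc[shared])
    return float(res.statistic), float(res.pvalue)
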