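"""Droplet-level quality control, downsampling and normalization.

Filters follow the village-study conventions: droplets are dropped when
their mitochondrial percentage deviates from the median by more than a set
number of median absolute deviations (raw MAD, no consistency factor,
two-sided), when they contain fewer than a minimum number of detected
genes, or when mitochondrial content exceeds a hard percentage cap.

Normalization is log1p of counts scaled to a fixed library size (log-CPM at
scale 10,000) with optional per-gene linear residualization against
continuous nuisance covariates — a deliberately simple, stated replacement
for regularized negative-binomial normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

NORM_SCALE = 10_000.0


@dataclass
class FilterResult:
    keep: np.ndarray  # boolean mask aligned to input order
    reasons: pd.DataFrame  # barcode, reason for every excluded droplet


def mad_filter(stats: pd.DataFrame, mito_mads: float = 4.0,
               min_genes: int = 1750) -> FilterResult:
    """Exclude droplets > ``mito_mads`` raw MADs from the mito-% median or
    with fewer than ``min_genes`` detected genes."""
    if len(stats) == 0:
        raise ValueError("empty droplet stats")
    mito = stats["mito_pct"].to_numpy(float)
    genes = stats["n_genes"].to_numpy()
    med = np.median(mito)
    mad = np.median(np.abs(mito - med))
    mito_out = np.abs(mito - med) > mito_mads * mad
    genes_out = genes < min_genes
    keep = ~(mito_out | genes_out)
    reasons = []
    for i in np.flatnonzero(~keep):
        reason = "mito_mad" if mito_out[i] else "low_genes"
        if mito_out[i] and genes_out[i]:
            reason = "mito_mad+low_genes"
        reasons.append({"barcode": stats["barcode"].iloc[i], "reason": reason})
    return FilterResult(keep=keep, reasons=pd.DataFrame(
        reasons, columns=["barcode", "reason"]))


def mito_threshold_filter(stats: pd.DataFrame, max_pct: float = 25.0) -> FilterResult:
    """Exclude droplets with mitochondrial content strictly above ``max_pct``."""
    if len(stats) == 0:
        raise ValueError("empty droplet stats")
    mito = stats["mito_pct"].to_numpy(float)
    keep = ~(mito > max_pct)
    reasons = pd.DataFrame(
        {"barcode": stats["barcode"].to_numpy()[~keep], "reason": "mito_threshold"},
        columns=["barcode", "reason"])
    return FilterResult(keep=keep, reasons=reasons)


def retention_ledger(captured: int, removals: dict[str, int]) -> dict:
    """Droplet-accounting bookkeeping: captured minus sequential removals.

    Returns the ledger with the final retained count; raises if more droplets
    are removed than were captured.
    """
    retained = captured - sum(removals.values())
    if retained < 0:
        raise ValueError("removals exceed captured droplets")
    return {"captured": captured, **removals, "retained": retained}


def downsample_groups(metadata: pd.DataFrame, group_by: list[str],
                      seed: int) -> pd.DataFrame:
    """Sample every group down to the global minimum group size.

    Mirrors the balanced design used for condition comparisons: each
    combination of ``group_by`` covariates is subsampled without replacement
    to the size of the smallest combination.
    """
    groups = metadata.groupby(group_by, observed=True, sort=True)
    sizes = groups.size()
    if (sizes == 0).any():
        empty = sizes[sizes == 0].index.tolist()
        raise ValueError(f"empty group(s): {empty}")
    n_min = int(sizes.min())
    rng = np.random.default_rng(seed)
    picks = []
    for _, idx in sorted(groups.indices.items(), key=lambda kv: str(kv[0])):
        chosen = np.sort(rng.choice(idx, size=n_min, replace=False))
        picks.append(chosen)
    sel = np.concatenate(picks)
    return metadata.iloc[np.sort(sel)].copy()


@dataclass
class NormalizeResult:
    matrix: np.ndarray  # genes x cells, log scale
    zero_droplets: list[str]  # barcodes left as all-zero


def normalize(counts, barcodes: list[str] | None = None,
              covariates: pd.DataFrame | None = None) -> NormalizeResult:
    """Log-CPM normalization with optional linear residualization.

    counts: genes x cells (sparse or dense, non-negative integers).
    Each cell is scaled to a library size of 10,000, then log1p.  If
    ``covariates`` (cells x continuous covariates) is given, each gene is
    residualized against them by OLS and re-centred on its own mean.
    Zero-total droplets stay all-zero and are reported.
    """
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    if (dense < 0).any():
        raise ValueError("counts must be non-negative")
    totals = dense.sum(axis=0)
    zero_cols = np.flatnonzero(totals == 0)
    safe_totals = np.where(totals > 0, totals, 1.0)
    mat = np.log1p(dense / safe_totals[None, :] * NORM_SCALE)
    zero_barcodes = ([barcodes[i] for i in zero_cols] if barcodes is not None
                     else [str(i) for i in zero_cols])
    if covariates is not None and len(covariates.columns) > 0:
        C = np.column_stack([np.ones(mat.shape[1]),
                             covariates.to_numpy(float)])
        # per-gene OLS residuals, shared pseudo-inverse across genes
        pinv = np.linalg.pinv(C)
        coef = (pinv @ mat.T).T  # genes x p
        fitted = coef @ C.T
        mat = mat - fitted + mat.mean(axis=1, keepdims=True)
    return NormalizeResult(matrix=mat, zero_droplets=zero_barcodes)
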