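"""Spliced/unspliced count batch correction for velocity preprocessing.

The spliced (S) and unspliced (U) matrices are combined into a total matrix
M = S + U with a splicing-ratio matrix R = S / (S + U) (R = 0 where
M = 0, by convention); M is batch-corrected to M_b; and corrected spliced
and unspliced matrices are re-derived as S_b = M_b * R and
U_b = M_b * (1 - R), so that S_b + U_b = M_b always holds.

Batch correction is a deterministic per-gene location-scale adjustment on
the log1p scale: within each batch the gene is standardized to the batch
mean/SD and rescaled to the pooled mean/SD, then the log1p is inverted.
A single batch is a no-op, and genes with zero variance in any batch pass
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PrefilterReport:
    removed_cells: list
    removed_genes: list


def velocity_prefilter(S: np.ndarray, U: np.ndarray,
                       cell_ids: list | None = None,
                       gene_ids: list | None = None,
                       min_unspliced_per_cell: int = 1000,
                       min_cells_expressing: int = 20,
                       min_unspliced_per_gene: int = 10
                       ) -> tuple[np.ndarray, np.ndarray, PrefilterReport]:
    """Drop low-signal cells then genes before velocity preprocessing.

    Cells with total unspliced counts < 1000 are removed first; then genes
    expressed (S + U > 0) in fewer than 20 remaining cells, or with total
    unspliced < 10, are removed.
    """
    S = np.asarray(S)
    U = np.asarray(U)
    if S.shape != U.shape:
        raise ValueError(f"shape mismatch: S {S.shape} vs U {U.shape}")
    g, n = S.shape
    cell_ids = list(cell_ids) if cell_ids is not None else list(range(n))
    gene_ids = list(gene_ids) if gene_ids is not None else list(range(g))

    cell_keep = U.sum(axis=0) >= min_unspliced_per_cell
    S1, U1 = S[:, cell_keep], U[:, cell_keep]
    expressed_cells = ((S1 + U1) > 0).sum(axis=1)
    gene_keep = (expressed_cells >= min_cells_expressing) & \
        (U1.sum(axis=1) >= min_unspliced_per_gene)
    report = PrefilterReport(
        removed_cells=[c for c, k in zip(cell_ids, cell_keep) if not k],
        removed_genes=[gn for gn, k in zip(gene_ids, gene_keep) if not k],
    )
    return S1[gene_keep], U1[gene_keep], report


def combine(S: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """M = S + U and R = S / (S + U), with R = 0 where M = 0."""
    S = np.asarray(S, float)
    U = np.asarray(U, float)
    if S.shape != U.shape:
        raise ValueError("S and U must have the same shape")
    if (S < 0).any() or (U < 0).any():
        raise ValueError("counts must be non-negative")
    M = S + U
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(M > 0, S / np.where(M > 0, M, 1.0), 0.0)
    return M, R


def batch_correct(M: np.ndarray, batches) -> np.ndarray:
    """Per-gene location-scale batch adjustment of M on the log1p scale."""
    M = np.asarray(M, float)
    batches = pd.Series(list(batches))
    if len(batches) != M.shape[1]:
        raise ValueError("one batch label per cell required")
    sizes = batches.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"batch(es) with a single cell: {small}")
    if sizes.size == 1:
        return M.copy()
    L = np.log1p(M)
    pooled_mean = L.mean(axis=1, keepdims=True)
    pooled_sd = L.std(axis=1, keepdims=True)
    out = L.copy()
    batch_masks = [(b, (batches == b).to_numpy()) for b in sizes.index]
    # genes with (numerically) zero variance in any batch pass through unchanged
    tol = 1e-12 * np.maximum(1.0, np.abs(pooled_mean[:, 0]))
    adjustable = pooled_sd[:, 0] > tol
    for _, mask in batch_masks:
        adjustable &= L[:, mask].std(axis=1) > tol
    for _, mask in batch_masks:
        sub = L[np.ix_(adjustable, mask)]
        bm = sub.mean(axis=1, keepdims=True)
        bs = sub.std(axis=1, keepdims=True)
        z = (sub - bm) / bs
        out[np.ix_(adjustable, mask)] = (
            z * pooled_sd[adjustable] + pooled_mean[adjustable])
    corrected = M.copy()
    corrected[adjustable] = np.expm1(out[adjustable])
    return corrected


def split(M_b: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """S_b = M_b * R and U_b = M_b * (1 - R)."""
    M_b = np.asarray(M_b, float)
    R = np.asarray(R, float)
    if M_b.shape != R.shape:
        raise ValueError("M_b and R must have the same shape")
    if ((R < 0) | (R > 1)).any():
        raise ValueError("R must lie in [0, 1]")
    S_b = M_b * R
    U_b = M_b * (1.0 - R)
    return S_b, U_b


def composite_batch_labels(metadata: pd.DataFrame,
                           cols: tuple[str, ...] = ("site", "line", "village")
                           ) -> pd.Series:
    """Joint batch label over site, line and village status."""
    return metadata[list(cols)].astype(str).agg("|".join, axis=1)
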