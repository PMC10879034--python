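"""Normalization and highly-variable-gene (HVG) selection.

The HVG statistic is the classical dispersion-based one: genes are binned
by mean expression and a within-bin z-score of the log dispersion
(variance/mean) is computed, so that variability is judged relative to
genes of similar abundance. Two presets are shipped:

* ``reference`` — used when fitting a basis: min_disp = 0.5, no top-N clamp.
* ``query`` — used for projection QC (POH): min_disp = 0.1, top 500 genes,
  VDJ segment genes of the TCR/IG loci excluded (their variance is driven
  by clonal structure, not by transcriptional programs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DomainError, ExpressionMatrix

__all__ = [
    "VDJ_PREFIXES",
    "HVG_PRESETS",
    "HvgStats",
    "normalize_and_log",
    "compute_hvg_stats",
    "select_hvgs",
    "is_vdj_gene",
]

logger = logging.getLogger(__name__)

#: Variable/diversity/joining segment gene prefixes of the TCR and IG loci.
#: Constant-region genes (TRBC..., IGHM...) are deliberately retained.
VDJ_PREFIXES = (
    "TRAV", "TRAJ", "TRBV", "TRBD", "TRBJ", "TRGV", "TRGJ",
    "TRDV", "TRDD", "TRDJ",
    "IGHV", "IGHD", "IGHJ", "IGKV", "IGKJ", "IGLV", "IGLJ",
)

HVG_PRESETS = {
    "reference": dict(min_mean=0.0125, max_mean=3.0, min_disp=0.5,
                      n_top=None, exclude_vdj=True),
    "query": dict(min_mean=0.0125, max_mean=3.0, min_disp=0.1,
                  n_top=500, exclude_vdj=True),
}


def is_vdj_gene(gene_id: str) -> bool:
    return gene_id.upper().startswith(VDJ_PREFIXES)


@dataclass
class HvgStats:
    """Per-gene HVG statistics.

    ``table`` has one row per gene of the input matrix with columns
    ``gene``, ``mean`` (log1p of the back-transformed mean), ``dispersion``
    (log of variance/mean; NaN where the dispersion is nonpositive),
    ``dispersion_norm`` (within-bin z-score) and ``hvg_flag``.
    """

    table: pd.DataFrame
    min_mean: float
    max_mean: float
    min_disp: float
    n_bins: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def flagged_genes(self) -> list[str]:
        return list(self.table.loc[self.table["hvg_flag"], "gene"])


def normalize_and_log(
    X: ExpressionMatrix, target_sum: float = 1e4, apply_log: bool = True
) -> ExpressionMatrix:
    """Rescale each column to ``target_sum`` total counts, optionally log1p.

    All-zero columns are left unchanged. With the default target this is
    the CP10K normalization used throughout single-cell work.
    """
    if target_sum <= 0:
        raise DomainError(f"target_sum must be positive, got {target_sum}")
    values = X.values.copy()
    colsums = values.sum(axis=0)
    nonzero = colsums > 0
    values[:, nonzero] *= target_sum / colsums[nonzero]
    if apply_log:
        values = np.log1p(values)
        kind = "cp10k_log"
    else:
        kind = "cp10k" if target_sum == 1e4 else "other"
    return ExpressionMatrix(values, list(X.gene_ids), list(X.column_ids), value_kind=kind)


def compute_hvg_stats(
    X_lognorm: ExpressionMatrix,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = 0.1,
    n_bins: int = 20,
) -> HvgStats:
    """Dispersion-based HVG statistics on a log1p-normalized matrix.

    Values are back-transformed with expm1 before computing the per-gene
    mean ``m`` and sample variance ``v`` (N-1 denominator); the reported
    mean is ``log1p(m)`` and the reported dispersion ``log(v/m)``. Genes
    are then cut into ``n_bins`` equal-width bins of the reported mean and
    the normalized dispersion is the z-score of the reported dispersion
    within its bin (0 for degenerate bins). A gene is flagged when
    ``min_mean < mean < max_mean`` and ``dispersion_norm > min_disp``.
    """
    if X_lognorm.n_columns < 2:
        raise DomainError("need at least 2 columns to compute a variance")
    y = np.expm1(X_lognorm.values)
    m = y.mean(axis=1)
    v = y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(m > 0, v / np.where(m > 0, m, 1.0), 0.0)
        mean_rep = np.log1p(m)
        disp_rep = np.where(disp > 0, np.log(np.where(disp > 0, disp, 1.0)), np.nan)

    # equal-width bins of the reported mean; degenerate bins get z = 0
    dispersion_norm = np.zeros(len(m))
    valid = np.isfinite(disp_rep)
    if valid.any():
        lo, hi = mean_rep.min(), mean_rep.max()
        # a range at floating-point noise level is a single bin, not 20
        if hi - lo > 1e-12 * max(1.0, abs(hi)):
            edges = np.linspace(lo, hi, n_bins + 1)
            bin_idx = np.clip(np.digitize(mean_rep, edges[1:-1]), 0, n_bins - 1)
        else:
            bin_idx = np.zeros(len(m), dtype=int)
        for b in np.unique(bin_idx):
            sel = (bin_idx == b) & valid
            if sel.sum() <= 1:
                continue
            mu = disp_rep[sel].mean()
            sd = disp_rep[sel].std(ddof=1)
            if sd > 0:
                dispersion_norm[sel] = (disp_rep[sel] - mu) / sd

    flag = (
        (mean_rep > min_mean)
        & (mean_rep < max_mean)
        & (dispersion_norm > min_disp)
        & valid
    )
    table = pd.DataFrame(
        {
            "gene": X_lognorm.gene_ids,
            "mean": mean_rep,
            "dispersion": disp_rep,
            "dispersion_norm": dispersion_norm,
            "hvg_flag": flag,
        }
    )
    return HvgStats(table, min_mean, max_mean, min_disp, n_bins)


def select_hvgs(
    stats: HvgStats, n_top: int | None = 500, exclude_vdj: bool = True
) -> list[str]:
    """Ordered HVG list: flagged genes, VDJ removed, ranked by dispersion z.

    Ties in normalized dispersion are broken by lexicographic gene
    identifier so the output is deterministic across runs and platforms.
    ``n_top=None`` disables the clamp.
    """
    if n_top is not None and n_top <= 0:
        raise DomainError(f"n_top must be positive, got {n_top}")
    cand = stats.table.loc[stats.table["hvg_flag"], ["gene", "dispersion_norm"]]
    if exclude_vdj:
        cand = cand.loc[~cand["gene"].map(is_vdj_gene)]
    order = np.lexsort((cand["gene"].to_numpy(), -cand["dispersion_norm"].to_numpy()))
    ranked = cand["gene"].to_numpy()[order].tolist()
    if n_top is not None and len(ranked) < n_top:
        logger.warning(
            "requested top %d HVGs but only %d genes are flagged", n_top, len(ranked)
        )
    return ranked if n_top is None else ranked[:n_top]
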