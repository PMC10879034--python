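"""Projection of a fixed gene-program basis onto new datasets (NMFproj).

A pre-computed gene-feature matrix W is held fixed and, for every column x
of a query expression matrix, the nonnegative activity h solving

    min_{h >= 0} || x - W h ||^2

is found exactly by active-set nonnegative least squares. Before solving,
the basis and query are aligned on their gene intersection (only
overlapped genes are used; W is not renormalized after subsetting), and
for cross-species transfer basis genes are renamed through a homolog
table. Two quality metrics accompany each projection:

* POH — the proportion of the query's highly variable genes contained in
  the basis gene set; below 0.1 the query carries variability the fixed
  programs cannot represent.
* Evar_all — overall explained variance of the reconstruction on the
  aligned gene slice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nnls import check_rank, kkt_residual, nnls_columns
from .containers import (
    DomainError,
    ExpressionMatrix,
    GeneProgramBasis,
    HomologMap,
    ProgramActivity,
)
from .decomposition import evar_all as _evar_all
from .preprocessing import HVG_PRESETS, compute_hvg_stats, normalize_and_log, select_hvgs

__all__ = [
    "POH_THRESHOLD",
    "AlignedBasis",
    "ProjectionResult",
    "FixedBasisProjector",
    "convert_species_basis",
    "align_to_basis",
    "project_fixed_basis",
    "compute_poh",
    "project_expression",
]

logger = logging.getLogger(__name__)

#: POH below this value flags a low-quality projection.
POH_THRESHOLD = 0.1


@dataclass
class AlignedBasis:
    """Basis and query restricted to their gene intersection, same order."""

    basis: GeneProgramBasis
    query: ExpressionMatrix
    dropped_basis_genes: list[str]
    dropped_query_genes: list[str]
    overlap_fraction_of_basis: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n_overlap_genes(self) -> int:
        return self.basis.n_genes


@dataclass
class ProjectionResult:
    """Activities plus quality metrics for one projection."""

    activity: ProgramActivity
    evar_all: float
    n_overlap_genes: int
    overlap_fraction_of_basis: float
    poh: float = float("nan")
    low_poh: bool = False
    warnings: list[str] = field(default_factory=list)

    def qc_dict(self) -> dict:
        return {
            "poh": None if np.isnan(self.poh) else float(self.poh),
            "low_poh": bool(self.low_poh),
            "evar_all": float(self.evar_all),
            "n_overlap_genes": int(self.n_overlap_genes),
            "overlap_fraction_of_basis": float(self.overlap_fraction_of_basis),
            "warnings": list(self.warnings),
        }


def convert_species_basis(W: GeneProgramBasis, map: HomologMap) -> GeneProgramBasis:
    """Rename basis genes through a homolog table (e.g. human -> mouse).

    Each basis gene with at least one homolog is renamed to the first
    homolog appearing in table order; genes without a homolog are dropped.
    When two source genes map to the same target, the first source in
    basis order is kept and the collision is logged. Weights are unchanged.
    """
    if len(map) == 0:
        raise DomainError("homolog map is empty")
    first = map.first_target()
    keep_rows: list[int] = []
    new_ids: list[str] = []
    seen: dict[str, str] = {}
    n_unmapped = 0
    for i, g in enumerate(W.gene_ids):
        t = first.get(g)
        if t is None:
            n_unmapped += 1
            continue
        if t in seen:
            logger.info("homolog collision: %s -> %s already taken by %s", g, t, seen[t])
            continue
        seen[t] = g
        keep_rows.append(i)
        new_ids.append(t)
    if n_unmapped:
        logger.info("%d basis genes had no homolog and were dropped", n_unmapped)
    if not new_ids:
        raise DomainError("no basis gene has a homolog; converted basis would be empty")
    universe = frozenset(first.get(g, g) for g in W.hvg_universe) | frozenset(new_ids)
    return GeneProgramBasis(
        W.weights[keep_rows], new_ids, list(W.component_ids), hvg_universe=universe
    )


def align_to_basis(
    W: GeneProgramBasis,
    X_query: ExpressionMatrix,
    min_overlap_fraction: float = 0.5,
) -> AlignedBasis:
    """Restrict basis and query to their shared genes, in query gene order."""
    basis_set = set(W.gene_ids)
    overlap = [g for g in X_query.gene_ids if g in basis_set]
    if len(overlap) < W.n_components:
        raise DomainError(
            f"only {len(overlap)} genes shared between basis and query; "
            f"projection onto {W.n_components} components is underdetermined"
        )
    frac = len(overlap) / W.n_genes
    notes = []
    if frac < min_overlap_fraction:
        msg = (
            f"only {frac:.1%} of basis genes found in the query "
            f"(threshold {min_overlap_fraction:.0%})"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    overlap_set = set(overlap)
    bloc = {g: i for i, g in enumerate(W.gene_ids)}
    basis_sub = GeneProgramBasis(
        W.weights[[bloc[g] for g in overlap]],
        overlap,
        list(W.component_ids),
        hvg_universe=W.hvg_universe,
    )
    query_sub = X_query.subset_genes(overlap)
    return AlignedBasis(
        basis=basis_sub,
        query=query_sub,
        dropped_basis_genes=[g for g in W.gene_ids if g not in overlap_set],
        dropped_query_genes=[g for g in X_query.gene_ids if g not in overlap_set],
        overlap_fraction_of_basis=frac,
        warnings=notes,
    )


def project_fixed_basis(aligned: AlignedBasis, kkt_tol: float = 1e-8) -> ProjectionResult:
    """Solve the fixed-W nonnegative least-squares problem per query column."""
    W = aligned.basis.weights
    X = aligned.query.values
    notes = list(aligned.warnings)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        full_rank = check_rank(W, aligned.basis.n_components)
        H = nnls_columns(W, X)
    for w in caught:
        notes.append(str(w.message))
        warnings.warn(w.message, stacklevel=2)  # recorded AND surfaced
    if full_rank:
        scale = max(1.0, float(np.abs(W.T @ X).max()))
        worst = max(
            (kkt_residual(W, X[:, j], H[:, j]) for j in range(X.shape[1])),
            default=0.0,
        )
        if worst / scale > kkt_tol:
            notes.append(f"KKT residual {worst:.2e} above tolerance")
    activity = ProgramActivity(
        H, list(aligned.basis.component_ids), list(aligned.query.column_ids)
    )
    ev = _evar_all(X, W, H) if np.any(X) else 0.0
    return ProjectionResult(
        activity=activity,
        evar_all=ev,
        n_overlap_genes=aligned.n_overlap_genes,
        overlap_fraction_of_basis=aligned.overlap_fraction_of_basis,
        warnings=notes,
    )


def compute_poh(
    query_hvgs, W: GeneProgramBasis, use_hvg_universe: bool = False
) -> float:
    """Proportion of the query's HVGs contained in the basis gene set.

    ``query_hvgs`` should come from the preprocessing ``query`` preset
    (top 500 by normalized dispersion, VDJ excluded). With
    ``use_hvg_universe`` the basis's fit-time HVG set is the reference
    instead of its retained gene rows.
    """
    query_hvgs = list(query_hvgs)
    if not query_hvgs:
        raise DomainError("query HVG list is empty")
    ref = W.hvg_universe if use_hvg_universe else set(W.gene_ids)
    return sum(g in ref for g in query_hvgs) / len(query_hvgs)


def project_expression(
    W: GeneProgramBasis,
    X_query: ExpressionMatrix,
    species_map: HomologMap | None = None,
    normalize: str = "none",
    min_overlap_fraction: float = 0.5,
    hvg_kwargs: dict | None = None,
) -> ProjectionResult:
    """End-to-end projection: species conversion, alignment, NNLS, QC.

    ``normalize`` is ``none`` (project the input scale as given — raw
    counts or TPM) or ``cp10k_log``. POH is computed from the query's own
    HVGs under the ``query`` preset, which needs at least 2 query columns;
    with a single column POH is reported as NaN.
    """
    if normalize not in ("none", "cp10k_log"):
        raise DomainError(f"unknown normalize mode {normalize!r}")
    if species_map is not None:
        W = convert_species_basis(W, species_map)
    X_proj = (
        normalize_and_log(X_query, apply_log=True) if normalize == "cp10k_log" else X_query
    )
    aligned = align_to_basis(W, X_proj, min_overlap_fraction=min_overlap_fraction)
    result = project_fixed_basis(aligned)

    if X_query.n_columns >= 2:
        preset = dict(HVG_PRESETS["query"])
        preset.update(hvg_kwargs or {})
        lognorm = (
            X_query
            if X_query.value_kind == "cp10k_log"
            else normalize_and_log(X_query, apply_log=True)
        )
        stats = compute_hvg_stats(
            lognorm,
            min_mean=preset["min_mean"],
            max_mean=preset["max_mean"],
            min_disp=preset["min_disp"],
        )
        hvgs = select_hvgs(stats, n_top=preset["n_top"], exclude_vdj=preset["exclude_vdj"])
        if not hvgs:
            result.warnings.append(
                "no query HVGs under the query preset; POH not computed"
            )
        else:
            result.poh = compute_poh(hvgs, W)
            result.low_poh = result.poh < POH_THRESHOLD
            if result.low_poh:
                result.warnings.append(
                    f"POH {result.poh:.3f} below threshold {POH_THRESHOLD}; the query "
                    "has variability the fixed basis cannot represent"
                )
    else:
        result.warnings.append("single-column query; POH not computed")
    return result


class FixedBasisProjector(TransformerMixin, BaseEstimator):
    """sklearn-style transformer projecting samples onto a fixed basis.

    ``transform`` takes X of shape (n_samples, n_genes) whose feature axis
    is already aligned to ``basis.gene_ids`` and returns nonnegative
    activities of shape (n_samples, n_components). Use
    :func:`align_to_basis` / :func:`project_expression` for identifier-aware
    alignment.
    """

    def __init__(self, basis: GeneProgramBasis = None):
        self.basis = basis

    def fit(self, X, y=None):
        if self.basis is None:
            raise DomainError("FixedBasisProjector requires a basis")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.basis.n_genes:
            raise DomainError(
                f"X must have {self.basis.n_genes} gene columns, got shape {X.shape}"
            )
        self.n_features_in_ = X.shape[1]
        self.components_ = self.basis.weights.T
        return self

    def transform(self, X):
        if not hasattr(self, "components_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if np.any(X < 0) or not np.all(np.isfinite(X)):
            raise DomainError("query matrix must be nonnegative and finite")
        return nnls_columns(self.basis.weights, X.T).T
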