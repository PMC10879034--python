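"""In-memory containers for expression matrices, gene-program bases and activities.

The canonical orientation throughout the package is genes x columns for
expression data (``X``), genes x components for a program basis (``W``) and
components x columns for program activities (``H``), so that ``X ~ W @ H``.
Single-cell containers usually store the transpose; readers accept both
orientations and normalize on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "FormatError",
    "ExpressionMatrix",
    "GeneProgramBasis",
    "ProgramActivity",
    "HomologMap",
    "VALUE_KINDS",
    "default_component_ids",
]


class DomainError(ValueError):
    """A value violates a mathematical precondition (negative counts, bad k...)."""


class FormatError(ValueError):
    """A file or table violates the expected on-disk structure."""


#: Recognized interpretations of matrix values.
VALUE_KINDS = ("raw_count", "cp10k", "cp10k_log", "tpm", "other")


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise FormatError(f"duplicate {what} identifiers: {sorted(set(dups))[:5]}")
    return ids


def _check_nonneg_finite(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise FormatError(f"{what} must be 2-dimensional, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise DomainError(f"{what} contains non-finite values")
    if np.any(values < 0):
        raise DomainError(f"{what} contains negative values")
    return values


def default_component_ids(k: int) -> list[str]:
    """Default component labels NMF0 ... NMF{k-1}."""
    return [f"NMF{c}" for c in range(k)]


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x columns expression matrix X = (x_ij).

    Parameters
    ----------
    values
        Dense nonnegative matrix, genes in rows, cells/samples in columns.
    gene_ids, column_ids
        Unique ordered identifiers matching the matrix dimensions.
    value_kind
        One of :data:`VALUE_KINDS`; records how the values were produced.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    value_kind: str = "raw_count"

    def __post_init__(self):
        self.values = _check_nonneg_finite(self.values, "expression matrix")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.column_ids = _check_unique(self.column_ids, "column")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if self.value_kind not in VALUE_KINDS:
            raise DomainError(f"unknown value_kind {self.value_kind!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order."""
        idx = pd.Index(self.gene_ids)
        locs = idx.get_indexer(genes)
        if np.any(locs < 0):
            missing = [g for g, l in zip(genes, locs) if l < 0]
            raise DomainError(f"genes not present in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values[locs], list(genes), list(self.column_ids), self.value_kind
        )


@dataclass
class GeneProgramBasis:
    """Nonnegative genes x components gene-feature matrix W = (w_ic).

    ``hvg_universe`` records the highly-variable-gene set the basis was fit
    on (a superset of ``gene_ids``); it is used by the alternative POH
    reference-set mode.
    """

    weights: np.ndarray
    gene_ids: list[str]
    component_ids: list[str] = None  # type: ignore[assignment]
    hvg_universe: frozenset = None  # type: ignore[assignment]

    def __post_init__(self):
        self.weights = _check_nonneg_finite(self.weights, "basis weights")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.component_ids is None:
            self.component_ids = default_component_ids(self.weights.shape[1])
        self.component_ids = [str(c) for c in self.component_ids]
        if self.weights.shape != (len(self.gene_ids), len(self.component_ids)):
            raise FormatError(
                f"basis shape {self.weights.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.component_ids)} components"
            )
        if self.n_components < 1:
            raise DomainError("basis must have at least one component")
        if self.hvg_universe is None:
            self.hvg_universe = frozenset(self.gene_ids)
        else:
            self.hvg_universe = frozenset(self.hvg_universe)
            if not self.hvg_universe.issuperset(self.gene_ids):
                raise DomainError("hvg_universe must contain all basis gene_ids")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.gene_ids, columns=self.component_ids)


@dataclass
class ProgramActivity:
    """Nonnegative components x columns cell/sample-feature matrix H = (h_cj)."""

    values: np.ndarray
    component_ids: list[str]
    column_ids: list[str]

    def __post_init__(self):
        self.values = _check_nonneg_finite(self.values, "activity values")
        self.component_ids = [str(c) for c in self.component_ids]
        self.column_ids = _check_unique(self.column_ids, "column")
        if self.values.shape != (len(self.component_ids), len(self.column_ids)):
            raise FormatError(
                f"activity shape {self.values.shape} does not match "
                f"{len(self.component_ids)} components x {len(self.column_ids)} columns"
            )

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.component_ids, columns=self.column_ids)


@dataclass
class HomologMap:
    """Ordered (source_symbol, target_symbol) gene homolog pairs.

    Order is preserved exactly as read: when a source gene has several
    homologs, the first pair in the table wins (multi-homolog resolution).
    Pairs are never deduplicated.
    """

    pairs: list = field(default_factory=list)

    def __post_init__(self):
        self.pairs = [(str(s), str(t)) for s, t in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    def first_target(self) -> dict:
        """source -> first target in table order."""
        out: dict = {}
        for s, t in self.pairs:
            out.setdefault(s, t)
        return out
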