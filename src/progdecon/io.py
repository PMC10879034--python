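"""Readers and writers for the on-disk formats the toolkit touches.

Supported formats: Matrix Market triplets (``.mtx``/``.mtx.gz``) with gene
and column identifier sidecar files; dense TSV/CSV with a header row and an
identifier column; the basis TSV (genes x NMF0..NMFk-1); two-column homolog
tables; and tidy result tables. Gzip is handled transparently by suffix.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    DomainError,
    ExpressionMatrix,
    FormatError,
    GeneProgramBasis,
    HomologMap,
    ProgramActivity,
)

__all__ = [
    "read_expression_matrix",
    "read_gene_feature_matrix",
    "write_gene_feature_matrix",
    "read_activity_matrix",
    "read_homolog_table",
    "write_table",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sep_for(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    return "," if name.endswith(".csv") else "\t"


def _read_id_file(path) -> list[str]:
    """Identifier sidecar: one id per line; extra tab-separated fields ignored."""
    ids = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_expression_matrix(
    matrix,
    genes=None,
    columns=None,
    orientation: str = "genes_in_rows",
    value_kind: str = "raw_count",
) -> ExpressionMatrix:
    """Read an expression matrix from MTX triplets or a dense TSV/CSV.

    Parameters
    ----------
    matrix
        Path to ``.mtx``/``.mtx.gz`` (requires ``genes`` and ``columns``
        sidecars) or to a dense TSV/CSV with a header row and the
        identifiers in the first column.
    orientation
        ``genes_in_rows`` (default) or ``genes_in_columns``; describes the
        on-disk layout. The returned matrix is always genes x columns.
    """
    if orientation not in ("genes_in_rows", "genes_in_columns"):
        raise DomainError(f"unknown orientation {orientation!r}")
    matrix = Path(matrix)
    name = matrix.name[:-3] if matrix.name.endswith(".gz") else matrix.name
    if name.endswith(".mtx"):
        if genes is None or columns is None:
            raise FormatError("MTX input requires gene and column identifier files")
        with _open_text(matrix, "rb") as fh:
            m = scipy.io.mmread(_io.BytesIO(fh.read()))
        values = np.asarray(
            m.toarray() if scipy.sparse.issparse(m) else m, dtype=float
        )
        row_ids = _read_id_file(genes)
        col_ids = _read_id_file(columns)
    else:
        df = pd.read_csv(matrix, sep=_sep_for(matrix), index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise FormatError(f"empty table in {matrix}")
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    if values.shape != (len(row_ids), len(col_ids)):
        raise FormatError(
            f"matrix shape {values.shape} does not match identifier counts "
            f"({len(row_ids)}, {len(col_ids)})"
        )
    if orientation == "genes_in_columns":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids, value_kind=value_kind)


def read_gene_feature_matrix(path) -> GeneProgramBasis:
    """Read a gene-feature basis W from TSV/CSV (genes in rows, components in header)."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty basis file {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"basis file {path} has no genes or no components")
    return GeneProgramBasis(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_gene_feature_matrix(basis: GeneProgramBasis, path) -> None:
    """Write W so that a read round-trips bit-exactly (17 significant digits)."""
    basis.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_activity_matrix(path) -> ProgramActivity:
    """Read an activity matrix H (components in rows, columns in header)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ProgramActivity(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


_HEADER_WORDS = {
    "source", "target", "human", "mouse", "human_symbol", "mouse_symbol",
    "symbol", "gene", "from", "to",
}


def read_homolog_table(path, header: str = "auto") -> HomologMap:
    """Read a two-column (source, target) homolog table.

    Row order is preserved and duplicates are kept: the first occurrence of
    a source symbol determines its homolog. ``header`` is ``auto`` (skip the
    first row when both fields look like column names), ``present`` or
    ``none``.
    """
    if header not in ("auto", "present", "none"):
        raise DomainError(f"unknown header mode {header!r}")
    pairs = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("," if _sep_for(path) == "," else "\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: expected two fields, got {line!r}")
            pairs.append((fields[0], fields[1]))
    if pairs and header != "none":
        first = {pairs[0][0].lower(), pairs[0][1].lower()}
        if header == "present" or first <= _HEADER_WORDS:
            pairs = pairs[1:]
    return HomologMap(pairs)


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV/CSV, floats at 10 significant digits."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    table.to_csv(path, sep=_sep_for(path), float_format="%.10g", index=index)
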