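"""NMF decomposition of expression matrices with explained-variance diagnostics.

The normalized genes x columns matrix X is factorized as X = W.H with W, H
nonnegative (squared Frobenius loss, no regularization). Model fit is
summarized by explained-variance statistics derived from residual sums of
squares:

    RSS_c   = sum_ij (x_ij - w_ic h_cj)^2        (rank-1 slice of component c)
    Evar_c  = 1 - RSS_c / sum_ij x_ij^2
    RSS_all = sum_ij (x_ij - (W.H)_ij)^2
    Evar_all = 1 - RSS_all / sum_ij x_ij^2

Rank selection combines two diagnostics over a scan of component numbers:
the elbow of Evar_all(k) and the maximum pairwise Spearman correlation
between basis columns, which jumps sharply once components become
redundant. The advisory k is the largest scanned k that lies at or beyond
the elbow and is immediately followed by such a jump.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF as _SKNMF

from ._nnls import nnls_columns
from .containers import (
    DomainError,
    ExpressionMatrix,
    GeneProgramBasis,
    ProgramActivity,
    default_component_ids,
)

__all__ = [
    "ProgramNMF",
    "DecompositionDiagnostics",
    "ScanResult",
    "fit_nmf",
    "evar_all",
    "evar_component",
    "rss_all",
    "rss_component",
    "max_intercomponent_correlation",
    "scan_components",
    "extract_top_genes",
]


def _as_x(X) -> np.ndarray:
    return np.asarray(X.values if isinstance(X, ExpressionMatrix) else X, dtype=float)


def _as_w(W) -> np.ndarray:
    return np.asarray(W.weights if isinstance(W, GeneProgramBasis) else W, dtype=float)


def _as_h(H) -> np.ndarray:
    return np.asarray(H.values if isinstance(H, ProgramActivity) else H, dtype=float)


@dataclass
class DecompositionDiagnostics:
    """Explained-variance and redundancy diagnostics for one fitted rank."""

    k: int
    sum_sq: float
    rss_all: float
    rss_per_component: np.ndarray
    max_spearman: float
    converged: bool
    n_iter: int

    @property
    def evar_all(self) -> float:
        return 1.0 - self.rss_all / self.sum_sq

    @property
    def evar_per_component(self) -> np.ndarray:
        return 1.0 - self.rss_per_component / self.sum_sq

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "evar_all": float(self.evar_all),
            "rss_all": float(self.rss_all),
            "evar_per_component": [float(v) for v in self.evar_per_component],
            "rss_per_component": [float(v) for v in self.rss_per_component],
            "max_spearman": float(self.max_spearman),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


def rss_all(X, W, H) -> float:
    X, W, H = _as_x(X), _as_w(W), _as_h(H)
    r = X - W @ H
    return float(np.sum(r * r))


def rss_component(X, W, H, c: int) -> float:
    X, W, H = _as_x(X), _as_w(W), _as_h(H)
    if not 0 <= c < W.shape[1]:
        raise DomainError(f"component index {c} out of range for k={W.shape[1]}")
    r = X - np.outer(W[:, c], H[c, :])
    return float(np.sum(r * r))


def _sum_sq(X) -> float:
    X = _as_x(X)
    ss = float(np.sum(X * X))
    if ss == 0:
        raise DomainError("explained variance undefined for an all-zero matrix")
    return ss


def evar_all(X, W, H) -> float:
    """Overall explained variance, 1 - RSS_all / sum(x^2)."""
    return 1.0 - rss_all(X, W, H) / _sum_sq(X)


def evar_component(X, W, H, c: int) -> float:
    """Explained variance of the rank-1 slice of component ``c`` of a joint fit."""
    return 1.0 - rss_component(X, W, H, c) / _sum_sq(X)


def max_intercomponent_correlation(W) -> float:
    """Maximum pairwise Spearman correlation between basis columns.

    Ties get average ranks. Pairs involving a constant column are
    undefined and excluded with a warning.
    """
    Wm = _as_w(W)
    k = Wm.shape[1]
    if k < 2:
        raise DomainError("need at least 2 components for inter-component correlation")
    constant = np.array([np.all(Wm[:, c] == Wm[0, c]) for c in range(k)])
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant basis column(s) excluded from "
            "Spearman correlation",
            stacklevel=2,
        )
    keep = np.flatnonzero(~constant)
    if len(keep) < 2:
        raise DomainError("fewer than 2 non-constant columns; correlation undefined")
    rho = scipy.stats.spearmanr(Wm[:, keep]).statistic
    if len(keep) == 2:
        return float(rho)
    iu = np.triu_indices(len(keep), k=1)
    return float(np.max(np.asarray(rho)[iu]))


def _nndsvda(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD init, zeros replaced by the matrix mean."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        x, y = U[:, j], Vt[j, :]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        mp = np.linalg.norm(xp) * np.linalg.norm(yp)
        mn = np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn and mp > 0:
            u, v, sig = xp / np.linalg.norm(xp), yp / np.linalg.norm(yp), mp
        elif mn > 0:
            u, v, sig = xn / np.linalg.norm(xn), yn / np.linalg.norm(yn), mn
        else:
            continue
        W[:, j] = np.sqrt(S[j] * sig) * u
        H[j, :] = np.sqrt(S[j] * sig) * v
    avg = X.mean()
    W[W == 0] = avg
    H[H == 0] = avg
    return W, H


class ProgramNMF(TransformerMixin, BaseEstimator):
    """NMF gene-program model with explained-variance diagnostics.

    Follows the sklearn transformer convention: ``fit``/``fit_transform``
    take an array of shape (n_samples, n_genes) — cells or samples in rows
    — and activities come back as (n_samples, n_components). Initialization
    is a nonnegative double SVD (zeros replaced by the matrix mean) with a
    small multiplicative perturbation seeded by ``random_state``, so two
    runs with the same seed are bit-identical.

    Attributes
    ----------
    components_ : ndarray (n_components, n_genes)
        Gene-program weights, ordered by decreasing per-component
        explained variance on the training matrix.
    diagnostics_ : DecompositionDiagnostics
    n_iter_ : int
    """

    def __init__(
        self,
        n_components: int = 12,
        random_state: int = 0,
        max_iter: int = 1000,
        tol: float = 1e-6,
        perturbation: float = 0.01,
    ):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.perturbation = perturbation

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DomainError("expected a 2-d matrix")
        if not np.all(np.isfinite(X)):
            raise DomainError("input contains non-finite values")
        if np.any(X < 0):
            raise DomainError("NMF requires a nonnegative matrix")
        return X

    def fit_transform(self, X, y=None):
        X = self._validate(X)
        k = self.n_components
        if k < 1 or k > min(X.shape):
            raise DomainError(
                f"n_components={k} must be in [1, min{X.shape}]"
            )
        W0, H0 = _nndsvda(X, k)
        rng = np.random.default_rng(self.random_state)
        eps = self.perturbation
        if eps > 0:
            W0 = W0 * rng.uniform(1 - eps, 1 + eps, size=W0.shape)
            H0 = H0 * rng.uniform(1 - eps, 1 + eps, size=H0.shape)
        est = _SKNMF(
            n_components=k,
            init="custom",
            solver="cd",
            tol=self.tol,
            max_iter=self.max_iter,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence handled via diagnostics
            A = est.fit_transform(X, W=W0, H=H0)
        self.n_iter_ = est.n_iter_
        comp = est.components_  # (k, n_genes)

        # order components by decreasing rank-1 explained variance
        ss = float(np.sum(X * X))
        rss_c = np.array(
            [np.sum((X - np.outer(A[:, c], comp[c])) ** 2) for c in range(k)]
        )
        order = np.argsort(rss_c, kind="stable")  # low RSS = high Evar first
        A = A[:, order]
        comp = comp[order]
        rss_c = rss_c[order]

        self.components_ = comp
        self.n_features_in_ = X.shape[1]
        max_sp = max_intercomponent_correlation(comp.T) if k >= 2 else float("nan")
        self.diagnostics_ = DecompositionDiagnostics(
            k=k,
            sum_sq=ss,
            rss_all=float(np.sum((X - A @ comp) ** 2)),
            rss_per_component=rss_c,
            max_spearman=max_sp,
            converged=self.n_iter_ < self.max_iter,
            n_iter=self.n_iter_,
        )
        return A

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X):
        """Nonnegative activities for new samples with the basis held fixed."""
        X = self._validate(X)
        if X.shape[1] != self.components_.shape[1]:
            raise DomainError(
                f"X has {X.shape[1]} genes, model was fit on "
                f"{self.components_.shape[1]}"
            )
        return nnls_columns(self.components_.T, X.T).T


def fit_nmf(
    X_norm: ExpressionMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[GeneProgramBasis, ProgramActivity, DecompositionDiagnostics]:
    """Fit NMF on a genes x columns matrix; components labelled NMF0.. by Evar."""
    est = ProgramNMF(
        n_components=k, random_state=seed, max_iter=max_iter, tol=tol
    )
    A = est.fit_transform(X_norm.values.T)
    labels = default_component_ids(k)
    basis = GeneProgramBasis(est.components_.T, list(X_norm.gene_ids), labels)
    activity = ProgramActivity(A.T, labels, list(X_norm.column_ids))
    return basis, activity, est.diagnostics_


@dataclass
class ScanResult:
    """Diagnostics for each scanned rank and the advisory component number."""

    k_values: list[int]
    diagnostics: list[DecompositionDiagnostics]
    advisory_k: int | None
    elbow_k: int | None = None
    jump_threshold: float = 0.1
    notes: list[str] = field(default_factory=list)

    @property
    def evar_curve(self) -> np.ndarray:
        return np.array([d.evar_all for d in self.diagnostics])

    @property
    def spearman_curve(self) -> np.ndarray:
        return np.array([d.max_spearman for d in self.diagnostics])


def scan_components(
    X_norm: ExpressionMatrix,
    k_values,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    jump_threshold: float = 0.1,
) -> ScanResult:
    """Fit NMF across ranks and suggest a component number.

    The elbow is the scanned k with the most negative second difference of
    Evar_all (the point where the curve flattens). The advisory k is the
    first scanned k at or beyond the elbow whose successor shows a jump of
    more than ``jump_threshold`` in the maximum inter-component Spearman
    correlation — i.e. the rank just before components become redundant.
    The advisory value is a suggestion only; diagnostics are always
    returned so the curves can be inspected.
    """
    k_values = [int(k) for k in k_values]
    if any(k < 2 for k in k_values):
        raise DomainError("scanned k values must all be >= 2")
    if sorted(k_values) != k_values:
        raise DomainError("k_values must be sorted ascending")
    diags = []
    for k in k_values:
        _, _, d = fit_nmf(X_norm, k, seed=seed, max_iter=max_iter, tol=tol)
        diags.append(d)
    result = ScanResult(k_values, diags, None, jump_threshold=jump_threshold)
    if len(k_values) < 3:
        result.notes.append("fewer than 3 ranks scanned; no advisory k")
        return result

    evar = result.evar_curve
    sp = result.spearman_curve
    second_diff = evar[2:] - 2 * evar[1:-1] + evar[:-2]
    elbow_i = int(np.argmin(second_diff)) + 1  # interior point
    result.elbow_k = k_values[elbow_i]
    advisory = None
    for i in range(len(k_values) - 1):
        if k_values[i] >= result.elbow_k and sp[i + 1] - sp[i] > jump_threshold:
            advisory = k_values[i]
            break
    result.advisory_k = advisory
    if advisory is None:
        result.notes.append("no rank met both the elbow and jump criteria")
    return result


def extract_top_genes(W: GeneProgramBasis, c, n: int = 100) -> list[str]:
    """Top ``n`` genes of component ``c`` by weight, ties lexicographic."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if isinstance(c, str):
        try:
            c = W.component_ids.index(c)
        except ValueError:
            raise DomainError(f"unknown component {c!r}") from None
    if not 0 <= c < W.n_components:
        raise DomainError(f"component index {c} out of range")
    genes = np.asarray(W.gene_ids)
    w = W.weights[:, c]
    order = np.lexsort((genes, -w))
    return genes[order][: min(n, len(genes))].tolist()
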