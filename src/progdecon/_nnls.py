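"""Column-wise nonnegative least squares shared by projection and transform."""

from __future__ import annotations

import warnings

import numpy as np
import scipy.optimize


def nnls_columns(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Solve min_{h>=0} ||x - W h||^2 for every column x of X.

    Exact active-set solution per column (Lawson-Hanson); deterministic.
    Returns H of shape (k, n_columns).
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    k = W.shape[1]
    H = np.empty((k, X.shape[1]))
    for j in range(X.shape[1]):
        H[:, j], _ = scipy.optimize.nnls(W, X[:, j])
    return H


def check_rank(W: np.ndarray, k: int) -> bool:
    """Warn when W has fewer independent columns than components."""
    rank = np.linalg.matrix_rank(W)
    if rank < k:
        warnings.warn(
            f"basis is rank-deficient ({rank} < {k} components); "
            "activities are not uniquely determined",
            stacklevel=3,
        )
        return False
    return True


def kkt_residual(W: np.ndarray, x: np.ndarray, h: np.ndarray) -> float:
    """Max violation of the NNLS KKT conditions (0 at an exact solution)."""
    g = W.T @ (W @ h - x)
    active = h > 0
    viol = 0.0
    if active.any():
        viol = max(viol, float(np.abs(g[active]).max()))
    if (~active).any():
        viol = max(viol, float(np.clip(-g[~active], 0, None).max()))
    return viol
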