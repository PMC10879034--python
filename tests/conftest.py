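import numpy as np
import pytest

from progdecon import ExpressionMatrix, GeneProgramBasis


@pytest.fixture
def small_dense(tmp_path):
    """2x2 dense TSV [[1,2],[3,4]] with genes g1,g2 and columns c1,c2."""
    path = tmp_path / "small.tsv"
    path.write_text("\tc1\tc2\ng1\t1\t2\ng2\t3\t4\n")
    return path


@pytest.fixture
def simple_basis():
    return GeneProgramBasis(
        np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        ["A", "B", "C"],
    )


def planted_dispersion_matrix(seed: int, n_background: int = 200, n_cells: int = 300):
    """Log-normalized matrix with one gene at 10x the background variance.

    All genes share exactly the same back-transformed mean (1.0), so the
    dispersion z-score isolates the variance difference.
    """
    rng = np.random.default_rng(seed)
    bg = rng.normal(1.0, 0.05, size=(n_background, n_cells))
    bg += 1.0 - bg.mean(axis=1, keepdims=True)
    pl = rng.normal(1.0, 0.05 * np.sqrt(10), size=(1, n_cells))
    pl += 1.0 - pl.mean()
    vals = np.vstack([bg, pl])
    assert (vals > 0).all()
    genes = [f"G{i:04d}" for i in range(n_background)] + ["PLANTED"]
    cols = [f"C{j:04d}" for j in range(n_cells)]
    return ExpressionMatrix(np.log1p(vals), genes, cols, value_kind="cp10k_log")


def bh_bruteforce(p):
    """Independent step-up BH oracle: sorted p*n/rank, cumulative minimum."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q
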