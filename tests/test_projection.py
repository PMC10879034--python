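import numpy as np
import pytest

from progdecon import (
    DomainError,
    ExpressionMatrix,
    FixedBasisProjector,
    GeneProgramBasis,
    HomologMap,
    POH_THRESHOLD,
    align_to_basis,
    compute_poh,
    convert_species_basis,
    project_expression,
    project_fixed_basis,
)
from progdecon.synthetic import simulate_basis, simulate_expression


def _em(values, genes, kind="raw_count"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values, genes, [f"c{j}" for j in range(values.shape[1])], value_kind=kind
    )


class TestSpeciesConversion:
    def test_rename_keeps_weights(self):
        W = GeneProgramBasis(np.array([[1.0], [2.0]]), ["FOXP3", "CD4"])
        out = convert_species_basis(W, HomologMap([("FOXP3", "Foxp3"), ("CD4", "Cd4")]))
        assert out.gene_ids == ["Foxp3", "Cd4"]
        np.testing.assert_array_equal(out.weights, W.weights)

    def test_first_homolog_wins(self):
        W = GeneProgramBasis(np.array([[1.0]]), ["A"])
        out = convert_species_basis(W, HomologMap([("A", "a1"), ("A", "a2")]))
        assert out.gene_ids == ["a1"]

    def test_unmapped_gene_dropped(self):
        W = GeneProgramBasis(np.array([[1.0], [2.0]]), ["A", "B"])
        out = convert_species_basis(W, HomologMap([("A", "a")]))
        assert out.gene_ids == ["a"]
        np.testing.assert_array_equal(out.weights, [[1.0]])

    def test_target_collision_keeps_first_source(self):
        W = GeneProgramBasis(np.array([[1.0], [2.0]]), ["A", "B"])
        out = convert_species_basis(W, HomologMap([("A", "x"), ("B", "x")]))
        assert out.gene_ids == ["x"]
        np.testing.assert_array_equal(out.weights, [[1.0]])

    def test_empty_results_rejected(self):
        W = GeneProgramBasis(np.array([[1.0]]), ["A"])
        with pytest.raises(DomainError):
            convert_species_basis(W, HomologMap([("Z", "z")]))
        with pytest.raises(DomainError):
            convert_species_basis(W, HomologMap([]))


class TestAlignment:
    def test_intersection_in_query_order(self):
        W = GeneProgramBasis(np.array([[1.0], [2.0], [3.0]]), ["A", "B", "C"])
        X = _em(np.ones((3, 2)), ["C", "B", "D"])
        aligned = align_to_basis(W, X)
        assert aligned.basis.gene_ids == ["C", "B"]
        assert aligned.query.gene_ids == ["C", "B"]
        assert aligned.dropped_basis_genes == ["A"]
        assert aligned.dropped_query_genes == ["D"]
        np.testing.assert_array_equal(aligned.basis.weights[:, 0], [3.0, 2.0])

    def test_disjoint_sets_rejected(self):
        W = GeneProgramBasis(np.ones((2, 1)), ["A", "B"])
        X = _em(np.ones((2, 2)), ["C", "D"])
        with pytest.raises(DomainError):
            align_to_basis(W, X)

    def test_low_overlap_warns_but_succeeds(self):
        rng = np.random.default_rng(0)
        W = GeneProgramBasis(rng.random((30, 3)), [f"g{i}" for i in range(30)])
        X = _em(np.ones((10, 2)), [f"g{i}" for i in range(10)])  # 33% overlap
        with pytest.warns(UserWarning, match="basis genes"):
            aligned = align_to_basis(W, X, min_overlap_fraction=0.5)
        assert aligned.n_overlap_genes == 10
        assert aligned.overlap_fraction_of_basis == pytest.approx(1 / 3)


class TestNnlsProjection:
    def test_hand_worked_exact_column(self, simple_basis):
        X = _em(np.array([[2.0], [3.0], [5.0]]), ["A", "B", "C"])
        res = project_fixed_basis(align_to_basis(simple_basis, X))
        np.testing.assert_allclose(res.activity.values[:, 0], [2.0, 3.0], atol=1e-9)
        assert res.evar_all == pytest.approx(1.0)

    def test_hand_worked_active_set_column(self, simple_basis):
        # unconstrained optimum has a negative coordinate; KKT forces h2=0
        X = _em(np.array([[1.0], [0.0], [0.0]]), ["A", "B", "C"])
        res = project_fixed_basis(align_to_basis(simple_basis, X))
        np.testing.assert_allclose(res.activity.values[:, 0], [0.5, 0.0], atol=1e-9)

    def test_zero_column_maps_to_zero(self, simple_basis):
        X = _em(np.zeros((3, 1)), ["A", "B", "C"])
        res = project_fixed_basis(align_to_basis(simple_basis, X))
        np.testing.assert_array_equal(res.activity.values, 0)

    def test_exact_recovery_noise_free(self):
        W = simulate_basis(100, 5, overlap=0.3, seed=0)
        X, H0 = simulate_expression(W, 50, noise_model="none", seed=0)
        res = project_fixed_basis(align_to_basis(W, X))
        rel = np.linalg.norm(res.activity.values - H0.values) / np.linalg.norm(H0.values)
        assert rel < 1e-6

    def test_monotone_degradation_with_noise(self):
        W = simulate_basis(60, 3, seed=1)
        levels = [0.0, 0.5, 2.0]
        means = []
        for scale in levels:
            evs = []
            for seed in range(20):
                X, _ = simulate_expression(
                    W, 20, noise_model="gaussian_clipped", noise_scale=scale, seed=seed
                )
                evs.append(project_fixed_basis(align_to_basis(W, X)).evar_all)
            means.append(np.mean(evs))
        assert means[0] > means[1] > means[2]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        W = simulate_basis(40, 4, overlap=0.2, seed=2)
        X, _ = simulate_expression(W, 10, noise_model="gaussian_clipped",
                                   noise_scale=0.1, seed=2)
        base = project_fixed_basis(align_to_basis(W, X)).activity.values
        cperm = rng.permutation(4)
        Wp = GeneProgramBasis(
            W.weights[:, cperm], list(W.gene_ids),
            [W.component_ids[c] for c in cperm],
        )
        permuted = project_fixed_basis(align_to_basis(Wp, X)).activity.values
        np.testing.assert_allclose(permuted, base[cperm], atol=1e-8)
        jperm = rng.permutation(10)
        Xp = ExpressionMatrix(
            X.values[:, jperm], list(X.gene_ids),
            [X.column_ids[j] for j in jperm],
        )
        colperm = project_fixed_basis(align_to_basis(W, Xp)).activity.values
        np.testing.assert_allclose(colperm, base[:, jperm], atol=1e-8)

    def test_rank_deficient_basis_warns(self):
        w = np.random.default_rng(3).random(5)
        W = GeneProgramBasis(np.column_stack([w, w]), [f"g{i}" for i in range(5)])
        X = _em(np.ones((5, 1)), [f"g{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = project_fixed_basis(align_to_basis(W, X))
        assert res.activity.values.min() >= 0


class TestPoh:
    def test_half_overlap(self):
        W = GeneProgramBasis(np.ones((4, 1)), ["A", "B", "X", "Y"])
        assert compute_poh(["A", "B", "C", "D"], W) == 0.5

    def test_subset_is_one(self):
        W = GeneProgramBasis(np.ones((4, 1)), ["A", "B", "C", "D"])
        assert compute_poh(["A", "B"], W) == 1.0

    def test_disjoint_is_zero(self):
        W = GeneProgramBasis(np.ones((2, 1)), ["A", "B"])
        assert compute_poh(["C", "D"], W) == 0.0

    def test_empty_rejected(self):
        W = GeneProgramBasis(np.ones((2, 1)), ["A", "B"])
        with pytest.raises(DomainError):
            compute_poh([], W)

    def test_bounds_and_universe_mode(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            genes = [f"g{i}" for i in rng.choice(100, size=20, replace=False)]
            W = GeneProgramBasis(
                np.ones((10, 1)), genes[:10], hvg_universe=frozenset(genes)
            )
            poh = compute_poh(genes[5:15], W)
            assert 0.0 <= poh <= 1.0
            assert compute_poh(genes[5:15], W, use_hvg_universe=True) == 1.0


class TestProjectExpression:
    def test_end_to_end_with_species_map(self):
        # basis genes embedded in a larger query so the query has its own HVGs
        W = simulate_basis(120, 3, seed=5)
        X, _ = simulate_expression(W, 30, noise_model="poisson", seed=5,
                                   target_column_sum=2000)
        rng = np.random.default_rng(5)
        lam = rng.gamma(2.0, 0.5, size=(2000, 1))
        bg = rng.poisson(lam, size=(2000, 30)).astype(float)
        genes = [g.lower() for g in X.gene_ids] + [f"bg{i:04d}" for i in range(2000)]
        Xm = ExpressionMatrix(np.vstack([X.values, bg]), genes, list(X.column_ids))
        hmap = HomologMap([(g, g.lower()) for g in W.gene_ids])
        res = project_expression(W, Xm, species_map=hmap)
        assert res.n_overlap_genes == 120
        assert res.activity.values.shape == (3, 30)
        assert 0 <= res.poh <= 1
        assert res.low_poh == (res.poh < POH_THRESHOLD)

    def test_single_column_query_has_no_poh(self):
        W = simulate_basis(50, 2, seed=6)
        X, _ = simulate_expression(W, 1, noise_model="none", seed=6)
        res = project_expression(W, X)
        assert np.isnan(res.poh)
        assert any("POH not computed" in w for w in res.warnings)

    def test_unknown_normalize_mode_rejected(self):
        W = simulate_basis(50, 2, seed=7)
        X, _ = simulate_expression(W, 3, seed=7)
        with pytest.raises(DomainError):
            project_expression(W, X, normalize="zscore")


class TestFixedBasisProjectorEstimator:
    def test_sklearn_api_and_agreement(self):
        from sklearn.base import clone

        W = simulate_basis(40, 3, seed=8)
        X, _ = simulate_expression(W, 12, noise_model="gaussian_clipped",
                                   noise_scale=0.1, seed=8)
        est = clone(FixedBasisProjector(basis=W))
        A = est.fit_transform(X.values.T)
        ref = project_fixed_basis(align_to_basis(W, X)).activity.values
        np.testing.assert_allclose(A.T, ref, atol=1e-10)

    def test_negative_query_rejected(self):
        W = simulate_basis(40, 3, seed=9)
        est = FixedBasisProjector(basis=W).fit(np.ones((2, 40)))
        with pytest.raises(DomainError):
            est.transform(-np.ones((2, 40)))
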