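"""PLS1 association: closed form, permutation inference, bootstrap z-scores."""

import numpy as np
import pandas as pd
import pytest

from morphotx import (
    ExpressionMatrix,
    bootstrap_gene_stats,
    fit_pls1,
    generate_spins,
    permutation_test_variance,
    top_gene_map_correlation,
    z_normalize,
)


def _centered(rng, n=20, p=30):
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    y = rng.normal(size=n)
    y -= y.mean()
    return X, y


class TestFitPls1:
    def test_hand_chosen_integer_matrix(self):
        X = np.array(
            [[1, 0, 2], [0, 1, -1], [2, 1, 0], [-1, 2, 1], [0, -2, 3]], dtype=float
        )
        y = np.array([2.0, -1.0, 1.0, 0.0, 3.0])
        w, scores, ve = fit_pls1(X, y)
        ref = X.T @ y
        ref = ref / np.linalg.norm(ref)
        assert w == pytest.approx(ref, abs=1e-10)
        assert scores == pytest.approx(X @ ref, abs=1e-10)

    def test_matches_sklearn_first_component(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        for _ in range(10):
            X, y = _centered(rng)
            w, _, _ = fit_pls1(X, y)
            ref = PLSRegression(n_components=1, scale=False).fit(X, y).x_weights_[:, 0]
            cos = abs(w @ ref) / np.linalg.norm(ref)
            assert cos > 0.999999

    def test_single_driver_gene_dominates(self, rng):
        n = 40
        y = rng.normal(size=n)
        y -= y.mean()
        noise = 1e-6 * rng.normal(size=(n, 9))
        X = np.column_stack([y, noise])
        w, _, ve = fit_pls1(X, y)
        assert np.argmax(np.abs(w)) == 0
        assert ve == pytest.approx(1.0, abs=1e-6)

    def test_region_reordering_invariance(self, rng):
        X, y = _centered(rng)
        w0, _, ve0 = fit_pls1(X, y)
        perm = rng.permutation(len(y))
        w1, _, ve1 = fit_pls1(X[perm], y[perm])
        assert w1 == pytest.approx(w0)
        assert ve1 == pytest.approx(ve0)

    def test_score_sign_convention(self, rng):
        X, y = _centered(rng)
        _, scores, _ = fit_pls1(X, y)
        assert np.corrcoef(scores, y)[0, 1] >= 0

    def test_degenerate_inputs_rejected(self, rng):
        X, y = _centered(rng)
        with pytest.raises(ValueError):
            fit_pls1(X[:10], y)
        with pytest.raises(ValueError):
            fit_pls1(X, np.zeros_like(y))


class TestPermutationTestVariance:
    def test_exact_association_gives_minimal_p(self, rng):
        n = 30
        y = rng.normal(size=n)
        y -= y.mean()
        X = np.column_stack([y, 1e-8 * rng.normal(size=(n, 5))])
        p = permutation_test_variance(X, y, n_perm=99, null_scheme="shuffle", seed=1)
        assert p == pytest.approx(1.0 / 100.0)

    def test_p_respects_smoothing_floor(self, rng):
        X, y = _centered(rng)
        for seed in range(5):
            p = permutation_test_variance(X, y, n_perm=49, null_scheme="shuffle", seed=seed)
            assert p >= 1.0 / 50.0

    def test_spin_scheme_requires_spins(self, rng):
        X, y = _centered(rng)
        with pytest.raises(ValueError, match="SpinNull"):
            permutation_test_variance(X, y, null_scheme="spin")

    def test_spin_scheme_runs_on_atlas_maps(self, cortex_only_atlas, rng):
        n = cortex_only_atlas.n_regions
        spins = generate_spins(cortex_only_atlas, n_perm=99, seed=2)
        X = rng.normal(size=(n, 40))
        y = rng.normal(size=n)
        p = permutation_test_variance(X, y, n_perm=99, spins=spins)
        assert 1.0 / 100.0 <= p <= 1.0


class TestBootstrapGeneStats:
    def test_duplicated_column_gets_equal_stats(self, rng):
        X, y = _centered(rng, n=30, p=10)
        X[:, 1] = X[:, 0]
        res = bootstrap_gene_stats(X, y, n_boot=200, seed=3)
        tab = res.gene_table
        assert tab.loc[0, "weight"] == pytest.approx(tab.loc[1, "weight"])
        assert tab.loc[0, "z"] == pytest.approx(tab.loc[1, "z"], rel=1e-8)

    def test_scale_invariance_through_z_normalization(self, rng):
        X, y = _centered(rng, n=25, p=8)
        a = bootstrap_gene_stats(X, y, n_boot=150, seed=4).gene_table
        b = bootstrap_gene_stats(2.0 * X, 5.0 * y, n_boot=150, seed=4).gene_table
        assert a["z"].to_numpy() == pytest.approx(b["z"].to_numpy())

    def test_planted_gene_has_positive_z(self, rng):
        n = 60
        y = rng.normal(size=n)
        X = np.column_stack([y + 0.01 * rng.normal(size=n), rng.normal(size=(n, 20))])
        res = bootstrap_gene_stats(X, y, n_boot=300, seed=5)
        tab = res.gene_table
        assert tab.loc[0, "z"] > 0
        assert tab.loc[0, "abs_z"] == tab["abs_z"].max()
        assert res.pls_plus[0] == tab.loc[0, "gene"]

    def test_lists_are_disjoint_and_ranked(self, rng):
        n = 80
        y = rng.normal(size=n)
        signal = np.outer(y, rng.normal(size=15)) + 0.5 * rng.normal(size=(n, 15))
        X = np.column_stack([signal, rng.normal(size=(n, 30))])
        res = bootstrap_gene_stats(X, y, n_boot=300, seed=6)
        plus, minus = res.pls_plus, res.pls_minus
        assert set(plus).isdisjoint(minus)
        tab = res.gene_table.set_index("gene")
        for lst in (plus, minus):
            zs = tab.loc[lst, "abs_z"].to_numpy()
            assert np.all(np.diff(zs) <= 1e-12)

    def test_small_bootstrap_rejected(self, rng):
        X, y = _centered(rng)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_gene_stats(X, y, n_boot=50)


class TestTopGeneMapCorrelation:
    def test_gene_equal_to_map_ranks(self, cortex_only_atlas, rng):
        n = cortex_only_atlas.n_regions
        y = rng.normal(size=n)
        vals = pd.DataFrame(
            {"GTOP": np.argsort(np.argsort(y)).astype(float), "GOTH": rng.normal(size=n)},
            index=pd.Index(cortex_only_atlas.region_ids, name="region_id"),
        )
        expr = ExpressionMatrix(vals)
        spins = generate_spins(cortex_only_atlas, n_perm=99, seed=9)
        rho, p = top_gene_map_correlation("GTOP", expr, y, spins)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 100.0)

    def test_unknown_gene_rejected(self, cortex_only_atlas, rng):
        vals = pd.DataFrame(
            {"G1": rng.normal(size=cortex_only_atlas.n_regions)},
            index=pd.Index(cortex_only_atlas.region_ids),
        )
        spins = generate_spins(cortex_only_atlas, n_perm=10, seed=1)
        with pytest.raises(ValueError, match="unknown gene"):
            top_gene_map_correlation("NOPE", ExpressionMatrix(vals), vals["G1"].to_numpy(), spins)
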