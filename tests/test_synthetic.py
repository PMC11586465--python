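"""Synthetic generators: atlas geometry, cohort model, planted structure."""

import numpy as np
import pandas as pd
import pytest

from morphotx import (
    AtrophySpec,
    CovariateParams,
    case_control_map,
    make_atlas,
    simulate_cohort,
    simulate_expression,
    simulate_gene_sets,
    simulate_receptor_map,
    spearman_correlation,
)
from morphotx.synthetic import spatial_covariance


class TestMakeAtlas:
    def test_study_scale_atlas(self):
        atlas = make_atlas(152, 7, seed=1, n_cortical_right_hemi=156)
        assert atlas.n_regions == 322
        assert atlas.mask(hemisphere="left").sum() == 159
        assert atlas.mask(tissue_class="cortical").sum() == 308

    def test_centroids_on_unit_sphere(self):
        atlas = make_atlas(7, 0, seed=1)
        assert atlas.n_regions == 14
        norms = np.linalg.norm(atlas.centroids(), axis=1)
        assert norms == pytest.approx(np.ones(14), abs=1e-9)

    def test_deterministic_under_seed(self):
        a = make_atlas(20, 2, seed=7).table.to_csv()
        b = make_atlas(20, 2, seed=7).table.to_csv()
        assert a == b

    def test_labels_cover_all_networks(self, small_atlas):
        for side in ("left", "right"):
            cort = small_atlas.table[
                (small_atlas.table.hemisphere == side)
                & (small_atlas.table.tissue_class == "cortical")
            ]
            assert cort.yeo_label.nunique() == 7
            assert cort.veconomo_label.nunique() == 7

    def test_hemispheres_separated(self, small_atlas):
        t = small_atlas.table
        cort = t[t.tissue_class == "cortical"]
        assert (cort.loc[cort.hemisphere == "left", "cx"] < 0).all()
        assert (cort.loc[cort.hemisphere == "right", "cx"] > 0).all()

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            make_atlas(5, 0, seed=1)


class TestSimulateCohort:
    def test_degenerate_noise_recovers_baselines(self, small_atlas):
        params = CovariateParams(beta_age=0, beta_sex=0, beta_tiv=0, noise_sd=0)
        subj = simulate_cohort(small_atlas, {"HC": 5, "FBTCS-": 3}, covariate_params=params, seed=4)
        gmv = subj.gmv()
        assert np.allclose(gmv.std(axis=0), 0.0, atol=1e-12)

    def test_unknown_group_rejected(self, small_atlas):
        with pytest.raises(ValueError, match="unknown group"):
            simulate_cohort(small_atlas, {"HC": 5, "XYZ": 3})

    def test_hc_atrophy_rejected(self, small_atlas):
        with pytest.raises(ValueError, match="controls"):
            simulate_cohort(
                small_atlas, {"HC": 5}, atrophy_specs={"HC": AtrophySpec((0,), 1.0)}
            )

    def test_deterministic_under_seed(self, small_atlas):
        a = simulate_cohort(small_atlas, {"HC": 6, "FBTCS+": 6}, seed=9).table
        b = simulate_cohort(small_atlas, {"HC": 6, "FBTCS+": 6}, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_null_group_t_centered_at_zero(self, small_atlas):
        tvals = []
        for s in range(40):
            subj = simulate_cohort(small_atlas, {"HC": 20, "FBTCS-": 10, "FBTCS+": 10}, seed=s)
            tvals.append(case_control_map(subj, "TLE").t_values)
        mean_t = np.mean(tvals)
        # SE of the grand mean ~ 1/sqrt(n_sims * n_regions_eff); allow generous slack
        assert abs(mean_t) < 0.1

    def test_planted_regions_rank_most_negative(self):
        atlas = make_atlas(30, 0, seed=5)
        planted = tuple(range(10))
        spec = AtrophySpec(planted, effect_size=2.0)
        hits = 0
        n_sims = 25
        for s in range(n_sims):
            subj = simulate_cohort(
                atlas,
                {"HC": 60, "FBTCS-": 37, "FBTCS+": 89},
                atrophy_specs={"FBTCS-": spec, "FBTCS+": spec},
                seed=100 + s,
            )
            t = case_control_map(subj, "TLE").t_values
            worst10 = set(np.argsort(t)[:10].tolist())
            if worst10 == set(planted):
                hits += 1
        assert hits >= int(0.95 * n_sims)

    def test_noise_autocorrelation_decays_with_angle(self, cortex_only_atlas):
        # empirical inter-region correlation of pure noise vs centroid angle
        K = spatial_covariance(cortex_only_atlas, corr_length=0.3)
        rng = np.random.default_rng(0)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(K.shape[0]))
        draws = (L @ rng.standard_normal((K.shape[0], 2000))).T
        corr = np.corrcoef(draws.T)
        C = cortex_only_atlas.centroids()
        theta = np.arccos(np.clip(C @ C.T, -1, 1))
        iu = np.triu_indices_from(corr, k=1)
        res = spearman_correlation(theta[iu], np.abs(corr[iu]))
        assert res.statistic < -0.5


class TestSimulateExpression:
    def _target(self, atlas):
        left = atlas.region_ids[atlas.mask(hemisphere="left")]
        rng = np.random.default_rng(1)
        return pd.Series(rng.normal(size=left.size), index=left)

    def test_full_alignment_is_exact(self, small_atlas):
        target = self._target(small_atlas)
        expr = simulate_expression(small_atlas, 20, target, n_aligned=5, alignment_strength=1.0, seed=2)
        left_rows = expr.values.loc[target.index]
        for g in expr.genes[:5]:
            r = np.corrcoef(left_rows[g], target)[0, 1]
            assert abs(r) == pytest.approx(1.0)

    def test_no_alignment_leaves_no_signal(self, small_atlas):
        target = self._target(small_atlas)
        expr = simulate_expression(small_atlas, 400, target, n_aligned=200, alignment_strength=0.0, seed=3)
        left = expr.values.loc[target.index]
        rs = np.array(
            [abs(spearman_correlation(left[g].to_numpy(), target.to_numpy()).statistic) for g in expr.genes]
        )
        aligned, rest = rs[:200], rs[200:]
        assert abs(aligned.mean() - rest.mean()) < 0.05

    def test_strength_out_of_range_rejected(self, small_atlas):
        with pytest.raises(ValueError):
            simulate_expression(small_atlas, 10, self._target(small_atlas), 2, alignment_strength=1.5)

    def test_deterministic_under_seed(self, small_atlas):
        target = self._target(small_atlas)
        a = simulate_expression(small_atlas, 15, target, 3, 0.5, seed=8).values
        b = simulate_expression(small_atlas, 15, target, 3, 0.5, seed=8).values
        pd.testing.assert_frame_equal(a, b)


class TestSimulateGeneSets:
    def test_planted_fraction_controls_intersection(self):
        universe = [f"G{i:04d}" for i in range(500)]
        planted = universe[:100]
        sets = simulate_gene_sets(universe, planted, n_sets=20, planted_fraction=0.5, seed=1, set_size=60)
        for gs in sets:
            assert len(gs.genes) == 60
            assert len(set(gs.genes) & set(planted)) == 30

    def test_zero_fraction_draws_uniformly(self):
        universe = [f"G{i}" for i in range(200)]
        sets = simulate_gene_sets(universe, (), n_sets=3, planted_fraction=0.0, seed=2, set_size=20)
        assert all(len(set(gs.genes)) == 20 for gs in sets)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_sets(["a", "b"], (), 1, planted_fraction=-0.1)

    def test_planted_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_sets(["a", "b"], ["zzz"], 1, planted_fraction=0.5, set_size=2)


class TestSimulateReceptorMap:
    def test_perfect_correlation(self, rng):
        ref = pd.Series(rng.normal(size=50))
        rec = simulate_receptor_map(ref, target_rho=1.0, seed=1)
        assert spearman_correlation(ref.to_numpy(), rec.to_numpy()).statistic == pytest.approx(1.0)

    def test_zero_target_is_unbiased(self, rng):
        ref = pd.Series(rng.normal(size=322))
        rs = [
            spearman_correlation(
                ref.to_numpy(), simulate_receptor_map(ref, 0.0, seed=s).to_numpy()
            ).statistic
            for s in range(500)
        ]
        assert abs(np.mean(rs)) < 0.01

    def test_moderate_target_realized_within_band(self, rng):
        ref = pd.Series(rng.normal(size=322))
        rs = np.array(
            [
                spearman_correlation(
                    ref.to_numpy(), simulate_receptor_map(ref, 0.24, seed=s).to_numpy()
                ).statistic
                for s in range(200)
            ]
        )
        assert np.mean((rs >= 0.10) & (rs <= 0.38)) >= 0.95
        assert np.mean(rs) == pytest.approx(0.24, abs=0.02)

    def test_invalid_rho_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_receptor_map(pd.Series(rng.normal(size=20)), 1.2)
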