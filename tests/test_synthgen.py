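"""Generator contracts: spatial structure, planted effects, determinism."""

import numpy as np
import pytest

from netatrophy import (
    SynthConfig,
    make_clinical_latent,
    make_expression_atlas,
    make_planted_atrophy,
    make_spatial_connectome,
    make_voxel_cohort,
    node_neighbour_correlation,
)
from netatrophy.synthgen import sphere_points


class TestSynthConfig:
    @pytest.mark.parametrize("kwargs", [
        {"density": 0.0}, {"density": 1.5}, {"spread_weight": -0.1},
        {"latent_corr": 2.0}, {"noise_sd": -1.0}, {"n_sites": 0},
        {"seed_region": 500},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)


class TestSpatialConnectome:
    def test_construction_contract(self):
        cfg = SynthConfig(n_parcels=50, density=0.2, distance_decay=2.0,
                          rng_seed=1)
        net = make_spatial_connectome(cfg)
        w = net.weights
        assert w.shape == (50, 50)
        np.testing.assert_array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        n_edges = (w > 0).sum() // 2
        # target density 0.2 of 1225 pairs = 245 edges, realized within +/-20%
        assert 0.8 * 245 <= n_edges <= 1.2 * 245
        assert np.all(w[w != 0] > 0)
        assert net.is_connected()

    def _logistic_slope(self, net):
        from sklearn.linear_model import LogisticRegression

        iu, ju = np.triu_indices(net.n_parcels, k=1)
        d = np.linalg.norm(net.coordinates[iu] - net.coordinates[ju], axis=1)
        present = (net.weights[iu, ju] > 0).astype(int)
        clf = LogisticRegression(C=1e6).fit(d[:, None], present)
        return clf.coef_[0, 0]

    def test_zero_decay_gives_flat_edge_probability(self):
        cfg = SynthConfig(n_parcels=80, density=0.2, distance_decay=0.0,
                          rng_seed=2)
        slope = self._logistic_slope(make_spatial_connectome(cfg))
        assert abs(slope) < 0.4

    def test_positive_decay_gives_negative_logistic_slope(self):
        cfg = SynthConfig(n_parcels=80, density=0.2, distance_decay=2.0,
                          rng_seed=3)
        assert self._logistic_slope(make_spatial_connectome(cfg)) < -0.5

    def test_unreachable_density_fails_with_parameters_named(self):
        cfg = SynthConfig(n_parcels=10, density=0.02, rng_seed=4)
        with pytest.raises(RuntimeError, match="density=0.02"):
            make_spatial_connectome(cfg, max_retries=3)

    def test_seed_determinism(self):
        cfg = SynthConfig(n_parcels=40, rng_seed=9)
        a = make_spatial_connectome(cfg)
        b = make_spatial_connectome(cfg)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)


class TestPlantedAtrophy:
    def test_pure_indicator_when_no_spread_no_noise(self, small_net, rng):
        obs, truth = make_planted_atrophy(small_net, 5, 0.0, 0.0, rng)
        expected = np.zeros(small_net.n_parcels)
        expected[5] = 1.0
        np.testing.assert_array_equal(obs, expected)
        np.testing.assert_array_equal(truth, expected)

    @pytest.mark.parametrize("spread_weight", [0.3, 0.7, 1.0])
    def test_seed_attains_maximum_without_noise(self, small_net, rng,
                                                spread_weight):
        obs, _ = make_planted_atrophy(small_net, 12, spread_weight, 0.0, rng)
        assert obs.argmax() == 12

    def test_isolated_seed_fails(self, rng):
        from netatrophy.network import WeightedNetwork

        w = np.zeros((12, 12))
        w[1:4, 1:4] = 1.0
        np.fill_diagonal(w, 0)
        net = WeightedNetwork(w)
        with pytest.raises(ValueError, match="isolated"):
            make_planted_atrophy(net, 0, 0.5, 0.1, rng)

    def test_node_neighbour_correlation_positive_across_replicates(self):
        positives = 0
        for rep in range(50):
            cfg = SynthConfig(n_parcels=80, rng_seed=300 + rep)
            net = make_spatial_connectome(cfg)
            rng = np.random.default_rng(rep)
            obs, _ = make_planted_atrophy(net, 3, 0.7, 0.1, rng)
            r, *_ = node_neighbour_correlation(net, obs)
            positives += r > 0
        assert positives >= 48


class TestVoxelCohort:
    def _labels(self, n_parcels=20, per=5):
        return np.repeat(np.arange(1, n_parcels + 1), per)

    def test_zero_noise_zero_effect_gives_zero_wscores(self):
        from netatrophy import compute_wscores, fit_normative_model

        cfg = SynthConfig(n_parcels=20, n_controls=30, n_patients=10,
                          rng_seed=5)
        cohort = make_voxel_cohort(cfg, np.ones(20), self._labels(),
                                   effect_scale=0.0, noise_sd=0.0)
        # degenerate voxels (residual sd 0) excluded: add tiny noise to sd only
        model = fit_normative_model(cohort)
        w = compute_wscores(cohort, model, target_group=1).values
        # with exact linear data residual sd is 0 -> all NaN (flagged); the
        # patients deviate by exactly 0 before standardization
        expected = cohort.values[cohort.group == 1] - model.predict(
            cohort.subset(cohort.group == 1)
        )
        np.testing.assert_allclose(expected, 0.0, atol=1e-10)
        assert np.all(np.isnan(w))

    def test_controls_never_receive_group_effect(self):
        cfg = SynthConfig(n_parcels=20, n_controls=30, n_patients=10,
                          rng_seed=6)
        a = make_voxel_cohort(cfg, np.zeros(20), self._labels())
        b = make_voxel_cohort(cfg, 10.0 * np.ones(20), self._labels())
        ctrl = a.group == 0
        np.testing.assert_array_equal(a.values[ctrl], b.values[ctrl])
        assert not np.allclose(a.values[~ctrl], b.values[~ctrl])

    def test_age_slope_recovered_within_3_se(self):
        cfg = SynthConfig(n_parcels=10, n_controls=90, n_patients=5,
                          n_sites=1, rng_seed=7)
        beta_age = -0.002
        cohort = make_voxel_cohort(cfg, np.zeros(10),
                                   self._labels(10), beta_age=beta_age,
                                   noise_sd=0.02)
        ctrl = cohort.group == 0
        X = np.column_stack([cohort.age[ctrl],
                             np.asarray(cohort.sex[ctrl], float),
                             np.ones(ctrl.sum())])
        # normal-equations oracle
        beta = np.linalg.solve(X.T @ X, X.T @ cohort.values[ctrl])
        resid = cohort.values[ctrl] - X @ beta
        sigma2 = (resid**2).sum(axis=0) / (ctrl.sum() - 3)
        se_age = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[0, 0])
        # noise is independent across voxels, so pool the per-voxel estimates
        n_vox = beta.shape[1]
        pooled_se = se_age.mean() / np.sqrt(n_vox)
        assert abs(beta[0].mean() - beta_age) < 3 * pooled_se
        # and no single voxel should be a gross outlier
        assert np.all(np.abs(beta[0] - beta_age) < 6 * se_age)

    def test_too_few_controls_per_site_fails(self):
        cfg = SynthConfig(n_parcels=5, n_controls=5, n_patients=5, n_sites=3,
                          rng_seed=8)
        with pytest.raises(ValueError, match="controls"):
            make_voxel_cohort(cfg, np.zeros(5), self._labels(5, 2))


class TestClinicalLatent:
    def test_perfect_latent_gives_rank_one_cross_covariance(self):
        from netatrophy import fit_pls

        cfg = SynthConfig(n_patients=40, n_parcels=30, n_measures=6,
                          latent_corr=1.0, rng_seed=9)
        rng = np.random.default_rng(0)
        X, table, _ = make_clinical_latent(cfg, rng, brain_noise_sd=0.0,
                                           behavior_noise_sd=0.0)
        model = fit_pls(X, table.data.to_numpy(), preprocessing="center")
        assert model.cov_explained_[0] == pytest.approx(1.0, abs=1e-10)

    def test_score_correlation_matches_planted_value(self):
        rs = []
        for rep in range(100):
            cfg = SynthConfig(n_patients=80, latent_corr=0.6,
                              rng_seed=rep)
            rng = np.random.default_rng([rep, 3])
            X, table, truth = make_clinical_latent(cfg, rng)
            bs = X @ truth.latent_brain_weights
            hs = table.data.to_numpy() @ truth.latent_behavior_weights
            rs.append(np.corrcoef(bs, hs)[0, 1])
        # planted rho = 0.6, mildly attenuated by measurement noise
        assert abs(np.mean(rs) - 0.6) < 0.05

    def test_invalid_latent_corr_fails(self):
        with pytest.raises(ValueError):
            SynthConfig(latent_corr=1.2)

    def test_missingness_injected_at_requested_rate(self, rng):
        cfg = SynthConfig(n_patients=200, n_measures=10, rng_seed=10)
        _, table, _ = make_clinical_latent(cfg, rng, missing_rate=0.2)
        frac = table.data.isna().to_numpy().mean()
        assert 0.15 < frac < 0.25
        assert not table.data.isna().all().any()

    def test_unit_norm_planted_weights(self, rng):
        cfg = SynthConfig(n_patients=30, rng_seed=11)
        _, _, truth = make_clinical_latent(cfg, rng)
        assert np.linalg.norm(truth.latent_brain_weights) == pytest.approx(1.0)
        assert np.linalg.norm(truth.latent_behavior_weights) == pytest.approx(1.0)


def moran_i(values: np.ndarray, adjacency: np.ndarray) -> float:
    """Moran's I spatial autocorrelation oracle."""
    z = values - values.mean()
    w_sum = adjacency.sum()
    n = values.size
    return (n / w_sum) * (z @ adjacency @ z) / (z @ z)


class TestExpressionAtlas:
    def test_background_genes_spatially_autocorrelated(self, medium_net, rng):
        cfg = SynthConfig(n_parcels=150, rng_seed=12)
        phenotype = rng.standard_normal(150)
        atlas, _, truth = make_expression_atlas(
            cfg, phenotype, rng, coordinates=medium_net.coordinates,
            n_genes=60, n_planted=5,
        )
        adjacency = (medium_net.weights > 0).astype(float)
        background = atlas.expression[:55]
        morans = [moran_i(g, adjacency) for g in background]
        assert np.all(np.array(morans) > 0)

    def test_cloned_gene_correlates_perfectly(self, rng):
        from netatrophy.gcea import ExpressionAtlas, gene_map_correlations

        phenotype = rng.standard_normal(50)
        atlas = ExpressionAtlas(phenotype[None, :], ["CLONE"], np.array([0.5]))
        z, symbols = gene_map_correlations(atlas, phenotype)
        assert symbols == ["CLONE"]
        assert z[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_zero_strength_planted_indistinguishable(self, rng):
        cfg = SynthConfig(n_parcels=100, rng_seed=13)
        coords = sphere_points(100, rng)
        phenotype = rng.standard_normal(100)
        atlas, cats, _ = make_expression_atlas(
            cfg, phenotype, rng, coordinates=coords, planted_strength=0.0,
        )
        from netatrophy.gcea import category_scores, gene_map_correlations

        z, symbols = gene_map_correlations(atlas, phenotype, ds_threshold=-1)
        scores, _ = category_scores(z, symbols, cats)
        background = [v for k, v in scores.items() if k != "planted"]
        spread = np.std(background)
        assert abs(scores["planted"] - np.mean(background)) < 4 * spread + 0.1

    def test_low_ds_fraction_assigned(self, rng):
        cfg = SynthConfig(n_parcels=60, rng_seed=14)
        atlas, _, _ = make_expression_atlas(
            cfg, rng.standard_normal(60), rng, n_genes=100, n_planted=10,
            low_ds_fraction=0.3,
        )
        n_low = (atlas.differential_stability[:90] < 0.1).sum()
        assert n_low == 27  # 30% of the 90 background genes
        assert np.all(atlas.differential_stability[90:] >= 0.1)

    def test_oversized_planted_category_fails(self, rng):
        cfg = SynthConfig(n_parcels=30, rng_seed=15)
        with pytest.raises(ValueError, match="larger than gene pool"):
            make_expression_atlas(cfg, np.zeros(30), rng, n_genes=10,
                                  n_planted=11)
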