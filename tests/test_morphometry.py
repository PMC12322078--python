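"""Normative model, w-scores, parcellation, tract and class tests."""

import numpy as np
import pytest

from netatrophy import (
    NormativeModel,
    SynthConfig,
    VoxelCohort,
    class_enrichment,
    compute_wscores,
    fit_normative_model,
    make_voxel_cohort,
    parcellate,
    tract_atrophy_test,
)
from netatrophy.morphometry import WScoreMap
from netatrophy.synthgen import sphere_points


def tiny_cohort(n_ctrl=20, n_pat=6, n_vox=8, seed=0, n_sites=2):
    rng = np.random.default_rng(seed)
    n = n_ctrl + n_pat
    age = rng.uniform(40, 80, n)
    sex = rng.integers(0, 2, n)
    site = np.tile(np.arange(n_sites), n // n_sites + 1)[:n]
    group = np.r_[np.zeros(n_ctrl, int), np.ones(n_pat, int)]
    values = (1.0 - 0.003 * age[:, None] + 0.05 * sex[:, None]
              + rng.normal(0, 0.05, (n, n_vox)))
    return VoxelCohort(values, age, sex, site, group)


class TestVoxelCohortValidation:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="age length"):
            VoxelCohort(np.zeros((4, 2)), np.zeros(3), np.zeros(4),
                        np.zeros(4), np.zeros(4))

    def test_nonfinite_values_rejected(self):
        v = np.zeros((6, 2))
        v[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            VoxelCohort(v, np.ones(6), np.zeros(6), np.zeros(6),
                        np.zeros(6, int))

    def test_missing_age_rejected(self):
        age = np.array([50.0, np.nan, 60.0, 55.0])
        with pytest.raises(ValueError, match="age"):
            VoxelCohort(np.zeros((4, 2)), age, np.zeros(4), np.zeros(4),
                        np.zeros(4, int))

    def test_too_few_controls_in_a_site_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3 controls"):
            VoxelCohort(np.zeros((6, 2)), np.ones(6), np.zeros(6),
                        np.array([0, 0, 0, 1, 1, 1]),
                        np.array([0, 0, 0, 0, 0, 1]))


class TestNormativeModel:
    def test_exactly_recovers_noiseless_linear_law(self):
        rng = np.random.default_rng(1)
        n = 24
        age = rng.uniform(40, 80, n)
        sex = rng.integers(0, 2, n)
        values = (2.0 - 0.01 * age[:, None] + 0.3 * sex[:, None]
                  + np.zeros((n, 3)))
        # add one noisy voxel so not everything is degenerate
        values = np.column_stack([values, rng.normal(0, 1, n)])
        cohort = VoxelCohort(values, age, sex, np.zeros(n, int),
                             np.zeros(n, int))
        model = fit_normative_model(cohort)
        beta = model.coef_[0]
        np.testing.assert_allclose(beta[0, :3], -0.01, atol=1e-10)
        np.testing.assert_allclose(beta[1, :3], 0.3, atol=1e-9)
        np.testing.assert_allclose(beta[2, :3], 2.0, atol=1e-8)
        assert model.degenerate_[0][:3].all()
        assert not model.degenerate_[0][3]

    def test_wscore_formula_hand_oracle(self):
        """w = -(obs - expected)/sd against a fully hand-computed OLS fit."""
        cohort = tiny_cohort(seed=2)
        model = fit_normative_model(cohort)
        w = compute_wscores(cohort, model, target_group=1).values
        pats = cohort.subset(cohort.group == 1)
        for s in np.unique(pats.site):
            ctrl = (cohort.group == 0) & (cohort.site == s)
            X = np.column_stack([cohort.age[ctrl],
                                 cohort.sex[ctrl].astype(float),
                                 np.ones(ctrl.sum())])
            beta = np.linalg.solve(X.T @ X, X.T @ cohort.values[ctrl])
            sd = (cohort.values[ctrl] - X @ beta).std(axis=0, ddof=1)
            m = pats.site == s
            Xp = np.column_stack([pats.age[m], pats.sex[m].astype(float),
                                  np.ones(m.sum())])
            expected_w = -(pats.values[m] - Xp @ beta) / sd
            np.testing.assert_allclose(w[m], expected_w, atol=1e-10)

    def test_wscores_sign_inverted_for_atrophy(self):
        # a patient with LOWER DBM than the norm must get a POSITIVE w-score
        cohort = tiny_cohort(seed=3)
        values = cohort.values.copy()
        values[cohort.group == 1] -= 1.0
        shifted = VoxelCohort(values, cohort.age, cohort.sex, cohort.site,
                              cohort.group)
        model = fit_normative_model(shifted)
        w = compute_wscores(shifted, model).values
        assert (w > 0).mean() > 0.95

    def test_control_wscores_standardized(self):
        cfg = SynthConfig(n_parcels=30, n_controls=200, n_patients=5,
                          n_sites=1, rng_seed=4)
        labels = np.repeat(np.arange(1, 31), 4)
        cohort = make_voxel_cohort(cfg, np.zeros(30), labels)
        model = fit_normative_model(cohort)
        w = compute_wscores(cohort, model, target_group=0).values
        np.testing.assert_allclose(w.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(w.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_single_sex_site_rejected(self):
        cohort = tiny_cohort(seed=5)
        sex = np.zeros_like(cohort.sex)
        bad = VoxelCohort(cohort.values, cohort.age, sex, cohort.site,
                          cohort.group)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_normative_model(bad)

    def test_unseen_site_rejected_at_predict(self):
        cohort = tiny_cohort(seed=6)
        model = fit_normative_model(cohort)
        other = VoxelCohort(cohort.values, cohort.age, cohort.sex,
                            np.full(cohort.n_subjects, 9), cohort.group)
        with pytest.raises(ValueError, match="absent"):
            model.predict(other)

    def test_voxel_space_mismatch_rejected(self):
        a, b = tiny_cohort(seed=7, n_vox=8), tiny_cohort(seed=7, n_vox=9)
        model = fit_normative_model(a)
        with pytest.raises(ValueError, match="voxel space"):
            compute_wscores(b, model)

    def test_sklearn_get_params_roundtrip(self):
        model = NormativeModel(ddof=0)
        assert model.get_params() == {"ddof": 0}
        assert NormativeModel().set_params(ddof=0).ddof == 0


class TestParcellate:
    def test_hand_oracle_mean_and_background(self):
        labels = np.array([0, 1, 1, 2, 2, 2])
        v = np.array([99.0, 1.0, 3.0, 2.0, 4.0, 6.0])
        np.testing.assert_allclose(parcellate(v, labels), [2.0, 4.0])

    def test_median_and_sum_reductions(self):
        labels = np.array([1, 1, 1])
        v = np.array([1.0, 2.0, 10.0])
        assert parcellate(v, labels, "median") == pytest.approx(2.0)
        assert parcellate(v, labels, "sum") == pytest.approx(13.0)

    def test_stack_input_keeps_subject_axis(self):
        labels = np.array([1, 2, 2])
        v = np.array([[1.0, 2.0, 4.0], [10.0, 20.0, 40.0]])
        np.testing.assert_allclose(parcellate(v, labels),
                                   [[1.0, 3.0], [10.0, 30.0]])

    def test_empty_parcel_is_nan(self):
        labels = np.array([1, 1, 3])
        out = parcellate(np.array([1.0, 2.0, 3.0]), labels)
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [1.5, 3.0])

    @pytest.mark.parametrize("labels,err", [
        (np.array([-1, 0, 1]), "nonnegative"),
        (np.array([0, 0, 0]), "background"),
        (np.array([[1, 2]]), "1-D"),
    ])
    def test_invalid_labels(self, labels, err):
        with pytest.raises(ValueError, match=err):
            parcellate(np.zeros(labels.size), labels)

    def test_unknown_reduction(self):
        with pytest.raises(ValueError, match="reduction"):
            parcellate(np.zeros(2), np.array([1, 1]), "max")


class TestTractAtrophyTest:
    def test_one_sample_matches_scipy_oracle(self, rng):
        from scipy import stats

        w = WScoreMap(rng.normal(0.5, 1.0, (25, 12)))
        labels = np.repeat([1, 2, 3], 4)
        res = tract_atrophy_test(w, labels)
        means = parcellate(w.values, labels)
        for k in range(3):
            ref = stats.ttest_1samp(means[:, k], 0.0)
            assert res["t"][k] == pytest.approx(ref.statistic)
            assert res["p"][k] == pytest.approx(ref.pvalue)
        assert (res["p_fdr"] >= res["p"] - 1e-15).all()

    def test_two_sample_matches_scipy_oracle(self, rng):
        from scipy import stats

        w = WScoreMap(rng.normal(0, 1, (30, 8)))
        labels = np.repeat([1, 2], 4)
        groups = np.r_[np.zeros(15, int), np.ones(15, int)]
        res = tract_atrophy_test(w, labels, two_sample_groups=groups)
        means = parcellate(w.values, labels)
        ref = stats.ttest_ind(means[groups == 0, 0], means[groups == 1, 0])
        assert res["t"][0] == pytest.approx(ref.statistic)

    def test_zero_variance_tract_rejected(self):
        w = WScoreMap(np.ones((5, 3)))
        with pytest.raises(ValueError, match="zero variance"):
            tract_atrophy_test(w, np.array([1, 1, 1]))

    def test_too_few_subjects_rejected(self, rng):
        w = WScoreMap(rng.normal(0, 1, (2, 3)))
        with pytest.raises(ValueError, match="subjects"):
            tract_atrophy_test(w, np.array([1, 1, 1]))


class TestClassEnrichment:
    def test_enriched_class_detected_and_null_classes_calm(self):
        rng = np.random.default_rng(8)
        coords = sphere_points(120, rng)
        classes = rng.integers(0, 4, 120)
        atrophy = rng.normal(0, 0.3, 120)
        atrophy[classes == 2] += 2.0
        res = class_enrichment(atrophy, classes, coords, n_spin=300,
                               rng=np.random.default_rng(9))
        idx = {c: k for k, c in enumerate(res["classes"])}
        assert res["p_fdr"][idx[2]] < 0.05
        assert res["mean"][idx[2]] == pytest.approx(
            atrophy[classes == 2].mean()
        )

    def test_rng_required_and_min_spins(self, rng):
        coords = sphere_points(30, rng)
        with pytest.raises(ValueError, match="rng"):
            class_enrichment(np.zeros(30), np.zeros(30, int), coords)
        with pytest.raises(ValueError, match="n_spin"):
            class_enrichment(np.zeros(30), np.zeros(30, int), coords,
                             n_spin=10, rng=rng)
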