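"""Metric matrix, PCA, Ward clustering and cluster summaries."""

import numpy as np
import pytest

from comorbtraj import (
    ArchetypeSpec,
    GeeFit,
    SimConfig,
    TrajectoryGEE,
    build_metric_matrix,
    cluster_comorbidities,
    cluster_summary,
    run_pca,
    simulate_panel,
    ward_cluster,
)


def _fit(label, alpha, p_alpha, gamma, p_gamma):
    return GeeFit(label=label, params=np.array([0.0, alpha, 0.0, gamma]),
                  cov=np.eye(4) * 0.01, converged=True, correlation="independence",
                  working_R=None, t_bar=3.0, n_members=10, n_obs=50,
                  p_alpha_centered=p_alpha, p_gamma=p_gamma)


class TestMetricMatrix:
    def test_signed_log10_evidence(self):
        m = build_metric_matrix([_fit("401", 0.7, 0.001, -0.2, 1.0)])
        np.testing.assert_allclose(m.values[0], [0.7, 3.0, -0.2, 0.0], atol=1e-12)

    def test_unsigned_option(self):
        m = build_metric_matrix([_fit("401", -0.7, 0.001, 0.2, 0.01)], signed=False)
        np.testing.assert_allclose(m.values[0], [-0.7, 3.0, 0.2, 2.0], atol=1e-12)

    def test_zero_pvalue_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            m = build_metric_matrix([_fit("401", 0.7, 0.0, 0.2, 0.5)])
        assert m.values[0, 1] == pytest.approx(300.0)

    def test_non_converged_fit_rejected(self):
        bad = _fit("401", 0.7, 0.5, 0.2, 0.5)
        bad.converged = False
        with pytest.raises(ValueError):
            build_metric_matrix([bad])


class TestPca:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        _, _, var, _ = run_pca(rng.normal(size=(177, 4)))
        assert var.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(var) <= 1e-12).all()

    def test_rank_one_input_loads_on_single_component(self):
        u = np.linspace(-1, 1, 50)[:, None]
        data = u @ np.array([[1.0, 2.0, -1.0, 0.5]])
        _, _, var, _ = run_pca(data, standardize=False)
        assert var[0] == pytest.approx(1.0, abs=1e-12)

    def test_orthonormal_loadings_and_exact_reconstruction(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(177, 4))
        scores, loadings, _, kept = run_pca(data, standardize=True)
        assert np.abs(loadings.T @ loadings - np.eye(4)).max() < 1e-10
        z = (data - data.mean(0)) / data.std(0, ddof=1)
        assert np.abs(scores @ loadings.T - (z - z.mean(0))).max() < 1e-8

    def test_zero_variance_column_dropped_when_standardizing(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(30, 4))
        data[:, 2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, loadings, var, kept = run_pca(data, standardize=True)
        assert kept == [0, 1, 3]
        assert scores.shape == (30, 3)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((1, 4)))


class TestWardCluster:
    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(4)
        blob1 = rng.normal(0, 0.1, size=(20, 3))
        blob2 = rng.normal(5, 0.1, size=(15, 3))
        Z, labels = ward_cluster(np.vstack([blob1, blob2]), k=2)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(5)
        Z, _ = ward_cluster(rng.normal(size=(40, 4)), k=3)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(6)
        _, labels = ward_cluster(rng.normal(size=(10, 2)), k=10)
        assert len(set(labels)) == 10

    def test_duplicated_rows_co_cluster(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(12, 3))
        data = np.vstack([base, base[3]])
        for k in range(2, 12):
            _, labels = ward_cluster(data, k=k)
            assert labels[3] == labels[-1]

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((5, 2)), k=6)


@pytest.fixture(scope="module")
def fitted_small_study():
    archetypes = (
        ArchetypeSpec("diverging", -1.2, 1.0, 0.05, 0.4, 6, jitter_sd=0.01),
        ArchetypeSpec("null", -1.0, 0.0, 0.0, 0.0, 6, jitter_sd=0.01),
    )
    panel, truth = simulate_panel(SimConfig(n_pairs=2000, seed=13, archetypes=archetypes))
    results = TrajectoryGEE(panel).fit()
    return panel, truth, results


class TestClusterPipeline:
    def test_planted_archetypes_recovered(self, fitted_small_study):
        from sklearn.metrics import adjusted_rand_score

        _, truth, results = fitted_small_study
        res = cluster_comorbidities(results.converged_fits, k=2)
        assert adjusted_rand_score(truth["archetype"], res.labels) == 1.0
        # cluster 1 = largest median gamma evidence (the diverging archetype)
        diverging = set(truth.loc[truth["archetype"] == "diverging", "comorbidity"])
        ones = {c for c, l in zip(res.comorbidities, res.labels) if l == 1}
        assert ones == diverging

    def test_permutation_invariance(self, fitted_small_study):
        from sklearn.metrics import adjusted_rand_score

        _, _, results = fitted_small_study
        fits = results.converged_fits
        res1 = cluster_comorbidities(fits, k=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(fits))
        res2 = cluster_comorbidities([fits[i] for i in perm], k=2)
        lab2 = dict(zip(res2.comorbidities, res2.labels))
        realigned = [lab2[c] for c in res1.comorbidities]
        assert adjusted_rand_score(res1.labels, realigned) == 1.0

    def test_summary_counts_partition_and_null_or_near_one(self, fitted_small_study):
        _, truth, results = fitted_small_study
        res = cluster_comorbidities(results.converged_fits, k=2)
        summary = cluster_summary(res, results.converged_fits)
        assert summary["n_comorbidities"].sum() == len(res.comorbidities)
        null_row = summary.set_index("cluster").loc[2]
        assert abs(np.log(null_row["or_alpha_median"])) < 0.1
        assert abs(np.log(null_row["or_gamma_median"])) < 0.1

    def test_singleton_cluster_summary_equals_raw_values(self):
        fits = [_fit("401", 0.7, 0.001, 0.3, 0.01), _fit("272", 0.1, 0.5, 0.0, 0.9),
                _fit("300", 0.12, 0.4, 0.01, 0.8)]
        res = cluster_comorbidities(fits, k=2)
        summary = cluster_summary(res, fits).set_index("cluster")
        solo = summary[summary["n_comorbidities"] == 1].iloc[0]
        assert solo["alpha_centered_median"] == pytest.approx(0.7)
        assert solo["or_alpha_median"] == pytest.approx(np.exp(0.7))
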