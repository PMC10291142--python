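import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from fluxcentral.errors import InputError, ParameterError
from fluxcentral.containers import ExpressionMatrix
from fluxcentral.phenotype import (
    cluster_stage_distribution,
    flux_stress_correlation,
    knn_cluster,
    ssgsea_scores,
    top_principal_components,
    tsne_embed,
)


def blobs(n_per_blob, centers, sd=1.0, d=42, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, c in enumerate(centers):
        center = np.full(d, float(c))
        rows.append(rng.normal(center, sd, size=(n_per_blob, d)))
        labels += [i] * n_per_blob
    X = pd.DataFrame(np.vstack(rows))
    X.index = [f"s{i}" for i in range(len(X))]
    return X, np.array(labels)


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(10.0)[:, None]
        v = np.ones((1, 5))
        X = pd.DataFrame(u @ v)
        scores = top_principal_components(X, 1)
        centered = X - X.mean(axis=0)
        total_var = float((centered**2).sum().sum())
        pc_var = float((scores**2).sum().iloc[0])
        assert pc_var == pytest.approx(total_var)

    def test_two_block_design_separated(self):
        X, labels = blobs(20, centers=[0, 10], d=6, seed=1)
        scores = top_principal_components(X, 2)
        assert abs(np.corrcoef(scores["PC1"], labels)[0, 1]) > 0.99

    def test_shape_and_zero_means(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((60, 42)))
        scores = top_principal_components(X, 12)
        assert scores.shape == (60, 12)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_explained_variance_nonincreasing(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((50, 10)))
        scores = top_principal_components(X, 5)
        variances = scores.var(axis=0).to_numpy()
        assert (np.diff(variances) <= 1e-10).all()

    def test_too_many_components_rejected(self):
        with pytest.raises(ParameterError):
            top_principal_components(pd.DataFrame(np.ones((5, 3))), 4)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((30, 8)))
        a = top_principal_components(X, 3)
        b = top_principal_components(X, 3)
        pd.testing.assert_frame_equal(a, b)


class TestTSNE:
    def test_separated_blobs_stay_separated(self):
        X, labels = blobs(100, centers=[0, 10], d=42, seed=5)
        emb = tsne_embed(X, seed=0, perplexity=30)
        assert silhouette_score(emb.coordinates, labels) > 0.5

    def test_same_seed_identical(self):
        X, _ = blobs(60, centers=[0, 3], d=10, seed=6)
        a = tsne_embed(X, seed=3, perplexity=20)
        b = tsne_embed(X, seed=3, perplexity=20)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_too_few_samples_rejected(self):
        X, _ = blobs(5, centers=[0, 1], d=4, seed=7)
        with pytest.raises(ParameterError):
            tsne_embed(X, seed=0, perplexity=30)


class TestKnnCluster:
    def test_recovers_three_blobs(self):
        X, truth = blobs(50, centers=[0, 10, 20], d=12, seed=8)
        labels = knn_cluster(X, k_neighbors=15, seed=1)
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_identical_rows_single_cluster(self):
        X = pd.DataFrame(np.ones((30, 5)))
        with pytest.warns(UserWarning, match="identical"):
            labels = knn_cluster(X, k_neighbors=5)
        assert labels.nunique() == 1

    def test_cluster_count_nondecreasing_in_resolution(self):
        X, _ = blobs(40, centers=[0, 5], d=8, seed=9)
        counts = [knn_cluster(X, k_neighbors=15, resolution=r, seed=2).nunique()
                  for r in (0.2, 0.8, 2.0)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_deterministic_given_seed(self):
        X, _ = blobs(40, centers=[0, 6], d=8, seed=10)
        a = knn_cluster(X, k_neighbors=10, seed=5)
        b = knn_cluster(X, k_neighbors=10, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_k_too_large_rejected(self):
        X, _ = blobs(5, centers=[0], d=3, seed=11)
        with pytest.raises(ParameterError):
            knn_cluster(X, k_neighbors=10)


class TestClusterStageDistribution:
    @staticmethod
    def _metadata(index, stages, types="T", status="tumor"):
        return pd.DataFrame({
            "cancer_type": types, "status": status, "stage": stages,
        }, index=index)

    def test_single_cluster_matches_global_distribution(self):
        idx = [f"s{i}" for i in range(10)]
        labels = pd.Series(0, index=idx, name="cluster")
        meta = self._metadata(idx, stages=["I"] * 6 + ["IV"] * 4)
        report = cluster_stage_distribution(labels, meta)
        assert report.n_clusters == 1
        assert report.stage_distribution.loc[0, "I"] == 6
        assert report.stage_distribution.loc[0, "IV"] == 4

    def test_stage_iv_concentrated_in_one_cluster(self):
        idx = [f"s{i}" for i in range(40)]
        labels = pd.Series([1] * 20 + [2] * 20, index=idx, name="cluster")
        meta = self._metadata(idx, stages=["I"] * 20 + ["IV"] * 20)
        report = cluster_stage_distribution(labels, meta)
        frac = report.stage_distribution.div(report.stage_distribution.sum(axis=1), axis=0)
        assert frac.loc[2, "IV"] == pytest.approx(1.0)
        assert report.stage_chi2_p < 0.001

    def test_missing_stage_tallied_as_na_without_test(self):
        idx = [f"s{i}" for i in range(6)]
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=idx, name="cluster")
        meta = self._metadata(idx, stages=pd.NA)
        with pytest.warns(UserWarning, match="sparse"):
            report = cluster_stage_distribution(labels, meta)
        assert report.stage_chi2_p is None
        assert report.stage_distribution["NA"].sum() == 6


class TestSsgsea:
    @staticmethod
    def four_gene_expression():
        values = pd.DataFrame({"s1": [4.0, 3.0, 2.0, 1.0]},
                              index=["g1", "g2", "g3", "g4"])
        return ExpressionMatrix(values)

    def test_hand_enumerated_alpha_zero(self):
        # ranked g1>g2>g3>g4, set {g1,g2}, alpha=0:
        # in-set cumulative fractions  (1/2, 1, 1, 1)
        # out-set cumulative fractions (0, 0, 1/2, 1)
        # ES = 0.5 + 1 + 0.5 + 0 = 2
        scores = ssgsea_scores(self.four_gene_expression(), {"S": ["g1", "g2"]}, alpha=0.0)
        assert scores.loc["s1", "S"] == pytest.approx(2.0)

    def test_full_set_is_maximal(self):
        expr = self.four_gene_expression()
        sets = {"all": ["g1", "g2", "g3", "g4"], "top": ["g1"], "bottom": ["g4"]}
        scores = ssgsea_scores(expr, sets)
        assert np.isfinite(scores.loc["s1", "all"])
        assert scores.loc["s1", "all"] == scores.loc["s1"].max()

    def test_rank_invariance_under_monotone_transform(self):
        expr = self.four_gene_expression()
        transformed = ExpressionMatrix(np.expm1(expr.values * 2.0))
        sets = {"S": ["g1", "g3"]}
        pd.testing.assert_frame_equal(
            ssgsea_scores(expr, sets), ssgsea_scores(transformed, sets))

    def test_row_order_irrelevant(self):
        expr = self.four_gene_expression()
        shuffled = ExpressionMatrix(expr.values.loc[["g3", "g1", "g4", "g2"]])
        sets = {"S": ["g1", "g2"]}
        pd.testing.assert_frame_equal(
            ssgsea_scores(expr, sets), ssgsea_scores(shuffled, sets))

    def test_no_overlap_gives_na_with_warning(self):
        with pytest.warns(UserWarning, match="no genes"):
            scores = ssgsea_scores(self.four_gene_expression(), {"S": ["absent"]})
        assert np.isnan(scores.loc["s1", "S"])


class TestFluxStressCorrelation:
    def test_identical_series_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        flux = pd.DataFrame({"M1": rng.random(20)}, index=[f"s{i}" for i in range(20)])
        scores = pd.DataFrame({"set1": flux["M1"]})
        corr = flux_stress_correlation(flux, scores)
        assert corr.loc["M1", "set1"] == pytest.approx(1.0)

    def test_antimonotone_correlate_negatively(self):
        flux = pd.DataFrame({"M1": np.arange(10.0)}, index=[f"s{i}" for i in range(10)])
        scores = pd.DataFrame({"set1": -np.arange(10.0)**3}, index=flux.index)
        assert flux_stress_correlation(flux, scores).loc["M1", "set1"] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(500)]
        flux = pd.DataFrame(rng.normal(size=(500, 5)),
                            columns=[f"M{i}" for i in range(5)], index=idx)
        scores = pd.DataFrame(rng.normal(size=(500, 4)),
                              columns=[f"set{i}" for i in range(4)], index=idx)
        corr = flux_stress_correlation(flux, scores)
        assert abs(np.median(corr.to_numpy())) < 0.1
        assert (corr.to_numpy() >= -1).all() and (corr.to_numpy() <= 1).all()

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(30)]
        flux = pd.DataFrame(rng.random((30, 3)), columns=list("abc"), index=idx)
        scores = pd.DataFrame(rng.random((30, 2)), columns=list("xy"), index=idx)
        pd.testing.assert_frame_equal(
            flux_stress_correlation(flux, scores),
            flux_stress_correlation(scores, flux).T,
            check_names=False,
        )

    def test_too_few_shared_samples_rejected(self):
        flux = pd.DataFrame({"M1": [1.0, 2.0]}, index=["a", "b"])
        scores = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(InputError):
            flux_stress_correlation(flux, scores)
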