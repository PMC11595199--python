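import math

import numpy as np
import pytest

from plperm.data_io import Dataset, DescriptorTable
from plperm.errors import ValidationError
from plperm.read_across_rasar import (
    ReadAcrossModel,
    SimilarityConfig,
    build_qrasar,
    compute_rasar_descriptors,
    default_grid,
    optimize_hyperparameters,
    ra_predict,
    similarity,
)

KERNELS = [
    SimilarityConfig("euclidean", n_close=1),
    SimilarityConfig("gaussian", sigma=1.0, n_close=1),
    SimilarityConfig("laplacian", gamma=1.0, n_close=1),
]


class TestSimilarity:
    @pytest.mark.parametrize("config", KERNELS)
    def test_identical_vectors_give_one(self, config):
        v = np.array([0.3, -1.2, 4.0])
        assert similarity(v, v, config) == pytest.approx(1.0)

    def test_gaussian_closed_form_at_sigma(self):
        config = SimilarityConfig("gaussian", sigma=2.0, n_close=1)
        a, b = np.zeros(1), np.array([2.0])  # d = sigma
        assert similarity(a, b, config) == pytest.approx(math.exp(-0.5))

    def test_laplacian_closed_form_at_gamma(self):
        config = SimilarityConfig("laplacian", gamma=0.5, n_close=1)
        a, b = np.zeros(1), np.array([0.5])  # d = gamma
        assert similarity(a, b, config) == pytest.approx(math.exp(-1.0))

    def test_euclidean_form(self):
        config = SimilarityConfig("euclidean", n_close=1)
        assert similarity(np.zeros(1), np.array([3.0]), config) == pytest.approx(
            0.25
        )

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValidationError):
            similarity(np.zeros(2), np.zeros(3), KERNELS[0])

    def test_invalid_configs(self):
        with pytest.raises(ValidationError):
            SimilarityConfig("cosine")
        with pytest.raises(ValidationError):
            SimilarityConfig("gaussian", sigma=-1.0)
        with pytest.raises(ValidationError):
            SimilarityConfig("euclidean", n_close=0)


def source_set(rng, n=8, p=3):
    ids = [f"s{i}" for i in range(n)]
    X = rng.normal(size=(n, p))
    y = X[:, 0] + rng.normal(0, 0.1, n)
    return ids, X, y


class TestRaPredict:
    def test_query_equal_to_source_with_one_neighbor(self, rng):
        ids, X, y = source_set(rng)
        config = SimilarityConfig("gaussian", sigma=1.0, n_close=1)
        pred, close_ids, _ = ra_predict(X[3], ids, X, y, config)
        assert close_ids == ["s3"]
        assert pred == pytest.approx(y[3])

    def test_equal_similarity_uniform_weights(self):
        # two sources symmetric about the query: prediction is the mean
        ids = ["a", "b", "c", "d"]
        X = np.array([[-1.0], [1.0], [-3.0], [3.0]])
        y = np.array([0.0, 1.0, 5.0, -5.0])
        config = SimilarityConfig("gaussian", sigma=1.0, n_close=2)
        pred, close_ids, _ = ra_predict(np.array([0.0]), ids, X, y, config)
        assert sorted(close_ids) == ["a", "b"]
        assert pred == pytest.approx(0.5)

    def test_matches_brute_force_weighted_mean(self, rng):
        ids, X, y = source_set(rng, n=8)
        config = SimilarityConfig("laplacian", gamma=1.5, n_close=4)
        query = rng.normal(size=3)
        pred, close_ids, sims = ra_predict(query, ids, X, y, config)

        # independent recomputation from first principles
        mean, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        Xs = (X - mean) / sd
        qs = (query - mean) / sd
        d = np.sqrt(((Xs - qs) ** 2).sum(axis=1))
        s = np.exp(-d / 1.5)
        top = np.argsort(-s)[:4]
        expected = float((s[top] * y[top]).sum() / s[top].sum())
        assert pred == pytest.approx(expected, rel=1e-12)

    def test_convexity_bound(self, rng):
        ids, X, y = source_set(rng, n=10)
        config = SimilarityConfig("euclidean", n_close=5)
        model = ReadAcrossModel(ids, X, y, config)
        for _ in range(10):
            query = rng.normal(size=3) * 2
            pred, close_ids, _ = model.predict_one(query)
            close_y = [y[ids.index(c)] for c in close_ids]
            assert min(close_y) - 1e-12 <= pred <= max(close_y) + 1e-12

    def test_n_close_exceeding_sources_errors(self, rng):
        ids, X, y = source_set(rng, n=3)
        with pytest.raises(ValidationError):
            ReadAcrossModel(ids, X, y, SimilarityConfig("euclidean", n_close=4))


class TestKernelLimits:
    def test_small_width_converges_to_nearest_neighbor(self, rng):
        ids, X, y = source_set(rng, n=10)
        query = X[4] + 0.01
        for kernel, param in (("gaussian", "sigma"), ("laplacian", "gamma")):
            config = SimilarityConfig(kernel, **{param: 1e-3}, n_close=5)
            pred, _, _ = ra_predict(query, ids, X, y, config)
            assert pred == pytest.approx(y[4], abs=1e-6)

    def test_large_width_converges_to_close_set_mean(self, rng):
        ids, X, y = source_set(rng, n=10)
        query = rng.normal(size=3)
        for kernel, param in (("gaussian", "sigma"), ("laplacian", "gamma")):
            config = SimilarityConfig(kernel, **{param: 1e6}, n_close=4)
            pred, close_ids, _ = ra_predict(query, ids, X, y, config)
            close_y = np.array([y[ids.index(c)] for c in close_ids])
            assert pred == pytest.approx(float(close_y.mean()), abs=1e-6)


class TestRasarDescriptors:
    def test_single_higher_response_neighbor(self):
        # 5 sources; query sits on the highest-response one
        ids = ["a", "b", "c", "d", "e"]
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        config = SimilarityConfig("gaussian", sigma=1.0, n_close=1)
        feats = compute_rasar_descriptors(X[4], ids, X, y, config)
        assert feats.max_pos == pytest.approx(1.0)
        assert feats.max_neg == 0.0
        assert feats.gm == 1

    def test_all_lower_response_close_set(self):
        ids = ["a", "b", "c", "d", "e", "f"]
        X = np.array([[0.0], [0.2], [0.4], [5.0], [5.2], [5.4]])
        y = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        config = SimilarityConfig("gaussian", sigma=0.5, n_close=3)
        feats = compute_rasar_descriptors(np.array([0.2]), ids, X, y, config)
        assert feats.max_pos == 0.0
        assert feats.gm == 0

    def test_uniform_similarity_ra_is_mean(self):
        ids = ["a", "b"]
        X = np.array([[-1.0], [1.0]])
        y = np.array([0.0, 1.0])
        config = SimilarityConfig("gaussian", sigma=1.0, n_close=2)
        feats = compute_rasar_descriptors(np.array([0.0]), ids, X, y, config)
        assert feats.ra_function == pytest.approx(0.5)
        assert feats.sd_sim == pytest.approx(0.0, abs=1e-12)
        assert feats.avg_sim == pytest.approx(feats.close_similarities.mean())

    def test_similarities_in_unit_interval(self, rng):
        ids, X, y = source_set(rng, n=12)
        config = SimilarityConfig("laplacian", gamma=0.8, n_close=6)
        model = ReadAcrossModel(ids, X, y, config)
        feats = model.features_one(rng.normal(size=3) * 3)
        assert np.all(feats.close_similarities >= 0)
        assert np.all(feats.close_similarities <= 1)
        assert 0 <= feats.max_pos <= 1 and 0 <= feats.max_neg <= 1
        assert feats.gm in (0, 1)

    def test_leave_self_out_excludes_own_row(self, rng):
        ids, X, y = source_set(rng, n=8)
        config = SimilarityConfig("gaussian", sigma=1.0, n_close=7)
        model = ReadAcrossModel(ids, X, y, config)
        feats = model.features_one(X[2], exclude_id="s2")
        assert "s2" not in feats.close_ids


class TestOptimizeHyperparameters:
    def test_single_point_grid(self, rng):
        ids, X, y = source_set(rng, n=20)
        grid = [SimilarityConfig("gaussian", sigma=1.0, n_close=3)]
        best, report = optimize_hyperparameters(ids, X, y, grid=grid, seed=1)
        assert best == grid[0]
        assert len(report) == 1

    def test_empty_grid_errors(self, rng):
        ids, X, y = source_set(rng, n=20)
        with pytest.raises(ValidationError, match="empty"):
            optimize_hyperparameters(ids, X, y, grid=[], seed=1)

    def test_determinism(self, rng):
        ids, X, y = source_set(rng, n=24)
        grid = default_grid(widths=(0.5, 1.0), n_close_values=(2, 3))
        b1, _ = optimize_hyperparameters(ids, X, y, grid=grid, seed=5)
        b2, _ = optimize_hyperparameters(ids, X, y, grid=grid, seed=5)
        assert b1 == b2

    def test_matches_exhaustive_loop_oracle(self, rng):
        ids, X, y = source_set(rng, n=24)
        grid = default_grid(widths=(0.5, 2.0), n_close_values=(2, 4))
        best, report = optimize_hyperparameters(ids, X, y, grid=grid, seed=3)

        # independent exhaustive recomputation with the same seeded split
        order = np.random.default_rng(3).permutation(24)
        n_sub = int(round(0.75 * 24))
        sub, val = order[:n_sub], order[n_sub:]
        best_rmse, best_cfg = None, None
        for config in grid:
            model = ReadAcrossModel([ids[i] for i in sub], X[sub], y[sub],
                                    config)
            preds = np.array([model.predict_one(X[i])[0] for i in val])
            rmse = float(np.sqrt(np.mean((y[val] - preds) ** 2)))
            if best_rmse is None or rmse < best_rmse - 1e-15:
                best_rmse, best_cfg = rmse, config
        assert best == best_cfg
        assert report["rmse"].min() == pytest.approx(best_rmse)


def make_dataset(rng, n_train=45, n_test=15, noise=0.05):
    n = n_train + n_test
    X = rng.normal(size=(n, 4))
    y = 0.3 + 1.2 * X[:, 0] - 0.8 * X[:, 1] + rng.normal(0, noise, n)
    ids = [f"c{i}" for i in range(n)]
    table = DescriptorTable(ids, ["d1", "d2", "d3", "d4"], X)
    roles = ["train"] * n_train + ["test"] * n_test
    return Dataset(table, y, roles)


class TestBuildQrasar:
    def test_recovers_informative_descriptors(self):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng, n_train=45, n_test=15, noise=0.05)
        config = SimilarityConfig("gaussian", sigma=1.0, n_close=4)
        result = build_qrasar(ds, ["d1", "d2", "d3", "d4"], config, max_size=3)
        assert {"d1", "d2"} <= set(result.selected)
        assert result.report.q2_f1 > 0.9

    def test_n_latent_exceeding_selection_errors(self, rng):
        ds = make_dataset(rng)
        config = SimilarityConfig("gaussian", sigma=1.0, n_close=4)
        with pytest.raises(ValidationError, match="n_latent"):
            build_qrasar(ds, ["d1", "d2"], config, max_size=1, n_latent=2)

    def test_deterministic_selection(self, rng):
        ds = make_dataset(rng)
        config = SimilarityConfig("laplacian", gamma=1.0, n_close=5)
        r1 = build_qrasar(ds, ["d1", "d2", "d3", "d4"], config, seed=2)
        r2 = build_qrasar(ds, ["d1", "d2", "d3", "d4"], config, seed=2)
        assert r1.selected == r2.selected
        np.testing.assert_array_equal(r1.pls_model.coef_, r2.pls_model.coef_)

    def test_train_features_are_leave_self_out(self, rng):
        # with n_close == n_train - 1 every other compound appears, never self
        ds = make_dataset(rng, n_train=10, n_test=2)
        config = SimilarityConfig("gaussian", sigma=2.0, n_close=9)
        model = ReadAcrossModel(ds.ids("train"), ds.X("train"), ds.y("train"),
                                config)
        for cid, row in zip(ds.ids("train"), ds.X("train")):
            feats = model.features_one(row, exclude_id=cid)
            assert cid not in feats.close_ids
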