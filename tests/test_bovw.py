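"""Dense SIFT, vocabulary learning, histogram encoding, linear SVM."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from oracles import hard_margin_svm_qp, lloyd_kmeans_loop
from treestump.bovw import (
    build_vocabulary,
    dense_sift,
    encode_histogram,
    nearest_centroid_indices,
    sift_grid_positions,
    train_linear_svm,
    VisualVocabulary,
)


class TestDenseSift:
    def test_constant_patch_gives_zero_descriptors(self):
        ds = dense_sift(np.full((64, 64), 0.5))
        assert len(ds) > 0
        assert np.allclose(ds.descriptors, 0.0)

    def test_descriptor_count_matches_grid_enumeration(self):
        ds = dense_sift(np.random.default_rng(0).uniform(size=(64, 64)),
                        stride_px=8, scales=(1, 2))
        expected = 0
        for scale in (1, 2):
            bin_px = 4 * scale
            xs = [x for x in range(2 * bin_px, 64 - 2 * bin_px + 1, 8)]
            ys = [y for y in range(2 * bin_px, 64 - 2 * bin_px + 1, 8)]
            expected += len(xs) * len(ys)
        assert len(ds) == expected
        xs, ys = sift_grid_positions(64, 64, 8, 4)
        assert list(xs) == [8, 16, 24, 32, 40, 48, 56]

    def test_quarter_turn_equivariance(self):
        # rotating the patch 90 deg CCW maps keypoint (x, y) -> (y, n - x)
        # (the half-open 16-px support shifts the grid by one), permutes the
        # 4x4 spatial cells by a quarter turn and rolls the 8 orientation
        # bins by two positions
        n = 64
        img = gaussian_filter(np.random.default_rng(0).uniform(size=(n, n)), 2.0)
        d0 = dense_sift(img, stride_px=8, scales=(1,))
        d1 = dense_sift(np.rot90(img), stride_px=8, scales=(1,))
        lookup = {tuple(k[:2]): i for i, k in enumerate(d1.keypoints)}
        checked = 0
        for i, k in enumerate(d0.keypoints):
            x, y = k[:2]
            j = lookup.get((y, n - x))
            assert j is not None
            v0 = d0.descriptors[i].reshape(4, 4, 8)
            v1 = d1.descriptors[j].reshape(4, 4, 8)
            mapped = np.roll(np.rot90(v1, k=3, axes=(0, 1)), -6, axis=2)
            assert np.allclose(mapped, v0, atol=1e-8)
            checked += 1
        assert checked == 49

    def test_undersized_patch_returns_empty_set_with_warning(self):
        with pytest.warns(UserWarning):
            ds = dense_sift(np.zeros((10, 10)))
        assert len(ds) == 0

    def test_descriptors_are_l2_bounded(self, rng):
        ds = dense_sift(rng.uniform(size=(64, 64)))
        norms = np.linalg.norm(ds.descriptors, axis=1)
        assert np.all(norms <= 1.0 + 1e-9)


class TestVocabulary:
    def test_saturated_clustering_zero_inertia(self, rng):
        pool = rng.uniform(size=(5, 16))
        vocab = build_vocabulary(pool, k=5, seed=0)
        # each descriptor is its own centroid
        assign = nearest_centroid_indices(pool, vocab.centroids)
        assert len(set(assign.tolist())) == 5
        recon = vocab.centroids[assign]
        assert np.allclose(recon, pool, atol=1e-10)

    def test_recovers_separated_clusters_and_matches_lloyd_oracle(self, rng):
        # 2000 points per cluster: the sample-mean error is ~sigma/sqrt(2000)
        # per dimension, far inside the 0.1 sigma recovery band
        sigma = 0.05
        true_means = np.array([[0.0] * 8, [3.0] * 8, [-3.0, 3.0] * 4])
        X = np.vstack([rng.normal(m, sigma, (2000, 8)) for m in true_means])
        vocab = build_vocabulary(X, k=3, seed=1, n_init=3)
        got = vocab.centroids[np.argsort(vocab.centroids[:, 0])]
        want = true_means[np.argsort(true_means[:, 0])]
        assert np.all(np.abs(got - want) < 0.1 * sigma)
        oracle = lloyd_kmeans_loop(X, centers_init=want + 0.2)
        oracle = oracle[np.argsort(oracle[:, 0])]
        assert np.allclose(got, oracle, atol=1e-6)

    def test_vocabulary_size_200(self, rng):
        pool = rng.uniform(size=(10_000, 128))
        vocab = build_vocabulary(pool, k=200, seed=0, n_init=1, max_iter=20)
        assert vocab.centroids.shape == (200, 128)

    def test_pool_smaller_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            build_vocabulary(rng.uniform(size=(10, 8)), k=20)


class TestEncoding:
    def _vocab(self, rng, k=5, dim=8):
        return VisualVocabulary(k=k, centroids=rng.uniform(size=(k, dim)),
                                training_seed=0)

    def test_identical_descriptors_give_one_hot(self, rng):
        vocab = self._vocab(rng)
        desc = np.tile(vocab.centroids[2], (7, 1))
        hist = encode_histogram(desc, vocab)
        assert hist.values[2] == pytest.approx(1.0)
        assert hist.values.sum() == pytest.approx(1.0)

    def test_histogram_sums_to_one(self, rng):
        vocab = self._vocab(rng)
        hist = encode_histogram(rng.uniform(size=(50, 8)), vocab)
        assert hist.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_assignment_matches_double_loop(self, rng):
        vocab = self._vocab(rng)
        desc = rng.uniform(size=(50, 8))
        hist = encode_histogram(desc, vocab)
        counts = np.zeros(5)
        for d in desc:
            dists = [np.linalg.norm(d - c) for c in vocab.centroids]
            counts[int(np.argmin(dists))] += 1
        assert np.allclose(hist.values, counts / counts.sum(), atol=1e-12)

    def test_order_invariance(self, rng):
        vocab = self._vocab(rng)
        desc = rng.uniform(size=(30, 8))
        h1 = encode_histogram(desc, vocab)
        h2 = encode_histogram(desc[::-1].copy(), vocab)
        assert np.array_equal(h1.values, h2.values)

    def test_empty_set_encodes_to_flagged_zero_vector(self, rng):
        vocab = self._vocab(rng)
        hist = encode_histogram(np.zeros((0, 8)), vocab)
        assert hist.empty and np.all(hist.values == 0)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            encode_histogram(rng.uniform(size=(3, 5)), self._vocab(rng))


class TestLinearSvm:
    def test_separable_dirichlet_modes_fit_perfectly(self, rng):
        a = rng.dirichlet([8, 1, 1, 1, 1], size=40)
        b = rng.dirichlet([1, 1, 1, 1, 8], size=40)
        X = np.vstack([a, b])
        y = np.array([1] * 40 + [0] * 40)
        model = train_linear_svm(X, y)
        assert np.all(model.predict(X) == y)

    def test_duplication_leaves_separable_optimum_unchanged(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (15, 3)), rng.normal(2, 0.3, (15, 3))])
        y = np.array([0] * 15 + [1] * 15)
        m1 = train_linear_svm(X, y)
        m2 = train_linear_svm(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(m1.w, m2.w, atol=1e-6)
        assert m1.b == pytest.approx(m2.b, abs=1e-6)

    def test_six_point_toy_matches_qp_oracle(self):
        X = np.array([[0.0, 0.0], [0.5, 1.0], [1.0, 0.2],
                      [3.0, 0.0], [3.5, 1.0], [4.0, 0.4]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = train_linear_svm(X, y, C=1e6)   # effectively hard margin
        w_ref, b_ref = hard_margin_svm_qp(X, y)
        assert np.allclose(model.w, w_ref, atol=1e-3)
        assert model.b == pytest.approx(b_ref, abs=1e-3)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_linear_svm(rng.uniform(size=(5, 3)), np.ones(5))
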