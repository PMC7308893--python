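"""Bark-colour model: augmentation, EM fit, Mahalanobis scoring, morphology."""

import numpy as np
import pytest
from skimage.morphology import disk

from oracles import (
    closing_loop,
    em_gmm_loop,
    mahalanobis_min_distance_loop,
    opening_loop,
)
from treestump.colormodel import (
    AugmentConfig,
    LikelihoodMap,
    augment_photometric,
    fit_color_model,
    load_color_model,
    save_color_model,
    score_pixels,
    threshold_and_clean,
)

IDENTITY_AUG = AugmentConfig(gain_range=(1, 1), gamma_range=(1, 1),
                             channel_gain_range=(1, 1), noise_sigma=0.0)


class TestAugmentation:
    def test_expands_hundreds_to_more_than_a_thousand(self):
        patches = [np.full((4, 4, 3), 0.4)] * 200
        out = augment_photometric(patches, 1000, seed=0)
        assert len(out) >= 1000

    def test_identity_config_copies_inputs(self):
        rng = np.random.default_rng(0)
        patches = [rng.uniform(size=(6, 6, 3)) for _ in range(3)]
        out = augment_photometric(patches, 9, seed=1, config=IDENTITY_AUG)
        for i, aug in enumerate(out):
            assert np.allclose(aug, patches[i % 3])

    def test_fixed_gain_closed_form(self):
        c = np.full((5, 5, 3), 0.8)
        cfg = AugmentConfig(gain_range=(1.4, 1.4), gamma_range=(1, 1),
                            channel_gain_range=(1, 1), noise_sigma=0.0)
        out = augment_photometric([c], 2, seed=0, config=cfg)
        assert np.allclose(out[1], np.minimum(1.4 * c, 1.0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_photometric([], 10)


class TestGmmFit:
    def test_single_colour_degenerates_to_floor_covariance(self):
        pixels = np.tile([0.3, 0.2, 0.1], (50, 1))
        model = fit_color_model(pixels, n_components=1, seed=0, reg_floor=1e-4)
        assert np.allclose(model.means[0], [0.3, 0.2, 0.1], atol=1e-9)
        assert np.allclose(model.covariances[0], np.eye(3) * 1e-4, atol=1e-8)

    def test_recovers_well_separated_clusters(self):
        # two clusters 10 sigma apart; recovery within 0.5 sigma, and the
        # from-scratch EM oracle agrees
        rng = np.random.default_rng(4)
        sigma = 0.02
        true_means = np.array([[0.2, 0.2, 0.2], [0.7, 0.6, 0.5]])
        X = np.vstack([rng.normal(m, sigma, (400, 3)) for m in true_means])
        model = fit_color_model(X, n_components=2, seed=0)
        got = model.means[np.argsort(model.means[:, 0])]
        assert np.all(np.abs(got - true_means) < 0.5 * sigma)
        _, oracle_means, _ = em_gmm_loop(X, 2, means_init=[[0.25, 0.25, 0.25],
                                                           [0.65, 0.65, 0.65]])
        oracle_sorted = oracle_means[np.argsort(oracle_means[:, 0])]
        assert np.all(np.abs(got - oracle_sorted) < 0.5 * sigma)

    def test_log_likelihood_is_monotone(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(300, 3))
        model = fit_color_model(X, n_components=3, seed=1)
        assert len(model.log_likelihood_path) >= 2
        assert np.all(np.diff(model.log_likelihood_path) >= -1e-8)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            fit_color_model(np.zeros((19, 3)), n_components=2)


class TestScoring:
    def _model(self, s=0.1):
        from treestump.colormodel import ColorModel
        return ColorModel(weights=np.array([1.0]),
                          means=np.array([[0.5, 0.5, 0.5]]),
                          covariances=np.array([np.eye(3) * s**2]),
                          reg_floor=1e-6)

    def test_distance_zero_at_component_mean(self):
        image = np.full((3, 3, 3), 0.5)
        lmap = score_pixels(self._model(), image)
        assert np.allclose(lmap.distances, 0.0, atol=1e-9)

    def test_one_sigma_offset_gives_distance_one(self):
        s = 0.1
        image = np.full((2, 2, 3), 0.5)
        image[..., 0] += s
        lmap = score_pixels(self._model(s), image)
        assert np.allclose(lmap.distances, 1.0, atol=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        image = rng.uniform(size=(16, 16, 3))
        means = rng.uniform(size=(3, 3))
        covs = []
        for _ in range(3):
            a = rng.uniform(size=(3, 3))
            covs.append(a @ a.T + np.eye(3) * 0.05)
        from treestump.colormodel import ColorModel
        model = ColorModel(weights=np.full(3, 1 / 3), means=means,
                           covariances=np.array(covs), reg_floor=1e-6)
        lmap = score_pixels(model, image)
        oracle = mahalanobis_min_distance_loop(image, means, covs)
        assert np.allclose(lmap.distances, oracle, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        image = rng.uniform(size=(8, 8, 3))
        lmap = score_pixels(self._model(), image)
        perm = rng.permutation(64)
        shuffled = image.reshape(-1, 3)[perm].reshape(8, 8, 3)
        lmap_shuffled = score_pixels(self._model(), shuffled)
        assert np.allclose(lmap_shuffled.distances.ravel(),
                           lmap.distances.ravel()[perm])

    def test_nonfinite_pixels_rejected(self):
        image = np.full((2, 2, 3), np.nan)
        with pytest.raises(ValueError):
            score_pixels(self._model(), image)


class TestThresholdAndClean:
    def test_all_distances_above_tau_gives_empty_mask(self):
        lmap = LikelihoodMap(np.full((5, 5), 10.0))
        assert not threshold_and_clean(lmap, tau=3.0).any()

    def test_opening_removes_isolated_pixel(self):
        dist = np.full((9, 9), 10.0)
        dist[4, 4] = 0.0
        mask = threshold_and_clean(LikelihoodMap(dist), tau=3.0,
                                   open_radius=1, close_radius=0)
        assert not mask.any()

    def test_closing_fills_interior_hole(self):
        dist = np.full((20, 20), 10.0)
        dist[4:16, 6:14] = 0.0
        dist[10, 10] = 10.0  # 1-px hole inside the bar
        mask = threshold_and_clean(LikelihoodMap(dist), tau=3.0,
                                   open_radius=0, close_radius=1)
        assert mask[10, 10]
        raw = dist <= 3.0
        assert np.array_equal(mask, closing_loop(raw, disk(1)))

    def test_morphology_matches_set_oracle(self, rng):
        # random interior mask (3-px false margin keeps borders neutral)
        mask = np.zeros((16, 16), dtype=bool)
        mask[3:-3, 3:-3] = rng.uniform(size=(10, 10)) < 0.5
        dist = np.where(mask, 0.0, 10.0)
        got = threshold_and_clean(LikelihoodMap(dist), tau=3.0,
                                  open_radius=1, close_radius=2)
        oracle = closing_loop(opening_loop(mask, disk(1)), disk(2))
        assert np.array_equal(got, oracle)

    def test_mask_monotone_in_tau(self, rng):
        dist = rng.uniform(0, 5, size=(12, 12))
        lmap = LikelihoodMap(dist)
        m1 = threshold_and_clean(lmap, tau=1.0, open_radius=0, close_radius=0)
        m2 = threshold_and_clean(lmap, tau=2.5, open_radius=0, close_radius=0)
        assert np.all(m2[m1])  # m1 subset of m2

    def test_augmented_bark_still_scores_bark_like(self):
        # mild photometric jitter must not push bark outside the 3-sigma gate
        from treestump.synthetic import generate_bark_patch
        patches = [generate_bark_patch(24, 24, ((0.42, 0.30, 0.20), 0.03),
                                       stria_strength=0.2, seed=s)
                   for s in range(6)]
        pixels = np.concatenate([p.reshape(-1, 3) for p in patches])
        model = fit_color_model(pixels, n_components=3, seed=0)
        mild = AugmentConfig(gain_range=(0.95, 1.05), gamma_range=(0.95, 1.05),
                             channel_gain_range=(0.97, 1.03), noise_sigma=0.005)
        augmented = augment_photometric(patches, 18, seed=2, config=mild)[6:]
        dists = np.concatenate([
            score_pixels(model, p).distances.ravel() for p in augmented
        ])
        assert (dists <= 3.0).mean() >= 0.8


def test_color_model_yaml_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    X = rng.uniform(size=(200, 3))
    model = fit_color_model(X, n_components=2, seed=0)
    path = tmp_path / "bark.yaml"
    save_color_model(model, str(path))
    loaded = load_color_model(str(path))
    assert np.allclose(loaded.means, model.means)
    assert np.allclose(loaded.covariances, model.covariances)
    assert np.allclose(loaded.weights, model.weights)
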