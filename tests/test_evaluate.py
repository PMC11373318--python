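"""Cropping, FID, nucleus detection, morphometry and metric behaviour."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ouroboros.evaluate import (MorphScaler, N_MORPH_FEATURES, center_crop,
                                compute_fid, detect_nuclei, embed_images,
                                morph_distance, morph_feature_matrix,
                                morph_features, paired_morph_test,
                                prediction_metrics)


class TestCenterCrop:
    def test_bounds_arithmetic(self, rng):
        img = rng.integers(0, 256, (256, 256, 3), dtype=np.uint8)
        crop = center_crop(img, 128)
        assert np.array_equal(crop, img[64:192, 64:192])

    def test_same_size_is_identity(self, rng):
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        assert np.array_equal(center_crop(img, 64), img)

    def test_crops_compose(self, rng):
        img = rng.integers(0, 256, (256, 256, 3), dtype=np.uint8)
        assert np.array_equal(center_crop(center_crop(img, 192), 128),
                              center_crop(img, 128))

    def test_oversized_crop_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            center_crop(np.zeros((64, 64, 3)), 65)


class TestEmbeddings:
    def test_seeded_embedding_deterministic(self, rng):
        imgs = rng.integers(0, 256, (6, 32, 32, 3), dtype=np.uint8)
        a = embed_images(imgs, seed=3)
        b = embed_images(imgs, seed=3)
        assert np.array_equal(a, b)
        assert a.shape == (6, 64)

    def test_handcrafted_constant_image_closed_form(self):
        img = np.full((16, 16, 3), 128, dtype=np.uint8)
        f = embed_images(img[None], method="handcrafted")[0]
        val = 128 / 255
        np.testing.assert_allclose(f[0:6:2], val, atol=1e-6)  # channel means
        np.testing.assert_allclose(f[1:6:2], 0.0, atol=1e-9)  # channel stds
        # each 8-bin histogram is one-hot at the 128/255 bin (index 4)
        hist = f[6:30].reshape(3, 8)
        np.testing.assert_allclose(hist[:, 4], 1.0)
        np.testing.assert_allclose(hist.sum(axis=1), 1.0)
        np.testing.assert_allclose(f[30:34], 0.0, atol=1e-9)  # gradients

    def test_external_pretrained_raises_helpfully(self, rng):
        with pytest.raises(RuntimeError, match="pretrained"):
            embed_images(rng.integers(0, 256, (2, 8, 8, 3), dtype=np.uint8),
                         method="external_pretrained")

    def test_embeddings_separate_structure_from_noise(self, small_cohort, rng):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        _, dataset, _ = small_cohort
        structured = dataset.images[:70]
        noise = rng.integers(0, 256, structured.shape, dtype=np.uint8)
        emb = embed_images(np.concatenate([structured, noise]), seed=1)
        y = np.r_[np.zeros(len(structured)), np.ones(len(noise))]
        acc = cross_val_score(LogisticRegression(max_iter=5000), emb, y, cv=3).mean()
        assert acc > 0.9


class TestFID:
    def test_identical_sets_give_zero(self, rng):
        e = rng.standard_normal((200, 8))
        assert compute_fid(e, e) < 1e-6

    def test_symmetry(self, rng):
        a, b = rng.standard_normal((100, 5)), rng.standard_normal((100, 5)) + 1
        assert abs(compute_fid(a, b) - compute_fid(b, a)) < 1e-8

    def test_univariate_gaussian_analytic_value(self, rng):
        # (mu_a - mu_b)^2 + (sigma_a - sigma_b)^2 = 1 for unit-variance shift 1
        a = rng.standard_normal((5000, 1))
        b = rng.standard_normal((5000, 1)) + 1.0
        assert abs(compute_fid(a, b) - 1.0) < 0.1

    def test_nonnegative_on_random_sets(self, rng):
        for _ in range(5):
            a = rng.standard_normal((50, 6))
            b = rng.standard_normal((60, 6)) * rng.uniform(0.5, 2)
            assert compute_fid(a, b) >= 0.0


class TestDetectNuclei:
    def test_blank_images_give_nothing(self):
        assert detect_nuclei(np.full((32, 32, 3), 255, dtype=np.uint8)) == []
        assert detect_nuclei(np.zeros((32, 32, 3), dtype=np.uint8)) == []

    def test_separated_nuclei_counted_exactly(self):
        from skimage.draw import disk

        # 7 dark nuclei on an eosin-pink background, far apart by construction
        img = np.full((64, 64, 3), (240, 185, 200), dtype=np.uint8)
        centers = [(10, 10), (10, 32), (10, 54), (32, 21), (32, 43),
                   (54, 10), (54, 40)]
        for cy, cx in centers:
            rr, cc = disk((cy, cx), 4, shape=(64, 64))
            img[rr, cc] = (70, 40, 120)
        assert len(detect_nuclei(img)) == 7

    def test_masks_are_disjoint(self, small_cohort):
        _, dataset, _ = small_cohort
        masks = detect_nuclei(dataset.images[0])
        total = np.zeros(dataset.images[0].shape[:2], dtype=int)
        for m in masks:
            total += m
        assert total.max() <= 1


class TestMorphFeatures:
    def _disc_patch(self, radius=10, size=64):
        img = np.full((size, size, 3), 245, dtype=np.uint8)
        yy, xx = np.mgrid[:size, :size]
        mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius ** 2
        img[mask] = (70, 40, 120)  # hematoxylin-dark disc
        return img, mask

    def test_disc_shape_descriptors(self):
        img, mask = self._disc_patch(radius=10)
        vec, n = morph_features(img, masks=[mask])
        assert n == 1
        area, perimeter, eq_diam = vec[0], vec[1], vec[2]
        ecc, solidity = vec[5], vec[6]
        assert abs(area - np.pi * 100) / (np.pi * 100) < 0.05
        assert abs(eq_diam - 20) < 1.0
        # pixel-centre convex hulls give rasterized discs solidity ~ 0.93
        assert ecc < 0.25 and solidity > 0.9

    def test_duplicated_patch_identical_features(self, small_cohort):
        _, dataset, _ = small_cohort
        v1, _ = morph_features(dataset.images[3])
        v2, _ = morph_features(dataset.images[3].copy())
        np.testing.assert_array_equal(v1, v2)

    def test_area_scales_with_squared_radius(self):
        img1, m1 = self._disc_patch(radius=6)
        img2, m2 = self._disc_patch(radius=12)
        v1, _ = morph_features(img1, masks=[m1])
        v2, _ = morph_features(img2, masks=[m2])
        ratio = v2[0] / v1[0]
        assert 3.3 < ratio < 4.7

    def test_zero_nucleus_patch_flagged(self):
        blank = np.full((32, 32, 3), 255, dtype=np.uint8)
        vec, n = morph_features(blank)
        assert vec is None and n == 0
        feats, counts = morph_feature_matrix(blank[None])
        assert np.isnan(feats).all() and counts[0] == 0

    def test_vector_length_is_63(self, small_cohort):
        _, dataset, _ = small_cohort
        vec, _ = morph_features(dataset.images[0])
        assert vec.shape == (N_MORPH_FEATURES,) == (63,)


class TestMorphDistance:
    def test_identity_and_hand_example(self):
        scaler = MorphScaler(scale=np.array([1.0, 2.0, 0.5]))
        f1 = np.array([1.0, 4.0, 2.0])
        f2 = np.array([2.0, 0.0, 1.0])
        assert morph_distance(f1, f1, scaler) == 0.0
        # ((-1/1)^2 + (4/2)^2 + (1/0.5)^2)^0.5 = sqrt(1 + 4 + 4) = 3
        assert abs(morph_distance(f1, f2, scaler) - 3.0) < 1e-12

    def test_metric_axioms(self, rng):
        scaler = MorphScaler(scale=rng.uniform(0.5, 2.0, 7))
        for _ in range(20):
            a, b, c = rng.standard_normal((3, 7))
            dab = morph_distance(a, b, scaler)
            assert abs(dab - morph_distance(b, a, scaler)) < 1e-12
            assert dab <= (morph_distance(a, c, scaler)
                           + morph_distance(c, b, scaler)) + 1e-9


class TestPairedMorphTest:
    def _features(self, rng, n=30, dim=63):
        # dimensionality matches the morphometry profile: distances between
        # high-dimensional vectors are nearly symmetric, as in the real test
        real = rng.standard_normal((n, dim)) * rng.uniform(0.5, 3.0, dim)
        wsi = np.repeat(["w1", "w2"], n // 2)
        return real, wsi

    def test_perfect_generator_is_significant(self, rng):
        real, wsi = self._features(rng)
        matched, base, p = paired_morph_test(real, real.copy(), wsi,
                                             n_random=20, seed=0)
        assert matched == 0.0
        assert base > 0
        assert p < 1e-4

    def test_shuffled_pairing_is_null(self, rng):
        real, wsi = self._features(rng, n=40)
        nonsig = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            perm = np.concatenate([r.permutation(np.flatnonzero(wsi == w))
                                   for w in ("w1", "w2")])
            _, _, p = paired_morph_test(real, real[perm], wsi,
                                        n_random=20, seed=rep)
            nonsig += p >= 0.05
        assert nonsig >= 16  # correct null behaviour in >= 80% of replicates

    def test_against_exact_signed_rank_enumeration(self):
        """scipy's one-sided Wilcoxon matches brute-force sign-pattern enumeration."""
        d_matched = np.array([1.0, 2.5, 0.5, 4.0, 1.5, 0.2, 3.1, 2.2, 0.9, 1.1])
        diffs = np.array([-1.1, 0.5, -0.85, 0.7, -2.0, -0.95, 0.1, -1.9,
                          -1.05, 0.05])  # all |diffs| distinct: tie-free ranks
        d_base = d_matched - diffs
        ranks = stats.rankdata(np.abs(diffs))
        t_obs = ranks[diffs > 0].sum()
        null = [np.sum(ranks[list(signs)]) for signs in
                (np.array(bits, dtype=bool) for bits in
                 itertools.product([0, 1], repeat=len(diffs)))]
        p_exact = np.mean([t <= t_obs for t in null])
        p_scipy = stats.wilcoxon(d_matched, d_base, alternative="less",
                                 method="exact").pvalue
        assert abs(p_exact - p_scipy) < 1e-12

    def test_too_few_pairs_rejected(self, rng):
        real, wsi = self._features(rng, n=30)
        bad = real.copy()
        bad[5:] = np.nan  # most synthetic counterparts flagged
        with pytest.raises(ValueError, match="10"):
            paired_morph_test(real, bad, wsi, seed=0)


class TestPredictionMetrics:
    def test_perfect_and_inverted_predictions(self, rng):
        y = rng.standard_normal((30, 4))
        m = prediction_metrics(y, y.copy())
        np.testing.assert_allclose(m["pearson"], 1.0)
        np.testing.assert_allclose(m["spearman"], 1.0)
        m2 = prediction_metrics(y, -y)
        np.testing.assert_allclose(m2["pearson"], -1.0)

    def test_hand_example_against_rank_oracle(self):
        y = np.array([[1.0], [3.0], [2.0], [5.0], [4.0], [6.0]])
        yhat = np.array([[2.0], [1.0], [3.0], [4.0], [6.0], [5.0]])
        m = prediction_metrics(np.tile(y, (1, 2)), np.tile(yhat, (1, 2)))
        # Spearman = Pearson of ranks, computed by hand
        ry = stats.rankdata(y[:, 0])
        rh = stats.rankdata(yhat[:, 0])
        rho = np.corrcoef(ry, rh)[0, 1]
        np.testing.assert_allclose(m["spearman"], rho)

    def test_constant_column_excluded_from_means(self, rng):
        y = rng.standard_normal((20, 3))
        yhat = y.copy()
        yhat[:, 1] = 7.0
        m = prediction_metrics(y, yhat)
        assert np.isnan(m["pearson"][1])
        assert m["n_undefined"] == 1
        np.testing.assert_allclose(m["mean_pearson"], 1.0)
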