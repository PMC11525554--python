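"""Labeler core: subsampling, Z-normalization, k-means, k-selection, assignment."""

import numpy as np
import pytest

from tissuedomains import (FittedLabeler, LabelerConfig, MifPreprocessConfig,
                           ZNormParams, adjusted_inertia, assign_domains,
                           domain_profile, fit_kmeans_over_k,
                           fit_mif_pipeline, fit_tissue_labeler,
                           generate_synthetic_mif, load_labeler,
                           log_mean_normalize, reduce_dimensions,
                           save_labeler, subsample_pixels, z_normalize)
from tissuedomains.labeler import total_sum_of_squares


def identity_model(centroids, n_features=None):
    centroids = np.asarray(centroids, dtype=float)
    d = n_features or centroids.shape[1]
    znorm = ZNormParams(mean=np.zeros(d), sd=np.ones(d),
                        kept=np.ones(d, dtype=bool))
    return FittedLabeler(centroids=centroids, znorm=znorm,
                         k=centroids.shape[0], inertia_curve={},
                         adjusted_curve={}, config=LabelerConfig(k=centroids.shape[0]))


class TestSubsample:
    def test_exact_fraction_count(self):
        feats = np.random.default_rng(0).random((40, 25, 2))
        mask = np.zeros((40, 25), dtype=bool)
        mask.ravel()[:1000] = True
        out = subsample_pixels([(feats, mask)], 0.2, seed=1)
        assert out.shape == (200, 2)

    def test_full_fraction_is_exhaustive_without_repeats(self):
        feats = np.arange(24.0).reshape(4, 3, 2)
        mask = np.ones((4, 3), dtype=bool)
        out = subsample_pixels([(feats, mask)], 1.0, seed=0)
        assert out.shape == (12, 2)
        assert np.array_equal(np.sort(out[:, 0]), np.arange(0.0, 24.0, 2))

    def test_deterministic_under_seed(self):
        feats = np.random.default_rng(2).random((30, 30, 3))
        mask = feats[:, :, 0] > 0.3
        a = subsample_pixels([(feats, mask)], 0.2, seed=9)
        b = subsample_pixels([(feats, mask)], 0.2, seed=9)
        assert np.array_equal(a, b)


class TestZNormalize:
    def test_hand_computed_column(self):
        z, params = z_normalize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(params.mean, [2.0])
        assert np.allclose(params.sd, [np.sqrt(2.0 / 3.0)])  # 0.816497
        assert np.allclose(z[:, 0], [-1.22474487, 0.0, 1.22474487])

    def test_idempotent_on_standardized_column(self):
        x = np.array([[-1.22474487], [0.0], [1.22474487]])
        z, _ = z_normalize(x)
        assert np.allclose(z, x, atol=1e-8)

    def test_constant_column_dropped_and_recorded(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            z, params = z_normalize(x)
        assert z.shape == (5, 1)
        assert params.kept.tolist() == [True, False]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            z_normalize(np.ones((4, 2)))


class TestKMeansOverK:
    def test_k1_closed_form(self):
        x = np.random.default_rng(0).random((20, 3))
        curve, cents = fit_kmeans_over_k(x, [1], seed=0)
        assert np.allclose(cents[1][0], x.mean(axis=0))
        assert np.isclose(curve[1], total_sum_of_squares(x))

    def test_two_separated_pairs(self):
        x = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
        curve, cents = fit_kmeans_over_k(x, [2], seed=0)
        assert np.allclose(np.sort(cents[2][:, 0]), [0.05, 10.05])
        assert np.isclose(curve[2], 4 * 0.05 ** 2)

    def test_inertia_non_increasing(self):
        x = np.random.default_rng(1).random((60, 4))
        curve, _ = fit_kmeans_over_k(x, range(1, 7), seed=1)
        vals = [curve[k] for k in range(1, 7)]
        assert np.all(np.diff(vals) <= 1e-9)

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fit_kmeans_over_k(np.zeros((3, 2)), [4], seed=0)


class TestAdjustedInertia:
    CURVE = {2: 40.0, 3: 20.0, 4: 10.0, 5: 9.0}

    def test_large_penalty_selects_k_min(self):
        _, k = adjusted_inertia(self.CURVE, alpha=1.0, inertia1=100.0)
        assert k == 2

    def test_zero_penalty_selects_raw_argmin(self):
        adj, k = adjusted_inertia(self.CURVE, alpha=0.0, inertia1=100.0)
        assert k == 5
        assert np.allclose([adj[x] for x in sorted(adj)],
                           [0.4, 0.2, 0.1, 0.09])

    def test_tie_resolves_to_smallest_k(self):
        # adjusted(2) = 0.2+2a, adjusted(3) = 0.1+3a: equal at a = 0.1
        adj, k = adjusted_inertia({2: 20.0, 3: 10.0}, alpha=0.1, inertia1=100.0)
        assert np.isclose(adj[2], adj[3])
        assert k == 2

    def test_missing_and_degenerate_inertia1(self):
        with pytest.raises(ValueError, match="required"):
            adjusted_inertia({2: 1.0}, alpha=0.1)
        with pytest.raises(ValueError, match="degenerate"):
            adjusted_inertia({2: 0.0}, alpha=0.1, inertia1=0.0)


class TestAssignDomains:
    def test_point_at_centroid_and_tie_break(self):
        model = identity_model([[-1.0], [1.0], [3.0]])
        labels = assign_domains([(np.array([[1.0], [0.0], [2.0]]), None)],
                                model)[0]
        assert labels[0] == 1       # exactly at centroid 1
        assert labels[1] == 0       # equidistant to 0 and 1 -> lowest index
        assert labels[2] == 1       # equidistant to 1 and 2 -> lowest index

    def test_background_labeled_minus_one(self):
        model = identity_model([[0.0], [10.0]])
        feats = np.zeros((2, 2, 1))
        mask = np.array([[True, False], [False, True]])
        labels = assign_domains([(feats, mask)], model)[0]
        assert labels[0, 1] == -1 and labels[1, 0] == -1
        assert labels[0, 0] == 0

    def test_training_subsample_reproduces_fit_labels(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(0, 0.1, (30, 2)),
                       rng.normal(5, 0.1, (30, 2))])
        cfg = LabelerConfig(k=2, subsample_fraction=1.0, seed=4)
        model = fit_tissue_labeler([(x, None)], cfg)
        labels = assign_domains([(x, None)], model)[0]
        # nearest-centroid relabeling of the training rows matches a direct
        # k-means run: within-cluster scatter must equal the fit inertia
        ss = sum(((x_z - model.centroids[l]) ** 2).sum()
                 for x_z, l in zip(model.znorm.transform(x), labels))
        assert np.isclose(ss, model.inertia_curve[2], rtol=1e-9)


class TestDomainProfile:
    def test_k1_profile_is_global_mean(self):
        rng = np.random.default_rng(0)
        x = rng.random((50, 3)) * [1.0, 5.0, 0.2] + [0.0, 1.0, 3.0]
        model = fit_tissue_labeler([(x, None)],
                                   LabelerConfig(k=1, subsample_fraction=1.0))
        prof = domain_profile(model)
        assert np.allclose(prof[0], x.mean(axis=0), atol=1e-6)

    def test_noise_free_profiles_match_planted_truth(self):
        imgs, truths = generate_synthetic_mif(
            n_slides=1, shape=(48, 48), k_true=3, noise_sd=0.0,
            gains=np.ones((1, 4)), seed=5)
        run = fit_mif_pipeline(
            imgs, MifPreprocessConfig(downsample_factor=1, sigma=0.0),
            LabelerConfig(k=3, subsample_fraction=1.0, seed=5))
        normed, _ = log_mean_normalize(imgs[0])
        truth = truths[0]
        expected = np.vstack([
            normed.pixels[truth.labels == d].mean(axis=0) for d in range(3)])
        prof = domain_profile(run.model)
        # match each planted domain to its nearest recovered profile
        for row in expected:
            assert np.min(np.abs(prof - row).max(axis=1)) < 1e-6

    def test_gene_space_back_projection_exact_at_full_rank(self):
        rng = np.random.default_rng(7)
        expr = rng.random((25, 3)) @ rng.random((3, 10))
        emb = reduce_dimensions(expr, 3, normalize=False)
        z, params = z_normalize(emb.coords)
        model = FittedLabeler(centroids=z[[2, 11]], znorm=params, k=2,
                              inertia_curve={}, adjusted_curve={},
                              config=LabelerConfig(k=2))
        prof = domain_profile(model, space="gene", reduction=emb)
        assert np.allclose(prof[0], expr[2], atol=1e-8)
        assert np.allclose(prof[1], expr[11], atol=1e-8)

    def test_gene_space_requires_reduction(self):
        model = identity_model([[0.0], [1.0]])
        with pytest.raises(ValueError, match="reduction"):
            domain_profile(model, space="gene")


class TestSerialization:
    def test_json_round_trip_preserves_assignments(self, tmp_path, mif_run):
        path = save_labeler(mif_run.model, tmp_path / "model.json")
        back = load_labeler(path)
        assert back.k == mif_run.model.k
        assert np.array_equal(back.centroids, mif_run.model.centroids)
        rng = np.random.default_rng(0)
        probe = rng.random((50, len(mif_run.model.feature_names)))
        a = assign_domains([(probe, None)], mif_run.model)[0]
        b = assign_domains([(probe, None)], back)[0]
        assert np.array_equal(a, b)


class TestGainInvarianceEndToEnd:
    def test_labels_identical_under_per_slide_gains(self, mif_small, mif_run):
        images, _ = mif_small
        from conftest import LAB_CFG, MIF_CFG
        gains = [2.0, 0.5]
        gained = [im.with_pixels(im.pixels * g) for im, g in zip(images, gains)]
        run2 = fit_mif_pipeline(gained, MIF_CFG, LAB_CFG)
        for a, b in zip(mif_run.results, run2.results):
            assert np.array_equal(a.labels, b.labels)
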