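"""Stage-2: patch extraction, triplet machinery, auto-encoder training,
clustering, and the deep-embedded-clustering comparison method."""

import numpy as np
import pytest
from scipy import ndimage

from imatseg import labels as L
from imatseg import tissuecluster as tc
from imatseg.labels import TissueLabelMap


@pytest.fixture()
def disk_mask():
    yy, xx = np.mgrid[0:64, 0:64]
    return (yy - 32) ** 2 + (xx - 32) ** 2 <= 24 ** 2


class TestExtractPatches:
    def test_one_patch_per_eroded_pixel(self, disk_mask):
        t2 = np.random.default_rng(0).random((64, 64))
        pd = np.random.default_rng(1).random((64, 64))
        ps = tc.extract_patches(t2, pd, disk_mask)
        eroded = ndimage.binary_erosion(disk_mask, np.ones((16, 16)))
        assert len(ps) == eroded.sum()
        assert ps.patches.shape[1:] == (2, 16, 16)

    def test_window_indexing_convention(self, disk_mask):
        t2 = np.arange(64 * 64, dtype=float).reshape(64, 64)
        pd = np.zeros((64, 64))
        ps = tc.extract_patches(t2, pd, disk_mask)
        r, c = ps.centers[0]
        expected = (t2 * disk_mask)[r - 8:r + 8, c - 8:c + 8]
        assert np.array_equal(ps.patches[0, 0], expected)

    def test_all_viable_map_gives_all_viable_labels(self, disk_mask):
        lab = TissueLabelMap(np.where(disk_mask, L.VIABLE, L.BACKGROUND))
        ps = tc.extract_patches(np.ones((64, 64)), np.ones((64, 64)),
                                disk_mask, lab)
        assert (ps.weak_labels == tc.LABEL_VIABLE).all()

    def test_too_small_mask_raises(self):
        small = np.zeros((64, 64), bool)
        small[30:40, 30:40] = True   # 10x10 < the 16x16 window
        with pytest.raises(ValueError, match="16x16"):
            tc.extract_patches(np.ones((64, 64)), np.ones((64, 64)), small)


class TestTripletSampling:
    def test_positive_shares_anchor_class(self, separable_patchset):
        for seed in range(10):
            a, p, n = tc.sample_triplet(separable_patchset, seed=seed)
            wl = separable_patchset.weak_labels
            assert wl[a] == wl[p]
            assert wl[a] != wl[n]
            assert a != p

    def test_deterministic_given_seed(self, separable_patchset):
        assert (tc.sample_triplet(separable_patchset, seed=3)
                == tc.sample_triplet(separable_patchset, seed=3))

    def test_rejects_single_class(self, separable_patchset):
        ps = tc.PatchSet(
            patches=separable_patchset.patches,
            centers=separable_patchset.centers,
            weak_labels=np.ones(len(separable_patchset), dtype=np.int8))
        with pytest.raises(ValueError):
            tc.sample_triplet(ps, seed=0)


class TestTripletLoss:
    def test_separated_pair_has_zero_loss(self):
        f_a = np.array([1.0, 0.0])
        f_n = np.array([1.0, np.sqrt(2.0)])   # |a-n|^2 = 2
        loss, _ = tc.triplet_loss(f_a, f_a, f_n, margin=1.0)
        assert loss == pytest.approx(0.0)

    def test_collapsed_embedding_pays_the_margin(self):
        v = np.array([0.3, 0.4])
        loss, _ = tc.triplet_loss(v, v, v, margin=1.0)
        assert loss == pytest.approx(1.0)

    def test_intermediate_arithmetic(self):
        f_a = np.zeros(1)
        f_p = np.array([np.sqrt(0.5)])
        f_n = np.array([1.0])
        loss, _ = tc.triplet_loss(f_a, f_p, f_n, margin=1.0)
        assert loss == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tc.triplet_loss(np.zeros(2), np.zeros(3), np.zeros(2))


class TestCombinedLoss:
    def test_perfect_model_zero_loss(self):
        assert tc.combined_loss(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_beta_zero_reduces_to_reconstruction(self):
        assert tc.combined_loss(7.0, 1.0, 2.0, 3.0, beta=0.0, lam=0.5) \
            == pytest.approx(3.0)

    def test_paper_weights_arithmetic(self):
        assert tc.combined_loss(1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            tc.combined_loss(1.0, 1.0, 1.0, 1.0, beta=-0.1)


@pytest.fixture(scope="module")
def small_trained(separable_patchset):
    cfg = tc.DCAEConfig(epochs=6, batch_size=64, seed=0)
    model, history = tc.train_dcaetl(separable_patchset, cfg)
    return model, history


class TestDcaetlTraining:
    def test_embeddings_on_unit_hypersphere(self, small_trained,
                                            separable_patchset):
        model, _ = small_trained
        z = model.embed(separable_patchset.patches)
        assert np.abs(np.linalg.norm(z, axis=1) - 1.0).max() < 1e-5

    def test_classes_separate_in_embedding(self, small_trained,
                                           separable_patchset):
        model, _ = small_trained
        z = model.embed(separable_patchset.patches)
        wl = separable_patchset.weak_labels
        za, zb = z[wl == 1], z[wl == 0]
        within = ((za[:100, None] - za[None, :100]) ** 2).sum(-1).mean()
        between = ((za[:100, None] - zb[None, :100]) ** 2).sum(-1).mean()
        assert within < between

    def test_loss_decreases(self, small_trained):
        _, history = small_trained
        assert history[-1] < history[0]

    def test_requires_weak_labels(self, separable_patchset):
        ps = tc.PatchSet(patches=separable_patchset.patches,
                         centers=separable_patchset.centers,
                         weak_labels=None)
        with pytest.raises(ValueError):
            tc.train_dcaetl(ps, tc.DCAEConfig(epochs=1))

    def test_checkpoint_roundtrip(self, small_trained, separable_patchset,
                                  tmp_path):
        model, _ = small_trained
        z = model.embed(separable_patchset.patches[:8])
        model.save(tmp_path / "dcae.npz")
        loaded = tc.DCAE.load(tmp_path / "dcae.npz")
        assert np.allclose(loaded.embed(separable_patchset.patches[:8]), z,
                           atol=1e-6)


@pytest.fixture(scope="module")
def trained(small_trained):
    return small_trained[0]


class TestClustering:
    def test_separable_clouds_cluster_perfectly(self, trained,
                                                separable_patchset):
        cm = tc.fit_clusters(trained, separable_patchset, seed=0)
        z = trained.embed(separable_patchset.patches)
        acc = (cm.labels_for(z) == separable_patchset.weak_labels).mean()
        assert acc == 1.0
        assert len(cm.centroids) == 2
        assert set(cm.cluster_to_label.values()) == {0, 1}

    def test_same_seed_identical_centroids(self, trained, separable_patchset):
        c1 = tc.fit_clusters(trained, separable_patchset, seed=0)
        c2 = tc.fit_clusters(trained, separable_patchset, seed=0)
        assert np.array_equal(c1.centroids, c2.centroids)

    def test_classify_pixels_constant_propagation(self, trained, disk_mask):
        # a slice whose muscle is uniformly low-T2: every interior patch
        # labels viable, and boundary fill must propagate that label
        rng = np.random.default_rng(3)
        t2 = 40.0 + rng.normal(0, 3.0, (64, 64))
        pd = 0.9 + rng.normal(0, 0.05, (64, 64))
        cm = tc.fit_clusters(trained, _subset_for_clusters(trained), seed=0)
        lab = tc.classify_pixels(cm, trained, t2, pd, disk_mask)
        assert (lab.labels[disk_mask] == L.VIABLE).all()
        assert (lab.labels[~disk_mask] == L.BACKGROUND).all()

    def test_every_mask_pixel_labeled(self, trained, disk_mask):
        rng = np.random.default_rng(4)
        t2 = np.where(rng.random((64, 64)) > 0.5, 150.0, 40.0)
        pd = np.full((64, 64), 0.9)
        cm = tc.fit_clusters(trained, _subset_for_clusters(trained), seed=0)
        lab = tc.classify_pixels(cm, trained, t2, pd, disk_mask)
        inside = lab.labels[disk_mask]
        assert ((inside == L.VIABLE) | (inside == L.IMAT)).all()


def _subset_for_clusters(model):
    """Small separable patch set regenerated for cluster fitting."""
    rng = np.random.default_rng(8)
    n = 60
    patches = np.empty((2 * n, 2, 16, 16), dtype=np.float32)
    labels = np.empty(2 * n, dtype=np.int8)
    for i in range(2 * n):
        viable = i < n
        patches[i, 0] = (40.0 if viable else 150.0) + rng.normal(0, 3, (16, 16))
        patches[i, 1] = 0.9 + rng.normal(0, 0.05, (16, 16))
        labels[i] = tc.LABEL_VIABLE if viable else tc.LABEL_IMAT
    return tc.PatchSet(patches=patches, centers=np.full((2 * n, 2), 8),
                       weak_labels=labels)


class TestIntensityKmeans:
    def test_bimodal_t2_partitions_perfectly(self, disk_mask):
        t2 = np.where(np.random.default_rng(0).random((64, 64)) > 0.4,
                      150.0, 40.0)
        pd = np.full((64, 64), 0.9)
        truth = np.where(disk_mask, np.where(t2 > 100, L.IMAT, L.VIABLE),
                         L.BACKGROUND)
        lab = tc.baseline_intensity_kmeans(t2, pd, disk_mask, seed=0)
        assert np.array_equal(lab.labels, truth)

    def test_constant_intensities_rejected(self, disk_mask):
        with pytest.raises(ValueError):
            tc.baseline_intensity_kmeans(np.ones((64, 64)), np.ones((64, 64)),
                                         disk_mask, seed=0)

    def test_deterministic(self, disk_mask):
        rng = np.random.default_rng(1)
        t2 = rng.normal(80, 40, (64, 64))
        pd = rng.normal(1, 0.1, (64, 64))
        a = tc.baseline_intensity_kmeans(t2, pd, disk_mask, seed=5)
        b = tc.baseline_intensity_kmeans(t2, pd, disk_mask, seed=5)
        assert np.array_equal(a.labels, b.labels)


class TestDcaeKmeans:
    def test_history_is_pure_reconstruction_loss(self, separable_patchset):
        cfg = tc.DCAEConfig(epochs=2, batch_size=64, seed=0)
        model, cm, history = tc.train_dcae_kmeans(separable_patchset, cfg)
        assert all(h >= 0 for h in history)
        z = model.embed(separable_patchset.patches)
        assert np.abs(np.linalg.norm(z, axis=1) - 1.0).max() < 1e-5

    def test_competitive_with_intensity_kmeans_on_separable_set(
            self, separable_patchset, disk_mask):
        cfg = tc.DCAEConfig(epochs=6, batch_size=64, seed=0)
        model, cm, _ = tc.train_dcae_kmeans(separable_patchset, cfg)
        z = model.embed(separable_patchset.patches)
        acc_dcae = (cm.labels_for(z) == separable_patchset.weak_labels).mean()
        # pixel-intensity baseline on an equally separable image
        t2 = np.where(np.random.default_rng(0).random((64, 64)) > 0.5,
                      150.0, 40.0)
        lab = tc.baseline_intensity_kmeans(t2, np.full((64, 64), 0.9),
                                           disk_mask, seed=0)
        truth = np.where(t2 > 100, L.IMAT, L.VIABLE)
        acc_km = (lab.labels[disk_mask] == truth[disk_mask]).mean()
        assert acc_dcae >= acc_km - 0.05


class TestDeepEmbeddedClustering:
    def test_soft_assignment_symmetry_and_arithmetic(self):
        mu = np.array([[0.0, 0.0], [2.0, 0.0]])
        q = tc.soft_assignment(np.array([[1.0, 0.0]]), mu)
        assert np.allclose(q, [0.5, 0.5])
        mu2 = np.array([[0.0], [np.sqrt(3.0)]])
        q2 = tc.soft_assignment(np.array([[0.0]]), mu2)
        assert np.allclose(q2, [0.8, 0.2])

    def test_soft_assignment_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        q = tc.soft_assignment(rng.normal(size=(50, 4)),
                               rng.normal(size=(2, 4)))
        assert np.abs(q.sum(axis=1) - 1.0).max() < 1e-12

    def test_target_distribution_examples(self):
        q = np.full((5, 2), 0.5)
        assert np.allclose(tc.target_distribution(q), q)
        q1 = np.array([[0.9, 0.1]])
        assert np.allclose(tc.target_distribution(q1), [[0.9, 0.1]])

    def test_target_distribution_sharpens(self):
        q = np.array([[0.6, 0.4], [0.4, 0.6]])
        p = tc.target_distribution(q)
        assert p[0, 0] > q[0, 0]
        assert p[1, 1] > q[1, 1]

    def test_target_distribution_rejects_empty(self):
        with pytest.raises(ValueError):
            tc.target_distribution(np.zeros((0, 2)))

    def test_kl_divergence_identity(self):
        p = np.array([[0.7, 0.3], [0.2, 0.8]])
        assert tc.kl_divergence(p, p) == pytest.approx(0.0)
        assert tc.kl_divergence(p, np.array([[0.5, 0.5], [0.5, 0.5]])) > 0

    def test_training_stops_when_assignments_stabilize(self,
                                                       separable_patchset):
        cfg = tc.DCAEConfig(epochs=50, batch_size=64, seed=0)
        model, cm, history = tc.train_dcae_dc(
            separable_patchset, cfg, update_interval=10, stop_delta=1.0)
        # delta = 1.0 means any change fraction < 1 triggers the stop at the
        # first target-distribution update
        assert len(history) < 50
        assert len(cm.centroids) == 2

    def test_separable_set_clusters_correctly(self, separable_patchset):
        cfg = tc.DCAEConfig(epochs=8, batch_size=64, seed=0)
        model, cm, _ = tc.train_dcae_dc(separable_patchset, cfg,
                                        update_interval=20)
        z = model.embed(separable_patchset.patches)
        q = tc.soft_assignment(z, cm.centroids)
        lut = np.array([cm.cluster_to_label[0], cm.cluster_to_label[1]])
        acc = (lut[np.argmax(q, axis=1)]
               == separable_patchset.weak_labels).mean()
        assert acc >= 0.95
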