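"""Augmentation, features, kernels and grouped CV: structure and separability."""

import numpy as np
import pytest

from fibromech import classify, synth
from fibromech.classify import (
    DEFAULT_GRIDS,
    KernelSpec,
    SegmentSample,
    build_segment_dataset,
    external_validate,
    extract_afm_features,
    extract_image_features,
    fuse_modalities,
    gram_matrix,
    grouped_cv_train_eval,
    kernel_eval,
    split_map,
    tile_image,
)


class TestSegmentation:
    def test_image_tiling_counts_and_disjointness(self, rng):
        img = rng.random((512, 512))
        tiles = tile_image(img, 128)
        assert len(tiles) == 16
        # union of tiles reconstructs the source exactly (pixel multiset)
        stacked = np.sort(np.concatenate([t.ravel() for t in tiles]))
        assert np.array_equal(stacked, np.sort(img.ravel()))

    def test_map_quadrants(self, rng):
        grid = rng.random((16, 16))
        segs = split_map(grid, 8)
        assert len(segs) == 4
        assert np.array_equal(
            np.sort(np.concatenate([s.ravel() for s in segs])),
            np.sort(grid.ravel()),
        )

    def test_oversized_tile_single_segment(self, rng):
        img = rng.random((50, 50))
        assert len(tile_image(img, 128)) == 1

    def test_augment_carries_specimen_labels(self, rng):
        data = {"s1": rng.random((8, 8)), "s2": rng.random((8, 8))}
        labels = {"s1": "control", "s2": "bleomycin"}
        segs = classify.augment_by_segmentation(data, labels, 4, kind="map")
        assert len(segs) == 8
        assert {(sid, lab) for sid, lab, _, _ in segs} == set(labels.items())


class TestImageFeatures:
    def test_constant_tile_zero_gradients(self):
        feats = extract_image_features(np.full((64, 64), 0.5))
        hog_part = feats[:-10]
        assert np.all(hog_part == 0)

    def test_lbp_histogram_mass_conserved(self, rng):
        tile = rng.random((64, 64))
        f0 = extract_image_features(tile)
        f180 = extract_image_features(np.rot90(tile, 2).copy())
        assert f0[-10:].sum() == pytest.approx(1.0)
        assert f180[-10:].sum() == pytest.approx(1.0)

    def test_fixed_dimension(self, rng):
        dims = {extract_image_features(rng.random((64, 64))).size for _ in range(3)}
        assert len(dims) == 1

    def test_collagen_contrast_linearly_separable(self):
        """High- vs low-collagen tiles: training accuracy 100% at n=40."""
        from sklearn.svm import LinearSVC

        feats, labels = [], []
        for i in range(20):
            hi = synth.simulate_polarized_image(0.25, 0.10, size=64, seed=i)
            lo = synth.simulate_polarized_image(0.02, 0.01, size=64, seed=100 + i)
            feats.append(extract_image_features(hi.polarized))
            labels.append(1)
            feats.append(extract_image_features(lo.polarized))
            labels.append(0)
        x = np.array(feats)
        y = np.array(labels)
        clf = LinearSVC(C=10.0).fit(x, y)
        assert clf.score(x, y) == 1.0


class TestAfmFeatures:
    def test_constant_segment(self):
        f = extract_afm_features(np.full(64, 5.0))
        hist = f[:16]
        assert (hist > 0).sum() == 1
        assert f[-2] == 0.0  # CV%
        assert f[-1] == 0.0  # IQR

    def test_order_invariance(self, rng):
        v = rng.lognormal(0.5, 0.4, 64)
        np.testing.assert_array_equal(
            extract_afm_features(v), extract_afm_features(rng.permutation(v))
        )

    def test_too_small_segment_rejected(self):
        with pytest.raises(ValueError):
            extract_afm_features(np.ones(8))

    def test_hep_weight_contrast_separable(self):
        """Mixtures differing only in hep_weight (0.1 vs 0.4): CV accuracy > 90%."""
        from sklearn.model_selection import cross_val_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        rng = np.random.default_rng(0)
        low = synth.TissueMechanicsModel(2.0, 0.15, 30.0, 0.22, 0.1)
        high = synth.TissueMechanicsModel(2.0, 0.15, 30.0, 0.22, 0.4)
        x = np.array(
            [extract_afm_features(low.sample_moduli(64, rng)) for _ in range(100)]
            + [extract_afm_features(high.sample_moduli(64, rng)) for _ in range(100)]
        )
        y = np.r_[np.zeros(100), np.ones(100)]
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear"))
        assert cross_val_score(clf, x, y, cv=5).mean() > 0.90


class TestKernels:
    def test_rbf_self_similarity(self, rng):
        spec = KernelSpec("rbf")
        for _ in range(3):
            x = rng.normal(0, 1, 10)
            assert kernel_eval(spec, x, x, gamma=0.7) == pytest.approx(1.0)

    def test_linear_gram_of_orthonormal_basis(self):
        spec = KernelSpec("linear")
        np.testing.assert_allclose(gram_matrix(spec, np.eye(5)), np.eye(5))

    def test_relu_kernel_parallel_vectors(self, rng):
        """At zero angle the arc-cosine kernel equals |x||y| exactly."""
        spec = KernelSpec("relu")
        x = rng.normal(0, 1, 6)
        y = 2.5 * x
        expected = np.linalg.norm(x) * np.linalg.norm(y)
        assert kernel_eval(spec, x, y) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("kind", ["linear", "rbf", "relu", "sigmoid"])
    def test_gram_symmetry(self, kind, rng):
        spec = KernelSpec(kind)
        x = rng.normal(0, 1, (12, 5))
        g = gram_matrix(spec, x, gamma=0.3, coef0=0.5)
        np.testing.assert_allclose(g, g.T, atol=1e-12)

    @pytest.mark.parametrize("kind", ["linear", "rbf", "relu"])
    def test_gram_positive_semidefinite(self, kind, rng):
        spec = KernelSpec(kind)
        x = rng.normal(0, 1, (20, 6))
        g = gram_matrix(spec, x, gamma=0.5)
        assert np.linalg.eigvalsh(g).min() >= -1e-8

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval(KernelSpec("linear"), np.ones(3), np.ones(4))


def _toy_cohort_samples(n_specs=24, segs=6, sep=4.0, seed=0, modality="afm"):
    """Perfectly structured segment samples: two Gaussian classes."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_specs):
        label = "control" if i < n_specs // 2 else "bleomycin"
        mu = 0.0 if label == "control" else sep
        for j in range(segs):
            samples.append(SegmentSample(
                features=rng.normal(mu, 1.0, 8),
                specimen_id=f"S{i}", modality=modality, label=label,
                segment_index=j,
            ))
    return samples


class TestGroupedCV:
    def test_no_specimen_leakage(self):
        samples = _toy_cohort_samples()
        res = grouped_cv_train_eval(samples, KernelSpec("linear", c_grid=(1.0,)),
                                    k=8, seed=0)
        assert res.is_test_accuracy
        assert res.k == 8  # the internal assertion guards the fold structure

    def test_separable_cohort_perfect_range(self):
        samples = _toy_cohort_samples(sep=8.0)
        res = grouped_cv_train_eval(samples, KernelSpec("linear", c_grid=(1.0,)),
                                    k=6, seed=1)
        assert res.accuracy_range == (1.0, 1.0)
        assert res.accuracy_range_percent == "100-100%"

    def test_k_lowered_when_few_groups(self):
        samples = _toy_cohort_samples(n_specs=6)
        res = grouped_cv_train_eval(samples, KernelSpec("linear", c_grid=(1.0,)),
                                    k=20, seed=0)
        assert res.k == 6
        assert "lowered" in res.warning

    def test_randomized_label_null(self):
        """Labels randomized independently of the data: accuracy at chance.

        iid relabeling is the unbiased randomization null; shuffling a fixed
        label multiset without replacement instead depletes a test specimen's
        own label from its feature cluster's training labels and pushes
        grouped-CV accuracy systematically below 50% at small specimen counts.
        """
        accs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            samples = _toy_cohort_samples(sep=5.0, seed=seed)
            ids = sorted({s.specimen_id for s in samples})
            relab = {i: ("control" if rng.random() < 0.5 else "bleomycin")
                     for i in ids}
            if len(set(relab.values())) < 2:
                continue
            for s in samples:
                s.label = relab[s.specimen_id]
            res = grouped_cv_train_eval(samples, KernelSpec("linear", c_grid=(1.0,)),
                                        k=8, seed=seed)
            accs.append(res.mean_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.10

    def test_optional_pca_reduction(self):
        """PCA stage (off by default) reduces dimension without breaking CV."""
        samples = _toy_cohort_samples(sep=6.0)
        res = grouped_cv_train_eval(samples, KernelSpec("linear", c_grid=(1.0,)),
                                    k=6, seed=0, pca_components=3)
        assert res.mean_accuracy > 0.9

    def test_selection_reproducible(self):
        samples = _toy_cohort_samples(sep=1.0)
        spec = KernelSpec("rbf", c_grid=(0.1, 1.0), gamma_grid=("scale", 0.1))
        a = grouped_cv_train_eval(samples, spec, k=6, seed=3)
        b = grouped_cv_train_eval(samples, spec, k=6, seed=3)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.fold_params == b.fold_params


class TestFusion:
    def test_fused_dimension_is_sum(self):
        opt = _toy_cohort_samples(modality="optical")
        afm = _toy_cohort_samples(modality="afm")
        fused, log = fuse_modalities(opt, afm)
        assert fused[0].features.size == 16
        assert log["unpaired_segments_dropped"] == 0

    def test_unmatched_specimen_excluded_and_logged(self):
        opt = _toy_cohort_samples(n_specs=6, modality="optical")
        afm = [s for s in _toy_cohort_samples(n_specs=6) if s.specimen_id != "S0"]
        fused, log = fuse_modalities(opt, afm)
        assert "S0" in log["specimens_excluded"]
        assert all(s.specimen_id != "S0" for s in fused)

    def test_self_fusion_accuracy_within_one_fold(self):
        """Fusing a modality with itself changes accuracy by <= one fold's worth."""
        afm = _toy_cohort_samples(sep=2.0, seed=5)
        fused, _ = fuse_modalities(afm, afm)
        spec = KernelSpec("linear", c_grid=(1.0,))
        single = grouped_cv_train_eval(afm, spec, k=8, seed=2).mean_accuracy
        double = grouped_cv_train_eval(fused, spec, k=8, seed=2).mean_accuracy
        assert abs(single - double) <= 1.0 / 8 + 1e-9


class TestExternalValidation:
    def test_unanimous_and_tie_calls(self):
        train = _toy_cohort_samples(sep=8.0, seed=7)
        holdout = []
        rng = np.random.default_rng(8)
        # clearly fibrotic specimen: unanimous vote
        for j in range(4):
            holdout.append(SegmentSample(rng.normal(8.0, 0.5, 8), "H0", "afm",
                                         "bleomycin", j))
        # engineered tie: two segments on each side of the boundary
        for j, mu in enumerate((-3.0, -3.0, 11.0, 11.0)):
            holdout.append(SegmentSample(rng.normal(mu, 0.01, 8), "H1", "afm",
                                         "bleomycin", j))
        calls = external_validate(train, holdout, KernelSpec("linear", c_grid=(1.0,)))
        by_id = {c.specimen_id: c for c in calls}
        assert by_id["H0"].call == "bleomycin"
        assert by_id["H0"].vote_fraction == 1.0
        assert by_id["H1"].call == "indeterminate"

    def test_overlapping_cohorts_rejected(self):
        train = _toy_cohort_samples(n_specs=4)
        with pytest.raises(ValueError):
            external_validate(train, train[:2], KernelSpec("linear"))

    def test_stronger_effect_holdout_all_called(self):
        """Holdout at larger effect size: all fibrotic specimens identified."""
        hits, total = 0, 0
        for seed in range(5):
            cohort = synth.simulate_cohort(
                synth.classification_design(n_control=8, n_bleomycin=8, seed=seed),
                include_curves=False,
            )
            opt, afm = build_segment_dataset(cohort)
            # human-like holdout: stronger fibrosis than the murine training arm
            strong = synth.TissueMechanicsModel(2.0, 0.2, 45.0, 0.22, 0.55)
            rng = np.random.default_rng(1000 + seed)
            holdout = [
                SegmentSample(extract_afm_features(strong.sample_moduli(16, rng)),
                              f"H{i}", "afm", "bleomycin", j)
                for i in range(3) for j in range(8)
            ]
            calls = external_validate(afm, holdout,
                                      KernelSpec("linear", c_grid=(1.0,)))
            hits += sum(c.call == "bleomycin" for c in calls)
            total += len(calls)
        assert hits / total >= 0.9


class TestDefaultExperiment:
    def test_segment_dataset_shapes(self):
        cohort = synth.simulate_cohort(
            synth.classification_design(n_control=3, n_bleomycin=3, seed=4),
            include_curves=False,
        )
        opt, afm = build_segment_dataset(cohort)
        assert len(opt) == len(afm) == 6 * 16
        fused, log = fuse_modalities(opt, afm)
        assert len(fused) == 6 * 16
        assert log["n_fused"] == 96
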