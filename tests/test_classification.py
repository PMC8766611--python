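"""Crop augmentation, CSP, PCA, LDA evaluation, balanced accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.linalg import subspace_angles

from thermoeeg.classification import (
    CropSet,
    _class_covariance,
    bacc,
    bacc_multiclass,
    crop_augment,
    csp_features,
    decode_crops,
    fit_csp,
    reduce_pca,
    train_eval,
)
from thermoeeg.preprocessing import EpochSet

FS = 512.0


def _epochs(data, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels if labels is not None else ["w"] * data.shape[0]
    return EpochSet(
        data=data, fs=FS, labels=np.array(labels),
        parent_ids=np.arange(data.shape[0]),
        channel_names=[f"ch{i}" for i in range(data.shape[1])],
        window=(0.0, data.shape[2] / FS),
    )


def _gaussian_crops(rng, cov, n_crops, n_samples=256):
    chol = np.linalg.cholesky(cov)
    return np.stack(
        [chol @ rng.standard_normal((cov.shape[0], n_samples)) for _ in range(n_crops)]
    )


class TestCropAugment:
    def test_thirty_second_trial_yields_ten_crops(self, rng):
        ep = _epochs(rng.normal(0, 1, (1, 2, int(30 * FS))))
        crops = crop_augment(ep, 3.0, 3.0)
        assert crops.n_crops == 10

    def test_fifty_trials_yield_five_hundred(self, rng):
        ep = _epochs(np.zeros((50, 1, int(30 * FS))))
        assert crop_augment(ep, 3.0, 3.0).n_crops == 500

    def test_window_equal_trial_is_identity(self, rng):
        data = rng.normal(0, 1, (2, 3, 1536))
        crops = crop_augment(_epochs(data), 3.0, 3.0)
        assert crops.n_crops == 2
        assert np.array_equal(crops.data, data)

    def test_window_longer_than_trial_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            crop_augment(_epochs(np.zeros((1, 1, 512))), 3.0, 3.0)

    def test_concatenating_crops_reconstructs_parent(self, rng):
        data = rng.normal(0, 1, (3, 2, int(30 * FS)))
        crops = crop_augment(_epochs(data), 3.0, 3.0)
        for parent in range(3):
            sel = crops.parent_ids == parent
            parts = crops.data[sel][np.argsort(crops.offsets[sel])]
            rebuilt = np.concatenate(list(parts), axis=1)
            assert np.array_equal(rebuilt, data[parent])


class TestCSP:
    def test_toy_two_channel_eigenvalue(self, rng):
        ca = np.diag([4.0, 1.0])
        cb = np.diag([1.0, 4.0])
        data = np.concatenate(
            [_gaussian_crops(rng, ca, 60, 2048), _gaussian_crops(rng, cb, 60, 2048)]
        )
        labels = ["A"] * 60 + ["B"] * 60
        model = fit_csp(data, labels, n_pairs=1, shrinkage=0.0)
        assert model.eigenvalues[0] == pytest.approx(0.8, abs=0.02)
        w = model.filters[0] / np.linalg.norm(model.filters[0])
        assert abs(w[0]) > 0.99  # aligned with the channel-1 axis

    def test_identical_covariances_give_half(self, rng):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        data = np.concatenate(
            [_gaussian_crops(rng, cov, 80, 2048), _gaussian_crops(rng, cov, 80, 2048)]
        )
        labels = ["A"] * 80 + ["B"] * 80
        model = fit_csp(data, labels, n_pairs=1)
        assert np.allclose(model.eigenvalues, 0.5, atol=0.03)

    def test_projected_class_covariances_diagonal(self, rng):
        n_ch = 5
        a = rng.normal(0, 1, (n_ch, n_ch))
        b = rng.normal(0, 1, (n_ch, n_ch))
        da = _gaussian_crops(rng, a @ a.T + np.eye(n_ch), 40)
        db = _gaussian_crops(rng, b @ b.T + np.eye(n_ch), 40)
        data = np.concatenate([da, db])
        labels = ["A"] * 40 + ["B"] * 40
        model = fit_csp(data, labels, n_pairs=2, shrinkage=0.0)
        # the full eigenbasis diagonalizes both class-average covariances
        full = fit_csp(data, labels, n_pairs=n_ch // 2, shrinkage=0.0)
        ca = _class_covariance(da)
        cb = _class_covariance(db)
        for cov in (ca, cb):
            proj = full.filters @ cov @ full.filters.T
            off = proj - np.diag(np.diag(proj))
            assert np.abs(off).max() < 1e-8

    @pytest.mark.parametrize("n_ch", [4, 6, 8])
    def test_against_dense_generalized_eig_oracle(self, rng, n_ch):
        a = rng.normal(0, 1, (n_ch, n_ch))
        b = rng.normal(0, 1, (n_ch, n_ch))
        da = _gaussian_crops(rng, a @ a.T + 0.5 * np.eye(n_ch), 30)
        db = _gaussian_crops(rng, b @ b.T + 0.5 * np.eye(n_ch), 30)
        data = np.concatenate([da, db])
        labels = ["A"] * 30 + ["B"] * 30
        n_pairs = n_ch // 2
        model = fit_csp(data, labels, n_pairs=n_pairs, shrinkage=0.0)
        # independent oracle: eigenvectors of inv(Ca+Cb) @ Ca via np.linalg.eig
        ca, cb = _class_covariance(da), _class_covariance(db)
        evals, evecs = np.linalg.eig(np.linalg.inv(ca + cb) @ ca)
        order = np.argsort(evals.real)
        keep = list(order[::-1][:n_pairs]) + list(order[:n_pairs])
        oracle = evecs.real[:, keep]
        angles = subspace_angles(model.filters.T, oracle)
        assert angles.max() < 1e-6

    def test_rank_deficiency_advises_shrinkage(self):
        data = np.zeros((8, 3, 64))
        data[:, 0, :] = np.random.default_rng(0).normal(size=(8, 64))
        labels = ["A"] * 4 + ["B"] * 4
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_csp(data, labels, n_pairs=1, shrinkage=0.0)


class TestCSPFeatures:
    def _model_and_crops(self, rng, n_ch=4, n_crops=12):
        data = rng.normal(0, 1, (n_crops, n_ch, 256))
        labels = ["A"] * (n_crops // 2) + ["B"] * (n_crops // 2)
        return fit_csp(data, labels, n_pairs=2), data

    def test_feature_length_is_twice_pairs(self, rng):
        model, data = self._model_and_crops(rng)
        feats = csp_features(model, data)
        assert feats.shape == (data.shape[0], 4)

    def test_scaling_shifts_by_two_log_c(self, rng):
        model, data = self._model_and_crops(rng)
        f1 = csp_features(model, data)
        f2 = csp_features(model, 3.0 * data)
        assert np.allclose(f2 - f1, 2 * np.log(3.0), atol=1e-9)

    def test_channel_count_mismatch_rejected(self, rng):
        model, data = self._model_and_crops(rng)
        with pytest.raises(ValueError, match="channel count"):
            csp_features(model, data[:, :3, :])


class TestPCA:
    def test_full_rank_preserves_variance(self, rng):
        x = rng.normal(0, 1, (50, 4))
        scores, evr = reduce_pca(x, k=4)
        assert evr.sum() == pytest.approx(1.0)
        assert scores.var(axis=0, ddof=1).sum() == pytest.approx(
            x.var(axis=0, ddof=1).sum()
        )

    def test_isotropic_split_even(self, rng):
        x = rng.normal(0, 1, (4000, 2))
        _, evr = reduce_pca(x, k=2)
        assert evr[0] == pytest.approx(0.5, abs=0.05)

    def test_rank_one_first_component_everything(self, rng):
        base = rng.normal(0, 1, (100, 1))
        x = base @ np.array([[1.0, -2.0, 0.5]])
        _, evr = reduce_pca(x, k=2)
        assert evr[0] == pytest.approx(1.0)

    def test_k_above_dimension_rejected(self, rng):
        with pytest.raises(ValueError):
            reduce_pca(rng.normal(0, 1, (10, 2)), k=3)

    def test_sign_convention_deterministic(self, rng):
        x = rng.normal(0, 1, (60, 5))
        s1, _ = reduce_pca(x, k=2)
        s2, _ = reduce_pca(x.copy(), k=2)
        assert np.array_equal(s1, s2)


class TestTrainEval:
    def test_separable_blobs_perfect(self, rng):
        x = np.concatenate(
            [rng.normal(-5, 0.3, (50, 2)), rng.normal(5, 0.3, (50, 2))]
        )
        y = ["a"] * 50 + ["b"] * 50
        rep = train_eval(x, y, seed=0)
        assert rep.test_bacc == 1.0
        assert rep.validation_bacc == 1.0

    def test_permuted_labels_at_chance(self, rng):
        x = rng.normal(0, 1, (500, 4))
        y = rng.permutation(["a", "b"] * 250)
        rep = train_eval(x, y, seed=1)
        assert 0.4 <= rep.test_bacc <= 0.6

    def test_group_purity_of_splits(self, rng):
        n_groups = 40
        groups = np.repeat(np.arange(n_groups), 10)
        y = np.repeat(["a", "b"] * (n_groups // 2), 10)
        x = rng.normal(0, 1, (len(y), 3))
        x[y == "b"] += 2.0
        rep = train_eval(x, y, seed=2, groups=groups)
        assert rep.group_aware
        # the confusion matrix accounts for whole test groups only
        assert rep.confusion.sum() % 10 == 0


class TestBacc:
    def test_diagonal_confusion_perfect(self):
        assert bacc(np.diag([7, 13])) == 1.0

    def test_hand_value(self):
        # TP=8 FN=2 / FP=4 TN=6 -> (0.8 + 0.6)/2
        assert bacc(np.array([[8, 2], [4, 6]])) == pytest.approx(0.7)

    def test_class_swap_invariance(self, rng):
        m = rng.integers(1, 20, (2, 2))
        swapped = m[::-1, ::-1]
        assert bacc(m) == pytest.approx(bacc(swapped))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            bacc(np.array([[0, 0], [3, 5]]))

    def test_multiclass_mean_recall(self):
        m = np.diag([5, 5, 5, 5, 5])
        assert bacc_multiclass(m) == 1.0
        m[0, 0], m[0, 1] = 0, 5
        assert bacc_multiclass(m) == pytest.approx(0.8)
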