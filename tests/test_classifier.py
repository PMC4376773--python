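"""Object features and the false-positive removal classifier."""

import numpy as np
import pytest

from scmseg import (DataError, FEATURE_NAMES, NotTrainedError,
                    extract_features, filter_objects, load_model,
                    save_model, train_classifier)


def disk_mask(radius: int, pad: int = 5):
    size = 2 * (radius + pad) + 1
    rr, cc = np.indices((size, size))
    c = radius + pad
    mask = (((rr - c) ** 2 + (cc - c) ** 2) <= radius**2).astype(np.int32)
    return mask


def separable_clusters(n: int, seed: int = 0):
    """Two Gaussian feature clusters 6 sigma apart: a perfect oracle for
    classifier accuracy (near-certain separability)."""
    rng = np.random.default_rng(seed)
    half = n // 2
    base = np.abs(rng.normal(5.0, 0.5, size=(n, len(FEATURE_NAMES))))
    base[half:] += 6.0 * 0.5  # shift the second cluster by 6 sigma
    labels = np.zeros(n, dtype=bool)
    labels[half:] = True
    return base, labels


class TestExtractFeatures:
    def test_uniform_disk_geometry(self):
        mask = disk_mask(25)
        image = np.where(mask > 0, 0.8, 0.2)
        (vec,) = extract_features(mask, image)
        feat = dict(zip(FEATURE_NAMES, vec))
        assert len(vec) == len(FEATURE_NAMES) == 8
        assert feat["eccentricity"] == pytest.approx(0.0, abs=0.05)
        assert feat["solidity"] == pytest.approx(1.0, abs=0.05)
        assert feat["extent"] == pytest.approx(np.pi / 4, abs=0.04)
        assert feat["fg_mean"] == pytest.approx(0.8)
        assert feat["fg_std"] == 0.0
        assert feat["bg_mean"] == pytest.approx(0.2)

    def test_single_pixel_conventions(self):
        mask = np.zeros((7, 7), dtype=np.int32)
        mask[3, 3] = 1
        (vec,) = extract_features(mask, np.full((7, 7), 0.5))
        feat = dict(zip(FEATURE_NAMES, vec))
        assert feat["area"] == 1
        assert feat["extent"] == 1
        assert feat["solidity"] == 1
        assert feat["eccentricity"] == 0

    def test_empty_mask_gives_empty_matrix(self):
        out = extract_features(np.zeros((5, 5), dtype=np.int32),
                               np.zeros((5, 5)))
        assert out.shape == (0, 8)

    def test_equivariant_under_relabeling(self, rng):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[2:8, 2:8] = 1
        mask[20:30, 15:22] = 2
        mask[33:36, 30:38] = 3
        image = rng.uniform(0.0, 1.0, size=(40, 40))
        feats = extract_features(mask, image)
        # Swap labels 1 and 3: rows must swap accordingly.
        remapped = mask.copy()
        remapped[mask == 1] = 3
        remapped[mask == 3] = 1
        swapped = extract_features(remapped, image)
        np.testing.assert_allclose(swapped, feats[[2, 1, 0]])

    def test_neighbouring_object_excluded_from_background_ring(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[8:12, 4:8] = 1
        mask[8:12, 9:13] = 2  # one pixel gap between objects
        image = np.full((20, 20), 0.1)
        image[mask == 2] = 1.0  # bright neighbour
        feats = extract_features(mask, image)
        bg_mean_1 = dict(zip(FEATURE_NAMES, feats[0]))["bg_mean"]
        assert bg_mean_1 == pytest.approx(0.1)


class TestTrainClassifier:
    def test_separable_clusters_reach_high_accuracy(self):
        X, y = separable_clusters(1800)
        clf = train_classifier(X, y, seed=3)
        assert clf.test_accuracy >= 0.95

    def test_split_sizes_follow_70_15_15(self):
        X, y = separable_clusters(1800)
        clf = train_classifier(X, y, seed=3)
        assert (clf.n_train, clf.n_val, clf.n_test) == (1260, 270, 270)

    def test_reproducible_for_fixed_seed(self):
        X, y = separable_clusters(400)
        a = train_classifier(X, y, seed=11)
        b = train_classifier(X, y, seed=11)
        assert a.test_accuracy == b.test_accuracy
        assert (a.predict(X) == b.predict(X)).all()

    def test_single_class_rejected(self):
        X, _ = separable_clusters(100)
        with pytest.raises(DataError):
            train_classifier(X, np.ones(100, dtype=bool), seed=0)

    def test_too_few_samples_rejected(self):
        X, y = separable_clusters(10)
        with pytest.raises(DataError):
            train_classifier(X, y, seed=0)


@pytest.fixture(scope="module")
def permissive_clf():
    X, y = separable_clusters(200, seed=1)
    return train_classifier(X, y, seed=5)


class TestFilterObjects:
    def test_empty_mask_passes_through(self, permissive_clf):
        mask = np.zeros((10, 10), dtype=np.int32)
        out = filter_objects(permissive_clf, mask, np.zeros((10, 10)))
        assert out.max() == 0

    def test_untrained_classifier_rejected(self):
        with pytest.raises(NotTrainedError):
            filter_objects("not a classifier",
                           np.zeros((5, 5), dtype=np.int32),
                           np.zeros((5, 5)))

    def test_never_creates_pixels_and_relabels_contiguously(self, rng,
                                                            permissive_clf):
        mask = np.zeros((30, 30), dtype=np.int32)
        mask[2:8, 2:8] = 1
        mask[12:20, 12:18] = 2
        mask[24:28, 5:15] = 3
        image = rng.uniform(0.0, 1.0, size=(30, 30))
        out = filter_objects(permissive_clf, mask, image)
        assert not out[mask == 0].any()
        present = np.unique(out)
        assert (np.diff(present) == 1).all()


class TestModelSerialization:
    def test_round_trip_preserves_decisions(self, tmp_path):
        X, y = separable_clusters(400)
        clf = train_classifier(X, y, seed=2)
        path = tmp_path / "model.json"
        save_model(clf, path)
        restored = load_model(path)
        np.testing.assert_allclose(restored.predict_proba(X),
                                   clf.predict_proba(X))
        assert (restored.predict(X) == clf.predict(X)).all()
        assert restored.test_accuracy == clf.test_accuracy

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(DataError):
            load_model(path)
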