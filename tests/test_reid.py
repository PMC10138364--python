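"""Bag-of-visual-words re-identification components."""

import numpy as np
import pytest

from gericare.reid import (
    DetectorParams,
    IdentityModel,
    Vocabulary,
    build_vocabulary,
    encode,
    extract_descriptors,
    predict_identity,
    train_identifier,
)
from gericare.synthetic import generate_ward_images


@pytest.fixture(scope="module")
def textured_image():
    return generate_ward_images(identities=1, per_class=2, seed=3)[0][0]


class TestDescriptors:
    def test_constant_image_yields_no_descriptors(self):
        img = np.full((32, 32), 100, dtype=np.uint8)
        assert len(extract_descriptors(img)) == 0

    def test_deterministic_on_identical_input(self, textured_image):
        d1 = extract_descriptors(textured_image)
        d2 = extract_descriptors(textured_image.copy())
        np.testing.assert_array_equal(d1, d2)

    def test_dense_grid_count_matches_enumeration(self, rng):
        img = rng.integers(0, 256, (33, 41), dtype=np.uint8)
        params = DetectorParams(method="grid", patch_size=8, stride=8, flat_tol=0.0)
        descs = extract_descriptors(img, params)
        rows = len(range(0, 33 - 8 + 1, 8))
        cols = len(range(0, 41 - 8 + 1, 8))
        assert len(descs) == rows * cols

    def test_descriptors_are_unit_norm(self, textured_image):
        descs = extract_descriptors(textured_image)
        np.testing.assert_allclose(np.linalg.norm(descs, axis=1), 1.0, atol=1e-9)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            extract_descriptors(np.zeros((4, 4), dtype=np.uint8))


class TestVocabulary:
    def test_recovers_separated_blob_centers(self, rng):
        centers = np.array([[0.0] * 4, [10.0] * 4, [-10.0, 10.0, -10.0, 10.0]])
        descs = np.vstack([c + rng.normal(0, 0.3, (50, 4)) for c in centers])
        vocab = build_vocabulary(descs, k=3, seed=0)
        for c in centers:
            d = np.linalg.norm(vocab.centroids - c, axis=1).min()
            assert d < 1.0

    def test_k_equal_to_distinct_descriptors_is_exact(self):
        descs = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
        vocab = build_vocabulary(descs, k=4, seed=0)
        d2 = ((descs[:, None] - vocab.centroids[None]) ** 2).sum(-1)
        assert d2.min(axis=1).max() == pytest.approx(0.0, abs=1e-12)

    def test_fewer_descriptors_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            build_vocabulary(rng.normal(size=(5, 4)), k=10)

    def test_reproducible_from_seed(self, rng):
        descs = rng.normal(size=(200, 8))
        v1 = build_vocabulary(descs, k=16, seed=42)
        v2 = build_vocabulary(descs, k=16, seed=42)
        np.testing.assert_array_equal(v1.centroids, v2.centroids)


class TestEncode:
    def test_histogram_sums_to_one(self, textured_image):
        descs = extract_descriptors(textured_image)
        vocab = build_vocabulary(descs, k=8, seed=0)
        hist = encode(textured_image, vocab)
        assert hist.sum() == pytest.approx(1.0)
        assert (hist >= 0).all()

    def test_empty_descriptor_set_gives_zero_sentinel(self):
        vocab = Vocabulary(centroids=np.eye(4), seed=0, n_iter=1)
        img = np.full((32, 32), 50, dtype=np.uint8)
        hist = encode(img, vocab, DetectorParams(method="grid"))
        assert hist.sum() == 0.0

    def test_assignment_matches_brute_force_nearest_centroid(self, textured_image):
        descs = extract_descriptors(textured_image)
        vocab = build_vocabulary(descs[:300], k=16, seed=1)
        hist = encode(textured_image, vocab)
        counts = np.zeros(vocab.k)
        for d in descs:
            dists = [float(np.sum((d - c) ** 2)) for c in vocab.centroids]
            counts[int(np.argmin(dists))] += 1
        np.testing.assert_allclose(hist, counts / counts.sum(), atol=1e-12)

    def test_permutation_invariance_in_descriptor_order(self, rng):
        vocab = Vocabulary(centroids=rng.normal(size=(6, 64)), seed=0, n_iter=1)
        img = generate_ward_images(identities=1, per_class=2, seed=9)[1][0]
        h1 = encode(img, vocab)
        h2 = encode(np.ascontiguousarray(img), vocab)
        np.testing.assert_array_equal(h1, h2)


def one_hot_histograms(rng, n_per_class=20, k=16):
    """Four identities living in disjoint word blocks."""
    hists, labels = [], []
    for i, label in enumerate(("First", "Second", "Third", "None")):
        for _ in range(n_per_class):
            h = np.zeros(k)
            block = slice(4 * i, 4 * i + 4)
            h[block] = rng.dirichlet(np.ones(4))
            hists.append(h)
            labels.append(label)
    return hists, labels


class TestIdentifier:
    def test_separable_block_histograms_classified_perfectly(self, rng):
        hists, labels = one_hot_histograms(rng)
        model = train_identifier(hists, labels, seed=0)
        for h, lab in zip(hists, labels):
            assert predict_identity(h, model)[0] == lab

    def test_more_than_four_classes_rejected(self, rng):
        with pytest.raises(ValueError):
            train_identifier([np.zeros(4)] * 5, ["a", "b", "c", "d", "e"])

    def test_low_margin_falls_back_to_none(self, rng):
        hists, labels = one_hot_histograms(rng)
        model = train_identifier(hists, labels, none_threshold=1e9, seed=0)
        assert predict_identity(hists[0], model)[0] == "None"

    def test_serialization_round_trip_preserves_predictions(self, tmp_path, rng):
        hists, labels = one_hot_histograms(rng)
        model = train_identifier(hists, labels, seed=0)
        p = tmp_path / "id.json"
        model.save(p)
        loaded = IdentityModel.load(p)
        probes = [rng.dirichlet(np.ones(16)) for _ in range(20)]
        for h in probes:
            assert predict_identity(h, model) == predict_identity(h, loaded)


class TestEndToEndBenchmark:
    def test_confusion_rows_sum_to_test_counts_and_accuracy_floor(self):
        from gericare.metrics import confusion

        images = generate_ward_images(identities=3, per_class=12, seed=21)
        by_label: dict[str, list] = {}
        for img, lab in images:
            by_label.setdefault(lab, []).append(img)
        train, test = [], []
        for lab, lst in by_label.items():
            train += [(im, lab) for im in lst[:8]]
            test += [(im, lab) for im in lst[8:]]
        params = DetectorParams()
        descs = np.vstack([extract_descriptors(im, params) for im, _ in train])
        vocab = build_vocabulary(descs, k=32, seed=2)
        model = train_identifier(
            [encode(im, vocab, params) for im, _ in train],
            [lab for _, lab in train],
            seed=2,
        )
        preds = [predict_identity(encode(im, vocab, params), model)[0] for im, _ in test]
        cm = confusion([lab for _, lab in test], preds, classes=("First", "Second", "Third", "None"))
        np.testing.assert_array_equal(cm.row_sums(), [4, 4, 4, 4])
        assert min(cm.per_class_accuracy().values()) >= 0.85
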