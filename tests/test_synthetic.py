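import numpy as np
import pytest
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening

import spermfusion as sf
from conftest import nearest_centroid_accuracy


def make_spec(**overrides):
    base = dict(
        n_classes=4,
        views=(("a", 8), ("b", 12)),
        separation=4.0,
        view_correlation=0.5,
        class_proportions=np.full(4, 0.25),
        n_samples=120,
        seed=7,
    )
    base.update(overrides)
    return sf.SyntheticSpec(**base)


class TestApportionment:
    @pytest.mark.parametrize("n", [10, 101, 3000])
    def test_counts_sum_exactly(self, n):
        _, props = sf.hi_lab_proportions()
        counts = sf.apportion_counts(props, n)
        assert counts.sum() == n

    def test_largest_remainder_is_deterministic(self):
        p = np.array([0.5, 0.3, 0.2])
        assert sf.apportion_counts(p, 7).tolist() == [4, 2, 1]
        # tie in fractional parts goes to the lower index
        assert sf.apportion_counts(np.array([0.25, 0.25, 0.5]), 2).tolist() == [1, 0, 1]


class TestFeatureGeneration:
    def test_shapes_ids_and_table(self):
        views, labels, table = sf.generate_synthetic_features(make_spec())
        assert [(v.source_id, v.dim) for v in views] == [("a", 8), ("b", 12)]
        assert all(v.n_samples == 120 for v in views)
        assert len(labels) == 120
        assert sum(table.counts) == 120
        assert views[0].sample_ids == views[1].sample_ids

    def test_determinism_bitwise(self):
        v1, l1, _ = sf.generate_synthetic_features(make_spec())
        v2, l2, _ = sf.generate_synthetic_features(make_spec())
        assert all((a.values == b.values).all() for a, b in zip(v1, v2))
        assert (l1 == l2).all()

    def test_zero_separation_is_chance_level(self):
        # with no class signal a linear classifier stays within 3 s.d. of chance
        from sklearn.linear_model import LogisticRegression

        accs = []
        for seed in range(10):
            spec = make_spec(separation=0.0, n_samples=400, seed=seed)
            views, labels, _ = sf.generate_synthetic_features(spec)
            X = views[0].values
            half = 200
            clf = LogisticRegression(max_iter=200).fit(X[:half], labels[:half])
            accs.append(np.mean(clf.predict(X[half:]) == labels[half:]))
        chance = 0.25
        sd = np.sqrt(chance * (1 - chance) / 200)
        assert abs(np.mean(accs) - chance) < 3 * sd

    def test_high_separation_is_separable(self):
        # oracle: nearest-centroid on well-separated Gaussians is near-perfect
        spec = sf.SyntheticSpec(
            n_classes=6,
            views=(("a", 16), ("b", 16), ("c", 16)),
            separation=8.0,
            view_correlation=0.5,
            class_proportions=np.full(6, 1 / 6),
            n_samples=1000,
            seed=3,
        )
        views, labels, _ = sf.generate_synthetic_features(spec)
        X = views[0].values
        half = 500
        acc = nearest_centroid_accuracy(X[:half], labels[:half], X[half:], labels[half:])
        assert acc >= 0.99
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(max_iter=500).fit(X[:half], labels[:half])
        assert np.mean(clf.predict(X[half:]) == labels[half:]) >= 0.99

    def test_full_view_correlation_duplicates_centroids(self):
        spec = make_spec(views=(("a", 8), ("b", 8)), view_correlation=1.0)
        views, labels, _ = sf.generate_synthetic_features(spec)
        # identical centroids across views: per-class mean difference ~ 0
        for cls in np.unique(labels):
            m = labels == cls
            d = views[0].values[m].mean(0) - views[1].values[m].mean(0)
            assert np.abs(d).max() < 0.6  # noise-only difference

    def test_permutation_preserves_pairing(self):
        views, labels, _ = sf.generate_synthetic_features(make_spec())
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(labels))
        shuffled = views[0].values[perm]
        for cls in np.unique(labels):
            orig = views[0].values[labels == cls].mean(0)
            after = shuffled[labels[perm] == cls].mean(0)
            assert np.allclose(orig, after)

    @pytest.mark.parametrize(
        "overrides,msg",
        [
            (dict(views=()), "at least one view"),
            (dict(separation=-1.0), "separation"),
            (dict(class_proportions=np.array([0.5, 0.2, 0.2, 0.2])), "sum to 1"),
            (dict(n_samples=3), "n_samples"),
        ],
    )
    def test_invalid_specs_raise(self, overrides, msg):
        with pytest.raises(ValueError, match=msg):
            make_spec(**overrides)


def head_eccentricity(image):
    """Oracle: image-moments eccentricity of the glyph's head region."""
    binary = image[:, :, 0] < 128
    opened = opening(binary, disk(2))  # strips the thin tail
    regions = regionprops(cc_label(opened))
    head = max(regions, key=lambda r: r.area)
    return head.eccentricity


class TestImageGeneration:
    def test_shape_and_channels(self):
        spec = make_spec(n_samples=8, views=(("a", 4),))
        images, labels = sf.generate_synthetic_images(spec, image_side=48)
        assert images.shape == (8, 48, 48, 3)
        assert images.dtype == np.uint8
        assert (images[..., 0] == images[..., 1]).all()  # grayscale replicated

    def test_determinism(self):
        spec = make_spec(n_samples=6, views=(("a", 4),))
        a, _ = sf.generate_synthetic_images(spec, image_side=32)
        b, _ = sf.generate_synthetic_images(spec, image_side=32)
        assert (a == b).all()

    def test_round_vs_tapered_head_eccentricity(self):
        spec = sf.SyntheticSpec(
            n_classes=2,
            views=(("a", 4),),
            separation=8.0,
            view_correlation=0.5,
            class_proportions=np.array([0.5, 0.5]),
            n_samples=40,
            seed=5,
            class_names=("RoundHead", "TaperedHead"),
        )
        images, labels = sf.generate_synthetic_images(spec, image_side=64)
        ecc = np.array([head_eccentricity(img) for img in images])
        round_e, taper_e = ecc[labels == "RoundHead"], ecc[labels == "TaperedHead"]
        gap = abs(taper_e.mean() - round_e.mean())
        within_sd = max(round_e.std(), taper_e.std(), 1e-6)
        assert taper_e.mean() > round_e.mean()
        assert gap >= within_sd

    def test_class_cap_and_small_side_raise(self):
        with pytest.raises(ValueError, match="image_side"):
            sf.generate_synthetic_images(make_spec(), image_side=16)
        bad = make_spec(
            n_classes=19,
            class_proportions=np.full(19, 1 / 19),
            views=(("a", 4),),
            n_samples=38,
        )
        with pytest.raises(ValueError, match="glyph"):
            sf.generate_synthetic_images(bad, image_side=32)

    def test_image_tree_round_trip(self, tmp_path):
        from spermfusion.synthetic import write_image_tree
        from spermfusion.backbones import read_image_tree

        spec = make_spec(n_samples=8, views=(("a", 4),))
        images, labels = sf.generate_synthetic_images(spec, image_side=32)
        write_image_tree(images, labels, tmp_path / "tree")
        back_images, back_labels = read_image_tree(tmp_path / "tree")
        assert back_images.shape == images.shape
        assert sorted(back_labels) == sorted(labels)


class TestCorrelatedSources:
    def test_marginal_accuracy_and_correlation(self):
        sources, truth = sf.simulate_correlated_sources(
            5000, 6, accuracy=0.7, error_correlation=0.25, seed=9
        )
        errs = np.stack([s.labels() != truth for s in sources])
        for e in errs:
            assert abs(e.mean() - 0.3) < 0.03
        corr = np.corrcoef(errs)[np.triu_indices(3, k=1)]
        assert (corr <= 0.33).all() and (corr >= 0.1).all()

    def test_rows_are_probabilities(self):
        sources, _ = sf.simulate_correlated_sources(100, 5, seed=1)
        for s in sources:
            assert np.allclose(s.values.sum(axis=1), 1.0, atol=1e-9)
            assert (s.values > 0).all()
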