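import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spermfusion as sf
from spermfusion.classifiers import AttentionMlp, attention_weights
from conftest import nearest_centroid_accuracy


@pytest.fixture(scope="module")
def separable2():
    rng = np.random.default_rng(42)
    X = rng.standard_normal((200, 10))
    y = np.repeat(["neg", "pos"], 100)
    X[y == "pos"] += 4.0
    perm = rng.permutation(200)
    return X[perm], y[perm]


@pytest.fixture(scope="module")
def fused18():
    names, props = sf.hi_lab_proportions()
    spec = sf.SyntheticSpec(
        n_classes=18,
        views=(("s", 24), ("m", 24), ("l", 24)),
        separation=8.0,
        view_correlation=0.5,
        class_proportions=props,
        n_samples=900,
        seed=21,
        class_names=names,
    )
    views, labels, _ = sf.generate_synthetic_features(spec)
    return sf.concat_features(views).matrix, labels


class TestStandardizer:
    def test_arithmetic_oracle_population_sd(self):
        # column (1,2,3): mu=2, population sigma=sqrt(2/3)
        s = sf.fit_standardizer(np.array([[1.0], [2.0], [3.0]]))
        out = sf.standardize(s, np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_centered_only(self):
        s = sf.fit_standardizer(np.array([[5.0], [5.0], [5.0]]))
        out = sf.standardize(s, np.array([[5.0], [5.0], [5.0]]))
        assert (out == 0.0).all()

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4)) * 3 + 1
        once = sf.standardize(sf.fit_standardizer(X), X)
        twice = sf.standardize(sf.fit_standardizer(once), once)
        assert np.allclose(once, twice, atol=1e-9)

    def test_train_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 6)) * 5 - 2
        out = sf.standardize(sf.fit_standardizer(X), X)
        assert np.abs(out.mean(axis=0)).max() < 1e-8
        assert np.abs(out.std(axis=0) - 1).max() < 1e-6

    def test_dimension_mismatch_raises(self):
        s = sf.fit_standardizer(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            sf.standardize(s, np.zeros((3, 5)))


class TestRbfKernel:
    def test_zero_distance_is_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert sf.rbf_kernel(x, x, gamma=0.7) == 1.0

    def test_closed_form(self):
        # gamma=0.5, squared distance 2 -> exp(-1)
        x, y = np.array([0.0, 0.0]), np.array([1.0, 1.0])
        assert abs(sf.rbf_kernel(x, y, gamma=0.5) - np.exp(-1.0)) < 1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        st.floats(1e-3, 10.0),
    )
    def test_symmetry_and_range(self, xs, ys, gamma):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        k = sf.rbf_kernel(x, y, gamma)
        assert k == sf.rbf_kernel(y, x, gamma)
        assert 0.0 <= k <= 1.0  # 0 only by float underflow at huge distances

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            sf.rbf_kernel(np.zeros(2), np.zeros(3), 1.0)


class TestSvm:
    def test_separable_two_class(self, separable2):
        X, y = separable2
        model = sf.fit_svm(X[:150], y[:150], sf.SvmConfig(gamma_grid=("scale",), c_grid=(1.0,)))
        probs = sf.predict_proba(model, X[150:])
        acc = np.mean(sf.predict_label(probs) == y[150:])
        oracle = nearest_centroid_accuracy(X[:150], y[:150], X[150:], y[150:])
        assert acc >= 0.99 and oracle >= 0.99
        assert np.abs(probs.values.sum(axis=1) - 1.0).max() < 1e-9

    def test_18_class_one_vs_rest_alphabetical(self, fused18):
        X, y = fused18
        model = sf.fit_svm(X, y, sf.SvmConfig(gamma_grid=("scale",), c_grid=(10.0,)))
        assert len(model.estimator.estimators_) == 18  # one binary classifier per class
        assert model.class_order == sorted(model.class_order)
        assert len(model.class_order) == 18

    def test_grid_selection_prefers_smaller_c_on_ties(self, separable2):
        X, y = separable2
        model = sf.fit_svm(
            X, y, sf.SvmConfig(gamma_grid=(0.01,), c_grid=(100.0, 1.0, 0.1), inner_folds=3)
        )
        # fully separable data: all C values tie at accuracy 1 -> smallest C wins
        assert model.config["C"] == 0.1

    def test_tiny_class_reduces_inner_folds_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((43, 4))
        y = np.array(["a"] * 40 + ["b"] * 3)
        X[y == "b"] += 5.0
        with pytest.warns(UserWarning, match="inner CV reduced"):
            sf.fit_svm(X, y, sf.SvmConfig(gamma_grid=("scale", 0.1), c_grid=(1.0,), inner_folds=5))

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="2 classes"):
            sf.fit_svm(np.zeros((5, 2)), np.repeat(["a"], 5))


class TestRandomForest:
    def test_single_tree_equals_ensemble(self, separable2):
        X, y = separable2
        model = sf.fit_rf(X, y, sf.RfConfig(n_trees=1, seed=0))
        ens = sf.predict_proba(model, X).values
        tree = model.estimator.estimators_[0].predict_proba(
            model.standardizer.transform(X)
        )
        assert np.allclose(ens, tree)

    def test_averaging_matches_arithmetic_mean_oracle(self):
        trees = [
            np.array([[0.9, 0.1]]),
            np.array([[0.6, 0.4]]),
            np.array([[0.3, 0.7]]),
        ]
        assert np.allclose(sf.average_tree_probabilities(trees), [[0.6, 0.4]])

    def test_forest_probability_is_mean_of_trees(self, separable2):
        X, y = separable2
        model = sf.fit_rf(X[:100], y[:100], sf.RfConfig(n_trees=20, seed=1))
        Xs = model.standardizer.transform(X[100:])
        per_tree = [t.predict_proba(Xs) for t in model.estimator.estimators_]
        assert np.allclose(
            sf.predict_proba(model, X[100:]).values,
            sf.average_tree_probabilities(per_tree),
            atol=1e-12,
        )

    def test_separable_accuracy(self, separable2):
        X, y = separable2
        model = sf.fit_rf(X[:150], y[:150], sf.RfConfig(n_trees=100, seed=2))
        acc = np.mean(sf.predict_label(sf.predict_proba(model, X[150:])) == y[150:])
        assert acc >= 0.99

    def test_invalid_tree_count_raises(self):
        with pytest.raises(ValueError, match="n_trees"):
            sf.RfConfig(n_trees=0)


class TestMlpaForward:
    def test_zero_attention_gives_half_gate(self):
        model = AttentionMlp(
            np.zeros((3, 3)), np.zeros(3), np.eye(3), np.zeros(3)
        )
        F = np.array([2.0, -4.0, 6.0])
        A = attention_weights(model, F)
        assert np.allclose(A, 0.5)
        # F_attended = F/2 -> logits = F/2
        probs = sf.mlpa_forward(model, F)
        expected = np.exp(F / 2) / np.exp(F / 2).sum()
        assert np.allclose(probs, expected, atol=1e-12)

    def test_hand_computed_oracle(self):
        # d=2, C=3: zero gate weights -> A=0.5, attended=(1,2),
        # head picks coordinates -> logits (1,2,0) -> softmax
        model = AttentionMlp(
            np.zeros((2, 2)),
            np.zeros(2),
            np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
            np.zeros(3),
        )
        probs = sf.mlpa_forward(model, np.array([2.0, 4.0]))
        e = np.exp([1.0, 2.0, 0.0])
        assert np.allclose(probs, e / e.sum(), atol=1e-4)
        assert np.allclose(probs, [0.2447, 0.6652, 0.0900], atol=1e-4)

    def test_rows_sum_to_one_and_large_logits_stable(self):
        rng = np.random.default_rng(3)
        model = AttentionMlp(
            rng.standard_normal((4, 4)),
            rng.standard_normal(4),
            rng.standard_normal((5, 4)) * 100,
            rng.standard_normal(5),
        )
        probs = sf.mlpa_forward(model, rng.standard_normal((10, 4)) * 10)
        assert np.isfinite(probs).all()
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-9

    def test_dimension_mismatch_raises(self):
        model = AttentionMlp(np.zeros((2, 2)), np.zeros(2), np.zeros((3, 2)), np.zeros(3))
        with pytest.raises(ValueError, match="dim"):
            sf.mlpa_forward(model, np.zeros(5))


class TestFitMlpa:
    def test_separable_accuracy_and_gate_range(self, separable2):
        X, y = separable2
        model = sf.fit_mlpa(X[:150], y[:150], sf.MlpaConfig(max_epochs=100, seed=4))
        probs = sf.predict_proba(model, X[150:])
        assert np.mean(sf.predict_label(probs) == y[150:]) >= 0.99
        A = attention_weights(model.estimator, model.standardizer.transform(X[:150]))
        assert (A > 0.0).all() and (A < 1.0).all()

    def test_same_seed_identical_parameters(self, separable2):
        X, y = separable2
        cfg = sf.MlpaConfig(max_epochs=15, seed=7)
        m1 = sf.fit_mlpa(X, y, cfg)
        m2 = sf.fit_mlpa(X, y, cfg)
        assert (m1.estimator.W_attn == m2.estimator.W_attn).all()
        assert (m1.estimator.W_final == m2.estimator.W_final).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="2 classes"):
            sf.fit_mlpa(np.zeros((5, 2)), np.repeat(["a"], 5))


class TestPredictLabel:
    def test_argmax(self):
        assert sf.predict_label(np.array([[0.2, 0.5, 0.3]])).tolist() == [1]

    def test_tie_breaks_to_lowest_index(self):
        assert sf.predict_label(np.array([[0.5, 0.5]])).tolist() == [0]
        assert sf.predict_label(np.array([[0.5, 0.5]]), ["a", "b"]).tolist() == ["a"]

    def test_self_vote_reproduces_model_labels(self, separable2):
        X, y = separable2
        model = sf.fit_rf(X, y, sf.RfConfig(n_trees=10, seed=0))
        probs = sf.predict_proba(model, X)
        vote_input = sf.VoteInput([("a", probs), ("b", probs), ("c", probs)])
        _, labels = sf.soft_vote(vote_input)
        assert (labels == probs.labels()).all()


class TestClassOrderAlignment:
    def test_all_three_classifiers_share_class_order(self, separable2):
        X, y = separable2
        svm = sf.fit_svm(X, y, sf.SvmConfig(gamma_grid=("scale",), c_grid=(1.0,)))
        rf = sf.fit_rf(X, y, sf.RfConfig(n_trees=10))
        mlpa = sf.fit_mlpa(X, y, sf.MlpaConfig(max_epochs=10))
        assert svm.class_order == rf.class_order == mlpa.class_order == ["neg", "pos"]

    def test_persistence_round_trip(self, separable2, tmp_path):
        X, y = separable2
        model = sf.fit_rf(X, y, sf.RfConfig(n_trees=10, seed=0))
        from spermfusion.classifiers import load_model, save_model

        save_model(model, tmp_path / "rf.joblib")
        back = load_model(tmp_path / "rf.joblib")
        assert (sf.predict_proba(back, X).values == sf.predict_proba(model, X).values).all()
        assert (tmp_path / "rf.joblib.json").exists()
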