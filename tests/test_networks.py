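"""The five base neural-network classifiers."""

import numpy as np
import pytest

from rnncluster.networks import (
    BASE_CLASSIFIERS,
    BPClassifier,
    CompetitiveClassifier,
    ElmanClassifier,
    LVQClassifier,
    PNNClassifier,
    TrainConfig,
    accuracy,
    fit_bp,
    make_base_classifier,
    model_from_dict,
    model_to_dict,
)
from rnncluster.synthetic import generate_feature_table

ALL_KINDS = sorted(BASE_CLASSIFIERS)


def two_clusters(n=20, sep=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(-sep, 1, n), rng.normal(sep, 1, n)])
    y = np.array(["a"] * n + ["b"] * n)
    return x[:, None], y


class TestUniformContract:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_deterministic_given_seed(self, kind, separable_table):
        X, y = separable_table.X, separable_table.y
        m1 = make_base_classifier(kind, TrainConfig(epochs=50)).fit(X, y)
        m2 = make_base_classifier(kind, TrainConfig(epochs=50)).fit(X, y)
        assert np.array_equal(m1.predict(X), m2.predict(X))
        for attr in ("w_hidden_", "prototypes_", "w_in_", "patterns_"):
            if hasattr(m1, attr):
                assert np.array_equal(getattr(m1, attr), getattr(m2, attr))

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_beats_chance_on_separated_classes(self, kind):
        # effect size 3, n=60: every network should beat 0.7 in >= 9/10 seeds
        wins = 0
        for seed in range(10):
            t = generate_feature_table(30, 10, planted_features=range(10),
                                       effect_size=3.0, seed=seed)
            idx = np.arange(60) % 2 == 0
            model = make_base_classifier(kind, random_state=seed)
            model.fit(t.X[idx], t.y[idx])
            wins += accuracy(model, t.X[~idx], t.y[~idx]) > 0.7
        assert wins >= 9

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_dimension_mismatch_rejected(self, kind, separable_table):
        model = make_base_classifier(kind, TrainConfig(epochs=5))
        model.fit(separable_table.X, separable_table.y)
        with pytest.raises(ValueError, match="features"):
            model.predict(separable_table.X[:, :3])

    @pytest.mark.parametrize("kind", ["bp", "pnn", "lvq", "elman"])
    def test_single_class_rejected(self, kind):
        X = np.random.default_rng(0).normal(size=(10, 3))
        model = make_base_classifier(kind, TrainConfig(epochs=5))
        with pytest.raises(ValueError, match="class"):
            model.fit(X, np.zeros(10))

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_serialization_round_trip(self, kind, separable_table):
        X, y = separable_table.X, separable_table.y
        model = make_base_classifier(kind, TrainConfig(epochs=20)).fit(X, y)
        clone = model_from_dict(model_to_dict(model))
        assert np.array_equal(model.predict(X), clone.predict(X))


class TestAccuracy:
    def test_counts(self, separable_table):
        X, y = separable_table.X, separable_table.y
        model = PNNClassifier().fit(X, y)

        class Stub:
            def predict(self, X_):
                return pred[: len(X_)]

        pred = y.copy()
        assert accuracy(Stub(), X, y) == 1.0
        pred = np.where(y == "case", "control", "case")
        assert accuracy(Stub(), X, y) == 0.0
        pred = y.copy()
        pred[0] = "control" if y[0] == "case" else "case"
        assert accuracy(Stub(), X[:4], y[:4]) == 0.75


class TestBP:
    def test_separable_clusters_reach_perfect_training(self):
        X, y = two_clusters()
        model = BPClassifier(epochs=200, random_state=0).fit(X, y)
        assert accuracy(model, X, y) == 1.0

    def test_xor_with_enough_hidden_units(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0, 1, 1, 0])
        model = BPClassifier(hidden_units=8, learning_rate=0.5, epochs=5000,
                             tol=0, random_state=3).fit(X, y)
        assert accuracy(model, X, y) == 1.0

    def test_loss_non_increasing_at_small_eta(self, separable_table):
        model = BPClassifier(learning_rate=0.01, epochs=200, tol=0,
                             random_state=1)
        model.fit(separable_table.X, separable_table.y)
        assert np.all(np.diff(model.loss_curve_) <= 1e-9)


class TestPNN:
    def test_training_point_recovers_its_class_at_small_sigma(self,
                                                              separable_table):
        X, y = separable_table.X, separable_table.y
        model = PNNClassifier(sigma=0.05).fit(X, y)
        assert np.array_equal(model.predict(X[:5]), y[:5])

    def test_flat_kernel_ties_break_to_first_class(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])  # equal class sizes
        model = PNNClassifier(sigma=1e9).fit(X, y)
        assert np.all(model.predict(np.array([[0.5], [2.5]])) == "a")

    def test_matches_brute_force_kernel_sum(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array(["u"] * 15 + ["v"] * 15)
        model = PNNClassifier(sigma=1.3).fit(X, y)
        queries = rng.normal(size=(50, 2))
        xs = (X - model.mean_) / model.scale_
        qs = (queries - model.mean_) / model.scale_
        expected = []
        for q in qs:
            scores = {}
            for cls in ("u", "v"):
                pats = xs[y == cls]
                scores[cls] = np.mean(
                    [np.exp(-np.sum((q - p) ** 2) / 1.3**2) for p in pats]
                )
            expected.append(max(sorted(scores), key=lambda c: scores[c]))
        assert np.array_equal(model.predict(queries), np.array(expected))

    def test_invalid_sigma_rejected(self, separable_table):
        with pytest.raises(ValueError, match="sigma"):
            PNNClassifier(sigma=0.0).fit(separable_table.X, separable_table.y)


class TestCompetitive:
    def test_prototypes_converge_to_cluster_means(self):
        X, y = two_clusters(n=100, seed=2)
        model = CompetitiveClassifier(n_prototypes=2, learning_rate=0.05,
                                      epochs=100, random_state=2).fit(X, y)
        xs = (X - model.mean_) / model.scale_
        means = sorted([xs[:100].mean(), xs[100:].mean()])
        protos = sorted(model.prototypes_[:, 0])
        assert abs(protos[0] - means[0]) < 0.5
        assert abs(protos[1] - means[1]) < 0.5

    def test_zero_learning_rate_leaves_prototypes_at_init(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array(["a", "b"] * 10)
        m0 = CompetitiveClassifier(learning_rate=0.0, epochs=10,
                                   random_state=7).fit(X, y)
        init = np.random.default_rng(7).uniform(-0.5, 0.5, (2, 3))
        assert np.allclose(m0.prototypes_, init)

    def test_more_prototypes_than_samples_rejected(self):
        X = np.zeros((3, 2)) + np.arange(3)[:, None]
        with pytest.raises(ValueError, match="prototypes"):
            CompetitiveClassifier(n_prototypes=5).fit(X, np.array([0, 1, 0]))


class TestLVQ:
    def test_separable_clusters_generalize(self):
        X, y = two_clusters(n=50, seed=4)
        Xt, yt = two_clusters(n=30, seed=5)
        model = LVQClassifier(random_state=4).fit(X, y)
        assert accuracy(model, Xt, yt) == 1.0

    def test_zero_eta_is_nearest_class_mean(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = LVQClassifier(learning_rate=0.0, epochs=5,
                              random_state=0).fit(X, y)
        xs = (X - model.mean_) / model.scale_
        qs = rng.normal(size=(25, 2))
        qstd = (qs - model.mean_) / model.scale_
        mu_a, mu_b = xs[:20].mean(0), xs[20:].mean(0)
        expected = np.where(
            np.sum((qstd - mu_a) ** 2, 1) <= np.sum((qstd - mu_b) ** 2, 1),
            "a", "b",
        )
        assert np.array_equal(model.predict(qs), expected)


class TestElman:
    def test_separable_clusters_reach_perfect_training(self, separable_table):
        X, y = separable_table.X, separable_table.y
        model = ElmanClassifier(random_state=0).fit(X, y)
        assert accuracy(model, X, y) == 1.0

    def test_loss_non_increasing_at_small_eta(self, separable_table):
        model = ElmanClassifier(learning_rate=0.01, epochs=200, tol=0,
                                random_state=1)
        model.fit(separable_table.X, separable_table.y)
        assert np.all(np.diff(model.loss_curve_) <= 1e-6)

    def test_zero_context_decay_silences_context_weights(self,
                                                         separable_table):
        X, y = separable_table.X, separable_table.y
        model = ElmanClassifier(context_decay=0.0, epochs=100,
                                random_state=2).fit(X, y)
        before = model.predict(X)
        model.w_ctx_ = np.zeros_like(model.w_ctx_)  # context cannot matter
        assert np.array_equal(model.predict(X), before)

    def test_invalid_context_decay_rejected(self, separable_table):
        with pytest.raises(ValueError, match="context_decay"):
            ElmanClassifier(context_decay=1.5).fit(
                separable_table.X, separable_table.y
            )


def test_functional_wrappers_respect_config(separable_table):
    X, y = separable_table.X, separable_table.y
    cfg = TrainConfig(hidden_units=4, epochs=30, seed=11)
    model = fit_bp(X, y, cfg)
    assert model.w_hidden_.shape == (4, X.shape[1])
    assert model.random_state == 11
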