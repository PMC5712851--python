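"""Classifiers: Fisher LDA, Parzen-window PNN, nearest-target MLP."""

import numpy as np
import pytest

from ratiodecode.decoders import (
    TEN_TARGETS,
    LDAClassifier,
    MLPNNClassifier,
    PNNClassifier,
    pnn_spread,
)


def gaussian_blobs(rng, centres, n_per_class, sd=1.0):
    X, y = [], []
    for k, c in enumerate(centres):
        X.append(rng.normal(c, sd, size=(n_per_class, len(c))))
        y += [f"C{k}"] * n_per_class
    return np.vstack(X), np.asarray(y)


class TestLDA:
    def test_two_separated_classes(self, rng):
        X, y = gaussian_blobs(rng, [[0.0], [10.0]], 20)
        model = LDAClassifier().fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_equal_means_zero_between_scatter(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array(["A"] * 20 + ["B"] * 20)
        Xc = X - X[:20].mean(0) * (np.arange(40) < 20)[:, None] \
               - X[20:].mean(0) * (np.arange(40) >= 20)[:, None]
        model = LDAClassifier().fit(Xc, y)
        assert np.all(np.abs(model.eigenvalues_) < 1e-8)

    def test_predicting_class_mean_returns_class(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [6, 0], [0, 6]], 15)
        model = LDAClassifier().fit(X, y)
        for k, lab in enumerate(model.classes_):
            mean = X[y == lab].mean(axis=0, keepdims=True)
            assert model.predict(mean)[0] == lab

    def test_matches_sklearn_assignments(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = gaussian_blobs(rng, [[0, 0, 0], [5, 1, 0], [1, 5, 3]], 20, sd=1.2)
        ours = LDAClassifier().fit(X, y).predict(X)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert (ours == ref).mean() >= 0.99

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array(["A", "A", "A", "A", "B"])
        with pytest.raises(ValueError, match="single sample"):
            LDAClassifier().fit(X, y)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = gaussian_blobs(rng, [[0.0], [5.0]], 10)
        model = LDAClassifier().fit(X, y)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((1, 3)))

    def test_loo_accuracy_on_well_separated_gaussians(self, rng):
        # two spherical classes 6 sigma apart: near-Bayes linear boundary
        X, y = gaussian_blobs(rng, [[0.0, 0.0], [6.0, 0.0]], 20)
        correct = 0
        for i in range(40):
            m = np.arange(40) != i
            model = LDAClassifier().fit(X[m], y[m])
            correct += model.predict(X[i : i + 1])[0] == y[i]
        assert correct / 40 >= 0.95


class TestPNNSpread:
    def test_one_dimensional_chain(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["A", "A", "A"])
        sig = pnn_spread(X, y)
        assert sig.shape == (1, 1)
        assert sig[0, 0] == 1.0

    def test_duplicate_samples_fall_back_to_global(self):
        X = np.array([[0.0], [0.0], [5.0], [7.0]])
        y = np.array(["A", "A", "B", "B"])
        sig = pnn_spread(X, y)
        # class A raw median is 0 -> replaced by the global feature median
        assert sig[0, 0] > 0
        assert sig[1, 0] == 2.0

    def test_matches_brute_force_enumeration(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.asarray(["A"] * 15 + ["B"] * 15)
        sig = pnn_spread(X, y)
        for a, lab in enumerate(["A", "B"]):
            Xi = X[y == lab]
            gaps = []
            for k in range(len(Xi)):
                dists = [
                    np.linalg.norm(Xi[k] - Xi[j]) for j in range(len(Xi)) if j != k
                ]
                nn = int(np.argmin(dists))
                nn_idx = [j for j in range(len(Xi)) if j != k][nn]
                gaps.append(np.abs(Xi[k] - Xi[nn_idx]))
            np.testing.assert_allclose(sig[a], np.median(np.asarray(gaps), axis=0))

    def test_single_sample_class_warns(self):
        X = np.array([[0.0], [5.0], [6.0]])
        y = np.array(["A", "B", "B"])
        with pytest.warns(UserWarning, match="single sample"):
            sig = pnn_spread(X, y)
        assert np.all(sig > 0)


class TestPNN:
    def test_training_vector_classified_to_own_class(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [8, 8]], 10)
        model = PNNClassifier().fit(X, y)
        assert model.predict(X[:1])[0] == y[0]

    def test_probabilities_normalised(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [3, 1], [1, 4]], 8)
        model = PNNClassifier().fit(X, y)
        P = model.predict_proba(rng.normal(size=(20, 2)))
        assert np.all(P >= 0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0)

    def test_sigma_to_zero_approaches_nearest_neighbour(self, rng):
        X = rng.normal(size=(50, 2))
        y = np.asarray(["A", "B", "C", "D", "E"] * 10)
        model = PNNClassifier(spread_mode="scalar", spread_scale=1e-8).fit(X, y)
        Xt = rng.normal(size=(50, 2))
        pred = model.predict(Xt)
        agree = 0
        counted = 0
        for i in range(50):
            d = np.linalg.norm(X - Xt[i], axis=1)
            order = np.sort(d)
            if order[1] - order[0] < 1e-9:  # exclude ties
                continue
            counted += 1
            agree += pred[i] == y[int(np.argmin(d))]
        assert counted > 0
        assert agree / counted >= 0.99

    def test_sigma_to_infinity_probabilities_flatten(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [5, 5]], 10)
        model = PNNClassifier(spread_mode="scalar", spread_scale=1e6).fit(X, y)
        P = model.predict_proba(np.array([[2.0, 1.0]]))
        np.testing.assert_allclose(P, 0.5, atol=1e-4)

    def test_equidistant_tie_goes_to_first_class(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        y = np.array(["A", "A", "B", "B"])
        model = PNNClassifier().fit(X, y)
        probs = model.predict_proba(np.array([[6.0]]))[0]
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)
        assert model.predict(np.array([[6.0]]))[0] == "A"

    def test_training_order_invariance(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [4, 4], [0, 5]], 8)
        perm = rng.permutation(len(y))
        a = PNNClassifier().fit(X, y)
        b = PNNClassifier().fit(X[perm], y[perm])
        Xt = rng.normal(2, 2, size=(25, 2))
        assert np.array_equal(a.predict(Xt), b.predict(Xt))
        np.testing.assert_allclose(a.predict_proba(Xt), b.predict_proba(Xt))


class TestMLPNN:
    def test_nearest_target_decoding(self):
        model = MLPNNClassifier()
        model.classes_, model.target_matrix_ = model._target_matrix()
        assert model.decode_pairs([[0.5, 0.5]])[0] == "R3"
        assert model.decode_pairs([[1.0, 1.0]])[0] == "R8"
        # (0.75, 0.75) is exactly equidistant from R3 (0.5, 0.5) and R8 (1, 1)
        assert model.decode_pairs([[0.75, 0.75]])[0] == "R3"

    def test_target_table_matches_code_volumes(self):
        from ratiodecode.simulate import encode_categories

        for b in encode_categories():
            assert TEN_TARGETS[b.category] == (b.volume_a, b.volume_b)

    def test_converges_on_separable_toy_set(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [6, 6]], 15, sd=0.3)
        y = np.where(y == "C0", "R1", "R5")
        model = MLPNNClassifier(epochs=2000, seed=0).fit(X, y)
        assert model.mse_ < 1e-3
        assert (model.predict(X) == y).mean() == 1.0

    def test_seeded_determinism(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [4, 4]], 10)
        y = np.where(y == "C0", "R1", "R8")
        a = MLPNNClassifier(epochs=50, seed=3).fit(X, y)
        b = MLPNNClassifier(epochs=50, seed=3).fit(X, y)
        np.testing.assert_array_equal(a.W1_, b.W1_)
        np.testing.assert_array_equal(a.W2_, b.W2_)

    def test_zero_epochs_returns_initial_network(self, rng):
        X, y = gaussian_blobs(rng, [[0.0], [5.0]], 5)
        y = np.where(y == "C0", "R1", "R5")
        a = MLPNNClassifier(epochs=0, seed=11).fit(X, y)
        b = MLPNNClassifier(epochs=0, seed=11).fit(X, y)
        np.testing.assert_array_equal(a.predict_pairs(X), b.predict_pairs(X))

    def test_training_order_invariance(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [5, 5]], 10)
        y = np.where(y == "C0", "R1", "R8")
        perm = rng.permutation(len(y))
        a = MLPNNClassifier(epochs=100, seed=5).fit(X, y)
        b = MLPNNClassifier(epochs=100, seed=5).fit(X[perm], y[perm])
        np.testing.assert_allclose(a.W1_, b.W1_, atol=1e-10)

    def test_unknown_label_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="target table"):
            MLPNNClassifier().fit(X, ["R1", "R1", "Q9", "Q9"])

    def test_json_round_trip(self, rng):
        X, y = gaussian_blobs(rng, [[0, 0], [5, 5]], 10)
        y = np.where(y == "C0", "R1", "R8")
        model = MLPNNClassifier(epochs=100, seed=5).fit(X, y)
        clone = MLPNNClassifier.from_json(model.to_json())
        np.testing.assert_allclose(model.predict_pairs(X), clone.predict_pairs(X))
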