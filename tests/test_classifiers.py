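import numpy as np
import pytest

from bayeslimit.classifiers import (
    CMVGBayes,
    HiddenLayerPerceptron,
    KDENaiveBayes,
    RandomDimensionalityExpansion,
    fit_on_dataset,
    model_accuracy,
)
from bayeslimit.datasets import LabeledDataset
from bayeslimit.dsc import DSCControl, build_class_params, sample_dsc_dataset
from bayeslimit.limit import bayes_limit_gaussian_1d

ALL_MODELS = [
    ("nbayes", lambda seed: KDENaiveBayes()),
    ("cmvg", lambda seed: CMVGBayes()),
    ("perceptron", lambda seed: HiddenLayerPerceptron(random_state=seed)),
]


def _gaussian_1d_dataset(d, n, rng):
    X = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(d, 1, n // 2)])[:, None]
    y = np.repeat([0, 1], n // 2)
    perm = rng.permutation(n)
    return LabeledDataset.from_arrays(X[perm], y[perm], rng)


@pytest.mark.parametrize("d", [1.0, 2.0])
def test_all_classifiers_are_bayes_optimal_on_1d_gaussians(d):
    """With ample data each model's test accuracy matches the closed-form
    limit Phi(d/2) of the 1-D equal-prior Gaussian problem within 0.01."""
    ds = _gaussian_1d_dataset(d, 100_000, np.random.default_rng(101))
    target = bayes_limit_gaussian_1d(d)
    for name, make in ALL_MODELS:
        model = make(0)
        fit_on_dataset(model, ds)
        assert model_accuracy(model, ds) == pytest.approx(target, abs=0.01), name


def test_posterior_rows_normalize_exactly(rng, fig6_dataset):
    Xte, _ = fig6_dataset.test()
    for name, make in ALL_MODELS:
        model = make(3)
        fit_on_dataset(model, fig6_dataset)
        p = model.predict_proba(Xte[:200])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9, err_msg=name)
        assert np.all(p >= 0)


class TestKDENaiveBayes:
    def test_invariant_under_monotone_feature_rescaling(self, rng):
        """Marginal-rank information is all naive Bayes uses, so strictly
        monotone per-feature maps barely move its accuracy."""
        X = np.vstack(
            [rng.normal([0, 0], 1, (5000, 2)), rng.normal([1.2, 0.5], 1, (5000, 2))]
        )
        y = np.repeat([0, 1], 5000)
        perm = rng.permutation(10_000)
        ds = LabeledDataset.from_arrays(X[perm], y[perm], rng)
        base = KDENaiveBayes()
        fit_on_dataset(base, ds)
        acc_raw = model_accuracy(base, ds)
        warped = ds.transformed(lambda X: np.column_stack(
            [np.exp(X[:, 0] / 2.0), X[:, 1] ** 3 + X[:, 1]]
        ))
        alt = KDENaiveBayes()
        fit_on_dataset(alt, warped)
        assert model_accuracy(alt, warped) == pytest.approx(acc_raw, abs=0.02)

    def test_constant_feature_falls_back_gracefully(self, rng):
        X = rng.normal(size=(200, 2))
        X[:100, 1] = 5.0  # class 0: zero variance in feature 1
        y = np.repeat([0, 1], 100)
        model = KDENaiveBayes().fit(X, y)
        p = model.predict_proba(rng.normal(size=(10, 2)))
        assert np.isfinite(p).all()

    def test_single_feature_reduces_to_marginal_ratio(self, rng):
        ds = _gaussian_1d_dataset(1.0, 2000, rng)
        model = KDENaiveBayes()
        fit_on_dataset(model, ds)
        # at the symmetry point the fitted marginals nearly tie
        q = model.predict_proba([[0.5]])
        assert q[0, 0] == pytest.approx(0.5, abs=0.05)

    def test_needs_two_rows_per_class(self):
        with pytest.raises(ValueError):
            KDENaiveBayes().fit(np.array([[0.0], [1.0]]), np.array([0, 1]))


class TestCMVGBayes:
    def test_parameter_recovery_on_simulated_data(self, rng):
        """Estimated moments converge: relative Frobenius error of the
        covariance below 0.05 at n = 1e5, D = 5."""
        ctrl = DSCControl(D=5, S=1.0, C=0.8)
        params = build_class_params(ctrl, rng)
        ds = sample_dsc_dataset(params, 200_000, rng)
        model = CMVGBayes().fit(ds.X, ds.y)
        for c, mu, sig in [(0, params.mu0, params.sigma0), (1, params.mu1, params.sigma1)]:
            n_c = np.sum(ds.y == c)
            assert np.all(
                np.abs(model.theta_[c] - mu) < 4 * np.sqrt(np.diag(sig) / n_c)
            )
            rel = np.linalg.norm(model.covariance_[c] - sig) / np.linalg.norm(sig)
            assert rel < 0.05

    def test_equal_moment_classes_posterior_near_half(self, rng):
        X = rng.normal(size=(20_000, 3))
        y = np.repeat([0, 1], 10_000)
        model = CMVGBayes().fit(X, y)
        p = model.predict_proba(rng.normal(size=(500, 3)))
        assert np.abs(p[:, 0] - 0.5).mean() < 0.05

    def test_singular_covariance_ridge_path(self, rng):
        v = rng.normal(size=400)
        X = np.column_stack([v, v])  # exactly collinear features
        y = np.repeat([0, 1], 200)
        model = CMVGBayes().fit(X + np.outer(y, [0.5, 0.5]), y)
        assert np.isfinite(model.predict_proba(X[:5])).all()


class TestRandomDimensionalityExpansion:
    def test_linearity(self, rng):
        X = rng.normal(size=(20, 3))
        rde = RandomDimensionalityExpansion(n_components=10, random_state=0).fit(X)
        np.testing.assert_array_equal(rde.transform(np.zeros((2, 3))), 0.0)
        np.testing.assert_allclose(rde.transform(3.5 * X), 3.5 * rde.transform(X))

    def test_projection_is_shared_between_calls(self, rng):
        X = rng.normal(size=(10, 2))
        rde = RandomDimensionalityExpansion(n_components=8, random_state=1).fit(X)
        np.testing.assert_array_equal(rde.transform(X), rde.transform(X))

    def test_must_expand(self, rng):
        with pytest.raises(ValueError):
            RandomDimensionalityExpansion(n_components=2).fit(rng.normal(size=(5, 3)))

    def test_rescues_naive_bayes_on_correlation_only_classes(self, rng):
        """Classes with identical marginals but opposite feature correlations
        defeat plain naive Bayes; random expansion restores discrimination."""
        c0 = np.array([[1.0, 0.7], [0.7, 1.0]])
        c1 = np.array([[1.0, -0.7], [-0.7, 1.0]])
        X = np.vstack(
            [
                rng.multivariate_normal([0, 0], c0, 4000),
                rng.multivariate_normal([0, 0], c1, 4000),
            ]
        )
        y = np.repeat([0, 1], 4000)
        perm = rng.permutation(8000)
        ds = LabeledDataset.from_arrays(X[perm], y[perm], rng)
        plain = KDENaiveBayes()
        fit_on_dataset(plain, ds)
        acc_plain = model_accuracy(plain, ds)
        rde = RandomDimensionalityExpansion(n_components=20, random_state=0)
        rde.fit(ds.train()[0])
        expanded = ds.transformed(rde.transform)
        boosted = KDENaiveBayes()
        fit_on_dataset(boosted, expanded)
        assert acc_plain < 0.56  # marginals carry nothing
        assert model_accuracy(boosted, expanded) > acc_plain + 0.1


class TestPerceptron:
    def test_separable_blobs_are_learned(self, rng):
        X = np.vstack([rng.normal([-3, 0], 0.3, (1000, 2)), rng.normal([3, 0], 0.3, (1000, 2))])
        y = np.repeat([0, 1], 1000)
        perm = rng.permutation(2000)
        ds = LabeledDataset.from_arrays(X[perm], y[perm], rng)
        model = HiddenLayerPerceptron(random_state=0)
        fit_on_dataset(model, ds)
        assert model_accuracy(model, ds) > 0.99
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_seeded_training_is_reproducible(self, fig6_dataset):
        accs = []
        for _ in range(2):
            model = HiddenLayerPerceptron(random_state=42)
            fit_on_dataset(model, fig6_dataset)
            accs.append(model_accuracy(model, fig6_dataset))
        assert accs[0] == pytest.approx(accs[1], abs=0.005)

    def test_capacity_plateau_at_hundred_hidden_units(self, rng):
        """On correlated surrogate data a 100-unit hidden layer reaches the
        accuracy of the moment-matched Bayes model; tiny layers fall short."""
        params = build_class_params(DSCControl(D=10, S=1.0, C=0.5), np.random.default_rng(8))
        ds = sample_dsc_dataset(params, 10_000, np.random.default_rng(9))
        ref = CMVGBayes()
        fit_on_dataset(ref, ds)
        acc_ref = model_accuracy(ref, ds)
        accs = {}
        for n_hidden in (2, 100):
            model = HiddenLayerPerceptron(n_hidden=n_hidden, random_state=0)
            fit_on_dataset(model, ds)
            accs[n_hidden] = model_accuracy(model, ds)
        assert accs[100] >= accs[2] - 0.01
        assert accs[100] == pytest.approx(acc_ref, abs=0.03)


class TestModelAccuracy:
    def test_perfect_and_chance_levels(self, rng):
        X = rng.normal(size=(2000, 2))
        y = rng.integers(0, 2, 2000)
        ds = LabeledDataset.from_arrays(X, y, rng)

        class Oracle:
            def predict(self, X_):
                mask = np.isin(ds.X[:, 0], X_[:, 0])
                return ds.y[mask]

        assert model_accuracy(Oracle(), ds) == 1.0

        class Coin:
            def predict(self, X_):
                return np.random.default_rng(0).integers(0, 2, len(X_))

        assert model_accuracy(Coin(), ds) == pytest.approx(0.5, abs=0.04)

    def test_empty_test_set_rejected(self, rng):
        ds = LabeledDataset(
            np.ones((4, 1)), np.zeros(4, int), np.arange(4), np.array([], int)
        )
        with pytest.raises(ValueError):
            model_accuracy(KDENaiveBayes(), ds)
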