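"""Reference classifiers under a common scikit-learn estimator contract.

Three deliberately different learning principles, all of which should reach
the data-inherent accuracy limit when their modeling assumptions hold:

* :class:`KDENaiveBayes` — per-(class, feature) Gaussian kernel density
  estimates (Scott bandwidth), flat priors, product-of-marginals likelihood.
  Blind to inter-feature correlations by construction.
* :class:`CMVGBayes` — correlated multivariate-Gaussian likelihoods with
  per-class estimated mean vector and full covariance matrix, flat priors.
* :class:`HiddenLayerPerceptron` — one ReLU hidden layer (default 100
  units), softmax output, categorical cross-entropy, Adam, minibatch 128.

Plus :class:`RandomDimensionalityExpansion`, a fitted linear transform
``v = M u`` with a tall iid standard-normal matrix ``M`` that turns
correlation information into marginal information, letting a naive Bayes
model discriminate classes whose marginals coincide.

Posterior rows are normalized in log space (log-sum-exp) and hard labels are
the row argmax with ties broken toward the lowest class index.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .datasets import LabeledDataset

__all__ = [
    "KDENaiveBayes",
    "CMVGBayes",
    "HiddenLayerPerceptron",
    "RandomDimensionalityExpansion",
    "fit_on_dataset",
    "model_accuracy",
]

logger = logging.getLogger(__name__)

_LOG_FLOOR = np.log(1e-300)


class _FlatPriorBayesMixin:
    """Shared posterior machinery: flat priors, log-space normalization."""

    def _joint_log_likelihood(self, X):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_log_proba(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X)
        logl = np.clip(self._joint_log_likelihood(X), _LOG_FLOOR, None)
        return logl - logsumexp(logl, axis=1, keepdims=True)

    def predict_proba(self, X):
        return np.exp(self.predict_log_proba(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_log_proba(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


class KDENaiveBayes(_FlatPriorBayesMixin, ClassifierMixin, BaseEstimator):
    """Naive Bayes with one 1-D Gaussian KDE per (class, feature).

    Parameters
    ----------
    bw_method : str or float, default "scott"
        Bandwidth rule passed to :class:`scipy.stats.gaussian_kde`.
    """

    def __init__(self, bw_method: str | float = "scott"):
        self.bw_method = bw_method

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        global_std = X.std(axis=0)
        self.kdes_ = []
        for c in range(len(self.classes_)):
            Xc = X[y_idx == c]
            if Xc.shape[0] < 2:
                raise ValueError("need >= 2 training rows per class")
            row = []
            for f in range(self.n_features_in_):
                vals = Xc[:, f]
                if np.ptp(vals) == 0.0:
                    # degenerate slice: a narrow Gaussian spike at the value
                    width = 1e-6 * (global_std[f] + 1e-12)
                    logger.info(
                        "constant feature %d in class %r: falling back to a "
                        "narrow Gaussian of width %.3g",
                        f,
                        self.classes_[c],
                        width,
                    )
                    row.append(stats.norm(loc=vals[0], scale=width))
                else:
                    row.append(stats.gaussian_kde(vals, bw_method=self.bw_method))
            self.kdes_.append(row)
        return self

    def _joint_log_likelihood(self, X):
        n, K = X.shape[0], len(self.classes_)
        logl = np.zeros((n, K))
        for c in range(K):
            for f in range(self.n_features_in_):
                dens = self.kdes_[c][f]
                if isinstance(dens, stats.gaussian_kde):
                    p = dens(X[:, f])
                else:  # frozen norm fallback
                    p = dens.pdf(X[:, f])
                logl[:, c] += np.log(np.clip(p, 1e-300, None))
        return logl


class CMVGBayes(_FlatPriorBayesMixin, ClassifierMixin, BaseEstimator):
    """Bayes classifier with correlated multivariate-Gaussian likelihoods.

    Per class the training rows yield a mean vector and a full covariance
    matrix.  A singular covariance gets one ridge repair
    ``lambda = ridge * trace / D`` on the diagonal before failing.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        self.theta_, self.covariance_, self._mvns = [], [], []
        for c in range(len(self.classes_)):
            Xc = X[y_idx == c]
            if Xc.shape[0] < 2:
                raise ValueError("need >= 2 training rows per class")
            mu = Xc.mean(axis=0)
            cov = np.atleast_2d(np.cov(Xc, rowvar=False))
            try:
                mvn = stats.multivariate_normal(mean=mu, cov=cov)
            except (np.linalg.LinAlgError, ValueError):
                lam = self.ridge * np.trace(cov) / self.n_features_in_
                cov = cov + lam * np.eye(self.n_features_in_)
                mvn = stats.multivariate_normal(mean=mu, cov=cov)  # may raise
            self.theta_.append(mu)
            self.covariance_.append(cov)
            self._mvns.append(mvn)
        return self

    def _joint_log_likelihood(self, X):
        return np.column_stack([m.logpdf(X) for m in self._mvns])


class HiddenLayerPerceptron(ClassifierMixin, BaseEstimator):
    """One-hidden-layer softmax perceptron (ReLU, Adam, minibatch 128).

    Trains for a fixed number of epochs (default 30 — the reference protocol
    demands at least 10) without early stopping; ``validation_fraction`` is
    kept for interface parity but is inert unless ``early_stopping`` is
    enabled.
    """

    def __init__(
        self,
        n_hidden: int = 100,
        epochs: int = 30,
        batch_size: int = 128,
        validation_fraction: float = 0.2,
        early_stopping: bool = False,
        random_state: int | None = None,
    ):
        self.n_hidden = n_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.early_stopping = early_stopping
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.net_ = MLPClassifier(
            hidden_layer_sizes=(self.n_hidden,),
            activation="relu",
            solver="adam",
            batch_size=min(self.batch_size, X.shape[0]),
            max_iter=self.epochs,
            early_stopping=self.early_stopping,
            validation_fraction=self.validation_fraction,
            random_state=self.random_state,
        )
        import warnings as _warnings
        from sklearn.exceptions import ConvergenceWarning

        with _warnings.catch_warnings():
            # a fixed epoch budget is intentional, not a convergence failure
            _warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(X, y)
        if not np.isfinite(self.net_.loss_curve_).all():
            raise RuntimeError(
                f"perceptron training diverged (random_state={self.random_state})"
            )
        self.classes_ = self.net_.classes_
        self.loss_curve_ = list(self.net_.loss_curve_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(check_array(X))

    def predict_log_proba(self, X):
        return np.log(np.clip(self.predict_proba(X), 1e-300, None))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


class RandomDimensionalityExpansion(TransformerMixin, BaseEstimator):
    """Fitted random linear expansion ``v = M u`` with ``M`` of shape (D2, D).

    ``M`` has iid standard-normal entries, is drawn once in :meth:`fit` and
    then shared between train and test data, as any fitted transform.
    """

    def __init__(self, n_components: int = 20, random_state: int | None = None):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        if self.n_components <= X.shape[1]:
            raise ValueError("n_components (D2) must exceed the input dimension D")
        rng = np.random.default_rng(self.random_state)
        self.projection_ = rng.standard_normal((self.n_components, X.shape[1]))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "projection_")
        X = check_array(X)
        return X @ self.projection_.T


def fit_on_dataset(model, ds: LabeledDataset):
    """Fit an estimator on the training part of a dataset."""
    Xtr, ytr = ds.train()
    return model.fit(Xtr, ytr)


def model_accuracy(model, ds: LabeledDataset) -> float:
    """Fraction of correctly predicted rows on the test part of a dataset."""
    Xte, yte = ds.test()
    if len(yte) == 0:
        raise ValueError("empty test set")
    return float(np.mean(model.predict(Xte) == yte))
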