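"""Embedding analysis: spectral preprocessing, autoencoder / deep classifier
compression, MDS projection, and layer-wise cluster-separability reports.

Epoch recordings are turned into MNIST-shaped inputs: per-subject z-scoring
of the concatenated signal, per-epoch FFT, square-rooted magnitudes, the 784
lowest-frequency bins kept, then global min-max normalization to [0, 1].

Two networks share their first four layers (sizes 784, 128, 64, 16, ReLU):

* an unsupervised autoencoder 784-128-64-16-64-128-784 trained to minimize
  reconstruction MSE (Adam), and
* a supervised deep classifier whose decoder is replaced by a K-unit softmax
  trained on categorical cross-entropy.

For layers L0 (input) through L3 (bottleneck) the activations of a common
point set are scored with the GDV and projected to 2-D by metric MDS, which
is how cluster enhancement by supervised vs unsupervised compression is
compared.  The MDS here is classical (Torgerson) scaling refined by SMACOF,
deterministic given the seed, so reports are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import smacof
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .datasets import train_test_split_indices
from .features import STAGES, EpochRecording
from .gdv import gdv

__all__ = [
    "ENCODER_LAYERS",
    "SpectralDataset",
    "spectral_preprocess",
    "Autoencoder",
    "DeepClassifier",
    "layer_activations",
    "mds_2d",
    "LayerReport",
    "layerwise_gdv_report",
]

#: shared fully connected encoder sizes, input through bottleneck
ENCODER_LAYERS = (784, 128, 64, 16)


@dataclass
class SpectralDataset:
    """784-dimensional normalized spectral vectors with labels and split."""

    X: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    provenance: list = field(default_factory=list)

    def train(self):
        return self.X[self.train_idx], self.y[self.train_idx]

    def test(self):
        return self.X[self.test_idx], self.y[self.test_idx]


def spectral_preprocess(
    recordings: list[EpochRecording] | EpochRecording,
    rng: np.random.Generator | None = None,
    n_keep: int = 784,
) -> SpectralDataset:
    """Map recordings to pooled, [0, 1]-normalized spectral vectors.

    Per subject the concatenated signal is z-scored (removing setup
    differences in offset and gain), then each epoch is Fourier transformed,
    the square roots of the spectral magnitudes are taken (phases are
    discarded as uninformative between epochs), and the ``n_keep`` lowest
    frequency bins are retained.  Min-max normalization is global over the
    pooled list, followed by an 80/20 split.
    """
    if isinstance(recordings, EpochRecording):
        recordings = [recordings]
    rng = rng or np.random.default_rng(0)
    vectors, labels, provenance = [], [], []
    for rec in recordings:
        flat = rec.epochs.ravel()
        sd = flat.std()
        if sd == 0.0:
            raise ValueError(f"zero-variance recording: {rec.subject_id}")
        z = (rec.epochs - flat.mean()) / sd
        mags = np.abs(np.fft.rfft(z, axis=1))[:, :n_keep]
        vectors.append(np.sqrt(mags))
        labels.extend(STAGES.index(l) for l in rec.labels)
        provenance.extend((rec.subject_id, e) for e in range(rec.n_epochs))
    X = np.vstack(vectors)
    lo, hi = X.min(), X.max()
    X = (X - lo) / (hi - lo)
    y = np.asarray(labels)
    train_idx, test_idx = train_test_split_indices(len(y), rng)
    return SpectralDataset(X, y, train_idx, test_idx, provenance)


def _forward_activations(coefs, intercepts, X, n_layers, hidden_activation="relu"):
    """Activations after the first ``n_layers`` hidden layers of an MLP."""
    a = np.asarray(X, dtype=float)
    for i in range(n_layers):
        a = a @ coefs[i] + intercepts[i]
        if hidden_activation == "relu":
            a = np.maximum(a, 0.0)
        else:  # pragma: no cover - only relu is used
            raise ValueError(hidden_activation)
    return a


class Autoencoder(BaseEstimator):
    """Fully connected 784-128-64-16-64-128-784 ReLU autoencoder (Adam, MSE).

    The output layer is linear, which for inputs in [0, 1] is a superset of
    a ReLU output and reconstructs equally well.
    """

    def __init__(self, epochs: int = 50, batch_size: int = 128, random_state: int | None = None):
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty input")
        self.net_ = MLPRegressor(
            hidden_layer_sizes=(128, 64, 16, 64, 128),
            activation="relu",
            solver="adam",
            batch_size=min(self.batch_size, X.shape[0]),
            max_iter=self.epochs,
            random_state=self.random_state,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(X, X)
        if not np.isfinite(self.net_.loss_curve_).all():
            raise RuntimeError(
                f"autoencoder training diverged (random_state={self.random_state})"
            )
        self.loss_curve_ = list(self.net_.loss_curve_)
        return self

    def reconstruct(self, X):
        return self.net_.predict(np.asarray(X, dtype=float))

    def reconstruction_mse(self, X) -> float:
        X = np.asarray(X, dtype=float)
        return float(np.mean((self.reconstruct(X) - X) ** 2))

    def encode(self, X):
        """Bottleneck (16-dimensional) activations."""
        return layer_activations(self, X, 3)


class DeepClassifier(BaseEstimator):
    """Encoder layers 784-128-64-16 plus a K-unit softmax head.

    Trained on categorical cross-entropy with Adam; the first four layers
    match :class:`Autoencoder` exactly, so layer-wise cluster separability
    is directly comparable between supervised and unsupervised training.
    """

    def __init__(self, epochs: int = 50, batch_size: int = 128, random_state: int | None = None):
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.size == 0 or y.size == 0:
            raise ValueError("labels and inputs required")
        self.net_ = MLPClassifier(
            hidden_layer_sizes=(128, 64, 16),
            activation="relu",
            solver="adam",
            batch_size=min(self.batch_size, X.shape[0]),
            max_iter=self.epochs,
            random_state=self.random_state,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(X, y)
        if not np.isfinite(self.net_.loss_curve_).all():
            raise RuntimeError(
                f"classifier training diverged (random_state={self.random_state})"
            )
        self.classes_ = self.net_.classes_
        self.loss_curve_ = list(self.net_.loss_curve_)
        return self

    def predict(self, X):
        return self.net_.predict(np.asarray(X, dtype=float))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def layer_activations(model, X, layer: int) -> np.ndarray:
    """Activations of layer ``layer`` (0 = raw input, 3 = bottleneck).

    Works for both :class:`Autoencoder` and :class:`DeepClassifier`; row
    order is preserved.
    """
    X = np.asarray(X, dtype=float)
    if layer == 0:
        return X
    net = getattr(model, "net_", model)
    n_hidden = len(net.hidden_layer_sizes)
    if not 1 <= layer <= n_hidden:
        raise ValueError(f"layer must lie in [0, {n_hidden}], got {layer}")
    return _forward_activations(net.coefs_, net.intercepts_, X, layer)


def _classical_scaling(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson classical scaling: eigendecomposition of the doubly
    centered squared-distance matrix, truncated to the top ``k`` axes."""
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    # deterministic sign convention: largest-magnitude entry positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def mds_2d(points: np.ndarray, seed: int = 0, refine: bool = True) -> np.ndarray:
    """Metric MDS projection of points to 2-D.

    Classical scaling provides a deterministic initialization (exact when a
    2-D embedding exists); SMACOF stress minimization refines it.  Returns
    ``(n, 2)`` coordinates; duplicate points are handled (zero distances are
    legal in SMACOF).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points")
    dist = squareform(pdist(points))
    init = _classical_scaling(dist, 2)
    if not refine:
        return init
    coords, _ = smacof(
        dist,
        n_components=2,
        init=init,
        n_init=1,
        random_state=seed,
        normalized_stress=False,
    )
    return coords


def mds_stress(points_2d: np.ndarray, original: np.ndarray) -> float:
    """Raw stress: sum of squared distance mismatches of an embedding."""
    return float(np.sum((pdist(points_2d) - pdist(original)) ** 2))


@dataclass
class LayerReport:
    """Per-layer separability report on one common point set."""

    layers: list[int]
    gdv_values: dict
    mds_coords: dict
    n_points: int
    subsample: int | None = None


def layerwise_gdv_report(
    model,
    X: np.ndarray,
    y: np.ndarray,
    layers: tuple = (0, 1, 2, 3),
    subsample: int | None = 10_000,
    seed: int = 0,
    with_mds: bool = True,
) -> LayerReport:
    """GDV (and optionally MDS coordinates) per layer for one point subset.

    The same subsample of rows is propagated through every requested layer,
    so GDV differences across layers reflect the transform, not the sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    if subsample is not None and X.shape[0] > subsample:
        idx = rng.choice(X.shape[0], size=subsample, replace=False)
        X, y = X[idx], y[idx]
    # classes need >= 2 points for a mean intra-class distance; drop rarities
    classes, counts = np.unique(y, return_counts=True)
    thin = classes[counts < 2]
    if thin.size:
        keep = ~np.isin(y, thin)
        X, y = X[keep], y[keep]
    gdv_values, mds_coords = {}, {}
    for layer in layers:
        act = layer_activations(model, X, layer)
        gdv_values[layer] = gdv(act, y).gdv
        if with_mds:
            mds_coords[layer] = mds_2d(act, seed=seed)
    return LayerReport(
        layers=list(layers),
        gdv_values=gdv_values,
        mds_coords=mds_coords,
        n_points=X.shape[0],
        subsample=subsample,
    )
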