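import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from bayeslimit.embedding import (
    Autoencoder,
    DeepClassifier,
    _classical_scaling,
    layer_activations,
    layerwise_gdv_report,
    mds_2d,
    mds_stress,
    spectral_preprocess,
)
from bayeslimit.features import EpochRecording, SyntheticSleepConfig, synth_sleep_recording
from bayeslimit.gdv import gdv


@pytest.fixture(scope="module")
def blobs():
    """Ten well-separated Gaussian classes in 784-D."""
    rng = np.random.default_rng(0)
    centers = rng.normal(0, 0.6, (10, 784))
    y = rng.integers(0, 10, 2000)
    X = centers[y] + rng.normal(0, 1.0, (2000, 784))
    return X, y


@pytest.fixture(scope="module")
def spectra():
    cfg = SyntheticSleepConfig(n_epochs=150)
    recs = [
        synth_sleep_recording(cfg, np.random.default_rng(s)) for s in range(3)
    ]
    return spectral_preprocess(recs, np.random.default_rng(5))


class TestSpectralPreprocess:
    def test_output_shape_and_range(self, spectra):
        assert spectra.X.shape[1] == 784
        assert spectra.X.min() >= 0.0 and spectra.X.max() <= 1.0
        assert len(spectra.train_idx) + len(spectra.test_idx) == len(spectra.y)

    def test_pure_tone_concentrates_at_its_bin(self):
        t = np.arange(1, 7681) / 256.0
        epochs = np.vstack(
            [np.cos(2 * np.pi * 5.0 * t), np.random.default_rng(0).normal(size=7680)]
        )
        rec = EpochRecording(epochs, ["N2", "Wake"], "tone")
        data = spectral_preprocess(rec, np.random.default_rng(0))
        # 5 Hz at 1/30 Hz resolution lands in bin 150
        assert int(np.argmax(data.X[0])) == 150

    def test_phase_randomization_leaves_spectra_unchanged(self, rng):
        spec = rng.normal(size=3841) + 1j * rng.normal(size=3841)
        spec[0] = 0.0
        spec[-1] = spec[-1].real
        x = np.fft.irfft(spec, n=7680)
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, 3841))
        phases[0] = phases[-1] = 1.0
        x2 = np.fft.irfft(spec * phases, n=7680)
        a = spectral_preprocess(EpochRecording(x[None, :], ["N2"]), np.random.default_rng(1))
        b = spectral_preprocess(EpochRecording(x2[None, :], ["N2"]), np.random.default_rng(1))
        np.testing.assert_allclose(a.X, b.X, atol=1e-9)

    def test_zero_variance_recording_rejected(self):
        rec = EpochRecording(np.ones((2, 7680)), ["N2", "N2"])
        with pytest.raises(ValueError):
            spectral_preprocess(rec, np.random.default_rng(0))


class TestAutoencoder:
    def test_bottleneck_is_sixteen_dimensional(self, spectra):
        Xtr, _ = spectra.train()
        ae = Autoencoder(epochs=5, random_state=0).fit(Xtr)
        assert ae.encode(Xtr[:7]).shape == (7, 16)

    def test_training_halves_reconstruction_error(self, spectra):
        Xtr, _ = spectra.train()
        Xte, _ = spectra.test()
        barely = Autoencoder(epochs=1, random_state=0).fit(Xtr)
        trained = Autoencoder(epochs=40, random_state=0).fit(Xtr)
        assert trained.reconstruction_mse(Xte) < 0.5 * barely.reconstruction_mse(Xte)

    def test_seeded_training_is_reproducible(self, spectra):
        Xtr, _ = spectra.train()
        a = Autoencoder(epochs=5, random_state=3).fit(Xtr)
        b = Autoencoder(epochs=5, random_state=3).fit(Xtr)
        assert a.loss_curve_[-1] == pytest.approx(b.loss_curve_[-1], abs=1e-4)


class TestDeepClassifier:
    def test_separable_blobs_are_classified(self, blobs):
        X, y = blobs
        clf = DeepClassifier(epochs=40, random_state=0).fit(X[:1600], y[:1600])
        assert clf.score(X[1600:], y[1600:]) > 0.95

    def test_encoder_layers_match_autoencoder(self, blobs, spectra):
        X, y = blobs
        clf = DeepClassifier(epochs=2, random_state=0).fit(X[:300], y[:300])
        ae = Autoencoder(epochs=2, random_state=0).fit(spectra.X[:300])
        for layer in (1, 2, 3):
            a = layer_activations(clf, X[:5], layer)
            b = layer_activations(ae, spectra.X[:5], layer)
            assert a.shape[1] == b.shape[1]


class TestLayerActivations:
    def test_layer_zero_is_identity(self, blobs):
        X, y = blobs
        clf = DeepClassifier(epochs=2, random_state=0).fit(X[:300], y[:300])
        np.testing.assert_array_equal(layer_activations(clf, X[:10], 0), X[:10])

    def test_bottleneck_dimension_and_determinism(self, blobs):
        X, y = blobs
        clf = DeepClassifier(epochs=2, random_state=0).fit(X[:300], y[:300])
        act = layer_activations(clf, X[:20], 3)
        assert act.shape == (20, 16)
        np.testing.assert_array_equal(act, layer_activations(clf, X[:20], 3))

    def test_invalid_layer_rejected(self, blobs):
        X, y = blobs
        clf = DeepClassifier(epochs=2, random_state=0).fit(X[:300], y[:300])
        with pytest.raises(ValueError):
            layer_activations(clf, X[:5], 9)


class TestMDS:
    def test_recovers_planar_configurations_exactly(self, rng):
        pts = rng.normal(size=(40, 2))
        emb = mds_2d(pts, seed=0)
        assert mds_stress(emb, pts) < 1e-6

    def test_tetrahedron_matches_classical_scaling_oracle(self):
        """Rank-2 classical scaling of a 3-D tetrahedron equals the top-2
        eigendecomposition of the doubly centered squared-distance matrix."""
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        dist = squareform(pdist(verts))
        emb = mds_2d(verts, seed=0, refine=False)
        # independent oracle, written out in full
        n = 4
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (dist**2) @ J
        vals, vecs = np.linalg.eigh(B)
        top = np.argsort(vals)[::-1][:2]
        oracle = vecs[:, top] * np.sqrt(vals[top])
        # orientation is arbitrary: compare the recovered Gram structure
        np.testing.assert_allclose(emb @ emb.T, oracle @ oracle.T, atol=1e-9)
        assert np.allclose(emb.sum(axis=0), 0.0, atol=1e-9)  # centered

    def test_seeded_coordinates_are_identical(self, rng):
        pts = rng.normal(size=(30, 5))
        np.testing.assert_array_equal(mds_2d(pts, seed=4), mds_2d(pts, seed=4))

    def test_duplicate_points_do_not_crash(self, rng):
        pts = np.repeat(rng.normal(size=(5, 3)), 3, axis=0)
        emb = mds_2d(pts, seed=0)
        assert emb.shape == (15, 2)

    def test_needs_three_points(self, rng):
        with pytest.raises(ValueError):
            mds_2d(rng.normal(size=(2, 3)))


class TestLayerwiseReports:
    def test_supervised_training_sharpens_clusters_layer_by_layer(self, blobs):
        X, y = blobs
        clf = DeepClassifier(epochs=40, random_state=0).fit(X[:1600], y[:1600])
        rep = layerwise_gdv_report(clf, X[1600:], y[1600:], subsample=None, with_mds=False)
        vals = [rep.gdv_values[k] for k in (0, 1, 2, 3)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_untrained_network_preserves_separability(self, blobs):
        X, y = blobs
        clf = DeepClassifier(epochs=1, random_state=1).fit(X[:200], y[:200])
        rep = layerwise_gdv_report(clf, X[1600:], y[1600:], subsample=None, with_mds=False)
        assert abs(rep.gdv_values[3] - rep.gdv_values[0]) < 0.05

    def test_label_shuffling_removes_the_layerwise_decrease(self, blobs):
        X, y = blobs
        ys = np.random.default_rng(2).permutation(y)
        clf = DeepClassifier(epochs=40, random_state=0).fit(X[:1600], ys[:1600])
        rep = layerwise_gdv_report(clf, X[1600:], ys[1600:], subsample=None, with_mds=False)
        vals = [rep.gdv_values[k] for k in (0, 1, 2, 3)]
        deltas = np.abs(np.diff(vals))
        assert np.all(deltas < 0.03)

    def test_unsupervised_compression_does_not_blur_clusters(self, spectra):
        Xtr, _ = spectra.train()
        Xte, yte = spectra.test()
        ae = Autoencoder(epochs=40, random_state=0).fit(Xtr)
        rep = layerwise_gdv_report(ae, Xte, yte, subsample=None, with_mds=False)
        for layer in (1, 2, 3):
            assert rep.gdv_values[layer] <= rep.gdv_values[0] + 0.01

    def test_report_is_consistent_with_direct_gdv_calls(self, blobs):
        X, y = blobs
        clf = DeepClassifier(epochs=5, random_state=0).fit(X[:400], y[:400])
        rep = layerwise_gdv_report(
            clf, X[:300], y[:300], layers=(0, 2), subsample=None, with_mds=True
        )
        for layer in (0, 2):
            direct = gdv(layer_activations(clf, X[:300], layer), y[:300]).gdv
            assert rep.gdv_values[layer] == pytest.approx(direct, abs=1e-12)
            assert rep.mds_coords[layer].shape == (300, 2)
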