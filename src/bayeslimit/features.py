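"""Epoch-level time-series features and a synthetic sleep-recording source.

A recording is a sequence of fixed-length single-channel signal epochs
(default 30 s at 256 Hz, i.e. 7680 samples) with one sleep-stage label per
epoch out of {Wake, REM, N1, N2, N3}.  Two interpretable feature families
compress an epoch into a low-dimensional vector:

* Fourier-magnitude features: the unnormalized magnitude of the projection
  of the epoch onto the sine/cosine pair at a tunable frequency (default
  grid 5, 10, ..., 30 Hz, below the 30 Hz hardware filter bound).
* Autocorrelation features: the normalized autocorrelation coefficient at a
  tunable integer sample lag (default 1, 3, ..., 11).

Clinical sleep EEG is not distributable, so :func:`synth_sleep_recording`
generates surrogate recordings: each epoch is band-limited noise with
stage-dependent spectral band weights (delta-dominant N3, alpha-rich Wake,
theta-mixed N1/REM/N2), a per-epoch lognormal amplitude gain whose spread is
widest in Wake (making Wake feature distributions the broadest and the most
mutually correlated), and a broadband noise floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import LabeledDataset, train_test_split_indices

__all__ = [
    "STAGES",
    "EpochRecording",
    "FourierFeatureSpec",
    "CorrFeatureSpec",
    "SyntheticSleepConfig",
    "fourier_feature",
    "autocorr_feature",
    "extract_features",
    "pointwise_transform",
    "synth_sleep_recording",
]

STAGES = ("Wake", "REM", "N1", "N2", "N3")

#: EEG frequency bands in Hz used by the synthetic generator; sigma is the
#: sleep-spindle band that characterizes N2
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}


@dataclass
class EpochRecording:
    """Fixed-length signal epochs with per-epoch stage labels."""

    epochs: np.ndarray  # (n_epochs, epoch_len)
    labels: list[str]
    subject_id: str = "synthetic"
    rate: int = 256

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must form a 2-D (n_epochs, length) array")
        if self.epochs.shape[0] != len(self.labels):
            raise ValueError("one label per epoch required")
        bad = set(self.labels) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def save(self, stem: str | Path) -> tuple[Path, Path]:
        """Delimited epoch matrix plus JSON sidecar (rate, labels, subject)."""
        stem = Path(stem)
        csv_path = stem.with_suffix(".csv")
        json_path = stem.with_suffix(".json")
        np.savetxt(csv_path, self.epochs, delimiter=",")
        json_path.write_text(
            json.dumps(
                {"rate": self.rate, "labels": self.labels, "subject_id": self.subject_id}
            )
        )
        return csv_path, json_path

    @classmethod
    def load(cls, stem: str | Path) -> "EpochRecording":
        stem = Path(stem)
        epochs = np.atleast_2d(np.loadtxt(stem.with_suffix(".csv"), delimiter=","))
        side = json.loads(stem.with_suffix(".json").read_text())
        return cls(epochs, side["labels"], side["subject_id"], side["rate"])


@dataclass(frozen=True)
class FourierFeatureSpec:
    """Frequencies (Hz) of the Fourier-magnitude features."""

    frequencies: tuple = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 30.0 for f in self.frequencies):
            raise ValueError("frequencies must lie in [0, 30] Hz")


@dataclass(frozen=True)
class CorrFeatureSpec:
    """Integer sample lags of the autocorrelation features."""

    lags: tuple = (1, 3, 5, 7, 9, 11)

    def __post_init__(self) -> None:
        if any((l != int(l) or l < 1) for l in self.lags):
            raise ValueError("lags must be positive integers (sample units)")


def fourier_feature(signal: np.ndarray, nu: float, rate: int = 256) -> float:
    """Magnitude of the projection onto the sinusoid pair at frequency ``nu``.

    Uses the convention ``t_n = n / rate`` with n starting at 1; the choice
    of origin shifts only the (discarded) phase.  At on-grid frequencies
    (an integer number of cycles per epoch) this equals the discrete Fourier
    magnitude.
    """
    if nu < 0:
        raise ValueError("frequency must be nonnegative")
    signal = np.asarray(signal, dtype=float)
    t = np.arange(1, signal.size + 1) / rate
    ang = 2.0 * np.pi * nu * t
    return float(np.hypot(np.dot(signal, np.cos(ang)), np.dot(signal, np.sin(ang))))


def autocorr_feature(signal: np.ndarray, lag: int) -> float:
    """Normalized autocorrelation at an integer sample lag.

    The average runs over the valid overlap of length ``L - lag`` and is
    normalized by the full-epoch population variance, so the value at lag 0
    is exactly 1 and finite-sample values can marginally exceed 1.
    """
    signal = np.asarray(signal, dtype=float)
    L = signal.size
    if not 0 <= lag < L:
        raise ValueError("lag must satisfy 0 <= lag < epoch length")
    x = signal - signal.mean()
    var = np.mean(x**2)
    if var == 0.0:
        raise ValueError("constant epoch: autocorrelation undefined")
    if lag == 0:
        return 1.0
    return float(np.mean(x[:-lag] * x[lag:]) / var)


def extract_features(
    rec: EpochRecording,
    spec: FourierFeatureSpec | CorrFeatureSpec,
    rng: np.random.Generator | None = None,
    test_fraction: float = 0.2,
) -> LabeledDataset:
    """One feature vector per epoch; labels carried through, 80/20 split.

    Labels are mapped to integers following the canonical stage order
    (Wake=0, REM=1, N1=2, N2=3, N3=4).  Feature extraction itself is
    label-agnostic: permuting epochs permutes rows identically.
    """
    rng = rng or np.random.default_rng(0)
    if isinstance(spec, FourierFeatureSpec):
        t = np.arange(1, rec.epoch_len + 1) / rec.rate
        cols = []
        for nu in spec.frequencies:
            ang = 2.0 * np.pi * nu * t
            cols.append(
                np.hypot(rec.epochs @ np.cos(ang), rec.epochs @ np.sin(ang))
            )
        X = np.column_stack(cols)
    elif isinstance(spec, CorrFeatureSpec):
        E = rec.epochs - rec.epochs.mean(axis=1, keepdims=True)
        var = np.mean(E**2, axis=1)
        if np.any(var == 0.0):
            raise ValueError("constant epoch: autocorrelation undefined")
        X = np.column_stack(
            [np.mean(E[:, :-lag] * E[:, lag:], axis=1) / var for lag in spec.lags]
        )
    else:
        raise TypeError(f"unknown feature spec: {type(spec).__name__}")
    y = np.array([STAGES.index(l) for l in rec.labels])
    return LabeledDataset.from_arrays(
        X,
        y,
        rng,
        test_fraction,
        meta={"subject_id": rec.subject_id, "feature_spec": repr(spec)},
    )


def pointwise_transform(X: np.ndarray, kind: str) -> np.ndarray:
    """Elementwise nonlinear feature transform: ``sin``, ``cos`` or ``sgn``.

    ``sgn`` maps negatives to -1 and everything else (including the
    measure-zero exact 0) to +1.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if kind == "sin":
        return np.sin(X)
    if kind == "cos":
        return np.cos(X)
    if kind == "sgn":
        return np.where(X < 0, -1.0, 1.0)
    raise ValueError(f"unknown transform kind: {kind!r}")


# ---------------------------------------------------------------------------
# synthetic sleep recordings
# ---------------------------------------------------------------------------

#: per-stage relative band powers (delta, theta, alpha, beta): textbook sleep
#: EEG structure — alpha-rich Wake, theta-dominant N1/REM, delta-dominant N3
DEFAULT_BAND_POWERS = {
    "Wake": {"delta": 0.3, "theta": 0.3, "alpha": 1.0, "sigma": 0.3, "beta": 0.6},
    "REM": {"delta": 0.3, "theta": 0.8, "alpha": 0.3, "sigma": 0.2, "beta": 0.5},
    "N1": {"delta": 0.4, "theta": 1.0, "alpha": 0.4, "sigma": 0.2, "beta": 0.2},
    "N2": {"delta": 0.8, "theta": 0.6, "alpha": 0.3, "sigma": 1.0, "beta": 0.2},
    "N3": {"delta": 1.5, "theta": 0.5, "alpha": 0.15, "sigma": 0.3, "beta": 0.1},
}

#: lognormal sigma of the per-epoch amplitude gain; widest in Wake, which
#: both broadens Wake feature distributions and correlates its features
DEFAULT_VARIABILITY = {"Wake": 0.4, "REM": 0.1, "N1": 0.12, "N2": 0.1, "N3": 0.08}

#: typical full-night hypnogram occupancies
DEFAULT_OCCUPANCY = {"Wake": 0.15, "REM": 0.15, "N1": 0.10, "N2": 0.45, "N3": 0.15}


@dataclass
class SyntheticSleepConfig:
    """Controls of the surrogate sleep-recording generator."""

    n_epochs: int = 960  # one 8-h night of 30-s epochs
    occupancy: dict = field(default_factory=lambda: dict(DEFAULT_OCCUPANCY))
    band_powers: dict = field(default_factory=lambda: dict(DEFAULT_BAND_POWERS))
    variability: dict = field(default_factory=lambda: dict(DEFAULT_VARIABILITY))
    noise_floor: float = 0.05
    band_jitter: float = 0.4  # lognormal sigma of per-epoch band-weight jitter
    persistence: float = 0.0  # probability of repeating the previous stage
    epoch_len: int = 7680
    rate: int = 256
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        occ = np.array([self.occupancy.get(s, 0.0) for s in STAGES])
        if np.any(occ < 0) or not np.isclose(occ.sum(), 1.0):
            raise ValueError("occupancy must be nonnegative and sum to 1")
        if occ.max() == 1.0:
            raise ValueError("degenerate occupancy: a single stage has mass 1")
        for s in STAGES:
            if any(v < 0 for v in self.band_powers[s].values()):
                raise ValueError("band powers must be nonnegative")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")


def _stage_sequence(cfg: SyntheticSleepConfig, rng: np.random.Generator) -> list[str]:
    occ = np.array([cfg.occupancy.get(s, 0.0) for s in STAGES])
    seq = []
    for e in range(cfg.n_epochs):
        if seq and rng.uniform() < cfg.persistence:
            seq.append(seq[-1])
        else:
            seq.append(STAGES[rng.choice(len(STAGES), p=occ)])
    return seq


def _band_epoch(
    weights: dict, cfg: SyntheticSleepConfig, rng: np.random.Generator
) -> np.ndarray:
    """One epoch of band-weighted noise, synthesized in the frequency domain."""
    L = cfg.epoch_len
    freqs = np.fft.rfftfreq(L, d=1.0 / cfg.rate)
    amp = np.full(freqs.shape, cfg.noise_floor)
    for band, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        amp[mask] += np.sqrt(weights.get(band, 0.0))
    # real stages vary in spectral shape epoch to epoch: jitter narrow
    # sub-bands independently, so that fluctuations of well-separated
    # spectral features are only weakly coupled (their residual coupling
    # comes from the per-epoch amplitude gain, largest in Wake)
    edges = np.arange(0.0, cfg.rate / 2 + 2.5, 5.0) + 2.5
    lo_edge = 0.0
    for hi_edge in edges:
        mask = (freqs >= lo_edge) & (freqs < hi_edge)
        amp[mask] *= np.exp(0.5 * cfg.band_jitter * rng.standard_normal())
        lo_edge = hi_edge
    spectrum = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spectrum[0] = 0.0  # zero-mean signal
    return np.fft.irfft(spectrum, n=L)


def synth_sleep_recording(
    cfg: SyntheticSleepConfig | None = None,
    rng: np.random.Generator | None = None,
) -> EpochRecording:
    """Generate one surrogate full-night recording with known stage labels."""
    cfg = cfg or SyntheticSleepConfig()
    rng = rng or np.random.default_rng()
    labels = _stage_sequence(cfg, rng)
    epochs = np.empty((cfg.n_epochs, cfg.epoch_len))
    for e, stage in enumerate(labels):
        gain = np.exp(cfg.variability[stage] * rng.standard_normal())
        epochs[e] = gain * _band_epoch(cfg.band_powers[stage], cfg, rng)
    return EpochRecording(epochs, labels, cfg.subject_id, cfg.rate)
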