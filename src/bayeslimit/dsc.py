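"""The DSC surrogate-data generator.

A two-level ("superstatistical") generator of labeled two-class Gaussian
datasets in which three high-level control quantities set the statistics:

* ``D`` — feature-space dimensionality,
* ``S`` — class separation: class-0 means are pinned at zero, class-1 means
  are drawn per dimension from ``uniform[0, S]``,
* ``C`` in ``[0, 2]`` — feature-correlation level: unit-diagonal covariance
  matrices whose off-diagonal entries are drawn from ``uniform[0, C]`` for
  ``C <= 1`` and ``uniform[C-1, 1]`` for ``C > 1``.

For each control triple, ``n_rep`` independent low-level parameter sets
``(mu^(c), Sigma^(c))`` are drawn, and from each a dataset of ``n_vec``
vectors (half per class) is sampled, shuffled, and split 80/20.  Because
every dataset obeys its own random parameters, repetitions mimic the
heterogeneity of real-world data sources.

Raw off-diagonal draws need not form a valid covariance matrix; indefinite
draws are repaired by clipping negative eigenvalues (see
:func:`repair_covariance`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset

__all__ = [
    "DSCControl",
    "ClassParams",
    "sample_offdiag_entries",
    "repair_covariance",
    "build_class_params",
    "sample_dsc_dataset",
    "make_dsc_datasets",
    "empirical_rms_offdiag",
]

#: eigenvalue floor accepted as "positive semidefinite" after repair
PSD_TOL = 1e-10


@dataclass(frozen=True)
class DSCControl:
    """High-level control triple plus replication counts and root seed."""

    D: int
    S: float
    C: float
    n_rep: int = 100
    n_vec: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be a positive integer")
        if self.S < 0:
            raise ValueError("S must be nonnegative")
        if not 0.0 <= self.C <= 2.0:
            raise ValueError(f"C must lie in [0, 2], got {self.C}")
        if self.n_rep < 1:
            raise ValueError("n_rep must be positive")
        if self.n_vec < 2 or self.n_vec % 2:
            raise ValueError("n_vec must be even and >= 2 (n_vec/2 per class)")


@dataclass
class ClassParams:
    """Low-level per-class Gaussian parameters drawn by the generator."""

    mu0: np.ndarray
    mu1: np.ndarray
    sigma0: np.ndarray
    sigma1: np.ndarray
    meta: dict = field(default_factory=dict)

    def validate(self, S: float | None = None) -> None:
        D = len(self.mu0)
        if np.any(self.mu0 != 0.0):
            raise ValueError("class-0 means must be exactly zero")
        if S is not None and (np.any(self.mu1 < 0) or np.any(self.mu1 > S)):
            raise ValueError("class-1 means must lie in [0, S]")
        for sig in (self.sigma0, self.sigma1):
            if sig.shape != (D, D):
                raise ValueError("covariance shape mismatch")
            if not np.allclose(sig, sig.T):
                raise ValueError("covariance must be symmetric")
            if not np.allclose(np.diag(sig), 1.0):
                raise ValueError("covariance diagonal must be 1")
            if np.linalg.eigvalsh(sig).min() < -PSD_TOL:
                raise ValueError("covariance is not positive semidefinite")


def sample_offdiag_entries(C: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` off-diagonal covariance entries from the box density q(x, C).

    ``uniform[0, C]`` for ``C <= 1``, else ``uniform[C-1, 1]``; the two
    limiting cases are degenerate: all zeros at ``C = 0`` (identity
    covariance) and all ones at ``C = 2`` (perfect correlation).
    """
    if not 0.0 <= C <= 2.0:
        raise ValueError(f"C must lie in [0, 2], got {C}")
    if C <= 1.0:
        lo, hi = 0.0, C
    else:
        lo, hi = C - 1.0, 1.0
    return rng.uniform(lo, hi, size=n)


def repair_covariance(M: np.ndarray) -> np.ndarray:
    """Repair a symmetric unit-diagonal matrix into a valid covariance.

    If ``M`` is already PSD it is returned unchanged.  Otherwise negative
    eigenvalues are reflected to their absolute values, the matrix
    reconstructed, and the diagonal rescaled back to exactly 1 (a congruence,
    so PSD is preserved).  One pass only; no resampling, so the drawn
    correlation structure is kept.

    Reflection (rather than clipping to zero) keeps the repaired matrix full
    rank: clipping concentrates each class on a lower-dimensional subspace,
    which makes two independently drawn classes almost surely separable and
    destroys the intended statistics of strongly correlated draws.
    Reflection is also what the classic SVD-based multivariate-normal
    samplers do implicitly when handed an indefinite matrix, so datasets
    generated this way have the familiar behavior of that ecosystem.
    """
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("input must be symmetric")
    if not np.allclose(np.diag(M), 1.0):
        raise ValueError("input must have unit diagonal")
    vals, vecs = np.linalg.eigh(M)
    if vals.min() >= -PSD_TOL:
        return M
    R = (vecs * np.abs(vals)) @ vecs.T
    d = np.sqrt(np.diag(R))
    d[d == 0.0] = 1.0
    R = R / np.outer(d, d)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def build_class_params(ctrl: DSCControl, rng: np.random.Generator) -> ClassParams:
    """Draw one low-level parameter set ``(mu^(c), Sigma^(c))`` for the triple."""
    D = ctrl.D
    mu0 = np.zeros(D)
    mu1 = rng.uniform(0.0, ctrl.S, size=D)
    n_off = D * (D - 1) // 2
    sigmas = []
    for _ in range(2):
        sig = np.eye(D)
        if n_off:
            off = sample_offdiag_entries(ctrl.C, n_off, rng)
            iu = np.triu_indices(D, k=1)
            sig[iu] = off
            sig.T[iu] = off
        sigmas.append(repair_covariance(sig))
    params = ClassParams(mu0, mu1, sigmas[0], sigmas[1])
    params.validate(S=ctrl.S)
    return params


def sample_dsc_dataset(
    params: ClassParams,
    n_vec: int,
    rng: np.random.Generator,
    meta: dict | None = None,
) -> LabeledDataset:
    """Sample ``n_vec/2`` Gaussian vectors per class, shuffle, split 80/20."""
    if n_vec % 2:
        raise ValueError("n_vec must be even")
    half = n_vec // 2
    # 'eigh' handles the singular covariances that arise at C near 2
    X0 = rng.multivariate_normal(
        params.mu0, params.sigma0, size=half, method="eigh", check_valid="ignore"
    )
    X1 = rng.multivariate_normal(
        params.mu1, params.sigma1, size=half, method="eigh", check_valid="ignore"
    )
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], half)
    perm = rng.permutation(n_vec)
    return LabeledDataset.from_arrays(X[perm], y[perm], rng, meta=meta)


def make_dsc_datasets(ctrl: DSCControl) -> list[LabeledDataset]:
    """Generate the full set of ``n_rep`` datasets for one control triple.

    Seeding uses one child stream per repetition spawned from the root seed,
    so increasing ``n_rep`` never perturbs earlier repetitions.
    """
    streams = np.random.SeedSequence(ctrl.seed).spawn(ctrl.n_rep)
    out = []
    for k, ss in enumerate(streams):
        param_ss, data_ss = ss.spawn(2)
        params = build_class_params(ctrl, np.random.default_rng(param_ss))
        meta = {
            "D": ctrl.D,
            "S": ctrl.S,
            "C": ctrl.C,
            "rep": k,
            "seed": ctrl.seed,
            "mu1": params.mu1,
        }
        out.append(
            sample_dsc_dataset(params, ctrl.n_vec, np.random.default_rng(data_ss), meta)
        )
    return out


def empirical_rms_offdiag(X_class: np.ndarray) -> float:
    """RMS of the strictly-upper-triangular empirical covariance entries.

    The scalar summary used to verify that the correlation level of sampled
    data tracks the control quantity ``C`` (near 0 at ``C=0``, near 1 at
    ``C=2``, almost linear in between).
    """
    X_class = np.asarray(X_class, dtype=float)
    if X_class.ndim != 2 or X_class.shape[1] < 2:
        raise ValueError("need an n x D matrix with D >= 2")
    if X_class.shape[0] < 2:
        raise ValueError("need at least two rows")
    cov = np.cov(X_class, rowvar=False)
    iu = np.triu_indices(X_class.shape[1], k=1)
    return float(np.sqrt(np.mean(cov[iu] ** 2)))
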