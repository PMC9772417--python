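"""Theoretical accuracy limit of classification under known densities.

Given class priors :math:`w_i` and class-conditional generation densities
:math:`p_{gen}(x|i)`, an ideal classifier assigns each point to the class
with the largest classification probability

.. math:: q(j|x) = p(x|j) / \\sum_k p(x|k)

(optionally weighted by priors).  The resulting binary class-indicator
function combines with the generation densities into confusion densities
whose integrals form the column-stochastic confusion matrix :math:`C_{ji}`,
and the achievable accuracy is :math:`A = \\sum_i w_i C_{ii}`.  When the
"learned" densities equal the generation densities this accuracy is the
data-inherent limit :math:`A_{max}` (one minus the Bayes error): no
classifier, however trained, can do better on data from this source.

The integral is evaluated either on a regular grid (dimensions <= 3) or by
Monte Carlo sampling from the generation densities.  All density work is in
log space so that the far tails of the integration window do not underflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import logsumexp, ndtr

__all__ = [
    "GenerativeSpec",
    "GridSpec",
    "ConfusionResult",
    "classification_probabilities",
    "hard_assign",
    "confusion_matrix_grid",
    "confusion_matrix_mc",
    "weighted_accuracy",
    "bayes_limit_gaussian_1d",
]

#: densities below this are treated as numerically zero at a query point
_LOG_FLOOR = np.log(1e-300)


@dataclass
class GenerativeSpec:
    """Priors plus per-class Gaussian densities: the ground-truth source.

    Attributes
    ----------
    w : (K,) priors, nonnegative, summing to 1.
    means : list of K mean vectors (length ``dim``).
    covs : list of K ``dim x dim`` covariance matrices.
    """

    w: np.ndarray
    means: list[np.ndarray]
    covs: list[np.ndarray]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.means = [np.atleast_1d(np.asarray(m, dtype=float)) for m in self.means]
        self.covs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in self.covs]
        if np.any(self.w < 0) or not np.isclose(self.w.sum(), 1.0):
            raise ValueError("priors must be nonnegative and sum to 1")
        if not (len(self.w) == len(self.means) == len(self.covs)):
            raise ValueError("w, means, covs must have equal length K")
        dims = {len(m) for m in self.means} | {c.shape[0] for c in self.covs}
        if len(dims) != 1:
            raise ValueError("all classes must share one feature dimension")
        self._frozen = [
            stats.multivariate_normal(mean=m, cov=c, allow_singular=True)
            for m, c in zip(self.means, self.covs)
        ]

    @property
    def K(self) -> int:
        return len(self.w)

    @property
    def dim(self) -> int:
        return len(self.means[0])

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        """Log generation densities, shape ``(n, K)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([f.logpdf(X) for f in self._frozen])

    def sample_class(self, i: int, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(
            self.means[i], self.covs[i], size=n, method="eigh", check_valid="ignore"
        )

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` labeled points with class frequencies given by the priors."""
        y = rng.choice(self.K, size=n, p=self.w)
        X = np.empty((n, self.dim))
        for i in range(self.K):
            mask = y == i
            if mask.any():
                X[mask] = self.sample_class(i, int(mask.sum()), rng)
        return X, y

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "w": self.w.tolist(),
            "means": [m.tolist() for m in self.means],
            "covs": [c.tolist() for c in self.covs],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerativeSpec":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["w"]), d["means"], d["covs"])


# the "learned" densities share the container; when computing the limit they
# are simply the generation densities themselves
LearnedDensities = GenerativeSpec


@dataclass(frozen=True)
class GridSpec:
    """Regular integration grid: per-dimension bounds and a common spacing."""

    lo: float = -8.0
    hi: float = 8.0
    spacing: float = 0.01

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("lo must be < hi")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        n = (self.hi - self.lo) / self.spacing
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(hi - lo) / spacing must be an integer")

    @property
    def n_points(self) -> int:
        return int(round((self.hi - self.lo) / self.spacing))

    def centers(self) -> np.ndarray:
        """Midpoints of the grid cells along one axis."""
        return self.lo + (np.arange(self.n_points) + 0.5) * self.spacing


@dataclass
class ConfusionResult:
    """Column-stochastic confusion matrix with its weighted accuracy."""

    matrix: np.ndarray
    accuracy: float
    method: str
    spacing: float | None = None
    n_samples: int | None = None
    extras: dict = field(default_factory=dict)

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def classification_probabilities(
    ld: GenerativeSpec, X: np.ndarray, use_priors: bool = False
) -> np.ndarray:
    """Posterior class probabilities ``q(j|x)`` for each row of ``X``.

    Computed in log space with a log-sum-exp normalization.  Points at which
    every class density is numerically zero get the uniform vector ``1/K``
    (a tie), with a warning.
    """
    logp = ld.logpdf(X)
    if use_priors:
        logp = logp + np.log(ld.w)
    dead = logp.max(axis=1) < _LOG_FLOOR
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} point(s) have zero density under every class; "
            "returning uniform probabilities there",
            RuntimeWarning,
            stacklevel=2,
        )
    q = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    q[dead] = 1.0 / ld.K
    return q


def hard_assign(q: np.ndarray) -> np.ndarray:
    """Argmax class assignment; ties go to the lowest class index."""
    q = np.asarray(q)
    if q.size == 0:
        raise ValueError("empty probability vector")
    return np.argmax(q, axis=-1)


def weighted_accuracy(matrix: np.ndarray, w: np.ndarray) -> float:
    """Prior-weighted trace ``A = sum_i w_i C_ii`` of a confusion matrix."""
    matrix = np.asarray(matrix, dtype=float)
    w = np.asarray(w, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if w.shape != (matrix.shape[0],):
        raise ValueError("prior vector length must match matrix size")
    return float(np.dot(w, np.diag(matrix)))


def confusion_matrix_grid(
    gen: GenerativeSpec,
    ld: GenerativeSpec | None = None,
    grid: GridSpec | None = None,
    use_priors: bool = False,
) -> ConfusionResult:
    """Confusion matrix of the ideal classifier by grid integration.

    Midpoint Riemann sum of the confusion densities over a regular grid
    (restricted to dimensions <= 3; use :func:`confusion_matrix_mc` above
    that).  Columns integrate each generation density and must come out as
    1 within 1e-3; probability mass escaping the grid triggers a warning.
    """
    ld = gen if ld is None else ld
    grid = grid or GridSpec()
    dim = gen.dim
    if dim > 3:
        raise ValueError(
            "grid integration is limited to dim <= 3; use confusion_matrix_mc"
        )
    axis = grid.centers()
    K = gen.K
    cell = grid.spacing**dim
    matrix = np.zeros((K, K))
    # chunk along the first axis so dim-3 grids stay in memory
    other = [axis] * (dim - 1)
    chunk = max(1, int(4e6 // max(1, len(axis) ** (dim - 1))))
    for start in range(0, len(axis), chunk):
        mesh = np.meshgrid(axis[start : start + chunk], *other, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        log_gen = gen.logpdf(pts)
        log_lea = log_gen if ld is gen else ld.logpdf(pts)
        if use_priors:
            log_lea = log_lea + np.log(ld.w)
        assign = hard_assign(log_lea)  # argmax in log space == argmax of q
        p_gen = np.exp(log_gen)
        for j in range(K):
            mask = assign == j
            if mask.any():
                matrix[j] += p_gen[mask].sum(axis=0) * cell
    col = matrix.sum(axis=0)
    if np.any(np.abs(col - 1.0) > 1e-3):
        warnings.warn(
            f"density mass outside the grid exceeds 1e-3 (column sums {col})",
            RuntimeWarning,
            stacklevel=2,
        )
    return ConfusionResult(
        matrix=matrix,
        accuracy=weighted_accuracy(matrix, gen.w),
        method="grid",
        spacing=grid.spacing,
    )


def confusion_matrix_mc(
    gen: GenerativeSpec,
    ld: GenerativeSpec | None = None,
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
    use_priors: bool = False,
) -> ConfusionResult:
    """Confusion matrix by Monte Carlo: sample each class, classify, count.

    Column ``i`` is the empirical assignment distribution of ``n_samples``
    draws from ``p_gen(.|i)``, so columns sum to exactly 1.
    """
    ld = gen if ld is None else ld
    rng = rng or np.random.default_rng()
    if n_samples < 100:
        warnings.warn(
            "n_samples < 100 gives unstable confusion estimates",
            RuntimeWarning,
            stacklevel=2,
        )
    K = gen.K
    matrix = np.zeros((K, K))
    for i in range(K):
        X = gen.sample_class(i, n_samples, rng)
        q = classification_probabilities(ld, X, use_priors=use_priors)
        assign = hard_assign(q)
        matrix[:, i] = np.bincount(assign, minlength=K) / n_samples
    return ConfusionResult(
        matrix=matrix,
        accuracy=weighted_accuracy(matrix, gen.w),
        method="monte_carlo",
        n_samples=n_samples,
    )


def bayes_limit_gaussian_1d(d: float, sigma: float = 1.0) -> float:
    """Closed-form limit for two equal-prior Gaussians separated by ``d``.

    For equal variances the ideal decision boundary is the midplane and the
    limit is ``Phi(d / (2 sigma))``; this also covers spherical classes in
    any dimension whose means differ along a single axis.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if d < 0:
        raise ValueError("d must be nonnegative")
    return float(ndtr(d / (2.0 * sigma)))
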