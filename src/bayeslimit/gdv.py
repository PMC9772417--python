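"""General Discrimination Value (GDV): a cluster-separability statistic.

Each dimension is z-scored (population standard deviation) and multiplied by
1/2, making the measure invariant under per-dimension affine rescaling and
translation.  For L labeled classes the GDV combines mean intra-class and
mean inter-class Euclidean distances,

.. math::

    \\mathrm{GDV} = \\frac{1}{\\sqrt{D}} \\Big[ \\frac{1}{L} \\sum_l
    \\bar d(C_l) - \\frac{2}{L(L-1)} \\sum_{l<m} \\bar d(C_l, C_m) \\Big],

with the :math:`1/\\sqrt{D}` prefactor making values comparable across
spaces of different dimensionality.  Unstructured (label-independent) data
give GDV near 0; two Gaussian clusters whose mean inter-cluster distance is
twice the cluster standard deviation give -1.

Zero-variance dimensions are undefined under z-scoring and are dropped; D
counts the retained dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = ["GDVResult", "gdv", "gdv_label_permutation_null"]


@dataclass
class GDVResult:
    """GDV value plus the per-class and per-pair mean distances behind it."""

    gdv: float
    mean_intra: dict
    mean_inter: dict
    dropped_dims: list[int]
    n_points: int
    classes: list = field(default_factory=list)

    def recombine(self) -> float:
        """Re-derive the GDV from the stored means (consistency check)."""
        L = len(self.mean_intra)
        intra = np.mean(list(self.mean_intra.values()))
        inter = np.mean(list(self.mean_inter.values()))
        D = self._n_dims
        return float((intra - inter) / np.sqrt(D))

    _n_dims: int = 0


def _half_zscore(points: np.ndarray) -> tuple[np.ndarray, list[int]]:
    mu = points.mean(axis=0)
    sigma = points.std(axis=0)  # population (1/N) standard deviation
    keep = sigma > 0
    dropped = list(np.flatnonzero(~keep))
    if not keep.any():
        raise ValueError("all dimensions have zero variance")
    s = 0.5 * (points[:, keep] - mu[keep]) / sigma[keep]
    return s, dropped


def gdv(
    points: np.ndarray,
    labels: np.ndarray,
    subsample: int | None = None,
    rng: np.random.Generator | None = None,
) -> GDVResult:
    """Compute the GDV of a labeled point set.

    Parameters
    ----------
    points : (N, D) array
    labels : (N,) array of class labels (any hashable values, >= 2 classes,
        >= 2 points per class).
    subsample : optional cap on N; if exceeded, a label-stratified-free
        uniform subsample of this size is drawn (the O(N^2) distance sums
        otherwise dominate at scale).
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim == 1:
        points = points[:, None]
    if points.shape[0] != labels.shape[0]:
        raise ValueError("points and labels must have equal length")
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    if subsample is not None and points.shape[0] > subsample:
        rng = rng or np.random.default_rng()
        idx = rng.choice(points.shape[0], size=subsample, replace=False)
        points, labels = points[idx], labels[idx]

    classes = [c for c in np.unique(labels)]
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    groups = {c: points[labels == c] for c in classes}
    for c, g in groups.items():
        if g.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than two points")

    s, dropped = _half_zscore(points)
    sgroups = {c: s[np.asarray(labels) == c] for c in classes}
    D = s.shape[1]

    mean_intra = {c: float(pdist(sgroups[c]).mean()) for c in classes}
    mean_inter = {}
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            ca, cb = classes[a], classes[b]
            mean_inter[(ca, cb)] = float(cdist(sgroups[ca], sgroups[cb]).mean())

    value = (
        np.mean(list(mean_intra.values())) - np.mean(list(mean_inter.values()))
    ) / np.sqrt(D)
    res = GDVResult(
        gdv=float(value),
        mean_intra=mean_intra,
        mean_inter=mean_inter,
        dropped_dims=dropped,
        n_points=points.shape[0],
        classes=classes,
    )
    res._n_dims = D
    return res


def gdv_label_permutation_null(
    points: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    subsample: int | None = None,
) -> dict:
    """Label-permutation null distribution of the GDV.

    Shuffling labels destroys any label/geometry association, so the null
    captures the GDV fluctuations expected from unstructured assignments.
    Returns the observed value, the null mean and standard deviation, and
    the empirical quantile of the observed value within the null.
    """
    rng = rng or np.random.default_rng()
    if n_perm < 20:
        warnings.warn(
            "n_perm < 20 gives a very coarse null distribution",
            RuntimeWarning,
            stacklevel=2,
        )
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if subsample is not None and points.shape[0] > subsample:
        idx = rng.choice(points.shape[0], size=subsample, replace=False)
        points, labels = points[idx], labels[idx]
    observed = gdv(points, labels).gdv
    null = np.array(
        [gdv(points, rng.permutation(labels)).gdv for _ in range(n_perm)]
    )
    quantile = float(np.mean(null <= observed))
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "quantile": quantile,
        "null": null,
    }
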