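"""Labeled feature datasets with a fixed train/test split.

The classification unit throughout the package is a flat table: an ``n x D``
feature matrix, integer class labels, and a disjoint 80/20 train/test index
partition attached at creation time.  Tables round-trip through delimited
text plus a JSON sidecar carrying the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "train_test_split_indices"]


def train_test_split_indices(
    n: int, rng: np.random.Generator, test_fraction: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint-and-exhaustive split of ``range(n)``.

    Returns ``(train_idx, test_idx)`` with a ``test_fraction`` share (rounded
    down) in the test part.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    perm = rng.permutation(n)
    n_test = int(np.floor(n * test_fraction))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


@dataclass
class LabeledDataset:
    """An ``n x D`` feature matrix with integer labels and a train/test split.

    Attributes
    ----------
    X : ndarray of shape (n, D)
    y : ndarray of shape (n,)
        Integer class labels in ``{0, ..., K-1}``.
    train_idx, test_idx : ndarray
        Disjoint, exhaustive row-index partition (default 80 % / 20 %).
    meta : dict
        Free-form provenance (generator parameters, seed, ...), serialized to
        the JSON sidecar.
    """

    X: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match number of rows of X")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite entries")
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        combined = np.sort(np.concatenate([self.train_idx, self.test_idx]))
        if not np.array_equal(combined, np.arange(self.X.shape[0])):
            raise ValueError("train/test split must be disjoint and exhaustive")

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator,
        test_fraction: float = 0.2,
        meta: dict | None = None,
    ) -> "LabeledDataset":
        train_idx, test_idx = train_test_split_indices(len(y), rng, test_fraction)
        return cls(X, y, train_idx, test_idx, meta or {})

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def train(self) -> tuple[np.ndarray, np.ndarray]:
        return self.X[self.train_idx], self.y[self.train_idx]

    def test(self) -> tuple[np.ndarray, np.ndarray]:
        return self.X[self.test_idx], self.y[self.test_idx]

    def transformed(self, func) -> "LabeledDataset":
        """Same labels and split, features mapped through ``func``."""
        return LabeledDataset(
            np.asarray(func(self.X), dtype=float),
            self.y,
            self.train_idx,
            self.test_idx,
            dict(self.meta),
        )

    # -- serialization: CSV table + JSON sidecar ---------------------------
    def save(self, stem: str | Path) -> tuple[Path, Path]:
        """Write ``<stem>.csv`` (features + final ``label`` column) and
        ``<stem>.json`` (split indices and metadata)."""
        stem = Path(stem)
        cols = [f"f{j}" for j in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.y
        csv_path = stem.with_suffix(".csv")
        json_path = stem.with_suffix(".json")
        df.to_csv(csv_path, index=False)
        sidecar = {
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "meta": _jsonable(self.meta),
        }
        json_path.write_text(json.dumps(sidecar))
        return csv_path, json_path

    @classmethod
    def load(cls, stem: str | Path) -> "LabeledDataset":
        stem = Path(stem)
        df = pd.read_csv(stem.with_suffix(".csv"))
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        y = df.pop("label").to_numpy()
        return cls(
            df.to_numpy(),
            y,
            np.asarray(sidecar["train_idx"]),
            np.asarray(sidecar["test_idx"]),
            sidecar.get("meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
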