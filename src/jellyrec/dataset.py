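"""Labelled example sets, class balancing, and the cross-validation plan.

An example is a pair (x, y) with x an 11-dimensional feature vector and
y in {1, 0} (jelly / not jelly).  Evaluation uses a stratified k-fold CV
framework in which, for each fold, 75% of the non-held-out examples are
randomly subsampled several times to form training sets, the held-out fold
serving as the (fixed) validation set — with the default 10 folds x 10
subsamples this yields 100 runs per recognition method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES

CSV_HEADER = ["image_id", "roi_id", *FEATURE_NAMES, "label"]


class DatasetError(ValueError):
    pass


@dataclass
class Dataset:
    """Feature matrix X (n x p), binary labels y, and feature names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise DatasetError("X must be 2-D with one row per label")
        if not np.isfinite(self.X).all():
            raise DatasetError("features must be finite")
        if not np.isin(self.y, (0, 1)).all():
            raise DatasetError("labels must be binary {0, 1}")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], self.feature_names)

    # -- CSV round trip (features-module table layout) -------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "image_id", [f"img{i}" for i in range(self.n)])
        df.insert(1, "roi_id", np.arange(self.n))
        df["label"] = self.y
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        df = pd.read_csv(path)
        missing = [c for c in FEATURE_NAMES if c not in df.columns]
        if missing:
            raise DatasetError(f"feature columns missing from table: {missing}")
        lab = df["label"]
        if lab.isna().any():
            raise DatasetError("table contains unlabelled rows (label = NA)")
        return cls(df[list(FEATURE_NAMES)].to_numpy(float), lab.to_numpy(int))


@dataclass
class CVPlan:
    """k stratified folds, each spawning several 75%-subsample training runs."""

    k_folds: int = 10
    subsamples_per_fold: int = 10
    subsample_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction < 1.0:
            raise DatasetError("subsample_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise DatasetError("k_folds must be >= 2")

    @property
    def n_runs(self) -> int:
        return self.k_folds * self.subsamples_per_fold


def balance(ds: Dataset, seed: int) -> Dataset:
    """Downsample the majority class to the minority-class size.

    Every minority example is kept; majority examples are drawn uniformly
    without replacement.  Deterministic given the seed.
    """
    counts = np.bincount(ds.y, minlength=2)
    if counts.min() == 0:
        raise DatasetError("balancing needs at least one example of each class")
    minority = int(np.argmin(counts))
    majority = 1 - minority
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(ds.y == majority)
    keep_maj = rng.choice(maj_idx, size=counts[minority], replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(ds.y == minority), keep_maj]))
    return ds.subset(idx)


def make_cv_runs(ds: Dataset, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """The list of (train_idx, validation_idx) pairs of the CV framework.

    Validation is a held-out stratified fold (fixed across that fold's
    runs); each run's training set is a fresh random 75% subsample of the
    remaining examples.  Reproducible given plan.seed.
    """
    counts = np.bincount(ds.y, minlength=2)
    if counts.min() < plan.k_folds:
        raise DatasetError(
            f"cannot stratify {plan.k_folds} folds with class counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=plan.k_folds, shuffle=True, random_state=plan.seed)
    rng = np.random.default_rng(plan.seed)
    runs: list[tuple[np.ndarray, np.ndarray]] = []
    for rest_idx, val_idx in skf.split(ds.X, ds.y):
        n_train = max(1, round(plan.subsample_fraction * len(rest_idx)))
        for _ in range(plan.subsamples_per_fold):
            train = np.sort(rng.choice(rest_idx, size=n_train, replace=False))
            runs.append((train, np.sort(val_idx)))
    return runs


def runs_to_json(runs: list[tuple[np.ndarray, np.ndarray]]) -> list[dict]:
    return [
        {"train": t.tolist(), "validation": v.tolist()} for t, v in runs
    ]
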