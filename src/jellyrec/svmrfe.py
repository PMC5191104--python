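"""Gaussian-kernel SVM with Recursive Feature Elimination.

A linear SVM ranks features by the magnitude of its weight-vector
components; RFE repeatedly drops the lowest-ranked feature (re-ranking on
the survivors), producing nested subsets of sizes p-1 .. 1.  Each subset
then trains a Gaussian-kernel SVM, exp(-gamma ||xi - xj||^2), whose C and
gamma come from a log-spaced grid search scored on the run's validation
set; the best-performing subset's model is recorded per CV run and feature
occurrences are tallied across the runs.  Features are standardized with
training-split statistics before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .dataset import CVPlan, Dataset, make_cv_runs


class SvmError(ValueError):
    pass


@dataclass
class SvmConfig:
    C_range: tuple[float, float] = (0.1, 100.0)
    gamma_range: tuple[float, float] = (10.0, 10000.0)
    grid_points: int = 10
    linear_C_for_ranking: float = 1.0
    seed: int = 0

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.geomspace(*self.C_range, self.grid_points),
            np.geomspace(*self.gamma_range, self.grid_points),
        )


@dataclass
class Standardizer:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        std = X.std(axis=0)
        std[std == 0] = 1.0
        return cls(X.mean(axis=0), std)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


@dataclass
class SvmModel:
    kernel: str
    C: float
    gamma: float | None
    feature_subset: np.ndarray
    clf: SVC
    scaler: Standardizer
    accuracy: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.apply(np.asarray(X, float))[:, self.feature_subset]
        return self.clf.predict(Z).astype(int)


@dataclass
class RfeTrace:
    """Nested subsets (sizes p-1 .. 1) and the |w| scores that ranked them."""

    subsets: list[np.ndarray]
    scores: list[np.ndarray]


def _linear_weights(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return np.abs(clf.coef_.ravel())


def rfe_rank(train: Dataset, cfg: SvmConfig | None = None,
             scaler: Standardizer | None = None) -> RfeTrace:
    """Recursive feature elimination with per-iteration re-ranking.

    Fits a linear SVM on the surviving features, drops the feature with
    the smallest |w|, and repeats until one feature remains.
    """
    cfg = cfg or SvmConfig()
    if np.bincount(train.y, minlength=2).min() < 2:
        raise SvmError("RFE needs at least 2 examples per class")
    scaler = scaler or Standardizer.fit(train.X)
    Z = scaler.apply(train.X)
    surviving = np.arange(train.p)
    subsets: list[np.ndarray] = []
    scores: list[np.ndarray] = []
    while len(surviving) > 1:
        w = _linear_weights(Z[:, surviving], train.y, cfg.linear_C_for_ranking)
        scores.append(w)
        drop = int(w.argmin())
        surviving = np.delete(surviving, drop)
        subsets.append(surviving.copy())
    return RfeTrace(subsets, scores)


def grid_search_gaussian(train: Dataset, validation: Dataset,
                         subset: np.ndarray, cfg: SvmConfig | None = None,
                         scaler: Standardizer | None = None
                         ) -> tuple[float, float, float, SVC]:
    """(C, gamma) grid search for the Gaussian kernel on one subset.

    Scores validation accuracy per grid point; ties go to the smallest C,
    then the smallest gamma.  Returns (C, gamma, accuracy, fitted clf).
    """
    cfg = cfg or SvmConfig()
    subset = np.asarray(subset, int)
    if len(subset) == 0:
        raise SvmError("empty feature subset")
    scaler = scaler or Standardizer.fit(train.X)
    Ztr = scaler.apply(train.X)[:, subset]
    Zva = scaler.apply(validation.X)[:, subset]
    Cs, gammas = cfg.grids()
    best = None
    for C in Cs:
        for gamma in gammas:
            clf = SVC(kernel="rbf", C=C, gamma=gamma)
            clf.fit(Ztr, train.y)
            acc = float(np.mean(clf.predict(Zva) == validation.y))
            if best is None or acc > best[2] + 1e-12:
                best = (float(C), float(gamma), acc, clf)
    return best


def best_model_for_run(tr: Dataset, va: Dataset,
                       cfg: SvmConfig | None = None) -> SvmModel:
    """RFE + per-subset grid search for one train/validation split;
    returns the best subset's model (ties to fewer features)."""
    cfg = cfg or SvmConfig()
    scaler = Standardizer.fit(tr.X)
    trace = rfe_rank(tr, cfg, scaler)
    best_model: SvmModel | None = None
    for subset in trace.subsets:
        C, gamma, acc, clf = grid_search_gaussian(tr, va, subset, cfg, scaler)
        better = best_model is None or acc > best_model.accuracy + 1e-12 or (
            abs(acc - best_model.accuracy) <= 1e-12
            and len(subset) < len(best_model.feature_subset)
        )
        if better:
            best_model = SvmModel("gaussian", C, gamma, subset, clf, scaler, acc)
    return best_model


def train_rfe_svm(ds: Dataset, plan: CVPlan, cfg: SvmConfig | None = None
                  ) -> tuple[list[SvmModel], dict[str, int], SvmModel]:
    """The full CV experiment.

    Per run: RFE on the training set, a Gaussian grid search per subset,
    and the best-performing subset's model recorded.  Returns (recorded
    models, per-feature occurrence counts, the chosen model maximizing
    accuracy with ties to the fewest features).
    """
    cfg = cfg or SvmConfig()
    runs = make_cv_runs(ds, plan)
    models = [
        best_model_for_run(ds.subset(t), ds.subset(v), cfg) for t, v in runs
    ]
    counts = {n: 0 for n in ds.feature_names}
    for m in models:
        for j in m.feature_subset:
            counts[ds.feature_names[j]] += 1
    chosen = max(
        models, key=lambda m: (m.accuracy, -len(m.feature_subset))
    )
    return models, counts, chosen
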