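"""Two-stage elastic-net (l1l2, Tikhonov-regularized) classifier.

The label relation is modelled linearly, y = beta . x with y encoded as
+1/-1, and beta minimizes

    (1/n) ||Y - X beta||_2^2  +  mu ||beta||_2^2  +  tau ||beta||_1

over zero-mean-centered features.  Stage I is a LASSO pass (mu tiny) that
sweeps the sparsity parameter tau over a geometric grid inside
[tau_max 10^-t, tau_max 10^-(t-1)] and picks tau_opt by internal
cross-validated misclassification error, defining the selected feature
support.  Stage II refits on that support with increasing mu and keeps the
largest mu within one standard error of the minimum internal-CV error —
the least sparse but most regularized solution.  The minimizer is found by
iterative soft-thresholding (ISTA), which decreases the objective
monotonically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .dataset import CVPlan, Dataset, make_cv_runs


class ElasticNetError(ValueError):
    pass


def _default_mu_grid() -> np.ndarray:
    # geometric progression 1e-10 .. 10, ratio 10
    return 10.0 ** np.arange(-10, 2)


@dataclass
class ElasticNetConfig:
    mu_stage1: float = 1e-10
    mu_grid: np.ndarray = field(default_factory=_default_mu_grid)
    t: int = 6
    tau_points: int = 20  # grid points inside the decade interval
    internal_splits: int | None = None  # None -> by training-set size
    tol: float = 1e-6
    max_iter: int = 100_000
    seed: int = 0

    def splits_for(self, n: int) -> int:
        if self.internal_splits is not None:
            return self.internal_splits
        return 5 if n <= 1000 else 10


@dataclass
class ElasticNetModel:
    beta: np.ndarray  # full p-vector (zeros off the support)
    selected: np.ndarray  # indices of nonzero beta
    tau_opt: float
    mu_opt: float
    centering: np.ndarray  # per-feature training means

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 iff (x - centering) . beta > 0, else 0."""
        score = (np.asarray(X, float) - self.centering) @ self.beta
        return (score > 0).astype(int)


def tau_max(X: np.ndarray, Y: np.ndarray) -> float:
    """Smallest tau with an all-zero minimizer: (2/n) max_j |X_j . Y|.

    At beta = 0 the subgradient optimality condition of the objective is
    |(2/n) X^T Y|_inf <= tau, independent of mu.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = len(Y)
    if n == 0:
        raise ElasticNetError("empty design")
    val = 2.0 / n * np.abs(X.T @ Y).max() if X.size else 0.0
    if val == 0.0:
        warnings.warn("tau_max is 0: labels orthogonal to every feature")
    return float(val)


def objective(X: np.ndarray, Y: np.ndarray, beta: np.ndarray,
              tau: float, mu: float) -> float:
    n = len(Y)
    r = Y - X @ beta
    return float(r @ r / n + mu * beta @ beta + tau * np.abs(beta).sum())


def fit_l1l2(X: np.ndarray, Y: np.ndarray, tau: float, mu: float,
             tol: float = 1e-8, max_iter: int = 100_000,
             beta0: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """ISTA minimization of the l1l2 objective.

    Iterates beta <- soft_threshold(beta - grad/L, tau/L) with L the
    Lipschitz constant of the smooth part; stops when successive iterates
    differ by less than `tol` in max-norm.  Returns (beta, info) where
    info carries the iteration count and a convergence flag.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, p = X.shape
    if tau < 0 or mu < 0:
        raise ElasticNetError("tau and mu must be non-negative")
    # L = 2 sigma_max(X^T X)/n + 2 mu
    s = np.linalg.norm(X, 2) if X.size else 0.0
    L = 2.0 * s * s / n + 2.0 * mu
    if L == 0.0:
        return np.zeros(p), {"n_iter": 0, "converged": True}
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    XtY = X.T @ Y
    XtX = X.T @ X  # p x p: cheap for p = 11
    thr = tau / L
    for it in range(1, max_iter + 1):
        grad = 2.0 / n * (XtX @ beta - XtY) + 2.0 * mu * beta
        z = beta - grad / L
        new = np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
        if np.abs(new - beta).max() < tol:
            return new, {"n_iter": it, "converged": True}
        beta = new
    warnings.warn(f"fit_l1l2 did not converge in {max_iter} iterations")
    return beta, {"n_iter": max_iter, "converged": False}


def _encode(y: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(y) == 1, 1.0, -1.0)


def tau_grid(X: np.ndarray, Y: np.ndarray, cfg: ElasticNetConfig) -> np.ndarray:
    """Geometric grid of cfg.tau_points values in
    [tau_max 10^-t, tau_max 10^-(t-1)]."""
    tmax = tau_max(X, Y)
    if tmax == 0.0:
        raise ElasticNetError("void design: tau_max is 0")
    lo, hi = tmax * 10.0 ** (-cfg.t), tmax * 10.0 ** (-cfg.t + 1)
    return np.geomspace(lo, hi, cfg.tau_points)


def _cv_errors_stage1(Xc, Ypm, y01, taus, cfg: ElasticNetConfig,
                      s: int) -> np.ndarray:
    """Mean internal-CV misclassification per tau (LASSO pass)."""
    kf = KFold(n_splits=s, shuffle=True, random_state=cfg.seed)
    errs = np.zeros((s, len(taus)))
    for f, (tr, va) in enumerate(kf.split(Xc)):
        mean = Xc[tr].mean(axis=0)
        Xtr, Xva = Xc[tr] - mean, Xc[va] - mean
        beta = None
        # sweep from the sparsest (largest tau) down, warm-starting
        for k in range(len(taus) - 1, -1, -1):
            beta, _ = fit_l1l2(Xtr, Ypm[tr], taus[k], cfg.mu_stage1,
                               tol=cfg.tol, max_iter=cfg.max_iter, beta0=beta)
            pred = (Xva @ beta > 0).astype(int)
            errs[f, k] = np.mean(pred != y01[va])
    return errs.mean(axis=0)


def stage1_select_tau(train: Dataset, cfg: ElasticNetConfig
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """LASSO stage: pick tau_opt by internal CV, return its support.

    Returns (tau_opt, selected feature indices, per-tau mean CV error).
    Tie on the error curve goes to the smaller tau (the less sparse,
    better-conditioned side of the interval).
    """
    Xc = train.X - train.X.mean(axis=0)
    Ypm = _encode(train.y)
    taus = tau_grid(Xc, Ypm, cfg)
    s = cfg.splits_for(train.n)
    errors = _cv_errors_stage1(Xc, Ypm, train.y, taus, cfg, s)
    tau_opt = float(taus[int(errors.argmin())])
    beta, _ = fit_l1l2(Xc, Ypm, tau_opt, cfg.mu_stage1,
                       tol=cfg.tol, max_iter=cfg.max_iter)
    selected = np.flatnonzero(np.abs(beta) > 1e-10)
    if len(selected) == 0:
        raise ElasticNetError("stage 1 selected a void model at every tau")
    return tau_opt, selected, errors


def stage2_regularize(train: Dataset, tau_opt: float, selected: np.ndarray,
                      cfg: ElasticNetConfig) -> ElasticNetModel:
    """Refit on the selected support for increasing mu.

    mu_opt is the largest mu whose internal-CV error is within one
    standard error of the minimum (the most regularized solution of
    equivalent prediction power).
    """
    centering = train.X.mean(axis=0)
    Xc = (train.X - centering)[:, selected]
    Ypm = _encode(train.y)
    s = cfg.splits_for(train.n)
    kf = KFold(n_splits=s, shuffle=True, random_state=cfg.seed)
    mus = np.asarray(cfg.mu_grid, float)
    errs = np.zeros((s, len(mus)))
    for f, (tr, va) in enumerate(kf.split(Xc)):
        for k, mu in enumerate(mus):
            beta, _ = fit_l1l2(Xc[tr], Ypm[tr], tau_opt, mu,
                               tol=cfg.tol, max_iter=cfg.max_iter)
            pred = (Xc[va] @ beta > 0).astype(int)
            errs[f, k] = np.mean(pred != train.y[va])
    mean_err = errs.mean(axis=0)
    se = errs.std(axis=0, ddof=1) / np.sqrt(s)
    k_min = int(mean_err.argmin())
    ok = np.flatnonzero(mean_err <= mean_err[k_min] + se[k_min])
    mu_opt = float(mus[ok.max()])
    beta_s, _ = fit_l1l2(Xc, Ypm, tau_opt, mu_opt,
                         tol=cfg.tol, max_iter=cfg.max_iter)
    beta = np.zeros(train.p)
    beta[selected] = beta_s
    return ElasticNetModel(beta=beta, selected=selected, tau_opt=tau_opt,
                           mu_opt=mu_opt, centering=centering)


def train_en(train: Dataset, cfg: ElasticNetConfig | None = None) -> ElasticNetModel:
    """The full two-stage procedure on one training set."""
    cfg = cfg or ElasticNetConfig()
    tau_opt, selected, _ = stage1_select_tau(train, cfg)
    return stage2_regularize(train, tau_opt, selected, cfg)


def predict_en(model: ElasticNetModel, x: np.ndarray) -> int:
    """Decision rule for a single feature vector."""
    return int(model.predict(np.atleast_2d(x))[0])


def sweep_t(ds: Dataset, plan: CVPlan, cfg: ElasticNetConfig | None = None,
            t_values=range(1, 11)) -> dict[int, dict]:
    """Per-t CV performance and feature selection-frequency report.

    For each t the full two-stage method runs on every CV run; the report
    gives mean/std of ACC, TPR, FPR, FNR, per-feature selection
    frequencies, and the 'stable' features selected in > 85% of runs.
    """
    from .evaluation import confusion

    cfg = cfg or ElasticNetConfig()
    runs = make_cv_runs(ds, plan)
    report: dict[int, dict] = {}
    for t in t_values:
        tcfg = ElasticNetConfig(
            mu_stage1=cfg.mu_stage1, mu_grid=cfg.mu_grid, t=t,
            tau_points=cfg.tau_points, internal_splits=cfg.internal_splits,
            tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed,
        )
        accs, tprs, fprs, fnrs = [], [], [], []
        sel_counts = np.zeros(ds.p)
        for train_idx, val_idx in runs:
            model = train_en(ds.subset(train_idx), tcfg)
            m = confusion(model.predict(ds.X[val_idx]), ds.y[val_idx])
            accs.append(m.ACC)
            tprs.append(m.TPR if m.TPR is not None else np.nan)
            fprs.append(m.FPR if m.FPR is not None else np.nan)
            fnrs.append(m.FNR if m.FNR is not None else np.nan)
            sel_counts[model.selected] += 1
        freq = sel_counts / len(runs)
        report[t] = {
            "n_runs": len(runs),
            "ACC": (float(np.mean(accs)), float(np.std(accs))),
            "TPR": (float(np.nanmean(tprs)), float(np.nanstd(tprs))),
            "FPR": (float(np.nanmean(fprs)), float(np.nanstd(fprs))),
            "FNR": (float(np.nanmean(fnrs)), float(np.nanstd(fnrs))),
            "selection_frequency": dict(zip(ds.feature_names, freq.tolist())),
            "stable_features": [
                n for n, f in zip(ds.feature_names, freq) if f > 0.85
            ],
        }
    return report
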