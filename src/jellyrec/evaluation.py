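"""Confusion metrics and the three-method comparison report.

ACC = (TP+TN)/(TP+FP+FN+TN), TPR = TP/(TP+FN), FPR = FP/(FP+TN),
FNR = FN/(FN+TP); rates with a zero denominator are reported as absent
(None) rather than 0.  The comparison runs the elastic-net, SVM-RFE and GP
recognizers on identical CV splits, aggregates mean/std of the rates over
runs, and flags the most feature-frugal method among those whose mean
accuracy sits within one pooled standard deviation of the best — the
criterion by which the lightest classifier is picked for onboard use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import CVPlan, Dataset, make_cv_runs
from . import elasticnet as en
from . import gp as gp_mod
from . import svmrfe as svm_mod


class EvaluationError(ValueError):
    pass


@dataclass
class Metrics:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def ACC(self) -> float:
        return (self.TP + self.TN) / self.n

    @property
    def TPR(self) -> float | None:
        d = self.TP + self.FN
        return self.TP / d if d else None

    @property
    def FPR(self) -> float | None:
        d = self.FP + self.TN
        return self.FP / d if d else None

    @property
    def FNR(self) -> float | None:
        d = self.FN + self.TP
        return self.FN / d if d else None


def confusion(predictions, truth) -> Metrics:
    pred = np.asarray(predictions, int)
    y = np.asarray(truth, int)
    if pred.shape != y.shape:
        raise EvaluationError("predictions and truth differ in length")
    if len(y) == 0:
        raise EvaluationError("empty label lists")
    return Metrics(
        TP=int(((pred == 1) & (y == 1)).sum()),
        FP=int(((pred == 1) & (y == 0)).sum()),
        TN=int(((pred == 0) & (y == 0)).sum()),
        FN=int(((pred == 0) & (y == 1)).sum()),
    )


@dataclass
class MethodSummary:
    name: str
    metrics: list[Metrics]
    selected_per_run: list[frozenset[str]]
    chosen_feature_count: int
    chosen_features: frozenset[str]

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = [getattr(m, attr) for m in self.metrics]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)), float(np.std(vals))  # population std

    @property
    def mean_std(self) -> dict[str, tuple[float, float]]:
        return {k: self._agg(k) for k in ("ACC", "TPR", "FPR", "FNR")}

    def selection_percentage(self, feature_names) -> dict[str, float]:
        n = len(self.selected_per_run)
        return {
            f: 100.0 * sum(f in s for s in self.selected_per_run) / n
            for f in feature_names
        }


@dataclass
class ComparisonReport:
    methods: dict[str, MethodSummary]
    feature_names: tuple[str, ...]
    chosen_method: str
    gp_pool: "gp_mod.PopulationPool | None" = None
    gp_relevance: "gp_mod.RelevanceResult | None" = None

    def to_dict(self) -> dict:
        return {
            "chosen_method": self.chosen_method,
            "methods": {
                name: {
                    "metrics": {
                        k: {"mean": m, "std": s}
                        for k, (m, s) in summ.mean_std.items()
                    },
                    "selection_percentage": summ.selection_percentage(
                        self.feature_names
                    ),
                    "chosen_feature_count": summ.chosen_feature_count,
                    "chosen_features": sorted(summ.chosen_features),
                }
                for name, summ in self.methods.items()
            },
        }

    def to_markdown(self) -> str:
        lines = ["| Method | ACC | TPR | FPR | FNR | #features |",
                 "|---|---|---|---|---|---|"]
        for name, summ in self.methods.items():
            ms = summ.mean_std
            cells = " | ".join(
                f"{ms[k][0]:.3f} ({ms[k][1]:.3f})" for k in ("ACC", "TPR", "FPR", "FNR")
            )
            lines.append(f"| {name} | {cells} | {summ.chosen_feature_count} |")
        lines.append("")
        lines.append("| Feature | " + " | ".join(self.methods) + " |")
        lines.append("|---" * (len(self.methods) + 1) + "|")
        pct = {n: s.selection_percentage(self.feature_names)
               for n, s in self.methods.items()}
        for f in self.feature_names:
            row = " | ".join(f"{pct[n][f]:.0f}" for n in self.methods)
            lines.append(f"| {f} | {row} |")
        lines.append("")
        lines.append(f"Chosen onboard method: **{self.chosen_method}**")
        return "\n".join(lines)


def compare_methods(ds: Dataset, plan: CVPlan,
                    en_cfg: "en.ElasticNetConfig | None" = None,
                    svm_cfg: "svm_mod.SvmConfig | None" = None,
                    gp_params: "gp_mod.GPParams | None" = None,
                    p_value: float = 0.001) -> ComparisonReport:
    """Run all three recognizers on identical CV splits and compare them."""
    en_cfg = en_cfg or en.ElasticNetConfig()
    svm_cfg = svm_cfg or svm_mod.SvmConfig()
    gp_params = gp_params or gp_mod.GPParams()
    runs = make_cv_runs(ds, plan)
    names = ds.feature_names

    res: dict[str, dict] = {
        m: {"metrics": [], "selected": [], "best": None}
        for m in ("en", "svm", "gp")
    }
    gp_individuals: list[gp_mod.Individual] = []
    for r, (train_idx, val_idx) in enumerate(runs):
        tr, va = ds.subset(train_idx), ds.subset(val_idx)

        model = en.train_en(tr, en_cfg)
        m = confusion(model.predict(va.X), va.y)
        sel = frozenset(names[j] for j in model.selected)
        res["en"]["metrics"].append(m)
        res["en"]["selected"].append(sel)
        if res["en"]["best"] is None or m.ACC > res["en"]["best"][0]:
            res["en"]["best"] = (m.ACC, sel)

        smodel = svm_mod.best_model_for_run(tr, va, svm_cfg)
        m = confusion(smodel.predict(va.X), va.y)
        sel = frozenset(names[j] for j in smodel.feature_subset)
        res["svm"]["metrics"].append(m)
        res["svm"]["selected"].append(sel)
        if res["svm"]["best"] is None or m.ACC > res["svm"]["best"][0] or (
            m.ACC == res["svm"]["best"][0] and len(sel) < len(res["svm"]["best"][1])
        ):
            res["svm"]["best"] = (m.ACC, sel)

        rng = np.random.default_rng((gp_params.seed, r))
        pset = gp_mod.PrimitiveSet.create(rng, names)
        ind = gp_mod.evolve(tr, gp_params, pset, rng)
        gp_individuals.append(ind)
        m = confusion(gp_mod.classify_batch(ind.tree, va.X, names), va.y)
        res["gp"]["metrics"].append(m)
        res["gp"]["selected"].append(ind.variables_used)

    pool = gp_mod.PopulationPool(gp_individuals, names)
    rel = gp_mod.relevance_test(pool, p_value)
    try:
        ensemble = gp_mod.build_ensemble(pool, rel)
        gp_features = frozenset().union(*[m.variables_used for m in ensemble.members])
    except gp_mod.GPError:
        # no pool member restricted to relevant features: fall back to the
        # most frugal individual
        frugal = min(pool.individuals,
                     key=lambda i: len(i.variables_used) or len(names))
        gp_features = frugal.variables_used
    res["gp"]["best"] = (None, gp_features)

    summaries = {
        name: MethodSummary(
            name=name,
            metrics=r["metrics"],
            selected_per_run=r["selected"],
            chosen_feature_count=len(r["best"][1]),
            chosen_features=r["best"][1],
        )
        for name, r in res.items()
    }

    mean_accs = {n: s.mean_std["ACC"][0] for n, s in summaries.items()}
    pooled_std = float(np.sqrt(np.mean(
        [s.mean_std["ACC"][1] ** 2 for s in summaries.values()]
    )))
    best_acc = max(mean_accs.values())
    contenders = [n for n, a in mean_accs.items() if a >= best_acc - pooled_std]
    chosen = min(contenders, key=lambda n: summaries[n].chosen_feature_count)

    return ComparisonReport(
        methods=summaries,
        feature_names=names,
        chosen_method=chosen,
        gp_pool=pool,
        gp_relevance=rel,
    )
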