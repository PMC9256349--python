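"""End-to-end staged feature-selection protocol and ensemble registry.

The protocol mirrors the comparative study it implements:

1. **Baselines (NFS)** — cross-validate the classifier roster on each
   entire feature set with no feature selection.
2. **Stage 1, importance sweeps** — rank each large ("All"-type) feature
   set with the configured filter/embedded methods and evaluate the top
   10%..80% cuts (step 10); when a set's coarse optimum sits at the 10%
   boundary the fine 1%..9% grid is swept as well.
3. **Regularizer supports** — Lasso / LassoLars / ElasticNet nonzero
   supports, each cross-validated.
4. **Stage 2, RFE-CV** — for each large set, the best stage-1 subset of
   each of the LR and LinSVM rankings is refined by recursive feature
   elimination with cross-validation.
5. **Registry / ensemble** — one trained model per configured selection;
   the registry in the full configuration has, per large set, NFS + three
   regularizers + two stage-1 subsets + their two RFE refinements (8),
   plus one NFS model per Avg-only set: 4 x 8 + 2 = 34 members, which are
   soft-voted with accuracy-proportional weights.

All stages are deterministic given the config seed, and every report
carries that seed in its header.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from .ensemble import EnsemblePredictor, MemberModel
from .errors import ConfigError
from .evaluation import CVReport, MetricSet, cross_validate, fit_and_test, fit_model
from .features import FeatureTable
from .selection import (
    METHOD_LABELS,
    RANKING_METHODS,
    SelectionResult,
    rfe_cv,
    score_chi2,
    score_embedded,
    score_mic,
    score_variance,
    select_by_regularizer,
    select_top_percent,
)

logger = logging.getLogger(__name__)

COARSE_PERCENTS = (10, 20, 30, 40, 50, 60, 70, 80)
FINE_PERCENTS = (1, 2, 3, 4, 5, 6, 7, 8, 9)

#: Sparse-model penalties used by the protocol.  For 0/1 labels regressed
#: on MinMax features the implementation-default penalty (alpha = 1) zeroes
#: every coefficient, so a moderate penalty is pinned instead — small
#: enough that mutually correlated informative features are all retained
#: rather than pruned as redundant, large enough to keep supports sparse.
DEFAULT_REGULARIZER_PARAMS: dict[str, dict] = {
    "lasso": {"alpha": 0.002, "max_iter": 50000},
    "lassolars": {"alpha": 0.002},
    "elasticnet": {"alpha": 0.002, "l1_ratio": 0.5, "max_iter": 50000},
}


@dataclass(frozen=True)
class ProtocolConfig:
    """What to run: feature sets, grids, methods, classifier, seeds."""

    full_sets: tuple[str, ...]
    avg_sets: tuple[str, ...] = ()
    baseline_classifiers: tuple[str, ...] = ("svm-rbf",)
    eval_classifier: str = "svm-rbf"
    ranking_methods: tuple[str, ...] = RANKING_METHODS
    coarse_percents: tuple[float, ...] = COARSE_PERCENTS
    fine_percents: tuple[float, ...] = FINE_PERCENTS
    regularizers: tuple[str, ...] = ("lasso", "lassolars", "elasticnet")
    regularizer_params: Mapping[str, dict] = field(
        default_factory=lambda: dict(DEFAULT_REGULARIZER_PARAMS))
    rfe_rankers: tuple[str, ...] = ("lr", "linsvm")
    rfe_step: int = 1
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.full_sets and not self.avg_sets:
            raise ConfigError("no feature sets configured")
        if not self.coarse_percents:
            raise ConfigError("empty percent grid")
        if self.eval_classifier not in self.baseline_classifiers:
            object.__setattr__(
                self, "baseline_classifiers",
                tuple(self.baseline_classifiers) + (self.eval_classifier,))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for key in ("full_sets", "avg_sets", "baseline_classifiers",
                    "ranking_methods", "coarse_percents", "fine_percents",
                    "regularizers", "rfe_rankers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


_SCORERS = {
    "variance": lambda table, seed: score_variance(table),
    "chi2": lambda table, seed: score_chi2(table),
    "mic": lambda table, seed: score_mic(table),
    "lr": lambda table, seed: score_embedded(table, "lr", seed),
    "linsvm": lambda table, seed: score_embedded(table, "linsvm", seed),
    "rf": lambda table, seed: score_embedded(table, "rf", seed),
}


@dataclass
class ProtocolResult:
    """Reports, selections and CV accuracies from one protocol run."""

    config: ProtocolConfig
    nfs_report: pd.DataFrame
    sweep_report: pd.DataFrame
    regularizer_report: pd.DataFrame
    rfe_report: pd.DataFrame
    test_report: pd.DataFrame
    selections: dict[tuple[str, str], SelectionResult]
    cv_accs: dict[tuple[str, str], float]

    def write(self, outdir: str | Path) -> Path:
        """Flush all reports as TSV (+ a JSON selections index)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# seed={self.config.seed}\tfolds={self.config.folds}\n"
        for name, frame in (
            ("nfs", self.nfs_report), ("sweep", self.sweep_report),
            ("regularizers", self.regularizer_report),
            ("rfe", self.rfe_report), ("test", self.test_report),
        ):
            path = outdir / f"report_{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t", index=False)
        index = {
            f"{s}/{o}": {"origin": sel.origin,
                         "n_features": len(sel.selected_names),
                         "cv_acc": self.cv_accs.get((s, o)),
                         "selected_names": sel.selected_names}
            for (s, o), sel in self.selections.items()
        }
        (outdir / "selections.json").write_text(json.dumps(index, indent=2))
        return outdir


def _metric_row(metrics: MetricSet) -> dict[str, float]:
    return metrics.as_dict(percent=True)


def run_protocol(
    config: ProtocolConfig,
    tables: Mapping[str, FeatureTable],
    test_tables: Mapping[str, FeatureTable] | None = None,
) -> ProtocolResult:
    """Execute the staged protocol on pre-extracted feature tables.

    ``tables`` maps feature-set names (config's ``full_sets`` and
    ``avg_sets``) to labelled training tables; ``test_tables`` optionally
    supplies independent test tables with matching names, scored by models
    fit on the entire training tables.
    """
    missing = [s for s in (*config.full_sets, *config.avg_sets)
               if s not in tables]
    if missing:
        raise ConfigError(f"feature tables missing for sets: {missing}")
    bad = set(config.ranking_methods) - set(_SCORERS)
    if bad:
        raise ConfigError(f"unknown ranking methods: {sorted(bad)}")

    seed = config.seed
    selections: dict[tuple[str, str], SelectionResult] = {}
    cv_accs: dict[tuple[str, str], float] = {}
    nfs_rows, sweep_rows, reg_rows, rfe_rows, test_rows = [], [], [], [], []

    def evaluate(set_name: str, origin: str,
                 sel: SelectionResult) -> CVReport:
        sub = tables[set_name].subset(sel.selected_names)
        report = cross_validate(sub, config.eval_classifier,
                                folds=config.folds, seed=seed)
        selections[(set_name, origin)] = sel
        cv_accs[(set_name, origin)] = report.pooled.ACC
        return report

    for set_name in (*config.avg_sets, *config.full_sets):
        table = tables[set_name]
        t0 = time.perf_counter()
        nfs_sel = SelectionResult(origin="NFS",
                                  selected_names=list(table.names),
                                  provenance={"count": table.n_features})
        for clf in config.baseline_classifiers:
            report = cross_validate(table, clf, folds=config.folds, seed=seed)
            nfs_rows.append({"set": set_name, "classifier": clf,
                             "n_features": table.n_features,
                             **_metric_row(report.pooled)})
            if clf == config.eval_classifier:
                selections[(set_name, "NFS")] = nfs_sel
                cv_accs[(set_name, "NFS")] = report.pooled.ACC
        logger.info("NFS baselines for %s (%d features): %.1fs", set_name,
                    table.n_features, time.perf_counter() - t0)

    from .evaluation import minmax_normalize

    for set_name in config.full_sets:
        table = tables[set_name]
        norm = minmax_normalize(table)
        t0 = time.perf_counter()
        rankings = {m: _SCORERS[m](norm, seed)
                    for m in config.ranking_methods}
        logger.info("rankings for %s: %.1fs", set_name,
                    time.perf_counter() - t0)

        def sweep(percents) -> None:
            for method, ranking in rankings.items():
                for p in percents:
                    sel = select_top_percent(ranking, p)
                    report = evaluate(set_name, sel.origin, sel)
                    sweep_rows.append({
                        "set": set_name, "method": method, "percent": p,
                        "origin": sel.origin,
                        "n_features": len(sel.selected_names),
                        **_metric_row(report.pooled)})

        sweep(config.coarse_percents)
        coarse = [r for r in sweep_rows if r["set"] == set_name]
        best_coarse = max(coarse, key=lambda r: r["ACC"])
        if best_coarse["percent"] == min(config.coarse_percents) \
                and config.fine_percents:
            logger.info("coarse optimum of %s at the grid boundary; "
                        "running the fine percent sweep", set_name)
            sweep(config.fine_percents)

        for method in config.regularizers:
            params = config.regularizer_params.get(method)
            sel = select_by_regularizer(norm, method, params=params,
                                        seed=seed)
            if not sel.selected_names:
                raise ConfigError(
                    f"{set_name}: {sel.origin} selected no features; "
                    f"lower the penalty in regularizer_params")
            report = evaluate(set_name, sel.origin, sel)
            reg_rows.append({"set": set_name, "origin": sel.origin,
                             "n_features": len(sel.selected_names),
                             **_metric_row(report.pooled)})

        for ranker in config.rfe_rankers:
            candidates = [r for r in sweep_rows
                          if r["set"] == set_name and r["method"] == ranker]
            if not candidates:
                raise ConfigError(
                    f"rfe ranker {ranker!r} not among ranking_methods")
            best = max(candidates,
                       key=lambda r: (r["ACC"], -r["n_features"]))
            start = selections[(set_name, best["origin"])]
            t0 = time.perf_counter()
            refined = rfe_cv(table, start, ranker, folds=config.folds,
                             step=config.rfe_step, seed=seed,
                             classifier=config.eval_classifier)
            report = evaluate(set_name, refined.origin, refined)
            rfe_rows.append({"set": set_name, "origin": refined.origin,
                             "start": start.origin,
                             "start_n": len(start.selected_names),
                             "n_features": len(refined.selected_names),
                             **_metric_row(report.pooled)})
            logger.info("RFE %s/%s: %d -> %d features, %.1fs", set_name,
                        refined.origin, len(start.selected_names),
                        len(refined.selected_names), time.perf_counter() - t0)

    if test_tables:
        for (set_name, origin), sel in selections.items():
            if set_name not in test_tables:
                continue
            train_sub = tables[set_name].subset(sel.selected_names)
            test_sub = test_tables[set_name].subset(sel.selected_names)
            _, metrics = fit_and_test(train_sub, test_sub,
                                      config.eval_classifier, seed=seed)
            test_rows.append({"set": set_name, "origin": origin,
                              "n_features": len(sel.selected_names),
                              **_metric_row(metrics)})

    return ProtocolResult(
        config=config,
        nfs_report=pd.DataFrame(nfs_rows),
        sweep_report=pd.DataFrame(sweep_rows),
        regularizer_report=pd.DataFrame(reg_rows),
        rfe_report=pd.DataFrame(rfe_rows),
        test_report=pd.DataFrame(test_rows),
        selections=selections,
        cv_accs=cv_accs,
    )


def registry_origins(config: ProtocolConfig,
                     result: ProtocolResult) -> list[tuple[str, str]]:
    """The (set, origin) pairs the member registry is built from.

    Per large set: NFS, each regularizer support, the best stage-1 subset
    of each RFE ranker, and its RFE refinement; per Avg-only set: NFS.
    """
    pairs: list[tuple[str, str]] = []
    for set_name in config.avg_sets:
        pairs.append((set_name, "NFS"))
    reg_labels = {"lasso": "Lasso", "lassolars": "LassoLars",
                  "elasticnet": "ElasticNet"}
    for set_name in config.full_sets:
        pairs.append((set_name, "NFS"))
        for method in config.regularizers:
            pairs.append((set_name, reg_labels[method]))
        for ranker in config.rfe_rankers:
            matches = [
                r for r in result.rfe_report.to_dict("records")
                if r["set"] == set_name
                and _ranker_of_origin(r["start"]) == ranker
            ]
            if not matches:
                raise ConfigError(
                    f"no RFE result for ranker {ranker!r} on {set_name}")
            entry = matches[0]
            pairs.append((set_name, entry["start"]))
            pairs.append((set_name, entry["origin"]))
    return pairs


def _ranker_of_origin(origin: str) -> str:
    for method, label in METHOD_LABELS.items():
        if origin.startswith(label) and origin[len(label):].replace(
                ".", "").isdigit():
            return method
    return ""


def build_member_registry(
    config: ProtocolConfig,
    result: ProtocolResult,
    tables: Mapping[str, FeatureTable],
) -> list[MemberModel]:
    """Train one member per configured selection, carrying its CV ACC."""
    members: list[MemberModel] = []
    seen: set[str] = set()
    for set_name, origin in registry_origins(config, result):
        key = (set_name, origin)
        if key not in result.selections:
            raise ConfigError(f"missing trained selection for {key}")
        full_origin = f"{set_name}/{origin}"
        if full_origin in seen:
            raise ConfigError(f"duplicate member origin {full_origin!r}")
        seen.add(full_origin)
        sel = result.selections[key]
        sub = tables[set_name].subset(sel.selected_names)
        fitted = fit_model(sub, config.eval_classifier, seed=config.seed)
        members.append(MemberModel(origin=full_origin, model=fitted,
                                   cv_acc=result.cv_accs[key],
                                   feature_set=set_name))
    return members


def build_ensemble(
    config: ProtocolConfig,
    result: ProtocolResult,
    tables: Mapping[str, FeatureTable],
) -> EnsemblePredictor:
    """Soft-voting ensemble over the full member registry."""
    return EnsemblePredictor(members=build_member_registry(
        config, result, tables))
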