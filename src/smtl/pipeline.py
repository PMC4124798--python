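"""End-to-end experiment orchestration and reporting.

One experiment runs the full protocol on a feature table: stratified outer
10-fold CV; per outer fold, nested inner-CV hyperparameter selection for
each requested method (single-task l1 baseline and/or subclass-based
multi-task selection, with a single- or multi-kernel SVM); per-fold metrics;
and a paired t-test comparing fold-wise accuracies of the two selection
methods.  Outer folds are shared across methods within a run, so the
comparison is genuinely paired.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .classification import grid_search_modality_weights, linear_kernel, \
    mk_decision_scores, modality_kernels, train_mk_svm
from .evaluation import MetricSet, PairedTTest, confusion_metrics, \
    nested_model_selection, paired_ttest, stratified_folds
from .io_config import ExperimentConfig, FeatureTable, component_seed, zscore_apply

logger = logging.getLogger("smtl")


@dataclass
class CVResult:
    """Outer-CV summary for one method."""

    method: str
    kernel: str                       # "SK" or "MK"
    fold_metrics: list[MetricSet]
    fold_params: list[dict]
    fold_selected: list[np.ndarray]

    @property
    def fold_acc(self) -> np.ndarray:
        return np.asarray([m.ACC for m in self.fold_metrics])

    @property
    def mean_acc(self) -> float:
        return float(self.fold_acc.mean())

    @property
    def sd_acc(self) -> float:
        return float(self.fold_acc.std(ddof=1))

    def mean_metrics(self) -> dict[str, float]:
        out = {}
        for name in ("ACC", "SEN", "SPEC", "BAC", "AUC"):
            vals = np.asarray([getattr(m, name) for m in self.fold_metrics])
            out[name] = float(np.nanmean(vals))
        return out


@dataclass
class RunManifest:
    config: dict
    seed: int
    methods: list[str]
    n_samples: int
    n_features: int
    version: str = __version__
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, default=str)


@dataclass
class ExperimentReport:
    results: dict[str, CVResult]
    comparison: PairedTTest | None
    outer_folds: np.ndarray
    manifest: RunManifest

    def summary_table(self) -> str:
        """Rows = method, columns = ACC(+/-SD)/SEN/SPEC/BAC/AUC, in percent."""
        lines = [f"{'method':<10} {'ACC (%)':>14} {'SEN':>7} {'SPEC':>7} "
                 f"{'BAC':>7} {'AUC':>7}"]
        for name, res in self.results.items():
            m = res.mean_metrics()
            lines.append(
                f"{name:<10} {100 * res.mean_acc:6.2f} ± {100 * res.sd_acc:5.2f} "
                f"{100 * m['SEN']:7.2f} {100 * m['SPEC']:7.2f} "
                f"{100 * m['BAC']:7.2f} {100 * m['AUC']:7.2f}"
            )
        if self.comparison is not None:
            lines.append(
                f"paired t (SMTL vs STL fold ACCs): t = {self.comparison.t:.3f}, "
                f"p = {self.comparison.p:.4g}"
            )
        return "\n".join(lines)


def _parse_method(spec: str) -> tuple[str, str]:
    parts = spec.upper().split("-")
    method = parts[0]
    kernel = parts[1] if len(parts) > 1 else "SK"
    if method not in {"STL", "SMTL"} or kernel not in {"SK", "MK"}:
        raise ValueError(f"unknown method spec {spec!r}")
    return method, kernel


def _evaluate_fold_mk(fitted, train_table, test_table, config, seed):
    """Replace the single-kernel SVM by a modality-weighted multi-kernel one."""
    Xtr = train_table.X
    Xte = test_table.X
    if fitted.standardizer is not None:
        Xtr = zscore_apply(fitted.standardizer, Xtr)
        Xte = zscore_apply(fitted.standardizer, Xte)
    kernels = modality_kernels(train_table, fitted.selection, X=Xtr)
    beta, C, _ = grid_search_modality_weights(
        kernels, train_table.labels, config.C_grid,
        step=config.modality_weight_step, inner_folds=config.n_inner_folds,
        seed=seed,
    )
    clf = train_mk_svm(kernels, train_table.labels, beta, C)
    sel = set(fitted.selection.selected.tolist())
    cross = {}
    for modality, idx in train_table.modality_indices().items():
        keep = np.asarray([j for j in idx if j in sel], dtype=int)
        cross[modality] = (
            linear_kernel(Xte[:, keep], Xtr[:, keep])
            if keep.size else np.zeros((Xte.shape[0], Xtr.shape[0]))
        )
    scores = mk_decision_scores(clf, cross)
    K_test = sum(beta[m] * cross[m] for m in cross)
    pred = clf.svm.predict(K_test).astype(int)
    return pred, scores, {"beta": beta, "C_mk": C, **fitted.params}


def run_experiment(
    table: FeatureTable,
    config: ExperimentConfig,
    methods=("STL", "SMTL"),
    seed: int | None = None,
) -> ExperimentReport:
    """Run the outer-CV protocol for each method on shared folds."""
    seed = config.master_seed if seed is None else seed
    labels = table.labels
    outer = stratified_folds(
        labels, config.n_outer_folds, seed=component_seed(seed, "outer_folds")
    )
    parsed = [_parse_method(m) for m in methods]
    names = [f"{m}-{k}" if k == "MK" else m for m, k in parsed]
    results = {
        name: CVResult(method=m, kernel=k, fold_metrics=[], fold_params=[],
                       fold_selected=[])
        for name, (m, k) in zip(names, parsed)
    }

    t0 = time.time()
    for f in range(config.n_outer_folds):
        train_table = table.subset_samples(outer != f)
        test_table = table.subset_samples(outer == f)
        for name, (method, kernel) in zip(names, parsed):
            fold_seed = component_seed(seed, f"fold{f}/{method}")
            fitted = nested_model_selection(train_table, config, method,
                                            seed=fold_seed)
            if kernel == "MK" and not fitted.selection.empty:
                pred, scores, params = _evaluate_fold_mk(
                    fitted, train_table, test_table, config, fold_seed
                )
            else:
                pred = fitted.predict(test_table.X)
                scores = fitted.decision_scores(test_table.X)
                params = dict(fitted.params)
            res = results[name]
            res.fold_metrics.append(
                confusion_metrics(test_table.labels, pred, scores)
            )
            res.fold_params.append(params)
            res.fold_selected.append(fitted.selection.selected.copy())
            logger.info("fold %d %s: ACC %.3f with %s", f, name,
                        res.fold_metrics[-1].ACC, params)

    comparison = None
    stl = next((n for n, (m, k) in zip(names, parsed) if m == "STL"), None)
    smtl = next((n for n, (m, k) in zip(names, parsed) if m == "SMTL"), None)
    if stl is not None and smtl is not None:
        comparison = paired_ttest(results[smtl].fold_acc, results[stl].fold_acc)

    manifest = RunManifest(
        config=config.as_dict(),
        seed=seed,
        methods=list(names),
        n_samples=table.n_samples,
        n_features=table.n_features,
        timings={"total_s": time.time() - t0},
    )
    return ExperimentReport(results=results, comparison=comparison,
                            outer_folds=outer, manifest=manifest)
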