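"""Model evaluation: metrics, nested CV model selection, and diagnostics.

Performance is reported with the five standard diagnostic metrics —
accuracy, sensitivity, specificity, balanced accuracy (the mean of
sensitivity and specificity, informative under class imbalance) and AUC —
computed per outer fold of a stratified 10-fold cross-validation.
Hyperparameters (number of subclasses K, sparsity penalty, SVM soft margin
C) are chosen per outer-training fold by an inner stratified 5-fold search
that never sees the outer test samples.  Methods are compared with a paired
t-test on fold-wise accuracies, and the multivariate-normality assumption of
a unimodal class model is probed with the Henze-Zirkler test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .clustering import subclass_discovery
from .encoding import build_code_set, encode_targets
from .io_config import ExperimentConfig, FeatureTable, Standardizer, component_rng, \
    component_seed, zscore_apply, zscore_fit
from .selection import SelectionResult, l1_lambda_max, l21_lambda_max, \
    select_features, solve_l1, solve_l21
from .classification import TrainedClassifier, train_svm


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSet:
    """ACC, SEN, SPEC, BAC, AUC on the [0, 1] scale (NaN where undefined)."""

    ACC: float
    SEN: float
    SPEC: float
    BAC: float
    AUC: float
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in ("ACC", "SEN", "SPEC", "BAC", "AUC")}


def confusion_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> MetricSet:
    """The five metrics from a +1/-1 truth/prediction pair.

    ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPEC = TN/(TN+FP),
    BAC = (SEN+SPEC)/2; AUC is the probability that a random positive
    outscores a random negative (ties counted 1/2), omitted (NaN) when
    ``scores`` is absent.  A class missing from ``y_true`` leaves its rate
    NaN rather than silently zero.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = y_true == 1
    neg = y_true == -1
    counts = ConfusionCounts(
        TP=int((pos & (y_pred == 1)).sum()),
        FN=int((pos & (y_pred == -1)).sum()),
        TN=int((neg & (y_pred == -1)).sum()),
        FP=int((neg & (y_pred == 1)).sum()),
    )
    acc = (counts.TP + counts.TN) / counts.total
    sen = counts.TP / pos.sum() if pos.any() else float("nan")
    spec = counts.TN / neg.sum() if neg.any() else float("nan")
    bac = (sen + spec) / 2.0
    if scores is not None and pos.any() and neg.any():
        auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    else:
        auc = float("nan")
    return MetricSet(ACC=float(acc), SEN=float(sen), SPEC=float(spec),
                     BAC=float(bac), AUC=auc, counts=counts)


# ---------------------------------------------------------------------------
# Folds


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int = 0) -> np.ndarray:
    """Per-class random partition into near-equal folds, as a fold-id vector."""
    labels = np.asarray(labels, dtype=int)
    for cls in np.unique(labels):
        if (labels == cls).sum() < n_folds:
            raise ValueError(
                f"class {cls:+d} has fewer samples than the {n_folds} folds"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    fold_ids = np.empty(labels.shape[0], dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels), labels)):
        fold_ids[test_idx] = f
    return fold_ids


# ---------------------------------------------------------------------------
# Statistical comparisons


@dataclass
class PairedTTest:
    t: float
    p: float
    degenerate: bool = False


def paired_ttest(acc_a, acc_b) -> PairedTTest:
    """Two-sided paired t-test on fold-wise (or seed-wise) accuracies.

    Zero-variance differences are flagged degenerate: identical vectors give
    (t=0, p=1); constant non-zero differences give t = +/-inf with p = 0.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTTest(t=0.0, p=1.0, degenerate=True)
        return PairedTTest(t=float(np.sign(d.mean()) * np.inf), p=0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTTest(t=float(res.statistic), p=float(res.pvalue))


def henze_zirkler(X: np.ndarray, alpha: float = 0.05):
    """Henze-Zirkler test of multivariate normality.

    The statistic is the weighted L2 distance between the empirical
    characteristic function of the standardized sample and the standard
    multivariate normal characteristic function, with the standard smoothing
    parameter  b = ((n(2p+1))/4)^(1/(p+4)) / sqrt(2)  from the original 1990
    reference.  Under the null the statistic is approximately log-normally
    distributed; its first two moments give the p-value.

    Returns ``(statistic, p_value, reject)`` with ``reject = p < alpha``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples than dimensions (n={n}, p={p})")
    S = np.cov(X, rowvar=False, bias=True)
    diff = X - X.mean(axis=0)
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular sample covariance; reduce the dimension before testing"
        ) from exc
    # squared Mahalanobis distances, pairwise and to the mean
    Y = diff @ np.linalg.cholesky(S_inv)  # rows have identity covariance
    sq = (Y * Y).sum(axis=1)
    Dij = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    np.fill_diagonal(Dij, 0.0)
    Dij = np.maximum(Dij, 0.0)
    Di = sq

    b2 = (1.0 / 2.0) * ((n * (2 * p + 1)) / 4.0) ** (2.0 / (p + 4))
    hz = n * (
        np.exp(-b2 / 2.0 * Dij).sum() / n**2
        - 2.0 * (1.0 + b2) ** (-p / 2.0) * np.exp(-b2 / (2.0 * (1.0 + b2)) * Di).mean()
        + (1.0 + 2.0 * b2) ** (-p / 2.0)
    )

    # null moments of the statistic (log-normal approximation)
    a = 1.0 + 2.0 * b2
    wb = (1.0 + b2) * (1.0 + 3.0 * b2)
    mu = 1.0 - a ** (-p / 2.0) * (
        1.0 + p * b2 / a + (p * (p + 2) * b2**2) / (2.0 * a**2)
    )
    si2 = (
        2.0 * (1.0 + 4.0 * b2) ** (-p / 2.0)
        + 2.0 * a ** (-p)
        * (1.0 + (2.0 * p * b2**2) / a**2 + (3.0 * p * (p + 2) * b2**4) / (4.0 * a**4))
        - 4.0 * wb ** (-p / 2.0)
        * (1.0 + (3.0 * p * b2**2) / (2.0 * wb) + (p * (p + 2) * b2**4) / (2.0 * wb**2))
    )
    pmu = np.log(np.sqrt(mu**4 / (si2 + mu**2)))
    psi = np.sqrt(np.log1p(si2 / mu**2))
    pval = float(stats.lognorm.sf(hz, psi, scale=np.exp(pmu)))
    return float(hz), pval, pval < alpha


# ---------------------------------------------------------------------------
# Nested model selection


@dataclass
class FittedPipeline:
    """A selection + SVM pipeline refitted on a full outer-training fold."""

    method: str
    standardizer: Standardizer | None
    selection: SelectionResult
    classifier: TrainedClassifier | None
    params: dict = field(default_factory=dict)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if self.standardizer is not None:
            X = zscore_apply(self.standardizer, X)
        return X[:, self.selection.selected]

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.classifier is None:
            # empty-support fallback: constant majority-class prediction
            return np.full(X.shape[0], self.params["majority_label"], dtype=int)
        return self.classifier.predict(self._prepare(X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        if self.classifier is None:
            return np.zeros(X.shape[0])
        return self.classifier.decision_scores(self._prepare(X))


logger = logging.getLogger("smtl")


def _kmeans_stream(stage: str, kp: int, km: int) -> str:
    """Substream name for one clustering trial (stable across runs)."""
    return (f"kmeans/{stage}/K{kp}" if kp == km
            else f"kmeans/{stage}/K{kp}x{km}")


def _chance_level(y: np.ndarray) -> float:
    """Majority-class rate: the accuracy of always guessing the larger class."""
    y = np.asarray(y, dtype=int)
    return float(max((y == 1).mean(), (y == -1).mean()))


def _smtl_selection(X, y, K_plus, K_minus, lam_frac, config, seed, W0=None):
    """Cluster, encode, solve the multi-task problem, select features.

    ``lam_frac`` is a fraction of the training set's critical penalty
    (the smallest lambda2 whose solution is identically zero)."""
    assignment = subclass_discovery(
        None, K_plus, K_minus, seed=seed, X=X, labels=y, n_restarts=10
    )
    Y = encode_targets(assignment, build_code_set(K_plus, K_minus)).Y
    lam = lam_frac * l21_lambda_max(X, Y)
    weights = solve_l21(X, Y, lam, rel_tol=config.rel_tol,
                        max_iter=config.max_iter, W0=W0)
    return select_features(weights, config.selection_tolerance), weights


def _stl_selection(X, y, lam_frac, config, w0=None):
    lam = lam_frac * l1_lambda_max(X, y)
    weights = solve_l1(X, y.astype(float), lam, rel_tol=config.rel_tol,
                       max_iter=config.max_iter, w0=w0)
    return select_features(weights, config.selection_tolerance), weights


def _score_selection(Xtr, ytr, Xva, yva, selection, C_grid):
    """Validation accuracy per C for one candidate selection."""
    out = {}
    if selection.empty:
        chance = _chance_level(ytr)
        return {float(C): chance for C in C_grid}
    Xtr_s = Xtr[:, selection.selected]
    Xva_s = Xva[:, selection.selected]
    for C in C_grid:
        clf = train_svm(Xtr_s, ytr, float(C))
        out[float(C)] = float((clf.predict(Xva_s) == yva).mean())
    return out


def nested_model_selection(
    train_table: FeatureTable,
    config: ExperimentConfig,
    method: str,
    seed: int = 0,
) -> FittedPipeline:
    """Choose hyperparameters by inner stratified CV, then refit on all
    training samples.

    For SMTL the grid is (K, lambda2-fraction, C) with a single K shared by
    both classes (capped at the smaller inner-training class size); for STL
    it is (lambda1-fraction, C).  The winner maximizes mean inner accuracy;
    ties break toward smaller K, then a larger (sparser) penalty, then
    smaller C.  A trial whose selection is empty scores the majority-class
    rate so the search routes around it.
    """
    if method not in {"STL", "SMTL"}:
        raise ValueError(f"method must be 'STL' or 'SMTL', got {method!r}")
    X_all, y_all = train_table.X, train_table.labels
    fold_ids = stratified_folds(
        y_all, config.n_inner_folds, seed=component_seed(seed, "inner_folds")
    )
    lam_grid = sorted(
        config.lambda2_grid if method == "SMTL" else config.lambda1_grid,
        reverse=True,  # sparse-to-dense with warm starts
    )
    if config.independent_K:
        k_pairs = [(kp, km) for kp in config.K_grid for km in config.K_grid]
    else:
        k_pairs = [(K, K) for K in config.K_grid]

    # accumulate inner accuracy per candidate
    acc: dict[tuple, list[float]] = {}
    for f in range(config.n_inner_folds):
        tr = fold_ids != f
        va = ~tr
        Xtr, ytr = X_all[tr], y_all[tr]
        Xva, yva = X_all[va], y_all[va]
        if config.standardize:
            std = zscore_fit(Xtr)
            Xtr, Xva = zscore_apply(std, Xtr), zscore_apply(std, Xva)
        if method == "SMTL":
            cap_plus = int((ytr == 1).sum())
            cap_minus = int((ytr == -1).sum())
            for kp, km in k_pairs:
                if kp > cap_plus or km > cap_minus:
                    continue
                W0 = None
                km_seed = component_rng(seed, _kmeans_stream(f"fold{f}", kp, km))
                for lam_frac in lam_grid:
                    selection, weights = _smtl_selection(
                        Xtr, ytr, kp, km, lam_frac, config, km_seed, W0=W0
                    )
                    W0 = weights.W
                    for C, a in _score_selection(
                        Xtr, ytr, Xva, yva, selection, config.C_grid
                    ).items():
                        acc.setdefault((kp, km, lam_frac, C), []).append(a)
                        logger.debug(
                            "inner fold %d K=(%d,%d) lam=%.3g C=%.3g acc=%.3f",
                            f, kp, km, lam_frac, C, a,
                        )
        else:
            w0 = None
            for lam_frac in lam_grid:
                selection, weights = _stl_selection(Xtr, ytr, lam_frac, config, w0=w0)
                w0 = weights.W
                for C, a in _score_selection(
                    Xtr, ytr, Xva, yva, selection, config.C_grid
                ).items():
                    acc.setdefault((lam_frac, C), []).append(a)
                    logger.debug("inner fold %d lam=%.3g C=%.3g acc=%.3f",
                                 f, lam_frac, C, a)

    # argmax mean accuracy with the deterministic tie rule:
    # fewer subclasses first, then the sparser penalty, then smaller C
    if method == "SMTL":
        key = lambda kv: (-np.mean(kv[1]), kv[0][0] + kv[0][1], kv[0][0],
                          -kv[0][2], kv[0][3])
    else:
        key = lambda kv: (-np.mean(kv[1]), -kv[0][0], kv[0][1])
    best, best_accs = sorted(acc.items(), key=key)[0]

    # refit on the full outer-training fold
    std = zscore_fit(X_all) if config.standardize else None
    X_fit = zscore_apply(std, X_all) if std is not None else X_all
    if method == "SMTL":
        kp, km, lam_frac, C = best
        selection, weights = _smtl_selection(
            X_fit, y_all, kp, km, lam_frac, config,
            component_rng(seed, _kmeans_stream("refit", kp, km)),
        )
        params = {"K": kp if kp == km else (kp, km),
                  "K_plus": kp, "K_minus": km,
                  "lambda_frac": lam_frac, "C": C,
                  "lambda": weights.lam, "inner_acc": float(np.mean(best_accs))}
    else:
        lam_frac, C = best
        selection, weights = _stl_selection(X_fit, y_all, lam_frac, config)
        params = {"lambda_frac": lam_frac, "C": C,
                  "lambda": weights.lam, "inner_acc": float(np.mean(best_accs))}

    logger.info("%s chose %s (%d features selected)", method, params,
                len(selection))
    if selection.empty:
        params["majority_label"] = 1 if (y_all == 1).sum() >= (y_all == -1).sum() else -1
        return FittedPipeline(method=method, standardizer=std,
                              selection=selection, classifier=None, params=params)
    clf = train_svm(X_fit[:, selection.selected], y_all, C)
    return FittedPipeline(method=method, standardizer=std,
                          selection=selection, classifier=clf, params=params)
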