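"""Linear SVM classification, single- and multi-kernel.

After feature selection, class prediction uses a soft-margin linear SVM.
For multimodal tables a multi-kernel variant combines one linear kernel per
modality, K = sum_m beta_m K_m, with nonnegative modality weights beta
summing to one.  The weights are searched exhaustively on a simplex lattice
(default step 0.1) jointly with the soft margin C, scored by inner
cross-validated accuracy.

The quadratic program itself is delegated to a standard dual solver
(scikit-learn's SVC, in precomputed-kernel mode for the multi-kernel case);
the contract here is the decision function, not solver internals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .io_config import FeatureTable, component_seed
from .selection import SelectionResult


@dataclass
class TrainedClassifier:
    """A fitted SVM exposing hard predictions and continuous decision scores."""

    kind: str                      # "single_kernel" or "multi_kernel"
    C: float
    svm: SVC
    modality_weights: dict[str, float] | None = None
    train_info: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(X).astype(int)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.svm.decision_function(X), dtype=float)


@dataclass
class KernelMatrix:
    """A (symmetric PSD) linear kernel over one modality's selected features."""

    matrix: np.ndarray
    modality: str
    n_features: int

    @property
    def empty(self) -> bool:
        return self.n_features == 0


def train_svm(X_sel: np.ndarray, y: np.ndarray, C: float) -> TrainedClassifier:
    """Train a soft-margin linear SVM on the selected features."""
    y = np.asarray(y, dtype=int)
    if C <= 0:
        raise ValueError("C must be positive")
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    svm = SVC(kernel="linear", C=C)
    svm.fit(X_sel, y)
    return TrainedClassifier(kind="single_kernel", C=float(C), svm=svm)


def linear_kernel(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    B = A if B is None else B
    return np.asarray(A, float) @ np.asarray(B, float).T


def modality_kernels(
    table: FeatureTable,
    selected: SelectionResult,
    X: np.ndarray | None = None,
) -> dict[str, KernelMatrix]:
    """One linear kernel per modality, on that modality's selected features.

    ``X`` may supply standardized values (same shape as ``table.X``).
    Modalities where no feature survived selection yield a zero kernel,
    flagged via ``KernelMatrix.empty``.
    """
    if selected.empty:
        raise ValueError("no selected features: cannot build kernels")
    X = table.X if X is None else np.asarray(X, float)
    sel = set(selected.selected.tolist())
    out: dict[str, KernelMatrix] = {}
    for modality, idx in table.modality_indices().items():
        keep = np.asarray([j for j in idx if j in sel], dtype=int)
        if keep.size:
            K = linear_kernel(X[:, keep])
        else:
            K = np.zeros((X.shape[0], X.shape[0]))
        out[modality] = KernelMatrix(matrix=K, modality=modality, n_features=keep.size)
    return out


def combine_kernels(
    kernels: dict[str, KernelMatrix | np.ndarray], beta: dict[str, float]
) -> np.ndarray:
    mats = {
        m: (k.matrix if isinstance(k, KernelMatrix) else np.asarray(k, float))
        for m, k in kernels.items()
    }
    first = next(iter(mats.values()))
    out = np.zeros_like(first)
    for m, K in mats.items():
        out += beta.get(m, 0.0) * K
    return out


def simplex_lattice(n_modalities: int, step: float = 0.1) -> list[tuple[float, ...]]:
    """All weight vectors on the step-lattice of the probability simplex."""
    if n_modalities < 1:
        raise ValueError("need at least one modality")
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1")
    out = []
    for combo in itertools.product(range(units + 1), repeat=n_modalities):
        if sum(combo) == units:
            out.append(tuple(c * step for c in combo))
    return out


def _kernel_cv_accuracy(K, y, C, fold_ids) -> float:
    accs = []
    for f in np.unique(fold_ids):
        tr = fold_ids != f
        va = ~tr
        if len(set(y[tr].tolist())) < 2:
            continue
        svm = SVC(kernel="precomputed", C=C)
        svm.fit(K[np.ix_(tr, tr)], y[tr])
        accs.append(float((svm.predict(K[np.ix_(va, tr)]) == y[va]).mean()))
    return float(np.mean(accs)) if accs else 0.0


def grid_search_modality_weights(
    kernels: dict[str, KernelMatrix | np.ndarray],
    y: np.ndarray,
    C_grid,
    step: float = 0.1,
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[dict[str, float], float, float]:
    """Exhaustive (beta, C) search on the simplex lattice by inner-CV accuracy.

    Ties break toward the most balanced beta (smallest maximum weight), then
    the smallest C, so reports are deterministic.  Returns
    ``(beta, C, best_accuracy)``.
    """
    from .evaluation import stratified_folds  # local import to avoid a cycle

    y = np.asarray(y, dtype=int)
    names = list(kernels)
    if len(names) == 1:
        betas = [(1.0,)]
    else:
        betas = simplex_lattice(len(names), step)
    fold_ids = stratified_folds(y, inner_folds, seed=component_seed(seed, "mk_weights"))

    candidates = []
    for beta_t in betas:
        beta = dict(zip(names, beta_t))
        K = combine_kernels(kernels, beta)
        for C in C_grid:
            acc = _kernel_cv_accuracy(K, y, float(C), fold_ids)
            candidates.append((-acc, max(beta_t), float(C), beta))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    neg_acc, _, C_best, beta_best = candidates[0]
    return beta_best, C_best, -neg_acc


def train_mk_svm(
    kernels: dict[str, KernelMatrix | np.ndarray],
    y: np.ndarray,
    beta: dict[str, float],
    C: float,
) -> TrainedClassifier:
    """Fit the multi-kernel SVM on precomputed training kernels."""
    total = sum(beta.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"modality weights must sum to 1, got {total}")
    y = np.asarray(y, dtype=int)
    K = combine_kernels(kernels, beta)
    svm = SVC(kernel="precomputed", C=C)
    svm.fit(K, y)
    return TrainedClassifier(
        kind="multi_kernel", C=float(C), svm=svm, modality_weights=dict(beta)
    )


def mk_decision_scores(
    clf: TrainedClassifier, cross_kernels: dict[str, np.ndarray]
) -> np.ndarray:
    """Scores for test samples given per-modality test-by-train kernels."""
    K = combine_kernels(cross_kernels, clf.modality_weights)
    return np.asarray(clf.svm.decision_function(K), dtype=float)
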