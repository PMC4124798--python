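"""Subclass discovery by per-class K-means clustering.

Each diagnostic class is assumed to follow a multipeak (mixture-like)
distribution driven by inter-subject variability.  Lloyd's algorithm is run
independently on the samples of each class; every recovered cluster is
treated as a subclass and receives a globally unique id (positive-class
clusters 1..K(+), negative-class clusters K(+)+1..K(+)+K(-)).

The Lloyd loop is written out explicitly (rather than delegated) because the
downstream contracts depend on its internals: a per-iteration non-increasing
objective, deterministic lowest-index tie-breaking, and an empty-cluster
repair rule that keeps exactly K non-empty subclasses for the encoding stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .io_config import FeatureTable


@dataclass
class SubclassAssignment:
    """Per-sample subclass ids and per-class cluster summaries.

    ``gamma[i]`` is the (1-based, globally unique) cluster id of sample i;
    ``means`` maps cluster id -> centroid; ``class_of_cluster`` maps cluster
    id -> the original class (+1/-1) it was discovered in.
    """

    gamma: np.ndarray
    K_plus: int
    K_minus: int
    means: dict[int, np.ndarray]
    objective_plus: float
    objective_minus: float
    class_of_cluster: dict[int, int]

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=int)
        if self.K_plus < 1 or self.K_minus < 1:
            raise ValueError("K_plus and K_minus must be >= 1")
        ids = set(range(1, self.K_plus + self.K_minus + 1))
        if set(self.means) != ids or set(self.class_of_cluster) != ids:
            raise ValueError("cluster ids must be 1..K_plus+K_minus")
        for obj in (self.objective_plus, self.objective_minus):
            if not np.isfinite(obj) or obj < -1e-12:
                raise ValueError("cluster objectives must be finite and nonnegative")

    def subclass_index(self, i: int) -> int:
        """0-based index of sample i's subclass within its own class."""
        g = int(self.gamma[i])
        return g - 1 if g <= self.K_plus else g - self.K_plus - 1


def _lloyd(samples: np.ndarray, k: int, init: np.ndarray, max_iter: int):
    """One Lloyd run from given initial centers.

    Returns (assignments, centers, objective, trace).  The objective is the
    within-cluster sum of squared Euclidean distances; the trace is asserted
    non-increasing across iterations.
    """
    n = samples.shape[0]
    centers = init.copy()
    prev_assign = None
    prev_obj = np.inf
    trace: list[float] = []
    for _ in range(max_iter):
        d = cdist(samples, centers, "sqeuclidean")
        assign = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
        # empty-cluster repair: re-seed at the sample farthest from its center
        while True:
            counts = np.bincount(assign, minlength=k)
            empty = np.flatnonzero(counts == 0)
            if empty.size == 0:
                break
            ck = int(empty[0])
            far = int(np.argmax(d[np.arange(n), assign]))
            centers[ck] = samples[far]
            d[:, ck] = cdist(samples, centers[ck : ck + 1], "sqeuclidean").ravel()
            assign = np.argmin(d, axis=1)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        for j in range(k):
            centers[j] = samples[assign == j].mean(axis=0)
        obj = float(
            cdist(samples, centers, "sqeuclidean")[np.arange(n), assign].sum()
        )
        assert obj <= prev_obj * (1 + 1e-9) + 1e-12, "K-means objective increased"
        trace.append(obj)
        prev_obj = obj
        prev_assign = assign
    obj = float(cdist(samples, centers, "sqeuclidean")[np.arange(n), assign].sum())
    return assign, centers, obj, trace


def kmeans(
    samples: np.ndarray,
    K: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 300,
    n_restarts: int = 10,
):
    """K-means with k-means++ seeding and multiple restarts.

    Runs Lloyd iterations until the assignment stops changing (or
    ``max_iter``), repeats from ``n_restarts`` seedings, and returns the run
    with the lowest within-cluster sum of squared errors.

    Returns ``(assignments, means, objective)`` with 0-based assignments.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise ValueError("samples must be a non-empty 2-D array")
    n = samples.shape[0]
    if not (1 <= K <= n):
        raise ValueError(f"K must satisfy 1 <= K <= n={n}, got {K}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        rs = int(rng.integers(2**31))
        if K == n:
            init = samples.copy()
        else:
            init, _ = kmeans_plusplus(samples, n_clusters=K, random_state=rs)
        assign, centers, obj, _ = _lloyd(samples, K, np.asarray(init, float), max_iter)
        if best is None or obj < best[2]:
            best = (assign, centers, obj)
    return best


def subclass_discovery(
    table: FeatureTable | None,
    K_plus: int,
    K_minus: int,
    seed: int | np.random.Generator = 0,
    *,
    X: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    max_iter: int = 300,
    n_restarts: int = 10,
) -> SubclassAssignment:
    """Cluster the +1 and -1 samples independently into subclasses.

    Either a :class:`FeatureTable` or an explicit ``(X, labels)`` pair (e.g.
    standardized training data) may be given.
    """
    if table is not None:
        X, labels = table.X, table.labels
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    idx_plus = np.flatnonzero(labels == 1)
    idx_minus = np.flatnonzero(labels == -1)
    if K_plus > idx_plus.size:
        raise ValueError(
            f"K_plus={K_plus} exceeds the {idx_plus.size} samples of the '+' class"
        )
    if K_minus > idx_minus.size:
        raise ValueError(
            f"K_minus={K_minus} exceeds the {idx_minus.size} samples of the '-' class"
        )

    a_plus, mu_plus, obj_plus = kmeans(
        X[idx_plus], K_plus, rng, max_iter=max_iter, n_restarts=n_restarts
    )
    a_minus, mu_minus, obj_minus = kmeans(
        X[idx_minus], K_minus, rng, max_iter=max_iter, n_restarts=n_restarts
    )

    gamma = np.zeros(X.shape[0], dtype=int)
    gamma[idx_plus] = a_plus + 1
    gamma[idx_minus] = a_minus + K_plus + 1
    means = {j + 1: mu_plus[j] for j in range(K_plus)}
    means.update({K_plus + j + 1: mu_minus[j] for j in range(K_minus)})
    class_of = {j + 1: +1 for j in range(K_plus)}
    class_of.update({K_plus + j + 1: -1 for j in range(K_minus)})
    return SubclassAssignment(
        gamma=gamma,
        K_plus=K_plus,
        K_minus=K_minus,
        means=means,
        objective_plus=obj_plus,
        objective_minus=obj_minus,
        class_of_cluster=class_of,
    )
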