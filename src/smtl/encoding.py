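"""Discriminative sparse codes for subclasses and the multi-task target matrix.

Each subclass gets a code vector of length S = 1 + K(+) + K(-): the first
element carries the original class label (+1 or -1), followed by a one-hot
block over the positive subclasses (entries in {0, +1}) and a one-hot block
over the negative subclasses (entries in {0, -1}).  The signs are chosen so
that any two distinct subclasses of the same original class sit at squared
Euclidean distance 2 while subclasses of different classes sit at distance 6
— close within a class, far across classes.  Stacking each training sample's
subclass code as a row yields the N x S target matrix of the multi-task
regression, whose first column reproduces the original binary labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import SubclassAssignment


@dataclass(frozen=True)
class SparseCodeSet:
    """The ordered code set: positive-subclass codes first, then negative."""

    K_plus: int
    K_minus: int
    codes_plus: np.ndarray   # (K_plus, S)
    codes_minus: np.ndarray  # (K_minus, S)

    @property
    def code_length(self) -> int:
        return 1 + self.K_plus + self.K_minus

    def code_for(self, label: int, subclass: int) -> np.ndarray:
        """Code of 0-based ``subclass`` within class ``label`` (+1/-1)."""
        if label == 1:
            return self.codes_plus[subclass]
        if label == -1:
            return self.codes_minus[subclass]
        raise ValueError(f"label must be +1 or -1, got {label}")

    def as_matrix(self) -> np.ndarray:
        return np.vstack([self.codes_plus, self.codes_minus])


@dataclass
class TargetMatrix:
    """N x S matrix whose row i is the sparse code of sample i's subclass."""

    Y: np.ndarray
    codes: SparseCodeSet

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape[1] != self.codes.code_length:
            raise ValueError("Y width does not match the code length")

    @property
    def n_tasks(self) -> int:
        return self.Y.shape[1]

    @property
    def original_labels(self) -> np.ndarray:
        return self.Y[:, 0].astype(int)


def build_code_set(K_plus: int, K_minus: int) -> SparseCodeSet:
    """Construct the sparse code set for K(+) positive and K(-) negative
    subclasses.

    Positive code l is ``[+1, e_l, 0]`` and negative code m is
    ``[-1, 0, -e_m]`` where ``e_l`` is the one-hot indicator over the
    corresponding subclass block.
    """
    if K_plus < 1 or K_minus < 1:
        raise ValueError("K_plus and K_minus must be positive integers")
    S = 1 + K_plus + K_minus
    plus = np.zeros((K_plus, S))
    plus[:, 0] = 1.0
    plus[np.arange(K_plus), 1 + np.arange(K_plus)] = 1.0
    minus = np.zeros((K_minus, S))
    minus[:, 0] = -1.0
    minus[np.arange(K_minus), 1 + K_plus + np.arange(K_minus)] = -1.0
    return SparseCodeSet(K_plus=K_plus, K_minus=K_minus,
                         codes_plus=plus, codes_minus=minus)


def encode_targets(assignment: SubclassAssignment, codes: SparseCodeSet) -> TargetMatrix:
    """Assign each sample the code of its subclass (new label vectors).

    Row i of the result is the code of the cluster sample i was assigned to;
    the first column therefore reproduces the original +1/-1 labels.
    """
    if (assignment.K_plus, assignment.K_minus) != (codes.K_plus, codes.K_minus):
        raise ValueError(
            f"subclass counts ({assignment.K_plus}, {assignment.K_minus}) do not "
            f"match the code set ({codes.K_plus}, {codes.K_minus})"
        )
    n = assignment.gamma.shape[0]
    Y = np.zeros((n, codes.code_length))
    for i in range(n):
        g = int(assignment.gamma[i])
        label = assignment.class_of_cluster[g]
        Y[i] = codes.code_for(label, assignment.subclass_index(i))
    return TargetMatrix(Y=Y, codes=codes)


def code_squared_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Euclidean distance between two code vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"code length mismatch: {a.shape} vs {b.shape}")
    return float(((a - b) ** 2).sum())
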