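"""Independent reference implementations used only to check the package.

These deliberately share no code with the solvers under test: the multi-task
problem is solved by block coordinate descent with closed-form row updates,
the single-task problem by elementwise coordinate descent, and AUC by brute
force over all positive-negative pairs.
"""

import numpy as np


def bcd_l21(X, Y, lam, max_sweeps=5000, tol=1e-14):
    """Block coordinate descent for  ||Y - XW||_F^2 + lam * ||W||_{2,1}.

    Row i's subproblem has the closed-form solution
    w_i = (1 - lam / (2 ||a||))_+ a / ||x_i||^2  with  a = x_i^T R.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, d = X.shape
    W = np.zeros((d, Y.shape[1]))
    R = Y.copy()
    col_sq = (X * X).sum(axis=0)
    prev = np.inf
    for _ in range(max_sweeps):
        for i in range(d):
            xi = X[:, i]
            R += np.outer(xi, W[i])
            a = xi @ R
            na = np.linalg.norm(a)
            W[i] = 0.0 if na <= lam / 2 else (1 - lam / (2 * na)) * a / col_sq[i]
            R -= np.outer(xi, W[i])
        obj = float((R * R).sum() + lam * np.sqrt((W * W).sum(axis=1)).sum())
        if abs(prev - obj) < tol * max(1.0, abs(obj)):
            break
        prev = obj
    return W, obj


def cd_l1(X, y, lam, max_sweeps=5000, tol=1e-14):
    """Coordinate descent for  ||y - Xw||^2 + lam * ||w||_1."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    d = X.shape[1]
    w = np.zeros(d)
    r = y.copy()
    col_sq = (X * X).sum(axis=0)
    prev = np.inf
    for _ in range(max_sweeps):
        for i in range(d):
            xi = X[:, i]
            r += xi * w[i]
            a = xi @ r
            w[i] = np.sign(a) * max(abs(a) - lam / 2, 0.0) / col_sq[i]
            r -= xi * w[i]
        obj = float(r @ r + lam * np.abs(w).sum())
        if abs(prev - obj) < tol * max(1.0, abs(obj)):
            break
        prev = obj
    return w, obj


def auc_all_pairs(y_true, scores):
    """P(random positive outscores random negative), ties counted 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, float)
    pos = scores[y_true == 1]
    neg = scores[y_true == -1]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
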