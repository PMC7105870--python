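"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: plain Python loops,
regexes and textbook formulas only.
"""

from __future__ import annotations

import re

import numpy as np

SCORE_COEFS = (1.06, 0.54, 0.58, 0.76, 2.3, 0.74, 0.67)


def score_by_hand(window7) -> float:
    total = 0.0
    for c, a in zip(SCORE_COEFS, window7):
        total += c * a
    return 0.0033 * total


def awakenings_by_regex(seg_labels) -> int:
    """Count wake runs strictly inside the segment followed by sleep."""
    s = "".join("S" if v == 1 else "W" for v in seg_labels)
    return len(re.findall(r"(?<=S)W+(?=S)", s))


def efficiency_by_count(seg_labels) -> float:
    s = [1 if v == 1 else 0 for v in seg_labels]
    return 100.0 * sum(s) / len(s)


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, p[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


def lasso_coordinate_descent(X, y, lam, n_iter=5000, tol=1e-12):
    """Textbook cyclic coordinate descent for the lasso on standardized X,
    centered y: minimizes (1/2N)||y - Xb||^2 + lam * ||b||_1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    b = np.zeros(p)
    col_sq = (X ** 2).sum(axis=0) / n
    for _ in range(n_iter):
        b_old = b.copy()
        for j in range(p):
            r = y - X @ b + X[:, j] * b[j]
            rho = X[:, j] @ r / n
            b[j] = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
        if np.max(np.abs(b - b_old)) < tol:
            break
    return b


def vif_by_ols(X):
    """1/(1-R^2) per column, R^2 from normal-equation OLS with intercept."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    out = []
    for j in range(p):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        r2 = 1 - (resid @ resid) / ((yj - yj.mean()) @ (yj - yj.mean()))
        out.append(1.0 / (1.0 - r2))
    return np.array(out)
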