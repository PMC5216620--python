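"""Linear epsilon-insensitive support vector regression.

A small dual coordinate-descent solver (L1-loss SVR dual, cyclic coordinate
order, bias folded in as a unit column) tuned for the many tiny fits the
nested cross-validation loop performs. Agreement with liblinear/libsvm
solutions is covered by the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def _dcd_solve(X, y, k, C, eps, tol, max_sweeps, beta, w):
    """Cyclic dual coordinate descent on the first ``k`` columns of X plus a
    unit bias column whose weight lives in ``w[-1]``. ``beta`` and ``w`` are
    updated in place (warm-startable)."""
    n = X.shape[0]
    qd = np.empty(n)
    for i in range(n):
        s = 1.0  # bias column
        for j in range(k):
            s += X[i, j] * X[i, j]
        qd[i] = s
    for _ in range(max_sweeps):
        max_d = 0.0
        for i in range(n):
            g = w[-1] - y[i]
            for j in range(k):
                g += X[i, j] * w[j]
            h = g - qd[i] * beta[i]
            if -h > eps:
                a = (-h - eps) / qd[i]
            elif -h < -eps:
                a = (-h + eps) / qd[i]
            else:
                a = 0.0
            if a > C:
                a = C
            elif a < -C:
                a = -C
            d = a - beta[i]
            if d != 0.0:
                beta[i] = a
                for j in range(k):
                    w[j] += d * X[i, j]
                w[-1] += d
                ad = abs(d)
                if ad > max_d:
                    max_d = ad
        if max_d < tol:
            break


@njit(cache=True)
def _scan_k_predict(Xtr, ytr, xte, kmax, C, eps, tol, max_sweeps):
    """For k = 1..kmax train on the first k columns (warm-started in k) and
    predict the held-out row; returns the kmax predictions."""
    n, f = Xtr.shape
    beta = np.zeros(n)
    w = np.zeros(f + 1)  # w[-1] is the bias weight
    preds = np.empty(kmax)
    for k in range(1, kmax + 1):
        s = 0.0
        for i in range(n):
            s += beta[i] * Xtr[i, k - 1]
        w[k - 1] = s
        _dcd_solve(Xtr, ytr, k, C, eps, tol, max_sweeps, beta, w)
        p = w[-1]
        for j in range(k):
            p += xte[j] * w[j]
        preds[k - 1] = p
    return preds


class LinearEpsilonSVR:
    """Linear epsilon-SVR (regularized bias), deterministic fit.

    Parameters mirror the libsvm convention: ``epsilon`` is the insensitive
    tube half-width, ``C`` the per-sample loss weight.
    """

    def __init__(self, epsilon: float = 0.001, C: float = 1.0,
                 tol: float = 1e-6, max_sweeps: int = 5000):
        if C <= 0 or epsilon < 0:
            raise ValueError("C must be > 0 and epsilon >= 0")
        self.epsilon = epsilon
        self.C = C
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearEpsilonSVR":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        n, f = X.shape
        beta = np.zeros(n)
        w = np.zeros(f + 1)
        _dcd_solve(X, y, f, self.C, self.epsilon, self.tol, self.max_sweeps,
                   beta, w)
        self.coef_ = w[:f].copy()
        self.intercept_ = float(w[-1])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def scan_k_predict(Xtr, ytr, xte, kmax, epsilon=0.001, C=1.0,
                   tol=1e-3, max_sweeps=2000) -> np.ndarray:
    """Predictions for a single held-out sample at every feature count."""
    Xtr = np.ascontiguousarray(Xtr, dtype=np.float64)
    ytr = np.ascontiguousarray(ytr, dtype=np.float64)
    xte = np.ascontiguousarray(xte, dtype=np.float64)
    return _scan_k_predict(Xtr, ytr, xte, int(kmax), float(C), float(epsilon),
                           float(tol), int(max_sweeps))
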