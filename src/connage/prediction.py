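"""Two-aspect connectome-based age prediction.

UVPA: leave-one-out cross-validated simple linear regression on a single
feature. MVPA: nested leave-one-out loops — the inner loop ranks features by
absolute correlation with age and picks the feature count whose inner
predictions correlate best with age; consensus features across inner folds
feed a linear epsilon-SVR evaluated in the outer loop. Significance comes
from label permutations with the +1-corrected exceedance p-value
p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, UninformativeFeaturesError
from .svr import LinearEpsilonSVR, scan_k_predict

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    predicted_ages: np.ndarray
    observed_ages: np.ndarray
    r_pred_obs: float
    mae: float
    p_perm: float | None = None
    per_fold_features: list[tuple] = field(default_factory=list)
    consensus_features: tuple = ()
    n_perm: int = 0
    epsilon: float | None = None
    rng_seed: int | None = None
    method: str = ""

    def to_jsonable(self) -> dict:
        def plain(x):
            return int(x) if isinstance(x, (int, np.integer)) else str(x)

        return {
            "method": self.method,
            "predicted_ages": [float(v) for v in self.predicted_ages],
            "observed_ages": [float(v) for v in self.observed_ages],
            "r_pred_obs": float(self.r_pred_obs),
            "mae": float(self.mae),
            "p_perm": None if self.p_perm is None else float(self.p_perm),
            "per_fold_features": [[plain(x) for x in f]
                                  for f in self.per_fold_features],
            "consensus_features": [plain(x) for x in self.consensus_features],
            "n_perm": self.n_perm,
            "epsilon": self.epsilon,
            "rng_seed": self.rng_seed,
        }


# ---------------------------------------------------------------------------
# elementary metrics


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean()
    bc = b - b.mean()
    den = np.sqrt((ac @ ac) * (bc @ bc))
    if den == 0.0:
        return np.nan
    return float((ac @ bc) / den)


def pearson_r(a, b) -> float:
    """Pearson correlation; NaN sentinel when either input is constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    if a.size < 3:
        raise InsufficientDataError("need at least 3 pairs")
    return _corr(a, b)


def mae(pred, obs) -> float:
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("inputs must have equal length")
    return float(np.mean(np.abs(pred - obs)))


def column_corrs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|r| source for ranking; constant columns get r = 0."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xc = X - X.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    ss_x = np.einsum("ij,ij->j", xc, xc)
    ss_y = float(yc @ yc)
    r = np.zeros(X.shape[1])
    ok = (ss_x > 0)
    if ss_y > 0:
        r[ok] = (yc @ xc[:, ok]) / np.sqrt(ss_x[ok] * ss_y)
    return r


def rank_features_by_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature order by descending |corr with y|; ties by ascending index."""
    r = column_corrs(X, y)
    # round so that sign-flipped / duplicated columns tie exactly and the
    # ascending-index rule decides
    key = np.round(np.abs(r), 12)
    return np.lexsort((np.arange(len(r)), -key))


# ---------------------------------------------------------------------------
# UVPA


def _uvpa_predictions(feature: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Explicit refit leave-one-out predictions of a 1-feature regression."""
    s = len(ages)
    preds = np.empty(s)
    for i in range(s):
        mask = np.arange(s) != i
        x = feature[mask]
        y = ages[mask]
        sx = x - x.mean()
        sxx = float(sx @ sx)
        if sxx == 0.0:
            logger.warning("zero-variance training feature in fold %d; "
                           "predicting training mean", i)
            preds[i] = y.mean()
            continue
        b = float(sx @ (y - y.mean())) / sxx
        a = y.mean() - b * x.mean()
        preds[i] = a + b * feature[i]
    return preds


def _uvpa_predictions_fast(feature: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Closed-form LOO predictions via the hat-matrix identity
    pred_i = y_i - e_i / (1 - h_i); exact match to the refit loop."""
    x = np.asarray(feature, float)
    y = np.asarray(ages, float)
    s = len(y)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        # every fold sees a constant feature -> predicts its training mean
        return (y.sum() - y) / (s - 1)
    b = float(xc @ (y - y.mean())) / sxx
    a = y.mean() - b * x.mean()
    fit = a + b * x
    h = 1.0 / s + xc * xc / sxx
    e = y - fit
    return y - e / (1.0 - h)


def uvpa_loocv(feature: np.ndarray, ages: np.ndarray, n_perm: int = 0,
               rng_seed: int | None = None) -> PredictionResult:
    """LOOCV simple linear regression of age on one connectivity feature."""
    feature = np.asarray(feature, float)
    ages = np.asarray(ages, float)
    if len(feature) != len(ages):
        raise ValueError("feature and ages must have equal length")
    if len(ages) < 5:
        raise InsufficientDataError("UVPA needs at least 5 subjects")
    preds = _uvpa_predictions(feature, ages)
    result = PredictionResult(
        predicted_ages=preds, observed_ages=ages.copy(),
        r_pred_obs=_corr(preds, ages), mae=mae(preds, ages),
        n_perm=n_perm, rng_seed=rng_seed, method="uvpa",
    )
    if n_perm > 0:
        result.p_perm = permutation_pvalue(
            lambda _X, y: _corr(_uvpa_predictions_fast(feature, y), y),
            feature[:, None], ages, n_perm=n_perm, rng_seed=rng_seed,
        )
    return result


# ---------------------------------------------------------------------------
# MVPA


def consensus_features(per_fold_selections, theta: float = 0.5,
                       fallback=None):
    """Features chosen in at least a ``theta`` fraction of folds.

    Empty consensus falls back to ``fallback`` (a single feature) when given.
    """
    if not per_fold_selections:
        raise ValueError("no fold selections supplied")
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    counts = Counter()
    for sel in per_fold_selections:
        counts.update(set(sel))
    n = len(per_fold_selections)
    chosen = sorted(f for f, c in counts.items() if c / n >= theta)
    if not chosen:
        if fallback is None:
            raise UninformativeFeaturesError("empty consensus and no fallback")
        logger.info("empty consensus; falling back to top-ranked feature")
        chosen = [fallback]
    return tuple(chosen)


def _standardize(train: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _outer_fold_predict(Xtr, ytr, xte, epsilon, C, k_grid, theta, tol,
                        max_sweeps):
    """Inner-loop feature-count selection + consensus, then one SVR fit.

    Returns (prediction for the held-out sample, consensus feature indices).
    """
    m, F = Xtr.shape
    kmax = int(max(k_grid))
    grid = np.asarray(sorted(k_grid), dtype=int)
    inner_preds = np.empty((m, kmax))
    orders = np.empty((m, F), dtype=int)
    for j in range(m):
        mask = np.arange(m) != j
        Xin = Xtr[mask]
        yin = ytr[mask]
        order = rank_features_by_corr(Xin, yin)
        orders[j] = order
        mu, sd = _standardize(Xin[:, order])
        Xs = (Xin[:, order] - mu) / sd
        xs = (Xtr[j, order] - mu) / sd
        ymu = yin.mean()
        inner_preds[j] = scan_k_predict(
            Xs, yin - ymu, xs, kmax, epsilon=epsilon, C=C, tol=tol,
            max_sweeps=max_sweeps,
        ) + ymu
    r_by_k = np.full(len(grid), -np.inf)
    for gi, k in enumerate(grid):
        r = _corr(inner_preds[:, k - 1], ytr)
        if np.isfinite(r):
            r_by_k[gi] = r
    k_star = int(grid[int(np.argmax(r_by_k))])  # first max -> smallest k
    selections = [tuple(orders[j, :k_star]) for j in range(m)]
    fallback = int(rank_features_by_corr(Xtr, ytr)[0])
    chosen = consensus_features(selections, theta=theta, fallback=fallback)
    feats = np.asarray(chosen, dtype=int)
    mu, sd = _standardize(Xtr[:, feats])
    ymu = ytr.mean()
    model = LinearEpsilonSVR(epsilon=epsilon, C=C, tol=1e-5, max_sweeps=20000)
    model.fit((Xtr[:, feats] - mu) / sd, ytr - ymu)
    pred = float(model.predict(((xte[feats] - mu) / sd)[None, :])[0] + ymu)
    return pred, chosen


def _mvpa_predictions(X, y, epsilon, C, k_grid, theta, tol, max_sweeps):
    s = X.shape[0]
    preds = np.empty(s)
    per_fold = []
    idx = np.arange(s)
    for i in range(s):
        tr = idx != i
        pred, chosen = _outer_fold_predict(
            X[tr], y[tr], X[i], epsilon, C, k_grid, theta, tol, max_sweeps
        )
        preds[i] = pred
        per_fold.append(chosen)
    return preds, per_fold


def overall_consensus(per_fold, theta: float):
    counts = Counter()
    for sel in per_fold:
        counts.update(set(sel))
    n = len(per_fold)
    chosen = sorted(f for f, c in counts.items() if c / n >= theta)
    if not chosen and counts:
        top = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        chosen = [top]
    return tuple(chosen)


def mvpa_nested_loocv(
    X: np.ndarray,
    y: np.ndarray,
    epsilon: float = 0.001,
    C: float = 1.0,
    k_grid=None,
    consensus_theta: float = 0.5,
    n_perm: int = 0,
    rng_seed: int | None = None,
    feature_labels: list[str] | None = None,
    tol: float = 1e-3,
    max_sweeps: int = 2000,
) -> PredictionResult:
    """Nested LOOCV: inner feature-count selection, outer evaluation."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    s, F = X.shape
    if s < 8:
        raise InsufficientDataError("MVPA needs at least 8 subjects")
    if F < 1:
        raise UninformativeFeaturesError("no features")
    if np.all(np.ptp(X, axis=0) == 0):
        raise UninformativeFeaturesError("all features are constant")
    if k_grid is None:
        k_grid = range(1, F + 1)
    k_grid = sorted({int(k) for k in k_grid})
    if not k_grid or k_grid[0] < 1 or k_grid[-1] > F:
        raise ValueError("k_grid must be within 1..F")
    preds, per_fold = _mvpa_predictions(
        X, y, epsilon, C, k_grid, consensus_theta, tol, max_sweeps
    )
    consensus = overall_consensus(per_fold, consensus_theta)

    def relabel(indices):
        if feature_labels is None:
            return tuple(int(i) for i in indices)
        return tuple(feature_labels[i] for i in indices)

    result = PredictionResult(
        predicted_ages=preds, observed_ages=y.copy(),
        r_pred_obs=_corr(preds, y), mae=mae(preds, y),
        per_fold_features=[relabel(sel) for sel in per_fold],
        consensus_features=relabel(consensus),
        n_perm=n_perm, epsilon=epsilon, rng_seed=rng_seed, method="mvpa",
    )
    if n_perm > 0:
        def r_of(_X, yp):
            p, _ = _mvpa_predictions(X, yp, epsilon, C, k_grid,
                                     consensus_theta, tol, max_sweeps)
            return _corr(p, yp)

        result.p_perm = permutation_pvalue(r_of, X, y, n_perm=n_perm,
                                           rng_seed=rng_seed)
    return result


def mvpa_per_fold_features(build_fold, y, epsilon=0.001, C=1.0, k_grid=None,
                           consensus_theta=0.5, tol=1e-3, max_sweeps=2000
                           ) -> PredictionResult:
    """Stricter variant: ``build_fold(i)`` supplies a fold-specific feature
    table ``(Xtr, xte)`` (features re-defined without the held-out subject)."""
    y = np.asarray(y, float)
    s = len(y)
    preds = np.empty(s)
    per_fold = []
    idx = np.arange(s)
    for i in range(s):
        Xtr, xte = build_fold(i)
        Xtr = np.asarray(Xtr, float)
        grid = k_grid if k_grid is not None else range(1, Xtr.shape[1] + 1)
        pred, chosen = _outer_fold_predict(
            Xtr, y[idx != i], np.asarray(xte, float), epsilon, C,
            sorted({int(k) for k in grid}), consensus_theta, tol, max_sweeps,
        )
        preds[i] = pred
        per_fold.append(chosen)
    return PredictionResult(
        predicted_ages=preds, observed_ages=y.copy(),
        r_pred_obs=_corr(preds, y), mae=mae(preds, y),
        per_fold_features=[tuple(p) for p in per_fold],
        consensus_features=(), epsilon=epsilon, method="mvpa-per-fold",
    )


# ---------------------------------------------------------------------------
# permutation inference


def permutation_pvalue(predictor, X, y, n_perm: int = 1000,
                       rng_seed: int | None = None) -> float:
    """Exceedance p-value of the observed prediction accuracy.

    ``predictor(X, y)`` must re-run the whole pipeline (selection included)
    and return its accuracy statistic r. p = (#{r_perm >= r_obs} + 1) /
    (n_perm + 1); permuted statistics that are NaN never exceed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, float)
    r_obs = predictor(X, y)
    if not np.isfinite(r_obs):
        return 1.0
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        r_p = predictor(X, yp)
        if np.isfinite(r_p) and r_p >= r_obs:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)
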