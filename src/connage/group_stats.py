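"""Group-level statistics on Fisher-z maps.

Covariates are removed by per-group residualization with group means
preserved; one-sample and pooled two-sample t-tests are thresholded by
Benjamini-Hochberg FDR and (in grid mode) a strict cluster-extent rule; the
surviving nodes define the "altered connectivity" features fed to the
prediction and classification stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMap
from .errors import EmptyFeatureError, InsufficientDataError

DIR_NONE = 0
DIR_INCREASE = 1
DIR_DECREASE = -1


@dataclass
class GroupStatResult:
    t_values: np.ndarray
    p_values: np.ndarray
    fdr_mask: np.ndarray
    cluster_mask: np.ndarray
    direction: np.ndarray  # +1 increase, -1 decrease, 0 none

    def frame(self, node_labels=None) -> pd.DataFrame:
        n = len(self.t_values)
        labels = node_labels if node_labels is not None else [str(i) for i in range(n)]
        return pd.DataFrame({
            "node": labels,
            "t": self.t_values,
            "p": self.p_values,
            "fdr_flag": self.fdr_mask,
            "cluster_flag": self.cluster_mask,
            "direction": self.direction,
        })


@dataclass(frozen=True)
class FeatureDefinition:
    label: str
    seed_label: str
    target_nodes: tuple[int, ...]
    direction: int  # DIR_INCREASE or DIR_DECREASE

    def __post_init__(self):
        if not self.target_nodes:
            raise EmptyFeatureError(f"feature {self.label!r} has no target nodes")


@dataclass
class FeatureTable:
    values: np.ndarray  # subjects x features
    subject_ids: list[str]
    feature_labels: list[str]
    directions: list[int] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _finalize(t, p, q, adjacency, k):
    fdr = fdr_bh(p, q=q)
    cluster = cluster_filter(fdr, adjacency, k=k) if adjacency is not None else fdr
    direction = np.where(cluster, np.sign(np.nan_to_num(t)), 0).astype(int)
    return GroupStatResult(t, p, fdr, cluster, direction)


def one_sample_t(zmaps: np.ndarray, q: float = 0.05, adjacency=None,
                 k: int = 23) -> GroupStatResult:
    """Per-node one-sample t-test of mean z against zero (df = S - 1)."""
    zmaps = np.asarray(zmaps, dtype=float)
    s = zmaps.shape[0]
    if s < 3:
        raise InsufficientDataError("need at least 3 subjects")
    mean = zmaps.mean(axis=0)
    sd = zmaps.std(axis=0, ddof=1)
    t = np.full(zmaps.shape[1], np.nan)
    p = np.full(zmaps.shape[1], np.nan)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(s))
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=s - 1)
    degen = (~ok) & (mean != 0) & np.isfinite(mean)
    t[degen] = np.sign(mean[degen]) * np.inf
    p[degen] = 0.0
    return _finalize(t, p, q, adjacency, k)


def residualize_covariates(zmaps: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Per-node OLS residuals on [intercept | covariates], means re-added."""
    zmaps = np.asarray(zmaps, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    s = zmaps.shape[0]
    if cov.shape[0] != s:
        raise InsufficientDataError("covariate rows must match subjects")
    if cov.shape[1] >= s:
        raise InsufficientDataError("need more subjects than covariates")
    design = np.hstack([np.ones((s, 1)), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("collinear covariates; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(zmaps, axis=0)
    filled = np.where(np.isnan(zmaps), col_mean, zmaps)
    beta, *_ = np.linalg.lstsq(design, filled, rcond=None)
    resid = filled - design @ beta
    out = resid + col_mean
    out[np.isnan(zmaps)] = np.nan
    return out


def two_sample_t(zA: np.ndarray, zB: np.ndarray, mask=None, q: float = 0.05,
                 adjacency=None, k: int = 23,
                 equal_var: bool = True) -> GroupStatResult:
    """Two-sided two-sample t per node (pooled variance by default).

    Positive t means group A > group B. Nodes outside ``mask`` get NaN.
    """
    zA = np.asarray(zA, dtype=float)
    zB = np.asarray(zB, dtype=float)
    if zA.shape[0] < 3 or zB.shape[0] < 3:
        raise InsufficientDataError("need at least 3 subjects per group")
    n = zA.shape[1]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty analysis mask", RuntimeWarning, stacklevel=2)
    t = np.full(n, np.nan)
    p = np.full(n, np.nan)
    valid = mask & np.all(np.isfinite(zA), axis=0) & np.all(np.isfinite(zB), axis=0)
    if valid.any():
        with warnings.catch_warnings():
            # constant columns trigger a scipy precision warning; the
            # degenerate cases are patched explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(zA[:, valid], zB[:, valid],
                                  equal_var=equal_var)
        tv = np.asarray(res.statistic, dtype=float)
        pv = np.asarray(res.pvalue, dtype=float)
        # zero pooled variance with distinct means -> infinite t, p = 0
        diff = zA[:, valid].mean(axis=0) - zB[:, valid].mean(axis=0)
        degen = ~np.isfinite(tv) & (diff != 0)
        tv[degen] = np.sign(diff[degen]) * np.inf
        pv[degen] = 0.0
        same = ~np.isfinite(tv) & (diff == 0)
        tv[same] = 0.0
        pv[same] = 1.0
        t[valid] = tv
        p[valid] = pv
    return _finalize(t, p, q, adjacency, k)


def union_mask(res_a: GroupStatResult, res_b: GroupStatResult) -> np.ndarray:
    """Explicit mask: union of the two groups' significant one-sample sets."""
    return res_a.cluster_mask | res_b.cluster_mask


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask; NaN p never rejected."""
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return mask
    order = np.argsort(pf, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passed = pf[order] <= thresh
    if passed.any():
        kmax = np.max(np.nonzero(passed)[0])
        rej = np.zeros(m, dtype=bool)
        rej[order[: kmax + 1]] = True
        mask[finite] = rej
    return mask


def cluster_filter(mask: np.ndarray, adjacency, k: int = 23) -> np.ndarray:
    """Keep only connected components of the mask strictly larger than k."""
    mask = np.asarray(mask, dtype=bool)
    if adjacency is None or not mask.any():
        return mask.copy()
    adj = sparse.csr_matrix(adjacency)
    idx = np.nonzero(mask)[0]
    sub = adj[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    out = np.zeros_like(mask)
    for c in range(n_comp):
        members = idx[labels == c]
        if members.size > k:
            out[members] = True
    return out


def grid_adjacency(shape, connectivity: int = 6) -> sparse.csr_matrix:
    """Face/edge/corner adjacency of a 3-D voxel grid, flattened C-order."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    shape = tuple(shape)
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append(d)
    coords = np.indices(shape).reshape(3, -1).T
    flat = np.ravel_multi_index(coords.T, shape)
    rows, cols = [], []
    for d in offsets:
        nb = coords + d
        ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        rows.append(flat[ok])
        cols.append(np.ravel_multi_index(nb[ok].T, shape))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = int(np.prod(shape))
    return sparse.csr_matrix((np.ones(len(rows), bool), (rows, cols)), shape=(n, n))


def define_features(diff: GroupStatResult, seed_label: str,
                    node_labels: list[str], adjacency=None
                    ) -> list[FeatureDefinition]:
    """One feature per (seed, surviving connected component, direction)."""
    feats: list[FeatureDefinition] = []
    mask = diff.cluster_mask
    if not mask.any():
        return feats
    if adjacency is None:
        components = [[i] for i in np.nonzero(mask)[0]]
    else:
        adj = sparse.csr_matrix(adjacency)
        idx = np.nonzero(mask)[0]
        _, labels = connected_components(adj[np.ix_(idx, idx)], directed=False)
        components = [list(idx[labels == c]) for c in range(labels.max() + 1)]
    for comp in components:
        for direction in (DIR_INCREASE, DIR_DECREASE):
            nodes = tuple(i for i in comp if diff.direction[i] == direction)
            if not nodes:
                continue
            name = "+".join(node_labels[i] for i in nodes)
            feats.append(FeatureDefinition(
                label=f"{name} and {seed_label}",
                seed_label=seed_label, target_nodes=nodes, direction=direction,
            ))
    return feats


def extract_feature_table(
    conn_maps: dict[str, dict[str, ConnectivityMap]],
    feature_defs: list[FeatureDefinition],
    subject_ids: list[str] | None = None,
) -> FeatureTable:
    """Mean z over each feature's target nodes, one row per subject."""
    if not feature_defs:
        raise EmptyFeatureError("no features defined")
    sids = subject_ids if subject_ids is not None else sorted(conn_maps)
    values = np.empty((len(sids), len(feature_defs)))
    for i, sid in enumerate(sids):
        for j, fd in enumerate(feature_defs):
            cmap = conn_maps[sid][fd.seed_label]
            values[i, j] = np.nanmean(cmap.z_values[list(fd.target_nodes)])
    return FeatureTable(values=values, subject_ids=list(sids),
                        feature_labels=[f.label for f in feature_defs],
                        directions=[f.direction for f in feature_defs])
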