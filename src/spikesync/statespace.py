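"""Highly comparative analysis of windowed recordings.

Windows a recording into non-overlapping segments, evaluates the measure
library per window, and provides the downstream pipeline: window clustering
and 2-D multidimensional scaling, silhouette-based recording fingerprinting
with permutation nulls, univariate/bivariate A' decoding with synergy, and
intrinsic-dimension estimation (PCA threshold counts and the TWO-NN / Gride
nearest-neighbor likelihood estimators).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, silhouette_samples
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .measures import measure_vector
from .types import MultiNeuronSpikeTrain

__all__ = [
    "WindowMatrix",
    "windowed_measure_matrix",
    "window_similarity",
    "cluster_windows",
    "mds_2d",
    "SilhouetteResult",
    "silhouette_fingerprint",
    "DecodingResult",
    "decode",
    "decoding_synergy",
    "IDEstimate",
    "pca_id",
    "nn_id",
]


@dataclass
class WindowMatrix:
    """Non-overlapping time windows x measures, with optional labels."""

    values: pd.DataFrame            # rows: windows, columns: measures
    window_s: float
    labels: Optional[pd.DataFrame] = None  # recording_id / state per window
    zscored: bool = False

    def zscore(self) -> "WindowMatrix":
        """Per-measure z-scoring across windows (NaN-aware)."""
        v = self.values
        z = (v - v.mean(skipna=True)) / v.std(skipna=True).replace(0, np.nan)
        return WindowMatrix(z, self.window_s, self.labels, zscored=True)


def windowed_measure_matrix(
    train: MultiNeuronSpikeTrain,
    window_s: float = 30.0,
    measure_set: str = "core",
    zscore: bool = False,
) -> WindowMatrix:
    """Evaluate the measure set on each non-overlapping window of a train."""
    if train.T < 2 * window_s:
        raise ValueError("recording must span at least two windows")
    n_win = int(train.T // window_s)
    rows = []
    for w in range(n_win):
        sub = train.window(w * window_s, (w + 1) * window_s)
        rows.append(measure_vector(sub, which=measure_set))
    wm = WindowMatrix(pd.DataFrame(rows).reset_index(drop=True), window_s)
    return wm.zscore() if zscore else wm


def window_similarity(wm: WindowMatrix) -> pd.DataFrame:
    """Signed Spearman correlation between every pair of windows."""
    vals = wm.values
    const = vals.T.std(skipna=True) == 0
    if const.any():
        warnings.warn(f"windows with constant profiles: {list(vals.index[const])}")
    rho = vals.T.corr(method="spearman", min_periods=3)
    return rho


def cluster_windows(wm: WindowMatrix):
    """Average-linkage clustering of windows on D = 1 - rho (signed rho)."""
    rho = window_similarity(wm)
    D = 1.0 - rho.to_numpy(dtype=float)
    D[~np.isfinite(D)] = 2.0
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, pd.DataFrame(D, index=rho.index, columns=rho.columns)


def mds_2d(Dw: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Classical (metric) MDS of a distance matrix to 2 dimensions."""
    D = np.asarray(Dw, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:2]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)


@dataclass
class SilhouetteResult:
    scores: np.ndarray        # per-window silhouette S_i
    mean: float
    threshold: float          # (1 - alpha) quantile of permuted means
    alpha: float
    n_permutations: int
    significant: bool
    perm_means: np.ndarray = field(repr=False, default=None)


def _silhouette_inputs(space, labels):
    labels = np.asarray(labels)
    if isinstance(space, WindowMatrix):
        X = space.values.to_numpy(dtype=float)
        X = np.where(np.isfinite(X), X, np.nan)
        med = np.nanmedian(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(med, inds[1])
        return X, "euclidean", labels
    space = np.asarray(space, dtype=float)
    if space.ndim == 2 and space.shape[0] == space.shape[1] and np.allclose(
        np.diag(space), 0.0
    ):
        return space, "precomputed", labels
    return space, "euclidean", labels


def silhouette_fingerprint(
    space,
    labels: Sequence,
    n_perm: int = 1000,
    alpha: float = 0.001,
    seed: int = 0,
) -> SilhouetteResult:
    """Mean silhouette of a labeling with a label-permutation null.

    ``space`` may be a WindowMatrix (euclidean on median-imputed values), a
    precomputed square distance matrix, or a coordinate array.
    """
    X, metric, y = _silhouette_inputs(space, labels)
    uniq, counts = np.unique(y, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 labels")
    if counts.min() < 2:
        raise ValueError("every label needs at least 2 windows")
    scores = silhouette_samples(X, y, metric=metric)
    rng = np.random.default_rng(seed)
    perm_means = np.empty(n_perm)
    for k in range(n_perm):
        perm_means[k] = silhouette_samples(X, rng.permutation(y), metric=metric).mean()
    thr = float(np.quantile(perm_means, 1.0 - alpha))
    mean = float(scores.mean())
    return SilhouetteResult(
        scores=scores,
        mean=mean,
        threshold=thr,
        alpha=alpha,
        n_permutations=n_perm,
        significant=mean > thr,
        perm_means=perm_means,
    )


@dataclass
class DecodingResult:
    a_prime: float
    scheme: str
    n_folds_used: int
    scores: np.ndarray = field(repr=False, default=None)  # held-out scores
    truth: np.ndarray = field(repr=False, default=None)


def _cv_scores(X, y, groups, scheme, seed):
    """Held-out linear-classifier scores under the chosen CV scheme."""
    folds = []
    if scheme == "within":
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    elif scheme == "loro":
        if groups is None:
            raise ValueError("LORO requires recording ids")
        groups = np.asarray(groups)
        for g in np.unique(groups):
            test = np.flatnonzero(groups == g)
            train = np.flatnonzero(groups != g)
            folds.append((train, test))
    else:
        raise ValueError("scheme must be 'within' or 'loro'")
    all_scores = np.full(y.size, np.nan)
    fold_aucs = []
    for train, test in folds:
        if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
            warnings.warn("fold skipped: a class is absent in train or test")
            continue
        scaler = StandardScaler().fit(X[train])
        clf = LogisticRegression(max_iter=1000)
        clf.fit(scaler.transform(X[train]), y[train])
        s = clf.decision_function(scaler.transform(X[test]))
        all_scores[test] = s
        fold_aucs.append(roc_auc_score(y[test], s))
    if not fold_aucs:
        raise ValueError("all folds were skipped")
    return all_scores, fold_aucs


def decode(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence,
    scheme: str = "within",
    groups: Optional[Sequence] = None,
    seed: int = 0,
) -> DecodingResult:
    """Two-class discriminability A' of one or two measure columns.

    A' is the ROC area of the held-out linear-classifier scores, averaged
    across cross-validation folds — a rank-based quantity, exactly invariant
    to strictly monotone transforms of a single feature.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] not in (1, 2):
        raise ValueError("decode expects one or two feature columns")
    y = pd.factorize(np.asarray(labels))[0]
    if np.unique(y).size != 2:
        raise ValueError("decoding requires exactly 2 classes")
    ok = np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y[ok]
    groups = np.asarray(groups)[ok] if groups is not None else None
    scores, fold_aucs = _cv_scores(X, y, groups, scheme, seed)
    return DecodingResult(a_prime=float(np.mean(fold_aucs)), scheme=scheme,
                          n_folds_used=len(fold_aucs), scores=scores, truth=y)


def decoding_synergy(a_pair: float, a_x: float, a_y: float) -> float:
    """Synergy of a pair over its best member, as a percentage:
    100 * (A'_{XY} - max(A'_X, A'_Y)) / (max(A'_X, A'_Y) - 0.5).
    A pair (X, X) has zero synergy by construction."""
    best = max(a_x, a_y)
    if best <= 0.5:
        return np.nan
    return 100.0 * (a_pair - best) / (best - 0.5)


@dataclass
class IDEstimate:
    method: str
    value: float                 # summary estimate
    scales: np.ndarray = None    # scale parameter per estimate
    values: np.ndarray = None    # estimate per scale
    sem: np.ndarray = None       # s.e.m. per scale (NN methods)
    threshold: float = None      # variance threshold (PCA)


def _impute_standardize(X: np.ndarray, standardize: bool = True) -> np.ndarray:
    X = np.asarray(X, dtype=float).copy()
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    inds = np.where(~np.isfinite(X))
    X[inds] = np.take(med, inds[1])
    if not standardize:
        return X
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def pca_id(
    matrix: np.ndarray | pd.DataFrame,
    threshold: float = 0.95,
    standardize: bool = True,
) -> IDEstimate:
    """Number of principal components needed to reach the variance threshold.

    Rows are data points; missing entries are median-imputed and, unless the
    coordinates are already on a common scale (``standardize=False``),
    columns are standardized before the decomposition.
    """
    X = _impute_standardize(np.asarray(matrix, dtype=float), standardize)
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    var = s**2
    tot = var.sum()
    if tot == 0:
        return IDEstimate(method="pca", value=1.0, threshold=threshold)
    cum = np.cumsum(var) / tot
    n = int(np.searchsorted(cum, threshold) + 1)
    return IDEstimate(method="pca", value=float(n), threshold=threshold)


def _knn_dists(X: np.ndarray, ks: Sequence[int]) -> np.ndarray:
    """Distances to the k-th nearest neighbors (columns follow ks)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(X)
    kmax = max(ks)
    d, _ = tree.query(X, k=kmax + 1)
    return d[:, list(ks)]


def _dedup(X: np.ndarray) -> np.ndarray:
    """Drop duplicate points (zero nearest-neighbor distances break the
    ratio likelihoods)."""
    _, idx = np.unique(np.round(X, 12), axis=0, return_index=True)
    if idx.size < X.shape[0]:
        warnings.warn(f"removed {X.shape[0] - idx.size} duplicate points")
    return X[np.sort(idx)]

def _twonn_mle(X: np.ndarray) -> tuple[float, float]:
    d = _knn_dists(X, [1, 2])
    ok = d[:, 0] > 0
    mu = d[ok, 1] / d[ok, 0]
    mu = mu[mu > 1.0]
    if mu.size < 3:
        return np.nan, np.nan
    est = mu.size / np.sum(np.log(mu))
    return float(est), float(est / math.sqrt(mu.size))


def _gride_mle(X: np.ndarray, n1: int) -> tuple[float, float]:
    """Gride likelihood estimate from the ratio r_{2*n1}/r_{n1}."""
    n2 = 2 * n1
    d = _knn_dists(X, [n1, n2])
    ok = d[:, 0] > 0
    mu = d[ok, 1] / d[ok, 0]
    mu = mu[mu > 1.0]
    if mu.size < 3:
        return np.nan, np.nan
    logmu = np.log(mu)

    def nll(dim):
        # log f(mu) = log d + (n2-n1-1)*log(mu^d - 1) - ((n2-1)d + 1)*log mu
        #           = log d + (n2-n1-1)*log1p(-mu^-d) - (n1*d + 1)*log mu
        if dim <= 0:
            return np.inf
        md = mu**-dim
        return -np.sum(
            math.log(dim)
            + (n2 - n1 - 1) * np.log1p(-md)
            - (n1 * dim + 1) * logmu
        )

    res = minimize_scalar(nll, bounds=(1e-3, 100.0), method="bounded")
    dim = float(res.x)
    # observed-information standard error
    h = 1e-3 * max(dim, 1.0)
    second = (nll(dim + h) - 2 * nll(dim) + nll(dim - h)) / h**2
    sem = float(1.0 / math.sqrt(second)) if second > 0 else np.nan
    return dim, sem


def nn_id(
    matrix: np.ndarray | pd.DataFrame,
    method: str = "gride",
    scales: Optional[Sequence[int]] = None,
    seed: int = 0,
    standardize: bool = True,
) -> IDEstimate:
    """Nearest-neighbor intrinsic dimension across scales.

    gride: scales are neighbor ranks n1 = 1, 2, 4, ... (ratio r_{2 n1}/r_{n1});
    twonn: scales are subsample fractions indexed by decimation factor
    1, 2, 4, ... of the data points.  Rows are points; missing entries are
    median-imputed and columns standardized.  The summary ``value`` is the
    median across scales.
    """
    X = _dedup(_impute_standardize(np.asarray(matrix, dtype=float), standardize))
    n = X.shape[0]
    if n < 8:
        raise ValueError("need at least 8 distinct points")
    rng = np.random.default_rng(seed)
    vals, sems, scl = [], [], []
    if method == "gride":
        if scales is None:
            scales = []
            k = 1
            while 2 * k < n - 1:
                scales.append(k)
                k *= 2
        for n1 in scales:
            v, s = _gride_mle(X, n1)
            vals.append(v)
            sems.append(s)
            scl.append(n1)
    elif method == "twonn":
        if scales is None:
            scales = []
            k = 1
            while n // k >= 16:
                scales.append(k)
                k *= 2
        for dec in scales:
            sub = X[rng.permutation(n)[: n // dec]]
            v, s = _twonn_mle(sub)
            vals.append(v)
            sems.append(s)
            scl.append(dec)
    else:
        raise ValueError("method must be 'twonn' or 'gride'")
    vals_a = np.asarray(vals, float)
    good = np.isfinite(vals_a)
    summary = float(np.median(vals_a[good])) if good.any() else np.nan
    return IDEstimate(
        method=method,
        value=summary,
        scales=np.asarray(scl),
        values=vals_a,
        sem=np.asarray(sems, float),
    )
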