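"""Benchmark orchestration and measure profiling.

Runs the 900-train synthetic grid into a trains x measures data matrix (the
highly comparative object), profiles every measure's Spearman correlation
with each generative parameter, organizes measures by empirical similarity
(average-linkage clustering of D = 1 - |rho|), and quantifies finite-sample
bias and variability when the time window or the neuron count is reduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .measures import measure_vector
from .synthgen import Params, build_benchmark_grid, generate_train
from .types import SingleScaleParams

__all__ = [
    "DataMatrix",
    "run_benchmark",
    "param_correlations",
    "measure_distance_matrix",
    "cluster_measures",
    "eq13_stats",
    "zscored_matrix",
    "measure_point_cloud",
    "BiasVariabilityResult",
    "bias_variability_sweep",
    "intermatrix_correlation",
]

FAMILY_PARAMS = {
    "single": ("m", "r0", "f0", "rhythmic"),
    "dual": ("Sigma", "p_fail", "f0", "rhythmic"),
}
SYNCHRONY_PARAM = {"single": "m", "dual": "Sigma"}


@dataclass
class DataMatrix:
    """Trains (or windows) x measures values with per-row metadata."""

    values: pd.DataFrame  # rows: items, columns: measure labels
    meta: pd.DataFrame    # same index; family/parameter/label columns

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share an index")

    def subset(self, family: Optional[str] = None) -> "DataMatrix":
        if family is None:
            return self
        mask = self.meta["family"] == family
        return DataMatrix(self.values.loc[mask], self.meta.loc[mask])


def run_benchmark(
    grid: Optional[Iterable[tuple[str, Params]]] = None,
    measure_set: str = "core",
    seed: int = 0,
    progress: Optional[Callable[[int, int], None]] = None,
) -> DataMatrix:
    """Generate every train of the grid and evaluate the measure set.

    One master seed; per-train child streams are spawned by grid position so
    the matrix is reproducible and trains are mutually independent.
    """
    grid = list(build_benchmark_grid() if grid is None else grid)
    ss = np.random.SeedSequence(seed)
    rows = []
    metas = []
    for i, (family, params) in enumerate(grid):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i,))
        )
        train = generate_train(params, rng)
        rows.append(measure_vector(train, which=measure_set))
        meta = {"family": family}
        for key in FAMILY_PARAMS[family] + ("Dc", "sequential"):
            meta[key] = train.meta[key]
        metas.append(meta)
        if progress is not None:
            progress(i + 1, len(grid))
    values = pd.DataFrame(rows).reset_index(drop=True)
    meta = pd.DataFrame(metas).reset_index(drop=True)
    return DataMatrix(values, meta)


def _spearman_p(x: np.ndarray, y: np.ndarray, rng=None, n_perm: int = 2000):
    """|Spearman rho| and p-value; exact-style permutation below n = 20."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = spearmanr(x, y)
    if not np.isfinite(rho):
        return np.nan, np.nan
    if x.size < 20:
        rng = np.random.default_rng(0) if rng is None else rng
        null = np.empty(n_perm)
        for k in range(n_perm):
            null[k] = spearmanr(x, rng.permutation(y))[0]
        p = float((np.sum(np.abs(null) >= abs(rho)) + 1) / (n_perm + 1))
    return abs(float(rho)), float(p)


def param_correlations(
    dm: DataMatrix, family: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """|Spearman rho| of every measure with every generative parameter.

    Returns (rho_abs, p_values), measures as rows ordered by descending
    correlation with the family's synchrony parameter.
    """
    if family not in FAMILY_PARAMS:
        raise ValueError(f"unknown family {family!r}")
    sub = dm.subset(family)
    params = FAMILY_PARAMS[family]
    rho = pd.DataFrame(index=sub.values.columns, columns=params, dtype=float)
    pv = pd.DataFrame(index=sub.values.columns, columns=params, dtype=float)
    for par in params:
        y = sub.meta[par].astype(float).to_numpy()  # rhythmic flag -> 0/1
        for meas in sub.values.columns:
            r, p = _spearman_p(sub.values[meas].to_numpy(), y)
            rho.loc[meas, par] = r
            pv.loc[meas, par] = p
    order = rho[SYNCHRONY_PARAM[family]].sort_values(ascending=False).index
    order = list(order) + [m for m in rho.index if m not in set(order)]
    return rho.loc[order], pv.loc[order]


def measure_distance_matrix(
    dm: DataMatrix | pd.DataFrame, max_missing: float = 0.5
) -> pd.DataFrame:
    """Inter-measure distance D = 1 - |Spearman rho| over the data items.

    Missing values are handled pairwise-complete; measures missing on more
    than ``max_missing`` of the rows are excluded with a warning.
    """
    values = dm.values if isinstance(dm, DataMatrix) else dm
    frac_missing = values.isna().mean()
    drop = frac_missing[frac_missing > max_missing].index
    if len(drop):
        warnings.warn(
            f"excluding {len(drop)} measures with >{max_missing:.0%} missing "
            f"values: {list(drop)}"
        )
    values = values.drop(columns=drop)
    const = values.std(skipna=True) == 0
    if const.any():
        warnings.warn(f"excluding constant measures: {list(values.columns[const])}")
        values = values.loc[:, ~const]
    rho = values.corr(method="spearman", min_periods=3)
    D = 1.0 - rho.abs()
    np.fill_diagonal(D.values, 0.0)
    return D


def cluster_measures(D: pd.DataFrame):
    """Average-linkage clustering of a measure distance matrix.

    Returns (Z, leaf_order): Z is the scipy linkage matrix; leaf_order lists
    measure labels by increasing height of the first (nonsingleton) cluster
    each measure is merged into.
    """
    Dv = D.to_numpy(dtype=float).copy()
    Dv[~np.isfinite(Dv)] = 1.0  # incomparable measures: maximal distance
    Dv = 0.5 * (Dv + Dv.T)
    np.fill_diagonal(Dv, 0.0)
    Z = linkage(squareform(Dv, checks=False), method="average")
    n = Dv.shape[0]
    # a leaf's first nonsingleton cluster is the first linkage row containing it
    first_height = np.full(n, np.inf)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, row in enumerate(Z):
        a, b, h = int(row[0]), int(row[1]), row[2]
        merged = members.pop(a) + members.pop(b)
        for leaf in merged:
            if not np.isfinite(first_height[leaf]):
                first_height[leaf] = h
        members[n + k] = merged
    order = np.lexsort((np.arange(n), first_height))
    return Z, [D.columns[i] for i in order]


def eq13_stats(values: np.ndarray, s_hat: float) -> dict[str, float]:
    """Finite-sample statistics of one measure at one sample-size point.

    S_bar = mean over realizations, sigma_S = SD (ddof=1), V_S = |CV| and
    B_S = (S_bar - S_hat)/sigma_S; with sigma_S = 0, B_S is 0 when the mean
    equals the reference and +-inf otherwise.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        return {"S_bar": np.nan, "sigma_S": np.nan, "V_S": np.nan, "B_S": np.nan}
    s_bar = float(values.mean())
    sigma = float(values.std(ddof=1))
    v = abs(sigma / s_bar) if s_bar != 0 else np.inf
    if sigma == 0:
        b = 0.0 if s_bar == s_hat else np.inf * np.sign(s_bar - s_hat)
    else:
        b = (s_bar - s_hat) / sigma
    return {"S_bar": s_bar, "sigma_S": sigma, "V_S": v, "B_S": float(b)}


@dataclass
class BiasVariabilityResult:
    """Eq-13 style statistics per measure per sample-size point."""

    axis: str                 # "time" or "space"
    grid_points: np.ndarray   # window lengths (s) or neuron counts
    n_realizations: int
    stats: pd.DataFrame       # MultiIndex (measure, point) -> S_bar..B_S
    s_hat: pd.Series          # ground-truth proxy per measure


def bias_variability_sweep(
    base_params: Params,
    axis: str = "time",
    grid_points: Optional[Sequence[float]] = None,
    n_realizations: int = 50,
    seed: int = 0,
    measure_set: str = "core",
) -> BiasVariabilityResult:
    """Sweep the window length (axis='time') or neuron count (axis='space').

    The ground-truth proxy S_hat of each measure is its average over the
    realizations at the largest grid point.  Purely asynchronous single-scale
    trains (m = 0) carry no synchrony signal and are rejected.
    """
    if axis not in ("time", "space"):
        raise ValueError("axis must be 'time' or 'space'")
    if n_realizations < 2:
        raise ValueError("n_realizations must be at least 2")
    if isinstance(base_params, SingleScaleParams) and base_params.m == 0:
        raise ValueError("purely asynchronous trains (m = 0) are excluded")
    if grid_points is None:
        grid_points = (
            [0.5, 1.0, 3.0, 10.0, 30.0, 100.0]
            if axis == "time"
            else [4, 7, 12, 20, 34, 58, 100]
        )
    pts = np.asarray(sorted(grid_points), dtype=float)
    ss = np.random.SeedSequence(seed)
    records: dict[tuple[str, float], np.ndarray] = {}
    all_rows: dict[float, pd.DataFrame] = {}
    counter = 0
    for g in pts:
        if axis == "time":
            params = replace(base_params, T=float(g))
        else:
            params = replace(base_params, N=int(g))
        rows = []
        for _ in range(n_realizations):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=ss.entropy, spawn_key=(counter,))
            )
            counter += 1
            train = generate_train(params, rng)
            rows.append(measure_vector(train, which=measure_set))
        all_rows[g] = pd.DataFrame(rows)
    largest = pts[-1]
    s_hat = all_rows[largest].mean(skipna=True)
    stats_rows = {}
    for g in pts:
        df = all_rows[g]
        for meas in df.columns:
            stats_rows[(meas, g)] = eq13_stats(
                df[meas].to_numpy(), float(s_hat[meas])
            )
    stats = pd.DataFrame(stats_rows).T
    stats.index.names = ["measure", "point"]
    return BiasVariabilityResult(
        axis=axis,
        grid_points=pts,
        n_realizations=n_realizations,
        stats=stats,
        s_hat=s_hat,
    )


def zscored_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing entries per measure, then z-score each measure
    across data items (zero-variance columns collapse to 0).

    The rows of the result are the data items (trains or windows) as points
    in the standardized measure space — the cloud whose geometry the
    intrinsic-dimension estimators probe.
    """
    filled = values.fillna(values.median(skipna=True)).fillna(0.0)
    sd = filled.std().replace(0, np.nan)
    z = (filled - filled.mean()) / sd
    return z.fillna(0.0)


def measure_point_cloud(values: pd.DataFrame) -> np.ndarray:
    """Measures-as-points view: each row is one measure's z-scored profile
    over the data items (the transpose of :func:`zscored_matrix`)."""
    return zscored_matrix(values).to_numpy(dtype=float).T


def intermatrix_correlation(D1: pd.DataFrame, D2: pd.DataFrame) -> float:
    """Pearson correlation of the vectorized upper triangles of two
    inter-measure distance matrices over entries finite in both."""
    common = [c for c in D1.columns if c in set(D2.columns)]
    if len(common) < 3:
        raise ValueError("distance matrices share fewer than 3 measures")
    if len(common) < len(D1.columns) or len(common) < len(D2.columns):
        D1 = D1.loc[common, common]
        D2 = D2.loc[common, common]
    if list(D1.columns) != list(D2.columns):
        D2 = D2.loc[D1.index, D1.columns]
    iu = np.triu_indices(len(common), k=1)
    v1 = D1.to_numpy()[iu]
    v2 = D2.to_numpy()[iu]
    ok = np.isfinite(v1) & np.isfinite(v2)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 comparable entries")
    return float(np.corrcoef(v1[ok], v2[ok])[0, 1])
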