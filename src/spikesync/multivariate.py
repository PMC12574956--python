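"""Multivariate measures: one scalar per multineuron spike train.

S_TS  pooled-train synchrony: (CV of pooled ISIs - 1)/sqrt(N); ~0 for
      asynchronous Poisson populations, ~1 for full synchrony.
S_GR  Golomb–Rinzel chi: sqrt of the ratio between the variance of the
      population-averaged smoothed rate and the mean single-neuron variance;
      1/sqrt(N) for independent units, 1 for identical ones.  The Gaussian
      smoothing width is the measure's timescale.
S_S   SPIKE-synchronization: fraction of spikes with an adaptive-window
      coincident partner, averaged over all pairs.
F_S   synfire indicator: mean signed delay asymmetry over ordered pairs
      under the leader-to-follower ordering that maximizes it.
S_C   Spike-contrast: maximum over bin scales of contrast x active-neuron
      fraction of the pooled spike histogram.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import _kernels as K

__all__ = [
    "MULTIVARIATE_FREE_NAMES",
    "tiesinga_sejnowski",
    "golomb_rinzel",
    "spike_synchronization",
    "synfire_indicator",
    "synfire_indicator_from_lead",
    "spike_contrast",
]

MULTIVARIATE_FREE_NAMES = ("S_TS", "S_S", "F_S", "S_C")  # S_GR is tau-dependent

_BIG = 1e9


def _clean(trains) -> list[np.ndarray]:
    return [np.ascontiguousarray(np.asarray(s, float)) for s in trains]


def tiesinga_sejnowski(trains, T: float) -> float:
    spikes = _clean(trains)
    N = len(spikes)
    pooled = np.sort(np.concatenate(spikes)) if N else np.empty(0)
    if N < 2 or pooled.size < 3:
        return np.nan
    isi = np.diff(pooled)
    mean = isi.mean()
    if mean <= 0:
        return np.nan
    cv = isi.std(ddof=1) / mean
    return float((cv - 1.0) / math.sqrt(N))


def golomb_rinzel(trains, T: float, taus, dt_grid: float = 5e-4) -> np.ndarray:
    """chi(tau) for each smoothing width tau (seconds).

    The grid step adapts to the timescale (at most tau/4, never finer than
    ``dt_grid``) so the Gaussian kernel always spans a few samples without
    making wide kernels needlessly expensive.
    """
    spikes = _clean(trains)
    taus = np.atleast_1d(np.asarray(taus, float))
    N = len(spikes)
    if N < 2 or sum(s.size for s in spikes) == 0:
        return np.full(taus.size, np.nan)
    out = np.empty(taus.size)
    for k, tau in enumerate(taus):
        dt = max(dt_grid, tau / 4.0)
        n_grid = max(2, int(round(T / dt)))
        counts = np.zeros((N, n_grid))
        for i, s in enumerate(spikes):
            idx = np.minimum((s / dt).astype(np.int64), n_grid - 1)
            np.add.at(counts[i], idx, 1.0)
        sig = gaussian_filter1d(counts, sigma=tau / dt, axis=1, mode="reflect")
        var_each = sig.var(axis=1)
        denom = var_each.mean()
        out[k] = math.sqrt(sig.mean(axis=0).var() / denom) if denom > 0 else np.nan
    return out


def spike_synchronization(trains, T: float) -> float:
    spikes = _clean(trains)
    N = len(spikes)
    num = 0
    den = 0
    for i in range(N):
        for j in range(i + 1, N):
            a, b = spikes[i], spikes[j]
            if a.size == 0 and b.size == 0:
                continue
            if a.size and b.size:
                ca, cb = K.spike_sync_counts(a, b, _BIG)
                num += ca + cb
            den += a.size + b.size
    return num / den if den else np.nan


def synfire_indicator_from_lead(lead: np.ndarray, exact_max_n: int = 8) -> float:
    """Optimal-ordering mean of an antisymmetric lead matrix.

    ``lead[i, j] > 0`` means neuron i tends to fire before neuron j.  Exact
    search over orderings for N <= ``exact_max_n``; row-sum seriation
    heuristic above that.
    """
    N = lead.shape[0]
    if N < 2:
        return np.nan
    L = np.where(np.isnan(lead), 0.0, lead)
    if N <= exact_max_n:
        best = -np.inf
        for perm in itertools.permutations(range(N)):
            s = sum(L[perm[p], perm[q]] for p in range(N) for q in range(p + 1, N))
            if s > best:
                best = s
    else:
        order = np.argsort(-L.sum(axis=1), kind="stable")
        sub = L[np.ix_(order, order)]
        best = np.triu(sub, 1).sum()
    return float(best / (N * (N - 1) / 2.0))


def synfire_indicator(trains, T: float) -> float:
    """F_S computed directly from spike trains (adaptive delay asymmetry)."""
    spikes = _clean(trains)
    N = len(spikes)
    lead = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            a, b = spikes[i], spikes[j]
            if a.size == 0 or b.size == 0:
                continue
            c_ab, c_ba = K.qq_adaptive_counts(a, b, _BIG)
            q = (c_ba - c_ab) / math.sqrt(a.size * b.size)  # >0: i leads j
            lead[i, j] = q
            lead[j, i] = -q
    return synfire_indicator_from_lead(lead)


def spike_contrast(trains, T: float, min_bin: float = 0.001) -> float:
    """Maximum over bin scales of contrast x active-fraction.

    Half-overlapping bins of width dt are swept from T/2 downwards by factors
    of 2 until ``min_bin``.
    """
    spikes = _clean(trains)
    N = len(spikes)
    total = sum(s.size for s in spikes)
    if N < 2 or total == 0:
        return np.nan
    best = 0.0
    dt = T / 2.0
    while dt >= min_bin:
        half = dt / 2.0
        n_half = int(math.ceil(T / half)) + 1
        pooled_half = np.zeros(n_half)
        active_half = np.zeros((N, n_half), dtype=bool)
        for i, s in enumerate(spikes):
            idx = np.minimum((s / half).astype(np.int64), n_half - 1)
            np.add.at(pooled_half, idx, 1.0)
            active_half[i, idx] = True
        theta = pooled_half[:-1] + pooled_half[1:]  # width-dt bins, step dt/2
        n_act = (active_half[:, :-1] | active_half[:, 1:]).sum(axis=0)
        tsum = theta.sum()
        if tsum > 0:
            contrast = np.abs(np.diff(theta)).sum() / (2.0 * tsum)
            active = ((theta * n_act).sum() / tsum - 1.0) / (N - 1) if N > 1 else 0.0
            best = max(best, contrast * max(active, 0.0))
        dt /= 2.0
    return float(best)
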