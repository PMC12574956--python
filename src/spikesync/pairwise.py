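"""Bivariate spike-train measures.

Each measure compares two single-neuron spike trains over a common window
[0, T).  Eleven measures are timescale-dependent (coincidence window, kernel
width, bin, or cost rate tau); eleven are timescale-free.  See
docs/methods.md for the exact conventions adopted where the original
publications leave choices open.

The module exposes a one-measure-at-a-time API (:func:`bivariate_measure`)
and the batch precompute/evaluate path used by
:func:`spikesync.measures.measure_vector`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K

__all__ = [
    "BIVARIATE_TAU_NAMES",
    "BIVARIATE_FREE_NAMES",
    "bivariate_measure",
    "TrainPre",
    "precompute_train",
    "pair_values",
]

#: timescale-dependent bivariate measures (window/kernel/cost timescale tau)
BIVARIATE_TAU_NAMES = (
    "STTC",   # spike time tiling coefficient
    "C_i",    # correlation index
    "D_VP",   # Victor–Purpura distance, shift cost 2|dt|/tau
    "D_VPN",  # VP normalized by total spike count
    "D_vR",   # van Rossum distance, exponential kernel decay tau
    "D_vRn",  # van Rossum normalized by sqrt(total spike count)
    "C_S",    # Schreiber correlation (Gaussian-filtered inner product)
    "C_K",    # Kruskal correlation (Pearson r of Gaussian-filtered rates)
    "S_HM",   # Hunter–Milton similarity
    "S_QQ",   # Quian Quiroga event synchronization
    "S_qq",   # Quian Quiroga delay asymmetry (antisymmetric)
)

#: timescale-free bivariate measures
BIVARIATE_FREE_NAMES = (
    "MPC",    # mean phase coherence (Kuramoto order parameter of spike phases)
    "PPC",    # pairwise phase consistency (unbiased MPC^2)
    "D_ISI",  # ISI-distance
    "D_S",    # SPIKE-distance
    "S_QQA",  # adaptive-timescale event synchronization
    "S_qqa",  # adaptive-timescale delay asymmetry (antisymmetric)
    "D_LZ",   # Lempel–Ziv distance on refractory-width binary words
    "D_EMD",  # earth mover's distance, mass = mean spike count
    "D_EMDN", # earth mover's distance of normalized distributions
    "D_MM",   # modulus metric (integral of nearest-spike distance gap)
    "D_MMN",  # modulus metric normalized by window length
)

LZ_BIN_S = 0.004  # binarization bin for D_LZ: the neuronal refractory width
_BIG = 1e9        # "infinite" ISI stand-in for adaptive timescales


@dataclass
class TrainPre:
    """Per-train precomputations reused across all pairings of that train."""

    spikes: np.ndarray
    n: int
    exp_self: np.ndarray     # sum_ij exp(-|t_i-t_j|/tau), per tau
    gauss_self: np.ndarray   # sum_ij exp(-(t_i-t_j)^2/(4 tau^2)), per tau
    tiling: np.ndarray       # STTC tiling fraction, per tau
    word: np.ndarray         # binary word at LZ_BIN_S resolution
    lz: int                  # LZ production complexity of word


def _tiling_fraction(a: np.ndarray, tau: float, T: float) -> float:
    """Fraction of [0, T] lying within +-tau of a spike of ``a``."""
    if a.size == 0:
        return 0.0
    starts = np.clip(a - tau, 0.0, T)
    ends = np.clip(a + tau, 0.0, T)
    prev_end = np.concatenate(([0.0], ends[:-1]))
    return float(np.sum(np.maximum(ends - np.maximum(starts, prev_end), 0.0)) / T)


def _binary_word(a: np.ndarray, T: float) -> np.ndarray:
    n_bins = max(1, int(math.ceil(T / LZ_BIN_S)))
    word = np.zeros(n_bins, dtype=np.int64)
    idx = np.minimum((a / LZ_BIN_S).astype(np.int64), n_bins - 1)
    word[idx] = 1
    return word


def precompute_train(a: np.ndarray, T: float, taus: np.ndarray) -> TrainPre:
    a = np.ascontiguousarray(a, dtype=np.float64)
    word = _binary_word(a, T)
    return TrainPre(
        spikes=a,
        n=a.size,
        exp_self=K.exp_sum_multi(a, a, taus) if a.size else np.zeros(taus.size),
        gauss_self=K.gauss_sum_multi(a, a, taus) if a.size else np.zeros(taus.size),
        tiling=np.array([_tiling_fraction(a, t, T) for t in taus]),
        word=word,
        lz=int(K.lz_complexity(word)),
    )


def _sttc_term(p: float, t: float) -> float:
    den = 1.0 - p * t
    if abs(den) < 1e-12:
        return np.nan
    return (p - t) / den


def _phase_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(MPC, PPC) averaged over the two reference directions."""
    mpcs = []
    ppcs = []
    for x, y in ((a, b), (b, a)):
        sc, ss, n = K.phase_stats(x, y)
        if n >= 1:
            r2 = sc * sc + ss * ss
            mpcs.append(math.sqrt(r2) / n)
            if n >= 2:
                ppcs.append((r2 - n) / (n * (n - 1.0)))
    mpc = float(np.mean(mpcs)) if mpcs else np.nan
    ppc = float(np.mean(ppcs)) if ppcs else np.nan
    return mpc, ppc


def _lz_distance(pa: TrainPre, pb: TrainPre) -> float:
    cxy = K.lz_concat_complexity(pa.word, pb.word)
    cyx = K.lz_concat_complexity(pb.word, pa.word)
    den = max(pa.lz, pb.lz)
    if den == 0:
        return np.nan
    return max(cxy - pa.lz, cyx - pb.lz) / den


def pair_values(
    pa: TrainPre, pb: TrainPre, T: float, taus: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate all bivariate measures for one unordered pair.

    Returns (tau_block, free_block): tau_block has shape
    (len(BIVARIATE_TAU_NAMES), len(taus)); free_block has length
    len(BIVARIATE_FREE_NAMES).  Antisymmetric entries (S_qq, S_qqa) carry the
    sign of the ordered pair (pa, pb).
    """
    a, b = pa.spikes, pb.spikes
    na, nb = pa.n, pb.n
    nt = taus.size
    tau_block = np.full((len(BIVARIATE_TAU_NAMES), nt), np.nan)
    free = np.full(len(BIVARIATE_FREE_NAMES), np.nan)

    both = na > 0 and nb > 0
    if both:
        d_a = K.nearest_dists(a, b)
        d_b = K.nearest_dists(b, a)
        n_coinc = K.coincidence_multi(a, b, taus)
        e_ab = K.exp_sum_multi(a, b, taus)
        g_ab = K.gauss_sum_multi(a, b, taus)
        c_ab, c_ba = K.qq_counts_multi(a, b, taus)
        sqrt_n = math.sqrt(na * nb)

    qs = 2.0 / taus
    d_vp = K.vp_multi(a, b, qs)

    for k in range(nt):
        tau = taus[k]
        tau_block[2, k] = d_vp[k]
        tau_block[3, k] = d_vp[k] / (na + nb) if na + nb else np.nan
        e_aa, e_bb = pa.exp_self[k], pb.exp_self[k]
        d2 = 0.5 * (e_aa + e_bb - (2.0 * e_ab[k] if both else 0.0))
        tau_block[4, k] = math.sqrt(max(d2, 0.0))
        tau_block[5, k] = (
            tau_block[4, k] / math.sqrt(na + nb) if na + nb else np.nan
        )
        if not both:
            continue
        # STTC
        p_a = float(np.mean(d_a <= tau))
        p_b = float(np.mean(d_b <= tau))
        ta = _sttc_term(p_a, pb.tiling[k])
        tb = _sttc_term(p_b, pa.tiling[k])
        tau_block[0, k] = 0.5 * (ta + tb)
        # correlation index
        tau_block[1, k] = n_coinc[k] * T / (2.0 * tau * na * nb)
        # Schreiber / Kruskal correlations
        g_aa, g_bb = pa.gauss_self[k], pb.gauss_self[k]
        if g_aa > 0 and g_bb > 0:
            tau_block[6, k] = g_ab[k] / math.sqrt(g_aa * g_bb)
        norm = 2.0 * tau * math.sqrt(math.pi) * T
        va = g_aa / norm - (na / T) ** 2
        vb = g_bb / norm - (nb / T) ** 2
        if va > 0 and vb > 0:
            cov = g_ab[k] / norm - (na / T) * (nb / T)
            tau_block[7, k] = cov / math.sqrt(va * vb)
        # Hunter–Milton
        tau_block[8, k] = 0.5 * (
            float(np.mean(np.exp(-d_a / tau))) + float(np.mean(np.exp(-d_b / tau)))
        )
        # event synchronization
        tau_block[9, k] = (c_ab[k] + c_ba[k]) / sqrt_n
        tau_block[10, k] = (c_ab[k] - c_ba[k]) / sqrt_n

    # timescale-free block
    if both:
        free[0], free[1] = _phase_pair(a, b)
        ca, cb = K.qq_adaptive_counts(a, b, _BIG)
        free[4] = (ca + cb) / sqrt_n
        free[5] = (ca - cb) / sqrt_n
        w1 = K.w1_distance(a, b)
        free[7] = w1 * 0.5 * (na + nb)
        free[8] = w1
        mm = K.modulus_metric(a, b, T)
        free[9] = mm
        free[10] = mm / T
    free[2] = K.isi_distance(a, b, T)
    free[3] = K.spike_distance(a, b, T)
    free[6] = _lz_distance(pa, pb)
    return tau_block, free


def bivariate_measure(
    name: str, a: np.ndarray, b: np.ndarray, T: float, tau: float | None = None
) -> float:
    """Evaluate a single bivariate measure by name.

    ``tau`` (seconds) is required for the timescale-dependent measures and
    ignored for the rest.
    """
    a = np.ascontiguousarray(np.sort(np.asarray(a, dtype=float)))
    b = np.ascontiguousarray(np.sort(np.asarray(b, dtype=float)))
    if name in BIVARIATE_TAU_NAMES:
        if tau is None:
            raise ValueError(f"measure {name!r} requires a timescale tau")
        taus = np.array([float(tau)])
    elif name in BIVARIATE_FREE_NAMES:
        taus = np.array([0.001])  # unused placeholder
    else:
        raise KeyError(f"unknown bivariate measure {name!r}")
    pa = precompute_train(a, T, taus)
    pb = precompute_train(b, T, taus)
    tau_block, free = pair_values(pa, pb, T, taus)
    if name in BIVARIATE_TAU_NAMES:
        return float(tau_block[BIVARIATE_TAU_NAMES.index(name), 0])
    return float(free[BIVARIATE_FREE_NAMES.index(name)])
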