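"""Univariate measures of firing intensity and variability.

All nine measures operate on a single neuron's sorted spike times over a
window of length ``T``.  ISI-based statistics need at least 2 spikes (3 for
the pairwise-consecutive ones); entries that cannot be computed are NaN and
are skipped by the cross-neuron average.

Conventions where the originals leave a constant free (see docs/methods.md):
``LvR`` uses refractoriness constant R = 5 ms; the log-ISI entropy uses a
fixed histogram bin of 0.25 octaves (log2 units); ``IR`` and ``S_M`` use
natural logarithms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNIVARIATE_NAMES", "univariate_measures"]

UNIVARIATE_NAMES = (
    "r",
    "CV_ISI",
    "LCV_ISI",
    "CV2_ISI",
    "Lv",
    "LvR",
    "IR",
    "Ent",
    "S_M",
)

LVR_R = 0.005          # LvR refractoriness constant (s)
ENT_BIN_OCTAVES = 0.25  # log2-ISI histogram bin width


def _isis(spikes: np.ndarray) -> np.ndarray:
    return np.diff(spikes)


def univariate_measures(spikes: np.ndarray, T: float) -> dict[str, float]:
    """All nine univariate measures for one neuron.

    Returns a dict keyed by :data:`UNIVARIATE_NAMES`; unavailable entries
    (too few spikes) are NaN.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    spikes = np.asarray(spikes, dtype=float)
    out = {name: np.nan for name in UNIVARIATE_NAMES}
    out["r"] = spikes.size / T
    if spikes.size < 2:
        return out
    isi = _isis(spikes)
    isi = isi[isi > 0]
    if isi.size == 0:
        return out

    mean_isi = isi.mean()
    out["CV_ISI"] = isi.std(ddof=1) / mean_isi if isi.size > 1 else np.nan

    log_isi = np.log(isi)
    out["LCV_ISI"] = log_isi.std(ddof=1) if isi.size > 1 else np.nan

    # entropy of the log2-ISI histogram with fixed bin width
    bins_lo = np.floor(np.log2(isi).min() / ENT_BIN_OCTAVES)
    bins_hi = np.floor(np.log2(isi).max() / ENT_BIN_OCTAVES) + 1
    edges = np.arange(bins_lo, bins_hi + 1) * ENT_BIN_OCTAVES
    counts, _ = np.histogram(np.log2(isi), bins=edges)
    p = counts[counts > 0] / isi.size
    out["Ent"] = float(-(p * np.log2(p)).sum())

    if isi.size < 2:
        return out
    i1 = isi[:-1]
    i2 = isi[1:]
    s = i1 + i2
    out["CV2_ISI"] = float(np.mean(2.0 * np.abs(i2 - i1) / s))
    out["Lv"] = float(np.mean(3.0 * ((i1 - i2) / s) ** 2))
    out["LvR"] = float(
        np.mean(3.0 * (1.0 - 4.0 * i1 * i2 / s**2) * (1.0 + 4.0 * LVR_R / s))
    )
    out["IR"] = float(np.mean(np.abs(np.log(i2 / i1))))
    out["S_M"] = float(np.mean(-0.5 * np.log(4.0 * i1 * i2 / s**2)))
    return out
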