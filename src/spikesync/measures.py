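"""Measure registry and the per-train measure vector.

The *core* set holds 46 measures: 9 univariate, 11 timescale-free bivariate,
4 timescale-free multivariate, 10 spectral, and 12 timescale-dependent
measures (11 bivariate plus the Golomb–Rinzel chi) evaluated at tau = 1 ms.
The *extended* set expands the 12 timescale-dependent measures over 7
timescales logarithmically spaced between 1 and 64 ms and adds the 13
dual-peak spectral parameters, for 131 measures in total.

Averaging policy: univariate measures are computed per neuron and averaged
across neurons; bivariate measures are computed for every unordered pair of
non-identical neuron indices and averaged across pairs (the antisymmetric
delay-asymmetry measures are averaged signed over i < j); multivariate and
spectral measures are evaluated once per train.  Missing entries (too few
spikes, no significant spectral peak) are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .multivariate import (
    golomb_rinzel,
    spike_contrast,
    spike_synchronization,
    synfire_indicator_from_lead,
    tiesinga_sejnowski,
)
from .pairwise import (
    BIVARIATE_FREE_NAMES,
    BIVARIATE_TAU_NAMES,
    pair_values,
    precompute_train,
)
from .spectral import (
    SPECTRAL_CORE_NAMES,
    SPECTRAL_DUAL_NAMES,
    SpectralConfig,
    spectral_measures,
)
from .types import MultiNeuronSpikeTrain
from .univariate import UNIVARIATE_NAMES, univariate_measures

__all__ = [
    "TIMESCALES_MS",
    "CORE_TAU_MS",
    "MeasureSpec",
    "measure_specs",
    "measure_names",
    "measure_vector",
]

TIMESCALES_MS = (1, 2, 4, 8, 16, 32, 64)
CORE_TAU_MS = 1

MULTI_FREE = ("S_TS", "S_S", "F_S", "S_C")
TAU_DEP_NAMES = BIVARIATE_TAU_NAMES + ("S_GR",)


@dataclass(frozen=True)
class MeasureSpec:
    """A named measure: its label in the matrix, arity, and timescale."""

    name: str
    label: str
    arity: str  # univariate | bivariate | multivariate | spectral
    timescale_ms: Optional[int] = None
    objective: str = ""

    @property
    def timescale_dependent(self) -> bool:
        return self.timescale_ms is not None


_OBJECTIVE = {
    "r": "firing intensity",
    "CV_ISI": "firing variability", "LCV_ISI": "firing variability",
    "CV2_ISI": "firing variability", "Lv": "firing variability",
    "LvR": "firing variability", "IR": "firing variability",
    "Ent": "firing variability", "S_M": "firing variability",
    "MPC": "phase relationships", "PPC": "phase relationships",
    "STTC": "synchrony", "C_i": "synchrony",
    "D_ISI": "synchrony", "D_S": "synchrony",
    "S_QQ": "synchrony", "S_QQA": "synchrony",
    "S_qq": "delay asymmetry", "S_qqa": "delay asymmetry",
    "D_VP": "firing pattern distance", "D_VPN": "firing pattern distance",
    "D_vR": "firing pattern distance", "D_vRn": "firing pattern distance",
    "D_EMD": "firing pattern distance", "D_EMDN": "firing pattern distance",
    "D_MM": "firing pattern distance", "D_MMN": "firing pattern distance",
    "D_LZ": "firing pattern similarity", "C_S": "firing pattern similarity",
    "C_K": "firing pattern similarity", "S_HM": "firing pattern similarity",
    "S_TS": "synchrony", "S_GR": "synchrony", "S_S": "synchrony",
    "F_S": "sequential structure", "S_C": "synchrony",
}


def measure_specs(which: str = "core") -> list[MeasureSpec]:
    """Ordered measure specifications for the core or extended set."""
    if which not in ("core", "extended"):
        raise ValueError("set must be 'core' or 'extended'")
    taus = (CORE_TAU_MS,) if which == "core" else TIMESCALES_MS
    specs: list[MeasureSpec] = []
    for n in UNIVARIATE_NAMES:
        specs.append(MeasureSpec(n, n, "univariate", objective=_OBJECTIVE[n]))
    for n in BIVARIATE_FREE_NAMES:
        specs.append(MeasureSpec(n, n, "bivariate", objective=_OBJECTIVE[n]))
    for n in MULTI_FREE:
        specs.append(MeasureSpec(n, n, "multivariate", objective=_OBJECTIVE[n]))
    for n in SPECTRAL_CORE_NAMES:
        specs.append(MeasureSpec(n, n, "spectral", objective="oscillations"))
    for tau in taus:
        for n in TAU_DEP_NAMES:
            arity = "multivariate" if n == "S_GR" else "bivariate"
            specs.append(
                MeasureSpec(n, f"{n}_{tau}ms", arity, timescale_ms=tau,
                            objective=_OBJECTIVE[n])
            )
    if which == "extended":
        for n in SPECTRAL_DUAL_NAMES:
            specs.append(MeasureSpec(n, n, "spectral", objective="oscillations"))
    return specs


def measure_names(which: str = "core") -> list[str]:
    return [s.label for s in measure_specs(which)]


def measure_vector(
    train: MultiNeuronSpikeTrain,
    which: str = "core",
    spectral_config: SpectralConfig = SpectralConfig(),
) -> pd.Series:
    """Evaluate the full measure set on one multineuron train."""
    specs = measure_specs(which)
    taus_ms = (CORE_TAU_MS,) if which == "core" else TIMESCALES_MS
    taus = np.asarray(taus_ms, dtype=float) / 1000.0
    T = train.T
    spikes = train.spikes
    N = train.N
    values: dict[str, float] = {}

    # univariate, averaged across neurons
    uni = pd.DataFrame([univariate_measures(s, T) for s in spikes])
    for n in UNIVARIATE_NAMES:
        col = uni[n]
        values[n] = float(col.mean()) if col.notna().any() else np.nan

    # bivariate, averaged across unordered pairs
    pre = [precompute_train(s, T, taus) for s in spikes]
    n_tau_meas = len(BIVARIATE_TAU_NAMES)
    tau_sum = np.zeros((n_tau_meas, taus.size))
    tau_cnt = np.zeros((n_tau_meas, taus.size))
    free_sum = np.zeros(len(BIVARIATE_FREE_NAMES))
    free_cnt = np.zeros(len(BIVARIATE_FREE_NAMES))
    lead = np.zeros((N, N))
    i_qqa = BIVARIATE_FREE_NAMES.index("S_qqa")
    for i in range(N):
        for j in range(i + 1, N):
            tb, fb = pair_values(pre[i], pre[j], T, taus)
            ok = np.isfinite(tb)
            tau_sum[ok] += tb[ok]
            tau_cnt += ok
            okf = np.isfinite(fb)
            free_sum[okf] += fb[okf]
            free_cnt += okf
            if np.isfinite(fb[i_qqa]):
                lead[i, j] = -fb[i_qqa]  # S_qqa > 0: i follows j
                lead[j, i] = fb[i_qqa]
    with np.errstate(invalid="ignore"):
        tau_mean = np.where(tau_cnt > 0, tau_sum / np.maximum(tau_cnt, 1), np.nan)
        free_mean = np.where(free_cnt > 0, free_sum / np.maximum(free_cnt, 1), np.nan)
    for idx, n in enumerate(BIVARIATE_FREE_NAMES):
        values[n] = float(free_mean[idx])
    for k, tau_ms in enumerate(taus_ms):
        for idx, n in enumerate(BIVARIATE_TAU_NAMES):
            values[f"{n}_{tau_ms}ms"] = float(tau_mean[idx, k])

    # multivariate
    values["S_TS"] = tiesinga_sejnowski(spikes, T)
    values["S_S"] = spike_synchronization(spikes, T)
    values["F_S"] = synfire_indicator_from_lead(lead) if N >= 2 else np.nan
    values["S_C"] = spike_contrast(spikes, T)
    chi = golomb_rinzel(spikes, T, taus)
    for k, tau_ms in enumerate(taus_ms):
        values[f"S_GR_{tau_ms}ms"] = float(chi[k])

    # spectral
    values.update(
        spectral_measures(spikes, T, config=spectral_config,
                          dual=(which == "extended"))
    )

    out = pd.Series({s.label: values[s.label] for s in specs}, dtype=float)
    return out
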