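"""Core containers: generator parameter sets and the multineuron spike train.

All spike times are double-precision seconds on the half-open window [0, T).
Neuron indexing is 0-based in storage; the sequential-offset formulas use the
1-based index j = storage index + 1, with j = 1 the most phase-advanced
("leader") neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "OUNoiseParams",
    "SingleScaleParams",
    "DualScaleParams",
    "GenerationTrace",
    "MultiNeuronSpikeTrain",
]


@dataclass(frozen=True)
class OUNoiseParams:
    """Ornstein–Uhlenbeck phase-noise parameters.

    tau_OU   autocorrelation time constant (s)
    sigma_OU stationary standard deviation (rad)
    dt       simulation step (s); must be small compared to tau_OU
    """

    tau_OU: float = 0.010
    sigma_OU: float = 0.0
    dt: float = 1e-5

    def __post_init__(self) -> None:
        if self.tau_OU <= 0:
            raise ValueError(f"tau_OU must be positive, got {self.tau_OU}")
        if self.sigma_OU < 0:
            raise ValueError(f"sigma_OU must be non-negative, got {self.sigma_OU}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")


def default_ou(f0: float, dt: float = 1e-5) -> OUNoiseParams:
    """OU noise with the benchmark defaults: tau = 10 ms, sigma = 0.4*pi*f0/1000 rad."""
    return OUNoiseParams(tau_OU=0.010, sigma_OU=0.4 * np.pi * f0 / 1000.0, dt=dt)


@dataclass(frozen=True)
class SingleScaleParams:
    """Parameters of the inhomogeneous-Poisson (single-scale) generator."""

    r0: float = 8.0            # mean firing rate (Hz)
    m: float = 0.5             # modulation amplitude in [0, 1]
    f0: float = 12.0           # modulation frequency (Hz)
    rhythmic: bool = True      # pseudo-rhythmic (linear phase) vs non-rhythmic
    Dc: float = 0.0            # duty cycle in [0, 1); 0 means non-sequential
    N: int = 100               # neuron count
    T: float = 10.0            # duration (s)
    t_refr_neu: float = 0.004  # neuronal refractory period (s)
    t_refr_pop: Optional[float] = None  # defaults to 0.1/(2*f0)
    ou: Optional[OUNoiseParams] = None  # defaults to default_ou(f0)
    phi_ic: Optional[float] = None      # initial phase (rad); None -> drawn per train

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValueError("r0 must be non-negative")
        if not 0 <= self.m <= 1:
            raise ValueError("m must lie in [0, 1]")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not 0 <= self.Dc < 1:
            raise ValueError("Dc must lie in [0, 1)")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def t_refr_pop_(self) -> float:
        return 0.1 / (2.0 * self.f0) if self.t_refr_pop is None else self.t_refr_pop

    @property
    def ou_(self) -> OUNoiseParams:
        return default_ou(self.f0) if self.ou is None else self.ou


@dataclass(frozen=True)
class DualScaleParams:
    """Parameters of the doubly stochastic (dual-scale) generator.

    Spikes are Gaussian-jittered copies of population events; Sigma is the
    Gaussian width expressed as a fraction of the mean inter-event interval
    1/f0, so the jitter SD is sigma = Sigma/f0 seconds.
    """

    f0: float = 12.0           # population event rate (Hz)
    Sigma: float = 0.2         # Gaussian width, fraction of mean IEI
    p_fail: float = 0.0        # independent spike deletion probability
    rhythmic: bool = True
    Dc: float = 0.0
    N: int = 100
    T: float = 10.0
    t_refr_neu: float = 0.004
    t_refr_pop: Optional[float] = None
    ou: Optional[OUNoiseParams] = None
    phi_thr: float = np.pi / 2  # reference phase for event detection (rad)

    def __post_init__(self) -> None:
        if self.Sigma <= 0:
            raise ValueError("Sigma must be positive")
        if not 0 <= self.p_fail <= 1:
            raise ValueError("p_fail must lie in [0, 1]")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not 0 <= self.Dc < 1:
            raise ValueError("Dc must lie in [0, 1)")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def sigma(self) -> float:
        """Jitter SD in seconds."""
        return self.Sigma / self.f0

    @property
    def t_refr_pop_(self) -> float:
        return 0.1 / (2.0 * self.f0) if self.t_refr_pop is None else self.t_refr_pop

    @property
    def ou_(self) -> OUNoiseParams:
        return default_ou(self.f0) if self.ou is None else self.ou


@dataclass
class GenerationTrace:
    """Optional record of the latent processes behind a synthetic train."""

    phase_noise: Optional[np.ndarray] = None        # OU series phi_n(t)
    piecewise_phase: Optional[np.ndarray] = None    # unwrapped phi_plp(t)
    node_times: Optional[np.ndarray] = None         # t_i^n of the phase process
    inter_node_intervals: Optional[np.ndarray] = None
    population_events: Optional[np.ndarray] = None  # t_i^pop
    inter_event_intervals: Optional[np.ndarray] = None
    jitters: Optional[np.ndarray] = None            # Delta_{i,j}, events x neurons
    lambda_: Optional[float] = None                 # refractory-exponential rate


@dataclass
class MultiNeuronSpikeTrain:
    """N sorted per-neuron spike-time arrays over [0, T)."""

    spikes: list[np.ndarray]
    T: float
    meta: dict = field(default_factory=dict)
    trace: Optional[GenerationTrace] = None

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for i, s in enumerate(self.spikes):
            if s.size and (s[0] < 0 or s[-1] >= self.T):
                raise ValueError(f"neuron {i}: spike times must lie in [0, T)")
            if s.size > 1 and np.any(np.diff(s) < 0):
                raise ValueError(f"neuron {i}: spike times must be sorted")

    @property
    def N(self) -> int:
        return len(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(s.size for s in self.spikes))

    def pooled(self) -> np.ndarray:
        """All spikes of all neurons, sorted."""
        if not self.spikes:
            return np.empty(0)
        return np.sort(np.concatenate(self.spikes))

    def window(self, start: float, stop: float) -> "MultiNeuronSpikeTrain":
        """Restrict to [start, stop) and shift times to start at 0."""
        sub = [s[(s >= start) & (s < stop)] - start for s in self.spikes]
        return MultiNeuronSpikeTrain(sub, T=stop - start, meta=dict(self.meta))
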