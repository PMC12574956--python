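"""Synthetic multineuron spike-train generators with controlled ground truth.

Two generative families are provided:

* **single-scale** — inhomogeneous Poisson processes whose instantaneous rate
  is a sinusoid of a phase variable.  Pseudo-rhythmic trains use a linear
  phase ``2*pi*f0*t`` perturbed by Ornstein–Uhlenbeck (OU) noise; non-rhythmic
  trains use a piecewise-linear phase whose inter-node intervals follow a
  refractory exponential distribution.  Synchrony is controlled by the
  modulation amplitude ``m``.

* **dual-scale** — a doubly stochastic hierarchy: population events are drawn
  first (phase crossings for pseudo-rhythmic trains, a refractory exponential
  renewal process for non-rhythmic ones) and each neuron then emits one
  Gaussian-jittered spike per event, with independent deletion probability
  ``p_fail``.  Synchrony tightness is controlled by the jitter width ``Sigma``
  (a fraction of the mean inter-event interval ``1/f0``).

Both families support sequential structure via the duty cycle ``Dc``: neuron
``j`` receives a phase offset (single-scale) or a time bias (dual-scale) that
progresses linearly from leader (j = 1) to follower (j = N).  ``Dc = 0``
reproduces the non-sequential case bit-for-bit under the same seed.

Rates are realized by per-step Bernoulli sampling with probability
``r(t)*dt`` on a ``dt = 0.01 ms`` grid, followed by enforcement of a
neuronal refractory period (default 4 ms).
"""

from __future__ import annotations

import math
from typing import Iterable, Union

import numpy as np
from scipy.signal import lfilter

from ._kernels import enforce_refractory
from .types import (
    DualScaleParams,
    GenerationTrace,
    MultiNeuronSpikeTrain,
    OUNoiseParams,
    SingleScaleParams,
)

__all__ = [
    "sample_ou_phase_noise",
    "sample_refractory_exponential",
    "generate_single_scale",
    "generate_dual_scale",
    "generate_train",
    "build_benchmark_grid",
]

Params = Union[SingleScaleParams, DualScaleParams]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _ou_series(ou: OUNoiseParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact-discretization OU series of length ``n`` started at 0.

    The transition is the exact one for the OU process: phi(t+dt) is normal
    with mean ``phi(t)*exp(-dt/tau)`` and SD ``sigma*sqrt(1-exp(-2*dt/tau))``.
    """
    if n < 1:
        return np.empty(0)
    a = math.exp(-ou.dt / ou.tau_OU)
    s = ou.sigma_OU * math.sqrt(1.0 - a * a)
    if s == 0.0:
        return np.zeros(n)
    w = rng.normal(0.0, s, size=n - 1)
    out = np.empty(n)
    out[0] = 0.0
    # AR(1) recursion x[k] = a*x[k-1] + w[k] via an IIR filter
    out[1:] = lfilter([1.0], [1.0, -a], w)
    return out


def sample_ou_phase_noise(ou: OUNoiseParams, T: float, seed=None) -> np.ndarray:
    """Sample the OU phase-noise series on the grid 0, dt, ..., ceil(T/dt)*dt."""
    if T <= 0:
        raise ValueError("T must be positive")
    n = int(math.ceil(T / ou.dt)) + 1
    return _ou_series(ou, n, _rng(seed))


def sample_refractory_exponential(
    lambda_: float, t_refr: float, n: int, seed=None
) -> np.ndarray:
    """Draw ``n`` intervals from a shifted (refractory) exponential.

    Intervals are ``t_refr + Exp(lambda_)``: the density is
    ``lambda_*exp(-lambda_*(x - t_refr))`` for ``x >= t_refr`` and 0 below.
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    if t_refr < 0:
        raise ValueError("t_refr must be non-negative")
    if n <= 0:
        raise ValueError("n must be positive")
    return t_refr + _rng(seed).exponential(1.0 / lambda_, size=n)


def _plp_nodes(
    lambda_: float,
    t_refr_pop: float,
    T: float,
    N: int,
    Dc: float,
    rng: np.random.Generator,
):
    """Node times of the piecewise-linear-phase process for each neuron.

    Returns (node_times, inis) where node_times has shape (n_nodes, N); column
    j holds the nodes of neuron j (already including the sequential
    compression of the leader-to-follower progression).  With ``Dc = 0`` all
    columns are identical.
    """
    mean_ini = t_refr_pop + 1.0 / lambda_
    n_draw = max(8, int(math.ceil(1.5 * T / mean_ini)) + 8)
    inis = sample_refractory_exponential(lambda_, t_refr_pop, n_draw, rng)
    while t_refr_pop - inis[0] + np.sum(inis[1:]) < T + 2 * mean_ini:
        inis = np.concatenate([inis, sample_refractory_exponential(lambda_, t_refr_pop, n_draw, rng)])
    # base times b_i = t_{i,N}; one cycle starts before 0 so every neuron has
    # a node at or below t = 0
    b = np.concatenate(([-inis[0]], -inis[0] + np.cumsum(inis)))
    if N > 1:
        j = np.arange(1, N + 1)
        c = 1.0 - Dc * (N - j) / (N - 1)
    else:
        c = np.ones(1)
    # t_{i+1, j} = b_i + INI_i * c_j
    nodes = b[:-1, None] + inis[: b.size - 1, None] * c[None, :]
    nodes = np.vstack([b[0] * np.ones((1, N)), nodes])
    return nodes, inis


def generate_single_scale(p: SingleScaleParams, seed=None) -> MultiNeuronSpikeTrain:
    """Generate a single-scale (inhomogeneous Poisson) multineuron train."""
    rng = _rng(seed)
    dt = p.ou_.dt
    n_steps = int(round(p.T / dt))
    t = np.arange(n_steps) * dt
    trace = GenerationTrace()

    peak = p.r0 * (1.0 + p.m) * dt
    if peak > 1.0:
        raise ValueError(
            f"r(t)*dt reaches {peak:.3g} > 1; rate too high for the simulation step"
        )

    if p.N > 1:
        jj = np.arange(1, p.N + 1)
        rel = (jj - 1) / (p.N - 1)
    else:
        rel = np.zeros(1)

    if p.rhythmic:
        phi_n = _ou_series(p.ou_, n_steps, rng)
        trace.phase_noise = phi_n
        theta = 2.0 * np.pi * p.f0 * t + phi_n
        sin_t = np.sin(theta)
        cos_t = np.cos(theta) if p.Dc > 0 else None
        phi_j = 2.0 * np.pi * p.Dc * (0.5 - rel)
        base_thr = (p.r0 * dt) * (1.0 + p.m * sin_t) if p.Dc == 0 else None

        def rate_of(j: int) -> np.ndarray:
            if p.Dc == 0:
                return base_thr
            s = sin_t * math.cos(phi_j[j]) + cos_t * math.sin(phi_j[j])
            return (p.r0 * dt) * (1.0 + p.m * s)

    else:
        lam = 2.0 * p.f0 * math.exp(p.t_refr_pop_ * 2.0 * p.f0)
        nodes, inis = _plp_nodes(lam, p.t_refr_pop_, p.T, p.N, p.Dc, rng)
        phi_ic = rng.uniform(0.0, 2.0 * np.pi) if p.phi_ic is None else p.phi_ic
        # unwrapped phase climbs by pi per node: phi(t_{i,j}) = i*pi - pi/2
        phase_at_nodes = np.arange(nodes.shape[0]) * np.pi - np.pi / 2.0
        trace.node_times = nodes[:, -1]
        trace.inter_node_intervals = inis
        trace.lambda_ = lam

        shared_thr = None

        def rate_of(j: int) -> np.ndarray:
            nonlocal shared_thr
            if p.Dc == 0 and shared_thr is not None:
                return shared_thr
            phi = np.interp(t, nodes[:, j], phase_at_nodes)
            if j == 0:
                trace.piecewise_phase = phi
            thr = (p.r0 * dt) * (1.0 + p.m * np.sin(phi + phi_ic))
            if p.Dc == 0:
                shared_thr = thr
            return thr

    spikes = []
    for j in range(p.N):
        thr_j = rate_of(j)
        u = rng.random(n_steps)
        times = t[u < thr_j]
        spikes.append(enforce_refractory(times, p.t_refr_neu))

    meta = {
        "family": "single",
        "r0": p.r0,
        "m": p.m,
        "f0": p.f0,
        "rhythmic": p.rhythmic,
        "Dc": p.Dc,
        "sequential": p.Dc > 0,
        "N": p.N,
        "T": p.T,
    }
    return MultiNeuronSpikeTrain(spikes, T=p.T, meta=meta, trace=trace)


def _rhythmic_events(p: DualScaleParams, rng: np.random.Generator) -> np.ndarray:
    """Population events: upward crossings of (2*pi*f0*t + phi_n) mod 2*pi
    through the reference phase, separated by at least t_refr_pop."""
    dt = p.ou_.dt
    n_steps = int(round(p.T / dt))
    t = np.arange(n_steps) * dt
    phi = 2.0 * np.pi * p.f0 * t + _ou_series(p.ou_, n_steps, rng)
    cyc = np.floor((phi - p.phi_thr) / (2.0 * np.pi))
    up = np.flatnonzero(np.diff(cyc) > 0) + 1
    if up.size == 0:
        return np.empty(0)
    cand = t[up]
    keep = enforce_refractory(cand, p.t_refr_pop_, strict=False)
    return keep


def generate_dual_scale(p: DualScaleParams, seed=None) -> MultiNeuronSpikeTrain:
    """Generate a dual-scale (doubly stochastic event-then-jitter) train."""
    rng = _rng(seed)
    trace = GenerationTrace()

    if p.rhythmic:
        events = _rhythmic_events(p, rng)
    else:
        lam = p.f0 * math.exp(p.t_refr_pop_ * p.f0)
        mean_iei = p.t_refr_pop_ + 1.0 / lam
        n_draw = max(8, int(math.ceil(1.5 * p.T / mean_iei)) + 8)
        ieis = sample_refractory_exponential(lam, p.t_refr_pop_, n_draw, rng)
        while np.sum(ieis) < p.T:
            ieis = np.concatenate(
                [ieis, sample_refractory_exponential(lam, p.t_refr_pop_, n_draw, rng)]
            )
        events = np.cumsum(ieis)
        events = events[events < p.T]
        trace.inter_event_intervals = ieis
        trace.lambda_ = lam
    trace.population_events = events

    n_ev = events.size
    sigma = p.sigma
    if p.N > 1:
        rel = (np.arange(1, p.N + 1) - 1) / (p.N - 1)
    else:
        rel = np.zeros(1)
    bias = (p.Dc / p.f0) * (rel - 0.5)  # zero when Dc == 0

    jit = rng.normal(0.0, sigma, size=(n_ev, p.N)) if n_ev else np.zeros((0, p.N))
    trace.jitters = jit
    drop = rng.random(size=(n_ev, p.N)) < p.p_fail if n_ev else np.zeros((0, p.N), bool)

    spikes = []
    for j in range(p.N):
        tj = events + bias[j] + jit[:, j]
        tj = tj[~drop[:, j]]
        tj = tj[(tj >= 0) & (tj < p.T)]
        tj.sort()
        spikes.append(enforce_refractory(tj, p.t_refr_neu))

    meta = {
        "family": "dual",
        "Sigma": p.Sigma,
        "p_fail": p.p_fail,
        "f0": p.f0,
        "rhythmic": p.rhythmic,
        "Dc": p.Dc,
        "sequential": p.Dc > 0,
        "N": p.N,
        "T": p.T,
    }
    return MultiNeuronSpikeTrain(spikes, T=p.T, meta=meta, trace=trace)


def generate_train(params: Params, seed=None) -> MultiNeuronSpikeTrain:
    """Dispatch on the parameter type."""
    if isinstance(params, SingleScaleParams):
        return generate_single_scale(params, seed)
    if isinstance(params, DualScaleParams):
        return generate_dual_scale(params, seed)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


# Benchmark grid (Cartesian parameter products of the two families)

R0_GRID = (1.0, 4.0, 8.0, 12.0, 36.0)
M_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
SIGMA_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)
PFAIL_GRID = (0.0, 0.2, 0.4, 0.6, 0.8)
F0_GRID = (4.0, 12.0, 36.0)
DC_GRID = (0.0, 0.2, 0.4)


def build_benchmark_grid(N: int = 100, T: float = 10.0) -> list[tuple[str, Params]]:
    """The full 900-train benchmark grid.

    450 single-scale trains (r0 x m x f0 x rhythmicity x Dc) and 450
    dual-scale trains (Sigma x p_fail x f0 x rhythmicity x Dc); Dc = 0 rows
    are the non-sequential members (150 per family), Dc in {0.2, 0.4} the
    sequential ones (300 per family).  ``N`` and ``T`` default to the
    benchmark values (100 neurons, 10 s) and may be overridden to scale the
    grid down without changing its size.
    """
    grid: list[tuple[str, Params]] = []
    for Dc in DC_GRID:
        for rhythmic in (True, False):
            for r0 in R0_GRID:
                for m in M_GRID:
                    for f0 in F0_GRID:
                        grid.append(
                            (
                                "single",
                                SingleScaleParams(
                                    r0=r0, m=m, f0=f0, rhythmic=rhythmic, Dc=Dc, N=N, T=T
                                ),
                            )
                        )
    for Dc in DC_GRID:
        for rhythmic in (True, False):
            for Sigma in SIGMA_GRID:
                for p_fail in PFAIL_GRID:
                    for f0 in F0_GRID:
                        grid.append(
                            (
                                "dual",
                                DualScaleParams(
                                    Sigma=Sigma,
                                    p_fail=p_fail,
                                    f0=f0,
                                    rhythmic=rhythmic,
                                    Dc=Dc,
                                    N=N,
                                    T=T,
                                ),
                            )
                        )
    return grid


def generate_grid(
    grid: Iterable[tuple[str, Params]], seed: int
) -> list[MultiNeuronSpikeTrain]:
    """Generate every train of a grid, with per-train child seeds spawned
    from one master seed so trains are independent and reproducible."""
    ss = np.random.SeedSequence(seed)
    trains = []
    for i, (_family, params) in enumerate(grid):
        child = np.random.default_rng(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i,)))
        tr = generate_train(params, child)
        tr.meta["grid_index"] = i
        trains.append(tr)
    return trains
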