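import numpy as np
import pytest

from spikesync import MultiNeuronSpikeTrain


def poisson_train(rate, T, rng, refractory=0.0):
    """Homogeneous Poisson spike times, optionally with a dead time."""
    k = max(1, rng.poisson(rate * T))
    t = np.sort(rng.uniform(0.0, T, size=k))
    if refractory > 0 and t.size:
        keep = [t[0]]
        for x in t[1:]:
            if x - keep[-1] > refractory:
                keep.append(x)
        t = np.asarray(keep)
    return t


def poisson_population(n_neurons, rate, T, rng, refractory=0.0):
    return MultiNeuronSpikeTrain(
        [poisson_train(rate, T, rng, refractory) for _ in range(n_neurons)], T=T
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_matrix():
    """Extended measure matrix of the full 900-train grid at reduced scale
    (N = 20 neurons, T = 10 s), shared across the geometry tests."""
    from spikesync.evalbench import run_benchmark
    from spikesync.synthgen import build_benchmark_grid

    grid = build_benchmark_grid(N=20, T=10.0)
    return run_benchmark(grid, measure_set="extended", seed=1)
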