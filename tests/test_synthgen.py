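"""Generator closed forms, refractory supports, and determinism."""

import numpy as np
import pytest

from spikesync import (
    DualScaleParams,
    OUNoiseParams,
    SingleScaleParams,
    generate_dual_scale,
    generate_single_scale,
    generate_train,
    build_benchmark_grid,
    population_rate,
    power_spectrum,
    sample_ou_phase_noise,
    sample_refractory_exponential,
)


class TestOUPhaseNoise:
    def test_zero_sigma_collapses_to_mean(self):
        ou = OUNoiseParams(tau_OU=0.01, sigma_OU=0.0, dt=1e-4)
        x = sample_ou_phase_noise(ou, 1.0, seed=0)
        assert x.size == int(np.ceil(1.0 / ou.dt)) + 1
        assert np.all(x == 0.0)

    def test_stationary_sd_matches_parameter(self):
        sigma = 0.4 * np.pi * 12 / 1000  # benchmark value at f0 = 12 Hz
        ou = OUNoiseParams(tau_OU=0.010, sigma_OU=sigma, dt=1e-5)
        x = sample_ou_phase_noise(ou, 100.0, seed=1)
        sd = x[200_000:].std()  # discard the transient from x(0) = 0
        assert sd == pytest.approx(sigma, rel=0.05)

    def test_lag_tau_autocorrelation_is_exp_minus_one(self):
        ou = OUNoiseParams(tau_OU=0.010, sigma_OU=0.02, dt=1e-5)
        x = sample_ou_phase_noise(ou, 100.0, seed=2)[200_000:]
        lag = int(round(ou.tau_OU / ou.dt))
        ac = np.corrcoef(x[:-lag], x[lag:])[0, 1]
        assert ac == pytest.approx(np.exp(-1), abs=0.03)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OUNoiseParams(tau_OU=-1.0)
        with pytest.raises(ValueError):
            OUNoiseParams(dt=0.0)


class TestRefractoryExponential:
    def test_plain_exponential_mean(self):
        iv = sample_refractory_exponential(10.0, 0.0, 100_000, seed=0)
        assert iv.mean() == pytest.approx(0.1, rel=0.02)

    def test_shifted_mean_closed_form(self):
        # benchmark parameters at f0 = 12 Hz: lambda = 24*e^0.1, shift 0.1/24
        lam = 24 * np.exp(0.1)
        shift = 0.1 / 24
        iv = sample_refractory_exponential(lam, shift, 100_000, seed=1)
        assert iv.mean() == pytest.approx(shift + 1 / lam, rel=0.02)

    def test_support_constraint(self):
        iv = sample_refractory_exponential(5.0, 0.02, 10_000, seed=2)
        assert np.all(iv >= 0.02)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            sample_refractory_exponential(0.0, 0.0, 10)
        with pytest.raises(ValueError):
            sample_refractory_exponential(1.0, 0.0, 0)


class TestSingleScale:
    def test_rate_conservation_without_modulation(self):
        p = SingleScaleParams(r0=8.0, m=0.0, N=100, T=10.0)
        tr = generate_single_scale(p, seed=3)
        expected = 8.0 * 100 * 10 / (1 + 8.0 * p.t_refr_neu)
        assert abs(tr.n_spikes - expected) < 3 * np.sqrt(expected)

    def test_rhythmic_spectral_peak_at_f0(self):
        p = SingleScaleParams(r0=12.0, m=1.0, f0=12.0, N=50, T=10.0)
        tr = generate_single_scale(p, seed=4)
        pr = population_rate(tr.spikes, tr.T)
        f, _, _, f_max, defined = power_spectrum(pr)
        df = f[1] - f[0]
        assert defined and abs(f_max - 12.0) <= df

    def test_sequential_lag_between_leader_and_follower(self):
        # phase span 2*pi*Dc -> time span Dc/f0 between first and last neuron
        p = SingleScaleParams(r0=30.0, m=1.0, f0=4.0, Dc=0.4, N=20, T=30.0)
        tr = generate_single_scale(p, seed=5)
        a, b = tr.spikes[0], tr.spikes[-1]
        diffs = b[None, :] - a[:, None]
        window = 0.5 / p.f0
        diffs = diffs[np.abs(diffs) < window]
        lags = np.linspace(-window, window, 201)
        hist, edges = np.histogram(diffs, bins=lags)
        centers = 0.5 * (edges[:-1] + edges[1:])
        kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
        smooth = np.convolve(hist, kernel, mode="same")
        peak_lag = centers[np.argmax(smooth)]
        assert peak_lag == pytest.approx(p.Dc / p.f0, abs=0.25 * p.Dc / p.f0)

    def test_neuronal_refractory_enforced(self):
        p = SingleScaleParams(r0=36.0, m=1.0, N=20, T=5.0)
        tr = generate_single_scale(p, seed=6)
        for s in tr.spikes:
            if s.size > 1:
                assert np.diff(s).min() > p.t_refr_neu

    def test_rate_too_high_for_step_rejected(self):
        ou = OUNoiseParams(dt=1e-2)
        p = SingleScaleParams(r0=120.0, m=1.0, ou=ou)
        with pytest.raises(ValueError, match="rate too high"):
            generate_single_scale(p, seed=0)

    def test_non_rhythmic_node_intervals_respect_refractory(self):
        p = SingleScaleParams(r0=8.0, m=1.0, f0=12.0, rhythmic=False, N=5, T=10.0)
        tr = generate_single_scale(p, seed=7)
        assert np.all(tr.trace.inter_node_intervals >= p.t_refr_pop_)


class TestDualScale:
    def test_non_rhythmic_event_rate_closed_form(self):
        p = DualScaleParams(f0=12.0, Sigma=0.2, rhythmic=False, N=5, T=10.0)
        tr = generate_dual_scale(p, seed=8)
        mean_iei = (0.05 + np.exp(-0.05)) / 12.0
        expected = 10.0 / mean_iei
        assert abs(tr.trace.population_events.size - expected) < 3 * np.sqrt(expected)

    def test_tight_jitter_confines_spikes_to_events(self):
        p = DualScaleParams(f0=12.0, Sigma=0.001, p_fail=0.0, N=20, T=10.0)
        tr = generate_dual_scale(p, seed=9)
        events = tr.trace.population_events
        for s in tr.spikes:
            d = np.min(np.abs(s[:, None] - events[None, :]), axis=1)
            # 5-sigma bound: ~2400 Gaussian draws make 4-sigma excursions
            # likely once in a few hundred runs
            assert np.all(d <= 5 * p.sigma + 1e-12)

    def test_deletion_thins_binomially(self):
        p = DualScaleParams(f0=12.0, Sigma=0.2, p_fail=0.8, N=50, T=10.0)
        tr = generate_dual_scale(p, seed=10)
        n_events = tr.trace.population_events.size
        per_neuron = np.array([s.size for s in tr.spikes])
        expected = 0.2 * n_events
        sd = np.sqrt(n_events * 0.2 * 0.8)
        assert abs(per_neuron.mean() - expected) < 3 * sd / np.sqrt(50)

    def test_event_refractory_support(self):
        p = DualScaleParams(f0=36.0, Sigma=0.1, rhythmic=True, N=5, T=10.0)
        tr = generate_dual_scale(p, seed=11)
        ieis = np.diff(tr.trace.population_events)
        assert np.all(ieis >= p.t_refr_pop_ - 1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            DualScaleParams(Sigma=0.0)


class TestDeterminismAndGrid:
    @pytest.mark.parametrize(
        "params",
        [
            SingleScaleParams(r0=8, m=0.5, f0=12, N=10, T=5),
            SingleScaleParams(r0=8, m=0.5, f0=12, rhythmic=False, Dc=0.2, N=10, T=5),
            DualScaleParams(f0=12, Sigma=0.2, p_fail=0.4, Dc=0.4, N=10, T=5),
        ],
        ids=["single-rhythmic", "single-seq-nonrhythmic", "dual-seq"],
    )
    def test_identical_seed_gives_identical_trains(self, params):
        t1 = generate_train(params, seed=42)
        t2 = generate_train(params, seed=42)
        assert all(np.array_equal(a, b) for a, b in zip(t1.spikes, t2.spikes))

    def test_grid_counts(self):
        grid = build_benchmark_grid()
        assert len(grid) == 900
        single = [p for fam, p in grid if fam == "single"]
        dual = [p for fam, p in grid if fam == "dual"]
        assert len(single) == len(dual) == 450
        assert sum(p.Dc == 0 for p in single) == 150
        assert sum(p.Dc == 0 for p in dual) == 150
        assert sum(p.Dc > 0 for p in single) == 300

    def test_grid_population_refractory_formula(self):
        grid = build_benchmark_grid()
        for fam, p in grid:
            assert p.t_refr_pop_ == pytest.approx(0.1 / (2 * p.f0))

    def test_scaled_grid_keeps_size(self):
        grid = build_benchmark_grid(N=6, T=2.0)
        assert len(grid) == 900
        assert all(p.N == 6 and p.T == 2.0 for _, p in grid)
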