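"""Bivariate measures: trivial identities, independent oracles, symmetry."""

import itertools

import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from spikesync import bivariate_measure
from spikesync.pairwise import (
    BIVARIATE_FREE_NAMES,
    BIVARIATE_TAU_NAMES,
    pair_values,
    precompute_train,
)

TAU = 0.001


def _random_pair(rng, n=40, T=10.0):
    a = np.sort(rng.uniform(0, T, rng.integers(5, n)))
    b = np.sort(rng.uniform(0, T, rng.integers(5, n)))
    return a, b, T


class TestTrivialIdentities:
    @pytest.mark.parametrize(
        "name,tau,expected",
        [
            ("D_VP", TAU, 0.0),
            ("D_vR", TAU, 0.0),
            ("D_EMD", None, 0.0),
            ("D_MM", None, 0.0),
            ("D_ISI", None, 0.0),
            ("D_S", None, 0.0),
            ("C_S", TAU, 1.0),
            ("MPC", None, 1.0),
            ("S_QQ", TAU, 1.0),
            ("S_QQA", None, 1.0),
            ("S_HM", TAU, 1.0),
        ],
    )
    def test_self_comparison(self, rng, name, tau, expected):
        a = np.sort(rng.uniform(0, 10, 40))
        assert bivariate_measure(name, a, a, 10.0, tau=tau) == pytest.approx(
            expected, abs=1e-9
        )

    def test_vp_deletion_of_single_spike_costs_one(self):
        assert bivariate_measure("D_VP", [0.1], [], 1.0, tau=TAU) == 1.0
        assert bivariate_measure("D_VP", [], [0.1, 0.2], 1.0, tau=TAU) == 2.0

    def test_vp_shift_cheaper_than_delete_insert(self):
        # 2*0.0005/0.001 = 1 < 2
        d = bivariate_measure("D_VP", [0.1000], [0.1005], 1.0, tau=TAU)
        assert d == pytest.approx(1.0)

    def test_phase_measures_missing_for_empty_train(self):
        assert np.isnan(bivariate_measure("MPC", [0.1, 0.2], [], 1.0))
        assert np.isnan(bivariate_measure("PPC", [0.1, 0.2], [], 1.0))

    def test_van_rossum_distance_to_empty_is_self_norm(self):
        d = bivariate_measure("D_vR", [0.5], [], 1.0, tau=TAU)
        assert d == pytest.approx(np.sqrt(0.5))  # single-spike self energy


class TestOracles:
    def _vp_exhaustive(self, a, b, q):
        """Minimum edit cost over every injective spike matching."""
        best = len(a) + len(b)
        for k in range(1, min(len(a), len(b)) + 1):
            for sa in itertools.combinations(range(len(a)), k):
                for sb in itertools.permutations(range(len(b)), k):
                    cost = (len(a) - k) + (len(b) - k) + sum(
                        q * abs(a[i] - b[j]) for i, j in zip(sa, sb)
                    )
                    best = min(best, cost)
        return best

    @pytest.mark.parametrize("seed", range(30))
    def test_vp_dynamic_program_matches_exhaustive_search(self, seed):
        r = np.random.default_rng(seed)
        a = np.sort(r.uniform(0, 0.05, r.integers(0, 5)))
        b = np.sort(r.uniform(0, 0.05, r.integers(0, 5)))
        q = 2.0 / TAU
        dp = bivariate_measure("D_VP", a, b, 0.05, tau=TAU)
        assert dp == pytest.approx(self._vp_exhaustive(list(a), list(b), q), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_van_rossum_recursion_matches_dense_sum(self, seed):
        r = np.random.default_rng(seed)
        a, b, T = _random_pair(r)
        tau = 0.01

        def dense(x, y):
            return np.exp(-np.abs(x[:, None] - y[None, :]) / tau).sum()

        expected = np.sqrt(max(0.5 * (dense(a, a) + dense(b, b) - 2 * dense(a, b)), 0))
        got = bivariate_measure("D_vR", a, b, T, tau=tau)
        assert got == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_emd_matches_scipy_wasserstein(self, seed):
        r = np.random.default_rng(seed)
        a, b, T = _random_pair(r)
        got = bivariate_measure("D_EMDN", a, b, T)
        assert got == pytest.approx(wasserstein_distance(a, b), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_modulus_metric_matches_grid_integration(self, seed):
        r = np.random.default_rng(seed)
        a = np.sort(r.uniform(0, 2, 8))
        b = np.sort(r.uniform(0, 2, 6))
        t = np.linspace(0, 2, 400_001)
        da = np.min(np.abs(t[:, None] - a[None, :]), axis=1)
        db = np.min(np.abs(t[:, None] - b[None, :]), axis=1)
        expected = np.trapezoid(np.abs(da - db), t)
        got = bivariate_measure("D_MM", a, b, 2.0)
        assert got == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_schreiber_matches_dense_gaussian_sum(self, seed):
        r = np.random.default_rng(seed)
        a, b, T = _random_pair(r)
        sig = 0.004

        def dense(x, y):
            return np.exp(-((x[:, None] - y[None, :]) ** 2) / (4 * sig**2)).sum()

        expected = dense(a, b) / np.sqrt(dense(a, a) * dense(b, b))
        got = bivariate_measure("C_S", a, b, T, tau=sig)
        # the windowed sum truncates kernel tails beyond 8 sigma
        assert got == pytest.approx(expected, rel=1e-4, abs=1e-7)


class TestStatisticalBehavior:
    def test_independent_poisson_sttc_near_zero_ci_near_one(self, rng):
        """Chance levels from a 20-surrogate ensemble: STTC ~ 0, C_i ~ 1."""
        sttc, ci = [], []
        for _ in range(20):
            a = np.sort(rng.uniform(0, 100, 1000))
            b = np.sort(rng.uniform(0, 100, 1000))
            sttc.append(bivariate_measure("STTC", a, b, 100.0, tau=TAU))
            ci.append(bivariate_measure("C_i", a, b, 100.0, tau=TAU))
        n = len(sttc)
        assert abs(np.mean(sttc)) < 3 * np.std(sttc, ddof=1) / np.sqrt(n)
        assert abs(np.mean(ci) - 1.0) < 3 * np.std(ci, ddof=1) / np.sqrt(n)

    def test_lz_distance_small_for_identical_large_for_disjoint(self, rng):
        a = np.sort(rng.uniform(0, 10, 60))
        b = np.sort(rng.uniform(0, 10, 60))
        assert bivariate_measure("D_LZ", a, a, 10.0) <= 0.1
        assert bivariate_measure("D_LZ", a, b, 10.0) > bivariate_measure(
            "D_LZ", a, a, 10.0
        )


class TestSymmetryAndRanges:
    SYMMETRIC_TAU = [n for n in BIVARIATE_TAU_NAMES if n != "S_qq"]
    SYMMETRIC_FREE = [n for n in BIVARIATE_FREE_NAMES if n != "S_qqa"]

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_measures_are_symmetric(self, seed):
        r = np.random.default_rng(100 + seed)
        a, b, T = _random_pair(r)
        for name in self.SYMMETRIC_TAU:
            x = bivariate_measure(name, a, b, T, tau=0.004)
            y = bivariate_measure(name, b, a, T, tau=0.004)
            assert x == pytest.approx(y, rel=1e-9), name
        for name in self.SYMMETRIC_FREE:
            x = bivariate_measure(name, a, b, T)
            y = bivariate_measure(name, b, a, T)
            assert x == pytest.approx(y, rel=1e-9), name

    @pytest.mark.parametrize("seed", range(5))
    def test_delay_asymmetry_is_antisymmetric(self, seed):
        r = np.random.default_rng(200 + seed)
        a, b, T = _random_pair(r)
        for name, tau in (("S_qq", 0.004), ("S_qqa", None)):
            x = bivariate_measure(name, a, b, T, tau=tau)
            y = bivariate_measure(name, b, a, T, tau=tau)
            assert x == pytest.approx(-y, abs=1e-9), name

    @pytest.mark.parametrize("seed", range(20))
    def test_documented_ranges_on_random_trains(self, seed):
        r = np.random.default_rng(300 + seed)
        a, b, T = _random_pair(r)
        taus = np.array([0.001, 0.008, 0.064])
        pa = precompute_train(a, T, taus)
        pb = precompute_train(b, T, taus)
        tau_block, free = pair_values(pa, pb, T, taus)
        tb = dict(zip(BIVARIATE_TAU_NAMES, tau_block))
        fr = dict(zip(BIVARIATE_FREE_NAMES, free))
        assert np.all(tb["STTC"] >= -1) and np.all(tb["STTC"] <= 1)
        assert np.all(tb["C_S"] >= 0) and np.all(tb["C_S"] <= 1)
        for dist in ("D_VP", "D_VPN", "D_vR", "D_vRn"):
            assert np.all(tb[dist] >= 0), dist
        for dist in ("D_ISI", "D_S", "D_EMD", "D_EMDN", "D_MM", "D_MMN", "D_LZ"):
            assert fr[dist] >= 0, dist
        assert 0 <= fr["D_ISI"] <= 1
        assert 0 <= fr["MPC"] <= 1
        assert -1 <= fr["PPC"] <= 1
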