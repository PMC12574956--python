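"""Windowed pipeline: clustering, MDS, fingerprinting, decoding, ID."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from spikesync import (
    WindowMatrix,
    cluster_windows,
    decode,
    decoding_synergy,
    mds_2d,
    nn_id,
    pca_id,
    silhouette_fingerprint,
    window_similarity,
    windowed_measure_matrix,
)
from tests.conftest import poisson_population


@pytest.fixture(scope="module")
def stationary_windows():
    rng = np.random.default_rng(77)
    train = poisson_population(6, 3.0, 600.0, rng)
    return windowed_measure_matrix(train, window_s=30.0, measure_set="core")


class TestWindowedMatrix:
    def test_600s_recording_gives_20_windows(self, stationary_windows):
        assert stationary_windows.values.shape == (20, 46)

    def test_zscored_columns_standardized(self, stationary_windows):
        z = stationary_windows.zscore().values
        m = z.mean(skipna=True).dropna()
        s = z.std(skipna=True).dropna()
        assert np.allclose(m, 0.0, atol=1e-12)
        assert np.allclose(s, 1.0, atol=1e-12)

    def test_stationary_train_shows_no_temporal_trend(self, stationary_windows):
        """On a stationary recording the fraction of measures with a
        significant rank trend over window index stays near the test level."""
        vals = stationary_windows.values
        idx = np.arange(len(vals))
        n_sig = 0
        n_tested = 0
        for col in vals.columns:
            y = vals[col].to_numpy()
            ok = np.isfinite(y)
            if ok.sum() < 10 or np.all(y[ok] == y[ok][0]):
                continue
            n_tested += 1
            _, p = spearmanr(idx[ok], y[ok])
            n_sig += p < 0.01
        assert n_tested > 30
        assert n_sig <= max(3, 0.15 * n_tested)

    def test_too_short_recording_rejected(self, rng):
        train = poisson_population(3, 5.0, 40.0, rng)
        with pytest.raises(ValueError):
            windowed_measure_matrix(train, window_s=30.0)


class TestWindowGeometry:
    def _wm(self, X):
        return WindowMatrix(pd.DataFrame(X), window_s=30.0)

    def test_duplicated_windows_coincide(self, rng):
        base = rng.normal(size=(5, 12))
        X = np.vstack([base, base[2]])
        Z, D = cluster_windows(self._wm(X))
        assert D.iloc[2, 5] == pytest.approx(0.0, abs=1e-12)
        xy = mds_2d(D)
        assert np.allclose(xy[2], xy[5], atol=1e-8)

    def test_mds_equilateral_for_three_equidistant(self):
        D = np.ones((3, 3)) - np.eye(3)
        xy = mds_2d(D)
        d01 = np.linalg.norm(xy[0] - xy[1])
        d02 = np.linalg.norm(xy[0] - xy[2])
        d12 = np.linalg.norm(xy[1] - xy[2])
        assert d01 == pytest.approx(d02, rel=1e-9)
        assert d01 == pytest.approx(d12, rel=1e-9)

    def test_window_similarity_is_spearman(self, rng):
        X = rng.normal(size=(6, 20))
        rho = window_similarity(self._wm(X))
        expected = spearmanr(X[0], X[1]).statistic
        assert rho.iloc[0, 1] == pytest.approx(expected)


class TestSilhouetteFingerprint:
    def test_separated_recordings_significant(self, rng):
        a = rng.normal(0.0, 0.3, size=(15, 5))
        b = rng.normal(4.0, 0.3, size=(15, 5))
        X = np.vstack([a, b])
        labels = ["r1"] * 15 + ["r2"] * 15
        res = silhouette_fingerprint(X, labels, n_perm=300, seed=0)
        assert res.mean > 0.8
        assert res.significant

    def test_random_labels_not_significant(self, rng):
        X = rng.normal(size=(40, 5))
        labels = rng.permutation(["r1"] * 20 + ["r2"] * 20)
        res = silhouette_fingerprint(X, labels, n_perm=300, seed=1, alpha=0.05)
        assert not res.significant

    def test_single_label_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_fingerprint(rng.normal(size=(10, 3)), ["r1"] * 10)

    def test_singleton_label_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_fingerprint(
                rng.normal(size=(5, 3)), ["a", "a", "a", "a", "b"]
            )


class TestDecoding:
    def test_perfectly_separable_feature(self, rng):
        y = np.repeat(["wake", "nrem"], 50)
        x = np.where(y == "wake", 1.0, 5.0) + rng.normal(0, 0.1, 100)
        res = decode(x, y, scheme="within", seed=0)
        assert res.a_prime == pytest.approx(1.0)

    def test_uninformative_feature_near_chance(self, rng):
        y = np.repeat(["wake", "nrem"], 100)
        x = rng.normal(size=200)
        res = decode(x, y, scheme="within", seed=0)
        assert 0.3 < res.a_prime < 0.7

    def test_monotone_transform_invariance(self, rng):
        y = np.repeat([0, 1], 60)
        x = rng.normal(y.astype(float), 0.8)
        a1 = decode(x, y, scheme="within", seed=0).a_prime
        a2 = decode(np.exp(x), y, scheme="within", seed=0).a_prime
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_loro_scheme(self, rng):
        y = np.tile(np.repeat([0, 1], 20), 3)
        groups = np.repeat(["g1", "g2", "g3"], 40)
        x = rng.normal(y.astype(float) * 3, 0.5)
        res = decode(x, y, scheme="loro", groups=groups, seed=0)
        assert res.n_folds_used == 3
        assert res.a_prime > 0.95

    def test_duplicate_pair_has_zero_synergy(self, rng):
        y = np.repeat([0, 1], 60)
        x = rng.normal(y.astype(float), 1.0)
        a_x = decode(x, y, seed=0).a_prime
        a_xx = decode(np.column_stack([x, x]), y, seed=0).a_prime
        assert decoding_synergy(a_xx, a_x, a_x) == pytest.approx(0.0, abs=1e-9)

    def test_two_classes_required(self, rng):
        with pytest.raises(ValueError):
            decode(rng.normal(size=10), np.zeros(10))


class TestIntrinsicDimension:
    def test_rank_one_matrix_has_pca_id_one(self, rng):
        u = rng.normal(size=50)
        X = np.outer(u, rng.normal(size=8))
        assert pca_id(X, threshold=0.99, standardize=False).value == 1.0

    def test_isotropic_gaussian_needs_all_components(self, rng):
        X = rng.normal(size=(800, 10))
        assert pca_id(X, threshold=0.95).value == 10.0

    @pytest.mark.parametrize("method", ["twonn", "gride"])
    def test_plane_embedded_in_ten_dimensions(self, rng, method):
        X = np.zeros((2000, 10))
        X[:, :2] = rng.uniform(0, 1, size=(2000, 2))
        Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        est = nn_id(X @ Q.T, method=method, standardize=False, seed=0)
        assert est.value == pytest.approx(2.0, rel=0.10)

    def test_scaling_invariance(self, rng):
        X = rng.normal(size=(500, 4))
        e1 = nn_id(X, method="gride", standardize=False, seed=0)
        e2 = nn_id(X * 7.3, method="gride", standardize=False, seed=0)
        assert e1.value == pytest.approx(e2.value, rel=1e-9)

    def test_duplicates_filtered_with_warning(self, rng):
        X = rng.normal(size=(60, 3))
        X[10] = X[3]
        with pytest.warns(UserWarning, match="duplicate"):
            nn_id(X, method="twonn", seed=0)
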