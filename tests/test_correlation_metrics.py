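"""R-squared, ADF stationarity, lagged cross-correlation, MIC and the
MIC - R^2 classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sensorbench.correlation_metrics import (MICConfig, adf_stationary,
                                             classify_association,
                                             cluster_pairs, cross_correlation,
                                             linear_r2, mic)
from conftest import make_series
from oracles import mic_brute


class TestLinearR2:
    def test_perfect_linear(self):
        x = np.arange(100.0)
        assert linear_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert linear_r2(x, y) < 0.01

    def test_symmetric_parabola_orthogonal(self):
        x = np.linspace(-1, 1, 201)
        assert linear_r2(x, x ** 2) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_returns_nan(self, caplog):
        with caplog.at_level("WARNING"):
            out = linear_r2(np.full(10, 3.0), np.arange(10.0))
        assert np.isnan(out)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert linear_r2(x, y) == pytest.approx(linear_r2(y, x))


class TestAdfStationary:
    def test_white_noise_rejection_rate(self):
        rng = np.random.default_rng(2)
        hits = sum(adf_stationary(rng.normal(size=500))[0] for _ in range(20))
        assert hits >= 18

    def test_random_walk_rarely_stationary(self):
        rng = np.random.default_rng(3)
        hits = sum(adf_stationary(np.cumsum(rng.normal(size=500)))[0]
                   for _ in range(20))
        assert hits <= 2

    def test_linear_ramp_nonstationary(self):
        rng = np.random.default_rng(4)
        stat, p = adf_stationary(np.arange(500.0) + rng.normal(0, 0.1, 500))
        assert not stat and p > 0.05

    def test_constant_series_convention(self):
        stat, p = adf_stationary(np.full(50, 2.0))
        assert stat and p == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            adf_stationary(np.arange(10.0))


class TestCrossCorrelation:
    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=2000)
        # y(t) = x(t - 2 s): y lags two seconds behind the reference
        x = make_series(base[2:], resolution_ms=1000, parameter="HR")
        y = make_series(base[:-2], resolution_ms=1000, parameter="HR", platform="BH")
        out = cross_correlation(x, y)
        assert out.best_lag == pytest.approx(2.0)
        assert out.peak > 0.95

    def test_identity_zero_lag(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=500)
        x = make_series(v, resolution_ms=1000, parameter="HR")
        out = cross_correlation(x, x)
        assert out.best_lag == 0.0
        assert out.coefficients[15] == pytest.approx(1.0)

    def test_independent_pair_bounded(self):
        rng = np.random.default_rng(7)
        x = make_series(rng.normal(size=10_000), resolution_ms=1000, parameter="HR")
        y = make_series(rng.normal(size=10_000), resolution_ms=1000,
                        parameter="HR", platform="BH")
        out = cross_correlation(x, y)
        assert np.nanmax(np.abs(out.coefficients)) < 0.1

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(8)
        a = make_series(rng.normal(size=400), resolution_ms=1000, parameter="HR")
        b = make_series(rng.normal(size=400), resolution_ms=1000,
                        parameter="HR", platform="BH")
        ab = cross_correlation(a, b, difference=False)
        ba = cross_correlation(b, a, difference=False)
        assert np.allclose(ab.coefficients, ba.coefficients[::-1], equal_nan=True)

    def test_random_walk_gets_differenced(self):
        rng = np.random.default_rng(9)
        x = make_series(np.cumsum(rng.normal(size=600)), resolution_ms=1000,
                        parameter="HR")
        y = make_series(np.cumsum(rng.normal(size=600)), resolution_ms=1000,
                        parameter="HR", platform="BH")
        out = cross_correlation(x, y)
        assert out.differenced >= 1

    def test_lag_range_is_pm15(self):
        rng = np.random.default_rng(10)
        x = make_series(rng.normal(size=200), resolution_ms=1000, parameter="HR")
        out = cross_correlation(x, x)
        assert out.lags[0] == -15.0 and out.lags[-1] == 15.0
        assert len(out.lags) == 31


class TestMic:
    def test_noiseless_identity_is_one(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(size=200)
        assert mic(x, x.copy()) == pytest.approx(1.0)

    def test_independent_uniforms_below_null_bound(self):
        rng = np.random.default_rng(13)
        assert mic(rng.uniform(size=1000), rng.uniform(size=1000)) < 0.2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_instance_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=30)
        y = x ** 2 + 0.3 * rng.normal(size=30) if seed % 2 else rng.uniform(size=30)
        assert mic(x, y) == pytest.approx(mic_brute(x, y), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(14)
        x, y = rng.uniform(size=120), rng.uniform(size=120)
        assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-12)

    def test_monotone_transform_invariance_small(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(0.1, 1.0, size=30)
        y = rng.uniform(0.1, 1.0, size=30)
        base = mic(x, y)
        assert mic(np.log(x), y) == pytest.approx(base, abs=1e-9)
        assert mic(x, y ** 3) == pytest.approx(base, abs=1e-9)

    def test_constant_input_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = mic(np.full(50, 2.0), np.arange(50.0))
        assert out == 0.0

    def test_preconditions(self):
        with pytest.raises(ValueError, match="n >= 25"):
            mic(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError, match="alpha"):
            MICConfig(alpha=1.5)


class TestClassifyAssociation:
    def test_printed_worked_example(self):
        out = classify_association(0.2, 0.91, epsilon=0.1)
        assert out.score == pytest.approx(-0.71)
        assert out.value == "false_linear"

    def test_boundary_is_true_linear(self):
        assert classify_association(0.5, 0.5).value == "true_linear"

    def test_forced_nonlinear(self):
        assert classify_association(0.9, 0.1).value == "nonlinear_functional"

    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(1e-6, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_partition_exhaustive_and_exclusive(self, m, r, eps):
        out = classify_association(m, r, eps)
        assert out.value in ("false_linear", "true_linear", "nonlinear_functional")
        if out.value == "false_linear":
            assert out.score < -eps
        elif out.value == "nonlinear_functional":
            assert out.score > eps
        else:
            assert -eps <= out.score <= eps

    def test_type_one_error_on_independent_pairs(self):
        # at adequate sample size the MIC null bias stays inside epsilon
        rng = np.random.default_rng(16)
        n_bad = 0
        for _ in range(10):
            x, y = rng.uniform(size=10_000), rng.uniform(size=10_000)
            cls = classify_association(mic(x, y), linear_r2(x, y), epsilon=0.1)
            n_bad += cls.value == "nonlinear_functional"
        assert n_bad == 0


class TestClusterPairs:
    def _profiles(self, means, n_participants=6, spread=0.02, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for m in means:
            rows.append(np.clip(rng.normal(m, spread, size=n_participants), 0, 1))
        return pd.DataFrame(rows, index=[f"pair{i}" for i in range(len(means))])

    def test_separated_blobs_recovered(self):
        means = [0.1] * 4 + [0.5] * 4 + [0.9] * 4
        labels = cluster_pairs(self._profiles(means), k=3, seed=0)
        assert list(labels[:4]) == ["low"] * 4
        assert list(labels[4:8]) == ["moderate"] * 4
        assert list(labels[8:]) == ["high"] * 4

    def test_identical_profiles_degenerate(self):
        prof = self._profiles([0.5] * 5, spread=0.0)
        labels = cluster_pairs(prof, k=3, seed=0)
        assert labels.nunique() <= 3  # k-means may leave clusters empty-ish

    def test_permutation_invariant_membership(self):
        means = [0.1] * 3 + [0.5] * 3 + [0.9] * 3
        prof = self._profiles(means, seed=1)
        labels = cluster_pairs(prof, k=3, seed=0)
        perm = prof.sample(frac=1.0, random_state=42)
        labels_perm = cluster_pairs(perm, k=3, seed=0)
        assert (labels_perm.loc[labels.index] == labels).all()

    def test_missing_cells_imputed(self):
        prof = self._profiles([0.1] * 3 + [0.9] * 3)
        prof.iloc[0, 0] = np.nan
        labels = cluster_pairs(prof, k=2, seed=0)
        assert labels.iloc[0] == labels.iloc[1]

    def test_fewer_pairs_than_k(self):
        with pytest.raises(ValueError):
            cluster_pairs(self._profiles([0.5, 0.6]), k=3)
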