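import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurospect import (
    EEGRecord,
    diff_series,
    extract_features,
    features_from_records,
    normalize_m0_across_channels,
    power_transform,
    raw_moments,
    subject_features,
)
from neurospect.tdpsd import RawMoments

from oracle_tdpsd import oracle_features

# Frozen output of the independent formula oracle for
# x = [1, 2, 3, 4, 3, 2, 1, 0], lambda = 0.1, eps = 1e-12.
FIXED_VECTOR = np.array([1.0, 2.0, 3.0, 4.0, 3.0, 2.0, 1.0, 0.0])
FIXED_EXPECTED = np.array([
    2.491794574690041,
    0.059287368283714,
    0.311305178606876,
    2.306498301245601,
    -0.031966592422156,
    -0.490414626504230,
    2.484906649788084,
])


class TestDiffSeries:
    def test_first_difference(self):
        assert np.array_equal(diff_series([1, 2, 4], 1), [1, 2])

    def test_constant_any_order(self):
        x = np.full(10, 3.5)
        assert np.all(diff_series(x, 1) == 0)
        assert np.all(diff_series(x, 2) == 0)

    def test_linear_ramp_second_order_zero(self):
        x = np.arange(20, dtype=float) * 0.7 + 1.0
        assert np.allclose(diff_series(x, 2), 0.0)

    def test_lengths(self):
        x = np.arange(9, dtype=float)
        assert diff_series(x, 1).size == 8
        assert diff_series(x, 2).size == 7

    def test_too_short(self):
        with pytest.raises(ValueError):
            diff_series([1.0], 1)
        with pytest.raises(ValueError):
            diff_series([1.0, 2.0], 2)


class TestRawMoments:
    def test_three_four_five(self):
        m = raw_moments([3.0, 4.0, 0.0])
        assert m.m0_bar == pytest.approx(5.0)

    def test_constant_signal_higher_moments_vanish(self):
        m = raw_moments(np.full(50, 2.0))
        assert m.m2_bar == 0.0
        assert m.m4_bar == 0.0
        assert m.m0_bar > 0

    def test_parseval_oracle_n64(self, rng):
        x = rng.standard_normal(64)
        time_power = raw_moments(x).m0_bar ** 2
        fft_power = np.sum(np.abs(np.fft.fft(x)) ** 2) / x.size
        assert time_power == pytest.approx(fft_power, rel=1e-9)

    def test_parseval_property_many_lengths(self, rng):
        """Parseval identity vs FFT oracle for 100 random signals, lengths
        16..1024."""
        for _ in range(100):
            n = int(rng.integers(16, 1025))
            x = rng.standard_normal(n) * float(rng.uniform(0.1, 50))
            time_power = float(np.sum(x**2))
            fft_power = float(np.sum(np.abs(np.fft.fft(x)) ** 2) / n)
            assert time_power == pytest.approx(fft_power, rel=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            raw_moments([1.0, np.nan, 2.0])

    def test_invariants(self, rng):
        m = raw_moments(rng.standard_normal(128))
        assert m.m0_bar >= 0 and m.m2_bar >= 0 and m.m4_bar >= 0


class TestPowerTransform:
    def test_unit_moment(self):
        nm = power_transform(RawMoments(1.0, 1.0, 1.0), lam=0.1)
        assert nm.m0 == pytest.approx(10.0)

    def test_zero_maps_to_zero(self):
        nm = power_transform(RawMoments(0.0, 0.0, 0.0), lam=0.1)
        assert nm.m0 == nm.m2 == nm.m4 == 0.0

    def test_power_of_two(self):
        # 1024**0.1 = 2, so the transform gives 2 / 0.1 = 20
        nm = power_transform(RawMoments(1024.0, 0.0, 0.0), lam=0.1)
        assert nm.m0 == pytest.approx(20.0, rel=1e-12)

    def test_monotone(self, rng):
        values = np.sort(rng.uniform(0.01, 100, 20))
        transformed = [power_transform(RawMoments(v, 0, 0), 0.1).m0 for v in values]
        assert np.all(np.diff(transformed) > 0)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            power_transform(RawMoments(1.0, 1.0, 1.0), lam=0.0)


class TestExtractFeatures:
    def test_fixed_vector_matches_frozen_oracle(self):
        out = extract_features(FIXED_VECTOR, lam=0.1)
        np.testing.assert_allclose(out.as_array(), FIXED_EXPECTED, atol=1e-9)

    def test_constant_signal_zero_sparseness(self):
        out = extract_features(np.full(100, 7.3))
        assert abs(out.f4) < 1e-9

    def test_all_zero_signal_flagged_not_raised(self):
        out = extract_features(np.zeros(50))
        assert out.degenerate
        assert np.all(np.isfinite(out.as_array()))

    def test_scale_invariance_and_shift(self, rng):
        lam = 0.1
        for _ in range(20):
            x = rng.standard_normal(256) + rng.uniform(0.5, 2)
            c = float(rng.uniform(0.1, 10))
            a = extract_features(x, lam=lam, eps=0.0).as_array()
            b = extract_features(c * x, lam=lam, eps=0.0).as_array()
            # f4, f5, f6 invariant
            np.testing.assert_allclose(b[3:6], a[3:6], rtol=1e-9, atol=1e-9)
            # f1 shifts by exactly lambda * log c
            assert b[0] - a[0] == pytest.approx(lam * np.log(c), abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1),
           st.floats(min_value=-5.0, max_value=5.0, allow_nan=False))
    def test_softplus_shift_invariance_of_scale_free_features(self, seed, logc):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(64) + 1.0
        c = float(np.exp(logc))
        a = extract_features(x, eps=0.0).as_array()
        b = extract_features(c * x, eps=0.0).as_array()
        np.testing.assert_allclose(b[3:6], a[3:6], rtol=1e-8, atol=1e-8)

    def test_oracle_equivalence_1000_random_signals(self, rng):
        for _ in range(1000):
            n = int(rng.integers(8, 257))
            x = rng.standard_normal(n) * float(rng.uniform(0.05, 20))
            impl = extract_features(x, lam=0.1).as_array()
            ref = np.array(oracle_features(list(x), lam=0.1))
            np.testing.assert_allclose(impl, ref, rtol=1e-9, atol=1e-9)

    def test_determinism(self, rng):
        x = rng.standard_normal(512)
        a = extract_features(x).as_array()
        b = extract_features(x).as_array()
        assert np.array_equal(a, b)

    def test_moment_ordering_high_freq_monotone(self):
        """Adding alternating-sign content raises m2/m0, monotonically in
        the perturbation amplitude."""
        rng = np.random.default_rng(8)
        base = np.cumsum(rng.standard_normal(512)) / 10
        alternating = np.tile([1.0, -1.0], 256)
        ratios = []
        for amp in [0.0, 0.5, 1.0, 2.0, 4.0]:
            m = raw_moments(base + amp * alternating)
            ratios.append(m.m2_bar / m.m0_bar)
        assert np.all(np.diff(ratios) > 0)


class TestNormalizeM0:
    def test_two_equal_channels(self):
        np.testing.assert_allclose(normalize_m0_across_channels([2.0, 2.0]), [0.5, 0.5])

    def test_single_channel(self):
        np.testing.assert_allclose(normalize_m0_across_channels([3.7]), [1.0])

    def test_sums_to_one(self, rng):
        v = rng.uniform(0.1, 10, 19)
        assert normalize_m0_across_channels(v).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_m0_across_channels([0.0, 0.0])


class TestSubjectFeatures:
    def _record(self, samples, fs=256.0):
        labels = tuple(f"C{i}" for i in range(samples.shape[0]))
        return EEGRecord(samples, fs, channel_labels=labels, class_label=1)

    def test_single_channel_mean_equals_channel(self, rng):
        x = rng.standard_normal(256)
        record = self._record(x[None, :])
        np.testing.assert_array_equal(
            subject_features(record, "mean"),
            extract_features(x).as_array(),
        )

    def test_identical_channels_mean_equals_any(self, rng):
        x = rng.standard_normal(256)
        record = self._record(np.tile(x, (19, 1)))
        np.testing.assert_allclose(
            subject_features(record, "mean"),
            extract_features(x).as_array(),
            rtol=1e-12,
        )

    def test_concat_shape(self, rng):
        record = self._record(rng.standard_normal((5, 128)))
        assert subject_features(record, "concat").shape == (7, 5)

    def test_feature_table_shape_from_cohort(self, quick_feature_table):
        assert quick_feature_table.matrix.shape == (7, 48)
        assert sorted(set(quick_feature_table.labels)) == [1, 2, 3]

    def test_unknown_aggregation(self, rng):
        record = self._record(rng.standard_normal((2, 64)))
        with pytest.raises(ValueError):
            subject_features(record, "median")

    def test_unlabelled_record_rejected(self, rng):
        record = EEGRecord(rng.standard_normal((1, 64)), 256.0,
                           channel_labels=("C0",))
        with pytest.raises(ValueError):
            features_from_records([record])
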