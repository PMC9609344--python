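"""Feature extraction: hand oracles, brute-force equality, spectral identities.

Every scalar feature is checked against an independent straight-from-the-
definition reimplementation; spectral features against the Parseval identity;
the wavelet decomposition against perfect reconstruction; AR estimation
against parameter recovery on synthesized processes and a hand-written Burg
recursion.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import pywt

from emghand import features
from emghand.acquire import WindowedTrial
from emghand.errors import ParameterError
from emghand.synth import gesture


# ---------------------------------------------------------------------------
# independent brute-force oracles (loops, straight from the definitions)

def bf_mav(x):
    return sum(abs(v) for v in x) / len(x)


def bf_zc(x, eps=0.0):
    count = 0
    for k in range(len(x) - 1):
        if (x[k] > eps and x[k + 1] < -eps) or (x[k] < -eps and x[k + 1] > eps):
            count += 1
    return count


def bf_ssc(x, eps=0.0):
    count = 0
    for k in range(1, len(x) - 1):
        up = x[k] - x[k - 1] > eps and x[k] - x[k + 1] > eps
        down = x[k - 1] - x[k] > eps and x[k + 1] - x[k] > eps
        if up or down:
            count += 1
    return count


def bf_wl(x):
    return sum(abs(x[k] - x[k - 1]) for k in range(1, len(x)))


def bf_burg(x, order):
    """Textbook Burg lattice recursion (forward+backward prediction error)."""
    x = np.asarray(x, dtype=float)
    a = np.array([1.0])
    f = x[1:].copy()   # forward prediction error
    b = x[:-1].copy()  # backward prediction error
    for _ in range(order):
        k = -2.0 * np.dot(f, b) / (np.dot(f, f) + np.dot(b, b))
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    # polynomial a has convention x_t + sum a_i x_{t-i} = e_t; flip the sign
    return -a[1:]


def simulate_ar(coeffs, n, seed, burn=500):
    rng = np.random.default_rng(seed)
    p = len(coeffs)
    x = np.zeros(n + burn)
    e = rng.standard_normal(n + burn)
    for k in range(p, n + burn):
        x[k] = np.dot(coeffs, x[k - p:k][::-1]) + e[k]
    return x[burn:]


finite_segments = arrays(np.float64, st.integers(16, 64),
                         elements=st.floats(-10, 10, allow_nan=False))


class TestTimeDomain:
    def test_mav_hand_values(self):
        assert features.mav([0.0, 0.0, 0.0]) == 0.0
        assert features.mav([2.5, 2.5]) == 2.5
        assert features.mav([-3.0, -3.0]) == 3.0
        assert features.mav([1.0, -2.0, 3.0]) == pytest.approx(2.0)

    def test_zc_hand_values(self):
        assert features.zero_crossings([1.0, 2.0, 3.0]) == 0
        assert features.zero_crossings([1.0, -1.0, 1.0, -1.0]) == 3
        # a zero-valued sample breaks both strict inequalities
        assert features.zero_crossings([1.0, 0.0, -1.0]) == 0

    def test_zc_deadband(self):
        assert features.zero_crossings([0.05, -0.05], deadband=0.1) == 0
        assert features.zero_crossings([0.5, -0.5], deadband=0.1) == 1

    def test_ssc_hand_values(self):
        assert features.slope_sign_changes([0.0, 1.0, 2.0, 3.0]) == 0  # monotone ramp
        assert features.slope_sign_changes([0.0, 1.0, 0.0, 1.0, 0.0]) == 3
        assert features.slope_sign_changes([2.0, 2.0, 2.0]) == 0  # constant

    def test_wl_hand_values(self):
        assert features.waveform_length([5.0, 5.0, 5.0]) == 0.0
        assert features.waveform_length([0.0, 1.0, 3.0]) == pytest.approx(3.0)
        ramp = np.linspace(-2.0, 7.0, 50)
        assert features.waveform_length(ramp) == pytest.approx(9.0)  # telescoping

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(finite_segments)
    def test_scalar_features_match_brute_force(self, x):
        assert features.mav(x) == pytest.approx(bf_mav(x), rel=1e-12, abs=1e-12)
        assert features.zero_crossings(x) == bf_zc(x)
        assert features.slope_sign_changes(x) == bf_ssc(x)
        assert features.waveform_length(x) == pytest.approx(bf_wl(x), rel=1e-12, abs=1e-12)

    def test_length_preconditions(self):
        with pytest.raises(ParameterError):
            features.mav([])
        with pytest.raises(ParameterError):
            features.zero_crossings([1.0])
        with pytest.raises(ParameterError):
            features.slope_sign_changes([1.0, 2.0])
        with pytest.raises(ParameterError):
            features.waveform_length([1.0])


class TestAutoregressive:
    def test_white_noise_has_no_memory(self, rng):
        x = rng.standard_normal(20_000)
        model = features.ar_fit(x)
        assert np.all(np.abs(model.coeffs) < 0.05)

    def test_ar2_parameter_recovery(self):
        x = simulate_ar([0.5, -0.3], n=10_000, seed=42)
        model = features.ar_fit(x, order=2)
        assert model.coeffs[0] == pytest.approx(0.5, abs=0.05)
        assert model.coeffs[1] == pytest.approx(-0.3, abs=0.05)

    def test_ar1_parameter_recovery(self):
        x = simulate_ar([0.9], n=10_000, seed=7)
        model = features.ar_fit(x, order=1)
        assert model.coeffs[0] == pytest.approx(0.9, abs=0.03)

    def test_matches_hand_written_burg_recursion(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(50, 300))
            x = x - x.mean()
            got = features.ar_fit(x, order=5).coeffs
            expected = bf_burg(x, 5)
            np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)

    def test_recovery_error_shrinks_with_n(self):
        """Burg RMSE on a simulated AR(2) decreases with segment length."""
        truth = np.array([0.5, -0.3])
        rmse = []
        for n in (500, 5_000, 50_000):
            errs = [np.linalg.norm(features.ar_fit(
                simulate_ar(truth, n=n, seed=100 + r), order=2).coeffs - truth)
                for r in range(5)]
            rmse.append(np.sqrt(np.mean(np.square(errs))))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_constant_segment_degenerate(self):
        model = features.ar_fit(np.full(100, 3.3))
        assert model.degenerate
        assert np.all(model.coeffs == 0.0)
        assert model.sigma2 == 0.0

    def test_short_segment_rejected(self):
        with pytest.raises(ParameterError):
            features.ar_fit(np.ones(10), order=5)


class TestSpectral:
    def test_zero_signal(self):
        assert features.fft_features(np.zeros(64)) == (0.0, 0.0)
        assert features.stft_features(np.zeros(64)) == (0.0,) * 6

    def test_unit_impulse_energy(self):
        x = np.zeros(128)
        x[0] = 1.0
        energy, power = features.fft_features(x)
        assert energy == pytest.approx(1.0, rel=1e-12)
        assert power == pytest.approx(1.0 / 128, rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(arrays(np.float64, st.integers(6, 96),
                  elements=st.floats(-100, 100, allow_nan=False)))
    def test_parseval_identity(self, x):
        energy, power = features.fft_features(x)
        time_energy = float(np.sum(np.square(x)))
        assert energy == pytest.approx(time_energy, rel=1e-9, abs=1e-9)
        assert power == pytest.approx(time_energy / x.size, rel=1e-9, abs=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(arrays(np.float64, st.integers(2, 32).map(lambda k: 3 * k),
                  elements=st.floats(-100, 100, allow_nan=False)))
    def test_stft_windows_partition_energy(self, x):
        stft = features.stft_features(x)
        total, _ = features.fft_features(x)
        assert sum(stft[0::2]) == pytest.approx(total, rel=1e-9, abs=1e-9)

    def test_energy_concentrated_in_first_window(self, rng):
        x = np.zeros(300)
        x[:100] = rng.standard_normal(100)
        x[100:] = 0.01 * rng.standard_normal(200)
        stft = features.stft_features(x)
        total, _ = features.fft_features(x)
        assert stft[0] >= 0.9 * total

    def test_remainder_appended_to_last_window(self):
        x = np.arange(10, dtype=float)  # 10 = 3+3+4
        stft = features.stft_features(x)
        assert stft[0] == pytest.approx(float(np.sum(x[:3] ** 2)), rel=1e-12)
        assert stft[4] == pytest.approx(float(np.sum(x[6:] ** 2)), rel=1e-12)
        assert stft[5] == pytest.approx(float(np.sum(x[6:] ** 2)) / 4, rel=1e-12)


class TestWavelet:
    def test_zero_signal_zero_variances(self):
        assert np.all(features.dwt_variances(np.zeros(500)) == 0.0)

    def test_perfect_reconstruction(self, rng):
        for _ in range(10):
            x = rng.standard_normal(500)
            coeffs = pywt.wavedec(x, "db5", mode="symmetric", level=5)
            back = pywt.waverec(coeffs, "db5", mode="symmetric")[: x.size]
            assert np.max(np.abs(back - x)) / np.max(np.abs(x)) < 1e-8

    def test_constant_segment_details_vanish(self):
        """db5 has 5 vanishing moments: constants live in the approximation."""
        x = np.full(500, 2.0)
        approx, detail = pywt.dwt(x, "db5", mode="symmetric")
        interior = detail[3:-3]  # away from boundary effects
        assert np.max(np.abs(interior)) < 1e-10
        assert np.all(features.dwt_variances(x) < 1e-20)

    def test_variances_match_stepwise_decomposition(self, rng):
        x = rng.standard_normal(500)
        got = features.dwt_variances(x)
        approx = x
        for j in range(5):
            approx, _ = pywt.dwt(approx, "db5", mode="symmetric")
            assert got[j] == pytest.approx(np.var(approx, ddof=1), rel=1e-12)

    def test_detail_variant(self, rng):
        x = rng.standard_normal(500)
        a = features.dwt_variances(x, use_details=False)
        d = features.dwt_variances(x, use_details=True)
        assert not np.allclose(a, d)

    def test_too_short_names_minimum(self):
        with pytest.raises(ParameterError, match="288"):
            features.dwt_variances(np.zeros(100))


class TestExtract:
    def test_vector_length_and_order(self, rng):
        x = rng.standard_normal(500)
        vec = features.extract(x)
        assert vec.values.shape == (20,)
        assert len(features.FEATURE_NAMES) == 20
        assert vec.values[0] == pytest.approx(features.mav(x))
        assert vec.values[1] == features.zero_crossings(x)
        assert vec.values[7] == pytest.approx(features.fft_features(x)[0])
        assert vec.values[15] == pytest.approx(features.dwt_variances(x)[0])

    def test_zero_trial_gives_zero_vector_with_ar_flag(self):
        vec = features.extract(np.zeros(500))
        assert np.all(vec.values == 0.0)
        assert vec.ar_degenerate

    def test_batch_extract_shapes(self, rng):
        trials = [WindowedTrial(samples=rng.standard_normal(500),
                                label=gesture(i % 5), window_bounds=(0, 500))
                  for i in range(10)]
        ds = features.batch_extract(trials)
        assert ds.X.shape == (20, 10)
        assert ds.labels.tolist() == [i % 5 for i in range(10)]

    def test_csv_round_trip_lossless(self, tmp_path, rng):
        trials = [WindowedTrial(samples=rng.standard_normal(500),
                                label=gesture(i), window_bounds=(0, 500))
                  for i in range(5)]
        ds = features.batch_extract(trials)
        path = tmp_path / "features.csv"
        ds.to_csv(path)
        back = features.FeatureDataset.from_csv(path)
        np.testing.assert_array_equal(back.X, ds.X)
        np.testing.assert_array_equal(back.labels, ds.labels)


class TestStandardizer:
    def test_train_split_statistics(self, rng):
        X = rng.standard_normal((20, 100)) * 5 + 2
        scaler = features.Standardizer().fit(X)
        Z = scaler.transform(X)
        np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=1), 1.0, rtol=1e-12)

    def test_constant_feature_scale_one(self):
        X = np.ones((20, 10))
        scaler = features.Standardizer().fit(X)
        assert np.all(scaler.scale == 1.0)
        assert np.all(scaler.transform(X) == 0.0)

    def test_dict_round_trip(self, rng):
        X = rng.standard_normal((20, 30))
        scaler = features.Standardizer().fit(X)
        clone = features.Standardizer.from_dict(scaler.to_dict())
        np.testing.assert_allclose(clone.transform(X), scaler.transform(X))
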