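"""Filter design, zero-phase filtering, drift removal, windowing."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import periodogram

from eegemo import preprocess as pre
from eegemo.types import ConfigurationError, RawEEG, ValidationError


# ---- Bessel polynomial ---------------------------------------------------
def bessel_recurrence(n: int) -> list[int]:
    """Independent oracle: B_n(s) = (2n-1)·B_{n-1}(s) + s²·B_{n-2}(s)."""
    polys = {0: [1], 1: [1, 1]}
    for m in range(2, n + 1):
        a = [(2 * m - 1) * c for c in polys[m - 1]] + [0] * (len(polys[m - 2]) + 2 - len(polys[m - 1]))
        for k, c in enumerate(polys[m - 2]):
            a[k + 2] += c
        polys[m] = a
    return polys[n]


def test_bessel_poly_order_four_coefficients():
    # direct factorial evaluation: a_0..a_4 = 105, 105, 45, 10, 1
    assert pre.bessel_poly_coeffs(4) == [105, 105, 45, 10, 1]


def test_bessel_poly_order_zero():
    assert pre.bessel_poly_coeffs(0) == [1]


@pytest.mark.parametrize("n", range(1, 9))
def test_bessel_poly_matches_recurrence(n):
    assert pre.bessel_poly_coeffs(n) == bessel_recurrence(n)


def test_bessel_poly_leading_coefficient_is_one():
    for n in range(8):
        assert pre.bessel_poly_coeffs(n)[-1] == 1


def test_bessel_poly_rejects_negative_order():
    with pytest.raises(ValueError):
        pre.bessel_poly_coeffs(-1)


# ---- bandpass design -----------------------------------------------------
class TestBesselBandpass:
    def test_standard_design_is_stable(self):
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, 128.0)
        from scipy.signal import sos2zpk

        _, p, _ = sos2zpk(f.sos)
        assert np.all(np.abs(p) < 1.0)

    def test_minus_3db_at_band_edges(self):
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, 128.0)
        mags = f.magnitude_db(np.array([0.5, 40.0]))
        assert np.all(np.abs(mags + 3.0) < 0.5)

    def test_unity_gain_at_geometric_center(self):
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, 128.0)
        center = math.sqrt(0.5 * 40.0)
        assert abs(f.magnitude_db(np.array([center]))[0]) < 0.5

    def test_stopband_attenuation_matches_transfer_function(self):
        # numerically evaluated response: a 4th-order Bessel rolls off
        # slowly; 60 Hz at fs=256 sits ~9.8 dB down single-pass
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, 256.0)
        att = -f.magnitude_db(np.array([60.0]))[0]
        assert att > 9.0

    def test_group_delay_nearly_constant_in_passband(self):
        # Bessel waveform-preservation contract: dispersion across the mid
        # passband stays below one sample (the bandpass transform and
        # bilinear warping preclude exact analog flatness; any residual
        # phase is cancelled by the forward-backward application anyway)
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, 128.0)
        freqs = np.linspace(5.0, 30.0, 50)
        gd = f.group_delay(freqs)
        assert gd.max() - gd.min() < 1.0

    def test_bad_edges_rejected(self):
        for low, high in [(0.0, 40.0), (40.0, 0.5), (0.5, 70.0)]:
            with pytest.raises(ConfigurationError):
                pre.design_bessel_bandpass(low, high, 4, 128.0)


class TestZeroPhase:
    def test_inband_sine_no_lag(self, fs):
        t = np.arange(0, 10, 1 / fs)
        x = RawEEG(data=np.sin(2 * np.pi * 10 * t)[None, :], fs=fs)
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, fs)
        y = pre.zero_phase_filter(x, f)
        xc = np.correlate(x.data[0], y.data[0], mode="full")
        lag = np.argmax(xc) - (len(t) - 1)
        assert lag == 0

    def test_inband_phase_shift_below_one_degree(self, fs):
        t = np.arange(0, 20, 1 / fs)
        x = RawEEG(data=np.sin(2 * np.pi * 10 * t)[None, :], fs=fs)
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, fs)
        y = pre.zero_phase_filter(x, f)
        spec_in = np.fft.rfft(x.data[0])
        spec_out = np.fft.rfft(y.data[0])
        k = np.argmax(np.abs(spec_in))
        dphi = np.angle(spec_out[k] / spec_in[k])
        assert abs(np.degrees(dphi)) < 1.0

    def test_dc_offset_removed(self, fs):
        t = np.arange(0, 20, 1 / fs)
        x = RawEEG(data=(50.0 + np.sin(2 * np.pi * 10 * t))[None, :], fs=fs)
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, fs)
        y = pre.zero_phase_filter(x, f)
        assert abs(np.mean(y.data)) < 0.5  # < 1% of the 50 µV offset

    def test_two_pass_attenuation_doubles_single_pass(self):
        # FFT amplitude-ratio oracle on a composite 10 Hz + 60 Hz signal
        fs = 256.0
        t = np.arange(0, 20, 1 / fs)
        x = RawEEG(data=(np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 60 * t))[None, :], fs=fs)
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, fs)
        y = pre.zero_phase_filter(x, f)
        spec_in = np.abs(np.fft.rfft(x.data[0]))
        spec_out = np.abs(np.fft.rfft(y.data[0]))
        freqs = np.fft.rfftfreq(len(t), 1 / fs)
        k60 = np.argmin(np.abs(freqs - 60.0))
        att_db = 20 * np.log10(spec_in[k60] / spec_out[k60])
        single = -f.magnitude_db(np.array([60.0]))[0]
        assert att_db == pytest.approx(2 * single, rel=0.15)

    def test_too_short_signal_rejected(self, fs):
        x = RawEEG(data=np.zeros((1, 10)), fs=fs)
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, fs)
        with pytest.raises(ValidationError):
            pre.zero_phase_filter(x, f)

    def test_linearity(self, fs):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(1, 2000)), rng.normal(size=(1, 2000))
        f = pre.design_bessel_bandpass(0.5, 40.0, 4, fs)
        lhs = pre.zero_phase_filter(RawEEG(data=2 * a + 3 * b, fs=fs), f).data
        rhs = (
            2 * pre.zero_phase_filter(RawEEG(data=a, fs=fs), f).data
            + 3 * pre.zero_phase_filter(RawEEG(data=b, fs=fs), f).data
        )
        assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-9)


# ---- baseline removal ----------------------------------------------------
class TestRemoveBaseline:
    def test_zero_in_zero_out(self, fs):
        x = RawEEG(data=np.zeros((2, 1024)), fs=fs)
        y = pre.remove_baseline(x)
        assert y.data.shape == x.data.shape
        assert np.allclose(y.data, 0)

    def test_recovers_clean_sine_under_drift(self, fs):
        t = np.arange(0, 60, 1 / fs)
        clean = 10 * np.sin(2 * np.pi * 10 * t)
        drift = 30 * np.sin(2 * np.pi * 0.05 * t)
        y = pre.remove_baseline(RawEEG(data=(clean + drift)[None, :], fs=fs))
        r = np.corrcoef(y.data[0], clean)[0, 1]
        assert r >= 0.99

    def test_sub_half_hz_power_reduced_90pct(self, fs):
        t = np.arange(0, 60, 1 / fs)
        x = 10 * np.sin(2 * np.pi * 10 * t) + 30 * np.sin(2 * np.pi * 0.05 * t)
        raw = RawEEG(data=x[None, :], fs=fs)
        y = pre.remove_baseline(raw)
        f0, P0 = periodogram(raw.data[0], fs)
        f1, P1 = periodogram(y.data[0], fs)
        m = f0 < 0.5
        assert P1[m].sum() <= 0.1 * P0[m].sum()

    def test_preserves_alpha_band_power(self, fs):
        from eegemo.features import band_decompose

        t = np.arange(0, 60, 1 / fs)
        alpha = 10 * np.sin(2 * np.pi * 10 * t)
        drift = 30 * np.sin(2 * np.pi * 0.05 * t)
        before = np.var(band_decompose(RawEEG(data=alpha[None, :], fs=fs))["alpha"].data)
        y = pre.remove_baseline(RawEEG(data=(alpha + drift)[None, :], fs=fs))
        after = np.var(band_decompose(y)["alpha"].data)
        assert abs(after - before) / before < 0.05

    def test_linearity(self, fs):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(1, 2048)), rng.normal(size=(1, 2048))
        lhs = pre.remove_baseline(RawEEG(data=2 * a - b, fs=fs)).data
        rhs = 2 * pre.remove_baseline(RawEEG(data=a, fs=fs)).data - pre.remove_baseline(
            RawEEG(data=b, fs=fs)
        ).data
        assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-9)

    def test_unsupported_wavelet_lists_supported(self):
        with pytest.raises(ConfigurationError, match="bior"):
            pre.WaveletConfig(family="bior9.9")


# ---- windowing -----------------------------------------------------------
class TestTaper:
    def test_endpoints_zero(self):
        for M in (8, 65, 128):
            w = pre.hamming_window(M)
            assert w[0] == 0.0 and w[-1] == pytest.approx(0.0, abs=1e-12)

    def test_odd_midpoint_is_one(self):
        w = pre.hamming_window(65)
        assert w[32] == pytest.approx(1.0)

    def test_hamming_variant_floor(self):
        w = pre.hamming_window(64, variant="hamming")
        assert w[0] == pytest.approx(0.08)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pre.hamming_window(1)


class TestSegment:
    def test_one_second_windows_count(self, fs):
        x = RawEEG(data=np.zeros((3, int(60 * fs))), fs=fs)
        wins = pre.segment(x, pre.WindowPlan.one_second(fs))
        assert wins.shape == (60, 3, int(fs))

    def test_constant_signal_yields_taper(self, fs):
        plan = pre.WindowPlan.one_second(fs)
        x = RawEEG(data=np.ones((1, int(3 * fs))), fs=fs)
        wins = pre.segment(x, plan)
        for w in wins:
            assert np.allclose(w[0], plan.taper)

    def test_partial_window_dropped(self, fs):
        x = RawEEG(data=np.zeros((1, int(10.5 * fs))), fs=fs)
        wins = pre.segment(x, pre.WindowPlan.one_second(fs))
        assert wins.shape[0] == 10

    def test_window_longer_than_signal_rejected(self, fs):
        x = RawEEG(data=np.zeros((1, 64)), fs=fs)
        with pytest.raises(ValidationError):
            pre.segment(x, pre.WindowPlan.one_second(fs))


class TestMovingAverage:
    def test_identity_for_k_one(self):
        s = np.array([1.0, 4.0, 2.0])
        assert np.array_equal(pre.moving_average(s, 1), s)

    def test_hand_computed_centered_means(self):
        out = pre.moving_average(np.array([0.0, 0.0, 3.0, 0.0, 0.0]), 3)
        assert np.allclose(out, [0.0, 1.0, 1.0, 1.0, 0.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30))
    def test_constant_offset_invariance(self, vals):
        s = np.asarray(vals)
        assert np.allclose(pre.moving_average(s + 7.0, 3), pre.moving_average(s, 3) + 7.0, atol=1e-9)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            pre.moving_average(np.arange(10.0), 4)

    def test_k_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            pre.moving_average(np.arange(3.0), 5)
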