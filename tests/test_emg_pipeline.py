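"""Unit and property tests for the sEMG preprocessing / RMS feature chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reloop import ConfigurationError, InputError
from reloop import emg_pipeline as ep

from conftest import FS, make_recording, sinusoid, steady_state


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_zero_signal_stays_zero(self, filter_spec):
        rec = make_recording({"wrist_flexor": np.zeros(10_000)})
        out = ep.apply_bandpass(rec, filter_spec)
        assert np.allclose(out.channels["wrist_flexor"], 0.0)

    def test_passband_tone_preserved(self, filter_spec):
        """A 100 Hz unit tone sits mid-band and should pass within 5%.

        Amplitude is measured as sqrt(2) x RMS: at 10 samples per period the
        sampled maximum systematically undershoots the crest.
        """
        rec = make_recording({"wrist_flexor": sinusoid(100, 10)})
        out = steady_state(ep.apply_bandpass(rec, filter_spec).channels["wrist_flexor"])
        assert np.sqrt(2) * _rms(out) == pytest.approx(1.0, rel=0.05)

    def test_below_band_tone_rejected(self, filter_spec):
        """5 Hz is well below the 20 Hz edge: output RMS < 10% of input RMS."""
        x = sinusoid(5, 10)
        rec = make_recording({"wrist_flexor": x})
        out = steady_state(ep.apply_bandpass(rec, filter_spec).channels["wrist_flexor"])
        assert _rms(out) < 0.1 * _rms(x)

    def test_band_edge_beyond_nyquist_rejected(self):
        rec = make_recording({"wrist_flexor": np.zeros(5000)}, fs=250.0)
        with pytest.raises(ConfigurationError):
            ep.apply_bandpass(rec, ep.FilterSpec(band_high_hz=150.0))

    def test_too_short_signal_rejected(self, filter_spec):
        rec = make_recording({"wrist_flexor": np.zeros(3)})
        with pytest.raises(InputError):
            ep.apply_bandpass(rec, filter_spec)


class TestNotch:
    def test_zero_signal_stays_zero(self, filter_spec):
        rec = make_recording({"wrist_flexor": np.zeros(10_000)})
        out = ep.apply_notch(rec, filter_spec)
        assert np.allclose(out.channels["wrist_flexor"], 0.0)

    def test_powerline_tone_suppressed_40db(self, filter_spec):
        """50 Hz interference must be attenuated by at least 40 dB."""
        x = sinusoid(50, 10)
        rec = make_recording({"wrist_flexor": x})
        out = steady_state(ep.apply_notch(rec, filter_spec).channels["wrist_flexor"])
        assert _rms(out) <= 0.01 * _rms(x)

    def test_neighbouring_tone_untouched(self, filter_spec):
        rec = make_recording({"wrist_flexor": sinusoid(120, 10)})
        out = steady_state(ep.apply_notch(rec, filter_spec).channels["wrist_flexor"])
        assert np.max(np.abs(out)) == pytest.approx(1.0, rel=0.05)


class TestSegmentation:
    @pytest.mark.parametrize(
        "duration_s, window_s, step_s, expected",
        [(20.0, 5.0, 5.0, 4), (5.0, 5.0, 5.0, 1), (7.0, 5.0, 5.0, 1), (12.5, 5.0, 2.5, 4)],
    )
    def test_window_count(self, duration_s, window_s, step_s, expected):
        """floor((T - w)/s) + 1 full windows; trailing partials dropped."""
        rec = make_recording({"wrist_flexor": np.ones(int(duration_s * FS))})
        blocks = ep.segment_windows(rec, window_s, step_s)["wrist_flexor"]
        assert blocks.shape == (expected, int(window_s * FS))

    def test_window_longer_than_signal_rejected(self):
        rec = make_recording({"wrist_flexor": np.ones(1000)})
        with pytest.raises(InputError):
            ep.segment_windows(rec, 5.0, 5.0)

    def test_nonoverlapping_windows_partition_signal(self):
        x = np.arange(15_000, dtype=float)
        rec = make_recording({"wrist_flexor": x})
        blocks = ep.segment_windows(rec, 5.0, 5.0)["wrist_flexor"]
        assert np.array_equal(np.concatenate(blocks), x)


class TestRms:
    @pytest.mark.parametrize(
        "block, expected",
        [(np.full(100, -3.0), 3.0), (np.zeros(50), 0.0)],
    )
    def test_constant_and_zero_blocks(self, block, expected):
        assert ep.window_rms(block) == pytest.approx(expected)

    def test_sinusoid_rms_closed_form(self):
        """Amplitude-A sinusoid over whole periods has RMS A/sqrt(2)."""
        x = sinusoid(10, 1.0, amp=2.0)  # 10 whole periods
        assert ep.window_rms(x) == pytest.approx(2.0 / np.sqrt(2.0), abs=1e-6)

    def test_empty_block_rejected(self):
        with pytest.raises(InputError):
            ep.window_rms([])

    @pytest.mark.parametrize("values, expected", [([1, 1, 1], 1.0), ([0.2, 0.4], 0.3)])
    def test_mean_rms_arithmetic(self, values, expected):
        assert ep.mean_rms(values) == pytest.approx(expected)

    def test_mean_rms_matches_bruteforce_on_burst(self):
        """Windowed mean RMS equals a direct per-window recomputation."""
        rng = np.random.default_rng(42)
        x = rng.normal(scale=0.3, size=20_000)
        x[5000:10_000] *= 4.0
        rec = make_recording({"wrist_flexor": x})
        series = ep.rms_series(rec)["wrist_flexor"]
        brute = [
            np.sqrt(np.sum(x[i * 5000 : (i + 1) * 5000] ** 2) / 5000) for i in range(4)
        ]
        assert np.allclose(series.rms_mv, brute, atol=1e-9)
        assert ep.mean_rms(series) == pytest.approx(float(np.mean(brute)), abs=1e-9)

    def test_mean_rms_empty_rejected(self):
        with pytest.raises(InputError):
            ep.mean_rms([])


class TestRmsChange:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(1.0, 1.048, 4.8), (2.0, 2.0, 0.0), (0.5, 0.4, -20.0)],
    )
    def test_signed_percent_change(self, before, after, expected):
        assert ep.rms_change_percent(before, after) == pytest.approx(expected)

    @pytest.mark.parametrize("before", [0.0, -1.0])
    def test_nonpositive_baseline_rejected(self, before):
        with pytest.raises(InputError):
            ep.rms_change_percent(before, 1.0)


class TestProperties:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
    )
    def test_filtering_is_linear(self, a, b):
        """filter(a x + b y) == a filter(x) + b filter(y)."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=6000)
        y = rng.normal(size=6000)
        spec = ep.FilterSpec()

        def chain(sig):
            rec = make_recording({"wrist_flexor": sig})
            return ep.preprocess(rec, spec).channels["wrist_flexor"]

        lhs = chain(a * x + b * y)
        rhs = a * chain(x) + b * chain(y)
        assert np.allclose(lhs, rhs, atol=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(c=st.floats(-100, 100, allow_nan=False))
    def test_rms_scale_equivariance(self, c):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        assert ep.window_rms(c * x) == pytest.approx(abs(c) * ep.window_rms(x), abs=1e-9)


def _direct_zero_phase(b, a, x, padlen):
    """Independent oracle: odd-extension pad + direct difference equation,
    run forward then backward with zero initial state."""
    left = 2 * x[0] - x[padlen:0:-1]
    right = 2 * x[-1] - x[-2 : -padlen - 2 : -1]
    e = np.concatenate([left, x, right])

    def recurse(sig):
        bb = np.asarray(b) / a[0]
        aa = np.asarray(a) / a[0]
        y = np.zeros_like(sig)
        for n in range(sig.size):
            acc = 0.0
            for i in range(min(bb.size, n + 1)):
                acc += bb[i] * sig[n - i]
            for j in range(1, min(aa.size, n + 1)):
                acc -= aa[j] * y[n - j]
            y[n] = acc
        return y

    y = recurse(e)
    y = recurse(y[::-1])[::-1]
    return y[padlen:-padlen]


def test_full_chain_matches_direct_convolution_oracle():
    """bandpass -> notch -> window -> RMS agrees with a direct
    difference-equation + direct-RMS reimplementation to 1e-6 relative."""
    from scipy import signal as ss

    t = np.arange(int(30 * FS)) / FS
    x = 0.4 * np.sin(2 * np.pi * 40 * t) + 0.25 * np.sin(2 * np.pi * 100 * t)
    rec = make_recording({"wrist_flexor": x})
    spec = ep.FilterSpec()
    blocks = ep.segment_windows(ep.preprocess(rec, spec))["wrist_flexor"]
    rms_impl = np.sqrt(np.mean(np.square(blocks), axis=1))

    bb, ab = ss.butter(4, [20, 150], btype="bandpass", fs=FS, output="ba")
    bn, an = ss.iirnotch(50, 30, fs=FS)
    padlen = int(3 * FS)
    y = _direct_zero_phase(bb, ab, x, padlen)
    y = _direct_zero_phase(bn, an, y, padlen)
    import math

    rms_oracle = np.array(
        [
            math.sqrt(sum(v * v for v in y[i * 5000 : (i + 1) * 5000]) / 5000)
            for i in range(6)
        ]
    )
    assert np.max(np.abs(rms_impl - rms_oracle) / rms_oracle) < 1e-6
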