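import numpy as np
import pytest

from reloop import emg_pipeline as ep

FS = 1000.0


def make_recording(signals: dict, fs: float = FS, **kw) -> ep.EmgRecording:
    """Build a two-channel recording, filling missing channels with zeros."""
    n = max(np.size(v) for v in signals.values())
    channels = {
        name: np.asarray(signals.get(name, np.zeros(n)), dtype=float)
        for name in ep.CHANNELS
    }
    return ep.EmgRecording(
        subject_id=kw.pop("subject_id", "T01"),
        phase=kw.pop("phase", "pre"),
        channels=channels,
        sample_rate_hz=fs,
        **kw,
    )


def sinusoid(freq_hz: float, duration_s: float, fs: float = FS, amp: float = 1.0):
    t = np.arange(int(round(duration_s * fs))) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


def steady_state(x: np.ndarray, fs: float = FS, edge_s: float = 0.5) -> np.ndarray:
    """Drop the first/last ``edge_s`` seconds (filter edge transients)."""
    k = int(round(edge_s * fs))
    return x[k:-k] if x.size > 2 * k else x


@pytest.fixture
def filter_spec():
    return ep.FilterSpec()
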