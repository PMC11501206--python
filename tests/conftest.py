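import numpy as np
import pytest

from epiphen.synth import SynthConfig, gen_background


@pytest.fixture(scope="session")
def bg600():
    """A 600-s, 4-channel background recording (seed 1) plus its manifest.

    Session-scoped and read-only: tests that inject events must copy the
    recording first.
    """
    rec, manifest = gen_background(SynthConfig(duration_s=600.0, seed=1))
    return rec, manifest


@pytest.fixture()
def bg600_copy(bg600):
    rec, manifest = bg600
    from copy import deepcopy
    return rec.copy(), deepcopy(manifest)


def make_sine_recording(amplitudes, fs=500.0, freq_hz=8.0, n_channels=1):
    """Piecewise sinusoid: ``amplitudes`` is a list of (duration_s, amp)
    segments concatenated in time, same on all channels."""
    from epiphen.eeg_io import Recording

    parts = []
    for dur, amp in amplitudes:
        t = np.arange(int(round(dur * fs))) / fs
        parts.append(amp * np.sin(2 * np.pi * freq_hz * t))
    x = np.concatenate(parts)
    sig = np.tile(x, (n_channels, 1))
    channels = tuple(f"ch{i}" for i in range(n_channels))
    return Recording(signal=sig, fs=fs, channels=channels)
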