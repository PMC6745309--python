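import numpy as np
import pytest

from delphi_tep.containers import EvokedResponse, RawTEPRecording, StimulationEvent
from delphi_tep.montage import default_montage
from delphi_tep.simulate import ComponentSpec, PHENOTYPES, ProtocolSpec, simulate_recording


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_protocol():
    return ProtocolSpec().small()


@pytest.fixture(scope="session")
def small_recording(small_protocol):
    """One fast synthetic session at 1 kHz (structure of the full protocol)."""
    return simulate_recording(
        "adult", small_protocol, seed=11, sampling_rate_hz=1000.0, subject_id="fix"
    )


@pytest.fixture(scope="session")
def component_spec():
    return ComponentSpec()


def make_composite(time_ms, components):
    """Sum of Gaussians: components = [(center, width, amplitude), ...]."""
    t = np.asarray(time_ms, dtype=float)
    v = np.zeros_like(t)
    for center, width, amp in components:
        v += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return v


CANONICAL = [(45.0, 8.0, -3.0), (60.0, 8.0, 4.0), (100.0, 15.0, -8.0), (180.0, 25.0, 5.0)]


@pytest.fixture()
def canonical_evoked():
    t = np.arange(-500.0, 500.0, 1.0)
    return EvokedResponse(make_composite(t, CANONICAL)[None, :], t, 1)


def flat_recording(montage, fs=1000.0, dur_s=20.0, events=None, value=0.0):
    data = np.full((montage.n_channels, int(dur_s * fs)), value)
    return RawTEPRecording(
        data=data, sampling_rate_hz=fs, events=events or [], montage=montage
    )


def events_at(times, intensity=40.0, freq=0.1, sham=False):
    return [StimulationEvent(t, intensity, freq, 0, sham) for t in times]
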