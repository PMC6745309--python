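"""Core in-memory containers for the TMS-EEG evoked-potential pipeline.

Conventions used throughout the package:

* voltages are microvolts (µV),
* time within an epoch is milliseconds relative to the TMS pulse at 0,
* selection windows are half-open ``[start, end)``; integration windows
  (charge transfer, connectivity) include both edge samples because the
  trapezoid rule needs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StimulationEvent",
    "RawTEPRecording",
    "EpochSet",
    "EvokedResponse",
    "QCReport",
]


@dataclass(frozen=True)
class StimulationEvent:
    """A single TMS pulse: when it occurred and how it was delivered.

    Parameters
    ----------
    onset_time : float
        Seconds from recording start.
    intensity_pct : float
        Stimulation intensity in % of maximal stimulator output (MSO).
    train_frequency_hz : float
        Nominal frequency of the train the pulse belongs to (0.1 Hz class
        for isolated single pulses).
    block_id : int
        Protocol block the pulse was delivered in.
    sham : bool
        True when the coil was spaced from the scalp (sham stimulation).
    """

    onset_time: float
    intensity_pct: float
    train_frequency_hz: float
    block_id: int = 0
    sham: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity_pct <= 100.0:
            raise ValueError(
                f"intensity_pct must lie in [0, 100], got {self.intensity_pct}"
            )
        if self.train_frequency_hz < 0:
            raise ValueError("train_frequency_hz must be >= 0")


@dataclass
class RawTEPRecording:
    """Continuous multichannel EEG with TMS stimulation events.

    ``data`` is channels x samples in µV, channel order matching
    ``montage.electrode_names``.
    """

    data: np.ndarray
    sampling_rate_hz: float
    events: list[StimulationEvent]
    montage: "SensorMontage"  # noqa: F821 - defined in montage.py
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.montage is not None and self.data.shape[0] != len(
            self.montage.electrode_names
        ):
            raise ValueError(
                "channel count does not match montage: "
                f"{self.data.shape[0]} != {len(self.montage.electrode_names)}"
            )
        onsets = [ev.onset_time for ev in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onset times must be strictly increasing")
        if onsets and onsets[-1] >= self.duration_s:
            raise ValueError("event onset beyond recording end")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, **kw) -> "RawTEPRecording":
        out = replace(self, **kw)
        return out


@dataclass
class EpochSet:
    """Trials x channels x time array cut around each pulse.

    ``trial_meta`` is a list of dicts with keys ``intensity_pct``,
    ``train_frequency_hz``, ``block_id`` and ``sham`` copied from the
    originating events.
    """

    data: np.ndarray
    time_axis_ms: np.ndarray
    trial_meta: list[dict]
    baseline_window_ms: tuple[float, float]
    montage: "SensorMontage" = None  # noqa: F821

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis_ms = np.asarray(self.time_axis_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.time_axis_ms.size:
            raise ValueError("time axis length mismatch")
        if np.any(np.diff(self.time_axis_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, indices) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[indices],
            time_axis_ms=self.time_axis_ms,
            trial_meta=[self.trial_meta[i] for i in indices],
            baseline_window_ms=self.baseline_window_ms,
            montage=self.montage,
        )


@dataclass
class EvokedResponse:
    """Trial-averaged channels x time waveform for one condition."""

    data: np.ndarray
    time_axis_ms: np.ndarray
    n_trials: int
    condition: dict = field(default_factory=dict)
    montage: "SensorMontage" = None  # noqa: F821

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis_ms = np.asarray(self.time_axis_ms, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.time_axis_ms.size:
            raise ValueError("data must be channels x time matching time axis")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def scaled(self, c: float) -> "EvokedResponse":
        return EvokedResponse(
            data=self.data * c,
            time_axis_ms=self.time_axis_ms,
            n_trials=self.n_trials,
            condition=dict(self.condition),
            montage=self.montage,
        )


@dataclass
class QCReport:
    """Trial-rejection bookkeeping for one recording."""

    n_trials_in: int
    n_trials_kept: int
    rejected_indices: list[int] = field(default_factory=list)
    channel_noise_rms_uv: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_trials_kept + len(self.rejected_indices) != self.n_trials_in:
            raise ValueError("kept + rejected must equal trials in")

    def to_dict(self) -> dict:
        return {
            "n_trials_in": self.n_trials_in,
            "n_trials_kept": self.n_trials_kept,
            "rejected_indices": list(map(int, self.rejected_indices)),
            "channel_noise_rms_uv": {
                k: float(v) for k, v in self.channel_noise_rms_uv.items()
            },
            "flags": list(self.flags),
        }
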