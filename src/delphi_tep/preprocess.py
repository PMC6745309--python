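"""Raw-recording cleaning, epoching, trial rejection and averaging.

The cleaning is deliberately conservative and fully reviewable: pulse
artifact samples are replaced by a cubic polynomial through the flanking
samples (cannot ring), then a zero-phase band-pass plus mains notch is
applied and the data resampled. All windows are configurable; defaults
are typical for TEP work and preserve N45 morphology.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet, EvokedResponse, QCReport, RawTEPRecording
from .plasticity import FrequencyClasses

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    """A condition selector matched no trials."""


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            if lo < merged[-1][1]:
                logger.warning("overlapping pulse-artifact windows merged")
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def remove_pulse_artifact(
    rec: RawTEPRecording, window_ms: tuple[float, float] = (-2.0, 10.0)
) -> RawTEPRecording:
    """Replace samples in a window around each pulse by cubic interpolation.

    The window must contain 0 (the pulse). Two samples on each flank anchor
    a cubic polynomial per channel; flat or linear flanks are reproduced
    exactly, and samples outside the windows are untouched bit-exact.
    """
    pre, post = window_ms
    if not (pre <= 0.0 <= post):
        raise ValueError("artifact window must contain the pulse at 0 ms")
    fs = rec.sampling_rate_hz
    n = rec.n_samples
    spans = []
    for ev in rec.events:
        center = int(round(ev.onset_time * fs))
        lo = center + int(math.floor(pre * fs / 1000.0))
        hi = center + int(math.ceil(post * fs / 1000.0)) + 1
        spans.append((max(lo, 0), min(hi, n)))
    data = rec.data.copy()
    for lo, hi in _merge_windows(spans):
        flank = [i for i in (lo - 2, lo - 1, hi, hi + 1) if 0 <= i < n]
        if len(flank) < 2:
            continue  # window swallows a recording edge; nothing to anchor on
        x = np.asarray(flank, dtype=float)
        y = data[:, flank].T  # points x channels
        deg = min(3, len(flank) - 1)
        coeffs = np.polyfit(x - lo, y, deg)
        inside = np.arange(lo, hi, dtype=float) - lo
        data[:, lo:hi] = np.polyval(coeffs, inside[:, None]).T
    return rec.copy_with(data=data)


def filter_recording(
    rec: RawTEPRecording,
    band_hz: tuple[float, float] = (1.0, 80.0),
    notch_hz: float | None = 50.0,
    resample_hz: float | None = 1000.0,
) -> RawTEPRecording:
    """Zero-phase band-pass + mains notch, then polyphase resampling.

    Event onsets are kept in seconds so they remain valid on the new
    sampling grid.
    """
    low, high = band_hz
    target_fs = resample_hz or rec.sampling_rate_hz
    if not 0 < low < high:
        raise ValueError("band must satisfy 0 < low < high")
    if high >= target_fs / 2:
        raise ValueError(
            f"band edge {high} Hz at or above Nyquist of {target_fs} Hz resample rate"
        )
    fs = rec.sampling_rate_hz
    data = rec.data
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    if notch_hz:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=fs)
        data = signal.filtfilt(b, a, data, axis=1)
    if resample_hz and resample_hz != fs:
        frac = Fraction(resample_hz / fs).limit_denominator(10000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    return RawTEPRecording(
        data=np.ascontiguousarray(data),
        sampling_rate_hz=float(target_fs),
        events=list(rec.events),
        montage=rec.montage,
        subject_id=rec.subject_id,
    )


def epoch_and_baseline(
    rec: RawTEPRecording,
    tmin_ms: float = -500.0,
    tmax_ms: float = 500.0,
    baseline_ms: tuple[float, float] = (-300.0, -50.0),
) -> EpochSet:
    """Cut one trial per event ([tmin, tmax) ms) and subtract the per-trial,
    per-channel baseline mean. Events too close to a recording edge are
    dropped and logged."""
    fs = rec.sampling_rate_hz
    i_min = int(round(tmin_ms * fs / 1000.0))
    n_t = int(round((tmax_ms - tmin_ms) * fs / 1000.0))
    time_axis = (np.arange(n_t) + i_min) / fs * 1000.0
    trials, meta, dropped = [], [], []
    for k, ev in enumerate(rec.events):
        center = int(round(ev.onset_time * fs))
        lo, hi = center + i_min, center + i_min + n_t
        if lo < 0 or hi > rec.n_samples:
            dropped.append(k)
            continue
        trials.append(rec.data[:, lo:hi])
        meta.append(
            {
                "intensity_pct": ev.intensity_pct,
                "train_frequency_hz": ev.train_frequency_hz,
                "block_id": ev.block_id,
                "sham": ev.sham,
            }
        )
    if dropped:
        logger.warning("dropped %d event(s) too close to recording edge", len(dropped))
    data = np.stack(trials) if trials else np.empty((0, rec.n_channels, n_t))
    b0, b1 = baseline_ms
    bmask = (time_axis >= b0) & (time_axis < b1)
    if bmask.any():
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    ep = EpochSet(
        data=data,
        time_axis_ms=time_axis,
        trial_meta=meta,
        baseline_window_ms=(b0, b1),
        montage=rec.montage,
    )
    ep.dropped_event_indices = dropped
    return ep


def reject_trials(
    ep: EpochSet,
    amp_thresh_uv: float = 150.0,
    flat_thresh_uv: float = 0.1,
    artifact_window_ms: tuple[float, float] = (-2.0, 10.0),
) -> tuple[EpochSet, QCReport]:
    """Drop trials with excursions beyond ``amp_thresh_uv`` outside the
    pulse-artifact window, or with a flat (dead) channel."""
    if amp_thresh_uv <= 0 or flat_thresh_uv <= 0:
        raise ValueError("thresholds must be > 0")
    t = ep.time_axis_ms
    outside = (t < artifact_window_ms[0]) | (t >= artifact_window_ms[1])
    amp_bad = np.abs(ep.data[:, :, outside]).max(axis=(1, 2)) > amp_thresh_uv
    p2p = ep.data.max(axis=2) - ep.data.min(axis=2)
    flat_bad = (p2p < flat_thresh_uv).any(axis=1)
    bad = amp_bad | flat_bad
    rejected = np.flatnonzero(bad).tolist()
    kept = ep.select(np.flatnonzero(~bad)) if (~bad).any() else None
    flags = []
    if flat_bad.any():
        flags.append("flat_channel_trials")
    if kept is None:
        raise RuntimeError(
            "all trials rejected; review amplitude/flat thresholds and input quality"
        )
    b0, b1 = ep.baseline_window_ms
    bmask = (t >= b0) & (t < b1)
    noise = np.sqrt((kept.data[:, :, bmask] ** 2).mean(axis=(0, 2)))
    names = (
        ep.montage.electrode_names
        if ep.montage is not None
        else [f"ch{i}" for i in range(ep.data.shape[1])]
    )
    report = QCReport(
        n_trials_in=ep.n_trials,
        n_trials_kept=kept.n_trials,
        rejected_indices=rejected,
        channel_noise_rms_uv=dict(zip(names, noise)),
        flags=flags,
    )
    return kept, report


@dataclass(frozen=True)
class ConditionSelector:
    """Selects trials by intensity range, frequency class and/or sham flag."""

    intensity_range: tuple[float, float] | None = None
    frequency_class: str | None = None  # baseline | inhibitory | excitatory
    sham: bool | None = None
    classes: FrequencyClasses = field(default_factory=FrequencyClasses)

    def matches(self, meta: dict) -> bool:
        if self.intensity_range is not None:
            lo, hi = self.intensity_range
            if not lo <= meta["intensity_pct"] <= hi:
                return False
        if self.frequency_class is not None:
            if self.classes.classify(meta["train_frequency_hz"]) != self.frequency_class:
                return False
        if self.sham is not None and bool(meta["sham"]) != self.sham:
            return False
        return True

    def describe(self) -> str:
        parts = []
        if self.intensity_range is not None:
            parts.append(f"intensity in {self.intensity_range}")
        if self.frequency_class is not None:
            parts.append(f"class={self.frequency_class}")
        if self.sham is not None:
            parts.append(f"sham={self.sham}")
        return ", ".join(parts) or "all trials"


def average_evoked(ep: EpochSet, selector: ConditionSelector | None = None) -> EvokedResponse:
    """Arithmetic mean over the selected trials."""
    selector = selector or ConditionSelector()
    idx = [i for i, m in enumerate(ep.trial_meta) if selector.matches(m)]
    if not idx:
        raise SelectionError(f"no trials match selector ({selector.describe()})")
    sub = ep.data[idx]
    return EvokedResponse(
        data=sub.mean(axis=0),
        time_axis_ms=ep.time_axis_ms,
        n_trials=len(idx),
        condition={
            "selector": selector.describe(),
            "frequency_class": selector.frequency_class,
            "intensity_range": selector.intensity_range,
        },
        montage=ep.montage,
    )
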