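"""Read and write EEG containers with TMS pulse markers.

BrainVision (.vhdr/.vmrk/.eeg) is the reference dialect: written here as
16-bit signed little-endian multiplexed binary at 0.5 µV/bit, which spans
the +/-16.384 mV input range of a typical DC amplifier. Reading goes
through :mod:`mne`; EDF is supported read-only the same way.

Marker convention (third-party data can be adapted to it): each pulse is a
marker of type ``Stimulus`` (or ``Sham`` for sham pulses) whose description
is ``S<intensity>/<frequency>/b<block>``, e.g. ``S40/0.1/b0`` for a pulse
at 40% maximal stimulator output in the 0.1 Hz class of block 0.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np

from .containers import RawTEPRecording, StimulationEvent
from .montage import SensorMontage, default_montage

logger = logging.getLogger(__name__)

#: µV per least-significant bit; int16 then spans +/-16384 µV.
RESOLUTION_UV = 0.5

_MARKER_RE = re.compile(
    r"^S(?P<intensity>[0-9.]+)/(?P<freq>[0-9.eE+-]+)(?:/b(?P<block>\d+))?$"
)


class FormatError(RuntimeError):
    """Input container is structurally unreadable (missing companion, bad binary)."""


class EventParseError(RuntimeError):
    """A pulse marker description does not follow the documented convention."""


def _parse_marker(description: str, index: int) -> StimulationEvent | None:
    """Parse an mne annotation description into a StimulationEvent skeleton.

    Returns None for non-pulse markers (New Segment etc.).
    """
    sham = False
    body = description
    if "/" in description:
        prefix, rest = description.split("/", 1)
        if prefix in ("Stimulus", "Sham"):
            sham = prefix == "Sham"
            body = rest
        elif prefix in ("New Segment", "Comment", "Response", "EDF Annotations"):
            return None
    body = body.strip()
    if body.startswith("New Segment") or body == "":
        return None
    m = _MARKER_RE.match(body)
    if m is None:
        raise EventParseError(
            f"marker {index}: cannot parse intensity/frequency from {description!r}"
        )
    return StimulationEvent(
        onset_time=0.0,  # filled by caller
        intensity_pct=float(m.group("intensity")),
        train_frequency_hz=float(m.group("freq")),
        block_id=int(m.group("block") or 0),
        sham=sham,
    )


def _events_from_annotations(raw, n_markers_hint: str) -> list[StimulationEvent]:
    events: list[StimulationEvent] = []
    for i, (onset, desc) in enumerate(
        zip(raw.annotations.onset, raw.annotations.description)
    ):
        parsed = _parse_marker(str(desc), i)
        if parsed is None:
            continue
        events.append(
            StimulationEvent(
                onset_time=float(onset),
                intensity_pct=parsed.intensity_pct,
                train_frequency_hz=parsed.train_frequency_hz,
                block_id=parsed.block_id,
                sham=parsed.sham,
            )
        )
    if not events:
        logger.warning("no pulse markers found in %s", n_markers_hint)
    return events


def _restrict_to_montage(raw, montage: SensorMontage) -> np.ndarray:
    missing = [ch for ch in montage.electrode_names if ch not in raw.ch_names]
    if missing:
        raise FormatError(f"recording lacks montage channels {missing}")
    raw = raw.copy().pick(list(montage.electrode_names))
    raw = raw.reorder_channels(list(montage.electrode_names))
    return raw.get_data() * 1e6  # Volts -> µV


def read_brainvision(
    header_path, montage: SensorMontage | None = None, subject_id: str | None = None
) -> RawTEPRecording:
    """Read a BrainVision triplet into a :class:`RawTEPRecording`.

    Channels are restricted and reordered to the montage, voltages converted
    to µV, and pulse markers parsed into events.
    """
    import mne

    header_path = Path(header_path)
    if montage is None:
        montage = default_montage()
    try:
        raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read BrainVision triplet {header_path}: {exc}") from exc
    data = _restrict_to_montage(raw, montage)
    _check_marker_positions(header_path, data.shape[1])
    events = _events_from_annotations(raw, str(header_path))
    try:
        return RawTEPRecording(
            data=data,
            sampling_rate_hz=float(raw.info["sfreq"]),
            events=events,
            montage=montage,
            subject_id=subject_id or header_path.stem,
        )
    except ValueError as exc:
        # markers beyond the data end indicate a truncated binary
        raise FormatError(f"inconsistent triplet {header_path}: {exc}") from exc


def _check_marker_positions(header_path: Path, n_samples: int) -> None:
    """A marker positioned beyond the data end means the binary is truncated
    relative to its marker file (mne silently drops such annotations)."""
    marker_path = header_path.with_suffix(".vmrk")
    if not marker_path.exists():
        return
    for line in marker_path.read_text(encoding="utf-8", errors="replace").splitlines():
        if not line.startswith("Mk") or "=" not in line:
            continue
        fields = line.split("=", 1)[1].split(",")
        if len(fields) >= 3 and fields[2].strip().isdigit():
            if int(fields[2]) > n_samples:
                raise FormatError(
                    f"{marker_path.name}: marker at sample {fields[2]} beyond "
                    f"data end ({n_samples} samples); binary may be truncated"
                )


def read_edf(
    path, montage: SensorMontage | None = None, subject_id: str | None = None
) -> RawTEPRecording:
    """Read an EDF/EDF+ file (secondary input dialect), same conventions."""
    import mne

    path = Path(path)
    if montage is None:
        montage = default_montage()
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    data = _restrict_to_montage(raw, montage)
    events = _events_from_annotations(raw, str(path))
    return RawTEPRecording(
        data=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        events=events,
        montage=montage,
        subject_id=subject_id or path.stem,
    )


def _format_marker(ev: StimulationEvent) -> tuple[str, str]:
    kind = "Sham" if ev.sham else "Stimulus"
    desc = f"S{ev.intensity_pct:g}/{ev.train_frequency_hz:g}/b{ev.block_id}"
    return kind, desc


def write_brainvision(rec: RawTEPRecording, header_path) -> Path:
    """Write a recording as a BrainVision triplet next to ``header_path``.

    Data are quantized to int16 at 0.5 µV/bit (max round-trip error one
    half bit); samples outside +/-16384 µV are clipped.
    """
    header_path = Path(header_path)
    if header_path.suffix != ".vhdr":
        raise ValueError("header_path must end in .vhdr")
    stem = header_path.stem
    data_path = header_path.with_suffix(".eeg")
    marker_path = header_path.with_suffix(".vmrk")

    sampling_interval_us = 1e6 / rec.sampling_rate_hz
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=INT_16",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.montage.electrode_names, start=1):
        lines.append(f"Ch{i}={name},,{RESOLUTION_UV:g},µV")
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    for k, ev in enumerate(rec.events, start=2):
        kind, desc = _format_marker(ev)
        pos = int(round(ev.onset_time * rec.sampling_rate_hz)) + 1  # 1-based
        mlines.append(f"Mk{k}={kind},{desc},{pos},1,0")
    marker_path.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    quantized = np.clip(
        np.round(rec.data / RESOLUTION_UV), -32768, 32767
    ).astype("<i2")
    quantized.T.tofile(data_path)  # multiplexed: sample-major
    return header_path
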