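"""Synthetic TMS-EEG cohort generator with known ground truth.

Every analysis stage in this package is validated against recordings
produced here: a left-M1 stimulation session of 420 pulses spanning
25-60% stimulator output and three frequency classes (single-pulse
baseline, 1 Hz inhibitory trains, 20 Hz excitatory trains), recorded on
the 20-electrode analysis montage at 5 kHz.

The evoked model is a sum of four Gaussian components (N45, P60, N100,
P180) whose amplitudes are scaled by a Boltzmann recruitment sigmoid of
stimulation intensity and by frequency-class modulation. Under the
inhibitory protocol the early components are scaled by ``m_q`` and the
late components by the signed ``m_slope``; healthy phenotypes have
``m_slope < 0`` (the protocol inverts the N100->P180 segment), the
mild-dementia (MD) phenotype carries a reversal flag that makes it
positive. With the default ``|m_slope| = m_q`` the injected
charge-transfer ratio is ``m_q`` and the injected late-slope ratio is
``m_slope``, so both are recoverable downstream.

Contralateral electrodes receive an attenuated copy of their homolog
mixed with an incoherent latency-perturbed variant; the mixing weight is
the interhemispheric coherence ``c`` (c=1 gives homologous r=1 by
construction; no conduction lag is modelled on the coherent pathway).

Phenotype parameter tables encode the *direction* of group effects
(amplitude and coherence decline with age, charge-transfer STP rises,
late-slope STP falls, MD reverses its sign); their magnitudes are
invented calibration constants, not measured values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import RawTEPRecording, StimulationEvent
from .montage import SensorMontage, default_montage

#: component -> (center ms, width ms, amplitude µV at full recruitment)
DEFAULT_COMPONENTS: dict[str, tuple[float, float, float]] = {
    "N45": (45.0, 8.0, -3.0),
    "P60": (60.0, 8.0, 4.0),
    "N100": (100.0, 15.0, -8.0),
    "P180": (180.0, 25.0, 5.0),
}

EARLY_COMPONENTS = ("N45", "P60")
LATE_COMPONENTS = ("N100", "P180")

#: spatial spread over the stimulated (left) hemisphere: gain and lag (ms)
#: relative to the C3 stimulation hub; contralateral homologs get an extra
#: attenuation factor.
IPSI_GAIN = {
    "C3": 1.00, "C5": 0.90, "CP1": 0.85,
    "CP5": 0.80, "CP3": 0.85, "FC5": 0.85,
    "F3": 0.75, "F5": 0.70,
    "O1": 0.60, "PO3": 0.65,
}
IPSI_LAG_MS = {
    "C3": 0.0, "C5": 0.5, "CP1": 1.0,
    "CP5": 2.0, "CP3": 1.5, "FC5": 1.5,
    "F3": 3.0, "F5": 3.5,
    "O1": 5.0, "PO3": 4.5,
}
CONTRA_ATTENUATION = 0.7

#: latency perturbation (ms) of the incoherent variant waveform
VARIANT_SHIFT_MS = {"N45": 20.0, "P60": 30.0, "N100": -35.0, "P180": 45.0}


@dataclass(frozen=True)
class ComponentSpec:
    components: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_COMPONENTS))

    def __post_init__(self) -> None:
        expected_signs = {"N45": -1, "P60": 1, "N100": -1, "P180": 1}
        for name, (center, width, amp) in self.components.items():
            if width <= 0:
                raise ValueError(f"{name}: width must be > 0")
            if np.sign(amp) != expected_signs[name]:
                raise ValueError(f"{name}: amplitude sign must be {expected_signs[name]}")


@dataclass(frozen=True)
class SubjectPhenotype:
    """Generator parameters for one subject class."""

    label: str
    amplitude_scale: float = 1.0
    coherence: float = 0.85
    slope_drift: float = 1.0  # multiplies P180 (single-pulse slope-ratio drift)
    m_q: float = 0.75  # inhibitory-protocol charge-transfer modulation
    m_slope: float = -0.75  # signed late-slope modulation (healthy < 0)
    stp_reversal: bool = False  # MD: late-slope STP sign flipped positive
    noise_sigma_uv: float = 1.6  # single-trial background RMS
    i50_pct: float = 40.0  # recruitment midpoint (% MSO)
    k_pct: float = 5.0  # recruitment steepness (% MSO)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")
        if self.stp_reversal and self.m_slope < 0:
            raise ValueError("reversal phenotype must have m_slope > 0")


#: default phenotype table; magnitudes are calibration constants encoding
#: only the direction of the group effects.
PHENOTYPES: dict[str, SubjectPhenotype] = {
    "young": SubjectPhenotype("young", 1.0, 0.85, 1.00, 0.70, -0.70, False),
    "adult": SubjectPhenotype("adult", 0.9, 0.70, 0.85, 0.75, -0.75, False),
    "elderly": SubjectPhenotype("elderly", 0.8, 0.55, 0.70, 0.85, -0.85, False),
    "md": SubjectPhenotype("md", 0.7, 0.35, 0.55, 0.90, +0.90, True),
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation schedule: 420 pulses across intensities and classes."""

    intensity_grid: tuple = (25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0)
    singles_per_intensity: int = 20
    single_freq_hz: float = 0.1
    single_isi_s: float = 1.1
    inhib_trains: int = 8
    inhib_pulses_per_train: int = 12
    inhib_extra_pulses: int = 4  # one short train at the grid midpoint
    inhib_freq_hz: float = 1.0
    excit_trains: int = 8
    excit_pulses_per_train: int = 20
    excit_freq_hz: float = 20.0
    inter_train_gap_s: float = 3.0
    start_offset_s: float = 2.0

    @property
    def n_pulses(self) -> int:
        return (
            len(self.intensity_grid) * self.singles_per_intensity
            + self.inhib_trains * self.inhib_pulses_per_train
            + self.inhib_extra_pulses
            + self.excit_trains * self.excit_pulses_per_train
        )

    def small(self) -> "ProtocolSpec":
        """A shrunk schedule for fast tests (same structure)."""
        return replace(
            self,
            singles_per_intensity=3,
            inhib_pulses_per_train=4,
            inhib_extra_pulses=0,
            excit_pulses_per_train=4,
            single_isi_s=1.05,
            inter_train_gap_s=1.2,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Group design: label -> (phenotype label, size); seed fixes everything."""

    groups: dict = field(
        default_factory=lambda: {
            "young": ("young", 5),
            "adult": ("adult", 5),
            "elderly": ("elderly", 5),
            "md": ("md", 5),
        }
    )
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    sampling_rate_hz: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, (ph, n) in self.groups.items():
            if n < 1:
                raise ValueError(f"group {label}: size must be >= 1")
            if ph not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {ph!r}")


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _component_amplitudes(
    spec: ComponentSpec,
    phenotype: SubjectPhenotype,
    intensity_pct: float,
) -> dict[str, float]:
    recruit = 1.0 / (1.0 + np.exp(-(intensity_pct - phenotype.i50_pct) / phenotype.k_pct))
    amps = {}
    for name, (_, _, amp) in spec.components.items():
        a = amp * phenotype.amplitude_scale * recruit
        if name == "P180":
            a *= phenotype.slope_drift
        amps[name] = a
    return amps


def _crossing_index(base: np.ndarray, t: np.ndarray, lag_ms: float) -> int | None:
    """Index just after the P60->N100 zero crossing of a channel's coherent
    waveform (search widened if the lagged window holds none)."""
    for lo, hi in ((55.0 + lag_ms, 105.0 + lag_ms), (40.0, 140.0)):
        idx = np.flatnonzero((t >= lo) & (t <= hi))
        if idx.size < 2:
            continue
        seg = base[idx]
        crossings = np.flatnonzero(seg[:-1] * seg[1:] <= 0)
        if crossings.size:
            return int(idx[crossings[0] + 1])
    return None  # degenerate (near-zero) waveform: nothing to flip


def _apply_protocol(
    w: np.ndarray,
    phenotype: SubjectPhenotype,
    protocol_class: str,
    flip_idx: int | None,
) -> np.ndarray:
    """Frequency-class modulation of one channel's baseline waveform.

    Inhibitory: scale by m_q, then scale the segment from ``flip_idx`` (the
    P60->N100 zero crossing of the channel's coherent waveform) by
    m_slope/m_q. With the default |m_slope| = m_q this is a pure sign flip
    of the late segment, which preserves |w| pointwise — so the injected
    charge-transfer ratio is exactly m_q and the injected late-slope ratio
    exactly m_slope. Excitatory: facilitation, scale by 1/m_q.
    """
    if protocol_class == "baseline":
        return w
    if protocol_class == "excitatory":
        return w / phenotype.m_q
    if protocol_class != "inhibitory":
        raise ValueError(f"unknown protocol class {protocol_class!r}")
    out = w * phenotype.m_q
    tail_factor = phenotype.m_slope / phenotype.m_q
    if tail_factor != 1.0 and flip_idx is not None:
        out[flip_idx:] = out[flip_idx:] * tail_factor
    return out


def _waveform(
    spec: ComponentSpec, amps: dict, t_ms: np.ndarray, lag_ms: float, shifts=None
) -> np.ndarray:
    w = np.zeros_like(t_ms)
    for name, (center, width, _) in spec.components.items():
        shift = (shifts or {}).get(name, 0.0)
        w += amps[name] * _gauss(t_ms, center + lag_ms + shift, width)
    return w


def simulate_evoked(
    spec: ComponentSpec,
    phenotype: SubjectPhenotype,
    intensity_pct: float,
    protocol_class: str = "baseline",
    time_axis_ms: np.ndarray | None = None,
    montage: SensorMontage | None = None,
) -> np.ndarray:
    """Noiseless channels x time evoked waveform (µV) on the montage."""
    montage = montage or default_montage()
    if time_axis_ms is None:
        time_axis_ms = np.arange(-100.0, 400.0, 1.0)
    t = np.asarray(time_axis_ms, dtype=float)
    amps = _component_amplitudes(spec, phenotype, intensity_pct)
    c = phenotype.coherence
    out = np.zeros((montage.n_channels, t.size))
    for i, name in enumerate(montage.electrode_names):
        if name in IPSI_GAIN:  # stimulated hemisphere
            lag = IPSI_LAG_MS[name]
            coherent = IPSI_GAIN[name] * _waveform(spec, amps, t, lag)
            w = coherent
        else:  # contralateral: coherent copy of homolog + incoherent variant
            h = montage.homolog(name)
            lag = IPSI_LAG_MS[h]
            coherent = IPSI_GAIN[h] * _waveform(spec, amps, t, lag)
            variant = IPSI_GAIN[h] * _waveform(
                spec, amps, t, lag, shifts=VARIANT_SHIFT_MS
            )
            w = CONTRA_ATTENUATION * (c * coherent + (1.0 - c) * variant)
        flip_idx = _crossing_index(coherent, t, lag)
        out[i] = _apply_protocol(w, phenotype, protocol_class, flip_idx)
    return out


def build_schedule(
    protocol: ProtocolSpec, rng: np.random.Generator, sham: bool = False
) -> list[StimulationEvent]:
    """Pulse schedule: shuffled single pulses, then inhibitory trains, then
    excitatory trains, with inter-train gaps."""
    events = []
    t = protocol.start_offset_s
    singles = [
        i for i in protocol.intensity_grid for _ in range(protocol.singles_per_intensity)
    ]
    rng.shuffle(singles)
    for inten in singles:
        events.append(StimulationEvent(t, inten, protocol.single_freq_hz, 0, sham))
        t += protocol.single_isi_s + rng.uniform(-0.05, 0.05)
    t += protocol.inter_train_gap_s
    grid = protocol.intensity_grid
    for k in range(protocol.inhib_trains):
        inten = grid[k % len(grid)]
        for _ in range(protocol.inhib_pulses_per_train):
            events.append(StimulationEvent(t, inten, protocol.inhib_freq_hz, 1, sham))
            t += 1.0 / protocol.inhib_freq_hz
        t += protocol.inter_train_gap_s
    if protocol.inhib_extra_pulses:
        inten = grid[len(grid) // 2]
        for _ in range(protocol.inhib_extra_pulses):
            events.append(StimulationEvent(t, inten, protocol.inhib_freq_hz, 1, sham))
            t += 1.0 / protocol.inhib_freq_hz
        t += protocol.inter_train_gap_s
    for k in range(protocol.excit_trains):
        inten = grid[k % len(grid)]
        for _ in range(protocol.excit_pulses_per_train):
            events.append(StimulationEvent(t, inten, protocol.excit_freq_hz, 2, sham))
            t += 1.0 / protocol.excit_freq_hz
        t += protocol.inter_train_gap_s
    return events


def pink_noise(
    rng: np.random.Generator, n: int, fs: float, alpha: float = 1.0
) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _background_noise(
    rng: np.random.Generator, n_channels: int, n: int, fs: float, sigma: float
) -> np.ndarray:
    """Per-channel 1/f + 50 Hz line + white noise with total RMS ``sigma``.

    Variance split: 60% pink, 30% white, 10% line.
    """
    out = np.empty((n_channels, n))
    t = np.arange(n) / fs
    for ch in range(n_channels):
        pink = pink_noise(rng, n, fs) * sigma * np.sqrt(0.6)
        white = rng.standard_normal(n) * sigma * np.sqrt(0.3)
        phase = rng.uniform(0, 2 * np.pi)
        line = sigma * np.sqrt(0.1) * np.sqrt(2.0) * np.sin(2 * np.pi * 50.0 * t + phase)
        out[ch] = pink + white + line
    return out


def _channel_gains(montage: SensorMontage) -> np.ndarray:
    gains = np.empty(montage.n_channels)
    for i, name in enumerate(montage.electrode_names):
        if name in IPSI_GAIN:
            gains[i] = IPSI_GAIN[name]
        else:
            gains[i] = CONTRA_ATTENUATION * IPSI_GAIN[montage.homolog(name)]
    return gains


def simulate_recording(
    phenotype: SubjectPhenotype | str,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    sampling_rate_hz: float = 5000.0,
    montage: SensorMontage | None = None,
    component_spec: ComponentSpec | None = None,
    sham: bool = False,
    evoked_scale: float = 1.0,
    subject_id: str = "sim",
) -> RawTEPRecording:
    """One full stimulation session, seed-deterministic.

    Each pulse inserts a decaying-exponential TMS artifact (first ~5 ms), the
    class- and intensity-dependent evoked waveform with log-normal
    trial-to-trial amplitude jitter, on top of 1/f + line + white background
    noise. With ``sham=True`` the same noise stream is generated and the
    evoked amplitudes are scaled to 3% (coil spaced from the scalp).
    """
    if isinstance(phenotype, str):
        phenotype = PHENOTYPES[phenotype]
    protocol = protocol or ProtocolSpec()
    montage = montage or default_montage()
    spec = component_spec or ComponentSpec()
    fs = float(sampling_rate_hz)
    rng = np.random.default_rng(seed)

    events = build_schedule(protocol, rng, sham=sham)
    # snap onsets to the sample grid so container round-trips are exact
    events = [
        StimulationEvent(
            round(ev.onset_time * fs) / fs,
            ev.intensity_pct,
            ev.train_frequency_hz,
            ev.block_id,
            ev.sham,
        )
        for ev in events
    ]
    n = int(round((events[-1].onset_time + 1.0) * fs))
    data = _background_noise(rng, montage.n_channels, n, fs, phenotype.noise_sigma_uv)

    gains = _channel_gains(montage)
    art_t = np.arange(0.0, 0.005, 1.0 / fs)
    artifact = 4000.0 * np.exp(-art_t / 0.0012)
    stamp_t = np.arange(0.0, 450.0, 1000.0 / fs)
    classes = {0: "baseline", 1: "inhibitory", 2: "excitatory"}
    amp_factor = (0.03 if sham else 1.0) * evoked_scale
    cache: dict = {}
    for ev in events:
        key = (ev.intensity_pct, classes[ev.block_id])
        if key not in cache:
            cache[key] = simulate_evoked(
                spec, phenotype, ev.intensity_pct, classes[ev.block_id],
                time_axis_ms=stamp_t, montage=montage,
            )
        jitter = float(np.exp(rng.normal(0.0, 0.08)))
        i0 = int(round(ev.onset_time * fs))
        hi = min(i0 + stamp_t.size, n)
        data[:, i0:hi] += amp_factor * jitter * cache[key][:, : hi - i0]
        ahi = min(i0 + art_t.size, n)
        data[:, i0:ahi] += (0.4 + 0.6 * gains)[:, None] * artifact[None, : ahi - i0]

    return RawTEPRecording(
        data=data,
        sampling_rate_hz=fs,
        events=events,
        montage=montage,
        subject_id=subject_id,
    )


def simulate_sham(
    phenotype: SubjectPhenotype | str,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    **kw,
) -> RawTEPRecording:
    """Sham session: identical schedule and noise stream for the same seed,
    evoked amplitudes attenuated to 3%, sham flag set on every event."""
    return simulate_recording(phenotype, protocol, seed, sham=True, **kw)


def _draw_subject_phenotype(
    base: SubjectPhenotype, rng: np.random.Generator
) -> SubjectPhenotype:
    m_q = base.m_q * float(np.exp(rng.normal(0.0, 0.03)))
    return replace(
        base,
        amplitude_scale=base.amplitude_scale * float(np.exp(rng.normal(0.0, 0.05))),
        coherence=float(np.clip(base.coherence + rng.normal(0.0, 0.03), 0.0, 1.0)),
        m_q=m_q,
        m_slope=float(np.sign(base.m_slope)) * m_q,
        i50_pct=base.i50_pct + float(rng.normal(0.0, 1.0)),
    )


def simulate_cohort(
    cohort: CohortSpec | None = None,
) -> list[tuple[RawTEPRecording, dict]]:
    """Per-subject recordings plus ground-truth records of every injected
    parameter (for recovery tests)."""
    cohort = cohort or CohortSpec()
    rng = np.random.default_rng(cohort.seed)
    out = []
    for group_label, (ph_label, size) in cohort.groups.items():
        base = PHENOTYPES[ph_label]
        for k in range(size):
            subject_id = f"{group_label}-{k:02d}"
            pheno = _draw_subject_phenotype(base, rng)
            seed = int(rng.integers(0, 2**31 - 1))
            rec = simulate_recording(
                pheno,
                cohort.protocol,
                seed=seed,
                sampling_rate_hz=cohort.sampling_rate_hz,
                subject_id=subject_id,
            )
            truth = {
                "subject_id": subject_id,
                "group_label": group_label,
                "phenotype": ph_label,
                "seed": seed,
                "amplitude_scale": pheno.amplitude_scale,
                "coherence": pheno.coherence,
                "slope_drift": pheno.slope_drift,
                "m_q": pheno.m_q,
                "m_slope": pheno.m_slope,
                "stp_reversal": pheno.stp_reversal,
                "noise_sigma_uv": pheno.noise_sigma_uv,
                "i50_pct": pheno.i50_pct,
                "k_pct": pheno.k_pct,
            }
            out.append((rec, truth))
    return out
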