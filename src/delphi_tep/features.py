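"""Single-pulse TEP features.

A TMS pulse over M1 evokes a stereotyped deflection sequence — N45, P60,
N100, P180 (negative/positive peaks at their nominal latencies in ms).
From an averaged evoked response this module extracts, per channel:

* component latencies and amplitudes (sign-constrained windowed extrema),
* the early (P60->N100) and late (N100->P180) slopes and their ratio,
* the charge transfer Q = rectified area over the 15-300 ms window,
* and, across stimulation intensities, the sigmoidal input/output
  recruitment curve.

When a window holds no sign-consistent local extremum (e.g. a
protocol-inverted late component), the largest-magnitude local extremum of
either sign is reported with ``found=False`` so that downstream slope
ratios remain defined; strict callers can discard unfound peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .containers import EpochSet, EvokedResponse
from .montage import REGION_ROLES, SensorMontage

#: component -> (sign, default search window [lo, hi) ms)
COMPONENTS: dict[str, tuple[int, tuple[float, float]]] = {
    "N45": (-1, (30.0, 57.0)),
    "P60": (+1, (50.0, 80.0)),
    "N100": (-1, (80.0, 140.0)),
    "P180": (+1, (140.0, 250.0)),
}

Q_WINDOW_MS = (15.0, 300.0)


@dataclass
class Peak:
    latency_ms: float
    amplitude_uv: float
    found: bool


@dataclass
class PeakSet:
    """Per-channel peak table: ``peaks[channel][component] -> Peak``."""

    peaks: list[dict]
    channel_names: tuple[str, ...]
    windows_ms: dict

    def component(self, name: str) -> list[Peak]:
        return [p[name] for p in self.peaks]


@dataclass
class SlopeFeatures:
    early_slope: np.ndarray  # µV/ms per channel
    late_slope: np.ndarray
    slope_ratio: np.ndarray  # late / early
    channel_names: tuple[str, ...]
    uses_unfound_peaks: np.ndarray = None  # bool per channel


@dataclass
class ChargeTransfer:
    q_uv_ms: np.ndarray  # per channel
    window_ms: tuple[float, float]
    channel_names: tuple[str, ...]


@dataclass
class IOCurve:
    intensities_pct: np.ndarray
    values: np.ndarray
    feature: str
    params: dict = field(default_factory=dict)  # floor, span, i50, k
    residual_rms: float = np.nan
    converged: bool = False

    def predict(self, intensity):
        p = self.params
        return p["floor"] + p["span"] / (
            1.0 + np.exp(-(np.asarray(intensity, dtype=float) - p["i50"]) / p["k"])
        )


def _local_extrema_mask(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of local minima / maxima of a 1-D trace (interior)."""
    minima = np.zeros(v.size, dtype=bool)
    maxima = np.zeros(v.size, dtype=bool)
    if v.size < 3:
        return minima, maxima
    left = v[1:-1] - v[:-2]
    right = v[2:] - v[1:-1]
    minima[1:-1] = (left < 0) & (right >= 0)
    maxima[1:-1] = (left > 0) & (right <= 0)
    return minima, maxima


def detect_peaks(
    ev: EvokedResponse,
    windows_ms: dict | None = None,
    noise_floor_k: float = 3.0,
) -> PeakSet:
    """Locate the four TEP components per channel.

    The reported peak is the local extremum of largest magnitude inside
    each half-open window, at sample resolution. The ``found`` confidence
    flag requires the extremum to carry the component's canonical sign
    (local minimum below zero for N, maximum above zero for P) and to
    exceed ``noise_floor_k`` times the pre-stimulus RMS (t <= -50 ms), so
    that a sham or absent response is not reported as a confident
    component. Magnitude outranks sign so that a protocol-inverted
    component is reported (flagged) rather than displaced by a small
    noise wiggle of the expected sign.
    """
    if windows_ms is None:
        windows_ms = {name: win for name, (_, win) in COMPONENTS.items()}
    t = ev.time_axis_ms
    for name, (lo, hi) in windows_ms.items():
        if lo < t[0] or hi > t[-1] + (t[1] - t[0]):
            raise ValueError(f"window {name} [{lo}, {hi}) outside evoked time axis")
    names = (
        ev.montage.electrode_names
        if ev.montage is not None
        else tuple(f"ch{i}" for i in range(ev.data.shape[0]))
    )
    pre_mask = t <= -50.0
    out = []
    for ch in range(ev.data.shape[0]):
        v = ev.data[ch]
        floor = (
            noise_floor_k * float(np.sqrt((v[pre_mask] ** 2).mean()))
            if pre_mask.any()
            else 0.0
        )
        minima, maxima = _local_extrema_mask(v)
        row = {}
        for name, (sign, _) in COMPONENTS.items():
            lo, hi = windows_ms[name]
            inwin = (t >= lo) & (t < hi)
            any_ext = inwin & (minima | maxima)
            pool = np.flatnonzero(any_ext if any_ext.any() else inwin)
            best = pool[np.argmax(np.abs(v[pool]))]
            consistent = bool(
                (minima if sign < 0 else maxima)[best]
                and sign * v[best] > 0
            )
            found = consistent and abs(v[best]) > floor
            row[name] = Peak(float(t[best]), float(v[best]), found)
        out.append(row)
    return PeakSet(peaks=out, channel_names=tuple(names), windows_ms=dict(windows_ms))


def compute_slopes(p: PeakSet, strict: bool = False) -> SlopeFeatures:
    """Early slope (P60->N100), late slope (N100->P180) and their ratio.

    Finite differences of the detected peak coordinates, no smoothing.
    With ``strict=True`` channels whose P60/N100/P180 were not
    sign-consistently found get NaN instead of fallback values.
    """
    n = len(p.peaks)
    early = np.full(n, np.nan)
    late = np.full(n, np.nan)
    ratio = np.full(n, np.nan)
    unfound = np.zeros(n, dtype=bool)
    for i, row in enumerate(p.peaks):
        p60, n100, p180 = row["P60"], row["N100"], row["P180"]
        unfound[i] = not (p60.found and n100.found and p180.found)
        if strict and unfound[i]:
            continue
        dt_e = n100.latency_ms - p60.latency_ms
        dt_l = p180.latency_ms - n100.latency_ms
        if dt_e == 0 or dt_l == 0:
            raise ValueError(f"degenerate peaks in channel {p.channel_names[i]}")
        early[i] = (n100.amplitude_uv - p60.amplitude_uv) / dt_e
        late[i] = (p180.amplitude_uv - n100.amplitude_uv) / dt_l
        if abs(early[i]) > 0:
            ratio[i] = late[i] / early[i]
    return SlopeFeatures(
        early_slope=early,
        late_slope=late,
        slope_ratio=ratio,
        channel_names=p.channel_names,
        uses_unfound_peaks=unfound,
    )


def _rectified_area(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact integral of |linear interpolant of v| along t, per channel.

    Equals the trapezoid rule of |v| on intervals without a sign change and
    integrates the triangle pair exactly across a zero crossing.
    """
    a, b = v[:, :-1], v[:, 1:]
    h = np.diff(t)
    same = a * b >= 0
    trap = 0.5 * (np.abs(a) + np.abs(b)) * h
    with np.errstate(divide="ignore", invalid="ignore"):
        cross = 0.5 * (a**2 + b**2) / (np.abs(a) + np.abs(b)) * h
    return np.where(same, trap, cross).sum(axis=1)


def compute_charge_transfer(
    ev: EvokedResponse, window_ms: tuple[float, float] = Q_WINDOW_MS
) -> ChargeTransfer:
    """Rectified area of the evoked response over the analysis window.

    Q = integral of |V(t)| with V the linear interpolant of the samples;
    both edge samples are included, so Q over [a, c] equals
    Q over [a, b] plus Q over [b, c] for any interior sample b.
    """
    lo, hi = window_ms
    t = ev.time_axis_ms
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ValueError(f"empty charge-transfer window [{lo}, {hi}] ms")
    q = _rectified_area(ev.data[:, mask], t[mask])
    names = (
        ev.montage.electrode_names
        if ev.montage is not None
        else tuple(f"ch{i}" for i in range(ev.data.shape[0]))
    )
    return ChargeTransfer(q_uv_ms=q, window_ms=(lo, hi), channel_names=tuple(names))


def _boltzmann(i, floor, span, i50, k):
    return floor + span / (1.0 + np.exp(-(i - i50) / k))


def fit_io_curve(
    epochs: EpochSet,
    feature: str = "q",
    window_ms: tuple[float, float] = Q_WINDOW_MS,
    channel: int | str | None = None,
) -> IOCurve:
    """Input/output recruitment: evoked feature vs stimulation intensity.

    Single-pulse trials (baseline frequency class) are averaged per distinct
    intensity level; the Boltzmann sigmoid
    ``floor + span / (1 + exp(-(I - I50)/k))`` is fitted by least squares
    from a fixed coarse initialization grid. With fewer than 4 intensity
    levels the raw grid is returned unfitted.
    """
    from .preprocess import ConditionSelector, average_evoked

    base = ConditionSelector(frequency_class="baseline")
    intensities = sorted(
        {
            m["intensity_pct"]
            for m in epochs.trial_meta
            if base.matches(m)
        }
    )
    values = []
    for inten in intensities:
        ev = average_evoked(
            epochs,
            ConditionSelector(
                intensity_range=(inten, inten), frequency_class="baseline"
            ),
        )
        t = ev.time_axis_ms
        mask = (t >= window_ms[0]) & (t <= window_ms[1])
        if channel is not None:
            ch = channel if isinstance(channel, int) else ev.montage.channel_index(channel)
            seg = ev.data[ch : ch + 1, :]
        else:
            seg = ev.data
        if feature == "q":
            per_ch = _rectified_area(seg[:, mask], t[mask])
        elif feature == "p2p":
            per_ch = seg[:, mask].max(axis=1) - seg[:, mask].min(axis=1)
        else:
            raise ValueError("feature must be 'q' or 'p2p'")
        values.append(float(per_ch.mean()))
    grid_i = np.asarray(intensities, dtype=float)
    grid_v = np.asarray(values, dtype=float)
    curve = IOCurve(intensities_pct=grid_i, values=grid_v, feature=feature)
    if grid_i.size < 4:
        return curve

    lo_i, hi_i = grid_i.min(), grid_i.max()
    floor0 = float(grid_v.min())
    span0 = float(max(grid_v.max() - grid_v.min(), 1e-12))
    best = None
    for i50_0 in np.linspace(lo_i, hi_i, 5):
        for k0 in (2.0, 5.0, 10.0):
            try:
                res = least_squares(
                    lambda p: _boltzmann(grid_i, *p) - grid_v,
                    x0=[floor0, span0, i50_0, k0],
                    bounds=([-np.inf, 0.0, lo_i - 30.0, 0.3],
                            [np.inf, np.inf, hi_i + 30.0, 100.0]),
                    method="trf",
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is not None and best.success:
        floor, span, i50, k = best.x
        curve.params = {"floor": float(floor), "span": float(span),
                        "i50": float(i50), "k": float(k)}
        curve.residual_rms = float(np.sqrt(2.0 * best.cost / grid_i.size))
        curve.converged = True
    return curve


def aggregate_by_region(
    values: np.ndarray, montage: SensorMontage
) -> dict[tuple[str, str], float]:
    """Mean of member-electrode feature values per region-role group
    (mean of features, not the feature of the mean waveform)."""
    values = np.asarray(values, dtype=float)
    out = {}
    for region, role in REGION_ROLES:
        out[(region, role)] = float(values[montage.group_indices(region, role)].mean())
    return out
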