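"""History dependence (short-term plasticity) of the evoked response.

Repeated stimulation modulates the TEP: trains in the low-frequency class
depress the response (LTD-like, "inhibitory" protocol), high-frequency
trains (>= 20 Hz) facilitate it ("excitatory" protocol). STP features are
dimensionless ratios of evoked features under a protocol relative to the
single-pulse baseline, so 1 means no modulation; a negative late-slope
ratio marks a sign reversal of the N100->P180 segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, EvokedResponse
from .features import (
    aggregate_by_region,
    compute_charge_transfer,
    compute_slopes,
    detect_peaks,
)
from .montage import REGION_ROLES


@dataclass(frozen=True)
class FrequencyClasses:
    """Protocol class boundaries in Hz. Baseline is the half-open low end
    [0, baseline_max]; the inhibitory class is [inhibitory_lo, inhibitory_hi];
    excitatory is everything at or above excitatory_min."""

    baseline_max: float = 0.5
    inhibitory_lo: float = 1.0
    inhibitory_hi: float = 5.0
    excitatory_min: float = 20.0

    def classify(self, freq_hz: float) -> str:
        if freq_hz <= self.baseline_max:
            return "baseline"
        if self.inhibitory_lo <= freq_hz <= self.inhibitory_hi:
            return "inhibitory"
        if freq_hz >= self.excitatory_min:
            return "excitatory"
        return "other"


def classify_trials_by_protocol(
    ep: EpochSet, classes: FrequencyClasses | None = None
) -> dict[str, list[int]]:
    """Partition trial indices into {baseline, inhibitory, excitatory, other}."""
    classes = classes or FrequencyClasses()
    parts: dict[str, list[int]] = {
        "baseline": [], "inhibitory": [], "excitatory": [], "other": []
    }
    for i, meta in enumerate(ep.trial_meta):
        parts[classes.classify(meta["train_frequency_hz"])].append(i)
    return parts


@dataclass
class STPProfile:
    """Protocol/baseline feature ratios, per channel and per region-role."""

    stp_q: np.ndarray
    stp_slope_late: np.ndarray
    stp_ratio: np.ndarray  # stp_q / stp_slope_late
    channel_names: tuple[str, ...]
    protocol_class: str
    region_values: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def region(self, feature: str) -> dict:
        return {rr: vals[feature] for rr, vals in self.region_values.items()}


def compute_stp(
    baseline_ev: EvokedResponse,
    protocol_ev: EvokedResponse,
    protocol_class: str = "inhibitory",
) -> STPProfile:
    """STP ratios of charge transfer and late slope, protocol over baseline.

    Channels with zero baseline Q or late slope get NaN with a flag;
    sign reversals of the late slope are preserved (negative ratios).
    """
    if baseline_ev.data.shape != protocol_ev.data.shape or not np.allclose(
        baseline_ev.time_axis_ms, protocol_ev.time_axis_ms
    ):
        raise ValueError("baseline and protocol evoked must share shape and time axis")
    q_b = compute_charge_transfer(baseline_ev).q_uv_ms
    q_p = compute_charge_transfer(protocol_ev).q_uv_ms
    sl_b = compute_slopes(detect_peaks(baseline_ev)).late_slope
    sl_p = compute_slopes(detect_peaks(protocol_ev)).late_slope

    flags = []
    with np.errstate(divide="ignore", invalid="ignore"):
        stp_q = np.where(q_b != 0, q_p / q_b, np.nan)
        stp_slope = np.where(sl_b != 0, sl_p / sl_b, np.nan)
        stp_ratio = np.where(np.abs(stp_slope) > 0, stp_q / stp_slope, np.nan)
    if np.isnan(stp_q).any():
        flags.append("zero_baseline_q")
    if np.isnan(stp_slope).any():
        flags.append("zero_baseline_late_slope")

    names = (
        baseline_ev.montage.electrode_names
        if baseline_ev.montage is not None
        else tuple(f"ch{i}" for i in range(baseline_ev.data.shape[0]))
    )
    region_values: dict = {}
    if baseline_ev.montage is not None and baseline_ev.montage.region_groups:
        agg_q = aggregate_by_region(stp_q, baseline_ev.montage)
        agg_s = aggregate_by_region(stp_slope, baseline_ev.montage)
        for rr in REGION_ROLES:
            s = agg_s[rr]
            region_values[rr] = {
                "stp_q": agg_q[rr],
                "stp_slope_late": s,
                "stp_ratio": agg_q[rr] / s if np.isfinite(s) and abs(s) > 0 else np.nan,
            }
    return STPProfile(
        stp_q=stp_q,
        stp_slope_late=stp_slope,
        stp_ratio=stp_ratio,
        channel_names=tuple(names),
        protocol_class=protocol_class,
        region_values=region_values,
        flags=flags,
    )


def stp_sign_feature(profile: STPProfile, tol: float = 1e-6) -> dict:
    """Sign (-1/0/+1) of the late-slope STP per region-role; NaN propagates."""
    out = {}
    for rr, vals in profile.region_values.items():
        v = vals["stp_slope_late"]
        if not np.isfinite(v):
            out[rr] = np.nan
        elif abs(v) < tol:
            out[rr] = 0
        else:
            out[rr] = int(np.sign(v))
    return out
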