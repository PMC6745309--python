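"""Subject-level physiological network profile.

Runs the full chain — artifact removal, filtering, epoching, rejection,
evoked averaging, single-pulse features, connectivity, short-term
plasticity — and assembles one profile: seven features per region-role
group (early/late slope, slope ratio, charge transfer Q, STP-Q, STP late
slope, STP ratio), a QC summary, and provenance. The demonstration
classifier labels a profile abnormal when the median region-level sign of
the late-slope STP is positive (the direction that separates a
mild-dementia phenotype from healthy aging); it is a demonstration rule,
not a clinical device.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .config import RunConfig
from .connectivity import evoked_connectivity, region_aggregate
from .containers import QCReport, RawTEPRecording
from .features import (
    aggregate_by_region,
    compute_charge_transfer,
    compute_slopes,
    detect_peaks,
    fit_io_curve,
)
from .montage import REGION_ROLES
from .plasticity import FrequencyClasses, compute_stp, stp_sign_feature
from .preprocess import (
    ConditionSelector,
    SelectionError,
    average_evoked,
    epoch_and_baseline,
    filter_recording,
    reject_trials,
    remove_pulse_artifact,
)

FEATURE_NAMES = (
    "early_slope",
    "late_slope",
    "slope_ratio",
    "q",
    "stp_q",
    "stp_slope_late",
    "stp_ratio",
)


class QCError(RuntimeError):
    def __init__(self, message: str, report: QCReport | None = None):
        super().__init__(message)
        self.report = report


@dataclass
class DelphiProfile:
    subject_id: str
    group_label: str | None
    features: dict  # (region, role) -> {feature: value}
    qc: dict
    provenance: dict
    flags: list = field(default_factory=list)
    # analysis intermediates kept for export/rendering
    connectivity_electrode: object = None
    connectivity_region: object = None
    io_curve: object = None
    peaks: object = None

    def to_dict(self) -> dict:
        def clean(v):
            return None if v is None or not np.isfinite(v) else float(v)

        return {
            "subject_id": self.subject_id,
            "group_label": self.group_label,
            "features": {
                f"{region}_{role}": {k: clean(v) for k, v in vals.items()}
                for (region, role), vals in self.features.items()
            },
            "qc": self.qc,
            "provenance": self.provenance,
            "flags": list(self.flags),
        }


def assemble_profile(
    rec: RawTEPRecording,
    config: RunConfig | None = None,
    group_label: str | None = None,
) -> DelphiProfile:
    """Run preprocessing, feature extraction, connectivity and plasticity
    with one configuration; deterministic for identical input and config."""
    cfg = config or RunConfig()
    flags: list[str] = []

    rec = remove_pulse_artifact(rec, cfg.artifact_window_ms)
    rec = filter_recording(rec, cfg.band_hz, cfg.notch_hz, cfg.resample_hz)
    ep = epoch_and_baseline(rec, *cfg.epoch_window_ms, cfg.baseline_ms)
    ep, qc = reject_trials(
        ep, cfg.reject["amp_uv"], cfg.reject["flat_uv"], cfg.artifact_window_ms
    )
    if qc.n_trials_kept < cfg.min_trial_retention * qc.n_trials_in:
        raise QCError(
            f"only {qc.n_trials_kept}/{qc.n_trials_in} trials retained "
            f"(minimum {cfg.min_trial_retention:.0%})",
            qc,
        )

    classes = FrequencyClasses(**cfg.freq_classes)
    baseline_ev = average_evoked(
        ep, ConditionSelector(frequency_class="baseline", classes=classes)
    )
    peaks = detect_peaks(baseline_ev)
    slopes = compute_slopes(peaks)
    q = compute_charge_transfer(baseline_ev, cfg.q_window_ms)
    if slopes.uses_unfound_peaks.any():
        flags.append("baseline_peaks_partially_unfound")

    conn_e = evoked_connectivity(baseline_ev, cfg.q_window_ms)
    conn_r = region_aggregate(conn_e, rec.montage)
    io = fit_io_curve(ep, cfg.io_feature, cfg.q_window_ms)

    nan_region = {rr: np.nan for rr in REGION_ROLES}
    stp_region = {rr: dict(stp_q=np.nan, stp_slope_late=np.nan, stp_ratio=np.nan)
                  for rr in REGION_ROLES}
    try:
        protocol_ev = average_evoked(
            ep, ConditionSelector(frequency_class=cfg.stp_protocol, classes=classes)
        )
        stp = compute_stp(baseline_ev, protocol_ev, cfg.stp_protocol)
        stp_region = stp.region_values
        flags.extend(stp.flags)
    except SelectionError:
        flags.append(f"no_{cfg.stp_protocol}_trials_stp_skipped")

    agg_early = aggregate_by_region(slopes.early_slope, rec.montage)
    agg_late = aggregate_by_region(slopes.late_slope, rec.montage)
    agg_ratio = aggregate_by_region(slopes.slope_ratio, rec.montage)
    agg_q = aggregate_by_region(q.q_uv_ms, rec.montage)

    features = {}
    for rr in REGION_ROLES:
        features[rr] = {
            "early_slope": agg_early[rr],
            "late_slope": agg_late[rr],
            "slope_ratio": agg_ratio[rr],
            "q": agg_q[rr],
            "stp_q": stp_region.get(rr, {}).get("stp_q", nan_region[rr]),
            "stp_slope_late": stp_region.get(rr, {}).get("stp_slope_late", np.nan),
            "stp_ratio": stp_region.get(rr, {}).get("stp_ratio", np.nan),
        }

    return DelphiProfile(
        subject_id=rec.subject_id,
        group_label=group_label,
        features=features,
        qc=qc.to_dict(),
        provenance={
            "config_hash": cfg.hash(),
            "software_version": __version__,
            "n_trials_baseline": int(baseline_ev.n_trials),
        },
        flags=flags,
        connectivity_electrode=conn_e,
        connectivity_region=conn_r,
        io_curve=io,
        peaks=peaks,
    )


def classify_profile(
    p: DelphiProfile, min_regions: int = 4, tol: float = 1e-6
) -> tuple[str, dict]:
    """Binary-step demonstration rule on the late-slope STP sign.

    Abnormal iff the median over region-roles of sign(stp_slope_late) is
    positive; healthy responses invert their late slope under the
    inhibitory protocol (negative sign). Returns (label, evidence).
    """
    signs = {}
    for rr, vals in p.features.items():
        v = vals.get("stp_slope_late", np.nan)
        if v is None or not np.isfinite(v):
            signs[rr] = np.nan
        else:
            signs[rr] = 0 if abs(v) < tol else int(np.sign(v))
    finite = [s for s in signs.values() if not (isinstance(s, float) and np.isnan(s))]
    evidence = {
        "per_region_sign": {f"{r}_{ro}": signs[(r, ro)] for r, ro in signs},
        "n_regions": len(finite),
        "rule": "abnormal iff median(sign(stp_slope_late)) > 0",
    }
    if len(finite) < min_regions:
        return "indeterminate", evidence
    med = float(np.median(finite))
    evidence["median_sign"] = med
    return ("abnormal" if med > 0 else "normal"), evidence
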