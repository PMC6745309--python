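"""Validation experiments: each function runs one synthetic-cohort study
of a pipeline property (oracle equivalence, parameter recovery, group
separation, reliability) and returns the measured quantities.

All randomness is driven by one integer seed; problem sizes default to
the scales the experiments are designed for and can be shrunk for quick
runs.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np
from scipy import signal as scisig
from scipy import stats as sps
from scipy.integrate import quad

from .connectivity import evoked_connectivity, group_mean_matrix, region_aggregate
from .containers import EvokedResponse
from .features import COMPONENTS, compute_charge_transfer, detect_peaks
from .montage import default_montage
from .plasticity import compute_stp, stp_sign_feature
from .simulate import (
    ComponentSpec,
    PHENOTYPES,
    _draw_subject_phenotype,
    simulate_evoked,
)
from .stats import anova_tukey, reliability, unpaired_t

TIME_MS = np.arange(-500.0, 500.0, 1.0)
CANONICAL = [(45.0, 8.0, -3.0), (60.0, 8.0, 4.0), (100.0, 15.0, -8.0), (180.0, 25.0, 5.0)]
_BPF = scisig.butter(4, [1.0, 80.0], btype="bandpass", fs=1000.0, output="sos")


def _composite(t, components):
    v = np.zeros_like(t)
    for c, w, a in components:
        v += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return v


def _random_components(rng):
    return [
        (rng.uniform(40, 50), rng.uniform(6, 10), -rng.uniform(2, 5)),
        (rng.uniform(58, 72), rng.uniform(6, 10), rng.uniform(2, 6)),
        (rng.uniform(90, 125), rng.uniform(12, 18), -rng.uniform(5, 10)),
        (rng.uniform(150, 230), rng.uniform(20, 30), rng.uniform(3, 7)),
    ]


def charge_transfer_oracle_error(seed: int, n_waveforms: int = 20) -> dict:
    """Q versus adaptive quadrature of the rectified interpolant."""
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_waveforms):
        v = _composite(TIME_MS, _random_components(rng))
        ev = EvokedResponse(v[None, :], TIME_MS, 1)
        q = compute_charge_transfer(ev).q_uv_ms[0]

        def f(x):
            return abs(np.interp(x, TIME_MS, v))

        # adaptive quadrature per sample interval: the integrand has at
        # most one kink inside each, so quad resolves it to full precision
        oracle = sum(quad(f, a, a + 1)[0] for a in range(15, 300))
        errs.append(abs(q - oracle) / oracle)
    return {"max_rel_err": float(max(errs)), "n": n_waveforms}


def peak_oracle_error(seed: int, n_waveforms: int = 20) -> dict:
    """Detected latencies versus dense-grid windowed argmax on noiseless
    sign-canonical composites."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_waveforms):
        comps = _random_components(rng)
        ev = EvokedResponse(_composite(TIME_MS, comps)[None, :], TIME_MS, 1)
        ps = detect_peaks(ev)
        for name, (sign, window) in COMPONENTS.items():
            tt = np.arange(window[0], window[1], 0.01)
            vv = _composite(tt, comps)
            lat = tt[np.argmin(vv) if sign < 0 else np.argmax(vv)]
            worst = max(worst, abs(ps.peaks[0][name].latency_ms - lat))
    return {"max_latency_err_ms": float(worst), "n": n_waveforms}


def feature_recovery_rate(seed: int, n_channels: int = 200) -> dict:
    """N100 latency within 3 ms and amplitude within 10% on 40-trial
    averages at single-trial SNR 5 (band-limited as the pipeline leaves
    data before feature extraction)."""
    rng = np.random.default_rng(seed)
    clean = _composite(TIME_MS, CANONICAL)
    tt = np.arange(80.0, 140.0, 0.01)
    vv = _composite(tt, CANONICAL)
    lat_true, amp_true = tt[np.argmin(vv)], vv.min()
    sigma = abs(amp_true) / 5.0
    hits = 0
    for _ in range(n_channels):
        avg = clean + rng.normal(0, sigma, (40, TIME_MS.size)).mean(axis=0)
        avg = scisig.sosfiltfilt(_BPF, avg)
        p = detect_peaks(EvokedResponse(avg[None, :], TIME_MS, 40)).peaks[0]["N100"]
        hits += (
            abs(p.latency_ms - lat_true) <= 3.0
            and abs(p.amplitude_uv - amp_true) <= 0.1 * abs(amp_true)
        )
    return {"pct_recovered": 100.0 * hits / n_channels, "n": n_channels}


def _stp_evoked_pair(phenotype, montage, rng=None, sigma=0.0, n_trials=40):
    spec = ComponentSpec()
    base = simulate_evoked(spec, phenotype, 50.0, "baseline", TIME_MS, montage)
    prot = simulate_evoked(spec, phenotype, 50.0, "inhibitory", TIME_MS, montage)
    if sigma:
        base = base + rng.normal(0, sigma, base.shape) / np.sqrt(n_trials)
        prot = prot + rng.normal(0, sigma, prot.shape) / np.sqrt(n_trials)
    return (
        EvokedResponse(base, TIME_MS, n_trials, montage=montage),
        EvokedResponse(prot, TIME_MS, n_trials, montage=montage),
    )


def stp_recovery_rate(seed: int, n_runs: int = 100) -> dict:
    """Injected inhibitory modulation m = 0.75 recovered as the
    charge-transfer STP ratio, noiseless and at SNR 5 / 40-trial averages."""
    montage = default_montage()
    ph = replace(PHENOTYPES["adult"], m_q=0.75, m_slope=-0.75)
    bev, pev = _stp_evoked_pair(ph, montage)
    zero_noise = compute_stp(bev, pev).stp_q
    pct_zero = 100.0 * np.mean(np.abs(zero_noise - 0.75) <= 0.05 * 0.75)
    rng = np.random.default_rng(seed)
    sigma = 8.0 * ph.amplitude_scale / 5.0  # N100 single-trial SNR 5
    hits = 0
    for _ in range(n_runs):
        bev, pev = _stp_evoked_pair(ph, montage, rng, sigma)
        got = float(np.median(compute_stp(bev, pev).stp_q))
        hits += abs(got - 0.75) <= 0.15 * 0.75
    return {
        "pct_within_5pct_zero_noise": float(pct_zero),
        "pct_within_15pct_snr5": 100.0 * hits / n_runs,
        "n": n_runs,
    }


def _interhemispheric_mean(region_matrix) -> float:
    vals = [
        region_matrix.entry(f"{reg}_ipsi", f"{reg}_contra")
        for reg in ("frontal", "parietal", "temporal", "occipital")
    ]
    return float(np.mean(vals))


def connectivity_monotonicity(
    seed: int, n_replicates: int = 20, n_subjects: int = 3
) -> dict:
    """Spearman correlation between the simulator coherence parameter and
    the recovered group-mean interhemispheric r, per seeded replicate."""
    montage = default_montage()
    levels = [0.1, 0.3, 0.5, 0.7, 0.9]
    rng = np.random.default_rng(seed)
    spec = ComponentSpec()
    rhos = []
    for _ in range(n_replicates):
        means = []
        for c in levels:
            mats = []
            for _ in range(n_subjects):
                ph = replace(PHENOTYPES["adult"], coherence=c)
                w = simulate_evoked(spec, ph, 50.0, "baseline", TIME_MS, montage)
                w = w + rng.normal(0, ph.noise_sigma_uv, w.shape) / np.sqrt(40)
                m = evoked_connectivity(
                    EvokedResponse(w, TIME_MS, 40, montage=montage)
                )
                mats.append(region_aggregate(m, montage))
            means.append(_interhemispheric_mean(group_mean_matrix(mats)))
        rhos.append(sps.spearmanr(levels, means).statistic)
    return {
        "mean_spearman": float(np.mean(rhos)),
        "min_spearman": float(np.min(rhos)),
        "n": n_replicates,
    }


def _classify_by_sign_rule(bev, pev) -> str:
    signs = [
        s for s in stp_sign_feature(compute_stp(bev, pev)).values()
        if np.isfinite(s)
    ]
    if len(signs) < 4:
        return "indeterminate"
    return "abnormal" if np.median(signs) > 0 else "normal"


def classifier_separation(seed: int, n_per_group: int = 10) -> dict:
    """Binary-step rule on the late-slope STP sign: healthy-elderly versus
    the MD reversal phenotype, noiseless and at the default noise level."""
    montage = default_montage()
    rng = np.random.default_rng(seed)
    results = {}
    for noise in ("zero", "default"):
        correct = 0
        for label, expected in (("elderly", "normal"), ("md", "abnormal")):
            for _ in range(n_per_group):
                ph = _draw_subject_phenotype(PHENOTYPES[label], rng)
                sigma = 0.0 if noise == "zero" else ph.noise_sigma_uv
                bev, pev = _stp_evoked_pair(ph, montage, rng, sigma)
                correct += _classify_by_sign_rule(bev, pev) == expected
        results[f"correct_{noise}_noise"] = correct
    results["n"] = 2 * n_per_group
    return results


def retest_reliability(seed: int, n_runs: int = 200, n_subjects: int = 30) -> dict:
    """Two sessions differing only in noise, true:noise variance 9:1; the
    attenuation closed form puts the expected r at 0.9."""
    rng = np.random.default_rng(seed)
    inside, rs = 0, []
    for _ in range(n_runs):
        true = rng.normal(0, 3.0, n_subjects)
        r, _ = reliability(
            true + rng.normal(0, 1.0, n_subjects),
            true + rng.normal(0, 1.0, n_subjects),
        )
        rs.append(r)
        inside += 0.8 <= r <= 0.97
    return {
        "pct_in_band": 100.0 * inside / n_runs,
        "mean_r": float(np.mean(rs)),
        "n": n_runs,
    }


def stats_closed_forms(seed: int, n_null: int = 2000) -> dict:
    """Textbook agreement of the statistical layer plus its null
    calibration (type-I error at alpha 0.05)."""
    t, df, p = unpaired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    t_err = abs(t - (-np.sqrt(1.5)))
    p_err = abs(p - 2 * sps.t.cdf(-np.sqrt(1.5), 4))
    res = anova_tukey({"x": [1.0, 2.0, 3.0], "y": [2.0, 3.0, 4.0]})
    f_err = abs(res.f_statistic - 1.5)  # F = t^2
    x = np.array([1.0, 2.0, 4.0, 8.0])
    r, _ = reliability(x, 2 * x + 1)
    r_err = abs(r - 1.0)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_null):
        groups = [rng.normal(0, 1, 15) for _ in range(3)]
        rejections += sps.f_oneway(*groups).pvalue < 0.05
    return {
        "max_closed_form_err": float(max(t_err, p_err, f_err, r_err)),
        "type1_error_rate": rejections / n_null,
        "n": n_null,
    }


def end_to_end_cohort(seed: int, out_dir, n_per_group: int = 5) -> dict:
    """Simulate the 4-group cohort at 1 kHz (full 420-pulse sessions),
    write it to disk and run the cohort pipeline to a full report."""
    from pathlib import Path

    from .cli import run_cohort, run_simulate
    from .simulate import CohortSpec

    out_dir = Path(out_dir)
    spec = CohortSpec(
        groups={
            "young": ("young", n_per_group),
            "adult": ("adult", n_per_group),
            "elderly": ("elderly", n_per_group),
            "md": ("md", n_per_group),
        },
        sampling_rate_hz=1000.0,
        seed=int(seed) % (2**31 - 1),
    )
    t0 = time.time()
    sim_code = run_simulate(out_dir / "dataset", spec)
    cohort_code = run_cohort(out_dir / "dataset" / "manifest.csv", out_dir / "report")
    return {
        "simulate_exit_code": sim_code,
        "cohort_exit_code": cohort_code,
        "runtime_s": time.time() - t0,
        "n": 4 * n_per_group,
    }
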