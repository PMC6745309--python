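"""Evoked-response Pearson connectivity.

"Coherence" here is waveform correlation: the Pearson r between the
single-pulse evoked responses of two sensors over the 15-300 ms analysis
window, computed on the subject-level average. Group matrices are
averaged through the Fisher z-transform (plain averaging of r is biased);
undefined correlations (a zero-variance channel) propagate as missing,
never imputed as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EvokedResponse
from .features import Q_WINDOW_MS
from .montage import REGION_ROLES, SensorMontage


@dataclass
class ConnectivityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    window_ms: tuple[float, float] = Q_WINDOW_MS
    n_subjects: int = 1
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")

    def validate(self) -> None:
        v = self.values
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("matrix not symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValueError("entries outside [-1, 1]")

    def entry(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def evoked_connectivity(
    ev: EvokedResponse, window_ms: tuple[float, float] = Q_WINDOW_MS
) -> ConnectivityMatrix:
    """Pairwise Pearson r between channel waveforms in the window."""
    t = ev.time_axis_ms
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    if mask.sum() < 3:
        raise ValueError("need >= 3 samples in the connectivity window")
    seg = ev.data[:, mask]
    sd = seg.std(axis=1)
    flags = []
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(seg)
    dead = sd == 0
    if dead.any():
        r[dead, :] = np.nan
        r[:, dead] = np.nan
        flags.append(f"zero_variance_channels={int(dead.sum())}")
    np.fill_diagonal(r, np.where(dead, np.nan, 1.0))
    r = np.clip(r, -1.0, 1.0)
    labels = (
        ev.montage.electrode_names
        if ev.montage is not None
        else tuple(f"ch{i}" for i in range(ev.data.shape[0]))
    )
    return ConnectivityMatrix(tuple(labels), r, (window_ms[0], window_ms[1]), 1, flags)


def region_aggregate(
    m: ConnectivityMatrix, montage: SensorMontage
) -> ConnectivityMatrix:
    """8x8 region-role matrix: mean r over all cross-electrode pairs; the
    diagonal is the mean within-group off-diagonal r (missing for
    single-electrode groups)."""
    index = {lab: i for i, lab in enumerate(m.labels)}
    labels = tuple(f"{region}_{role}" for region, role in REGION_ROLES)
    out = np.full((8, 8), np.nan)
    flags = list(m.flags)
    groups = [
        [index[e] for e in montage.group(region, role)] for region, role in REGION_ROLES
    ]
    for a, ga in enumerate(groups):
        for b, gb in enumerate(groups):
            vals = [m.values[i, j] for i in ga for j in gb if i != j]
            if not vals:
                if a == b:
                    flags.append(f"single_electrode_group={labels[a]}")
                continue
            out[a, b] = float(np.mean(vals))
    return ConnectivityMatrix(labels, out, m.window_ms, m.n_subjects, flags)


def group_mean_matrix(ms: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Fisher z-average of subject matrices; any missing input entry makes
    the group entry missing."""
    if not ms:
        raise ValueError("need at least one matrix")
    labels = ms[0].labels
    for m in ms[1:]:
        if m.labels != labels:
            raise ValueError("matrices must share labels")
    stack = np.stack([m.values for m in ms])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(np.clip(stack, -1.0, 1.0))
        mean_r = np.tanh(z.mean(axis=0))
    mean_r[np.isnan(stack).any(axis=0)] = np.nan
    return ConnectivityMatrix(labels, mean_r, ms[0].window_ms, len(ms))


def matrix_contrast(
    a: ConnectivityMatrix,
    b: ConnectivityMatrix,
    subject_values_a: list[ConnectivityMatrix] | None = None,
    subject_values_b: list[ConnectivityMatrix] | None = None,
    fdr: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Entrywise difference a - b plus, when per-subject matrices are given,
    a two-sample pooled t-test on Fisher-z values per entry.

    No multiplicity correction by default; ``fdr=True`` applies
    Benjamini-Hochberg over the upper triangle.
    """
    if a.labels != b.labels:
        raise ValueError("matrices must share labels")
    diff = a.values - b.values
    if not subject_values_a or not subject_values_b:
        return diff, None
    if len(subject_values_a) < 2 or len(subject_values_b) < 2:
        return diff, None
    from .stats import unpaired_t

    za = np.arctanh(np.clip(np.stack([m.values for m in subject_values_a]), -0.999999999, 0.999999999))
    zb = np.arctanh(np.clip(np.stack([m.values for m in subject_values_b]), -0.999999999, 0.999999999))
    n = len(a.labels)
    pmat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            xa, xb = za[:, i, j], zb[:, i, j]
            if np.isnan(xa).any() or np.isnan(xb).any():
                continue
            _, _, p = unpaired_t(xa, xb, pooled=True)
            pmat[i, j] = pmat[j, i] = p
    if fdr:
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(n)
        ps = pmat[iu]
        ok = np.isfinite(ps)
        if ok.any():
            adj = ps.copy()
            adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
            pmat[iu] = adj
            pmat.T[iu] = adj
    return diff, pmat
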