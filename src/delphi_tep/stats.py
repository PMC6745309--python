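"""Group statistics: one-way ANOVA with Tukey HSD, unpaired t-tests,
Pearson test-retest reliability, and significance stars."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparisonResult:
    feature: str
    group_labels: tuple[str, ...]
    group_summary: dict  # label -> {n, mean, sd, sem}
    f_statistic: float
    p_value: float
    pairwise: list  # dicts: a, b, estimate, statistic, p, adjusted
    method: str = "anova_tukey"
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "groups": list(self.group_labels),
            "summary": self.group_summary,
            "F": self.f_statistic,
            "p": self.p_value,
            "pairwise": self.pairwise,
            "method": self.method,
            "flags": self.flags,
        }


def _summary(x: np.ndarray) -> dict:
    n = x.size
    sd = float(x.std(ddof=1)) if n > 1 else np.nan
    return {
        "n": int(n),
        "mean": float(x.mean()),
        "sd": sd,
        "sem": sd / np.sqrt(n) if n > 1 else np.nan,
    }


def anova_tukey(values_by_group: dict, feature: str = "") -> GroupComparisonResult:
    """One-way ANOVA omnibus F plus Tukey HSD pairwise comparisons
    (studentized-range adjusted p). Groups with n < 2 are excluded and
    flagged."""
    flags = []
    usable = {}
    for label, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            flags.append(f"group_excluded_n<2:{label}")
            continue
        usable[label] = arr
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    labels = tuple(usable)
    groups = [usable[g] for g in labels]
    if all(np.allclose(g, groups[0].mean()) for g in groups) and all(
        np.allclose(g, g.mean()) for g in groups
    ):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*groups)
        if not np.isfinite(f_stat):
            f_stat, p = 0.0, 1.0
            flags.append("degenerate_anova")
    tk = sps.tukey_hsd(*groups)
    pairwise = []
    for (ia, a), (ib, b) in itertools.combinations(enumerate(labels), 2):
        pairwise.append(
            {
                "a": a,
                "b": b,
                "estimate": float(usable[a].mean() - usable[b].mean()),
                "statistic": float(tk.statistic[ia, ib]),
                "p": float(tk.pvalue[ia, ib]),
                "adjusted": True,
            }
        )
    return GroupComparisonResult(
        feature=feature,
        group_labels=labels,
        group_summary={g: _summary(usable[g]) for g in labels},
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise=pairwise,
        flags=flags,
    )


def unpaired_t(x, y, pooled: bool = True) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; pooled-variance Student by default,
    Welch with ``pooled=False``. Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return np.inf, float(x.size + y.size - 2), 0.0
    res = sps.ttest_ind(x, y, equal_var=pooled)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def reliability(x_session1, y_session2) -> tuple[float, float]:
    """Pearson r between paired session values across subjects, with
    two-sided p. Zero variance in either session is undefined (NaN)."""
    x = np.asarray(x_session1, dtype=float)
    y = np.asarray(y_session2, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star label (strict thresholds):
    p<0.05 '*', p<0.01 '**', p<0.001 '***', p<0.0001 '****', else 'ns'."""
    if np.isnan(p):
        return "ns"
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
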