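"""Pseudo-color region maps and connectivity images.

Region maps fill eight wedge patches of a schematic head (four regions per
hemisphere, stimulated hemisphere on the left) by colormap lookup; a JSON
sidecar records the exact value -> color assignment so images are
comparable across subjects. Connectivity images use a reversed red-blue
map (blue = high r, red = low r).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib import colormaps  # noqa: E402
from matplotlib.patches import Circle, Polygon, Wedge  # noqa: E402

from .montage import REGION_ROLES  # noqa: E402

#: wedge angular spans (degrees, front = 90, ipsi = left hemisphere)
_WEDGE_ANGLES = {
    ("frontal", "ipsi"): (90, 135),
    ("frontal", "contra"): (45, 90),
    ("parietal", "ipsi"): (135, 180),
    ("parietal", "contra"): (0, 45),
    ("temporal", "ipsi"): (180, 225),
    ("temporal", "contra"): (315, 360),
    ("occipital", "ipsi"): (225, 270),
    ("occipital", "contra"): (270, 315),
}


@dataclass
class RegionValueMap:
    values: dict  # (region, role) -> float
    vmin: float
    vmax: float
    cmap: str = "RdYlBu_r"
    title: str = ""
    flags: list = field(default_factory=list)


def _lookup(m: RegionValueMap, value: float) -> tuple[str, float, bool]:
    if not np.isfinite(value):
        return "#bbbbbb", np.nan, False
    norm = (value - m.vmin) / (m.vmax - m.vmin)
    clipped = norm < 0 or norm > 1
    norm = float(np.clip(norm, 0.0, 1.0))
    rgba = colormaps[m.cmap](norm)
    return matplotlib.colors.to_hex(rgba), norm, clipped


def render_region_map(m: RegionValueMap, out_path) -> Path:
    """Write the pseudo-color head schematic PNG plus its JSON sidecar."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(4, 4))
    sidecar = {
        "scale": {"vmin": m.vmin, "vmax": m.vmax, "cmap": m.cmap},
        "title": m.title,
        "regions": {},
    }
    for region, role in REGION_ROLES:
        value = m.values.get((region, role), np.nan)
        color, norm, clipped = _lookup(m, value)
        th1, th2 = _WEDGE_ANGLES[(region, role)]
        ax.add_patch(Wedge((0, 0), 0.95, th1, th2, facecolor=color,
                           edgecolor="black", linewidth=0.8))
        sidecar["regions"][f"{region}_{role}"] = {
            "value": None if not np.isfinite(value) else float(value),
            "normalized": None if not np.isfinite(norm) else float(norm),
            "color": color,
            "clipped": bool(clipped),
        }
        if clipped:
            m.flags.append(f"clipped:{region}_{role}")
    ax.add_patch(Circle((0, 0), 0.95, fill=False, linewidth=1.5))
    ax.add_patch(Polygon([[-0.08, 0.94], [0.08, 0.94], [0.0, 1.08]],
                         closed=True, fill=False, linewidth=1.5))
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    ax.set_aspect("equal")
    ax.axis("off")
    if m.title:
        ax.set_title(m.title)
    sm = plt.cm.ScalarMappable(
        cmap=m.cmap, norm=matplotlib.colors.Normalize(m.vmin, m.vmax)
    )
    fig.colorbar(sm, ax=ax, shrink=0.7)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    out_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return out_path


def render_connectivity(matrix, out_path, title: str = "") -> Path:
    """Color-mapped connectivity matrix (blue = high r, red = low r)."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(matrix.values, cmap="RdBu", vmin=-1.0, vmax=1.0)
    ax.set_xticks(range(len(matrix.labels)))
    ax.set_yticks(range(len(matrix.labels)))
    ax.set_xticklabels(matrix.labels, rotation=90, fontsize=6)
    ax.set_yticklabels(matrix.labels, fontsize=6)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
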