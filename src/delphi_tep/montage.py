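"""Analysis montage: electrode set, schematic positions, region groups.

Twenty scalp electrodes are grouped into four regions (frontal, parietal,
temporal, occipital) times two hemisphere roles — ipsilateral or
contralateral to the stimulated left M1 hub. One commonly circulated
variant of this grouping lists "CF5", which is not a 10-10 label; the
montage here uses FC5, mirroring the contralateral FC6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

REGIONS = ("frontal", "parietal", "temporal", "occipital")
ROLES = ("ipsi", "contra")

#: Fixed presentation order of the eight region-role groups.
REGION_ROLES: tuple[tuple[str, str], ...] = tuple(
    (region, role) for region in REGIONS for role in ROLES
)


@dataclass(frozen=True)
class SensorMontage:
    electrode_names: tuple[str, ...]
    positions_2d: dict = field(default_factory=dict)
    region_groups: dict = field(default_factory=dict)
    stim_site: str = "C3"

    def __post_init__(self) -> None:
        names = set(self.electrode_names)
        for (region, role), members in self.region_groups.items():
            missing = set(members) - names
            if missing:
                raise ValueError(
                    f"group ({region}, {role}) references unknown electrodes {sorted(missing)}"
                )
        if self.region_groups:
            keys = set(self.region_groups)
            expected = set(REGION_ROLES)
            if keys != expected:
                raise ValueError(
                    "region_groups must contain exactly the 4 regions x 2 roles; "
                    f"got {sorted(keys)}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.electrode_names)

    def group(self, region: str, role: str) -> tuple[str, ...]:
        return tuple(self.region_groups[(region, role)])

    def group_indices(self, region: str, role: str) -> np.ndarray:
        index = {name: i for i, name in enumerate(self.electrode_names)}
        return np.array([index[e] for e in self.group(region, role)], dtype=int)

    def channel_index(self, name: str) -> int:
        return self.electrode_names.index(name)

    def homolog(self, name: str) -> str:
        """Mirror electrode in the opposite hemisphere (position in group)."""
        for region in REGIONS:
            for role, other in (("ipsi", "contra"), ("contra", "ipsi")):
                members = self.group(region, role)
                if name in members:
                    return self.group(region, other)[members.index(name)]
        raise KeyError(name)


def default_montage() -> SensorMontage:
    """The packaged 20-electrode left-M1 montage with 8 region-role groups."""
    with resources.files("delphi_tep.data").joinpath("default_montage.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    groups: dict[tuple[str, str], tuple[str, ...]] = {}
    order: list[str] = []
    for region in REGIONS:
        for role in ROLES:
            members = tuple(raw["region_groups"][region][role])
            groups[(region, role)] = members
            order.extend(members)
    return SensorMontage(
        electrode_names=tuple(order),
        positions_2d={k: tuple(v) for k, v in raw["positions_2d"].items()},
        region_groups=groups,
        stim_site=raw["stim_site"],
    )
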