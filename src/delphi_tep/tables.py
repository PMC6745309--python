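"""Tidy feature tables: one row per subject x region x role x feature."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .montage import REGION_ROLES

COLUMNS = ("subject_id", "group_label", "region", "role", "feature", "value")


class SchemaError(ValueError):
    """Profiles disagree on their feature schema."""


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Flatten DelphiProfiles into a tidy DataFrame (one value per row)."""
    rows = []
    schema = None
    for prof in profiles:
        keys = tuple(
            sorted({f for rr in prof.features for f in prof.features[rr]})
        )
        if schema is None:
            schema = keys
        elif keys != schema:
            raise SchemaError(
                f"subject {prof.subject_id!r} has feature schema {keys}, "
                f"expected {schema}"
            )
        for region, role in REGION_ROLES:
            for feature in schema:
                value = prof.features.get((region, role), {}).get(feature, np.nan)
                rows.append(
                    (prof.subject_id, prof.group_label, region, role, feature, value)
                )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_feature_table(profiles, path) -> Path:
    """Write profiles as CSV; values keep 17 significant digits so a
    read-back reproduces them bit-exactly."""
    path = Path(path)
    frame = profiles_to_frame(profiles)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
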