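"""CSV/YAML serialization.

Maps travel in a documented long format with one row per grid point:

    patient_id, side, group, layer, radius_mm, angle_deg, value

where ``layer`` is ``pachymetry`` | ``epithelium`` | ``power`` and
``value`` is um for thickness layers and diopters for power; the vertex
point is the row with ``radius_mm == 0``.  Feature tables are plain CSV
with id columns plus the fourteen variable columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .maps import ThicknessMap
from .reference import FEATURE_NAMES
from .synthetic import EyeRecord

_LAYER_TAGS = {"pachymetry": "pachymetry", "epithelium": "epithelium", "power": "power"}


def maps_to_frame(records: list[EyeRecord]) -> pd.DataFrame:
    """Long-format table of every map of every eye."""
    parts = []
    for eye in records:
        layers = {"pachymetry": eye.pachymetry, "epithelium": eye.epithelium}
        if eye.power is not None:
            layers["power"] = eye.power
        for layer, tmap in layers.items():
            df = tmap.to_frame()
            df.insert(0, "patient_id", eye.patient_id)
            df.insert(1, "side", eye.side)
            df.insert(2, "group", eye.group)
            df.insert(3, "layer", layer)
            parts.append(df)
    return pd.concat(parts, ignore_index=True)


def write_maps_csv(records: list[EyeRecord], path) -> None:
    maps_to_frame(records).to_csv(path, index=False, float_format="%.6g")


def read_maps_csv(path) -> list[EyeRecord]:
    """Rebuild eye records from the long map format.  The slit-lamp flag
    is recovered from the group label (keratoconic eyes are, by study
    construction, slit-lamp positive)."""
    df = pd.read_csv(path)
    records = []
    for (pid, side, group), sub in df.groupby(["patient_id", "side", "group"], sort=False):
        maps = {}
        for layer, msub in sub.groupby("layer", sort=False):
            maps[layer] = ThicknessMap.from_frame(msub, tag=_LAYER_TAGS[layer])
        records.append(
            EyeRecord(
                patient_id=str(pid), side=str(side), group=str(group),
                pachymetry=maps["pachymetry"], epithelium=maps["epithelium"],
                power=maps.get("power"), slit_lamp_kc=group == "keratoconic",
            )
        )
    return records


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format="%.6g")


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return df


def load_config(path) -> dict:
    """Read a YAML run configuration (see pipeline.RunConfig.from_dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {Path(path)} must be a mapping")
    return cfg
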