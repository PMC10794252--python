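"""File formats, configuration and run manifests.

Everything tabular is CSV (UTF-8, '.' decimal, documented columns);
fields are multi-page TIFF with one channel per page in the fixed order
nucleus, body, TGN, cargo, with a JSON sidecar for simulation ground
truth; run manifests are JSON carrying the package version, seed and a
hash of the effective configuration so any output can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import DOSE_GRID_UM, FieldImage

__all__ = [
    "PlateMapError", "RunConfig",
    "read_plate_map", "validate_plate_map",
    "read_field", "write_field",
    "read_table", "write_table",
    "write_manifest", "config_hash",
]

WELL_RE = re.compile(r"^([A-P])(\d{2})$")
ROLES = {"negative_control", "positive_control", "compound", "empty"}
PLATE_SHAPES = {384: (16, 24), 96: (8, 12)}


class PlateMapError(ValueError):
    """Schema violation in a plate-map table, with row/column context."""


@dataclass
class RunConfig:
    """Effective analysis configuration; every output records its hash."""

    channel_order: tuple[str, ...] = ("nucleus", "body", "tgn", "cargo")
    min_nucleus_area: int = 64
    threshold_method: str = "otsu"
    zprime_min: float = 0.3
    ssmd_min: float = 3.0
    cv_max: float = 10.0
    activity_z: float = -3.0
    toxicity_z: float = -2.0
    pc1_cutoff: float = 0.75
    dose_grid_uM: tuple[float, ...] = DOSE_GRID_UM
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("channel_order", "dose_grid_uM"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_order"] = list(d["channel_order"])
        d["dose_grid_uM"] = list(d["dose_grid_uM"])
        return d


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_plate_map(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a plate-map table; errors name the offending cell."""
    required = {"plate", "well", "role"}
    missing = required - set(df.columns)
    if missing:
        raise PlateMapError(f"missing columns: {sorted(missing)}")
    for idx, row in df.iterrows():
        m = WELL_RE.match(str(row["well"]))
        if not m or int(m.group(2)) < 1 or int(m.group(2)) > 24:
            raise PlateMapError(
                f"row {idx}: malformed well id {row['well']!r} "
                "(expected e.g. 'A01')")
        if row["role"] not in ROLES:
            raise PlateMapError(
                f"row {idx} (well {row['well']}): unknown role {row['role']!r}")
        if row["role"] == "compound" and "concentration_uM" in df:
            conc = row["concentration_uM"]
            if pd.notna(conc) and conc <= 0:
                raise PlateMapError(
                    f"row {idx} (well {row['well']}): non-positive "
                    f"concentration {conc}")
    for plate, grp in df.groupby("plate"):
        if grp["well"].duplicated().any():
            dup = grp.loc[grp["well"].duplicated(), "well"].iloc[0]
            raise PlateMapError(f"plate {plate}: duplicate well {dup!r}")
        roles = set(grp["role"])
        if not {"negative_control", "positive_control"} <= roles:
            raise PlateMapError(f"plate {plate}: both control roles required")
    return df


def read_plate_map(path) -> pd.DataFrame:
    return validate_plate_map(pd.read_csv(path))


def write_field(path, fieldimg: FieldImage, truth=None) -> None:
    """Multi-page TIFF, one channel per page; optional JSON truth sidecar."""
    path = Path(path)
    tifffile.imwrite(path, fieldimg.stack().astype(np.float32),
                     photometric="minisblack", planarconfig="separate",
                     metadata={"pixel_size_um": fieldimg.pixel_size,
                               "channels": list(FieldImage.CHANNEL_ORDER)})
    if truth is not None:
        sidecar = path.with_suffix(".truth.json")
        payload = {
            "cells": truth.cells.to_dict(orient="records"),
            "nucleus_labels": truth.nucleus_labels.tolist(),
            "cell_labels": truth.cell_labels.tolist(),
            "tgn_labels": truth.tgn_labels.tolist(),
        }
        sidecar.write_text(json.dumps(payload))


def read_field(path, pixel_size: float | None = None) -> FieldImage:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        if pixel_size is None:
            meta = tf.shaped_metadata or tf.imagej_metadata or [{}]
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            pixel_size = float(meta.get("pixel_size_um", 1.0))
    if stack.ndim == 2:
        raise ValueError("expected a multi-page (multi-channel) TIFF")
    return FieldImage.from_stack(np.asarray(stack, dtype=float),
                                 pixel_size=pixel_size)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path, config: RunConfig, command: str,
                   extra: dict | None = None) -> dict:
    from . import __version__
    manifest = {
        "version": __version__,
        "command": command,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
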