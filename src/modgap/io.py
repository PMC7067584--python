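"""Tabular I/O, run configuration and manifests.

CSV is the sole tabular exchange format (one row per recorded cell:
animal_id, feature_name, location_um, value); threshold tables and run
manifests are JSON.  Locations are absolute µm from the dorsal border of
the structure, increasing ventrally; no coordinate transforms are applied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import DEFAULT_EXTENT_UM, FeatureSample

logger = logging.getLogger("modgap")

__all__ = ["RunConfig", "read_feature_table", "write_feature_table"]

_LONG_COLUMNS = {"animal_id", "feature_name", "value"}


@dataclass
class RunConfig:
    """Workflow configuration; defaults are the toolkit's standard analysis.

    kmax=8 is the largest plausible number of grid modules; alpha_per_k=0.01
    fixes each per-k false-positive rate; min_n=34 is the per-animal sample
    size at which a 5-SD-separated modular organization is detected in at
    least half of animals.
    """

    seed: int = 0
    kmax: int = 8
    alpha_per_k: float = 0.01
    B: int = 100
    null_reps: int = 1000
    min_n: int = 34
    extent_um: float = DEFAULT_EXTENT_UM
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_manifest(self, path: str | Path, **extra) -> None:
        doc = {"config": self.to_dict(), **extra}
        Path(path).write_text(json.dumps(doc, indent=2, default=str))


def read_feature_table(path: str | Path) -> list[FeatureSample]:
    """Read a per-cell feature CSV into FeatureSamples.

    Long format requires columns animal_id, feature_name, value (plus
    optional location_um); wide format requires animal_id plus one column
    per feature (optional location_um), and is melted.  Rows with
    non-finite values are dropped with a logged count.  Output ordering is
    deterministic: (animal_id, feature_name) lexicographic.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty input file: {path}")
    if "animal_id" not in df.columns:
        raise ValueError("missing mandatory column: animal_id")
    if "value" in df.columns and "feature_name" not in df.columns:
        raise ValueError("missing mandatory column: feature_name")
    if "value" not in df.columns:
        # wide format: every non-id, non-location column is a feature
        id_vars = [c for c in ("animal_id", "location_um") if c in df.columns]
        feature_cols = [c for c in df.columns if c not in id_vars]
        if not feature_cols:
            raise ValueError("missing mandatory column: value (and no feature columns found)")
        df = df.melt(id_vars=id_vars, value_vars=feature_cols,
                     var_name="feature_name", value_name="value")

    n0 = len(df)
    df = df.assign(value=pd.to_numeric(df["value"], errors="coerce"))
    df = df[np.isfinite(df["value"])]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("dropped %d rows with non-finite values", dropped)

    has_loc = "location_um" in df.columns
    samples = []
    for (animal, feature), grp in sorted(
        df.groupby(["animal_id", "feature_name"], sort=True), key=lambda kv: kv[0]
    ):
        samples.append(
            FeatureSample(
                animal_id=str(animal),
                feature_name=str(feature),
                values=grp["value"].to_numpy(dtype=float),
                locations=grp["location_um"].to_numpy(dtype=float) if has_loc else None,
            )
        )
    return samples


def write_feature_table(samples: list[FeatureSample], path: str | Path,
                        sidecar: str | Path | None = None) -> None:
    """Write FeatureSamples to long CSV (+ optional JSON sidecar of metadata)."""
    frames = []
    for fs in samples:
        d = {"animal_id": fs.animal_id, "feature_name": fs.feature_name, "value": fs.values}
        if fs.locations is not None:
            d["location_um"] = fs.locations
        if fs.labels is not None:
            d["true_label"] = fs.labels
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if sidecar is not None:
        meta = {f"{fs.animal_id}/{fs.feature_name}": fs.meta for fs in samples}
        Path(sidecar).write_text(json.dumps(meta, indent=2, default=str))
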