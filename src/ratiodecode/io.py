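"""CSV dataset interchange, YAML configuration, and run manifests.

The on-disk dataset format is a flat UTF-8 CSV with header
``sample_id,category,sensor_id,channel,time_s,shift_hz`` and one row per
timestamp per channel.  A JSON sidecar ``<file>.manifest.json`` written
next to every output records the timeline, configuration snapshot, seeds
and input digests needed to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .dataset import SensorArrayDataset
from .simulate import (
    CHANNELS,
    RATIO_LABELS,
    ExperimentDesign,
    ExperimentTimeline,
    SensorModel,
    SensorTimeSeries,
    default_sensors,
    default_timeline,
    encode_categories,
)

__all__ = [
    "DATASET_COLUMNS",
    "RunManifest",
    "write_dataset",
    "read_dataset",
    "design_from_config",
    "load_config",
]

DATASET_COLUMNS = ["sample_id", "category", "sensor_id", "channel", "time_s", "shift_hz"]


@dataclass
class RunManifest:
    """Provenance record paired with every CLI/pipeline output."""

    stage: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    created: str = ""

    def write(self, path: str | Path) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        self.created = self.created or time.strftime("%Y-%m-%dT%H:%M:%S")
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def manifest_path(out: str | Path) -> Path:
    out = Path(out)
    return out.with_name(out.name + ".manifest.json")


def write_dataset(dataset: SensorArrayDataset, path: str | Path) -> Path:
    """Write a dataset to the documented CSV dialect (plus timeline sidecar)."""
    rows = []
    for p in dataset.profiles:
        for ch in CHANNELS:
            if ch not in p.shifts:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": p.sample_id,
                        "category": p.category,
                        "sensor_id": p.sensor_id,
                        "channel": ch,
                        "time_s": p.times,
                        "shift_hz": p.shifts[ch],
                    }
                )
            )
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    sidecar = {"timeline": asdict(dataset.timeline)}
    manifest_path(path).write_text(
        json.dumps({"stage": "dataset", "config": sidecar}, indent=2) + "\n"
    )
    return path


def read_dataset(
    path: str | Path, timeline: ExperimentTimeline | None = None
) -> SensorArrayDataset:
    """Parse a dataset CSV back into profiles, validating the invariants.

    Rows may appear in any order (the parse is keyed, not positional).
    The timeline is taken from the sidecar manifest when present, from the
    ``timeline`` argument otherwise, falling back to the default timeline
    with the grid step inferred from the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} is missing columns {missing}")
    if timeline is None:
        side = manifest_path(path)
        if side.exists():
            cfg = json.loads(side.read_text()).get("config", {}).get("timeline")
            if cfg:
                timeline = ExperimentTimeline(**cfg)

    profiles: list[SensorTimeSeries] = []
    grid: np.ndarray | None = None
    for (sample_id, sensor_id), grp in df.groupby(
        ["sample_id", "sensor_id"], sort=False
    ):
        cats = grp["category"].unique()
        if len(cats) > 1:
            raise ValueError(f"profile {sample_id}/{sensor_id} has conflicting categories")
        shifts: dict[str, np.ndarray] = {}
        times_ref: np.ndarray | None = None
        for ch, sub in grp.groupby("channel", sort=False):
            sub = sub.sort_values("time_s")
            t = sub["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"non-monotone / duplicate timestamps in {sample_id}/{sensor_id}/{ch}"
                )
            if times_ref is None:
                times_ref = t
            elif t.shape != times_ref.shape or not np.allclose(t, times_ref):
                raise ValueError(
                    f"channel grids disagree in profile {sample_id}/{sensor_id}"
                )
            shifts[str(ch)] = sub["shift_hz"].to_numpy(dtype=float)
        unknown = set(shifts) - set(CHANNELS)
        if unknown:
            raise ValueError(
                f"profile {sample_id}/{sensor_id} has unknown channels {sorted(unknown)}"
            )
        if grid is None:
            grid = times_ref
        elif times_ref.shape != grid.shape or not np.allclose(times_ref, grid):
            raise ValueError(
                f"profile {sample_id}/{sensor_id} is truncated or off the shared grid"
            )
        steps = np.diff(times_ref)
        if times_ref.size > 1 and not np.allclose(steps, steps[0]):
            raise ValueError(f"irregular time grid in profile {sample_id}/{sensor_id}")
        tl = timeline or ExperimentTimeline(
            sample_interval=float(steps[0]) if times_ref.size > 1 else 1.0,
            total_duration=float(times_ref[-1]) if times_ref[-1] > 100 else 1050.0,
        )
        profiles.append(
            SensorTimeSeries(
                sample_id=str(sample_id),
                category=str(cats[0]),
                sensor_id=str(sensor_id),
                times=times_ref,
                shifts=shifts,
                timeline=tl,
            )
        )
    return SensorArrayDataset(profiles)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    return cfg or {}


def design_from_config(cfg: Mapping[str, Any] | None = None, seed: int | None = None) -> ExperimentDesign:
    """Build an ExperimentDesign from a (possibly partial) config mapping.

    Recognised keys: ``ratios``, ``low_total``, ``high_total``,
    ``repeats_low``, ``repeats_high``, ``injection_jitter_sd``, ``seed``,
    ``timeline`` (mapping) and ``sensors`` (list of SensorModel field
    mappings).  Anything omitted falls back to the defaults.
    """
    cfg = dict(cfg or {})
    blends = tuple(
        encode_categories(
            cfg.get("ratios") or RATIO_LABELS,
            low_total=cfg.get("low_total", 1.0),
            high_total=cfg.get("high_total", 2.0),
        )
    )
    sensors = (
        tuple(SensorModel(**s) for s in cfg["sensors"])
        if "sensors" in cfg
        else default_sensors()
    )
    tl = ExperimentTimeline(**cfg["timeline"]) if "timeline" in cfg else default_timeline()
    return ExperimentDesign(
        blends=blends,
        sensors=sensors,
        timeline=tl,
        repeats_low=cfg.get("repeats_low", 6),
        repeats_high=cfg.get("repeats_high", 3),
        injection_jitter_sd=cfg.get("injection_jitter_sd", 8.0),
        seed=seed if seed is not None else cfg.get("seed", 0),
    )


def write_feature_csv(fm, path: str | Path) -> Path:
    """Feature matrix CSV: ``sample_id,category,<feature_1..k>``."""
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "category", fm.categories)
    df.insert(0, "sample_id", fm.sample_ids)
    path = Path(path)
    df.to_csv(path, index=False)
    return path
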