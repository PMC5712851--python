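"""End-to-end pipeline: simulate -> extract -> evaluate -> decode-rt.

Each stage draws its randomness from a child of one root seed, so a full
run is reproducible from (config, seed) alone; every stage writes its
artifact plus a manifest describing how to regenerate it.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decoders import LDAClassifier, MLPNNClassifier, PNNClassifier
from .evaluation import sfs, station_sweep
from .features import FeatureSpec
from .io import RunManifest, design_from_config, manifest_path, write_dataset, write_feature_csv
from .realtime import decode_stream
from .simulate import simulate_design

log = logging.getLogger("ratiodecode")

STAGES = ("simulate", "extract", "evaluate", "decode-rt")


def classifier_factory(method: str, seed: int = 0, **kw):
    method = method.lower()
    if method == "lda":
        return lambda: LDAClassifier(**kw)
    if method == "pnn":
        return lambda: PNNClassifier(**kw)
    if method == "mlpnn":
        kw.setdefault("epochs", 400)
        return lambda: MLPNNClassifier(seed=seed, **kw)
    raise ValueError(f"unknown method {method!r}")


def run_pipeline(
    config: Mapping | None,
    seed: int,
    outdir: str | Path,
    stages: Sequence[str] = STAGES,
) -> dict[str, Path]:
    """Run the configured stages in order, returning artifact paths.

    Stages must be a subsequence of simulate -> extract -> evaluate ->
    decode-rt; later stages depend on the simulated dataset.  An empty
    stage list is a no-op that still writes the run manifest.
    """
    config = dict(config or {})
    stages = list(stages)
    order = {s: i for i, s in enumerate(STAGES)}
    unknown = [s for s in stages if s not in order]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    if [order[s] for s in stages] != sorted(order[s] for s in stages):
        raise ValueError(f"stages out of dependency order: {stages}")
    if stages and stages[0] != "simulate":
        raise ValueError("pipeline stages must start from 'simulate'")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    stage_seeds = {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, root.spawn(len(STAGES)))}
    artifacts: dict[str, Path] = {}
    manifest = RunManifest(stage="run", seed=seed, config=config)

    dataset = None
    if "simulate" in stages:
        log.info("stage simulate: seed %d", stage_seeds["simulate"])
        design = design_from_config(config.get("design"), seed=stage_seeds["simulate"])
        dataset = simulate_design(design)
        artifacts["dataset"] = write_dataset(dataset, outdir / "dataset.csv")

    if "extract" in stages:
        log.info("stage extract")
        station = float(config.get("extract", {}).get("time", 650.0))
        for name in config.get("extract", {}).get("features", ["Orig", "LnF", "Deriv"]):
            fm = _extract(dataset, name, station)
            artifacts[f"features_{name}"] = write_feature_csv(
                fm, outdir / f"features_{name}.csv"
            )

    if "evaluate" in stages:
        ev = dict(config.get("evaluate", {}))
        method = ev.get("method", "pnn")
        stations = ev.get("stations", list(np.arange(150.0, 1050.0, 50.0)))
        factory = classifier_factory(method, seed=stage_seeds["evaluate"])
        log.info("stage evaluate: %s over %d stations", method, len(stations))
        specs = [FeatureSpec(name=n) for n in ev.get("features", ["Orig"])]
        expand = dataset.timeline.sample_interval if ev.get("expand") else None
        if ev.get("sfs"):
            res = sfs(factory, dataset, float(ev.get("sfs_station", 650.0)), expand_offset=expand)
            pd.DataFrame(res.history, columns=["feature", "rate"]).to_csv(
                outdir / "sfs.csv", index=False
            )
            artifacts["sfs"] = outdir / "sfs.csv"
        curve = station_sweep(
            factory, specs, dataset, stations, method=method, expand_offset=expand
        )
        path = outdir / "recognition_curve.csv"
        pd.DataFrame({"station_s": curve.stations, "rate": curve.rates}).to_csv(
            path, index=False
        )
        artifacts["recognition_curve"] = path

    if "decode-rt" in stages:
        rt = dict(config.get("realtime", {}))
        log.info("stage decode-rt")
        traj = decode_stream(dataset, time_step=float(rt.get("time_step", 1.0)))
        long = []
        for row, sid in enumerate(traj.sample_ids):
            long.append(
                pd.DataFrame(
                    {
                        "time_s": traj.times,
                        "sample_id": sid,
                        "true_code": traj.true_codes[row],
                        "decoded_code": traj.decoded[row],
                    }
                )
            )
        pd.concat(long, ignore_index=True).to_csv(outdir / "decoded.csv", index=False)
        pd.DataFrame({"time_s": traj.times, "ratio": traj.ratio}).to_csv(
            outdir / "decode_ratio.csv", index=False
        )
        artifacts["decoded"] = outdir / "decoded.csv"
        artifacts["decode_ratio"] = outdir / "decode_ratio.csv"

    manifest.inputs = {}
    manifest.outputs = [str(p) for p in artifacts.values()]
    manifest.config["stage_seeds"] = stage_seeds
    manifest.write(manifest_path(outdir / "run"))
    return artifacts


def _extract(dataset, name: str, station: float):
    from .features import extract

    if dataset is None:
        raise ValueError("extract stage needs a simulated dataset")
    return extract(dataset, FeatureSpec(name=name), station)
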