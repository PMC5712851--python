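"""In-memory container for a sensor-array measurement campaign."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .simulate import CHANNELS, ExperimentTimeline, SensorTimeSeries


class SensorArrayDataset:
    """A collection of per-sensor profiles sharing one acquisition grid.

    Profiles are keyed by (sample_id, sensor_id); a *sample* is one
    injection observed simultaneously by every sensor of the array.  Sample
    and sensor order follow first appearance, which for simulated designs
    is category order R1..R10 and the array order (PE, PSB, PEVA).
    """

    def __init__(self, profiles: Iterable[SensorTimeSeries], design=None):
        self.profiles: list[SensorTimeSeries] = list(profiles)
        if not self.profiles:
            raise ValueError("dataset needs at least one profile")
        self.design = design

        self.sample_ids: list[str] = []
        self.sensor_ids: list[str] = []
        self._by_key: dict[tuple[str, str], SensorTimeSeries] = {}
        cat: dict[str, str] = {}
        times = self.profiles[0].times
        for p in self.profiles:
            if p.times.shape != times.shape or not np.allclose(p.times, times):
                raise ValueError(
                    f"profile {p.sample_id}/{p.sensor_id} is not on the shared time grid"
                )
            key = (p.sample_id, p.sensor_id)
            if key in self._by_key:
                raise ValueError(f"duplicate profile for {key}")
            self._by_key[key] = p
            if p.sample_id not in cat:
                self.sample_ids.append(p.sample_id)
                cat[p.sample_id] = p.category
            elif cat[p.sample_id] != p.category:
                raise ValueError(f"sample {p.sample_id} has conflicting categories")
            if p.sensor_id not in self.sensor_ids:
                self.sensor_ids.append(p.sensor_id)
        missing = [
            (s, j)
            for s in self.sample_ids
            for j in self.sensor_ids
            if (s, j) not in self._by_key
        ]
        if missing:
            raise ValueError(f"incomplete sensor coverage, missing {missing[:3]} ...")
        self.categories: list[str] = [cat[s] for s in self.sample_ids]
        self.times: np.ndarray = times
        self.timeline: ExperimentTimeline = self.profiles[0].timeline
        self._arrays: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    def profile(self, sample_id: str, sensor_id: str) -> SensorTimeSeries:
        return self._by_key[(sample_id, sensor_id)]

    def array(self, channel: str = "differential") -> np.ndarray:
        """Stacked traces, shape (n_samples, n_sensors, n_times)."""
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        if channel not in self._arrays:
            X = np.empty((len(self.sample_ids), len(self.sensor_ids), self.times.size))
            for i, s in enumerate(self.sample_ids):
                for j, sen in enumerate(self.sensor_ids):
                    X[i, j, :] = self._by_key[(s, sen)].shifts[channel]
            self._arrays[channel] = X
        return self._arrays[channel]

    def time_index(self, t: float) -> int:
        """Grid index of time station ``t``; rejects off-grid stations."""
        idx = int(round((t - self.times[0]) / self.timeline.sample_interval))
        if not 0 <= idx < self.times.size or abs(self.times[idx] - t) > 1e-6:
            raise ValueError(f"time station {t} s is not on the acquisition grid")
        return idx

    def subset(self, sample_ids: Sequence[str]) -> "SensorArrayDataset":
        keep = set(sample_ids)
        return SensorArrayDataset(
            [p for p in self.profiles if p.sample_id in keep], design=self.design
        )
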