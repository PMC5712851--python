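"""Evaluation protocols: leave-one-out recognition, station sweeps,
sequential forward feature selection, and neighbour expansion.

Recognition is always scored by exhaustive leave-one-out (LOO): every
sample in turn is the single test case and the classifier is retrained on
the rest.  With tens of samples this is the only cross-validation scheme
that wastes no data, and being exhaustive it is deterministic.

For neighbour-expanded datasets each original sample also contributes the
feature vector extracted one acquisition step earlier; the two rows are
temporal twins of the same physical injection, so the default LOO guard
removes a held-out row's twin from the training fold (otherwise the twin
leaks an almost identical copy of the test point into training).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .dataset import SensorArrayDataset
from .features import FeatureMatrix, FeatureSpec, extract

__all__ = [
    "RecognitionCurve",
    "ExpandedDataset",
    "SFSResult",
    "leave_one_out",
    "station_sweep",
    "sfs",
    "expand_with_neighbours",
]

#: A zero-argument factory producing a fresh fit/predict classifier.
ClassifierFactory = Callable[[], object]

#: Default SFS feature pool.
SFS_POOL: tuple[str, ...] = ("Orig", "Zscore", "AR", "AS", "LnF", "Deriv", "Tau1", "Tau2")


@dataclass
class RecognitionCurve:
    """LOO recognition rate as a function of time station."""

    method: str
    features: tuple[str, ...]
    stations: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.stations = np.asarray(self.stations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.stations) <= 0):
            raise ValueError("stations must be increasing")
        if np.any((self.rates < 0) | (self.rates > 1)):
            raise ValueError("rates must lie in [0, 1]")

    def time_to_rate(self, threshold: float = 1.0) -> float:
        """Earliest station whose rate reaches ``threshold`` (NaN if never)."""
        hit = np.where(self.rates >= threshold - 1e-12)[0]
        return float(self.stations[hit[0]]) if hit.size else float("nan")


@dataclass
class ExpandedDataset:
    """A feature matrix doubled with each sample's temporal neighbour."""

    base: FeatureMatrix
    neighbour_offset: float
    combined: FeatureMatrix
    provenance: list[str]  # "original" | "neighbour" per combined row


def leave_one_out(
    factory: ClassifierFactory,
    features: FeatureMatrix,
    *,
    guard: bool = True,
) -> float:
    """Exhaustive LOO recognition rate of a classifier on a feature matrix.

    With ``guard`` (default) all rows sharing the held-out row's group —
    its temporal twins in an expanded dataset — are excluded from the
    training fold.  A training failure on a fold counts that fold as
    incorrect with a warning.
    """
    X = features.values
    y = np.asarray(features.categories)
    groups = np.asarray(features.groups)
    n = X.shape[0]
    correct = 0
    for i in range(n):
        train = (groups != groups[i]) if guard else (np.arange(n) != i)
        try:
            model = factory()
            model.fit(X[train], y[train])
            pred = model.predict(X[i : i + 1])[0]
        except Exception as exc:  # noqa: BLE001 - fold failure is data-dependent
            warnings.warn(f"fold {i} failed to train: {exc}", stacklevel=2)
            continue
        if pred == y[i]:
            correct += 1
    return correct / n


def _station_matrix(
    dataset: SensorArrayDataset,
    specs: Sequence[FeatureSpec],
    station: float,
    expand_offset: float | None,
) -> FeatureMatrix:
    fm = FeatureMatrix.concat([extract(dataset, s, station) for s in specs])
    if expand_offset is None:
        return fm
    return expand_with_neighbours(dataset, specs, station, expand_offset).combined


def station_sweep(
    factory: ClassifierFactory,
    specs: Sequence[FeatureSpec] | FeatureSpec,
    dataset: SensorArrayDataset,
    stations: Sequence[float],
    *,
    method: str = "",
    expand_offset: float | None = None,
    guard: bool = True,
) -> RecognitionCurve:
    """One LOO rate per time station for a feature (combination).

    Feature combinations are column-concatenations of the individual
    feature matrices; ``expand_offset`` switches on neighbour expansion at
    every station.
    """
    if isinstance(specs, FeatureSpec):
        specs = [specs]
    stations = list(stations)
    if not stations:
        raise ValueError("station list is empty")
    rates = [
        leave_one_out(
            factory, _station_matrix(dataset, specs, t, expand_offset), guard=guard
        )
        for t in stations
    ]
    return RecognitionCurve(
        method=method,
        features=tuple(s.name for s in specs),
        stations=np.asarray(stations, dtype=float),
        rates=np.asarray(rates),
    )


@dataclass
class SFSResult:
    selected: tuple[str, ...]
    rate: float
    history: list[tuple[str, float]]  # (feature added, rate after adding)


def sfs(
    factory: ClassifierFactory,
    dataset: SensorArrayDataset,
    station: float,
    *,
    pool: Sequence[str] = SFS_POOL,
    base_spec: FeatureSpec | None = None,
    expand_offset: float | None = None,
    guard: bool = True,
) -> SFSResult:
    """Greedy sequential forward feature selection at one time station.

    Starting from the empty set, the pool feature whose addition maximises
    the LOO rate is appended (ties broken by pool order) until no addition
    improves the rate.  Returns the selected subset and its rate.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("feature pool is empty")
    base = base_spec or FeatureSpec(name=pool[0])
    cache = {
        name: _station_matrix(dataset, [replace(base, name=name)], station, expand_offset)
        for name in pool
    }
    selected: list[str] = []
    best_rate = -np.inf
    history: list[tuple[str, float]] = []
    while True:
        round_best: tuple[float, str] | None = None
        for name in pool:
            if name in selected:
                continue
            fm = FeatureMatrix.concat([cache[f] for f in selected + [name]])
            rate = leave_one_out(factory, fm, guard=guard)
            if round_best is None or rate > round_best[0]:
                round_best = (rate, name)
        if round_best is None or round_best[0] <= best_rate:
            break
        best_rate, chosen = round_best
        selected.append(chosen)
        history.append((chosen, best_rate))
    return SFSResult(tuple(selected), float(max(best_rate, 0.0)), history)


def expand_with_neighbours(
    dataset: SensorArrayDataset,
    specs: Sequence[FeatureSpec] | FeatureSpec,
    station: float,
    offset: float | None = None,
) -> ExpandedDataset:
    """Double a station's feature matrix with each sample's neighbour row.

    The neighbour row is the same feature vector extracted at
    ``station - offset`` (default: one acquisition interval) and carries
    the same category; sampling is much faster than the sensor response,
    so the neighbour is a near-duplicate observation that doubles the
    sample count.
    """
    if isinstance(specs, FeatureSpec):
        specs = [specs]
    if offset is None:
        offset = dataset.timeline.sample_interval
    if offset >= station:
        raise ValueError("neighbour offset must be smaller than the station")
    if offset == 0:
        warnings.warn("offset 0 duplicates rows exactly", stacklevel=2)
    base = FeatureMatrix.concat([extract(dataset, s, station) for s in specs])
    shifted = FeatureMatrix.concat([extract(dataset, s, station - offset) for s in specs])
    combined = FeatureMatrix(
        time_station=station,
        feature_names=list(base.feature_names),
        values=np.vstack([base.values, shifted.values]),
        categories=list(base.categories) + list(shifted.categories),
        sample_ids=list(base.sample_ids)
        + [f"{s}@-{offset:g}s" for s in shifted.sample_ids],
        groups=list(base.sample_ids) + list(shifted.sample_ids),
    )
    provenance = ["original"] * base.n_samples + ["neighbour"] * shifted.n_samples
    return ExpandedDataset(base, offset, combined, provenance)
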