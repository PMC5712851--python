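"""Synthetic SAW-resonator array responses to binary pheromone blends.

This module generates labelled sensor-array time series that emulate a
chemoreceiver made of three polymer-coated surface-acoustic-wave resonator
(SAWR) sensors — polyethylene (PE), polystyrene-co-butadiene (PSB) and
polyethylene-co-vinyl-acetate (PEVA) — exposed to binary blends of the two
*Spodoptera littoralis* pheromone components E11-14:OAc and Z9-14:OAc.

A message is encoded ratiometrically: five volume ratios (1:0, 2:1, 1:1,
1:2, 0:1) at two total-volume levels give ten category codes R1..R10.  Each
sensor responds with a first-order frequency-shift rise

    f(t) = f_inf * (1 - exp(-(t - t_inj) / tau)),   t >= t_inj,

where the stationary shift ``f_inf`` is linear in the injected component
volumes (partition-coefficient sorption at low concentration) and ``tau``
is an effective rise time folding in wind-tunnel transport.  Each component
sorbs with its own kinetics, so a blend response is a superposition of two
such exponentials (one per component); a single shared ``tau`` recovers the
plain one-exponential model exactly.

Noise model (all terms seedable, all off when their amplitudes are zero):

* multiplicative Gaussian noise of relative size ``noise_rel`` on the
  response, i.i.d. per timestamp — steady-state repeatability;
* an additive i.i.d. Gaussian floor (``floor_sd_hz``) — oscillator jitter,
  dominant before injection where the response is ~0;
* a per-profile Gaussian baseline offset (``baseline_sd_hz``) on each
  channel — imperfect common-mode rejection of the dual-SAWR pair;
* a per-injection timing jitter (``injection_jitter_sd`` of the design),
  shared by all sensors observing the same injection — syringe-pump and
  plume-transport variability.

The sense channel carries baseline drift plus the response; the uncoated
reference channel carries the drift plus a fraction ``ref_coupling`` of the
response; the differential channel is their difference and is the signal
used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from math import floor
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RATIO_LABELS",
    "RATIO_FRACTIONS",
    "CATEGORY_ORDER",
    "category_index",
    "BlendSpec",
    "SensorModel",
    "ExperimentTimeline",
    "SensorTimeSeries",
    "ExperimentDesign",
    "CalibrationReport",
    "encode_categories",
    "simulate_profile",
    "simulate_design",
    "calibration_report",
    "default_sensors",
    "default_timeline",
    "default_design",
]

#: The five ratio labels (E11-14:OAc : Z9-14:OAc), in code-table column order.
RATIO_LABELS: tuple[str, ...] = ("1:0", "2:1", "1:1", "1:2", "0:1")

#: Volume fraction of each component for every ratio label.
RATIO_FRACTIONS: Mapping[str, tuple[float, float]] = {
    "1:0": (1.0, 0.0),
    "2:1": (2.0 / 3.0, 1.0 / 3.0),
    "1:1": (0.5, 0.5),
    "1:2": (1.0 / 3.0, 2.0 / 3.0),
    "0:1": (0.0, 1.0),
}

#: Category codes in canonical (index) order; R1-R5 low volume, R6-R10 high.
CATEGORY_ORDER: tuple[str, ...] = tuple(f"R{i}" for i in range(1, 11))


def category_index(category: str) -> int:
    """0-based index of a category code (R1 -> 0 ... R10 -> 9)."""
    try:
        idx = int(category[1:]) - 1
    except (ValueError, IndexError):
        raise ValueError(f"not a category code: {category!r}") from None
    if category[0] != "R" or not 0 <= idx < 10:
        raise ValueError(f"not a category code: {category!r}")
    return idx


def _trunc2(x: float) -> float:
    """Truncate toward zero at 2 decimals (0.666... -> 0.66)."""
    return floor(x * 100.0 + 1e-9) / 100.0


@dataclass(frozen=True)
class BlendSpec:
    """One ratiometric code: component volumes plus its category label.

    ``volume_a`` is the E11-14:OAc volume and ``volume_b`` the Z9-14:OAc
    volume, both in microlitres.
    """

    volume_a: float
    volume_b: float
    ratio_label: str
    category: str
    volume_level: str  # "low" | "high"

    def __post_init__(self) -> None:
        if self.ratio_label not in RATIO_FRACTIONS:
            raise ValueError(f"unknown ratio label {self.ratio_label!r}")
        if self.volume_level not in ("low", "high"):
            raise ValueError(f"volume_level must be low/high, got {self.volume_level!r}")
        if self.volume_a < 0 or self.volume_b < 0:
            raise ValueError("component volumes must be non-negative")
        if self.volume_a + self.volume_b <= 0:
            raise ValueError("total volume must be positive")
        category_index(self.category)
        fa, fb = RATIO_FRACTIONS[self.ratio_label]
        total = self.volume_a + self.volume_b
        # volumes must be the (truncated) ratio split of the total
        if abs(self.volume_a - _trunc2(fa * total)) > 0.02 + 1e-9 or abs(
            self.volume_b - _trunc2(fb * total)
        ) > 0.02 + 1e-9:
            raise ValueError(
                f"volumes ({self.volume_a}, {self.volume_b}) inconsistent with "
                f"ratio {self.ratio_label}"
            )

    @property
    def total_volume(self) -> float:
        return self.volume_a + self.volume_b


def encode_categories(
    ratios: Sequence[str] = RATIO_LABELS,
    low_total: float = 1.0,
    high_total: float = 2.0,
) -> list[BlendSpec]:
    """Encode ratio labels into blend specifications at both volume levels.

    Every ratio is emitted at the low and the high total volume; component
    volumes are the ratio fraction of the total, truncated toward zero at
    two decimals (so 2/3 of 1 uL is 0.66 uL, matching the code table).
    Category codes are assigned R1..R5 to the low-volume blends and
    R6..R10 to the high-volume blends, in the order the ratios are given.

    Returns ``2 * len(ratios)`` specs, all low-volume blends first.
    """
    if low_total <= 0 or high_total <= 0:
        raise ValueError("volume totals must be positive")
    for r in ratios:
        if r not in RATIO_FRACTIONS:
            raise ValueError(f"unknown ratio label {r!r}")
    blends: list[BlendSpec] = []
    for level, total, base in (("low", low_total, 0), ("high", high_total, 5)):
        for k, r in enumerate(ratios):
            fa, fb = RATIO_FRACTIONS[r]
            blends.append(
                BlendSpec(
                    volume_a=_trunc2(fa * total),
                    volume_b=_trunc2(fb * total),
                    ratio_label=r,
                    category=f"R{base + k + 1}",
                    volume_level=level,
                )
            )
    return blends


@dataclass(frozen=True)
class SensorModel:
    """Response model of one polymer-coated dual SAWR sensor.

    Parameters
    ----------
    polymer_id:
        Coating name (PE, PSB or PEVA for the default array).
    sensitivity_a, sensitivity_b:
        Steady-state frequency shift per microlitre of E11-14:OAc and
        Z9-14:OAc respectively (Hz/uL).  Their ratio differs between
        polymers; that contrast is what makes the blend ratio decodable.
    tau:
        Characteristic rise time in seconds.  Used for both components
        unless ``tau_a``/``tau_b`` are given.
    tau_a, tau_b:
        Optional per-component rise times (s); sorption kinetics differ
        slightly between the two acetates, which gives blends a weakly
        composition-dependent transient shape.
    noise_rel:
        Relative (multiplicative) noise level on the response.
    drift_rate:
        Common-mode baseline drift (Hz/s), present on both channels.
    ref_coupling:
        Fraction of the response also seen by the uncoated reference.
    floor_sd_hz:
        Additive i.i.d. noise floor per channel (Hz).
    baseline_sd_hz:
        SD of the per-profile baseline offset per channel (Hz).
    tau_volume_coeff:
        Relative slowdown of the rise per extra microlitre injected:
        both component rise times are multiplied by
        ``1 + tau_volume_coeff * (total_volume - 1)``.  A larger dose
        evaporates for longer, so higher-volume blends rise more slowly;
        at a 1 uL total the multiplier is exactly 1.
    """

    polymer_id: str
    sensitivity_a: float
    sensitivity_b: float
    tau: float
    tau_a: float | None = None
    tau_b: float | None = None
    noise_rel: float = 0.0
    drift_rate: float = 0.0
    ref_coupling: float = 0.0
    floor_sd_hz: float = 0.0
    baseline_sd_hz: float = 0.0
    tau_volume_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or (self.tau_a is not None and self.tau_a <= 0) or (
            self.tau_b is not None and self.tau_b <= 0
        ):
            raise ValueError("rise times must be positive")
        if self.sensitivity_a < 0 or self.sensitivity_b < 0:
            raise ValueError("sensitivities must be non-negative")
        if self.sensitivity_a + self.sensitivity_b <= 0:
            raise ValueError("at least one sensitivity must be positive")
        if not 0.0 <= self.ref_coupling < 1.0:
            raise ValueError("ref_coupling must be in [0, 1)")
        if min(self.noise_rel, self.floor_sd_hz, self.baseline_sd_hz) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.tau_volume_coeff < 0:
            raise ValueError("tau_volume_coeff must be non-negative")

    @property
    def effective_tau_a(self) -> float:
        return self.tau if self.tau_a is None else self.tau_a

    @property
    def effective_tau_b(self) -> float:
        return self.tau if self.tau_b is None else self.tau_b

    def steady_state(self, blend: BlendSpec) -> float:
        """Noiseless stationary differential shift f_inf for a blend (Hz)."""
        return (1.0 - self.ref_coupling) * (
            self.sensitivity_a * blend.volume_a + self.sensitivity_b * blend.volume_b
        )


@dataclass(frozen=True)
class ExperimentTimeline:
    """Regular acquisition grid with a pre-injection baseline period."""

    sample_interval: float = 1.0
    baseline_duration: float = 100.0
    injection_time: float = 100.0
    total_duration: float = 1050.0

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not 0 < self.injection_time < self.total_duration:
            raise ValueError("injection_time must fall inside the recording")
        if self.baseline_duration < 0:
            raise ValueError("baseline_duration must be non-negative")

    def times(self) -> np.ndarray:
        n = int(round(self.total_duration / self.sample_interval)) + 1
        return np.arange(n) * self.sample_interval


CHANNELS: tuple[str, ...] = ("sense", "reference", "differential")


@dataclass
class SensorTimeSeries:
    """Frequency-shift traces of one sensor for one injection (all channels).

    ``shifts`` maps channel name (sense / reference / differential) to a
    Hz-valued array aligned with ``times``; the differential trace equals
    sense minus reference at every timestamp.
    """

    sample_id: str
    category: str
    sensor_id: str
    times: np.ndarray
    shifts: dict[str, np.ndarray]
    timeline: ExperimentTimeline

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times not strictly increasing in {self.sample_id}")
        for ch, arr in self.shifts.items():
            arr = np.asarray(arr, dtype=float)
            self.shifts[ch] = arr
            if arr.shape != self.times.shape:
                raise ValueError(
                    f"channel {ch!r} of {self.sample_id}/{self.sensor_id} has "
                    f"{arr.size} samples for {self.times.size} timestamps"
                )
        if all(ch in self.shifts for ch in CHANNELS):
            resid = self.shifts["differential"] - (
                self.shifts["sense"] - self.shifts["reference"]
            )
            if np.max(np.abs(resid)) > 1e-4:  # tolerance covers CSV rounding
                raise ValueError("differential channel is not sense - reference")

    @property
    def differential(self) -> np.ndarray:
        return self.shifts["differential"]


def _response(
    blend: BlendSpec, sensor: SensorModel, t: np.ndarray, t_inj: float
) -> np.ndarray:
    """Noise-free sorption response (Hz) on the coated surface."""
    dt = np.clip(t - t_inj, 0.0, None)
    slow = 1.0 + sensor.tau_volume_coeff * (blend.total_volume - 1.0)
    rise_a = -np.expm1(-dt / (slow * sensor.effective_tau_a))
    rise_b = -np.expm1(-dt / (slow * sensor.effective_tau_b))
    return (
        sensor.sensitivity_a * blend.volume_a * rise_a
        + sensor.sensitivity_b * blend.volume_b * rise_b
    )


def simulate_profile(
    blend: BlendSpec,
    sensor: SensorModel,
    timeline: ExperimentTimeline,
    seed: int | np.random.Generator,
    *,
    sample_id: str | None = None,
    injection_offset: float = 0.0,
) -> SensorTimeSeries:
    """Simulate one injection as seen by one sensor (all three channels).

    ``injection_offset`` shifts the effective injection instant (timing
    jitter of the emitter/plume); the expected differential response is 0
    before the effective injection and rises first-order after it, with
    stationary value ``sensitivity_a*volume_a + sensitivity_b*volume_b``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = timeline.times()
    t_inj = timeline.injection_time + injection_offset
    resp = _response(blend, sensor, t, t_inj)
    drift = sensor.drift_rate * t

    def channel(clean_resp: np.ndarray) -> np.ndarray:
        mult = clean_resp * sensor.noise_rel * rng.standard_normal(t.size)
        floor_noise = sensor.floor_sd_hz * rng.standard_normal(t.size)
        offset = sensor.baseline_sd_hz * rng.standard_normal()
        return drift + clean_resp + mult + floor_noise + offset

    sense = channel(resp)
    reference = channel(sensor.ref_coupling * resp)
    shifts = {
        "sense": sense,
        "reference": reference,
        "differential": sense - reference,
    }
    return SensorTimeSeries(
        sample_id=sample_id or f"{blend.category}_r0",
        category=blend.category,
        sensor_id=sensor.polymer_id,
        times=t,
        shifts=shifts,
        timeline=timeline,
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """Full measurement campaign: blends x repeats x sensors on one timeline."""

    blends: tuple[BlendSpec, ...]
    sensors: tuple[SensorModel, ...]
    timeline: ExperimentTimeline
    repeats_low: int = 6
    repeats_high: int = 3
    injection_jitter_sd: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blends", tuple(self.blends))
        object.__setattr__(self, "sensors", tuple(self.sensors))
        if self.repeats_low < 1 or self.repeats_high < 1:
            raise ValueError("repeat counts must be >= 1")
        if self.injection_jitter_sd < 0:
            raise ValueError("injection_jitter_sd must be non-negative")

    def repeats_for(self, blend: BlendSpec) -> int:
        return self.repeats_low if blend.volume_level == "low" else self.repeats_high

    @property
    def profiles_per_sensor(self) -> int:
        return sum(self.repeats_for(b) for b in self.blends)


def simulate_design(design: ExperimentDesign) -> "SensorArrayDataset":
    """Simulate every (blend, repeat, sensor) profile of a design.

    Deterministic for a given design seed: every injection gets its own
    child random stream, so repeats of a category differ only by their
    noise realisation and the profile count follows the design arithmetic
    (``repeats_low`` per low-volume blend + ``repeats_high`` per high-volume
    blend, per sensor).  The three sensors of one injection share that
    injection's timing jitter.
    """
    from .dataset import SensorArrayDataset

    root = np.random.SeedSequence(design.seed)
    injections = [
        (blend, rep) for blend in design.blends for rep in range(design.repeats_for(blend))
    ]
    children = root.spawn(len(injections))
    profiles: list[SensorTimeSeries] = []
    for (blend, rep), child in zip(injections, children):
        streams = child.spawn(len(design.sensors) + 1)
        jitter_rng = np.random.default_rng(streams[0])
        offset = 0.0
        if design.injection_jitter_sd > 0:
            offset = float(
                np.clip(
                    jitter_rng.normal(0.0, design.injection_jitter_sd),
                    -3.0 * design.injection_jitter_sd,
                    3.0 * design.injection_jitter_sd,
                )
            )
        sample_id = f"{blend.category}_r{rep}"
        for sensor, stream in zip(design.sensors, streams[1:]):
            profiles.append(
                simulate_profile(
                    blend,
                    sensor,
                    design.timeline,
                    np.random.default_rng(stream),
                    sample_id=sample_id,
                    injection_offset=offset,
                )
            )
    return SensorArrayDataset(profiles, design=design)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------


@dataclass
class CalibrationReport:
    """Repeatability and selectivity statistics of a simulated dataset.

    ``relative_deviation`` maps (sensor_id, category) to the trace of
    SD-over-repeats divided by |mean-over-repeats| of the differential
    signal; ``sensor_correlations`` maps sensor pairs to the mean Pearson
    correlation of their differential traces over matched samples (NaN for
    degenerate constant traces).
    """

    relative_deviation: dict[tuple[str, str], np.ndarray]
    sensor_correlations: dict[tuple[str, str], float]
    steady_state_relative_deviation: dict[tuple[str, str], float]

    def max_steady_state_deviation(self) -> float:
        return max(self.steady_state_relative_deviation.values())

    def correlation_range(self) -> tuple[float, float]:
        vals = [v for v in self.sensor_correlations.values() if np.isfinite(v)]
        return (min(vals), max(vals))


def calibration_report(dataset, steady_window_s: float = 100.0) -> CalibrationReport:
    """Compute the repeatability / correlation statistics of a dataset.

    The steady-state relative deviation is the mean of the deviation trace
    over the final ``steady_window_s`` seconds; correlations are averaged
    over matched samples for every sensor pair.
    """
    if len(dataset.sensor_ids) < 2:
        raise ValueError("calibration needs at least two sensors")
    if len(dataset.sample_ids) < 2:
        raise ValueError("calibration needs at least two profiles")
    X = dataset.array("differential")  # (samples, sensors, times)
    times = dataset.times
    cats = np.asarray(dataset.categories)
    n_tail = max(1, int(round(steady_window_s / dataset.timeline.sample_interval)))

    rel_dev: dict[tuple[str, str], np.ndarray] = {}
    steady: dict[tuple[str, str], float] = {}
    for j, sensor in enumerate(dataset.sensor_ids):
        for cat in dict.fromkeys(cats):
            sel = X[cats == cat, j, :]
            if sel.shape[0] < 2:
                continue
            mean = sel.mean(axis=0)
            sd = sel.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                trace = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.nan)
            rel_dev[(sensor, cat)] = trace
            steady[(sensor, cat)] = float(np.nanmean(trace[-n_tail:]))

    corr: dict[tuple[str, str], float] = {}
    for j in range(len(dataset.sensor_ids)):
        for k in range(j + 1, len(dataset.sensor_ids)):
            vals = []
            for i in range(X.shape[0]):
                a, b = X[i, j, :], X[i, k, :]
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    vals.append(np.nan)
                    warnings.warn(
                        "constant trace: correlation undefined", stacklevel=2
                    )
                    continue
                vals.append(float(np.corrcoef(a, b)[0, 1]))
            corr[(dataset.sensor_ids[j], dataset.sensor_ids[k])] = float(
                np.nanmean(vals)
            ) if np.any(np.isfinite(vals)) else float("nan")
    _ = times  # times kept for future per-window statistics
    return CalibrationReport(rel_dev, corr, steady)


# --------------------------------------------------------------------------
# defaults
# --------------------------------------------------------------------------


def default_sensors() -> tuple[SensorModel, SensorModel, SensorModel]:
    """The default three-polymer array.

    Sensitivity ratios differ per polymer (PE prefers E11-14:OAc, PEVA
    prefers Z9-14:OAc, PSB is balanced) so the five ratios map to distinct
    directions in sensor space; absolute scales are order-of-magnitude
    choices (hundreds of Hz for ~1 uL doses).  PE carries the largest
    relative noise, matching its poorer steady-state repeatability.
    """
    return (
        SensorModel(
            polymer_id="PE",
            sensitivity_a=700.0,
            sensitivity_b=170.0,
            tau=135.0,
            tau_a=95.0,
            tau_b=170.0,
            noise_rel=0.030,
            drift_rate=0.05,
            ref_coupling=0.15,
            floor_sd_hz=2.0,
            baseline_sd_hz=7.0,
            tau_volume_coeff=0.3,
        ),
        SensorModel(
            polymer_id="PSB",
            sensitivity_a=430.0,
            sensitivity_b=520.0,
            tau=172.0,
            tau_a=130.0,
            tau_b=215.0,
            noise_rel=0.015,
            drift_rate=0.04,
            ref_coupling=0.12,
            floor_sd_hz=1.5,
            baseline_sd_hz=5.0,
            tau_volume_coeff=0.3,
        ),
        SensorModel(
            polymer_id="PEVA",
            sensitivity_a=180.0,
            sensitivity_b=720.0,
            tau=215.0,
            tau_a=170.0,
            tau_b=260.0,
            noise_rel=0.015,
            drift_rate=0.04,
            ref_coupling=0.12,
            floor_sd_hz=1.5,
            baseline_sd_hz=5.0,
            tau_volume_coeff=0.3,
        ),
    )


def default_timeline() -> ExperimentTimeline:
    """1 s sampling, injection at 100 s, 1050 s recording."""
    return ExperimentTimeline()


def default_design(seed: int = 0) -> ExperimentDesign:
    """The reference campaign: 10 codes, 6 low / 3 high repeats, 3 sensors.

    Yields 45 profiles per sensor (135 in total), the sample arithmetic of
    the reference measurement campaign.
    """
    return ExperimentDesign(
        blends=tuple(encode_categories()),
        sensors=default_sensors(),
        timeline=default_timeline(),
        repeats_low=6,
        repeats_high=3,
        seed=seed,
    )


def noiseless_sensors() -> tuple[SensorModel, ...]:
    """Default array with every stochastic term switched off (for tests)."""
    return tuple(
        replace(s, noise_rel=0.0, floor_sd_hz=0.0, baseline_sd_hz=0.0)
        for s in default_sensors()
    )
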