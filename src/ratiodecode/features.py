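"""Steady-state and transient features of sensor-array traces.

At a *time station* ``t`` (elapsed recording time) every sample i and
sensor j contributes a differential frequency shift ``f_ij(t)``.  Ten
features are derived from it:

========  ================================================================
Orig      raw shift f_ij(t)
Zscore    (f_ij - mu_j) / sigma_j, statistics over the N samples at t
AS        autoscaled: f_ij / L_i with L_i the Euclidean norm over sensors
AR        autoranged: f_ij / R_j with R_j the RMS over samples
XC        f_ij / C_i, C_i = 1 for low-volume, 2 for high-volume samples
LnF       ln(max(|f_ij|, eps))
Deriv     smoothed finite-difference df/dt (Hz/s)
Tau1      rise time from the log-decrement:  -1 / d ln(f_inf - f) / dt
Tau2      rise time from the slope:          f_inf / (df/dt)
RatioF    the three pairwise sensor ratios f_i1/f_i2, f_i1/f_i3, f_i2/f_i3
========  ================================================================

For a first-order rise f(t) = f_inf (1 - exp(-t/tau)), Tau1 recovers tau
exactly at any station, while Tau2 equals tau * exp(t/tau) and is a valid
tau estimate only for t << tau.  The stationary value f_inf is not known
mid-measurement; it is estimated per profile either offline (mean of the
final smoothing window of the recording, the default) or online (running
maximum of the smoothed trace up to t).

All divisions, logs and log-decrements are clipped at a per-profile
relative floor ``eps = 1e-6 * max|f|`` so the feature matrix stays
rectangular with no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dataset import SensorArrayDataset
from .simulate import category_index

__all__ = ["FEATURE_NAMES", "FeatureSpec", "FeatureMatrix", "extract", "pca_scores"]

FEATURE_NAMES: tuple[str, ...] = (
    "Orig",
    "Zscore",
    "AS",
    "AR",
    "XC",
    "LnF",
    "Deriv",
    "Tau1",
    "Tau2",
    "RatioF",
)

#: Default rise-time guard: estimated time constants are capped here (s),
#: keeping the occasional degenerate estimate (clipped log-decrement or
#: derivative) bounded so it cannot dominate a feature matrix's scale.
TAU_CAP = 2000.0


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature to extract and the numerical guards to use.

    ``smoothing_window`` (odd, samples) is the moving-average window used
    before differencing and the local fit window of the Tau1 log-slope.
    ``epsilon_hz`` overrides the per-profile relative floor when given.
    ``f_inf_mode`` selects the offline/online stationary-value estimate;
    ``channel`` selects which trace carries the signal.
    """

    name: str
    smoothing_window: int = 21
    epsilon_hz: float | None = None
    f_inf_mode: str = "offline"
    channel: str = "differential"
    tau_cap: float = TAU_CAP

    def __post_init__(self) -> None:
        if self.name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.name!r}")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.epsilon_hz is not None and self.epsilon_hz <= 0:
            raise ValueError("epsilon_hz must be positive")
        if self.f_inf_mode not in ("offline", "online"):
            raise ValueError("f_inf_mode must be 'offline' or 'online'")
        if self.tau_cap <= 0:
            raise ValueError("tau_cap must be positive")


@dataclass
class FeatureMatrix:
    """Samples x feature-values at one time station, with category labels.

    ``groups`` tracks the originating sample of each row; it differs from
    ``sample_ids`` only for neighbour-expanded datasets, where a sample
    contributes several rows that must be held out together.
    """

    time_station: float
    feature_names: list[str]
    values: np.ndarray
    categories: list[str]
    sample_ids: list[str]
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, k = self.values.shape
        if len(self.categories) != n or len(self.sample_ids) != n:
            raise ValueError("row labels do not match the value matrix")
        if len(self.feature_names) != k:
            raise ValueError("feature names do not match the value matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.groups is None:
            self.groups = list(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @staticmethod
    def concat(matrices: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        """Column-concatenate feature matrices over identical samples."""
        first = matrices[0]
        for m in matrices[1:]:
            if m.sample_ids != first.sample_ids:
                raise ValueError("cannot combine features over different samples")
        return FeatureMatrix(
            time_station=first.time_station,
            feature_names=[n for m in matrices for n in m.feature_names],
            values=np.hstack([m.values for m in matrices]),
            categories=list(first.categories),
            sample_ids=list(first.sample_ids),
            groups=list(first.groups),
        )


def _smooth(X: np.ndarray, window: int) -> np.ndarray:
    """Moving average along the last axis, edges renormalised."""
    if window == 1:
        return X
    kernel = np.ones(window) / window
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, X)
    # renormalise the shrinking edge windows
    norm = np.convolve(np.ones(X.shape[-1]), kernel, mode="same")
    return sm / norm


def _derivative_at(X: np.ndarray, idx: int, window: int, dt: float) -> np.ndarray:
    """Central difference of the smoothed traces at grid index ``idx``.

    Falls back to one-sided differences at the recording boundaries.
    """
    sm = _smooth(X, window)
    lo = max(idx - 1, 0)
    hi = min(idx + 1, X.shape[-1] - 1)
    return (sm[..., hi] - sm[..., lo]) / ((hi - lo) * dt)


def _slope_at(X: np.ndarray, idx: int, window: int, dt: float, min_idx: int) -> np.ndarray:
    """Least-squares slope over the window around ``idx``.

    The window never reaches below ``min_idx``: the rise-time estimators
    must not mix pre-injection baseline into a post-injection fit.
    """
    half = window // 2
    lo = max(idx - half, min_idx, 0)
    hi = min(idx + half, X.shape[-1] - 1)
    if hi - lo < 2:
        hi = min(lo + 2, X.shape[-1] - 1)
    seg = X[..., lo : hi + 1]
    tgrid = np.arange(lo, hi + 1) * dt
    tc = tgrid - tgrid.mean()
    return (seg * tc).sum(axis=-1) / float(np.sum(tc * tc))


def _f_inf(X: np.ndarray, idx: int, spec: FeatureSpec) -> np.ndarray:
    """Per-profile stationary-value estimate, shape (samples, sensors)."""
    w = spec.smoothing_window
    if spec.f_inf_mode == "offline":
        return X[..., -w:].mean(axis=-1)
    sm = _smooth(X, w)
    return sm[..., : idx + 1].max(axis=-1)


def _tau1(
    X: np.ndarray, idx: int, spec: FeatureSpec, dt: float, min_idx: int
) -> np.ndarray:
    """Log-decrement rise time via a local least-squares slope fit."""
    eps = _epsilon(X, spec)[..., None]
    logdec = np.log(np.clip(_f_inf(X, idx, spec)[..., None] - X, eps, None))
    slope = _slope_at(logdec, idx, spec.smoothing_window, dt, min_idx)
    slope = np.minimum(slope, -1.0 / spec.tau_cap)  # non-decaying fits -> capped tau
    return -1.0 / slope


def _injection_index(dataset: SensorArrayDataset) -> int:
    """First grid index at or after the nominal injection instant."""
    tl = dataset.timeline
    return int(np.ceil(tl.injection_time / tl.sample_interval - 1e-9))


def _epsilon(X: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Per-profile clipping floor, shape (samples, sensors)."""
    if spec.epsilon_hz is not None:
        return np.full(X.shape[:-1], spec.epsilon_hz)
    m = np.abs(X).max(axis=-1)
    return np.where(m > 0, 1e-6 * m, 1e-12)


def _clip_denominator(d: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Push denominators away from 0 keeping their sign (0 counts as +)."""
    sign = np.where(d < 0, -1.0, 1.0)
    return sign * np.maximum(np.abs(d), eps)


def extract(dataset: SensorArrayDataset, spec: FeatureSpec, t: float) -> FeatureMatrix:
    """Extract one feature for every sample at time station ``t``.

    Output width is one value per sensor (3 for the default array) for all
    features; RatioF emits the three pairwise sensor ratios instead.
    """
    idx = dataset.time_index(t)
    X = dataset.array(spec.channel)  # (samples, sensors, times)
    f = X[..., idx]
    n_sensors = X.shape[1]
    cats = dataset.categories
    dt = dataset.timeline.sample_interval
    name = spec.name

    if name == "Orig":
        vals = f
    elif name == "Zscore":
        mu = f.mean(axis=0)
        sd = f.std(axis=0)
        vals = np.where(sd > 0, (f - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    elif name == "AS":
        L = np.sqrt((f**2).sum(axis=1, keepdims=True))
        vals = np.where(L > 0, f / np.where(L > 0, L, 1.0), 0.0)
    elif name == "AR":
        R = np.sqrt((f**2).mean(axis=0, keepdims=True))
        vals = f / _clip_denominator(R, np.full_like(R, 1e-12))
    elif name == "XC":
        C = np.array([1.0 if category_index(c) < 5 else 2.0 for c in cats])
        vals = f / C[:, None]
    elif name == "LnF":
        vals = np.log(np.maximum(np.abs(f), _epsilon(X, spec)))
    elif name == "Deriv":
        vals = _derivative_at(X, idx, spec.smoothing_window, dt)
    elif name == "Tau1":
        inj = _injection_index(dataset)
        vals = np.minimum(_tau1(X, idx, spec, dt, inj), spec.tau_cap)
    elif name == "Tau2":
        eps = _epsilon(X, spec)
        inj = _injection_index(dataset)
        deriv = np.maximum(_slope_at(X, idx, spec.smoothing_window, dt, inj), eps)
        vals = np.minimum(np.abs(_f_inf(X, idx, spec)) / deriv, spec.tau_cap)
    elif name == "RatioF":
        eps = _epsilon(X, spec)
        pairs = [(a, b) for a in range(n_sensors) for b in range(a + 1, n_sensors)]
        vals = np.column_stack(
            [f[:, a] / _clip_denominator(f[:, b], eps[:, b]) for a, b in pairs]
        )
        names = [
            f"RatioF_{dataset.sensor_ids[a]}/{dataset.sensor_ids[b]}" for a, b in pairs
        ]
        return FeatureMatrix(t, names, vals, list(cats), list(dataset.sample_ids))
    else:  # pragma: no cover - guarded by FeatureSpec
        raise ValueError(name)

    names = [f"{name}_{s}" for s in dataset.sensor_ids]
    return FeatureMatrix(t, names, vals, list(cats), list(dataset.sample_ids))


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (n_components, n_features)


def pca_scores(features: FeatureMatrix | np.ndarray, n_components: int = 2) -> PCAResult:
    """Mean-centred principal-component scores of a feature matrix.

    Components are ordered by decreasing variance; each component's sign is
    fixed so its largest-magnitude loading is positive.  Requesting more
    components than the matrix rank truncates with a warning.
    """
    import warnings

    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    flip = np.sign(Vt[np.arange(n_components), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    var = s**2 / (X.shape[0] - 1)
    total = np.var(Xc, axis=0, ddof=1).sum()
    return PCAResult(scores, var, var / total if total > 0 else var, Vt)


def replace_spec(spec: FeatureSpec, **kw) -> FeatureSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **kw)
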