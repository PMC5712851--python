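"""Decoders for the ratiometric codes: Fisher LDA, Parzen-window PNN,
and a two-output multilayer perceptron with nearest-target decoding.

All three share a minimal estimator surface (``fit(X, y)``, ``predict(X)``)
and break prediction ties toward the lowest class index (classes ordered
R1..R10, or by natural sort for generic labels), so every decision is
deterministic and reproducible.
"""

from __future__ import annotations

import json
import warnings
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.special import expit, logsumexp

from .simulate import CATEGORY_ORDER

__all__ = [
    "TEN_TARGETS",
    "class_sort_key",
    "LDAClassifier",
    "PNNClassifier",
    "pnn_spread",
    "MLPNNClassifier",
]

#: Concentration-pair targets (E11-14:OAc uL, Z9-14:OAc uL) for R1..R10.
TEN_TARGETS: dict[str, tuple[float, float]] = {
    "R1": (1.00, 0.00),
    "R2": (0.66, 0.33),
    "R3": (0.50, 0.50),
    "R4": (0.33, 0.66),
    "R5": (0.00, 1.00),
    "R6": (2.00, 0.00),
    "R7": (1.33, 0.66),
    "R8": (1.00, 1.00),
    "R9": (0.66, 1.33),
    "R10": (0.00, 2.00),
}


def class_sort_key(label):
    """Canonical class order: R1..R10 first, then natural ordering."""
    if isinstance(label, str) and label in CATEGORY_ORDER:
        return (0, CATEGORY_ORDER.index(label))
    return (1, label)


def _ordered_classes(y: Sequence) -> list:
    return sorted(set(y), key=class_sort_key)


# --------------------------------------------------------------------------
# Fisher linear discriminant analysis
# --------------------------------------------------------------------------


class LDAClassifier:
    """Fisher LDA with a nearest-class-mean linear classifier.

    The discriminant basis maximises the between/within scatter ratio; the
    pooled within-class covariance is ridged by ``ridge * trace/dim`` so it
    stays invertible when features outnumber samples.  Up to ``c - 1``
    discriminant directions are kept and samples are assigned to the class
    whose mean is nearest in discriminant space.
    """

    def __init__(self, ridge: float = 1e-6, n_components: int | None = None):
        self.ridge = ridge
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: Sequence) -> "LDAClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.classes_ = _ordered_classes(y)
        y = np.asarray(y)
        if len(self.classes_) < 2:
            raise ValueError("LDA needs at least two classes")
        n, d = X.shape
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        bad = [c for c, k in counts.items() if k < 2]
        if bad:
            raise ValueError(
                f"classes {bad} have a single sample; merge or drop them before LDA"
            )
        grand = X.mean(axis=0)
        Sw = np.zeros((d, d))
        Sb = np.zeros((d, d))
        means = []
        for c in self.classes_:
            Xi = X[y == c]
            mi = Xi.mean(axis=0)
            means.append(mi)
            dev = Xi - mi
            Sw += dev.T @ dev
            Sb += len(Xi) * np.outer(mi - grand, mi - grand)
        Sw /= n - len(self.classes_)
        Sw += self.ridge * (np.trace(Sw) / d if np.trace(Sw) > 0 else 1.0) * np.eye(d)
        k = min(len(self.classes_) - 1, d)
        if self.n_components is not None:
            k = min(k, self.n_components)
        evals, evecs = linalg.eigh(Sb, Sw)
        order = np.argsort(evals)[::-1][:k]
        self.eigenvalues_ = evals[order]
        self.scalings_ = evecs[:, order]  # (d, k); Sw-orthogonal columns
        self.means_ = np.asarray(means)
        self.class_means_ = self.means_ @ self.scalings_
        self.n_features_ = d
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1]}"
            )
        return X @ self.scalings_

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Negative distances to class means in discriminant space."""
        Z = self.transform(X)
        d2 = ((Z[:, None, :] - self.class_means_[None, :, :]) ** 2).sum(axis=-1)
        return -np.sqrt(d2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        idx = scores.argmax(axis=1)  # argmax keeps the lowest index on ties
        return np.asarray([self.classes_[i] for i in idx], dtype=object)


# --------------------------------------------------------------------------
# probabilistic neural network (Parzen-window classifier)
# --------------------------------------------------------------------------


def pnn_spread(
    X: np.ndarray, y: Sequence, mode: str = "per_class_feature"
) -> np.ndarray:
    """Gaussian kernel bandwidths from within-class nearest-neighbour gaps.

    For every class the nearest neighbour of each sample (full-vector
    Euclidean distance) is found; the median of those neighbour gaps sets
    the bandwidth.  Modes:

    * ``per_class_feature`` (default): sigma[a, k] = median over class-a
      samples of the coordinate-k gap |x_ik - x_nn(i),k|;
    * ``per_feature``: one sigma per feature, pooling all classes;
    * ``scalar``: a single sigma, the median full-vector neighbour gap.

    Zero or undefined medians fall back to the global per-feature median
    (then to the feature SD, then to 1.0), so every bandwidth is positive.
    Single-sample classes trigger the fallback with a warning.

    Returns an array of shape (n_classes, n_features) indexed by the
    canonically ordered classes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = _ordered_classes(y)
    p = X.shape[1]
    per_class = np.full((len(classes), p), np.nan)
    all_coord_gaps: list[np.ndarray] = []
    all_dist: list[float] = []
    for a, c in enumerate(classes):
        Xi = X[y == c]
        if len(Xi) < 2:
            warnings.warn(
                f"class {c!r} has a single sample; using global fallback spread",
                stacklevel=2,
            )
            continue
        d2 = ((Xi[:, None, :] - Xi[None, :, :]) ** 2).sum(axis=-1)
        np.fill_diagonal(d2, np.inf)
        nn = d2.argmin(axis=1)
        gaps = np.abs(Xi - Xi[nn])  # per-coordinate gaps of NN pairs
        per_class[a] = np.median(gaps, axis=0)
        all_coord_gaps.append(gaps)
        all_dist.extend(np.sqrt(d2[np.arange(len(Xi)), nn]).tolist())

    pooled = (
        np.vstack(all_coord_gaps) if all_coord_gaps else np.zeros((1, p))
    )
    global_feature = np.median(pooled, axis=0)
    # layered fallback so every bandwidth ends up strictly positive
    feat_sd = X.std(axis=0)
    global_feature = np.where(global_feature > 0, global_feature, feat_sd)
    global_feature = np.where(global_feature > 0, global_feature, 1.0)

    if mode == "scalar":
        s = float(np.median(all_dist)) if all_dist else 0.0
        if s <= 0:
            s = float(np.mean(global_feature))
        return np.full((len(classes), p), s)
    if mode == "per_feature":
        med = np.median(pooled, axis=0)
        med = np.where(med > 0, med, global_feature)
        return np.tile(med, (len(classes), 1))
    if mode != "per_class_feature":
        raise ValueError(f"unknown spread mode {mode!r}")
    bad = ~(per_class > 0)
    if np.any(bad):
        per_class = np.where(bad, global_feature[None, :], per_class)
    return per_class


class PNNClassifier:
    """Parzen-window probabilistic neural network.

    The class density at a test point is the average of Gaussian kernels
    centred on that class's training vectors,

        f_a(X) = (2 pi)^(-p/2) / prod_k sigma_ak * (1/n_a)
                 * sum_i exp( -1/2 sum_k ((X_k - Y_aik) / sigma_ak)^2 ),

    a diagonal-bandwidth generalisation of the scalar-sigma kernel (each
    feature gets its own smoothing, so wildly different feature scales need
    no prior normalisation).  Bandwidths come from the within-class
    median-nearest-neighbour rule (:func:`pnn_spread`), optionally scaled:
    as the scale tends to 0 the classifier approaches 1-nearest-neighbour,
    as it grows the boundaries flatten toward linear ones.

    The default ``per_feature`` mode pools the neighbour gaps of all
    classes into one bandwidth per feature; with only a handful of repeats
    per class, per-class medians occasionally collapse to a tiny value and
    starve the true class of density, while the pooled estimate stays
    stable (the per-class mode remains available as ``per_class_feature``).
    """

    def __init__(self, spread_mode: str = "per_feature", spread_scale: float = 1.0):
        self.spread_mode = spread_mode
        self.spread_scale = spread_scale

    def fit(self, X: np.ndarray, y: Sequence) -> "PNNClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.classes_ = _ordered_classes(y)
        self.templates_ = [X[y == c] for c in self.classes_]
        self.spreads_ = pnn_spread(X, y, self.spread_mode) * self.spread_scale
        self.p_ = X.shape[1]
        return self

    def log_density(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p_:
            raise ValueError(f"expected {self.p_} features, got {X.shape[1]}")
        out = np.empty((X.shape[0], len(self.classes_)))
        for a, Y in enumerate(self.templates_):
            sig = self.spreads_[a]
            z = (X[:, None, :] - Y[None, :, :]) / sig
            d2 = (z**2).sum(axis=-1)
            out[:, a] = (
                logsumexp(-0.5 * d2, axis=1)
                - np.log(len(Y))
                - 0.5 * self.p_ * np.log(2 * np.pi)
                - np.log(sig).sum()
            )
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logf = self.log_density(X)
        bad = ~np.isfinite(logf).any(axis=1)
        shifted = logf - logf.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            prob = np.exp(shifted)
            prob /= prob.sum(axis=1, keepdims=True)
        if np.any(bad):
            warnings.warn(
                "PNN densities underflowed; falling back to nearest template",
                stacklevel=2,
            )
            for i in np.where(bad)[0]:
                prob[i] = 0.0
                prob[i, self._nearest_class(X[i])] = 1.0
        return prob

    def _nearest_class(self, x: np.ndarray) -> int:
        best, best_d = 0, np.inf
        for a, Y in enumerate(self.templates_):
            d = np.min(((Y - x) ** 2).sum(axis=1))
            if d < best_d:
                best, best_d = a, d
        return best

    def predict(self, X: np.ndarray) -> np.ndarray:
        prob = self.predict_proba(X)
        idx = prob.argmax(axis=1)
        return np.asarray([self.classes_[i] for i in idx], dtype=object)


# --------------------------------------------------------------------------
# two-output multilayer perceptron with nearest-target decoding
# --------------------------------------------------------------------------


class MLPNNClassifier:
    """Single-hidden-layer perceptron regressing concentration pairs.

    Instead of ten one-hot outputs the network regresses the two component
    concentrations; a category is decoded as the Euclidean-nearest row of
    the target table (``TEN_TARGETS`` by default — keeping the network at
    two outputs keeps it small and fast to train).  Sigmoid hidden layer,
    linear output, trained by full-batch gradient descent with momentum on
    the mean squared error; inputs are standardised internally (the affine
    scaling is part of the fitted model).  Deterministic for a given seed.
    """

    def __init__(
        self,
        hidden: int = 10,
        epochs: int = 2000,
        lr: float = 0.01,
        momentum: float = 0.9,
        seed: int = 0,
        patience: int = 200,
        tol: float = 1e-9,
        targets: dict | None = None,
    ):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.momentum = momentum
        self.seed = seed
        self.patience = patience
        self.tol = tol
        self.targets = dict(targets) if targets is not None else dict(TEN_TARGETS)

    def _target_matrix(self) -> tuple[list, np.ndarray]:
        labels = sorted(self.targets, key=class_sort_key)
        return labels, np.asarray([self.targets[c] for c in labels], dtype=float)

    def fit(self, X: np.ndarray, y: Sequence) -> "MLPNNClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        labels, tmat = self._target_matrix()
        unknown = set(y) - set(labels)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)!r} missing from the target table")
        T = np.asarray([self.targets[c] for c in y], dtype=float)

        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_sd_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.x_mean_) / self.x_sd_

        rng = np.random.default_rng(self.seed)
        d, h, o = X.shape[1], self.hidden, tmat.shape[1]
        W1 = rng.normal(0.0, 1.0 / np.sqrt(d), (d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(h), (h, o))
        b2 = np.zeros(o)
        vW1 = np.zeros_like(W1)
        vb1 = np.zeros_like(b1)
        vW2 = np.zeros_like(W2)
        vb2 = np.zeros_like(b2)

        n = Xs.shape[0]
        best = (np.inf, W1.copy(), b1.copy(), W2.copy(), b2.copy())
        stale = 0
        self.loss_curve_ = []
        for _ in range(self.epochs):
            H = expit(Xs @ W1 + b1)
            out = H @ W2 + b2
            err = out - T
            mse = float((err**2).mean())
            self.loss_curve_.append(mse)
            if mse < best[0] - self.tol:
                best = (mse, W1.copy(), b1.copy(), W2.copy(), b2.copy())
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
            gout = 2.0 * err / (n * o)
            gW2 = H.T @ gout
            gb2 = gout.sum(axis=0)
            gH = gout @ W2.T * H * (1.0 - H)
            gW1 = Xs.T @ gH
            gb1 = gH.sum(axis=0)
            vW1 = self.momentum * vW1 - self.lr * gW1
            vb1 = self.momentum * vb1 - self.lr * gb1
            vW2 = self.momentum * vW2 - self.lr * gW2
            vb2 = self.momentum * vb2 - self.lr * gb2
            W1 += vW1
            b1 += vb1
            W2 += vW2
            b2 += vb2
        else:
            if best[0] > self.tol and len(self.loss_curve_) == self.epochs:
                warnings.warn(
                    "MLPNN stopped at the epoch cap before converging; "
                    "returning the best weights seen",
                    stacklevel=2,
                )
        self.mse_, self.W1_, self.b1_, self.W2_, self.b2_ = best
        self.classes_, self.target_matrix_ = labels, tmat
        self.n_features_ = d
        return self

    def predict_pairs(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} features, got {X.shape[1]}")
        Xs = (X - self.x_mean_) / self.x_sd_
        return expit(Xs @ self.W1_ + self.b1_) @ self.W2_ + self.b2_

    def decode_pairs(self, pairs: np.ndarray) -> np.ndarray:
        """Map predicted concentration pairs to nearest-target categories."""
        pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
        d2 = ((pairs[:, None, :] - self.target_matrix_[None, :, :]) ** 2).sum(axis=-1)
        idx = d2.argmin(axis=1)  # first minimum -> lowest class index on ties
        return np.asarray([self.classes_[i] for i in idx], dtype=object)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decode_pairs(self.predict_pairs(X))

    # -- portable serialisation ------------------------------------------
    def to_json(self) -> str:
        state = {
            "hidden": self.hidden,
            "targets": {k: list(v) for k, v in self.targets.items()},
            "x_mean": self.x_mean_.tolist(),
            "x_sd": self.x_sd_.tolist(),
            "W1": self.W1_.tolist(),
            "b1": self.b1_.tolist(),
            "W2": self.W2_.tolist(),
            "b2": self.b2_.tolist(),
        }
        return json.dumps(state)

    @classmethod
    def from_json(cls, payload: str) -> "MLPNNClassifier":
        state = json.loads(payload)
        model = cls(hidden=state["hidden"], targets={k: tuple(v) for k, v in state["targets"].items()})
        model.x_mean_ = np.asarray(state["x_mean"])
        model.x_sd_ = np.asarray(state["x_sd"])
        model.W1_ = np.asarray(state["W1"])
        model.b1_ = np.asarray(state["b1"])
        model.W2_ = np.asarray(state["W2"])
        model.b2_ = np.asarray(state["b2"])
        model.classes_, model.target_matrix_ = model._target_matrix()
        model.n_features_ = model.x_mean_.size
        return model
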