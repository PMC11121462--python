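"""From-scratch 8-12-6 multilayer perceptron honey-type classifier.

Architecture and training follow the classification-ANN recipe common in
food chemometrics: eight min-max-normalized physicochemical inputs
(glucose, fructose, sucrose, acidity, conductivity, moisture, diastase,
insoluble matter — 5-HMF is excluded), one logistic hidden layer of 12
units, a softmax output over the six botanical classes, mean categorical
cross-entropy loss, and quasi-Newton (BFGS) optimization.  The data are
split 70/30 into training and test subsets (stratified by class by default,
which protects the smallest class); the best of several random weight
initializations is kept.  Everything is deterministic given the seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .data_model import HoneySample, HoneyType, SampleTable

__all__ = [
    "FEATURES",
    "CLASSES",
    "TrainingConfig",
    "MLPModel",
    "EvaluationReport",
    "normalize_features",
    "forward_probabilities",
    "loss_and_grad",
    "penalized_loss_and_grad",
    "stratified_split",
    "train_classifier",
    "evaluate_classifier",
]

#: Input features, in network order (5-HMF deliberately excluded).
FEATURES = ("glu", "fru", "suc", "acid", "econd", "mc", "dia", "ins")

#: Output classes, in network order.
CLASSES = tuple(HoneyType)

N_IN, N_OUT = len(FEATURES), len(CLASSES)


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol.

    ``weight_decay`` is a small L2 penalty on the weights (not biases) —
    the standard regularization for a 186-parameter network fitted to a
    few hundred records.  ``val_fraction`` > 0 carves a stratified
    validation subset out of the training split: each restart keeps the
    BFGS iterate with the lowest validation loss (early stopping), and the
    best restart is the one with the lowest validation loss.  With
    ``val_fraction = 0`` every restart trains on the full training split to
    the iteration cap and selection falls back to training loss.
    """

    train_fraction: float = 0.70
    split_seed: int = 0
    init_seed: int = 0
    init_scale: float = 0.5
    max_iter: int = 500
    gtol: float = 1e-6
    restarts: int = 10
    stratify: bool = True
    hidden: int = 12
    weight_decay: float = 1e-4
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must lie in (0, 1)")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val fraction must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class MLPModel:
    """Trained network: weights, biases, and the stored feature scaling."""

    w1: np.ndarray  # (hidden, 8)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (6, hidden)
    b2: np.ndarray  # (6,)
    feature_min: np.ndarray
    feature_max: np.ndarray
    classes: tuple[HoneyType, ...] = CLASSES

    @property
    def n_parameters(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def to_json(self, path: str | Path) -> None:
        doc = {
            "architecture": [N_IN, self.w1.shape[0], N_OUT],
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "features": list(FEATURES),
            "classes": [c.value for c in self.classes],
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            w1=np.array(doc["w1"]),
            b1=np.array(doc["b1"]),
            w2=np.array(doc["w2"]),
            b2=np.array(doc["b2"]),
            feature_min=np.array(doc["feature_min"]),
            feature_max=np.array(doc["feature_max"]),
            classes=tuple(HoneyType(c) for c in doc["classes"]),
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix (true x predicted, class order = CLASSES) and rates."""

    confusion: np.ndarray
    per_class_rate: dict[str, float]  # percent; NaN for absent classes
    accuracy: float  # percent

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class_rate": self.per_class_rate,
            "accuracy": self.accuracy,
        }


def _raw_features(table: SampleTable) -> np.ndarray:
    return np.array([[getattr(s, f) for f in FEATURES] for s in table], dtype=float)


def normalize_features(
    table: SampleTable,
    feature_min: np.ndarray | None = None,
    feature_max: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min-max scale the eight inputs to [0, 1].

    Returns (X, min, max).  When min/max are given (inference on a stored
    model) they are applied as-is, with out-of-range values clipped to
    [0, 1].  A constant feature maps to 0.
    """
    if len(table) == 0:
        raise ValueError("cannot normalize an empty table")
    raw = _raw_features(table)
    if feature_min is None:
        feature_min = raw.min(axis=0)
    if feature_max is None:
        feature_max = raw.max(axis=0)
    span = feature_max - feature_min
    x = np.zeros_like(raw)
    nz = span > 0
    x[:, nz] = (raw[:, nz] - feature_min[nz]) / span[nz]
    return np.clip(x, 0.0, 1.0), np.asarray(feature_min), np.asarray(feature_max)


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _unpack(theta: np.ndarray, hidden: int) -> tuple[np.ndarray, ...]:
    i = 0
    w1 = theta[i : i + hidden * N_IN].reshape(hidden, N_IN)
    i += hidden * N_IN
    b1 = theta[i : i + hidden]
    i += hidden
    w2 = theta[i : i + N_OUT * hidden].reshape(N_OUT, hidden)
    i += N_OUT * hidden
    b2 = theta[i : i + N_OUT]
    return w1, b1, w2, b2


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def forward_probabilities(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Class probabilities for one scaled feature vector or a batch.

    h = logistic(W1 x + b1), p = softmax(W2 h + b2); rows sum to 1.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    h = _logistic(x @ model.w1.T + model.b1)
    p = _softmax(h @ model.w2.T + model.b2)
    return p[0] if single else p


def _forward_batch(theta: np.ndarray, x: np.ndarray, hidden: int):
    w1, b1, w2, b2 = _unpack(theta, hidden)
    h = _logistic(x @ w1.T + b1)
    p = _softmax(h @ w2.T + b2)
    return h, p, (w1, b1, w2, b2)


def loss_and_grad(
    theta: np.ndarray, x: np.ndarray, y_onehot: np.ndarray, hidden: int
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its analytic gradient.

    Backpropagation through softmax+cross-entropy (delta2 = p - y) and the
    logistic hidden layer (delta1 = (delta2 W2) h (1-h)).
    """
    n = x.shape[0]
    h, p, (w1, b1, w2, b2) = _forward_batch(theta, x, hidden)
    eps = 1e-12
    loss = -float(np.sum(y_onehot * np.log(p + eps))) / n
    d2 = (p - y_onehot) / n  # (n, 6)
    gw2 = d2.T @ h
    gb2 = d2.sum(axis=0)
    d1 = (d2 @ w2) * h * (1.0 - h)  # (n, hidden)
    gw1 = d1.T @ x
    gb1 = d1.sum(axis=0)
    return loss, _pack(gw1, gb1, gw2, gb2)


def penalized_loss_and_grad(
    theta: np.ndarray,
    x: np.ndarray,
    y_onehot: np.ndarray,
    hidden: int,
    weight_decay: float,
) -> tuple[float, np.ndarray]:
    """Cross-entropy plus an L2 ridge on the weight matrices (biases free)."""
    loss, g = loss_and_grad(theta, x, y_onehot, hidden)
    if weight_decay > 0:
        w1, b1, w2, b2 = _unpack(theta, hidden)
        loss += weight_decay * 0.5 * (float(np.sum(w1**2)) + float(np.sum(w2**2)))
        g = g.copy()
        g[: hidden * N_IN] += weight_decay * w1.ravel()
        off = hidden * N_IN + hidden
        g[off : off + N_OUT * hidden] += weight_decay * w2.ravel()
    return loss, g


def _labels(table: SampleTable) -> np.ndarray:
    index = {c: i for i, c in enumerate(CLASSES)}
    return np.array([index[s.effective_type] for s in table], dtype=int)


def stratified_split(
    labels: np.ndarray, train_fraction: float, seed: int, stratify: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/test index split.

    Stratified mode splits each class separately (rounding keeps at least
    one training record per class); plain mode permutes the whole index.
    """
    rng = np.random.default_rng(seed)
    n = labels.size
    if not stratify:
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx.size)
        n_train = max(1, int(round(train_fraction * idx.size)))
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _init_theta(rng: np.random.Generator, hidden: int, scale: float) -> np.ndarray:
    w1 = rng.uniform(-scale, scale, (hidden, N_IN)) / np.sqrt(N_IN)
    b1 = rng.uniform(-scale, scale, hidden) / np.sqrt(N_IN)
    w2 = rng.uniform(-scale, scale, (N_OUT, hidden)) / np.sqrt(hidden)
    b2 = rng.uniform(-scale, scale, N_OUT) / np.sqrt(hidden)
    return _pack(w1, b1, w2, b2)


def _evaluate_arrays(p: np.ndarray, y: np.ndarray) -> EvaluationReport:
    pred = p.argmax(axis=1)
    k = N_OUT
    conf = np.zeros((k, k), dtype=int)
    for t, q in zip(y, pred):
        conf[t, q] += 1
    rates = {}
    for i, c in enumerate(CLASSES):
        row = conf[i].sum()
        rates[c.value] = float(100.0 * conf[i, i] / row) if row else float("nan")
    acc = float(100.0 * np.trace(conf) / max(1, conf.sum()))
    return EvaluationReport(confusion=conf, per_class_rate=rates, accuracy=acc)


def train_classifier(
    table: SampleTable, config: TrainingConfig | None = None
) -> tuple[MLPModel, dict[str, EvaluationReport]]:
    """Train the 8-12-6 network on a (reclassified) table.

    Min-max scaling is fitted on the training split and stored with the
    model.  Each restart runs BFGS (Wolfe line search, so accepted steps
    never increase the penalized loss) from a fresh random initialization;
    with a validation carve-out the best-validation iterate of the best-
    validation restart wins (early stopping), otherwise the lowest final
    training loss.  Returns the model and evaluation reports for the train
    and test subsets.
    """
    config = config or TrainingConfig()
    labels = _labels(table)
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("training needs at least two classes present")
    train_idx, test_idx = stratified_split(
        labels, config.train_fraction, config.split_seed, config.stratify
    )
    if np.unique(labels[train_idx]).size < present.size:
        raise ValueError("a class is absent from the training split; use stratify=True")
    raw = _raw_features(table)
    fmin = raw[train_idx].min(axis=0)
    fmax = raw[train_idx].max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    x_all = np.clip((raw - fmin) / span, 0.0, 1.0)
    x_all[:, fmax <= fmin] = 0.0
    y_onehot = np.eye(N_OUT)[labels]

    if config.val_fraction > 0:
        a, b = stratified_split(
            labels[train_idx], 1.0 - config.val_fraction, config.split_seed + 1, config.stratify
        )
        fit_idx, val_idx = train_idx[a], train_idx[b]
    else:
        fit_idx, val_idx = train_idx, None
    x_fit, y_fit = x_all[fit_idx], y_onehot[fit_idx]

    def _criterion(theta: np.ndarray) -> float:
        if val_idx is None:
            return penalized_loss_and_grad(
                theta, x_fit, y_fit, config.hidden, config.weight_decay
            )[0]
        return loss_and_grad(theta, x_all[val_idx], y_onehot[val_idx], config.hidden)[0]

    rng = np.random.default_rng(config.init_seed)
    best: tuple[float, np.ndarray] | None = None
    for _ in range(config.restarts):
        theta0 = _init_theta(rng, config.hidden, config.init_scale)
        trace = [theta0.copy()]
        res = minimize(
            penalized_loss_and_grad,
            theta0,
            args=(x_fit, y_fit, config.hidden, config.weight_decay),
            method="BFGS",
            jac=True,
            callback=(lambda tk: trace.append(tk.copy())) if val_idx is not None else None,
            options={"maxiter": config.max_iter, "gtol": config.gtol},
        )
        if val_idx is None:
            candidate = (float(res.fun), res.x.copy())
        else:
            # early stopping: keep the iterate with the lowest validation loss
            scores = [_criterion(tk) for tk in trace]
            k = int(np.argmin(scores))
            candidate = (float(scores[k]), trace[k])
        if best is None or candidate[0] < best[0]:
            best = candidate
    assert best is not None
    w1, b1, w2, b2 = _unpack(best[1], config.hidden)
    model = MLPModel(w1=w1, b1=b1, w2=w2, b2=b2, feature_min=fmin, feature_max=fmax)

    reports = {}
    for name, idx in (("train", train_idx), ("test", test_idx)):
        p = forward_probabilities(model, x_all[idx])
        reports[name] = _evaluate_arrays(np.atleast_2d(p), labels[idx])
    return model, reports


def evaluate_classifier(model: MLPModel, table: SampleTable) -> EvaluationReport:
    """Confusion matrix and per-class recognition rates on a labelled table."""
    if len(table) == 0:
        raise ValueError("cannot evaluate on an empty table")
    x, _, _ = normalize_features(table, model.feature_min, model.feature_max)
    p = np.atleast_2d(forward_probabilities(model, x))
    return _evaluate_arrays(p, _labels(table))
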