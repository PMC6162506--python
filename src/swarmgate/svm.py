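"""Soft-margin dual SVM: SMO solver, one-vs-one multiclass, evaluation.

The binary classifier solves the dual problem

    max  sum(alpha) - 1/2 sum_ij alpha_i alpha_j y_i y_j k(x_i, x_j)
    s.t. 0 <= alpha_i <= c,   sum_i alpha_i y_i = 0

with a second-order working-set method (two dual variables per step,
closed-form update; the first index is the maximal KKT violator, the
second maximizes the objective decrease).  Multiclass problems train one
binary model per class pair; prediction is by majority vote with ties
broken toward the lowest class index.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
from numba import njit

from .errors import SchemaError
from .events import EventTable, ScalingParams
from .kernels import KernelSpec, gram

__all__ = [
    "SvmModel",
    "BinaryClassifier",
    "EvaluationReport",
    "train_binary",
    "train_multiclass",
    "predict",
    "decision_values",
    "evaluate",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

# alpha > SV_RTOL * c counts as a support vector
SV_RTOL = 1e-8
KKT_TOL = 1e-3


@dataclass
class BinaryClassifier:
    """One trained class pair: support vectors, dual weights alpha_i*y_i, bias."""

    classes: tuple[int, int]  # (lower, higher); +1 internal label = lower class
    support_vectors: np.ndarray
    dual_weights: np.ndarray  # alpha_i * y_i, nonzero
    bias: float
    dual_objective: float
    n_iterations: int

    def decision(self, X: np.ndarray, spec: KernelSpec) -> np.ndarray:
        K = gram(spec, X, self.support_vectors)
        return K @ self.dual_weights + self.bias


@dataclass
class SvmModel:
    """One-vs-one multiclass soft-margin SVM."""

    kernel: KernelSpec
    c: float
    n_classes: int
    channel_names: list[str]
    classifiers: list[BinaryClassifier] = field(default_factory=list)
    scaling: Optional[ScalingParams] = None
    label_names: Optional[list[str]] = None

    @property
    def class_pairs(self) -> list[tuple[int, int]]:
        return [clf.classes for clf in self.classifiers]

    @property
    def n_support_vectors(self) -> int:
        """Distinct support vectors across all pairwise models."""
        if not self.classifiers:
            return 0
        all_sv = np.vstack([clf.support_vectors for clf in self.classifiers])
        return np.unique(all_sv, axis=0).shape[0]


@dataclass
class EvaluationReport:
    """Held-out correctness, confusion matrix and model size."""

    correctness: float  # percentage, 100 * n_correct / n_total
    n_correct: int
    n_total: int
    n_support_vectors: int
    confusion: np.ndarray  # K x K, rows = true class
    elapsed_seconds: float = 0.0


@njit(cache=True)
def _smo_core(K, y, c, tol, max_iter):  # pragma: no cover - exercised via _smo
    n = K.shape[0]
    alpha = np.zeros(n)
    yf = y.copy()  # yf[k] = y_k - f(x_k), f = decision without bias
    objective = 0.0
    window_gain = 1e300
    it = 0
    while it < max_iter:
        if it % 1000 == 0:
            # stagnation at machine precision: optimal to attainable accuracy
            if window_gain <= 1e-12 * max(1.0, abs(objective)):
                return alpha, it, False
            window_gain = 0.0
        # pass 1: maximal violator i over the "up" set, minimum M over "low"
        i = -1
        m = -1e300
        M = 1e300
        for k in range(n):
            if (y[k] > 0.0 and alpha[k] < c) or (y[k] < 0.0 and alpha[k] > 0.0):
                if yf[k] > m:
                    m = yf[k]
                    i = k
            if (y[k] < 0.0 and alpha[k] < c) or (y[k] > 0.0 and alpha[k] > 0.0):
                if yf[k] < M:
                    M = yf[k]
        if i < 0 or M == 1e300:
            return alpha, it, False
        # scale-aware KKT gap: relative to the multiplier magnitude, so
        # badly scaled kernels (large c*K) terminate at the same relative
        # precision as normalized ones
        scale = max(1.0, max(abs(m), abs(M)))
        if m - M <= tol * scale:
            return alpha, it, False
        # pass 2: second-order choice of j (maximal objective decrease)
        Kii = K[i, i]
        j = -1
        best = 1e300
        for k in range(n):
            if (y[k] < 0.0 and alpha[k] < c) or (y[k] > 0.0 and alpha[k] > 0.0):
                if yf[k] < m:
                    b = m - yf[k]
                    a = Kii + K[k, k] - 2.0 * K[i, k]
                    if a < 1e-12:
                        a = 1e-12
                    score = -(b * b) / a
                    if score < best:
                        best = score
                        j = k
        if j < 0:
            return alpha, it, False
        quad = Kii + K[j, j] - 2.0 * K[i, j]
        if quad < 1e-12:
            quad = 1e-12
        t = (m - yf[j]) / quad
        # box limits along the feasible direction alpha += t*(y_i e_i - y_j e_j)
        t_max_i = (c - alpha[i]) if y[i] > 0.0 else alpha[i]
        t_max_j = alpha[j] if y[j] > 0.0 else (c - alpha[j])
        if t > t_max_i:
            t = t_max_i
        if t > t_max_j:
            t = t_max_j
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        gain = t * (m - yf[j]) - 0.5 * t * t * quad
        objective += gain
        window_gain += gain
        for k in range(n):
            yf[k] -= t * (K[k, i] - K[k, j])
        it += 1
    return alpha, it, True


def _smo(
    K: np.ndarray, y: np.ndarray, c: float, tol: float = KKT_TOL, max_iter: int | None = None
) -> tuple[np.ndarray, float, float, int]:
    """Working-set SMO on a precomputed kernel matrix.

    The first index is the maximal KKT violator; the second is chosen by
    maximal second-order objective decrease.  Terminates when the KKT
    gap falls below ``tol`` (measured relative to the multiplier
    magnitude), when the dual objective stagnates at machine precision,
    or when the iteration budget runs out — in the last case the current
    feasible iterate is returned with a warning, so a single badly
    scaled (c, g) candidate cannot stall an entire tuning run.

    Returns ``(alpha, bias, dual_objective, n_iterations)``.
    """
    n = len(y)
    if max_iter is None:
        # well-posed problems need a small multiple of n steps; the cap
        # only ever binds on extreme kernel scales
        max_iter = min(max(10 * n * n, 5000), 300 * n + 30_000)
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    alpha, it, hit_budget = _smo_core(K, y, float(c), float(tol), int(max_iter))
    if hit_budget:
        logger.warning(
            "SMO stopped at its %d-iteration budget before meeting KKT "
            "tolerance %g (extreme kernel scale); returning the current "
            "feasible solution", max_iter, tol,
        )
    yf = y - K @ (alpha * y)
    pos = y > 0
    free = (alpha > SV_RTOL * c) & (alpha < c * (1 - SV_RTOL))
    if free.any():
        bias = float(yf[free].mean())
    else:
        up = (pos & (alpha < c)) | (~pos & (alpha > 0))
        lo = (~pos & (alpha < c)) | (pos & (alpha > 0))
        hi = yf[up].max() if up.any() else 0.0
        lw = yf[lo].min() if lo.any() else 0.0
        bias = float((hi + lw) / 2.0)
    objective = float(alpha.sum() - 0.5 * alpha @ ((y * alpha) @ K * y))
    return alpha, bias, objective, it


def train_binary(train: EventTable, c: float, spec: KernelSpec) -> SvmModel:
    """Train a single-pair soft-margin SVM on a two-class table."""
    labels = train.require_labels()
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"train_binary needs exactly 2 classes, got {len(classes)}")
    if not c > 0:
        raise ValueError("penalty factor c must be positive")
    clf = _fit_pair(train.values, labels, int(classes[0]), int(classes[1]), c, spec)
    return SvmModel(
        kernel=spec,
        c=c,
        n_classes=int(classes[1]) + 1,
        channel_names=list(train.channel_names),
        classifiers=[clf],
        label_names=train.label_names,
    )


def _fit_pair(
    X: np.ndarray, labels: np.ndarray, lo: int, hi: int, c: float, spec: KernelSpec
) -> BinaryClassifier:
    mask = (labels == lo) | (labels == hi)
    Xp = X[mask]
    y = np.where(labels[mask] == lo, 1.0, -1.0)
    K = gram(spec, Xp)
    alpha, bias, obj, it = _smo(K, y, c)
    sv = alpha > SV_RTOL * c
    return BinaryClassifier(
        classes=(lo, hi),
        support_vectors=Xp[sv],
        dual_weights=alpha[sv] * y[sv],
        bias=bias,
        dual_objective=obj,
        n_iterations=it,
    )


def train_multiclass(train: EventTable, c: float, spec: KernelSpec) -> SvmModel:
    """Train K(K-1)/2 one-vs-one binary models."""
    labels = train.require_labels()
    classes = [int(k) for k in np.unique(labels)]
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if not c > 0:
        raise ValueError("penalty factor c must be positive")
    classifiers = [
        _fit_pair(train.values, labels, lo, hi, c, spec)
        for lo, hi in combinations(classes, 2)
    ]
    return SvmModel(
        kernel=spec,
        c=c,
        n_classes=max(classes) + 1,
        channel_names=list(train.channel_names),
        classifiers=classifiers,
        label_names=train.label_names,
    )


def decision_values(model: SvmModel, events: EventTable) -> np.ndarray:
    """Per-pair decision values, shape ``(n_events, n_pairs)``."""
    if list(events.channel_names) != list(model.channel_names):
        raise SchemaError(
            f"channel mismatch: model {model.channel_names} vs "
            f"events {events.channel_names}"
        )
    return np.column_stack(
        [clf.decision(events.values, model.kernel) for clf in model.classifiers]
    )


def predict(model: SvmModel, events: EventTable) -> np.ndarray:
    """Majority-vote class labels; ties broken toward the lowest class index."""
    dec = decision_values(model, events)
    votes = np.zeros((events.n_events, model.n_classes), dtype=int)
    for k, clf in enumerate(model.classifiers):
        lo, hi = clf.classes
        win_lo = dec[:, k] >= 0  # boundary ties favour the lower class index
        votes[win_lo, lo] += 1
        votes[~win_lo, hi] += 1
    return votes.argmax(axis=1)  # argmax returns the lowest index on ties


def evaluate(model: SvmModel, test: EventTable) -> EvaluationReport:
    """Correctness percentage, confusion matrix and support-vector count."""
    truth = test.require_labels()
    t0 = time.perf_counter()
    pred = predict(model, test)
    elapsed = time.perf_counter() - t0
    k = max(model.n_classes, int(truth.max()) + 1)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (truth, pred), 1)
    n_correct = int(np.trace(confusion))
    n_total = test.n_events
    return EvaluationReport(
        correctness=100.0 * n_correct / n_total,
        n_correct=n_correct,
        n_total=n_total,
        n_support_vectors=model.n_support_vectors,
        confusion=confusion,
        elapsed_seconds=elapsed,
    )


_FORMAT_VERSION = 1


def save_model(model: SvmModel, path: str | Path) -> None:
    """Serialize a model to versioned JSON."""
    doc = {
        "format_version": _FORMAT_VERSION,
        "kernel": model.kernel.to_dict(),
        "c": model.c,
        "n_classes": model.n_classes,
        "channel_names": model.channel_names,
        "label_names": model.label_names,
        "scaling": None
        if model.scaling is None
        else {
            "channel_names": model.scaling.channel_names,
            "mins": model.scaling.mins.tolist(),
            "maxs": model.scaling.maxs.tolist(),
        },
        "classifiers": [
            {
                "classes": list(clf.classes),
                "support_vectors": clf.support_vectors.tolist(),
                "dual_weights": clf.dual_weights.tolist(),
                "bias": clf.bias,
                "dual_objective": clf.dual_objective,
                "n_iterations": clf.n_iterations,
            }
            for clf in model.classifiers
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> SvmModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    scaling = None
    if doc["scaling"] is not None:
        scaling = ScalingParams(
            doc["scaling"]["channel_names"],
            np.asarray(doc["scaling"]["mins"]),
            np.asarray(doc["scaling"]["maxs"]),
        )
    return SvmModel(
        kernel=KernelSpec(**doc["kernel"]),
        c=doc["c"],
        n_classes=doc["n_classes"],
        channel_names=doc["channel_names"],
        label_names=doc["label_names"],
        scaling=scaling,
        classifiers=[
            BinaryClassifier(
                classes=tuple(d["classes"]),
                support_vectors=np.asarray(d["support_vectors"], dtype=float),
                dual_weights=np.asarray(d["dual_weights"], dtype=float),
                bias=d["bias"],
                dual_objective=d["dual_objective"],
                n_iterations=d["n_iterations"],
            )
            for d in doc["classifiers"]
        ],
    )
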