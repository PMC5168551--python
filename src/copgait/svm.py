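"""Kernel SVM trained through its Lagrangian dual.

The binary machine solves

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j k(x_i, x_j)
    s.t.   0 <= a_i <= C,  sum_i a_i y_i = 0

with sequential minimal optimization (pairwise coordinate ascent on a
maximal-violating pair, second-order pair selection), giving the decision
function f(x) = sum_i a_i y_i k(x_i, x) + b.  C is the soft-margin box bound;
``C=inf`` requests the hard-margin formulation and is rendered numerically as
a large finite box (1e6).  The bias b is read off the KKT conditions at the
optimum (mean over free support vectors).

Three kernels: linear <x1,x2>; polynomial (<x1,x2> + R)^d; Gaussian
exp(-||x1-x2||^2 / (2 sigma^2)).  Multiclass problems use one-vs-one voting.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, UsageError

logger = logging.getLogger(__name__)

HARD_MARGIN_BOX = 1e6  # numerical rendering of C = inf
SV_THRESHOLD = 1e-8
_TAU = 1e-12


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its parameters (R, d polynomial; sigma Gaussian)."""

    kind: str = "linear"
    R: float = 1.0
    d: int = 2
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "gaussian"):
            raise UsageError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and (self.d < 1 or self.d != int(self.d)):
            raise UsageError("polynomial degree d must be an integer >= 1")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise UsageError("gaussian sigma must be > 0")

    def __str__(self) -> str:
        if self.kind == "linear":
            return "linear"
        if self.kind == "polynomial":
            return f"polynomial(R={self.R:g}, d={self.d})"
        return f"gaussian(sigma={self.sigma:g})"


def kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix k(a_i, b_j) for rows of A against rows of B."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise UsageError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if spec.kind == "linear":
        return A @ B.T
    if spec.kind == "polynomial":
        return (A @ B.T + spec.R) ** spec.d
    d2 = (
        (A**2).sum(axis=1)[:, None] - 2 * A @ B.T + (B**2).sum(axis=1)[None, :]
    )
    return np.exp(-np.maximum(d2, 0.0) / (2 * spec.sigma**2))


def kernel_eval(spec: KernelSpec, x1: np.ndarray, x2: np.ndarray) -> float:
    """Single kernel evaluation k(x1, x2)."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    return float(kernel_matrix(spec, x1[None, :], x2[None, :])[0, 0])


@dataclass
class SVMBinaryModel:
    sv_inputs: np.ndarray  # (n_sv, dim) support-vector samples
    sv_labels: np.ndarray  # (n_sv,) labels in {-1, +1}
    alpha: np.ndarray  # (n_sv,) dual coefficients at the support vectors
    b: float
    kernel: KernelSpec
    C: float
    omega: np.ndarray | None = None  # explicit weights, linear kernel only
    n_iter: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "sv_inputs": self.sv_inputs.tolist(),
                "sv_labels": self.sv_labels.tolist(),
                "alpha": self.alpha.tolist(),
                "b": self.b,
                "kernel": {"kind": self.kernel.kind, "R": self.kernel.R,
                           "d": self.kernel.d, "sigma": self.kernel.sigma},
                "C": None if np.isinf(self.C) else self.C,
                "omega": None if self.omega is None else self.omega.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SVMBinaryModel":
        obj = json.loads(text)
        return cls(
            sv_inputs=np.asarray(obj["sv_inputs"], dtype=float),
            sv_labels=np.asarray(obj["sv_labels"], dtype=float),
            alpha=np.asarray(obj["alpha"], dtype=float),
            b=float(obj["b"]),
            kernel=KernelSpec(**obj["kernel"]),
            C=np.inf if obj["C"] is None else float(obj["C"]),
            omega=None if obj["omega"] is None else np.asarray(obj["omega"], dtype=float),
        )


def _smo_core(Q, y, box, tol, max_iter):
    """Minimize 1/2 a'Qa - e'a s.t. y'a = 0, 0 <= a <= box.

    Q is the label-signed Gram matrix (y_i y_j k_ij).  Returns (alpha,
    gradient, iterations, converged).  Pair selection: the first index is the
    maximal KKT violator among the 'up' set, the second minimizes the
    second-order objective decrease among 'down'-set violators.  ``tol``
    bounds the KKT violation relative to the gradient scale: near-hard-margin
    fits on inseparable data drive the dual coefficients (and gradients) to
    the box bound, where an absolute threshold would sit below float64
    resolution.  Written with explicit loops so numba can compile it.
    """
    n = len(y)
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of the dual objective at alpha = 0
    QD = np.empty(n)
    for t in range(n):
        QD[t] = Q[t, t]
    tau = 1e-12
    it = 0
    for it in range(1, max_iter + 1):
        # select i: maximal -y G over the 'up' set; track bounds for the stop rule
        i = -1
        Gmax = -np.inf
        Gmin = np.inf
        gscale = 1.0
        for t in range(n):
            g = -y[t] * G[t]
            a = abs(G[t])
            if a > gscale:
                gscale = a
            if ((y[t] > 0 and alpha[t] < box) or (y[t] < 0 and alpha[t] > 0)) and g > Gmax:
                Gmax = g
                i = t
            if ((y[t] < 0 and alpha[t] < box) or (y[t] > 0 and alpha[t] > 0)) and g < Gmin:
                Gmin = g
        if i < 0 or Gmax - Gmin < tol * gscale:
            return alpha, G, it, True
        # select j: best second-order decrease among violating 'low' indices
        j = -1
        best = 0.0
        for t in range(n):
            if not ((y[t] < 0 and alpha[t] < box) or (y[t] > 0 and alpha[t] > 0)):
                continue
            g = -y[t] * G[t]
            if g >= Gmax:
                continue
            grad_diff = Gmax - g
            # curvature along the feasible pair direction is K_ii + K_tt - 2 K_it
            quad = QD[i] + QD[t] - 2.0 * Q[i, t] * (y[i] * y[t])
            if quad <= 0:
                quad = tau
            obj = -(grad_diff * grad_diff) / quad
            if obj < best:
                best = obj
                j = t
        if j < 0:
            return alpha, G, it, True

        old_i, old_j = alpha[i], alpha[j]
        if y[i] != y[j]:
            qc = QD[i] + QD[j] + 2.0 * Q[i, j]
            if qc <= 0:
                qc = tau
            delta = (-G[i] - G[j]) / qc
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > 0:
                if alpha[i] > box:
                    alpha[i] = box
                    alpha[j] = box - diff
            else:
                if alpha[j] > box:
                    alpha[j] = box
                    alpha[i] = box + diff
        else:
            qc = QD[i] + QD[j] - 2.0 * Q[i, j]
            if qc <= 0:
                qc = tau
            delta = (G[i] - G[j]) / qc
            s = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if s > box:
                if alpha[i] > box:
                    alpha[i] = box
                    alpha[j] = s - box
            else:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = s
            if s > box:
                if alpha[j] > box:
                    alpha[j] = box
                    alpha[i] = s - box
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = s
        di = alpha[i] - old_i
        dj = alpha[j] - old_j
        for t in range(n):
            G[t] += Q[t, i] * di + Q[t, j] * dj
    return alpha, G, it, False


try:  # compiled inner loop when numba is available; pure python otherwise
    from numba import njit

    _smo_compiled = njit(cache=True, fastmath=False)(_smo_core)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _smo_compiled = _smo_core


def _smo(Q: np.ndarray, y: np.ndarray, box: float, tol: float, max_iter: int):
    alpha, G, n_iter, converged = _smo_compiled(
        np.ascontiguousarray(Q), np.ascontiguousarray(y), float(box), float(tol), int(max_iter)
    )
    if not converged:
        minus_yG = -y * G
        raise ConvergenceError(
            f"SMO did not reach tolerance {tol} in {max_iter} iterations "
            f"(n={len(y)}, box={box}, violation {minus_yG.max() - minus_yG.min():.3e})"
        )
    return alpha, G, n_iter


def svm_train(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    C: float = 1.0,
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> SVMBinaryModel:
    """Train a binary SVM on labels in {-1, +1}."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y) or len(y) < 2:
        raise UsageError("need n >= 2 samples with matching labels")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise UsageError("binary labels must be -1/+1")
    if len(np.unique(y)) < 2:
        raise UsageError("both classes must be present")
    box = HARD_MARGIN_BOX if np.isinf(C) else float(C)
    if box <= 0:
        raise UsageError("C must be positive")
    K = kernel_matrix(kernel, X, X)
    Q = (y[:, None] * y[None, :]) * K
    if max_iter is None:
        # near-hard-margin fits on inseparable data climb the dual coefficients
        # to the box bound in O(box) small steps; the compiled loop runs a few
        # million iterations per second, so a generous cap is cheap
        max_iter = 100_000_000
    alpha, G, n_iter = _smo(Q, y, box, tol, max_iter)

    # bias from KKT: -y_i G_i equals b at every free support vector
    minus_yG = -y * G
    free = (alpha > SV_THRESHOLD) & (alpha < box - SV_THRESHOLD)
    if free.any():
        b = float(minus_yG[free].mean())
    else:
        up = ((y > 0) & (alpha < box)) | ((y < 0) & (alpha > 0))
        low = ((y < 0) & (alpha < box)) | ((y > 0) & (alpha > 0))
        hi = minus_yG[up].max() if up.any() else minus_yG.max()
        lo = minus_yG[low].min() if low.any() else minus_yG.min()
        b = float((hi + lo) / 2)

    sv = alpha > SV_THRESHOLD
    omega = (alpha[sv] * y[sv]) @ X[sv] if kernel.kind == "linear" else None
    return SVMBinaryModel(
        sv_inputs=X[sv],
        sv_labels=y[sv],
        alpha=alpha[sv],
        b=b,
        kernel=kernel,
        C=C,
        omega=omega,
        n_iter=n_iter,
    )


def svm_decision(model: SVMBinaryModel, x: np.ndarray) -> float:
    """f(x) = sum_i a_i y_i k(x_i, x) + b."""
    x = np.asarray(x, dtype=float).ravel()
    k = kernel_matrix(model.kernel, model.sv_inputs, x[None, :])[:, 0]
    return float((model.alpha * model.sv_labels) @ k + model.b)


def svm_decision_batch(model: SVMBinaryModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = kernel_matrix(model.kernel, model.sv_inputs, X)
    return (model.alpha * model.sv_labels) @ K + model.b


def svm_predict(model: SVMBinaryModel, x: np.ndarray) -> int:
    """Sign of the decision value; an exact 0 maps to +1."""
    return 1 if svm_decision(model, x) >= 0 else -1


@dataclass
class MultiClassModel:
    """One-vs-one ensemble: one binary model (or constant fallback) per pair."""

    class_labels: np.ndarray
    pair_models: dict  # (label_a, label_b) a < b -> SVMBinaryModel | ("const", label)
    kernel: KernelSpec
    C: float

    def to_json(self) -> str:
        pairs = {}
        for (a, b), m in self.pair_models.items():
            key = f"{a},{b}"
            if isinstance(m, tuple):
                pairs[key] = {"const": int(m[1])}
            else:
                pairs[key] = json.loads(m.to_json())
        return json.dumps(
            {
                "class_labels": self.class_labels.tolist(),
                "pairs": pairs,
                "kernel": {"kind": self.kernel.kind, "R": self.kernel.R,
                           "d": self.kernel.d, "sigma": self.kernel.sigma},
                "C": None if np.isinf(self.C) else self.C,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MultiClassModel":
        obj = json.loads(text)
        pair_models: dict = {}
        for key, val in obj["pairs"].items():
            a_s, b_s = key.split(",")
            pair = tuple(type(obj["class_labels"][0])(v) for v in (a_s, b_s))
            if "const" in val:
                pair_models[pair] = ("const", val["const"])
            else:
                pair_models[pair] = SVMBinaryModel.from_json(json.dumps(val))
        return cls(
            class_labels=np.asarray(obj["class_labels"]),
            pair_models=pair_models,
            kernel=KernelSpec(**obj["kernel"]),
            C=np.inf if obj["C"] is None else float(obj["C"]),
        )


def multiclass_train(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    C: float = 1.0,
) -> MultiClassModel:
    """Train one binary machine per unordered class pair (+1 = smaller label)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).ravel()
    labels = np.unique(y)
    if len(labels) < 2:
        raise UsageError("need at least 2 classes")
    pair_models = {}
    for a, b in itertools.combinations(labels.tolist(), 2):
        mask = (y == a) | (y == b)
        yy = np.where(y[mask] == a, 1.0, -1.0)
        try:
            pair_models[(a, b)] = svm_train(X[mask], yy, kernel, C)
        except (ConvergenceError, UsageError) as exc:
            maj = a if (y[mask] == a).sum() >= (y[mask] == b).sum() else b
            logger.warning("pair (%s, %s) fell back to majority label %s: %s", a, b, maj, exc)
            pair_models[(a, b)] = ("const", maj)
    return MultiClassModel(class_labels=labels, pair_models=pair_models, kernel=kernel, C=C)


def multiclass_predict(model: MultiClassModel, x: np.ndarray):
    """Majority vote over pairs; ties by summed |decision| in the class's favor,
    then by lowest class label."""
    votes: dict = {c: 0 for c in model.class_labels.tolist()}
    strength: dict = {c: 0.0 for c in model.class_labels.tolist()}
    for (a, b), m in model.pair_models.items():
        if isinstance(m, tuple):
            winner, mag = m[1], 0.0
        else:
            f = svm_decision(m, x)
            winner, mag = (a, abs(f)) if f >= 0 else (b, abs(f))
        votes[winner] += 1
        strength[winner] += mag
    best = max(votes.values())
    tied = [c for c, v in votes.items() if v == best]
    if len(tied) > 1:
        top = max(strength[c] for c in tied)
        tied = [c for c in tied if strength[c] == top]
    return min(tied)


def multiclass_predict_batch(model: MultiClassModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.asarray([multiclass_predict(model, x) for x in X])
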