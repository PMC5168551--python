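"""Fuzzy C-means clustering.

Minimizes J = sum_i sum_j u_ij^m ||x_j - v_i||^2 subject to each sample's
memberships summing to 1, by alternating the center update

    v_i = sum_j u_ij^m x_j / sum_j u_ij^m

with the membership update

    u_ij = [ sum_r (||x_j - v_i|| / ||x_j - v_r||)^(2/(m-1)) ]^(-1),

stopping when the membership matrix changes by less than epsilon (max-abs
entry) or the iteration cap is hit.  The alternation never increases J, but
the fixed point reached depends on the random initial memberships, so the
driver restarts from several seeds and keeps the lowest-objective run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateClusterError, UsageError
from .pressure_io import FeatureTable

logger = logging.getLogger(__name__)

_ZERO = 1e-12


@dataclass
class FCMConfig:
    """Clustering hyperparameters.

    c: number of clusters; m: fuzziness exponent (> 1; crisper as m -> 1);
    epsilon: stop when max |U_new - U| < epsilon; max_iter: per-restart cap;
    seed: RNG seed; n_restarts: random restarts, lowest objective kept.
    """

    c: int
    m: float = 2.0
    epsilon: float = 1e-5
    max_iter: int = 100
    seed: int | None = None
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if self.c < 2:
            raise UsageError("c must be >= 2")
        if self.m <= 1:
            raise UsageError("m must be > 1")
        if self.epsilon <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise UsageError("epsilon > 0, max_iter >= 1, n_restarts >= 1 required")


@dataclass
class FCMResult:
    U: np.ndarray  # (c, n) memberships, columns sum to 1
    V: np.ndarray  # (c, s) cluster centers
    objective_trace: list[float]
    iterations: int
    converged: bool
    labels: np.ndarray  # (n,) 1-based hard assignments
    config: FCMConfig | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "U": self.U.tolist(),
                "V": self.V.tolist(),
                "objective_trace": self.objective_trace,
                "iterations": self.iterations,
                "converged": self.converged,
                "labels": self.labels.tolist(),
                "config": None
                if self.config is None
                else {
                    "c": self.config.c,
                    "m": self.config.m,
                    "epsilon": self.config.epsilon,
                    "max_iter": self.config.max_iter,
                    "seed": self.config.seed,
                    "n_restarts": self.config.n_restarts,
                },
            },
            indent=2,
        )


def _sqdist(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """(c, n) squared Euclidean distances between centers and samples."""
    diff = V[:, None, :] - X[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def update_memberships(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    """Membership update; samples coinciding with centers get full membership
    split equally among the coinciding centers."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    d2 = _sqdist(X, V)  # (c, n)
    U = np.zeros_like(d2)
    zero_cols = (d2 <= _ZERO).any(axis=0)
    if zero_cols.any():
        hits = d2[:, zero_cols] <= _ZERO
        U[:, zero_cols] = hits / hits.sum(axis=0)
    reg = ~zero_cols
    if reg.any():
        # u_ij = 1 / sum_r (d_ij / d_rj)^(1/(m-1)) on squared distances
        p = 1.0 / (m - 1.0)
        dpow = d2[:, reg] ** p
        U[:, reg] = (1.0 / dpow) / (1.0 / dpow).sum(axis=0)
    return U


def update_centers(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    """Center update v_i = sum_j u_ij^m x_j / sum_j u_ij^m."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    U = np.asarray(U, dtype=float)
    W = U**m
    mass = W.sum(axis=1)
    if np.any(mass <= _ZERO):
        raise DegenerateClusterError(
            f"cluster(s) {np.nonzero(mass <= _ZERO)[0].tolist()} have no membership mass"
        )
    return (W @ X) / mass[:, None]


def fcm_objective(X: np.ndarray, U: np.ndarray, V: np.ndarray, m: float) -> float:
    """J = sum_i sum_j u_ij^m ||x_j - v_i||^2."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return float((np.asarray(U) ** m * _sqdist(X, np.atleast_2d(V))).sum())


def harden(U: np.ndarray) -> np.ndarray:
    """Hard labels: per-sample argmax membership, 1-based, ties to lowest index."""
    return np.asarray(U).argmax(axis=0) + 1


def _random_memberships(c: int, n: int, rng: np.random.Generator) -> np.ndarray:
    U = rng.random((c, n))
    return U / U.sum(axis=0)


def _centers_with_reseed(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    """Center update that re-seeds massless clusters at the worst-covered sample."""
    W = U**m
    mass = W.sum(axis=1)
    good = mass > _ZERO
    V = np.empty((U.shape[0], X.shape[1]))
    V[good] = (W[good] @ X) / mass[good, None]
    if not good.all():
        d2 = _sqdist(X, V[good])
        order = np.argsort(-d2.min(axis=0))  # farthest-from-any-good-center first
        for rank, i in enumerate(np.nonzero(~good)[0]):
            j = int(order[rank % len(order)])
            V[i] = X[j]
            logger.warning("re-seeded degenerate cluster %d at sample %d", i, j)
    return V


def _single_run(
    X: np.ndarray,
    config: FCMConfig,
    rng: np.random.Generator,
    init_U: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    n = X.shape[0]
    if init_U is not None:
        U = np.asarray(init_U, dtype=float).copy()
        if U.shape != (config.c, n):
            raise UsageError(f"init_U must have shape ({config.c}, {n})")
    else:
        U = _random_memberships(config.c, n, rng)
    trace: list[float] = []
    V = np.empty((config.c, X.shape[1]))
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        try:
            V = update_centers(X, U, config.m)
        except DegenerateClusterError:
            V = _centers_with_reseed(X, U, config.m)
        U_new = update_memberships(X, V, config.m)
        trace.append(fcm_objective(X, U_new, V, config.m))
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta < config.epsilon:
            converged = True
            break
    return U, V, trace, it, converged


def fcm_cluster(
    X: FeatureTable | np.ndarray,
    config: FCMConfig,
    init_U: np.ndarray | None = None,
) -> FCMResult:
    """Cluster samples, multi-restart, keeping the lowest-objective run.

    ``init_U`` fixes the initial membership matrix (single run, no restarts);
    otherwise each restart draws a random column-stochastic U from the seed.
    """
    if isinstance(X, FeatureTable):
        X = X.X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n <= config.c:
        raise UsageError(f"need more samples ({n}) than clusters ({config.c})")
    rng = np.random.default_rng(config.seed)
    best = None
    n_restarts = 1 if init_U is not None else config.n_restarts
    for _ in range(n_restarts):
        U, V, trace, iters, conv = _single_run(X, config, rng, init_U)
        J = trace[-1] if trace else np.inf
        if best is None or J < best[0]:
            best = (J, U, V, trace, iters, conv)
    assert best is not None
    _, U, V, trace, iters, conv = best
    return FCMResult(
        U=U,
        V=V,
        objective_trace=trace,
        iterations=iters,
        converged=conv,
        labels=harden(U),
        config=config,
    )
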