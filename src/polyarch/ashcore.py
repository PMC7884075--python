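"""Empirical-Bayes point-mass-plus-normal-mixture fit for (beta, se) pairs.

The marginal model is betahat_i ~ sum_k w_k * Normal(0, sd_k^2 + se_i^2)
with sd_1 = 0 (the point mass).  The null weight w_1 ("pi0") receives a
Dirichlet-style penalty that favours the null, and the weights are fitted
by EM; the component grid is fixed up front, so each EM step only updates
weights and the penalized log-likelihood is provably nondecreasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError, PolyarchError

__all__ = ["AshModel", "fit_ash", "posterior_mean_effects", "bootstrap_pi0", "default_grid"]


@dataclass
class AshModel:
    component_sds: np.ndarray
    weights: np.ndarray
    pi0: float
    penalty: float
    loglik: float
    loglik_trace: np.ndarray = field(repr=False)
    n_iter: int
    converged: bool

    def to_json(self) -> str:
        return json.dumps({
            "component_sds": self.component_sds.tolist(),
            "weights": self.weights.tolist(),
            "pi0": self.pi0,
            "penalty": self.penalty,
            "loglik": self.loglik,
            "loglik_trace": self.loglik_trace.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
        })

    @classmethod
    def from_json(cls, s: str) -> "AshModel":
        d = json.loads(s)
        return cls(
            component_sds=np.asarray(d["component_sds"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            pi0=d["pi0"],
            penalty=d["penalty"],
            loglik=d["loglik"],
            loglik_trace=np.asarray(d["loglik_trace"], dtype=float),
            n_iter=d["n_iter"],
            converged=d["converged"],
        )


def default_grid(betahat: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Component sds: 0, then min(se)/10 .. 2*max|betahat| at sqrt(2) spacing."""
    bmax = float(np.max(np.abs(betahat)))
    lo = float(np.min(se)) / 10.0
    if bmax == 0.0:
        return np.array([0.0, lo])
    hi = 2.0 * bmax
    if hi <= lo:
        return np.array([0.0, lo])
    n_steps = int(np.ceil(np.log(hi / lo) / np.log(np.sqrt(2.0))))
    sds = lo * np.sqrt(2.0) ** np.arange(n_steps + 1)
    return np.concatenate(([0.0], sds))


def _likelihood_matrix(betahat: np.ndarray, se: np.ndarray, sds: np.ndarray) -> np.ndarray:
    var = sds[None, :] ** 2 + se[:, None] ** 2
    L = np.exp(-0.5 * betahat[:, None] ** 2 / var) / np.sqrt(2.0 * np.pi * var)
    return L


def _em_weights(
    L: np.ndarray,
    penalty: float,
    counts: np.ndarray | None = None,
    tol: float = 1e-7,
    maxiter: int = 2000,
):
    """Accelerated EM over mixture weights for fixed component likelihoods.

    ``L`` is (n x K).  ``counts`` is (n x B) row multiplicities for B
    parallel fits sharing ``L`` (bootstrap); None means a single fit with
    unit counts.  Returns (W (K x B), trace list per column, n_cycles,
    converged flags).  Component 0 carries the null penalty.

    Uses SQUAREM extrapolation over pairs of EM steps with a fallback to
    the plain EM iterate whenever the extrapolated point does not improve
    the penalized log-likelihood, so the recorded trace is nondecreasing.
    Plain EM is provably monotone; the flat near-null direction of this
    likelihood makes acceleration necessary in practice.
    """
    n, K = L.shape
    if counts is None:
        C = np.ones((n, 1))
    else:
        C = np.asarray(counts, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    B = C.shape[1]
    pen = penalty - 1.0
    tiny = np.finfo(float).tiny

    def em_step(W):
        P = np.maximum(L @ W, tiny)
        W_new = W * (L.T @ (C / P))
        W_new[0] += pen
        W_new /= W_new.sum(axis=0, keepdims=True)
        return W_new

    def objective(W):
        P = np.maximum(L @ W, tiny)
        return (C * np.log(P)).sum(axis=0) + pen * np.log(np.maximum(W[0], tiny))

    W = np.full((K, B), 1.0 / K)
    obj = objective(W)
    traces = [[o] for o in obj] if B > 1 else [[obj[0]]]
    active = np.ones(B, dtype=bool)
    n_iter = np.zeros(B, dtype=int)

    for _ in range(maxiter):
        W1 = em_step(W)
        W2 = em_step(W1)
        R = W1 - W
        V = (W2 - W1) - R
        vnorm = np.sqrt((V * V).sum(axis=0))
        rnorm = np.sqrt((R * R).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = -np.where(vnorm > 0, rnorm / vnorm, 1.0)
        alpha = np.clip(alpha, -1e3, -1.0)
        W_acc = W - 2.0 * alpha[None, :] * R + (alpha[None, :] ** 2) * V
        np.maximum(W_acc, 0.0, out=W_acc)
        W_acc /= np.maximum(W_acc.sum(axis=0, keepdims=True), tiny)
        W_acc = em_step(W_acc)  # stabilization step
        obj_acc = objective(W_acc)
        obj_em = objective(W2)
        take_acc = obj_acc >= obj_em
        W_next = np.where(take_acc[None, :], W_acc, W2)
        obj_next = np.where(take_acc, obj_acc, obj_em)

        W = np.where(active[None, :], W_next, W)
        improved = obj_next - obj
        obj = np.where(active, obj_next, obj)
        for b in range(B):
            if active[b]:
                traces[b].append(obj[b])
        n_iter += active
        active &= improved >= tol
        if not active.any():
            break

    converged = ~active
    return W, traces, n_iter, converged


def fit_ash(
    betahat,
    se,
    grid: np.ndarray | None = None,
    penalty: float = 10.0,
    tol: float = 1e-7,
    maxiter: int = 2000,
) -> AshModel:
    """Fit the point-mass-plus-normal mixture; pi0 is the point-mass weight."""
    b = np.asarray(betahat, dtype=float)
    s = np.asarray(se, dtype=float)
    if b.shape != s.shape:
        raise DomainError("betahat and se must have equal length")
    if len(b) < 10:
        raise InsufficientDataError("need at least 10 observations")
    if not (np.isfinite(b).all() and np.isfinite(s).all()):
        raise DomainError("non-finite inputs")
    if np.any(s <= 0):
        raise DomainError("se must be strictly positive")
    if penalty < 1:
        raise DomainError("penalty must be >= 1")
    sds = np.asarray(grid, dtype=float) if grid is not None else default_grid(b, s)
    if sds[0] != 0 or np.any(np.diff(sds) < 0):
        raise DomainError("grid must start at 0 and be nondecreasing")

    if np.all(b == 0.0):
        # degenerate data: all-zero effects are exactly the point mass
        w = np.zeros(len(sds))
        w[0] = 1.0
        ll = float(np.sum(-0.5 * np.log(2 * np.pi * s**2)))
        return AshModel(sds, w, 1.0, penalty, ll, np.array([ll]), 1, True)

    L = _likelihood_matrix(b, s, sds)
    W, traces, n_iter, converged = _em_weights(L, penalty, tol=tol, maxiter=maxiter)
    w = W[:, 0]
    trace = np.asarray(traces[0])
    return AshModel(
        component_sds=sds,
        weights=w,
        pi0=float(w[0]),
        penalty=penalty,
        loglik=float(trace[-1]),
        loglik_trace=trace,
        n_iter=int(n_iter[0]) + 1,
        converged=bool(converged[0]),
    )


def posterior_mean_effects(model: AshModel, betahat, se) -> np.ndarray:
    """Posterior mean effect per observation under the fitted mixture."""
    if model.weights is None or len(model.weights) == 0:
        raise PolyarchError("model not fitted")
    b = np.asarray(betahat, dtype=float)
    s = np.asarray(se, dtype=float)
    sds = model.component_sds
    var = sds[None, :] ** 2 + s[:, None] ** 2
    L = np.exp(-0.5 * b[:, None] ** 2 / var) / np.sqrt(2.0 * np.pi * var)
    R = L * model.weights[None, :]
    R /= np.maximum(R.sum(axis=1, keepdims=True), np.finfo(float).tiny)
    shrink = sds[None, :] ** 2 / var  # conjugate-normal posterior mean factor
    return (R * shrink).sum(axis=1) * b


def bootstrap_pi0(
    betahat,
    se,
    n_boot: int = 50,
    seed: int = 0,
    grid: np.ndarray | None = None,
    penalty: float = 10.0,
    tol: float = 1e-6,
    maxiter: int = 500,
) -> np.ndarray:
    """pi0 over ``n_boot`` within-sample multinomial resamples.

    All replicates share one likelihood matrix, so the resampled EMs run as
    a single batched fit; returns the vector of bootstrap pi0 values.
    """
    b = np.asarray(betahat, dtype=float)
    s = np.asarray(se, dtype=float)
    n = len(b)
    rng = np.random.default_rng(seed)
    sds = np.asarray(grid, dtype=float) if grid is not None else default_grid(b, s)
    L = _likelihood_matrix(b, s, sds)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).T  # (n x B)
    W, _, _, _ = _em_weights(L, penalty, counts=counts, tol=tol, maxiter=maxiter)
    return W[0]
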