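"""Nuclear-norm matrix completion by singular value shrinkage (SVS).

Minimizes  ||A o (M - X)||_F^2 + lam * ||X||_*  by proximal gradient:
a masked gradient step followed by soft-thresholding of the singular
values at lam / (2 * step).  With step >= 1 the quadratic term is
majorized, so every iteration is an exact proximal step and the objective
is non-increasing.  Scores are interaction propensities, so the converged
estimate is projected onto the nonnegative orthant; projecting the final
estimate rather than every iterate keeps the iteration an exact proximal
map (same fixed point as the unconstrained minimizer) while leaving the
ranking of scores untouched.

This solver is both the plain matrix-completion baseline and the X-update
engine of the graph-regularized model: `_svs_proximal` accepts the two
proxy-attraction terms and reduces to plain SVS when they are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskedProblem",
    "ShrinkageConfig",
    "soft_threshold",
    "masked_residual",
    "nuclear_norm",
    "svs_solve",
]


@dataclass(frozen=True)
class MaskedProblem:
    """Partially observed matrix M with binary observation mask A."""

    observed: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.observed, dtype=float)
        A = np.asarray(self.mask, dtype=float)
        if M.shape != A.shape:
            raise ValueError(f"observed {M.shape} and mask {A.shape} shapes differ")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("mask must be binary")
        if not np.isfinite(M[A == 1.0]).all():
            raise ValueError("observed entries must be finite wherever mask = 1")
        object.__setattr__(self, "observed", M)
        object.__setattr__(self, "mask", A)

    @property
    def shape(self) -> tuple[int, int]:
        return self.observed.shape


@dataclass(frozen=True)
class ShrinkageConfig:
    """SVS solver knobs.

    lam is the nuclear-norm weight; step is the inverse gradient step size
    (>= 1 so each iteration majorizes the masked quadratic); iteration stops
    when the relative objective change drops below tol.
    """

    lam: float = 1.0
    step: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6
    nonneg: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.step < 1:
            raise ValueError("step must be >= 1 for a monotone iteration")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be positive and tol > 0")


def soft_threshold(values: np.ndarray, tau: float) -> np.ndarray:
    """Shrink nonnegative singular values toward zero: max(value - tau, 0)."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("singular values must be nonnegative")
    return np.maximum(values - tau, 0.0)


def masked_residual(problem: MaskedProblem, X: np.ndarray) -> float:
    """Squared Frobenius norm of the residual on the observed entries."""
    R = problem.mask * (problem.observed - X)
    return float(np.sum(R * R))


def nuclear_norm(X: np.ndarray) -> float:
    return float(np.linalg.svd(X, compute_uv=False).sum())


def _svs_proximal(
    problem: MaskedProblem,
    config: ShrinkageConfig,
    X0: np.ndarray | None = None,
    proxies: tuple[tuple[float, np.ndarray], ...] = (),
) -> tuple[np.ndarray, list[float]]:
    """Proximal-gradient loop shared by plain SVS and the stacked X-update.

    Each (weight, T) in `proxies` adds weight * ||T - X||_F^2 to the data
    term, which is the column-stacked least-squares system of the
    graph-regularized X-update.  The inverse step is raised to
    step + sum(weights) so the stacked quadratic stays majorized.
    """
    M, A = problem.observed, problem.mask
    X = np.zeros_like(M) if X0 is None else np.array(X0, dtype=float)
    a = config.step + sum(w for w, _ in proxies)

    def objective(X: np.ndarray) -> float:
        val = masked_residual(problem, X) + config.lam * nuclear_norm(X)
        for w, T in proxies:
            val += w * float(np.sum((T - X) ** 2))
        return val

    history = [objective(X)]
    for _ in range(config.max_iter):
        G = A * (M - A * X)
        for w, T in proxies:
            G = G + w * (T - X)
        B = X + G / a
        U, s, Vt = np.linalg.svd(B, full_matrices=False)
        s = soft_threshold(s, config.lam / (2.0 * a))
        X = (U * s) @ Vt
        history.append(objective(X))
        prev, cur = history[-2], history[-1]
        if abs(prev - cur) <= config.tol * max(abs(prev), 1e-12):
            break
    if config.nonneg:
        X = np.maximum(X, 0.0)
    return X, history


def svs_solve(
    problem: MaskedProblem,
    config: ShrinkageConfig,
    X0: np.ndarray | None = None,
    return_history: bool = False,
):
    """Complete a partially observed matrix by singular value shrinkage.

    Returns the recovered matrix, or (matrix, objective history) when
    return_history is set.  Initialization is X = 0 unless X0 is given;
    the objective is convex, so the minimizer does not depend on it.
    """
    X, history = _svs_proximal(problem, config, X0=X0)
    if return_history:
        return X, history
    return X
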