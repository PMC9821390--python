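"""Generic estimating-equation machinery.

Root solving for systems of estimating equations, numerical Jacobians of
per-observation estimating functions, and the empirical outer-product
("meat") matrix used by sandwich covariance estimators.  All estimators in
:mod:`histest.estimators` are built on these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObservationSet",
    "EstimatingFunction",
    "JacobianSet",
    "SolverResult",
    "RootFindingError",
    "solve_root",
    "estimate_jacobians",
]

# finite-difference step policy: central differences, second-order accurate
_SQRT_EPS = float(np.sqrt(np.finfo(float).eps))


def _fd_step(x: np.ndarray) -> np.ndarray:
    return _SQRT_EPS * np.maximum(1.0, np.abs(x))


class RootFindingError(RuntimeError):
    """Raised when the Newton iteration fails; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class ObservationSet:
    """The current-study data: a flat table of outcome + covariate values."""

    frame: pd.DataFrame

    def __post_init__(self):
        if len(self.frame) < 1:
            raise ValueError("ObservationSet requires at least one observation")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class EstimatingFunction:
    """A pair of per-observation estimating functions.

    ``psi(theta, eta, y) -> (p,)`` estimates theta given eta; the optional
    ``gamma(theta, eta, y) -> (q,)`` estimates eta given theta.  ``y`` is a
    1-D array holding one observation's row (order given by the data's
    columns).
    """

    psi: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    p: int
    q: int
    gamma: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None

    def psi_mean(self, theta: np.ndarray, eta: np.ndarray, data: ObservationSet) -> np.ndarray:
        rows = data.values
        out = np.zeros(self.p)
        for y in rows:
            out += np.asarray(self.psi(theta, eta, y), dtype=float)
        return out / len(rows)

    def gamma_mean(self, theta: np.ndarray, eta: np.ndarray, data: ObservationSet) -> np.ndarray:
        if self.gamma is None:
            raise ValueError("estimating function has no gamma component")
        rows = data.values
        out = np.zeros(self.q)
        for y in rows:
            out += np.asarray(self.gamma(theta, eta, y), dtype=float)
        return out / len(rows)


@dataclass(frozen=True)
class JacobianSet:
    """Limit matrices of an estimating function, estimated by sample averages.

    ``D_theta`` and ``D_eta`` are the mean derivatives of psi with respect to
    theta and eta; ``meat`` is the mean of psi psi^T.  ``D_blocks`` splits
    ``D_eta`` column-wise by historical-study parameter blocks.
    """

    D_theta: np.ndarray
    D_eta: np.ndarray
    meat: np.ndarray
    D_blocks: tuple[np.ndarray, ...] = field(default_factory=tuple)

    def __post_init__(self):
        D_theta = np.atleast_2d(np.asarray(self.D_theta, dtype=float))
        D_eta = np.atleast_2d(np.asarray(self.D_eta, dtype=float))
        meat = np.atleast_2d(np.asarray(self.meat, dtype=float))
        object.__setattr__(self, "D_theta", D_theta)
        object.__setattr__(self, "D_eta", D_eta)
        object.__setattr__(self, "meat", 0.5 * (meat + meat.T))
        if self.D_blocks:
            blocks = tuple(np.atleast_2d(np.asarray(b, dtype=float)) for b in self.D_blocks)
            object.__setattr__(self, "D_blocks", blocks)
            cat = np.hstack(blocks)
            if cat.shape != D_eta.shape or not np.allclose(cat, D_eta, atol=1e-8):
                raise ValueError("horizontal concatenation of D_blocks must equal D_eta")
        cond = np.linalg.cond(D_theta)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"D_theta is numerically singular (condition number {cond:.3e})"
            )


@dataclass(frozen=True)
class SolverResult:
    x: np.ndarray
    iterations: int
    norm: float
    converged: bool


def solve_root(
    F: Callable[[np.ndarray], np.ndarray],
    init: Sequence[float] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> SolverResult:
    """Solve F(x)=0 by damped Newton with a central-difference Jacobian.

    The step is halved (up to 30 times) until the residual norm does not
    increase.  Convergence is declared on ``||F(x)||_inf <= tol``.
    """
    x = np.atleast_1d(np.asarray(init, dtype=float)).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("initial point must be finite")
    fx = np.atleast_1d(np.asarray(F(x), dtype=float))
    norm = float(np.max(np.abs(fx)))
    for it in range(1, max_iter + 1):
        if norm <= tol:
            return SolverResult(x=x, iterations=it - 1, norm=norm, converged=True)
        J = _numeric_jacobian(F, x, len(fx))
        cond = np.linalg.cond(J)
        if not np.isfinite(cond) or cond > 1e14:
            raise RootFindingError(
                f"singular Jacobian at iteration {it} (condition number {cond:.3e})",
                last_iterate=x,
            )
        step = np.linalg.solve(J, -fx)
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * step
            f_new = np.atleast_1d(np.asarray(F(x_new), dtype=float))
            n_new = float(np.max(np.abs(f_new)))
            if np.isfinite(n_new) and n_new <= norm:
                break
            lam *= 0.5
        else:
            raise RootFindingError(
                f"line search failed at iteration {it} (||F||_inf={norm:.3e})",
                last_iterate=x,
            )
        x, fx, norm = x_new, f_new, n_new
    if norm <= tol:
        return SolverResult(x=x, iterations=max_iter, norm=norm, converged=True)
    raise RootFindingError(
        f"no convergence after {max_iter} iterations (||F||_inf={norm:.3e})",
        last_iterate=x,
    )


def _numeric_jacobian(F, x: np.ndarray, out_dim: int) -> np.ndarray:
    d = len(x)
    J = np.zeros((out_dim, d))
    h = _fd_step(x)
    for j in range(d):
        xp, xm = x.copy(), x.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        J[:, j] = (np.atleast_1d(F(xp)) - np.atleast_1d(F(xm))) / (2 * h[j])
    return J


def estimate_jacobians(
    ef: EstimatingFunction,
    data: ObservationSet,
    theta: Sequence[float] | np.ndarray,
    eta: Sequence[float] | np.ndarray,
    q_splits: Sequence[int] | None = None,
) -> JacobianSet:
    """Estimate D_theta, D_eta and the meat matrix at (theta, eta).

    Per-observation psi is differentiated by central differences and averaged
    over the sample; the meat is the sample average of psi psi^T.  ``q_splits``
    partitions the eta-columns into per-study blocks (must sum to q).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if q_splits is not None and sum(q_splits) != ef.q:
        raise ValueError(f"q_splits {list(q_splits)} do not sum to q={ef.q}")
    rows = data.values
    p, q = ef.p, ef.q
    D_theta = np.zeros((p, p))
    D_eta = np.zeros((p, q))
    meat = np.zeros((p, p))
    h_t, h_e = _fd_step(theta), _fd_step(eta)
    for idx, y in enumerate(rows):
        val = np.atleast_1d(np.asarray(ef.psi(theta, eta, y), dtype=float))
        if not np.all(np.isfinite(val)):
            raise ValueError(f"non-finite psi value at observation index {idx}")
        meat += np.outer(val, val)
        for j in range(p):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h_t[j]
            tm[j] -= h_t[j]
            der = (np.atleast_1d(ef.psi(tp, eta, y)) - np.atleast_1d(ef.psi(tm, eta, y))) / (2 * h_t[j])
            if not np.all(np.isfinite(der)):
                raise ValueError(f"non-finite theta-derivative at observation index {idx}")
            D_theta[:, j] += der
        for j in range(q):
            ep, em = eta.copy(), eta.copy()
            ep[j] += h_e[j]
            em[j] -= h_e[j]
            der = (np.atleast_1d(ef.psi(theta, ep, y)) - np.atleast_1d(ef.psi(theta, em, y))) / (2 * h_e[j])
            if not np.all(np.isfinite(der)):
                raise ValueError(f"non-finite eta-derivative at observation index {idx}")
            D_eta[:, j] += der
    n = len(rows)
    D_theta /= n
    D_eta /= n
    meat /= n
    blocks: tuple[np.ndarray, ...] = ()
    if q_splits is not None:
        edges = np.cumsum([0, *q_splits])
        blocks = tuple(D_eta[:, edges[i]: edges[i + 1]] for i in range(len(q_splits)))
    return JacobianSet(D_theta=D_theta, D_eta=D_eta, meat=meat, D_blocks=blocks)
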