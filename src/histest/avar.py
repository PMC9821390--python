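"""Asymptotic covariance matrices and efficiency comparisons.

Houses the limiting covariance of the plug-in (Type-I) estimator, of the
two-step pooled (Type-II) estimator, and of the summary-combination
estimator, all on the sqrt(n) scale; delta-method variances for smooth
functionals; the scalar asymptotic relative efficiency 1 - w2*r^2; and
Loewner-order comparisons between covariance matrices.

Notation: theta (p-dim) is the current-study parameter of interest, eta
(q-dim) the concatenated historical parameters.  Sigma is the sqrt(m)-scale
covariance of the stacked historical estimates, Upsilon the sqrt(n)-scale
covariance of the current-study joint estimates, rho = n/m the sampling
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .estimating import JacobianSet
    from .pooling import HistoricalSet

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionedCov",
    "ScalarCase",
    "avar_type_a",
    "avar_type_b",
    "avar_type_c",
    "delta_variance",
    "loewner_leq",
    "check_comparison_conditions",
    "scalar_are",
    "per_study_scale",
]

_SQRT_EPS = float(np.sqrt(np.finfo(float).eps))


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """A^{-1} B via a linear solve (never an explicit inverse)."""
    return np.linalg.solve(A, B)


def _inv(A: np.ndarray) -> np.ndarray:
    return _sym(np.linalg.solve(A, np.eye(A.shape[0])))


@dataclass(frozen=True)
class PartitionedCov:
    """A (p+q)x(p+q) symmetric covariance on the sqrt(n) scale.

    Provides named access to the theta-theta, theta-eta and eta-eta blocks.
    """

    full: np.ndarray
    p: int
    q: int

    def __post_init__(self):
        M = np.atleast_2d(np.asarray(self.full, dtype=float))
        if M.shape != (self.p + self.q, self.p + self.q):
            raise ValueError(f"matrix shape {M.shape} inconsistent with (p,q)=({self.p},{self.q})")
        if np.max(np.abs(M - M.T)) > 1e-8 * max(1.0, np.max(np.abs(M))):
            raise ValueError("covariance matrix is not symmetric")
        M = _sym(M)
        eig_min = float(np.linalg.eigvalsh(M).min())
        if eig_min < -1e-8 * max(1.0, float(np.trace(M))):
            raise ValueError(f"covariance matrix is not PSD (min eigenvalue {eig_min:.3e})")
        object.__setattr__(self, "full", M)

    @property
    def theta_theta(self) -> np.ndarray:
        return self.full[: self.p, : self.p]

    @property
    def theta_eta(self) -> np.ndarray:
        return self.full[: self.p, self.p:]

    @property
    def eta_theta(self) -> np.ndarray:
        return self.full[self.p:, : self.p]

    @property
    def eta_eta(self) -> np.ndarray:
        return self.full[self.p:, self.p:]

    @classmethod
    def from_blocks(cls, tt: np.ndarray, te: np.ndarray, ee: np.ndarray) -> "PartitionedCov":
        tt = np.atleast_2d(np.asarray(tt, dtype=float))
        te = np.atleast_2d(np.asarray(te, dtype=float))
        ee = np.atleast_2d(np.asarray(ee, dtype=float))
        full = np.block([[tt, te], [te.T, ee]])
        return cls(full=_sym(full), p=tt.shape[0], q=ee.shape[0])

    def labels(self) -> list[str]:
        return [f"theta.{i + 1}" for i in range(self.p)] + [f"eta.{i + 1}" for i in range(self.q)]

    def to_frame(self):
        import pandas as pd

        lab = self.labels()
        return pd.DataFrame(self.full, index=lab, columns=lab)


@dataclass(frozen=True)
class ScalarCase:
    """The scalar (p=q=1) summary-combination problem.

    ``r`` is the asymptotic correlation between the current estimates of
    theta and eta, ``w2`` the limiting weight on the historical estimate, and
    ``are = 1 - w2*r^2`` the asymptotic relative efficiency of the combined
    estimator of theta relative to the current-study-only one.
    """

    upsilon_tt: float
    upsilon_te: float
    upsilon_ee: float
    sigma2: float
    gamma: float
    r: float
    w2: float
    are: float


def scalar_are(upsilon_tt: float, upsilon_te: float, upsilon_ee: float,
               sigma2: float, n: int, m: int) -> ScalarCase:
    """Scalar efficiency gain from borrowing a historical estimate of eta.

    ``upsilon_*`` are the sqrt(n)-scale current covariance entries, ``sigma2``
    the sqrt(m)-scale historical variance.  Satisfies 1-r^2 <= are <= 1.
    """
    if upsilon_tt <= 0 or upsilon_ee <= 0 or sigma2 <= 0:
        raise ValueError("variances must be positive")
    gamma = n / (n + m)
    r = upsilon_te / np.sqrt(upsilon_tt * upsilon_ee)
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"implied correlation |r|={abs(r):.4f} exceeds 1")
    w2 = ((1 - gamma) / sigma2) / (gamma / upsilon_ee + (1 - gamma) / sigma2)
    are = 1.0 - w2 * r * r
    return ScalarCase(upsilon_tt=upsilon_tt, upsilon_te=upsilon_te, upsilon_ee=upsilon_ee,
                      sigma2=sigma2, gamma=gamma, r=float(r), w2=float(w2), are=float(are))


def avar_type_a(jac: "JacobianSet", hist: "HistoricalSet", rho: float):
    """Limiting covariance of the plug-in estimator (eta fixed at history).

    theta-block: D_theta^{-1} [Sigma_psi + rho D_eta Sigma D_eta^T] D_theta^{-T};
    the additive term rho D_eta Sigma D_eta^T is the plug-in penalty paid for
    substituting estimates for the true nuisance values.  Returns the
    partitioned covariance and the penalty matrix.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    Sigma = hist.Sigma
    Dt, De = jac.D_theta, jac.D_eta
    penalty = rho * De @ Sigma @ De.T
    inner = jac.meat + penalty
    tt = _sym(_solve(Dt, _solve(Dt, inner.T).T))
    te = -rho * _solve(Dt, De @ Sigma)
    ee = rho * Sigma
    cov = PartitionedCov.from_blocks(tt, te, ee)
    return cov, _sym(penalty)


def _pooled_kernel(ups_ee: np.ndarray, Sigma: np.ndarray, rho: float) -> np.ndarray:
    """(Upsilon_ee^{-1} + (rho Sigma)^{-1})^{-1}: the pooled-precision kernel."""
    return _inv(_inv(ups_ee) + _inv(rho * Sigma))


def avar_type_b(jac: "JacobianSet", upsilon: PartitionedCov, hist: "HistoricalSet",
                rho: float) -> PartitionedCov:
    """Limiting covariance of the two-step pooled estimator.

    Structurally identical to the plug-in covariance with rho*Sigma replaced
    by the pooled-precision kernel (Upsilon_ee^{-1}+(rho Sigma)^{-1})^{-1}.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    K = _pooled_kernel(upsilon.eta_eta, hist.Sigma, rho)
    Dt, De = jac.D_theta, jac.D_eta
    inner = jac.meat + De @ K @ De.T
    tt = _sym(_solve(Dt, _solve(Dt, inner.T).T))
    te = -_solve(Dt, De @ K)
    return PartitionedCov.from_blocks(tt, te, K)


def pooling_weights(ups_ee: np.ndarray, Sigma: np.ndarray, gamma: float):
    """Weight matrices W1 (current) and W2 (historical) with W1+W2=I."""
    P = gamma * _inv(ups_ee) + (1 - gamma) * _inv(Sigma)
    W1 = _solve(P, gamma * _inv(ups_ee))
    W2 = _solve(P, (1 - gamma) * _inv(Sigma))
    return W1, W2


def avar_type_c(upsilon: PartitionedCov, hist: "HistoricalSet", rho: float) -> PartitionedCov:
    """Limiting covariance of the summary-combination estimator.

    Computed twice -- via the M V M^T representation (with the pooling weight
    matrices) and via the closed-form blocks -- and cross-checked to 1e-10; a
    disagreement indicates an internal bug and raises.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    p, q = upsilon.p, upsilon.q
    Sigma = hist.Sigma
    ups_ee = upsilon.eta_eta
    K = _pooled_kernel(ups_ee, Sigma, rho)
    rSinv = _inv(rho * Sigma)

    # closed-form blocks
    R = upsilon.theta_eta @ _inv(ups_ee)
    tt = upsilon.theta_theta - R @ K @ rSinv @ upsilon.theta_eta.T
    te = R @ K
    closed = PartitionedCov.from_blocks(_sym(tt), te, K)

    # M V M^T route with the limiting weights (gamma = rho/(1+rho))
    gamma = rho / (1.0 + rho)
    W1, W2 = pooling_weights(ups_ee, Sigma, gamma)
    M = np.zeros((p + q, p + 2 * q))
    M[:p, :p] = np.eye(p)
    M[:p, p: p + q] = -R @ W2
    M[:p, p + q:] = R @ W2
    M[p:, p: p + q] = W1
    M[p:, p + q:] = W2
    V = np.zeros((p + 2 * q, p + 2 * q))
    V[: p + q, : p + q] = upsilon.full
    V[p + q:, p + q:] = rho * Sigma
    mvm = _sym(M @ V @ M.T)

    gap = float(np.max(np.abs(mvm - closed.full)))
    if gap > 1e-10 * max(1.0, float(np.max(np.abs(closed.full)))):
        raise AssertionError(
            f"internal disagreement between MVM^T and closed-form routes (gap {gap:.3e})"
        )
    return PartitionedCov(full=_sym(0.5 * (mvm + closed.full)), p=p, q=q)


def delta_variance(phi: Callable[[np.ndarray], np.ndarray], omega: np.ndarray,
                   cov: PartitionedCov | np.ndarray) -> np.ndarray:
    """Delta-method covariance of phi(omega): grad(phi) cov grad(phi)^T.

    The gradient is computed by central differences with the same step
    policy as the estimating-equation machinery.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    C = cov.full if isinstance(cov, PartitionedCov) else np.atleast_2d(np.asarray(cov, float))
    d = len(omega)
    f0 = np.atleast_1d(np.asarray(phi(omega), dtype=float))
    G = np.zeros((len(f0), d))
    h = _SQRT_EPS * np.maximum(1.0, np.abs(omega))
    for j in range(d):
        xp, xm = omega.copy(), omega.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        G[:, j] = (np.atleast_1d(phi(xp)) - np.atleast_1d(phi(xm))) / (2 * h[j])
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite gradient in delta_variance")
    return _sym(G @ C @ G.T)


def loewner_leq(V1: np.ndarray, V2: np.ndarray, tol: float = 1e-8):
    """Test V1 <= V2 in the Loewner order (V2 - V1 PSD, up to relative tol).

    Returns ``(leq, min_eig)`` where ``min_eig`` is the smallest eigenvalue
    of V2 - V1; the comparison passes when it is >= -tol * trace(V2).
    """
    V1 = np.atleast_2d(np.asarray(V1, dtype=float))
    V2 = np.atleast_2d(np.asarray(V2, dtype=float))
    if V1.shape != V2.shape:
        raise ValueError("matrices must have the same shape")
    for name, V in (("V1", V1), ("V2", V2)):
        if np.max(np.abs(V - V.T)) > 1e-8 * max(1.0, np.max(np.abs(V))):
            raise ValueError(f"{name} is not symmetric")
    diff = _sym(V2 - V1)
    min_eig = float(np.linalg.eigvalsh(diff).min())
    leq = min_eig >= -tol * max(1.0, abs(float(np.trace(V2))))
    return leq, min_eig


def check_comparison_conditions(jac_psi: "JacobianSet", jac_lambda: "JacobianSet",
                                tol: float = 1e-8) -> dict:
    """Sufficient conditions under which the two-step estimator dominates.

    Condition "sensitivity": D_theta^{-1} D_eta of the raw-data estimating
    function is component-wise no larger than that of the summary-combination
    one.  Condition "efficiency": the raw-data sandwich core is no larger in
    the Loewner order.  When both hold the two-step covariance is dominated
    by the summary-combination covariance.
    """
    S_psi = np.linalg.solve(jac_psi.D_theta, jac_psi.D_eta)
    S_lam = np.linalg.solve(jac_lambda.D_theta, jac_lambda.D_eta)
    cond_sensitivity = bool(np.all(S_psi <= S_lam + tol))

    def core(j):
        return _sym(np.linalg.solve(j.D_theta, np.linalg.solve(j.D_theta, j.meat.T).T))

    leq, min_eig = loewner_leq(core(jac_psi), core(jac_lambda), tol=tol)
    return {
        "sensitivity_componentwise": cond_sensitivity,
        "efficiency_loewner": bool(leq),
        "efficiency_min_eig": min_eig,
        "implies_b_leq_c": bool(cond_sensitivity and leq),
    }


def per_study_scale(cov: PartitionedCov | np.ndarray, n: int) -> np.ndarray:
    """Convert a sqrt(n)-scale covariance to the finite-sample scale (divide by n)."""
    M = cov.full if isinstance(cov, PartitionedCov) else np.asarray(cov, dtype=float)
    return M / n
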