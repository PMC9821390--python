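"""Point estimators for current-study parameters with historical borrowing.

Three estimators are provided, matching the three ways historical estimates
enter an analysis:

* ``estimate_type_a`` -- plug-in: the nuisance eta is fixed at its
  historical value and only theta is solved for (the only option when the
  current data do not identify eta);
* ``estimate_type_b`` -- two-step: theta and eta are first estimated jointly
  from the current data, eta is pooled with the historical estimate by
  inverse-variance weighting, and theta is re-solved at the pooled eta;
* ``estimate_type_c`` -- summary combination: only current-study summary
  statistics (estimates + covariance) are available and are combined with
  the historical estimate through the regression adjustment
  theta_c = theta_tilde - Ups_te Ups_ee^{-1} (eta_tilde - eta_bar).

``estimate_augmented`` solves the one-shot augmented system in which the
historical information enters as a pseudo-score; it is first-order
equivalent to the two-step estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .avar import (PartitionedCov, _inv, avar_type_a, avar_type_b, avar_type_c)
from .estimating import (EstimatingFunction, JacobianSet, ObservationSet,
                         SolverResult, estimate_jacobians, solve_root)
from .pooling import HistoricalSet, pool_eta

logger = logging.getLogger(__name__)

__all__ = [
    "CurrentSummary",
    "EstimateResult",
    "estimate_type_a",
    "estimate_type_b",
    "estimate_type_c",
    "estimate_augmented",
    "joint_sandwich",
]


@dataclass(frozen=True)
class CurrentSummary:
    """Current-study summary statistics: the coarsened-data interface."""

    theta_tilde: np.ndarray
    eta_tilde: np.ndarray
    upsilon: PartitionedCov
    n: int

    def __post_init__(self):
        object.__setattr__(self, "theta_tilde",
                           np.atleast_1d(np.asarray(self.theta_tilde, dtype=float)))
        object.__setattr__(self, "eta_tilde",
                           np.atleast_1d(np.asarray(self.eta_tilde, dtype=float)))
        if self.n < 1:
            raise ValueError("current sample size must be >= 1")
        if (len(self.theta_tilde), len(self.eta_tilde)) != (self.upsilon.p, self.upsilon.q):
            raise ValueError("estimate dimensions inconsistent with covariance blocks")


@dataclass(frozen=True)
class EstimateResult:
    theta_bar: np.ndarray
    eta_bar: np.ndarray
    avar: PartitionedCov
    kind: str
    n: int
    m: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def rho(self) -> float:
        return self.n / self.m

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "theta": self.theta_bar.tolist(),
            "eta": self.eta_bar.tolist(),
            "avar_blocks": {
                "theta_theta": self.avar.theta_theta.tolist(),
                "theta_eta": self.avar.theta_eta.tolist(),
                "eta_eta": self.avar.eta_eta.tolist(),
            },
            "n": self.n,
            "m": self.m,
            "rho": self.rho,
            "solver": self.diagnostics,
        }


def _solver_diag(res: SolverResult) -> dict:
    return {"iterations": res.iterations, "norm": res.norm, "converged": res.converged}


def joint_sandwich(ef: EstimatingFunction, data: ObservationSet,
                   theta: np.ndarray, eta: np.ndarray) -> PartitionedCov:
    """Sandwich covariance of the joint (theta, eta) solution, sqrt(n) scale.

    Bread is the mean derivative of the stacked (psi, gamma) with respect to
    (theta, eta); meat the mean outer product of the stacked function.
    """
    if ef.gamma is None:
        raise ValueError("joint sandwich requires a gamma component")
    p, q = ef.p, ef.q

    # stack (psi, gamma) as one function of the full omega = (theta, eta)
    def h(omega_t, omega_e, y):
        th, et = omega_t[:p], omega_t[p:]
        return np.concatenate([
            np.atleast_1d(ef.psi(th, et, y)),
            np.atleast_1d(ef.gamma(th, et, y)),
        ])

    hf = EstimatingFunction(psi=h, p=p + q, q=0)
    omega = np.concatenate([np.atleast_1d(theta), np.atleast_1d(eta)])
    jac = estimate_jacobians(hf, data, omega, np.zeros(0))
    G = jac.D_theta
    full = np.linalg.solve(G, np.linalg.solve(G, jac.meat.T).T)
    full = 0.5 * (full + full.T)
    return PartitionedCov(full=full, p=p, q=q)


def estimate_type_a(ef: EstimatingFunction, data: ObservationSet,
                    hist: HistoricalSet, init: Sequence[float] | None = None,
                    ) -> EstimateResult:
    """Plug-in estimator: solve psi(theta, eta_hat)=0 with eta fixed.

    When the estimating function also carries a gamma component the data
    would support a two-step analysis, which is asymptotically more
    efficient; a warning is logged in that case.
    """
    if ef.gamma is not None:
        logger.warning(
            "data admit a joint (Type II) analysis; the plug-in estimator is "
            "asymptotically inferior to the two-step estimator"
        )
    eta_hat = hist.eta_hat
    if len(eta_hat) != ef.q:
        raise ValueError("historical stack dimension does not match the estimating function")
    x0 = np.zeros(ef.p) if init is None else np.asarray(init, dtype=float)
    res = solve_root(lambda th: ef.psi_mean(th, eta_hat, data), x0)
    jac = estimate_jacobians(ef, data, res.x, eta_hat, q_splits=hist.q_splits)
    rho = data.n / hist.m
    cov, _ = avar_type_a(jac, hist, rho)
    return EstimateResult(theta_bar=res.x, eta_bar=eta_hat, avar=cov, kind="A",
                          n=data.n, m=hist.m, diagnostics=_solver_diag(res))


def _joint_solve(ef: EstimatingFunction, data: ObservationSet,
                 init: Sequence[float] | None) -> SolverResult:
    p, q = ef.p, ef.q
    x0 = np.zeros(p + q) if init is None else np.asarray(init, dtype=float)

    def F(x):
        th, et = x[:p], x[p:]
        return np.concatenate([ef.psi_mean(th, et, data), ef.gamma_mean(th, et, data)])

    try:
        return solve_root(F, x0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{exc}; the joint system may not identify (theta, eta) -- "
            "consider a Type-I (plug-in) analysis"
        ) from exc


def estimate_type_b(ef: EstimatingFunction, data: ObservationSet,
                    hist: HistoricalSet, init: Sequence[float] | None = None,
                    upsilon: PartitionedCov | None = None) -> EstimateResult:
    """Two-step estimator: joint solve, pool eta, re-solve theta.

    ``upsilon`` overrides the step-1 sandwich covariance with a model- or
    design-based one (useful when the residual variance is known); by
    default the empirical sandwich at the joint solution is used.
    """
    if ef.gamma is None:
        raise ValueError("the two-step estimator requires a gamma component")
    p = ef.p
    res1 = _joint_solve(ef, data, init)
    theta_tilde, eta_tilde = res1.x[:p], res1.x[p:]
    ups = upsilon if upsilon is not None else joint_sandwich(ef, data, theta_tilde, eta_tilde)
    current = CurrentSummary(theta_tilde=theta_tilde, eta_tilde=eta_tilde,
                             upsilon=ups, n=data.n)
    pooled = pool_eta(current, hist)
    res3 = solve_root(lambda th: ef.psi_mean(th, pooled.eta_bar, data), theta_tilde)
    jac = estimate_jacobians(ef, data, res3.x, pooled.eta_bar, q_splits=hist.q_splits)
    rho = data.n / hist.m
    cov = avar_type_b(jac, ups, hist, rho)
    diag = {"step1": _solver_diag(res1), "step3": _solver_diag(res3)}
    return EstimateResult(theta_bar=res3.x, eta_bar=pooled.eta_bar, avar=cov,
                          kind="B", n=data.n, m=hist.m, diagnostics=diag)


def estimate_type_c(current: CurrentSummary, hist: HistoricalSet) -> EstimateResult:
    """Summary-combination estimator from current summary statistics alone.

    theta_c = theta_tilde - Ups_te Ups_ee^{-1} (eta_tilde - eta_bar) with
    eta_bar the pooled estimate.  When Ups_te = 0 the historical information
    cannot improve theta and theta_c = theta_tilde.
    """
    pooled = pool_eta(current, hist)
    R = current.upsilon.theta_eta @ _inv(current.upsilon.eta_eta)
    theta_c = current.theta_tilde - R @ (current.eta_tilde - pooled.eta_bar)
    rho = current.n / hist.m
    cov = avar_type_c(current.upsilon, hist, rho)
    return EstimateResult(theta_bar=theta_c, eta_bar=pooled.eta_bar, avar=cov,
                          kind="C", n=current.n, m=hist.m,
                          diagnostics={"gamma": pooled.gamma})


def estimate_augmented(ef: EstimatingFunction, data: ObservationSet,
                       hist: HistoricalSet, init: Sequence[float] | None = None,
                       scale: float = 1.0) -> EstimateResult:
    """One-shot estimator from the augmented estimating equations.

    Solves psi(theta,eta)=0 jointly with gamma(theta,eta) + (m/n) Sigma^{-1}
    (eta_hat - eta) = 0, where the second term is the pseudo-score of the
    normal approximation to the historical estimate (written here on the
    per-observation average scale).  ``scale`` multiplies the historical
    precision and exists to probe the no-borrowing limit (scale=0).
    """
    if ef.gamma is None:
        raise ValueError("the augmented estimator requires a gamma component")
    p, q = ef.p, ef.q
    n, m = data.n, hist.m
    Sig_inv = _inv(hist.Sigma)
    eta_hat = hist.eta_hat
    x0 = np.zeros(p + q) if init is None else np.asarray(init, dtype=float)

    def F(x):
        th, et = x[:p], x[p:]
        aug = scale * (m / n) * (Sig_inv @ (eta_hat - et))
        return np.concatenate([ef.psi_mean(th, et, data),
                               ef.gamma_mean(th, et, data) + aug])

    res = solve_root(F, x0)
    theta_bar, eta_bar = res.x[:p], res.x[p:]
    ups = joint_sandwich(ef, data, theta_bar, eta_bar)
    jac = estimate_jacobians(ef, data, theta_bar, eta_bar, q_splits=hist.q_splits)
    cov = avar_type_b(jac, ups, hist, n / m)
    return EstimateResult(theta_bar=theta_bar, eta_bar=eta_bar, avar=cov,
                          kind="augmented", n=n, m=m,
                          diagnostics=_solver_diag(res))
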