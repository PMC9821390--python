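"""2x2 factorial combination trial with historical single-treatment studies.

The outcome model is E(Y | T1, T2) = eta0 + eta1*T1 + eta2*T2 + theta*T1*T2
with homoscedastic residual variance sigma2.  Two historical two-arm studies
(treatment 1 vs control, treatment 2 vs control) provide estimates of
(eta0, eta1, eta2); the current study estimates the interaction theta.  This
module reconstructs the pooled historical estimate and its covariance from
per-study arm summaries, evaluates the design-dependent asymptotic variance
of the interaction estimator for each current-study design (all-combination
plug-in, four-arm two-step, three-arm no-control), and searches for the
variance-minimizing allocation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .avar import PartitionedCov, _inv
from .estimating import EstimatingFunction, ObservationSet
from .estimators import (CurrentSummary, EstimateResult, estimate_type_a,
                         estimate_type_b, estimate_type_c)
from .pooling import HistoricalSet, HistoricalStudy, build_historical_set, pool_linear

__all__ = [
    "AnovaParams",
    "HistoricalAnovaReport",
    "DesignXi",
    "BackCalculated",
    "sigma_balanced",
    "backcalculate_historical",
    "upsilon_for_design",
    "anova_var_type1",
    "anova_var_type2",
    "anova_var_threearm",
    "optimize_design",
    "estimate_anova",
    "anova_table",
    "make_psi",
]

ARM_ORDER = ("00", "10", "01", "11")

# (theta, eta0, eta1, eta2) as linear combinations of the four arm means
# (Ybar_00, Ybar_10, Ybar_01, Ybar_11)
_L_FULL = np.array([
    [1.0, -1.0, -1.0, 1.0],   # theta = Y11 - Y10 - Y01 + Y00
    [1.0, 0.0, 0.0, 0.0],     # eta0 = Y00
    [-1.0, 1.0, 0.0, 0.0],    # eta1 = Y10 - Y00
    [-1.0, 0.0, 1.0, 0.0],    # eta2 = Y01 - Y00
])

_A_THREEARM = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])


@dataclass(frozen=True)
class AnovaParams:
    eta0: float
    eta1: float
    eta2: float
    theta: float
    sigma2: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def arm_mean(self, t1: int, t2: int) -> float:
        return self.eta0 + self.eta1 * t1 + self.eta2 * t2 + self.theta * t1 * t2


@dataclass(frozen=True)
class HistoricalAnovaReport:
    """Arm summaries of the two historical single-treatment studies.

    Study i compared treatment i with a control: ``ybar_control_i`` and
    ``ybar_treat_i`` are the arm means, ``m_control_i``/``m_treat_i`` the
    arm sizes.  ``sigma2`` is the (assumed common) residual variance used for
    the covariance reconstruction.
    """

    ybar_control_1: float
    ybar_treat_1: float
    m_control_1: int
    m_treat_1: int
    ybar_control_2: float
    ybar_treat_2: float
    m_control_2: int
    m_treat_2: int
    sigma2: float = 1.0

    def __post_init__(self):
        for nm in ("m_control_1", "m_treat_1", "m_control_2", "m_treat_2"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be >= 1")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @classmethod
    def from_estimates(cls, eta0_1: float, se0_1: float, eta1: float,
                       eta0_2: float, se0_2: float, eta2: float,
                       sigma2: float = 1.0) -> "HistoricalAnovaReport":
        """Reconstruct arm means and sizes from reported (estimate, SE) pairs.

        Under homoscedasticity the control-arm size of study i is
        sigma2 / se(eta0_i)^2; the treatment-arm mean is eta0_i + eta_i.
        Assumes each study is internally balanced.
        """
        m1 = max(1, round(sigma2 / se0_1 ** 2))
        m2 = max(1, round(sigma2 / se0_2 ** 2))
        return cls(ybar_control_1=eta0_1, ybar_treat_1=eta0_1 + eta1,
                   m_control_1=m1, m_treat_1=m1,
                   ybar_control_2=eta0_2, ybar_treat_2=eta0_2 + eta2,
                   m_control_2=m2, m_treat_2=m2, sigma2=sigma2)

    @property
    def m(self) -> int:
        return self.m_control_1 + self.m_treat_1 + self.m_control_2 + self.m_treat_2


@dataclass(frozen=True)
class DesignXi:
    """Allocation fractions over the four treatment combinations."""

    xi00: float
    xi10: float
    xi01: float
    xi11: float

    def __post_init__(self):
        for nm in ("xi00", "xi10", "xi01", "xi11"):
            if getattr(self, nm) < -1e-12:
                raise ValueError(f"{nm} must be nonnegative")
        if abs(self.xi00 + self.xi10 + self.xi01 + self.xi11 - 1.0) > 1e-12:
            raise ValueError("allocation fractions must sum to 1")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.xi00, self.xi10, self.xi01, self.xi11])

    @classmethod
    def balanced(cls) -> "DesignXi":
        return cls(0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class BackCalculated:
    """Pooled historical estimate of (eta0, eta1, eta2) with its covariance."""

    eta_hat: np.ndarray
    Sigma: np.ndarray
    m: int

    def to_historical_set(self) -> HistoricalSet:
        """Wrap as a single pre-aggregated historical study."""
        study = HistoricalStudy(label="pooled-historical", eta_hat=self.eta_hat,
                                cov=self.Sigma / self.m, m=self.m)
        return build_historical_set([study])


def sigma_balanced(sigma2: float = 1.0) -> np.ndarray:
    """sqrt(m)-scale historical covariance when both studies are balanced
    and of equal size."""
    return sigma2 * np.array([[2.0, -2.0, -2.0], [-2.0, 6.0, 2.0], [-2.0, 2.0, 6.0]])


def backcalculate_historical(report: HistoricalAnovaReport) -> BackCalculated:
    """Pool the two historical studies into one estimate of (eta0, eta1, eta2).

    The shared control mean eta0 is the size-weighted average of the two
    control arms; eta_i subtracts it from study i's treatment-arm mean.  The
    covariance follows from the estimates being a fixed linear map of four
    independent arm means with variances sigma2 / arm size.
    """
    r = report
    m0 = r.m_control_1 + r.m_control_2
    w1, w2 = r.m_control_1 / m0, r.m_control_2 / m0
    # arm means ordered (control1, treat1, control2, treat2)
    u = np.array([r.ybar_control_1, r.ybar_treat_1, r.ybar_control_2, r.ybar_treat_2])
    L = np.array([
        [w1, 0.0, w2, 0.0],    # eta0: weighted control average
        [-w1, 1.0, -w2, 0.0],  # eta1 = treat1 - eta0
        [-w1, 0.0, -w2, 1.0],  # eta2 = treat2 - eta0
    ])
    eta_hat = L @ u
    arm_var = r.sigma2 / np.array([r.m_control_1, r.m_treat_1,
                                   r.m_control_2, r.m_treat_2], dtype=float)
    cov = L @ np.diag(arm_var) @ L.T
    m = r.m
    return BackCalculated(eta_hat=eta_hat, Sigma=m * 0.5 * (cov + cov.T), m=m)


def upsilon_for_design(xi: DesignXi, sigma2: float = 1.0) -> PartitionedCov:
    """sqrt(n)-scale covariance of (theta~, eta~) for a four-arm design.

    Derived from the usual contrasts of the four independent arm means,
    whose sqrt(n)-scale variances are sigma2 / xi_ij.  All four fractions
    must be strictly positive.
    """
    x = xi.as_array
    if np.any(x <= 0):
        raise ValueError(
            "all four allocation fractions must be positive for the four-arm "
            "covariance; use the three-arm or plug-in (Type I) variants otherwise"
        )
    full = sigma2 * _L_FULL @ np.diag(1.0 / x) @ _L_FULL.T
    return PartitionedCov(full=0.5 * (full + full.T), p=1, q=3)


def anova_var_type1(rho: float, sigma2: float = 1.0) -> dict:
    """Variance of the plug-in interaction estimator, all-combination design.

    Returns the asymptotic value sigma2*(1+10*rho) and the exact
    finite-sample function sigma2*(1/n + 10/m).
    """
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    return {
        "asymptotic": sigma2 * (1.0 + 10.0 * rho),
        "exact": lambda n, m: sigma2 * (1.0 / n + 10.0 / m),
    }


def anova_var_type2(xi: DesignXi, rho: float, sigma2: float = 1.0,
                    Sigma: np.ndarray | None = None) -> float:
    """Asymptotic theta-variance of the two-step estimator for design xi.

    xi11^{-1}*sigma2 + 1^T (Ups_ee^{-1} + (rho Sigma)^{-1})^{-1} 1 with the
    design-based Ups_ee.  ``Sigma`` must include the sigma2 scale; defaults
    to the balanced-history matrix.
    """
    if xi.xi11 <= 0:
        raise ValueError("xi11 must be positive")
    S = sigma_balanced(sigma2) if Sigma is None else np.asarray(Sigma, dtype=float)
    ups_ee = upsilon_for_design(xi, sigma2).eta_eta
    K = _inv(_inv(ups_ee) + _inv(rho * S))
    one = np.ones(3)
    return float(sigma2 / xi.xi11 + one @ K @ one)


def anova_var_threearm(xi: DesignXi, rho: float, sigma2: float = 1.0,
                       Sigma: np.ndarray | None = None) -> float:
    """Asymptotic theta-variance for the no-control three-arm design.

    Requires xi00 = 0.  The single-treatment arm means carry information
    A eta with A = [[1,1,0],[1,0,1]]; their information term vanishes as
    xi10 = xi01 -> 0, recovering the plug-in (Type I) value sigma2*(1+10*rho).
    """
    if abs(xi.xi00) > 1e-12:
        raise ValueError("the three-arm design requires xi00 = 0")
    if xi.xi11 <= 0:
        raise ValueError("xi11 must be positive")
    S = sigma_balanced(sigma2) if Sigma is None else np.asarray(Sigma, dtype=float)
    one = np.ones(3)
    if xi.xi10 <= 0 and xi.xi01 <= 0:
        K = rho * S
    else:
        if xi.xi10 <= 0 or xi.xi01 <= 0:
            raise ValueError("xi10 and xi01 must both be positive (or both zero)")
        V = sigma2 * np.diag([1.0 / xi.xi10, 1.0 / xi.xi01])
        K = _inv(_A_THREEARM.T @ _inv(V) @ _A_THREEARM + _inv(rho * S))
    return float(sigma2 / xi.xi11 + one @ K @ one)


def _eta_cov_batch(xi00: np.ndarray, xi10: np.ndarray, xi01: np.ndarray,
                   sigma2: float) -> np.ndarray:
    """Design-based Ups_ee for a batch of allocations (vectorized)."""
    N = len(xi00)
    U = np.empty((N, 3, 3))
    a = sigma2 / xi00
    U[:, 0, 0] = a
    U[:, 0, 1] = U[:, 1, 0] = -a
    U[:, 0, 2] = U[:, 2, 0] = -a
    U[:, 1, 1] = a + sigma2 / xi10
    U[:, 2, 2] = a + sigma2 / xi01
    U[:, 1, 2] = U[:, 2, 1] = a
    return U


def optimize_design(rho: float, step: float = 0.001, min_xi00: float = 0.02,
                    sigma2: float = 1.0, Sigma: np.ndarray | None = None,
                    allow_asymmetric: bool = False):
    """Grid search for the variance-minimizing four-arm allocation.

    By default the search is restricted to symmetric designs xi01 = xi10
    (optimal for a symmetric historical covariance) with xi00 = 1 - 2*xi10 -
    xi11 constrained to at least ``min_xi00`` (the design covariance is
    singular at xi00 = 0).  Ties are broken toward larger xi11, then larger
    xi10.  Returns (DesignXi, minimal variance).
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    S = sigma_balanced(sigma2) if Sigma is None else np.asarray(Sigma, dtype=float)
    k = int(round(1.0 / step))
    if allow_asymmetric:
        grids = np.arange(1, k, dtype=float) * step
        combos = [(a, b, c) for a in grids for b in grids for c in grids
                  if 1.0 - a - b - c >= min_xi00 - 1e-12]
        if len(combos) > 5_000_000:
            raise ValueError("asymmetric grid too large; increase the step size")
        if not combos:
            raise ValueError("empty feasible grid")
        arr = np.array(combos)
        xi10a, xi01a, xi11a = arr[:, 0], arr[:, 1], arr[:, 2]
        xi00a = 1.0 - xi10a - xi01a - xi11a
    else:
        vals = np.arange(k - 1, 0, -1, dtype=float) * step  # descending for tie-breaks
        x11g, x10g = np.meshgrid(vals, vals, indexing="ij")
        x11g, x10g = x11g.ravel(), x10g.ravel()
        feas = 1.0 - 2.0 * x10g - x11g >= min_xi00 - 1e-12
        xi11a, xi10a = x11g[feas], x10g[feas]
        # order by descending xi11 then descending xi10 so argmin tie-breaks
        order = np.lexsort((-xi10a, -xi11a))
        xi11a, xi10a = xi11a[order], xi10a[order]
        xi01a = xi10a
        xi00a = 1.0 - 2.0 * xi10a - xi11a
        if len(xi11a) == 0:
            raise ValueError("empty feasible grid")
    U = _eta_cov_batch(xi00a, xi10a, xi01a, sigma2)
    K = np.linalg.inv(np.linalg.inv(U) + np.linalg.inv(rho * S)[None])
    values = sigma2 / xi11a + K.sum(axis=(1, 2))
    i = int(np.argmin(values))
    best = DesignXi(xi00=float(xi00a[i]), xi10=float(xi10a[i]),
                    xi01=float(xi01a[i]), xi11=float(xi11a[i]))
    return best, float(values[i])


def make_psi(with_gamma: bool = True) -> EstimatingFunction:
    """Closed-form estimating functions for the factorial model.

    Rows carry (t1, t2, y).  psi contributes only on the combination arm:
    1{t1=t2=1} * (y - eta0 - eta1 - eta2 - theta).  gamma is the normal score
    for eta at unit variance: x * (y - x'eta - theta*t1*t2), x = (1, t1, t2).
    """

    def psi(theta, eta, y):
        t1, t2, val = y[0], y[1], y[2]
        return np.array([t1 * t2 * (val - eta[0] - eta[1] * t1 - eta[2] * t2 - theta[0])])

    def gamma(theta, eta, y):
        t1, t2, val = y[0], y[1], y[2]
        x = np.array([1.0, t1, t2])
        resid = val - eta[0] - eta[1] * t1 - eta[2] * t2 - theta[0] * t1 * t2
        return x * resid

    return EstimatingFunction(psi=psi, p=1, q=3, gamma=gamma if with_gamma else None)


def _arm_summaries(data: ObservationSet) -> dict:
    df = data.frame
    out = {}
    for (t1, t2), grp in df.groupby(["t1", "t2"]):
        out[f"{int(t1)}{int(t2)}"] = (float(grp["y"].mean()), len(grp))
    return out


def estimate_anova(data: ObservationSet, hist: HistoricalSet | BackCalculated,
                   kind: str, sigma2: float | None = None) -> EstimateResult:
    """Closed-form interaction estimators for the factorial designs.

    ``kind``: "type1" (combination arm only; plug-in), "type2" (four arms;
    two-step with the design-based covariance), "type2_summary" (four arms;
    summary combination), or "threearm" (no control arm).  ``sigma2``
    defaults to the pooled within-arm residual variance.
    """
    if isinstance(hist, BackCalculated):
        hist = hist.to_historical_set()
    arms = _arm_summaries(data)
    if "11" not in arms:
        raise ValueError("the combination arm (t1=1, t2=1) is required")
    if sigma2 is None:
        df = data.frame
        resid = df["y"] - df.groupby(["t1", "t2"])["y"].transform("mean")
        dof = len(df) - df.groupby(["t1", "t2"]).ngroups
        sigma2 = float((resid ** 2).sum() / max(dof, 1))

    n = data.n
    if kind == "type1":
        missing = [a for a in ("00", "10", "01") if a in arms]
        if missing:
            raise ValueError(
                f"plug-in design expects only the combination arm; found arms {missing}"
            )
        ef = make_psi(with_gamma=False)
        res = estimate_type_a(ef, data, hist,
                              init=[arms["11"][0] - hist.eta_hat.sum()])
        # model-based variance: for the all-combination linear model the
        # estimating-function moments are known up to sigma2
        from .avar import avar_type_a
        from .estimating import JacobianSet

        jac = JacobianSet(D_theta=[[-1.0]], D_eta=[[-1.0, -1.0, -1.0]],
                          meat=[[sigma2]])
        cov, _ = avar_type_a(jac, hist, n / hist.m)
        return EstimateResult(theta_bar=res.theta_bar, eta_bar=res.eta_bar,
                              avar=cov, kind="A", n=n, m=hist.m,
                              diagnostics=res.diagnostics)
    if kind in ("type2", "type2_summary"):
        missing = [a for a in ARM_ORDER if a not in arms]
        if missing:
            raise ValueError(f"four-arm design requires arms {missing}")
        xi = DesignXi(*[arms[a][1] / n for a in ARM_ORDER])
        ups = upsilon_for_design(xi, sigma2)
        if kind == "type2":
            ef = make_psi(with_gamma=True)
            means = {a: arms[a][0] for a in ARM_ORDER}
            init = np.array([
                means["11"] - means["10"] - means["01"] + means["00"],
                means["00"], means["10"] - means["00"], means["01"] - means["00"],
            ])
            return estimate_type_b(ef, data, hist, init=init, upsilon=ups)
        omega = _L_FULL @ np.array([arms[a][0] for a in ARM_ORDER])
        current = CurrentSummary(theta_tilde=omega[:1], eta_tilde=omega[1:],
                                 upsilon=ups, n=n)
        return estimate_type_c(current, hist)
    if kind == "threearm":
        if "00" in arms:
            raise ValueError("three-arm design excludes the control arm")
        for a in ("10", "01"):
            if a not in arms:
                raise ValueError(f"three-arm design requires arm {a}")
        xi10, xi01 = arms["10"][1] / n, arms["01"][1] / n
        xi11 = arms["11"][1] / n
        S = np.array([arms["10"][0], arms["01"][0]])
        V = sigma2 * np.diag([1.0 / xi10, 1.0 / xi01])
        eta_dag = pool_linear(S, _A_THREEARM, V, hist, n)
        theta_d = arms["11"][0] - eta_dag.sum()
        rho = n / hist.m
        xi = DesignXi(0.0, xi10, xi01, xi11)
        var = anova_var_threearm(xi, rho, sigma2,
                                 Sigma=hist.Sigma if hist.q == 3 else None)
        K = _inv(_A_THREEARM.T @ _inv(V) @ _A_THREEARM + _inv(rho * hist.Sigma))
        one = np.ones(3)
        te = -(one @ K)[None, :]
        cov = PartitionedCov.from_blocks(np.array([[var]]), te, K)
        return EstimateResult(theta_bar=np.array([theta_d]), eta_bar=eta_dag,
                              avar=cov, kind="D", n=n, m=hist.m,
                              diagnostics={"sigma2": sigma2})
    raise ValueError(f"unknown design kind {kind!r}")


def anova_table(sizes: Sequence[int] = (100, 200, 500, 1000, 2000, 5000),
                sigma2: float = 1.0) -> pd.DataFrame:
    """Plug-in and two-step asymptotic variances over a grid of (n, m).

    Rows are current-study sizes n, columns historical sizes m; each cell
    holds the pair (plug-in, two-step) for the all-combination and balanced
    four-arm designs respectively.
    """
    rows = []
    for n in sizes:
        for m in sizes:
            rho = n / m
            rows.append({
                "n": n, "m": m, "rho": rho,
                "A_theta_theta": anova_var_type1(rho, sigma2)["asymptotic"],
                "B_theta_theta": anova_var_type2(DesignXi.balanced(), rho, sigma2),
            })
    return pd.DataFrame(rows)
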