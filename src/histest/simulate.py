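"""Seeded generators and Monte-Carlo validation of the asymptotic formulas.

The generators emulate the interchangeability assumption: historical and
current experimental units are drawn from one population, so arm means
differ only through the treatment received.  ANOVA scenarios draw normal
outcomes with the factorial mean structure; the drug-interaction scenario
draws binomial no-effect counts.  ``mc_validate`` replays the full pipeline
(fresh historical and current data each replication), compares the
empirical covariance of sqrt(n)*(estimate - truth) with the theoretical
matrix, and computes Wald coverage.

For the normal model the arm means and within-arm sums of squares are
sufficient, and their sampling distributions are exact (normal and scaled
chi-square); the Monte-Carlo harness therefore simulates these sufficient
statistics directly, which is distributionally identical to drawing raw
observations and keeps large replication counts cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .anova import (AnovaParams, DesignXi, sigma_balanced,
                    anova_var_threearm, upsilon_for_design, _A_THREEARM, _L_FULL)
from .avar import PartitionedCov, _inv, loewner_leq
from .bliss import ArmCounts, BlissParams, bliss_phi
from .estimating import ObservationSet
from .pooling import HistoricalSet

__all__ = ["SimConfig", "MCReport", "simulate_current", "simulate_historical",
           "mc_validate", "jackknife_se_var"]

_Z975 = float(stats.norm.ppf(0.975))

SCENARIOS = ("anova_type1", "anova_type2", "anova_threearm", "bliss")


@dataclass(frozen=True)
class SimConfig:
    scenario: str
    params: Union[AnovaParams, BlissParams]
    n: int
    m: int
    design: Union[DesignXi, ArmCounts, None] = None
    reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.scenario == "anova_type1" and self.design is None:
            object.__setattr__(self, "design", DesignXi(0.0, 0.0, 0.0, 1.0))
        if self.scenario == "anova_type2" and self.design is None:
            object.__setattr__(self, "design", DesignXi.balanced())


@dataclass(frozen=True)
class MCReport:
    empirical_cov: np.ndarray
    asymptotic_cov: np.ndarray
    max_abs_rel_gap: float
    coverage: dict
    loewner_checks: tuple = field(default_factory=tuple)
    var_theta_empirical: float = float("nan")
    var_theta_theory: float = float("nan")
    var_theta_mcse: float = float("nan")
    reps: int = 0
    failures: int = 0

    def to_dict(self) -> dict:
        return {
            "empirical_cov": np.asarray(self.empirical_cov).tolist(),
            "asymptotic_cov": np.asarray(self.asymptotic_cov).tolist(),
            "max_abs_rel_gap": self.max_abs_rel_gap,
            "coverage": self.coverage,
            "loewner_checks": [[lbl, bool(ok)] for lbl, ok in self.loewner_checks],
            "var_theta_empirical": self.var_theta_empirical,
            "var_theta_theory": self.var_theta_theory,
            "var_theta_mcse": self.var_theta_mcse,
            "reps": self.reps,
            "failures": self.failures,
        }


def _rng(seed: int, rep: int) -> np.random.Generator:
    # one stream per replication: order-independent and parallel-safe
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(rep,)))


def _anova_arm_counts(n: int, xi: DesignXi) -> dict[str, int]:
    counts = {}
    arms = {"00": xi.xi00, "10": xi.xi10, "01": xi.xi01, "11": xi.xi11}
    for arm, frac in arms.items():
        c = int(round(n * frac))
        if frac > 0 and c == 0:
            raise ValueError(
                f"arm {arm} has positive fraction {frac} but rounds to zero "
                f"observations at n={n}; increase n"
            )
        counts[arm] = c
    drift = n - sum(counts.values())
    if drift:
        biggest = max(counts, key=counts.get)
        counts[biggest] += drift
    return counts


def simulate_current(cfg: SimConfig, rep: int = 0) -> ObservationSet:
    """One current-study dataset: factorial normal outcomes or binomial arms."""
    rng = _rng(cfg.seed, rep)
    if cfg.scenario == "bliss":
        counts: ArmCounts = cfg.design
        p = cfg.params
        rows = []
        for arm, c, prob in (("12", counts.n12, p.theta), ("1", counts.n1, p.eta1),
                             ("2", counts.n2, p.eta2)):
            y = rng.binomial(1, prob, size=c)
            rows.append(pd.DataFrame({"arm": arm, "y": y}))
        return ObservationSet(pd.concat(rows, ignore_index=True))
    params: AnovaParams = cfg.params
    xi: DesignXi = cfg.design
    counts = _anova_arm_counts(cfg.n, xi)
    sd = np.sqrt(params.sigma2)
    frames = []
    for arm, c in counts.items():
        if c == 0:
            continue
        t1, t2 = int(arm[0]), int(arm[1])
        y = rng.normal(params.arm_mean(t1, t2), sd, size=c)
        frames.append(pd.DataFrame({"t1": t1, "t2": t2, "y": y}))
    return ObservationSet(pd.concat(frames, ignore_index=True))


def simulate_historical(cfg: SimConfig, rep: int = 0) -> HistoricalSet:
    """Two balanced historical single-treatment studies, back-calculated.

    Each study has m/4 units on its treatment and m/4 on control; arm means
    and a pooled residual variance are computed and the shared control mean
    aggregated, exactly as a real analysis of reported summaries would.
    """
    if cfg.scenario == "bliss":
        raise ValueError("historical draws for the bliss scenario are binomial; "
                         "use mc_validate")
    rng = _rng(cfg.seed, 10_000_019 + rep)  # offset: independent of the current draw
    params: AnovaParams = cfg.params
    m_arm = cfg.m // 4
    if m_arm < 2:
        raise ValueError("m must be at least 8 for two balanced two-arm studies")
    sd = np.sqrt(params.sigma2)
    means = {"c1": params.eta0, "t1": params.eta0 + params.eta1,
             "c2": params.eta0, "t2": params.eta0 + params.eta2}
    ybar, ss = {}, 0.0
    for arm, mu in means.items():
        y = rng.normal(mu, sd, size=m_arm)
        ybar[arm] = float(y.mean())
        ss += float(((y - y.mean()) ** 2).sum())
    sigma2_hat = ss / (4 * m_arm - 4)
    from .anova import HistoricalAnovaReport, backcalculate_historical

    report = HistoricalAnovaReport(
        ybar_control_1=ybar["c1"], ybar_treat_1=ybar["t1"],
        m_control_1=m_arm, m_treat_1=m_arm,
        ybar_control_2=ybar["c2"], ybar_treat_2=ybar["t2"],
        m_control_2=m_arm, m_treat_2=m_arm, sigma2=sigma2_hat)
    return backcalculate_historical(report).to_historical_set()


def jackknife_se_var(x: np.ndarray) -> float:
    """Jackknife standard error of the sample variance of x."""
    x = np.asarray(x, dtype=float)
    R = len(x)
    if R < 3:
        return float("nan")
    S1, S2 = x.sum(), (x ** 2).sum()
    mean_loo = (S1 - x) / (R - 1)
    var_loo = (S2 - x ** 2 - (R - 1) * mean_loo ** 2) / (R - 2)
    return float(np.sqrt((R - 1) / R * ((var_loo - var_loo.mean()) ** 2).sum()))


def _hist_draw(rng, params: AnovaParams, m: int):
    """Sufficient statistics of the two balanced historical studies."""
    m_arm = m // 4
    se = np.sqrt(params.sigma2 / m_arm)
    mu = np.array([params.eta0, params.eta0 + params.eta1,
                   params.eta0, params.eta0 + params.eta2])
    u = rng.normal(mu, se)
    dof = 4 * (m_arm - 1)
    sigma2_hat = params.sigma2 * rng.chisquare(dof) / dof
    L = np.array([[0.5, 0, 0.5, 0], [-0.5, 1, -0.5, 0], [-0.5, 0, -0.5, 1]])
    eta_hat = L @ u
    Sigma_hat = sigma_balanced(sigma2_hat)
    return eta_hat, Sigma_hat, sigma2_hat


def _anova_truth(params: AnovaParams):
    return np.array([params.theta, params.eta0, params.eta1, params.eta2])


def mc_validate(cfg: SimConfig, estimator_kind: str = "auto") -> MCReport:
    """Replicate the full analysis pipeline and compare with the theory.

    Each replication draws fresh historical and current data, runs the
    estimator matching the scenario (plug-in for the all-combination design,
    two-step for the four-arm design, linear pooling for the three-arm
    design, plug-in frequencies for the interaction study), and records the
    estimate and its Wald interval.  The report contrasts the empirical
    covariance of sqrt(n)*(estimate - truth) with the theoretical limit and
    lists the Loewner-order checks on the theoretical matrices.
    """
    if cfg.scenario == "bliss":
        return _mc_bliss(cfg)
    params: AnovaParams = cfg.params
    n, m, reps = cfg.n, cfg.m, cfg.reps
    rho = n / m
    truth = _anova_truth(params)
    Sigma0 = sigma_balanced(params.sigma2)
    kind = {"anova_type1": "A", "anova_type2": "B",
            "anova_threearm": "D"}[cfg.scenario] if estimator_kind == "auto" else estimator_kind

    ests = np.empty((reps, 4))
    covered = np.zeros(reps, dtype=bool)
    failures = 0
    one = np.ones(3)
    xi: DesignXi = cfg.design

    if kind in ("B", "C") and cfg.scenario != "anova_type2":
        raise ValueError("two-step/summary estimators need the four-arm scenario")

    for r in range(reps):
        rng = _rng(cfg.seed, r)
        eta_hat, Sigma_hat, s2_hist = _hist_draw(rng, params, m)
        if kind == "A":
            ybar12 = rng.normal(params.arm_mean(1, 1), np.sqrt(params.sigma2 / n))
            dof = n - 1
            s2_cur = params.sigma2 * rng.chisquare(dof) / dof
            theta_bar = ybar12 - eta_hat.sum()
            s2_pool = ((n - 1) * s2_cur + (m - 4) * s2_hist) / (n + m - 5)
            se = np.sqrt(s2_pool * (1.0 / n + 10.0 / m))
            ests[r] = [theta_bar, *eta_hat]
        elif kind in ("B", "C"):
            counts = _anova_arm_counts(n, xi)
            arm_mu = {a: params.arm_mean(int(a[0]), int(a[1])) for a in counts}
            ybar = {a: rng.normal(arm_mu[a], np.sqrt(params.sigma2 / c))
                    for a, c in counts.items()}
            dof = n - 4
            s2_cur = params.sigma2 * rng.chisquare(dof) / dof
            omega_t = _L_FULL @ np.array([ybar[a] for a in ("00", "10", "01", "11")])
            theta_t, eta_t = omega_t[0], omega_t[1:]
            ups_ee = upsilon_for_design(xi, s2_cur).eta_eta
            P1, P2 = n * _inv(ups_ee), m * _inv(Sigma_hat)
            eta_bar = np.linalg.solve(P1 + P2, P1 @ eta_t + P2 @ eta_hat)
            theta_bar = ybar["11"] - eta_bar.sum()
            K_hat = _inv(_inv(ups_ee) + _inv(rho * Sigma_hat))
            b_tt = s2_cur / xi.xi11 + one @ K_hat @ one
            se = np.sqrt(b_tt / n)
            ests[r] = [theta_bar, *eta_bar]
        else:  # three-arm pooling
            xi3: DesignXi = cfg.design
            counts = {a: int(round(n * f)) for a, f in
                      (("10", xi3.xi10), ("01", xi3.xi01), ("11", xi3.xi11))}
            ybar = {a: rng.normal(params.arm_mean(int(a[0]), int(a[1])),
                                  np.sqrt(params.sigma2 / c))
                    for a, c in counts.items()}
            dof = n - 3
            s2_cur = params.sigma2 * rng.chisquare(dof) / dof
            S = np.array([ybar["10"], ybar["01"]])
            V = s2_cur * np.diag([n / counts["10"], n / counts["01"]])
            P = n * _A_THREEARM.T @ _inv(V) @ _A_THREEARM + m * _inv(Sigma_hat)
            rhs = (n * _A_THREEARM.T @ _inv(V) @ S
                   + m * _inv(Sigma_hat) @ eta_hat)
            eta_dag = np.linalg.solve(P, rhs)
            theta_bar = ybar["11"] - eta_dag.sum()
            v = anova_var_threearm(xi3, rho, s2_cur,
                                   Sigma=Sigma_hat)
            se = np.sqrt(v / n)
            ests[r] = [theta_bar, *eta_dag]
        covered[r] = abs(ests[r, 0] - truth[0]) <= _Z975 * se

    dev = np.sqrt(n) * (ests - truth)
    emp = np.cov(dev.T)
    theory = _anova_theory_cov(cfg, kind, Sigma0)
    rel = np.abs(emp - theory.full) / np.maximum(np.abs(theory.full), 1e-8)
    checks = _theory_loewner_checks(cfg, Sigma0)
    return MCReport(
        empirical_cov=emp, asymptotic_cov=theory.full,
        max_abs_rel_gap=float(rel.max()),
        coverage={"theta": float(covered.mean())},
        loewner_checks=checks,
        var_theta_empirical=float(dev[:, 0].var(ddof=1)),
        var_theta_theory=float(theory.theta_theta[0, 0]),
        var_theta_mcse=jackknife_se_var(dev[:, 0]),
        reps=reps, failures=failures,
    )


def _anova_theory_cov(cfg: SimConfig, kind: str, Sigma0: np.ndarray) -> PartitionedCov:
    params: AnovaParams = cfg.params
    rho = cfg.n / cfg.m
    one = np.ones(3)
    if kind == "A":
        tt = params.sigma2 + rho * one @ Sigma0 @ one
        te = -rho * (one @ Sigma0)[None, :]
        return PartitionedCov.from_blocks(np.array([[tt]]), te, rho * Sigma0)
    if kind in ("B", "C"):
        xi: DesignXi = cfg.design
        ups_ee = upsilon_for_design(xi, params.sigma2).eta_eta
        K = _inv(_inv(ups_ee) + _inv(rho * Sigma0))
        tt = params.sigma2 / xi.xi11 + one @ K @ one
        te = -(one @ K)[None, :]
        return PartitionedCov.from_blocks(np.array([[tt]]), te, K)
    xi3: DesignXi = cfg.design
    V = params.sigma2 * np.diag([1 / xi3.xi10, 1 / xi3.xi01])
    K = _inv(_A_THREEARM.T @ _inv(V) @ _A_THREEARM + _inv(rho * Sigma0))
    tt = params.sigma2 / xi3.xi11 + one @ K @ one
    te = -(one @ K)[None, :]
    return PartitionedCov.from_blocks(np.array([[tt]]), te, K)


def _theory_loewner_checks(cfg: SimConfig, Sigma0: np.ndarray):
    """B <= A and C <= Upsilon on the scenario's theoretical matrices."""
    params: AnovaParams = cfg.params
    rho = cfg.n / cfg.m
    checks = []
    xi = cfg.design if isinstance(cfg.design, DesignXi) and cfg.design.xi00 > 0 \
        else DesignXi.balanced()
    ups = upsilon_for_design(xi, params.sigma2)
    one = np.ones(3)
    # plug-in vs two-step on the SAME four-arm design: the plug-in analysis
    # uses only the combination arm, so its theta-block is sigma2/xi11 plus
    # the full penalty rho 1' Sigma 1
    a_tt = params.sigma2 / xi.xi11 + rho * one @ Sigma0 @ one
    A = PartitionedCov.from_blocks(np.array([[a_tt]]),
                                   -rho * (one @ Sigma0)[None, :], rho * Sigma0)
    cfg_b = SimConfig(scenario="anova_type2", params=params, n=cfg.n, m=cfg.m,
                      design=xi, reps=1, seed=cfg.seed)
    B = _anova_theory_cov(cfg_b, "B", Sigma0)
    checks.append(("B_leq_A", loewner_leq(B.full, A.full)[0]))
    from .avar import avar_type_c
    from .pooling import HistoricalStudy, build_historical_set

    hist = build_historical_set([HistoricalStudy(
        label="theory", eta_hat=np.zeros(3), cov=Sigma0 / cfg.m, m=cfg.m)])
    C = avar_type_c(ups, hist, rho)
    checks.append(("C_leq_Upsilon", loewner_leq(C.full, ups.full)[0]))
    return tuple(checks)


def _mc_bliss(cfg: SimConfig) -> MCReport:
    params: BlissParams = cfg.params
    counts: ArmCounts = cfg.design
    reps = cfg.reps
    truth_phi = (np.log(params.theta) - np.log(params.eta1)
                 - np.log(params.eta2))
    phis = np.empty(reps)
    covered = np.zeros(reps, dtype=bool)
    failures = 0
    for r in range(reps):
        rng = _rng(cfg.seed, r)
        x1 = rng.binomial(counts.m1, params.eta1)
        x2 = rng.binomial(counts.m2, params.eta2)
        y12 = rng.binomial(counts.n12, params.theta)
        y1 = rng.binomial(counts.n1, params.eta1) if counts.n1 else 0
        y2 = rng.binomial(counts.n2, params.eta2) if counts.n2 else 0
        th = y12 / counts.n12
        e1 = (x1 + y1) / (counts.m1 + counts.n1)
        e2 = (x2 + y2) / (counts.m2 + counts.n2)
        if min(th, e1, e2) <= 0 or max(th, e1, e2) >= 1:
            failures += 1
            phis[r] = np.nan
            continue
        phi, se = bliss_phi(th, e1, e2, counts=counts)
        phis[r] = phi
        covered[r] = abs(phi - truth_phi) <= _Z975 * se
    if failures > 0.01 * reps:
        raise RuntimeError(f"{failures}/{reps} replications had degenerate arms")
    ok = ~np.isnan(phis)
    from .bliss import interaction_variance

    v_theory = interaction_variance(counts, params)
    emp = np.array([[np.var(phis[ok], ddof=1)]])
    rel = abs(emp[0, 0] - v_theory) / v_theory
    return MCReport(
        empirical_cov=emp, asymptotic_cov=np.array([[v_theory]]),
        max_abs_rel_gap=float(rel),
        coverage={"phi": float(covered[ok].mean())},
        loewner_checks=(),
        var_theta_empirical=float(emp[0, 0]),
        var_theta_theory=float(v_theory),
        var_theta_mcse=jackknife_se_var(phis[ok]),
        reps=reps, failures=failures,
    )
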