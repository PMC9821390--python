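"""Historical-estimate data model and precision-weighted pooling.

A historical study reports a parameter estimate, its finite-sample
covariance (or standard errors) and its sample size.  Several independent
studies are stacked into a single historical set with the block-diagonal
sqrt(m)-scale covariance Sigma = BlockDiag(kappa_1 Sigma_1, ..., kappa_K
Sigma_K), kappa_j = m/m_j.  Pooling combines the historical stack with the
current-study estimate of the same parameters by inverse-variance (GLS)
weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .avar import _inv, _sym

if TYPE_CHECKING:  # pragma: no cover
    from .estimators import CurrentSummary

logger = logging.getLogger(__name__)

__all__ = [
    "HistoricalStudy",
    "HistoricalSet",
    "PooledEta",
    "build_historical_set",
    "pool_eta",
    "pool_linear",
    "read_historical_csv",
]


@dataclass(frozen=True)
class HistoricalStudy:
    """One historical study: estimate, finite-sample covariance, size.

    ``cov`` is the covariance of the reported estimate itself (squared
    standard errors on the diagonal); the sqrt(m_j)-scale matrix Sigma_j is
    derived internally as m_j * cov, matching how published studies report
    uncertainty.
    """

    label: str
    eta_hat: np.ndarray
    cov: np.ndarray
    m: int

    def __post_init__(self):
        eta = np.atleast_1d(np.asarray(self.eta_hat, dtype=float))
        C = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "eta_hat", eta)
        object.__setattr__(self, "cov", _sym(C))
        if self.m < 1:
            raise ValueError(f"study {self.label!r}: sample size must be >= 1")
        if C.shape != (len(eta), len(eta)):
            raise ValueError(f"study {self.label!r}: covariance shape mismatch")
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"study {self.label!r}: covariance is not positive definite"
            ) from exc

    @property
    def q(self) -> int:
        return len(self.eta_hat)

    @property
    def Sigma(self) -> np.ndarray:
        """sqrt(m_j)-scale covariance of the study's estimate."""
        return self.m * self.cov


@dataclass(frozen=True)
class HistoricalSet:
    """K stacked independent historical studies."""

    studies: tuple[HistoricalStudy, ...]

    def __post_init__(self):
        if len(self.studies) < 1:
            raise ValueError("at least one historical study is required")
        object.__setattr__(self, "studies", tuple(self.studies))

    @property
    def K(self) -> int:
        return len(self.studies)

    @property
    def m(self) -> int:
        return sum(s.m for s in self.studies)

    @property
    def q(self) -> int:
        return sum(s.q for s in self.studies)

    @property
    def q_splits(self) -> list[int]:
        return [s.q for s in self.studies]

    @property
    def kappa(self) -> np.ndarray:
        m = self.m
        return np.array([m / s.m for s in self.studies])

    @property
    def eta_hat(self) -> np.ndarray:
        return np.concatenate([s.eta_hat for s in self.studies])

    @property
    def Sigma(self) -> np.ndarray:
        """Block-diagonal sqrt(m)-scale covariance of the stacked estimate."""
        blocks = [k * s.Sigma for k, s in zip(self.kappa, self.studies)]
        q = self.q
        out = np.zeros((q, q))
        pos = 0
        for b in blocks:
            d = b.shape[0]
            out[pos: pos + d, pos: pos + d] = b
            pos += d
        return out


def build_historical_set(studies: Sequence[HistoricalStudy]) -> HistoricalSet:
    """Assemble independent historical studies into a HistoricalSet."""
    return HistoricalSet(studies=tuple(studies))


@dataclass(frozen=True)
class PooledEta:
    """Inverse-variance pooled estimate of eta with its weight matrices.

    ``eta_bar = W1 eta_tilde + W2 eta_hat`` up to o_p(1), with W1 + W2 = I;
    ``cov_block`` is the sqrt(n)-scale covariance of the pooled estimate,
    (Upsilon_ee^{-1} + (rho Sigma)^{-1})^{-1}.
    """

    eta_bar: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    gamma: float
    rho: float
    cov_block: np.ndarray

    def __post_init__(self):
        resid = np.max(np.abs(self.W1 + self.W2 - np.eye(self.W1.shape[0])))
        if resid > 1e-10:
            raise AssertionError(f"W1 + W2 deviates from identity by {resid:.3e}")


def pool_eta(current: "CurrentSummary", hist: HistoricalSet) -> PooledEta:
    """Precision-weighted (GLS) pooling of current and historical eta.

    The pooled estimate solves
    (n Ups_ee^{-1} + m Sigma^{-1}) eta = n Ups_ee^{-1} eta_tilde + m Sigma^{-1} eta_hat,
    the normal-likelihood MLE when both covariances are treated as known.
    """
    eta_tilde = np.atleast_1d(np.asarray(current.eta_tilde, dtype=float))
    eta_hat = hist.eta_hat
    if len(eta_tilde) != len(eta_hat):
        raise ValueError(
            f"current eta has dimension {len(eta_tilde)} but historical stack has {len(eta_hat)}"
        )
    n, m = current.n, hist.m
    ups_ee = current.upsilon.eta_eta
    Sigma = hist.Sigma
    P1 = n * _inv(ups_ee)
    P2 = m * _inv(Sigma)
    eta_bar = np.linalg.solve(P1 + P2, P1 @ eta_tilde + P2 @ eta_hat)
    gamma = n / (n + m)
    rho = n / m
    W1 = np.linalg.solve(P1 + P2, P1)
    W2 = np.linalg.solve(P1 + P2, P2)
    cov_block = _inv(_inv(ups_ee) + _inv(rho * Sigma))
    return PooledEta(eta_bar=eta_bar, W1=W1, W2=W2, gamma=gamma, rho=rho,
                     cov_block=cov_block)


def pool_linear(S: np.ndarray, A: np.ndarray, V: np.ndarray,
                hist: HistoricalSet, n: int) -> np.ndarray:
    """Pool a linear summary S ~ (A eta, V/n) with the historical stack.

    Returns (n A^T V^{-1} A + m Sigma^{-1})^{-1} (n A^T V^{-1} S + m Sigma^{-1} eta_hat);
    with A = I and V = Ups_ee this reduces to ``pool_eta``.
    """
    S = np.atleast_1d(np.asarray(S, dtype=float))
    A = np.atleast_2d(np.asarray(A, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    m = hist.m
    Vinv = _inv(V)
    P = n * A.T @ Vinv @ A + m * _inv(hist.Sigma)
    rhs = n * A.T @ Vinv @ S + m * _inv(hist.Sigma) @ hist.eta_hat
    cond = np.linalg.cond(P)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"combined precision matrix is numerically singular (cond {cond:.3e})"
        )
    return np.linalg.solve(P, rhs)


def read_historical_csv(path, cov_path=None) -> HistoricalSet:
    """Read historical studies from CSV.

    Main file columns: study_id, param_name, estimate, se, m.  The optional
    companion file supplies within-study covariances with columns study_id,
    param_a, param_b, cov; missing off-diagonals default to 0 with a warning.
    """
    df = pd.read_csv(path)
    required = {"study_id", "param_name", "estimate", "se", "m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"historical CSV is missing columns: {sorted(missing)}")
    cov_df = pd.read_csv(cov_path) if cov_path is not None else None
    studies = []
    for sid, grp in df.groupby("study_id", sort=False):
        names = list(grp["param_name"])
        est = grp["estimate"].to_numpy(dtype=float)
        se = grp["se"].to_numpy(dtype=float)
        if np.any(se <= 0):
            raise ValueError(f"study {sid!r}: standard errors must be positive")
        m_vals = grp["m"].unique()
        if len(m_vals) != 1:
            raise ValueError(f"study {sid!r}: inconsistent sample size entries")
        C = np.diag(se ** 2)
        if cov_df is not None:
            sub = cov_df[cov_df["study_id"] == sid]
            for _, row in sub.iterrows():
                ia, ib = names.index(row["param_a"]), names.index(row["param_b"])
                C[ia, ib] = C[ib, ia] = float(row["cov"])
        elif len(names) > 1:
            logger.warning(
                "study %r: no covariance file given; off-diagonal covariances set to 0", sid
            )
        studies.append(HistoricalStudy(label=str(sid), eta_hat=est, cov=C,
                                       m=int(m_vals[0])))
    return build_historical_set(studies)
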