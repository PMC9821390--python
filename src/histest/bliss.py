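"""Design of single-dose drug-interaction studies under Bliss independence.

Two drugs with no-effect probabilities eta1 and eta2 are Bliss independent
when the combination's no-effect probability is theta = eta1*eta2.  The
interaction measure is the log contrast phi = log(theta) - log(eta1) -
log(eta2); phi < 0 indicates synergy, phi > 0 antagonism.  Historical
binomial experiments of sizes m1 and m2 provide estimates of eta1 and eta2;
a current study of size n allocates n12 units to the combination and n1, n2
units to replicating the single-drug arms.  The allocation minimizing the
large-sample variance of phi is found by a greedy procedure that assigns
each unit to the arm with the largest marginal variance reduction — the
objective is separable with decreasing marginal gains, so the greedy
allocation is exactly optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, sqrt

import numpy as np
import pandas as pd

__all__ = [
    "BlissParams",
    "ArmCounts",
    "AllocationResult",
    "NminResult",
    "bliss_phi",
    "interaction_variance",
    "greedy_allocate",
    "find_nmin",
    "bliss_table",
]


@dataclass(frozen=True)
class BlissParams:
    """No-effect probabilities of the single drugs and the combination."""

    eta1: float
    eta2: float
    theta: float

    def __post_init__(self):
        for nm in ("eta1", "eta2", "theta"):
            v = getattr(self, nm)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{nm} must lie strictly in (0, 1)")

    @classmethod
    def independent(cls, eta1: float, eta2: float) -> "BlissParams":
        """Parameters under the Bliss-independence null theta = eta1*eta2."""
        return cls(eta1=eta1, eta2=eta2, theta=eta1 * eta2)


@dataclass(frozen=True)
class ArmCounts:
    """Current-study arm sizes plus the historical binomial sizes."""

    n12: int
    n1: int
    n2: int
    m1: int
    m2: int

    def __post_init__(self):
        if min(self.n12, self.n1, self.n2) < 0:
            raise ValueError("arm counts must be nonnegative")
        if min(self.m1, self.m2) < 1:
            raise ValueError("historical sizes must be positive")

    @property
    def n(self) -> int:
        return self.n12 + self.n1 + self.n2


@dataclass(frozen=True)
class AllocationResult:
    counts: ArmCounts
    variance: float
    trace: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class NminResult:
    """Smallest n at which the optimal allocation replicates a historical arm."""

    n_min: int | None
    allocation: AllocationResult
    exceeded_n_max: bool = False


def bliss_phi(theta_hat: float, eta1_hat: float, eta2_hat: float,
              counts: ArmCounts | None = None):
    """Log-contrast interaction measure, optionally with its standard error.

    Returns phi = log(theta) - log(eta1) - log(eta2); with ``counts`` given,
    returns (phi, se) using the large-sample variance at the plug-in
    estimates.
    """
    for nm, v in (("theta_hat", theta_hat), ("eta1_hat", eta1_hat),
                  ("eta2_hat", eta2_hat)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{nm} must lie strictly in (0, 1): the log "
                             "contrast is undefined at 0 or 1")
    phi = log(theta_hat) - log(eta1_hat) - log(eta2_hat)
    if counts is None:
        return phi
    params = BlissParams(eta1=eta1_hat, eta2=eta2_hat, theta=theta_hat)
    return phi, sqrt(interaction_variance(counts, params))


def interaction_variance(counts: ArmCounts, params: BlissParams) -> float:
    """Large-sample variance of the log contrast at the given arm sizes.

    (1/n12)(1-theta)/theta + (1/(n1+m1))(1-eta1)/eta1
    + (1/(n2+m2))(1-eta2)/eta2.  Strictly decreasing in every count.
    """
    if counts.n12 < 1:
        raise ValueError("the interaction cannot be estimated unless n12 >= 1")
    return (
        (1.0 - params.theta) / params.theta / counts.n12
        + (1.0 - params.eta1) / params.eta1 / (counts.n1 + counts.m1)
        + (1.0 - params.eta2) / params.eta2 / (counts.n2 + counts.m2)
    )


def _odds(p: float) -> float:
    return (1.0 - p) / p


def greedy_allocate(n: int, m1: int, m2: int, eta1_hat: float, eta2_hat: float,
                    keep_trace: bool = False) -> AllocationResult:
    """Sequentially allocate n units to the arm that most reduces the variance.

    Design probabilities are the plug-ins eta1_hat, eta2_hat and theta =
    eta1_hat*eta2_hat (the estimate under Bliss independence).  The first
    unit is forced into the combination arm, where the variance is infinite
    otherwise.  Ties are broken combination arm first, then arm 1, then
    arm 2, so the returned allocation is deterministic; other optimal
    allocations may exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = BlissParams.independent(eta1_hat, eta2_hat)
    c12, c1, c2 = _odds(params.theta), _odds(params.eta1), _odds(params.eta2)
    n12 = n1 = n2 = 0
    trace: list[str] = []
    for _ in range(n):
        if n12 == 0:
            choice = "12"
        else:
            g12 = c12 / (n12 * (n12 + 1))
            g1 = c1 / ((n1 + m1) * (n1 + m1 + 1))
            g2 = c2 / ((n2 + m2) * (n2 + m2 + 1))
            if g12 >= g1 and g12 >= g2:
                choice = "12"
            elif g1 >= g2:
                choice = "1"
            else:
                choice = "2"
        if choice == "12":
            n12 += 1
        elif choice == "1":
            n1 += 1
        else:
            n2 += 1
        if keep_trace:
            trace.append(choice)
    counts = ArmCounts(n12=n12, n1=n1, n2=n2, m1=m1, m2=m2)
    return AllocationResult(counts=counts,
                            variance=interaction_variance(counts, params),
                            trace=tuple(trace))


def find_nmin(m1: int, m2: int, eta1_hat: float, eta2_hat: float,
              n_max: int = 10_000) -> NminResult:
    """Smallest current-study size at which a single-drug arm is replicated.

    The greedy allocations are nested in n, so this is the first step at
    which the greedy picks a non-combination arm.
    """
    result = greedy_allocate(n_max, m1, m2, eta1_hat, eta2_hat, keep_trace=True)
    for i, choice in enumerate(result.trace):
        if choice != "12":
            n_min = i + 1
            return NminResult(n_min=n_min,
                              allocation=greedy_allocate(n_min, m1, m2,
                                                         eta1_hat, eta2_hat))
    return NminResult(n_min=None, allocation=result, exceeded_n_max=True)


def bliss_table(eta_pairs=((0.3, 0.3), (0.3, 0.5), (0.3, 0.7), (0.3, 0.9),
                           (0.5, 0.7), (0.5, 0.9), (0.7, 0.7), (0.7, 0.9)),
                m_pairs=((10, 10), (20, 10), (30, 10), (10, 20), (10, 30)),
                n_max: int = 10_000) -> pd.DataFrame:
    """Tabulate n_min and its allocation over a grid of (eta1, eta2, m1, m2)."""
    rows = []
    for eta1, eta2 in eta_pairs:
        for m1, m2 in m_pairs:
            res = find_nmin(m1, m2, eta1, eta2, n_max=n_max)
            c = res.allocation.counts
            rows.append({"eta1": eta1, "eta2": eta2, "m1": m1, "m2": m2,
                         "n_min": res.n_min, "n12": c.n12, "n1": c.n1,
                         "n2": c.n2})
    return pd.DataFrame(rows)
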