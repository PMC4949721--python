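"""Variance decomposition, cluster-mean correlation and design effects.

The individual-level mixed model decomposes the total outcome variance
sigma1^2 into four nonnegative proportions:

    eta_C   random cluster intercepts,
    eta_S   random subject intercepts (cohort studies; 0 cross-sectionally),
    eta_CT  cluster-by-time fluctuations,
    eta_ST  subject-by-time / residual variation,

with eta_C + eta_S + eta_CT + eta_ST = 1.  With m observations per
cluster-period, the cluster-period means follow a compound-symmetric
model with

    sigma^2 = (eta_C + eta_S/m + eta_CT + eta_ST/m) * sigma1^2
    rho / (1 - rho) = (m eta_C + eta_S) / (m eta_CT + eta_ST)

and the single parameter that drives design efficiency is the
cluster-mean correlation (CMC)

    R = T rho / (1 + (T - 1) rho),

the proportion of a cluster-mean's variance arising from time-independent
random effects.  In a cross-sectional study R = M eta_C / (1 + (M-1) eta_C)
with M = T*m, linking R directly to the conventional ICC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .design import DesignCoefficients

__all__ = [
    "VarianceComponents",
    "ClusterMeanModel",
    "cluster_mean_model",
    "cmc",
    "design_effect",
]

_TOL = 1e-12


@dataclass(frozen=True)
class VarianceComponents:
    """Variance-component proportions of the individual-level model.

    All eta's are proportions of the total individual variance
    ``sigma1_sq`` and must sum to one.  ``m`` is the number of
    observations per cluster-period.
    """

    eta_C: float
    eta_S: float
    eta_ST: float
    eta_CT: float
    m: int
    sigma1_sq: float = 1.0

    def __post_init__(self):
        etas = (self.eta_C, self.eta_S, self.eta_ST, self.eta_CT)
        if any(e < 0 for e in etas):
            raise ValueError("variance proportions must be nonnegative")
        if abs(sum(etas) - 1.0) > _TOL:
            raise ValueError("eta_C + eta_S + eta_ST + eta_CT must equal 1")
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError("m must be a positive integer")
        if self.sigma1_sq <= 0:
            raise ValueError("sigma1_sq must be positive")

    @classmethod
    def cross_sectional(cls, icc: float, m: int, sigma1_sq: float = 1.0,
                        eta_CT: float = 0.0) -> "VarianceComponents":
        """Cross-sectional study: eta_S = 0; ``icc`` is the conventional
        intra-cluster correlation eta_C."""
        return cls(eta_C=icc, eta_S=0.0, eta_ST=1.0 - icc - eta_CT,
                   eta_CT=eta_CT, m=m, sigma1_sq=sigma1_sq)

    @property
    def is_cross_sectional(self) -> bool:
        return self.eta_S == 0 and self.eta_CT == 0


@dataclass(frozen=True)
class ClusterMeanModel:
    """Compound-symmetric model for the cluster-period means.

    ``sigma_sq`` is the variance of a single cluster-period mean, ``rho``
    the within-cluster correlation of two such means, and ``R`` the
    cluster-mean correlation at ``T`` time points.
    """

    T: int
    rho: float
    sigma_sq: float
    R: float

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (0 <= self.rho <= 1):
            raise ValueError("rho must lie in [0, 1]")
        if self.sigma_sq <= 0:
            raise ValueError("sigma_sq must be positive")
        if abs(self.R - cmc(self.T, self.rho)) > 1e-9:
            raise ValueError("R inconsistent with (T, rho)")

    @classmethod
    def from_rho(cls, T: int, rho: float, sigma_sq: float = 1.0) -> "ClusterMeanModel":
        return cls(T=T, rho=rho, sigma_sq=sigma_sq, R=cmc(T, rho))


def cmc(T: int, rho: float) -> float:
    """Cluster-mean correlation R(T, rho) = T rho / (1 + (T-1) rho).

    Strictly increasing in rho on (0, 1) for T >= 2 and in T for
    rho in (0, 1); R(1, rho) = rho.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 <= rho <= 1):
        raise ValueError("rho must lie in [0, 1]")
    return T * rho / (1 + (T - 1) * rho)


def cluster_mean_model(vc: VarianceComponents, T: int) -> ClusterMeanModel:
    """Aggregate individual-level components to the cluster-period-mean scale.

    Returns the (rho, sigma^2, R) triple implied by the variance
    decomposition.  When all time-varying variance vanishes
    (m*eta_CT + eta_ST = 0) the means are perfectly correlated and the
    model is returned at the boundary rho = R = 1.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    m = vc.m
    sigma_sq = (vc.eta_C + vc.eta_S / m + vc.eta_CT + vc.eta_ST / m) * vc.sigma1_sq
    num = m * vc.eta_C + vc.eta_S
    den = m * vc.eta_CT + vc.eta_ST
    if den == 0:
        rho = 1.0  # degenerate: no time-varying variance at the mean level
    else:
        rho = num / (num + den)
    return ClusterMeanModel(T=T, rho=rho, sigma_sq=sigma_sq, R=cmc(T, rho))


def design_effect(vc: VarianceComponents, coeffs: DesignCoefficients, T: int) -> float:
    """Design effect vs an individually randomised trial.

    DE = (m eta_CT + eta_ST) / (4 (a - b R)); multiplies the RCT sample
    size in power calculations.  For a cross-sectional parallel design it
    reduces to the classical 1 + (M - 1) eta_C with M = T*m.  A design
    with a - bR <= 0 has no information on the treatment effect and the
    design effect is infinite.
    """
    cm = cluster_mean_model(vc, T)
    factor = float(coeffs.precision_factor(cm.R))
    numer = vc.m * vc.eta_CT + vc.eta_ST
    if factor <= 0:
        return math.inf
    return numer / (4 * factor)
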