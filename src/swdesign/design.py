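"""Treatment-matrix calculus for stepped cluster designs.

A stepped cluster design is a K x T binary matrix J of treatment
indicators: J[i, j] = 1 if cluster i is exposed to the intervention at
observation time j.  Once the intervention is taken up it persists, so a
*stepped* design has nondecreasing rows (the irreversibility constraint).

Two design coefficients drive the precision of the best linear unbiased
estimate (BLUE) of the treatment effect under the mixed-effects model:

* ``a`` -- the within-column variance of J, averaged over columns,
* ``b`` -- the between-row variance of the row means,

both with equal weight on every lattice point.  The BLUE precision is

    Pi = K*T / (sigma^2 * (1 - rho)) * (a - b * R)

where ``sigma^2`` is the variance of a cluster-period mean, ``rho`` the
correlation of two cluster-period means within a cluster, and ``R`` the
cluster-mean correlation R = T*rho / (1 + (T-1)*rho).

An equivalent "lattice" form of the precision, valid for row-monotone
designs with clusters ordered by uptake time, maps the design onto a
centred unit-square lattice and sums the margin Rx_j - y_i over treated
points; it is the basis of the sweep-line optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Sequence

import numpy as np

__all__ = [
    "SteppedDesign",
    "DesignCoefficients",
    "Lattice",
    "coefficients",
    "precision",
    "relative_efficiency",
    "are",
    "lattice",
    "precision_lattice",
    "canonical_order",
]


def _as_fraction(x) -> Fraction:
    """Exact conversion of ints, Fractions and floats (floats are binary
    rationals, so this is lossless)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(x)


@dataclass(frozen=True)
class SteppedDesign:
    """A K x T binary treatment-indicator matrix.

    Parameters
    ----------
    J : array-like of 0/1, shape (K, T)
        Rows are clusters, columns are observation times.  Row 1 (index 0)
        is the earliest-uptake cluster under the canonical ordering.
    name : str, optional
        Display label.
    """

    J: np.ndarray
    name: str | None = None

    def __post_init__(self):
        J = np.asarray(self.J, dtype=np.int64)
        if J.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        if not np.isin(J, (0, 1)).all():
            raise ValueError("design matrix entries must be 0 or 1")
        object.__setattr__(self, "J", J)

    @property
    def K(self) -> int:
        return self.J.shape[0]

    @property
    def T(self) -> int:
        return self.J.shape[1]

    @property
    def n_treated(self) -> int:
        """Total number of treated lattice points, J_total."""
        return int(self.J.sum())

    def is_monotone(self) -> bool:
        """True if every row is nondecreasing (irreversibility)."""
        return bool((np.diff(self.J, axis=1) >= 0).all())

    def is_canonical(self) -> bool:
        """True if monotone and clusters are ordered by uptake time
        (row i treated whenever row i+1 is, column by column)."""
        return self.is_monotone() and bool((np.diff(self.J, axis=0) <= 0).all())

    def uptake_columns(self) -> np.ndarray:
        """First treated column index (1-based) per cluster; T+1 if never
        treated.  Requires a monotone design."""
        if not self.is_monotone():
            raise ValueError("uptake times are defined only for monotone designs")
        return self.T + 1 - self.J.sum(axis=1)

    def __eq__(self, other):
        if not isinstance(other, SteppedDesign):
            return NotImplemented
        return self.J.shape == other.J.shape and bool((self.J == other.J).all())


@dataclass(frozen=True)
class DesignCoefficients:
    """The pair (a, b): within-column and between-row variances of J.

    For any design 0 <= a <= 1/4; for stepped (irreversible) designs
    b <= a as well, so the precision factor a - b*R is nonnegative on
    R in [0, 1].
    """

    a: Fraction
    b: Fraction

    @property
    def four_a(self) -> Fraction:
        return 4 * self.a

    @property
    def four_b(self) -> Fraction:
        return 4 * self.b

    def precision_factor(self, R):
        """a - b*R, clamped at 0 against floating-point underflow."""
        v = self.a - self.b * R
        return v if v >= 0 else type(v)(0)


@dataclass(frozen=True)
class Lattice:
    """The centred design lattice: x_j = (j - (T+1)/2)/T, y_i = (i - (K+1)/2)/K.

    All points lie strictly inside a unit square centred on the origin and
    each coordinate sequence sums to zero.
    """

    x: tuple
    y: tuple


def coefficients(d: SteppedDesign) -> DesignCoefficients:
    """Design coefficients (a, b), computed exactly in rational arithmetic.

    ``a`` is the within-column variance of the indicators averaged over
    columns; ``b`` the variance of the row means.  Both are population
    (divide-by-N) variances with equal weight on all K*T lattice points.
    The formula applies to any 0/1 configuration, reversible or not.
    """
    J = d.J
    K, T = d.K, d.T
    n_j = J.sum(axis=0)  # column totals
    m_i = J.sum(axis=1)  # row totals
    tot = int(J.sum())
    # a = mean(J) - mean_j( col_mean_j^2 )
    a = Fraction(tot, K * T) - Fraction(int((n_j.astype(object) ** 2).sum()), T * K * K)
    # b = mean_i( row_mean_i^2 ) - mean(J)^2
    b = Fraction(int((m_i.astype(object) ** 2).sum()), K * T * T) - Fraction(tot, K * T) ** 2
    return DesignCoefficients(a, b)


def precision(d: SteppedDesign, R, sigma_sq, rho) -> float:
    """BLUE precision of the treatment effect: KT/(sigma^2 (1-rho)) (a - bR).

    ``rho`` must lie in [0, 1); for fixed cluster effects (the rho -> 1
    limit) evaluate at R = 1 and carry the 1/(1-rho) scale separately.
    """
    if not (0 <= R <= 1):
        raise ValueError("R must lie in [0, 1]")
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be positive")
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1); use the fixed-cluster-effects"
                         " form (R = 1) for rho = 1")
    c = coefficients(d)
    return float(d.K * d.T * c.precision_factor(R) / (sigma_sq * (1 - rho)))


def relative_efficiency(d: SteppedDesign, R):
    """Precision relative to the cluster cross-over design: 4(a - bR).

    The cluster-level variance parameters cancel, so efficiency depends on
    the design only through (a, b) and on the dependency structure only
    through the cluster-mean correlation R.
    """
    if not (0 <= R <= 1):
        raise ValueError("R must lie in [0, 1]")
    c = coefficients(d)
    return 4 * c.precision_factor(R)


def are(d: SteppedDesign):
    """Asymptotic relative efficiency vs the cross-over design (R -> 1):
    4a - 4b."""
    c = coefficients(d)
    return 4 * (c.a - c.b)


def lattice(K: int, T: int) -> Lattice:
    """Map row/column indices onto the centred unit-square lattice."""
    if K < 1 or T < 1:
        raise ValueError("K and T must be >= 1")
    x = tuple(Fraction(2 * j - T - 1, 2 * T) for j in range(1, T + 1))
    y = tuple(Fraction(2 * i - K - 1, 2 * K) for i in range(1, K + 1))
    return Lattice(x, y)


def precision_lattice(d: SteppedDesign, R, sigma_sq, rho) -> float:
    """Precision via the lattice (sweep-line) form.

    For a row-monotone design in canonical cluster order,

        KT (a - bR) = 2 sum_{ij} (R x_j - y_i) J_ij - R (J_tot - J_tot^2/(KT))

    which equals the standard form to rounding error.  Valid only under the
    irreversibility constraint with clusters ordered by uptake time;
    reversible designs (e.g. a cross-over) are rejected.
    """
    if not d.is_canonical():
        raise ValueError("the lattice precision form requires a row-monotone "
                         "design in canonical (uptake-ordered) cluster order")
    if not (0 <= R <= 1):
        raise ValueError("R must lie in [0, 1]")
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1)")
    lat = lattice(d.K, d.T)
    Rq = _as_fraction(R)
    s = Fraction(0)
    J = d.J
    for i in range(d.K):
        for j in range(d.T):
            if J[i, j]:
                s += Rq * lat.x[j] - lat.y[i]
    tot = d.n_treated
    val = 2 * s - Rq * (Fraction(tot) - Fraction(tot * tot, d.K * d.T))
    if val < 0:
        val = Fraction(0)
    return float(val / (_as_fraction(sigma_sq) * (1 - _as_fraction(rho))))


def canonical_order(d: SteppedDesign) -> SteppedDesign:
    """Sort clusters so that earlier uptake gets a smaller row index.

    Row permutations leave (a, b) and hence the precision unchanged; this
    merely produces the ordering assumed by the lattice form and by design
    schematics.
    """
    u = d.uptake_columns()
    order = np.argsort(u, kind="stable")
    return SteppedDesign(d.J[order], name=d.name)
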