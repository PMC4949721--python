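"""Sweep-line optimization of uptake-time configurations.

On the centred lattice, the precision of a row-monotone, uptake-ordered
design with J_tot treated points is (up to the variance scale)

    2 * sum_{treated} (R x_j - y_i)  -  R * (J_tot - J_tot^2 / (K T)).

For fixed J_tot only the first term varies, so the best configuration is
obtained by sweeping a straight line of slope R up the lattice and
treating points in decreasing order of the margin R x_j - y_i until
exactly J_tot are included.  The overall optimum maximizes over J_tot;
the best *balanced* design (BBD) fixes J_tot = KT/2, equivalently treats
every point below the boundary line y = R x through the origin plus half
of the points lying exactly on it.

Exact rational arithmetic (``fractions.Fraction``) is used whenever R is
supplied as a rational number, so boundary ties are detected exactly and
"balanced optimum equals overall optimum" is decided without tolerance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Iterator, Sequence

import numpy as np

from .design import SteppedDesign, coefficients, lattice, _as_fraction

__all__ = [
    "OptimizationResult",
    "BBDStructure",
    "best_for_total",
    "optimal_design",
    "best_balanced_design",
    "grid_study",
    "GridStudySummary",
    "enumerate_monotone",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class OptimizationResult:
    """An optimized design with its sigma-free precision factor a - bR."""

    design: SteppedDesign
    J_total: int
    precision_factor: object  # Fraction when R was rational, else float
    is_balanced: bool


@dataclass(frozen=True)
class BBDStructure:
    """Structure of a best balanced design: P always-treated clusters at
    the top, P never-treated at the bottom, and K - 2P genuinely stepped
    clusters in between.  ``l`` is set when the middle block is exactly a
    modified stepped wedge, which requires T = 2 (K - 2P) l."""

    P: int
    middle: int
    uptake_columns: tuple
    l: int | None


def _keys(K: int, T: int, R):
    """All lattice margins R x_j - y_i, sorted for the sweep.

    Ordering: decreasing margin; ties broken by later time column first,
    then smaller cluster index.  Returns a list of (key, i, j) with i, j
    zero-based.
    """
    lat = lattice(K, T)
    exact = isinstance(R, Rational)
    Rq = _as_fraction(R) if exact else float(R)
    pts = []
    for i in range(K):
        yi = lat.y[i] if exact else float(lat.y[i])
        for j in range(T):
            xj = lat.x[j] if exact else float(lat.x[j])
            pts.append((Rq * xj - yi, i, j))
    pts.sort(key=lambda t: (-t[0], -t[2], t[1]))
    return pts


def _design_from_points(K: int, T: int, chosen, name=None) -> SteppedDesign:
    J = np.zeros((K, T), dtype=int)
    for _, i, j in chosen:
        J[i, j] = 1
    d = SteppedDesign(J, name=name)
    if not d.is_canonical():  # the sweep guarantees this for R >= 0
        raise AssertionError("sweep produced a non-canonical design")
    return d


def _objective(prefix, J_total: int, N: int, R):
    """2 * prefix_sum - R * (J - J^2/N), the sigma-free lattice objective
    (equals KT (a - bR))."""
    if isinstance(R, Rational):
        return 2 * prefix[J_total] - _as_fraction(R) * (J_total - Fraction(J_total ** 2, N))
    return 2 * prefix[J_total] - R * (J_total - J_total ** 2 / N)


def _prefix_sums(pts):
    acc = Fraction(0) if isinstance(pts[0][0], Rational) else 0.0
    out = [acc]
    for k, _, _ in pts:
        acc = acc + k
        out.append(acc)
    return out


def best_for_total(K: int, T: int, R, J_total: int) -> OptimizationResult:
    """Best design with exactly ``J_total`` treated points.

    Treats the ``J_total`` lattice points with the largest margin
    R x_j - y_i.  Ties contribute the same objective value, so the
    deterministic tie-break (later column, then smaller cluster index)
    loses no precision.
    """
    N = K * T
    if not (1 <= J_total <= N - 1):
        raise ValueError("J_total must lie in [1, KT - 1]")
    if R < 0 or R > 1:
        raise ValueError("R must lie in [0, 1]")
    pts = _keys(K, T, R)
    chosen = pts[:J_total]
    d = _design_from_points(K, T, chosen)
    val = _objective(_prefix_sums(pts), J_total, N, R)
    if val < 0:
        val = val * 0
    return OptimizationResult(design=d, J_total=J_total,
                              precision_factor=val / N,
                              is_balanced=(2 * J_total == N))


def optimal_design(K: int, T: int, R) -> OptimizationResult:
    """Overall optimal uptake configuration: maximize the sweep objective
    over every treated-point total J_tot in {1, ..., KT-1}."""
    if K < 2 or T < 2:
        raise ValueError("K and T must be >= 2")
    N = K * T
    pts = _keys(K, T, R)
    prefix = _prefix_sums(pts)
    best_J, best_val = None, None
    for J_tot in range(1, N):
        val = _objective(prefix, J_tot, N, R)
        if best_val is None or val > best_val:
            best_J, best_val = J_tot, val
    d = _design_from_points(K, T, pts[:best_J])
    return OptimizationResult(design=d, J_total=best_J,
                              precision_factor=best_val / N,
                              is_balanced=(2 * best_J == N))


def best_balanced_design(K: int, T: int, R) -> tuple[OptimizationResult, BBDStructure]:
    """Best design among those with treated points equal to half the lattice.

    Construction: treat every point strictly below the boundary line
    y = R x, plus half of any points lying exactly on it (the first half
    in the deterministic tie order).  By the central symmetry of the
    lattice this always yields exactly KT/2 treated points.
    """
    N = K * T
    if N % 2:
        raise ValueError("KT must be even: no balanced design exists")
    if R < 0 or R > 1:
        raise ValueError("R must lie in [0, 1]")
    res = best_for_total(K, T, R, N // 2)
    d = res.design

    # structural summary
    row_tot = d.J.sum(axis=1)
    n_always = int((row_tot == T).sum())
    n_never = int((row_tot == 0).sum())
    P = min(n_always, n_never)
    middle = K - n_always - n_never
    uptake = tuple(int(u) for u, m in zip(d.uptake_columns(), row_tot)
                   if 0 < m < T)
    l = None
    if middle > 0 and T % (2 * middle) == 0:
        l_cand = T // (2 * middle)
        expected = tuple(l_cand + 2 * l_cand * k + 1 for k in range(middle))
        if uptake == expected:
            l = l_cand
    struct = BBDStructure(P=P, middle=K - 2 * P, uptake_columns=uptake, l=l)
    return OptimizationResult(design=d, J_total=N // 2,
                              precision_factor=res.precision_factor,
                              is_balanced=True), struct


def balanced_precision_factor(K: int, T: int, R: float) -> float:
    """Precision factor a - bR of the best balanced design, without
    constructing the matrix (float fast path for simulation loops)."""
    N = K * T
    if N % 2:
        raise ValueError("KT must be even")
    x = (np.arange(1, T + 1) - (T + 1) / 2) / T
    y = (np.arange(1, K + 1) - (K + 1) / 2) / K
    keys = (R * x[None, :] - y[:, None]).ravel()
    top = -np.partition(-keys, N // 2 - 1)[: N // 2]
    val = 2.0 * top.sum() - R * (N / 2) * 0.5
    return max(val, 0.0) / N


@dataclass(frozen=True)
class GridStudySummary:
    fraction_bbd_optimal: float
    min_rel_eff: float
    argmin_R: object
    mean_rel_eff: float
    rel_eff: tuple  # per-grid-point ratios, aligned with R_grid


def grid_study(K: int, T: int, R_grid: Sequence) -> GridStudySummary:
    """Compare the best balanced design with the overall optimum over a
    grid of cluster-mean correlations.

    For each R the relative efficiency is the ratio of precision factors
    (a - bR) of the BBD and the optimal design; the BBD counts as optimal
    when the ratio equals 1 (exactly for rational R, else within 1e-12).
    """
    N = K * T
    ratios = []
    n_opt = 0
    min_ratio, argmin_R = None, None
    for R in R_grid:
        exact = isinstance(R, Rational)
        pts = _keys(K, T, R)
        prefix = _prefix_sums(pts)
        best_val = max(_objective(prefix, J, N, R) for J in range(1, N))
        bbd_val = _objective(prefix, N // 2, N, R)
        ratio = bbd_val / best_val
        if (exact and ratio == 1) or (not exact and abs(ratio - 1) <= _TIE_TOL):
            n_opt += 1
        if min_ratio is None or ratio < min_ratio:
            min_ratio, argmin_R = ratio, R
        ratios.append(ratio)
    n = len(ratios)
    return GridStudySummary(
        fraction_bbd_optimal=n_opt / n,
        min_rel_eff=float(min_ratio),
        argmin_R=argmin_R,
        mean_rel_eff=float(sum(ratios) / n),
        rel_eff=tuple(ratios),
    )


def enumerate_monotone(K: int, T: int, cap: int = 10 ** 6) -> Iterator[SteppedDesign]:
    """Every uptake-ordered row-monotone K x T design, exactly once.

    Designs correspond to nondecreasing uptake vectors u in {1, ..., T+1}^K
    (u_i = first treated column; T+1 means never treated); there are
    C(T+K, K) of them.  Used as the brute-force oracle for the sweep.
    """
    n = math.comb(T + K, K)
    if n > cap:
        raise ValueError(f"enumeration size {n} exceeds cap {cap}")
    for u in itertools.combinations_with_replacement(range(1, T + 2), K):
        J = np.zeros((K, T), dtype=int)
        for i, ui in enumerate(u):
            if ui <= T:
                J[i, ui - 1:] = 1
        yield SteppedDesign(J)
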