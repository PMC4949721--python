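"""Named design families and their closed-form design coefficients.

The catalogue covers the classical layouts for stepped cluster studies:

* ``CXO``    cluster cross-over: half the clusters start treated and all
             cross over at mid-study (reversible; reference design),
* ``PD``     parallel design: half treated throughout, half control,
* ``DCD``    delay-control design DCD(p, q, r): all-control period of
             length pT, a parallel period qT, all-treated period rT,
* ``SW``     standard g-step stepped wedge: g equal cluster groups with
             uptake at time fractions 1/(g+1), ..., g/(g+1),
* ``MSW``    modified stepped wedge: uptake at (2k-1)/(2g), so the lead-in
             and tail periods are half the between-step spacing,
* ``HYBRID`` beta*K clusters in an MSW_g layout, the rest split equally
             between always-treated and never-treated (parallel) arms.

Closed-form (4a, 4b) values (exact under the divisibility conditions noted
on :func:`realize`):

=========  ==========================  =========================
family     4a                          4b
=========  ==========================  =========================
CXO        1                           0
PD         1                           1
DCD        q                           q^2
SW_g       (2/3)(1 - 1/g)              (1/3)(1 - 2/(g+1))
MSW_g      (2/3)(1 - 1/g^2)            (1/3)(1 - 1/g^2)
HYBRID     1 - (b^2/3)(1 + 2/g^2)      1 - (b/3)(2 + 1/g^2)
=========  ==========================  =========================

Unequal allocation in the parallel component (a proportion ``s`` of
control clusters, default 1/2) multiplies both coefficients of PD and DCD
by 4s(1-s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np

from .design import DesignCoefficients, SteppedDesign, coefficients, _as_fraction

__all__ = [
    "DesignFamilySpec",
    "closed_form_coefficients",
    "realize",
    "sw_vs_pd_threshold",
    "cxo",
    "parallel",
    "delay_control",
    "stepped_wedge",
    "modified_stepped_wedge",
    "hybrid",
]

_FAMILIES = {"CXO", "PD", "DCD", "SW", "MSW", "HYBRID"}


def _is_inf(g) -> bool:
    return g is not None and not isinstance(g, str) and math.isinf(g)


@dataclass(frozen=True)
class DesignFamilySpec:
    """Symbolic description of a catalogue design.

    ``g`` may be ``math.inf`` for the large-study stepped-wedge or hybrid
    limit; such specs have closed-form coefficients but cannot be realized
    as a finite matrix.
    """

    family: str
    g: object = None          # int or math.inf (SW / MSW / HYBRID)
    beta: object = None       # Fraction or float in [0, 1]  (HYBRID)
    p: object = None          # DCD time fractions, p + q + r = 1
    q: object = None
    r: object = None
    s: object = Fraction(1, 2)  # proportion of control clusters (PD / DCD)

    def __post_init__(self):
        fam = self.family.upper()
        if fam not in _FAMILIES:
            raise ValueError(f"unknown design family {self.family!r}")
        object.__setattr__(self, "family", fam)
        if fam in {"SW", "MSW", "HYBRID"}:
            g = self.g
            if g is None or (not _is_inf(g) and (int(g) != g or g < 1)):
                raise ValueError(f"{fam} requires a positive integer (or infinite) g")
        if fam == "HYBRID":
            if self.beta is None or not (0 <= self.beta <= 1):
                raise ValueError("HYBRID requires beta in [0, 1]")
        if fam == "DCD":
            p, q, r = (_as_fraction(v) for v in (self.p, self.q, self.r))
            if min(p, q, r) < 0 or p + q + r != 1:
                raise ValueError("DCD requires p, q, r >= 0 with p + q + r = 1")
            object.__setattr__(self, "p", p)
            object.__setattr__(self, "q", q)
            object.__setattr__(self, "r", r)
        if not (0 < _as_fraction(self.s) < 1):
            raise ValueError("s must lie in (0, 1)")
        object.__setattr__(self, "s", _as_fraction(self.s))

    @property
    def label(self) -> str:
        fam = self.family
        if fam == "SW":
            return f"SW_{self.g}"
        if fam == "MSW":
            return f"MSW_{self.g}"
        if fam == "HYBRID":
            return f"H({float(self.beta):g},{self.g})"
        if fam == "DCD":
            return f"DCD({float(self.p):g},{float(self.q):g},{float(self.r):g})"
        return fam


# -- convenience constructors ------------------------------------------------

def cxo() -> DesignFamilySpec:
    return DesignFamilySpec("CXO")


def parallel(s=Fraction(1, 2)) -> DesignFamilySpec:
    return DesignFamilySpec("PD", s=s)


def delay_control(p, q, r, s=Fraction(1, 2)) -> DesignFamilySpec:
    return DesignFamilySpec("DCD", p=p, q=q, r=r, s=s)


def stepped_wedge(g) -> DesignFamilySpec:
    return DesignFamilySpec("SW", g=g)


def modified_stepped_wedge(g) -> DesignFamilySpec:
    return DesignFamilySpec("MSW", g=g)


def hybrid(beta, g) -> DesignFamilySpec:
    return DesignFamilySpec("HYBRID", g=g, beta=beta)


def closed_form_coefficients(spec: DesignFamilySpec) -> DesignCoefficients:
    """Table of closed-form (a, b) pairs; exact rational arithmetic where
    the parameters are rational, with the g -> infinity limit substituted
    symbolically for infinite-g specs."""
    fam = spec.family
    if fam == "CXO":
        fa, fb = Fraction(1), Fraction(0)
    elif fam == "PD":
        fa, fb = Fraction(1), Fraction(1)
    elif fam == "DCD":
        q = _as_fraction(spec.q)
        fa, fb = q, q * q
    elif fam == "SW":
        if _is_inf(spec.g):
            fa, fb = Fraction(2, 3), Fraction(1, 3)
        else:
            g = int(spec.g)
            fa = Fraction(2, 3) * (1 - Fraction(1, g))
            fb = Fraction(1, 3) * (1 - Fraction(2, g + 1))
    elif fam == "MSW":
        if _is_inf(spec.g):
            fa, fb = Fraction(2, 3), Fraction(1, 3)
        else:
            g = int(spec.g)
            fa = Fraction(2, 3) * (1 - Fraction(1, g * g))
            fb = Fraction(1, 3) * (1 - Fraction(1, g * g))
    elif fam == "HYBRID":
        beta = _as_fraction(spec.beta)
        if _is_inf(spec.g):
            inv_g2 = Fraction(0)
        else:
            g = int(spec.g)
            inv_g2 = Fraction(1, g * g)
        fa = 1 - (beta * beta / 3) * (1 + 2 * inv_g2)
        fb = 1 - (beta / 3) * (2 + inv_g2)
    else:  # pragma: no cover
        raise AssertionError(fam)
    if fam in {"PD", "DCD"} and spec.s != Fraction(1, 2):
        scale = 4 * spec.s * (1 - spec.s)
        fa, fb = scale * fa, scale * fb
    return DesignCoefficients(fa / 4, fb / 4)


def _uptake_fractions(spec: DesignFamilySpec, K: int):
    """Per-cluster uptake time fractions in [0, 1], or None for
    never-treated clusters, in canonical (earliest-first) order, together
    with the list of strict divisibility conditions that must hold."""
    fam = spec.family
    conds: list[tuple[bool, str]] = []
    fracs: list = []
    s = spec.s
    if fam == "PD":
        n_ctrl = s * K
        conds.append((n_ctrl.denominator == 1, f"s*K = {s}*{K} must be an integer"))
        n_ctrl = int(n_ctrl) if n_ctrl.denominator == 1 else round(float(n_ctrl))
        fracs = [Fraction(0)] * (K - n_ctrl) + [None] * n_ctrl
    elif fam == "DCD":
        n_ctrl = s * K
        conds.append((n_ctrl.denominator == 1, f"s*K = {s}*{K} must be an integer"))
        n_ctrl = int(n_ctrl) if n_ctrl.denominator == 1 else round(float(n_ctrl))
        late = None if spec.r == 0 else spec.p + spec.q
        fracs = [spec.p] * (K - n_ctrl) + [late] * n_ctrl
    elif fam == "SW":
        g = int(spec.g)
        conds.append((K % g == 0, f"K = {K} must be a multiple of g = {g}"))
        size = K // g if K % g == 0 else None
        for k in range(1, g + 1):
            fracs.extend([Fraction(k, g + 1)] * (size or round(K / g)))
        fracs = fracs[:K]
    elif fam == "MSW":
        g = int(spec.g)
        conds.append((K % g == 0, f"K = {K} must be a multiple of g = {g}"))
        size = K // g if K % g == 0 else None
        for k in range(1, g + 1):
            fracs.extend([Fraction(2 * k - 1, 2 * g)] * (size or round(K / g)))
        fracs = fracs[:K]
    elif fam == "HYBRID":
        beta = _as_fraction(spec.beta)
        g = int(spec.g)
        n_sw = beta * K
        conds.append((n_sw.denominator == 1, f"beta*K = {beta}*{K} must be an integer"))
        n_sw = int(n_sw) if n_sw.denominator == 1 else round(float(n_sw))
        n_par = K - n_sw
        conds.append((n_par % 2 == 0, f"(1-beta)*K = {n_par} must be even"))
        if n_sw:
            conds.append((n_sw % g == 0,
                          f"beta*K = {n_sw} must be a multiple of g = {g}"))
        half = n_par // 2
        fracs = [Fraction(0)] * (n_par - half)
        size = n_sw // g if n_sw % g == 0 else max(1, round(n_sw / g))
        for k in range(1, g + 1):
            fracs.extend([Fraction(2 * k - 1, 2 * g)] * size)
        fracs = fracs[: K - half] + [None] * half
    else:  # pragma: no cover
        raise AssertionError(fam)
    return fracs, conds


def realize(spec: DesignFamilySpec, K: int, T: int, mode: str = "strict") -> SteppedDesign:
    """Construct the explicit K x T treatment matrix for a family spec.

    In ``strict`` mode the divisibility conditions under which the closed
    forms are exact must hold (e.g. SW_g: T a multiple of g+1 and K of g;
    MSW_g / HYBRID: T a multiple of 2g) and the matrix ANOVA reproduces
    :func:`closed_form_coefficients` exactly.  In ``approximate`` mode
    uptake times are rounded to the nearest column boundary and the closed
    forms are approximations.
    """
    if mode not in {"strict", "approximate"}:
        raise ValueError("mode must be 'strict' or 'approximate'")
    if _is_inf(getattr(spec, "g", None)):
        raise ValueError("infinite-g specs are symbolic and cannot be realized")
    fam = spec.family
    if fam == "CXO":
        if mode == "strict" and (K % 2 or T % 2):
            raise ValueError("strict CXO requires even K and even T")
        half_t = T // 2
        J = np.zeros((K, T), dtype=int)
        J[: (K + 1) // 2, :half_t] = 1
        J[(K + 1) // 2:, half_t:] = 1
        return SteppedDesign(J, name=spec.label)

    fracs, conds = _uptake_fractions(spec, K)
    # column-boundary conditions: uptake must fall on a lattice boundary
    for f in sorted({f for f in fracs if f is not None}):
        col = f * T
        conds.append((isinstance(col, Fraction) and col.denominator == 1,
                      f"uptake fraction {f} must land on a column boundary "
                      f"(T = {T})"))
    if mode == "strict":
        failed = [msg for ok, msg in conds if not ok]
        if failed:
            raise ValueError("strict-mode conditions violated: " + "; ".join(failed))
    J = np.zeros((K, T), dtype=int)
    for i, f in enumerate(fracs):
        if f is None:
            continue
        col = f * T
        start = int(col) if (isinstance(col, Fraction) and col.denominator == 1) \
            else round(float(col))
        J[i, start:] = 1
    return SteppedDesign(J, name=spec.label)


def sw_vs_pd_threshold(g: int, sw_type: str = "standard"):
    """Cluster-mean correlation above which a g-step wedge beats the
    parallel design: (1 + 1/g)/2 for the standard wedge and
    (g^2 + 2)/(2 g^2 + 1) for the modified wedge.  Both thresholds
    decrease to 1/2 as g grows: a wedge of either type can beat a parallel
    design only if R > 1/2."""
    if sw_type not in {"standard", "modified"}:
        raise ValueError("sw_type must be 'standard' or 'modified'")
    if _is_inf(g):
        return Fraction(1, 2)
    g = int(g)
    if g < 1:
        raise ValueError("g must be >= 1")
    if sw_type == "standard":
        return Fraction(1, 2) * (1 + Fraction(1, g))
    return Fraction(g * g + 2, 2 * g * g + 1)
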