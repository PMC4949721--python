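"""Large-study efficiency frontier, admissible hybrids and minimax design.

When both K and T are large the best achievable efficiency (relative to a
cluster cross-over) at cluster-mean correlation R is the quadratic

    frontier(R) = 1 - R + R^2 / 3,

attained by the hybrid design with a proportion beta = R of clusters in a
(large-g) modified stepped-wedge layout and the rest in a parallel
layout.  Hybrids are the admissible family: each generates a tangent to
the frontier, touching at R = beta, and every other stepped design is
weakly dominated by one of them.

If R is unknown, the minimax hybrid maximizes the guaranteed fraction of
the best achievable precision.  Equalizing the relative loss at the two
extremes R = 0 and R = 1 (the curve between is better than both, by the
convexity of the frontier) gives

    beta_minimax = (3 - sqrt(3)) / 2 = 0.634...,

which secures at least sqrt(3)/2 = 86.6% of the available precision for
every R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .families import DesignFamilySpec, closed_form_coefficients, hybrid

__all__ = [
    "frontier",
    "hybrid_efficiency",
    "minimax_beta",
    "LargeStudyEvaluation",
    "evaluate_near_minimax",
    "worst_relative_precision_vs_minimax",
    "table_near_minimax",
]

#: Denominator of the relative precision at R = 1: the efficiency of the
#: large-g modified stepped wedge, the best possible design there.
BEST_EFF_AT_1 = Fraction(1, 3)


def frontier(R):
    """Best achievable large-study efficiency vs the cross-over: 1 - R + R^2/3."""
    if not (0 <= R <= 1):
        raise ValueError("R must lie in [0, 1]")
    return 1 - R + R * R / 3


def hybrid_efficiency(beta, g, R):
    """Efficiency 4a - 4bR of the hybrid with SW proportion ``beta`` and
    ``g`` uptake points (``g`` may be ``math.inf``).

    For g = inf the curve is the tangent to the frontier at R = beta:
    it equals frontier(beta) there and lies below the frontier elsewhere.
    """
    c = closed_form_coefficients(hybrid(beta, g))
    return 4 * c.precision_factor(R)


def minimax_beta():
    """SW-cluster proportion of the large-study minimax hybrid: (3 - sqrt(3))/2."""
    return (3 - math.sqrt(3)) / 2


@dataclass(frozen=True)
class LargeStudyEvaluation:
    """Endpoint efficiencies and relative precisions of a hybrid design.

    Relative precision compares with the best possible large-study design:
    the parallel design (efficiency 1) at R = 0 and the large-g modified
    stepped wedge (efficiency 1/3) at R = 1.  For hybrids the relative
    precision curve is worst at an endpoint, so the worst relative
    precision (WRP) is min(rp_at_0, rp_at_1).
    """

    eff_at_0: float
    eff_at_1: float
    rp_at_0: float
    rp_at_1: float
    wrp: float

    def as_percent(self, ndigits: int = 1) -> tuple:
        """(rp_at_0, rp_at_1, wrp) as half-up rounded percentages."""
        return tuple(_round_half_up(100 * v, ndigits)
                     for v in (self.rp_at_0, self.rp_at_1, self.wrp))


def _round_half_up(x: float, ndigits: int) -> float:
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def evaluate_near_minimax(beta, g) -> LargeStudyEvaluation:
    """Endpoint performance of a (near-minimax) hybrid design."""
    e0 = float(hybrid_efficiency(beta, g, 0))
    e1 = float(hybrid_efficiency(beta, g, 1))
    rp0 = e0 / 1.0
    rp1 = e1 / float(BEST_EFF_AT_1)
    return LargeStudyEvaluation(eff_at_0=e0, eff_at_1=e1, rp_at_0=rp0,
                                rp_at_1=rp1, wrp=min(rp0, rp1))


def worst_relative_precision_vs_minimax(beta, g, grid_step: float = 1e-4) -> float:
    """Worst case over R of the hybrid's precision relative to the
    large-study minimax hybrid.

    Both curves are linear in R, so the ratio is monotone and the minimum
    sits at an endpoint; a dense grid is scanned anyway as a guard.
    """
    ca = closed_form_coefficients(hybrid(beta, g))
    cm = closed_form_coefficients(hybrid(minimax_beta(), math.inf))
    a1, b1 = float(ca.four_a), float(ca.four_b)
    a2, b2 = float(cm.four_a), float(cm.four_b)
    n = round(1 / grid_step)
    worst = math.inf
    for k in range(n + 1):
        R = k / n
        worst = min(worst, (a1 - b1 * R) / (a2 - b2 * R))
    return worst


def table_near_minimax(rows=None):
    """Evaluate a list of hybrid designs against the large-study optima.

    ``rows`` is a sequence of (label, n_parallel, n_sw, g) with ``None``
    entries allowed for the purely symbolic rows; defaults to nine
    near-minimax candidates plus the minimax, parallel and large-g
    stepped-wedge references.  Returns a list of dict records with 1-dp
    percentage columns.
    """
    if rows is None:
        rows = [
            ("1", 2, 3, 3), ("2", 2, 4, 4), ("3", 4, 6, 6), ("4", 4, 7, 7),
            ("5", 4, 8, 8), ("6", 6, 9, 9), ("7", 6, 10, 5), ("8", 6, 10, 10),
            ("9", 6, 12, 6),
            ("Minimax", None, None, math.inf),
            ("PD", None, None, None),
            ("SW_inf", None, None, math.inf),
        ]
    out = []
    for label, n_par, n_sw, g in rows:
        if label == "Minimax":
            beta = minimax_beta()
        elif label == "PD":
            beta, g = 0, 1  # g irrelevant at beta = 0
        elif label == "SW_inf":
            beta = 1
        else:
            beta = Fraction(n_sw, n_par + n_sw)
        ev = evaluate_near_minimax(beta, g)
        rp0, rp1, wrp = ev.as_percent(1)
        out.append({
            "label": label,
            "n_parallel": n_par,
            "n_sw": n_sw,
            "beta": float(beta),
            "g": g,
            "rp_at_0_pct": rp0,
            "rp_at_1_pct": rp1,
            "wrp_pct": wrp,
        })
    return out
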