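"""Sweep-line optimizer, best balanced designs and the enumeration oracle."""

import math
from fractions import Fraction

import numpy as np
import pytest

import swdesign as sw
from swdesign.optimize import balanced_precision_factor


def brute_force_best(K, T, R, J_total=None):
    """Exhaustive maximum of the precision factor over ordered monotone
    designs, optionally at fixed treated-point total."""
    best = None
    for d in sw.enumerate_monotone(K, T):
        tot = d.n_treated
        if tot in (0, K * T):
            continue
        if J_total is not None and tot != J_total:
            continue
        v = sw.coefficients(d).precision_factor(R)
        if best is None or v > best:
            best = v
    return best


class TestEnumeration:
    @pytest.mark.parametrize("K,T,count", [(2, 2, 6), (1, 1, 2), (6, 6, 924)])
    def test_counts_match_binomial(self, K, T, count):
        designs = list(sw.enumerate_monotone(K, T))
        assert len(designs) == count == math.comb(K + T, K)

    def test_designs_are_unique_and_canonical(self):
        seen = set()
        for d in sw.enumerate_monotone(3, 3):
            assert d.is_canonical()
            seen.add(d.J.tobytes())
        assert len(seen) == math.comb(6, 3)

    def test_cap(self):
        with pytest.raises(ValueError, match="cap"):
            next(sw.enumerate_monotone(30, 30, cap=1000))


class TestBestForTotal:
    def test_zero_cmc_fills_whole_clusters(self):
        # horizontal boundary: parallel-type layouts
        res = sw.best_for_total(6, 4, Fraction(0), 8)
        assert list(res.design.J.sum(axis=1)) == [4, 4, 0, 0, 0, 0]

    def test_unit_slope_diagonal(self):
        # R = 1, K = T: boundary of slope 1 through the lattice diagonal
        res = sw.best_for_total(4, 4, Fraction(1), 8)
        treated = res.design.J
        lat = sw.lattice(4, 4)
        for i in range(4):
            for j in range(4):
                key = lat.x[j] - lat.y[i]
                if key > 0:
                    assert treated[i, j] == 1
                elif key < 0:
                    assert treated[i, j] == 0

    def test_matches_brute_force_at_fixed_total(self):
        for K, T in [(2, 3), (3, 3), (4, 3), (4, 4)]:
            for Rk in range(0, 11, 2):
                R = Fraction(Rk, 10)
                for J_total in range(1, K * T):
                    res = sw.best_for_total(K, T, R, J_total)
                    assert res.precision_factor == brute_force_best(K, T, R, J_total)

    def test_out_of_range_total(self):
        with pytest.raises(ValueError):
            sw.best_for_total(3, 3, Fraction(1, 2), 0)
        with pytest.raises(ValueError):
            sw.best_for_total(3, 3, Fraction(1, 2), 9)


class TestOptimalDesign:
    def test_matches_brute_force(self):
        for K in range(2, 5):
            for T in range(2, 5):
                for Rk in range(0, 11):
                    R = Fraction(Rk, 10)
                    res = sw.optimal_design(K, T, R)
                    assert res.precision_factor == brute_force_best(K, T, R)
                    assert res.design.is_canonical()

    def test_two_by_two_at_zero_is_parallel(self):
        res = sw.optimal_design(2, 2, Fraction(0))
        assert (res.design.J == np.array([[1, 1], [0, 0]])).all()

    def test_ten_by_six_at_zero_is_parallel(self):
        res = sw.optimal_design(10, 6, Fraction(0))
        assert list(res.design.J.sum(axis=1)) == [6] * 5 + [0] * 5

    def test_ten_by_six_at_point_six_omits_diagonal(self):
        # the optimum drops all six boundary-line points, so it is unbalanced
        res = sw.optimal_design(10, 6, Fraction(3, 5))
        lat = sw.lattice(10, 6)
        on_diag = [(i, j) for i in range(10) for j in range(6)
                   if Fraction(3, 5) * lat.x[j] == lat.y[i]]
        assert len(on_diag) == 6
        assert all(res.design.J[i, j] == 0 for i, j in on_diag)
        assert res.J_total == 27


class TestBestBalancedDesign:
    def test_balance_and_value(self):
        for K, T in [(4, 4), (10, 6), (6, 8)]:
            for Rk in (0, 3, 6, 10):
                res, struct = sw.best_balanced_design(K, T, Fraction(Rk, 10))
                assert res.J_total == K * T // 2
                assert res.design.n_treated == K * T // 2
                assert res.precision_factor == \
                    sw.best_for_total(K, T, Fraction(Rk, 10), K * T // 2).precision_factor

    def test_odd_lattice_rejected(self):
        with pytest.raises(ValueError, match="even"):
            sw.best_balanced_design(3, 3, Fraction(1, 2))

    def test_transition_point_ties_have_equal_value(self):
        # at R = 0.12 the parallel layout and its neighbour are both BBDs
        res, _ = sw.best_balanced_design(10, 6, Fraction(12, 100))
        pd = sw.realize(sw.parallel(), 10, 6)
        c = sw.coefficients(pd)
        assert res.precision_factor == c.precision_factor(Fraction(12, 100))

    def test_parallel_layout_below_first_transition(self):
        res, struct = sw.best_balanced_design(10, 6, Fraction(1, 10))
        assert (res.design == sw.realize(sw.parallel(), 10, 6))
        assert struct.middle == 0

    def test_tie_split_at_point_six(self):
        # six lattice points sit exactly on the slope-0.6 diagonal; the BBD
        # treats half of them, and every resolution attains the same value
        R = Fraction(3, 5)
        res, struct = sw.best_balanced_design(10, 6, R)
        assert res.J_total == 30
        lat = sw.lattice(10, 6)
        ties = [(i, j) for i in range(10) for j in range(6)
                if R * lat.x[j] == lat.y[i]]
        n_treated_ties = sum(res.design.J[i, j] for i, j in ties)
        assert len(ties) == 6 and n_treated_ties == 3
        # alternative resolution: the hybrid H(0.6, 3) is one of the 20 BBDs
        h = sw.realize(sw.hybrid(Fraction(3, 5), 3), 10, 6)
        ch = sw.coefficients(h)
        assert ch.precision_factor(R) == res.precision_factor

    def test_structure_inequalities_on_grid(self):
        # K R (1 - 1/T) - 1 <= K - 2P <= K R (1 - 1/T) + 1
        for K in (4, 6, 10, 14, 20):
            for T in (2, 4, 6, 9, 12):
                if (K * T) % 2:
                    continue
                for Rk in range(0, 11):
                    R = Fraction(Rk, 10)
                    _, struct = sw.best_balanced_design(K, T, R)
                    bound = K * R * (1 - Fraction(1, T))
                    assert bound - 1 <= K - 2 * struct.P <= bound + 1

    def test_exact_msw_middle_block(self):
        # K = 4, T = 8, R = 4/7 puts 2 stepped clusters in the middle with
        # T = 2 * middle * l for l = 2: an exact modified-wedge block
        res, struct = sw.best_balanced_design(4, 8, Fraction(4, 7))
        assert struct.middle == 2
        assert struct.l == 2
        assert struct.uptake_columns == (3, 7)

    def test_fast_factor_agrees_with_construction(self, rng):
        for _ in range(50):
            K = int(rng.integers(2, 12))
            T = int(rng.integers(2, 12))
            if (K * T) % 2:
                T += 1
            R = float(rng.uniform())
            res, _ = sw.best_balanced_design(K, T, R)
            assert balanced_precision_factor(K, T, R) == pytest.approx(
                float(res.precision_factor), abs=1e-12)


class TestGridStudy:
    def test_relative_efficiency_never_exceeds_one(self):
        g = sw.grid_study(6, 4, [Fraction(k, 20) for k in range(21)])
        assert all(r <= 1 for r in g.rel_eff)

    def test_balance_is_optimal_at_zero_cmc(self):
        for K, T in [(4, 4), (6, 4), (10, 6)]:
            g = sw.grid_study(K, T, [Fraction(0)])
            assert g.fraction_bbd_optimal == 1.0

    def test_coarse_ten_by_six_summary(self):
        g = sw.grid_study(10, 6, [Fraction(k, 100) for k in range(101)])
        assert g.min_rel_eff == pytest.approx(0.98830, abs=1e-4)
        assert float(g.argmin_R) == 0.6
        assert g.mean_rel_eff > 0.998
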