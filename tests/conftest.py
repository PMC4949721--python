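"""Shared fixtures: the classic eight-cluster layouts and random designs."""

import numpy as np
import pytest
from fractions import Fraction

import swdesign as sw


@pytest.fixture(scope="session")
def eight_cluster_layouts():
    """The five classic eight-cluster schematics as strict realizations:
    cross-over, parallel, delay-control (1/6, 2/3, 1/6), four-step wedge
    and the 50:50 hybrid with g = 4."""
    return {
        "CXO": sw.realize(sw.cxo(), 8, 4),
        "PD": sw.realize(sw.parallel(), 8, 4),
        "DCD": sw.realize(sw.delay_control(Fraction(1, 6), Fraction(2, 3), Fraction(1, 6)), 8, 6),
        "SW4": sw.realize(sw.stepped_wedge(4), 8, 5),
        "H05_4": sw.realize(sw.hybrid(Fraction(1, 2), 4), 8, 8),
    }


def random_monotone_design(rng, K=None, T=None):
    K = K or int(rng.integers(2, 9))
    T = T or int(rng.integers(2, 9))
    u = np.sort(rng.integers(1, T + 2, K))
    J = np.zeros((K, T), dtype=int)
    for i, ui in enumerate(u):
        if ui <= T:
            J[i, ui - 1:] = 1
    return sw.SteppedDesign(J)


@pytest.fixture
def rng():
    return np.random.default_rng(20160107)
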