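"""Ground-truth verification: direct GLS precision and outcome simulation.

The closed-form precision formula is validated here by an independent
route.  The BLUE of the treatment effect depends on the data only through
the cluster-period means, which follow a compound-symmetric mixed model:
within each cluster the T means have covariance

    Sigma = sigma^2 [ (1 - rho) I + rho 11' ].

``gls_precision`` builds the full KT x KT problem with fixed time effects
(one per time point, or one per column group) and the treatment column,
whitens by the block Cholesky factor, and reads the precision of theta as
the residual sum of squares of the whitened treatment column after
projecting out the nuisance columns.  With random cluster effects this
must reproduce KT/(sigma^2 (1-rho)) * (a - bR); with fixed cluster
effects (cluster dummies in the mean, i.i.d. residuals) it must reproduce
the same expression evaluated at R = 1.

``simulate_outcomes`` draws individual-level data from the component
model and ``estimate_theta`` applies the GLS weights, so that the
empirical variance of theta-hat can be checked against 1/precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .design import SteppedDesign
from .variance import VarianceComponents, cluster_mean_model

__all__ = [
    "gls_precision",
    "simulate_outcomes",
    "estimate_theta",
    "OutcomeSample",
]

_RANK_TOL = 1e-10


def _whitener(T: int, rho: float, sigma_sq: float) -> np.ndarray:
    """Inverse Cholesky factor of the T x T compound-symmetry covariance."""
    Sigma = sigma_sq * ((1 - rho) * np.eye(T) + rho * np.ones((T, T)))
    L = np.linalg.cholesky(Sigma)
    return np.linalg.inv(L)


def _time_dummies(K: int, T: int, column_map: Sequence | None) -> np.ndarray:
    """KT x L fixed-effect matrix of time (or column-group) indicators,
    stacked cluster by cluster.  The intercept is absorbed in the time
    effects, so no global constant column is added."""
    if column_map is None:
        labels = list(range(T))
    else:
        if len(column_map) != T:
            raise ValueError("column_map must assign a label to each time point")
        labels = list(column_map)
    uniq = sorted(set(labels), key=labels.index)
    D = np.zeros((T, len(uniq)))
    for j, lab in enumerate(labels):
        D[j, uniq.index(lab)] = 1.0
    return np.tile(D, (K, 1))


def gls_precision(d: SteppedDesign, rho: float, sigma_sq: float = 1.0,
                  cluster_effects: str = "random",
                  column_map: Sequence | None = None) -> float:
    """Precision of the treatment-effect BLUE by direct generalized least
    squares on the cluster-period means.

    Parameters
    ----------
    d : SteppedDesign
    rho : correlation of cluster-period means within a cluster, in [0, 1).
    sigma_sq : variance of a cluster-period mean.
    cluster_effects : 'random' (compound-symmetric covariance) or 'fixed'
        (cluster-indicator dummies in the mean, i.i.d. residuals with
        variance (1-rho) sigma^2).
    column_map : optional labels collapsing time points into columns; the
        model then carries one time parameter per column.  Valid whenever
        the design has a single uptake pattern per column.

    Returns 0 (confounded) when the treatment column lies in the span of
    the nuisance effects.
    """
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1); use cluster_effects='fixed' "
                         "for the perfectly-correlated limit")
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be positive")
    if cluster_effects not in {"random", "fixed"}:
        raise ValueError("cluster_effects must be 'random' or 'fixed'")
    K, T = d.K, d.T
    j_col = d.J.reshape(-1).astype(float)  # KT vector, cluster-major
    Z = _time_dummies(K, T, column_map)
    if cluster_effects == "fixed":
        C = np.kron(np.eye(K), np.ones((T, 1)))
        Z = np.hstack([Z, C])
        scale = 1.0 / math.sqrt(sigma_sq * (1 - rho))
        Wj = scale * j_col
        WZ = scale * Z
    else:
        A = _whitener(T, rho, sigma_sq)  # T x T
        Wj = (A @ j_col.reshape(K, T).T).T.reshape(-1)
        WZ = np.vstack([A @ Z[i * T:(i + 1) * T] for i in range(K)])
    # precision of theta = squared norm of Wj's component orthogonal to WZ
    coef, *_ = np.linalg.lstsq(WZ, Wj, rcond=None)
    resid = Wj - WZ @ coef
    prec = float(resid @ resid)
    if prec <= _RANK_TOL * float(Wj @ Wj):
        return 0.0
    return prec


@dataclass(frozen=True)
class OutcomeSample:
    """One simulated replicate of the individual-level outcome model."""

    values: np.ndarray        # K x T x m
    cluster: np.ndarray       # c_i, K
    subject: np.ndarray       # s_l(i), K x m
    cluster_time: np.ndarray  # (ct)_ij, K x T
    subject_time: np.ndarray  # (st)_l(i)j, K x T x m
    theta: float
    seed: object


def simulate_outcomes(d: SteppedDesign, vc: VarianceComponents, theta: float,
                      time_effects: Sequence | None = None, n_reps: int = 1,
                      seed=None) -> Iterator[OutcomeSample]:
    """Draw replicates from the component model.

    Each observation is c_i + t_j + theta J_ij + (ct)_ij + s_l(i) +
    (st)_l(i)j with independent normal components at the stated
    variances; cluster-period means of a replicate then follow the
    compound-symmetric model used by the GLS oracle.
    """
    K, T, m = d.K, d.T, vc.m
    t = np.zeros(T) if time_effects is None else np.asarray(time_effects, float)
    if t.shape != (T,):
        raise ValueError("time_effects must have length T")
    rng = np.random.default_rng(seed)
    s1 = vc.sigma1_sq
    sd = {k: math.sqrt(v * s1) for k, v in
          dict(C=vc.eta_C, S=vc.eta_S, CT=vc.eta_CT, ST=vc.eta_ST).items()}
    for _ in range(n_reps):
        c = rng.normal(0, sd["C"], K)
        s = rng.normal(0, sd["S"], (K, m))
        ct = rng.normal(0, sd["CT"], (K, T))
        st = rng.normal(0, sd["ST"], (K, T, m))
        fixed = t[None, :] + theta * d.J
        values = (c[:, None, None] + fixed[:, :, None]
                  + ct[:, :, None] + s[:, None, :] + st)
        yield OutcomeSample(values=values, cluster=c, subject=s,
                            cluster_time=ct, subject_time=st,
                            theta=theta, seed=seed)


def estimate_theta(sample: OutcomeSample, d: SteppedDesign, rho: float,
                   sigma_sq: float) -> float:
    """GLS estimate of the treatment effect from one replicate.

    Reduces the data to cluster-period means, whitens with the known
    covariance and solves the fixed-effects model (time effects plus
    treatment).  Raises if the treatment effect is confounded.
    """
    K, T = d.K, d.T
    if sample.values.shape[:2] != (K, T):
        raise ValueError("sample dimensions do not match the design")
    if gls_precision(d, rho, sigma_sq) == 0.0:
        raise ValueError("treatment effect is confounded in this design")
    y = sample.values.mean(axis=2)  # K x T cluster-period means
    A = _whitener(T, rho, sigma_sq)
    Z = _time_dummies(K, T, None)
    X = np.hstack([Z, d.J.reshape(-1, 1).astype(float)])
    WX = np.vstack([A @ X[i * T:(i + 1) * T] for i in range(K)])
    Wy = (A @ y.T).T.reshape(-1)
    coef, *_ = np.linalg.lstsq(WX, Wy, rcond=None)
    return float(coef[-1])
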