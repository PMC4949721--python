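# swdesign

Design-stage precision calculus and uptake-time optimization for
**stepped cluster studies** — trials in which an intervention, once
introduced into a cluster, persists to the end of the study.  The class
covers parallel cluster designs, delay-control designs, stepped wedges
and parallel/wedge hybrids, in both cross-sectional and closed-cohort
(longitudinal) studies.

The package is aimed at biostatisticians planning cluster trials: it
answers "how precisely will this layout estimate the treatment effect?",
"which uptake times are optimal for my K clusters and T periods?", and
"how badly can my choice perform if the correlation assumptions are
wrong?".

## The model and the two numbers that matter

Observations follow a linear mixed effects model (Hussey–Hughes form at
the cluster-period level) with fixed time effects `t_j`, a fixed
treatment effect `θ`, and random cluster, subject and interaction
components.  The cluster-period means `Y_ij` then satisfy

    Y_ij = γ_i + t_j + θ J_ij + ε_ij,

where `J` is the K×T binary treatment matrix.  The precision (inverse
variance) of the best linear unbiased estimate of `θ` is

    Π = KT / (σ²(1−ρ)) · (a_D − b_D·R),     R = Tρ / (1 + (T−1)ρ),

where `σ²` and `ρ` are the variance and within-cluster correlation of
the cluster-period means, `R` is the **cluster-mean correlation (CMC)**,
and `(a_D, b_D)` are the design coefficients: the within-column and
between-row variances of the indicator matrix `J`.  In a cross-sectional
study `R = Mη_C/(1+(M−1)η_C)` with cluster size `M = Tm` and ICC `η_C`,
so `R` can be large even when the ICC is small.

Everything else in the package builds on this: relative efficiency vs
the cluster cross-over is `4(a−bR)`; design effects for sample-size
calculations are `(mη_CT+η_ST)/(4(a−bR))`; the sweep-line optimizer
maximizes `a−bR` over irreversible treatment matrices; the large-study
frontier `1−R+R²/3`, the minimax hybrid with SW proportion
`(3−√3)/2 ≈ 0.634`, and the logit-normal-prior robustness study all
follow from the same two coefficients.  A direct GLS oracle and a
Monte-Carlo outcome simulator cross-validate the closed form.

## Worked example

Plan a cross-sectional study in K=10 clusters over T=6 periods with
m=10 subjects per cluster-period and an anticipated ICC of 0.05:

```python
from fractions import Fraction
import swdesign as sw

vc = sw.VarianceComponents.cross_sectional(icc=0.05, m=10)
cm = sw.cluster_mean_model(vc, T=6)
print(f"rho = {cm.rho:.4f}, R = {cm.R:.4f}")

res, struct = sw.best_balanced_design(10, 6, Fraction(3, 4))
c = sw.coefficients(res.design)
print("J_total =", res.J_total, " P =", struct.P, " middle =", struct.middle)
print("4a =", c.four_a, " 4b =", c.four_b, " a-bR =", float(res.precision_factor))
print("design effect =", round(sw.design_effect(vc, c, T=6), 3))
```

prints

```
rho = 0.3448, R = 0.7595
J_total = 30  P = 2  middle = 6
4a = 61/75  4b = 23/45  a-bR = 0.1075
design effect = 2.235
```

The ICC of 0.05 becomes a cluster-mean correlation of 0.76: most of the
cluster-mean variance is time-independent, so a stepped layout is
worthwhile.  The best balanced design at R = 0.75 keeps 2 clusters
always treated, 2 never treated and steps the middle 6; its precision
factor `a − bR = 0.1075` and a design effect of 2.24 (versus 3.95 for a
parallel design with the same clusters) quantify the gain.  The same
construction is available from the shell:

```
swdesign optimize --K 10 --T 6 --R 3/4 --balanced --out bbd.csv
swdesign minimax            # β̃, the 86.6% floor and the candidate table
swdesign verify --design bbd.csv --rho 0.3448   # closed form vs GLS oracle
```

## Layout

- `swdesign.design` — treatment matrices, design coefficients, precision
  (standard and lattice forms)
- `swdesign.variance` — variance components, cluster-mean correlation,
  design effects
- `swdesign.families` — named design families and Table-style closed forms
- `swdesign.optimize` — sweep-line optimizer, best balanced designs, grid
  study, enumeration oracle
- `swdesign.largestudy` — efficiency frontier, admissible hybrids, minimax
- `swdesign.uncertainty` — logit-normal prior robustness study
- `swdesign.oracle` — direct GLS precision and outcome simulation
- `swdesign.io`, `swdesign.cli` — CSV/config formats and the `swdesign`
  command-line tool

See `docs/methods.md` for the methodological details and design choices.
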