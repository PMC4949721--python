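# Methods

## Model and scope

The package works entirely at the design stage: variance parameters are
treated as known inputs and nothing is estimated from data.  The outcome
model is a linear mixed effects model for `m` observations per
cluster-period,

    Y'_ijl = c_i + t_j + θ J_ij + (ct)_ij + s_l(i) + (st)_l(i)j ,

with independent normal random components whose variances are the
proportions `η_C, η_CT, η_S, η_ST` (summing to 1) of the total
individual-level variance `σ₁²`.  Cross-sectional studies set
`η_S = η_CT = 0` (so `η_C` is the usual ICC); closed-cohort studies have
`η_S > 0`.  Open cohorts (drop-out, rolling recruitment) are out of
scope, as are generalized-linear-mixed extensions; for binary outcomes
the normal model is the standard large-`m` approximation.

The BLUE of `θ` depends on the data only through the cluster-period
means, which follow a compound-symmetric model with variance `σ²` and
within-cluster correlation `ρ`.  All efficiency statements reduce to the
cluster-mean correlation `R = Tρ/(1+(T−1)ρ)` and the design coefficients
`(a, b)` of the K×T indicator matrix:

    Π = KT/(σ²(1−ρ)) · (a − bR).

`a` (within-column variance) measures the treatment/control contrast
available at each time; `b` (between-row variance) measures how much of
that contrast is confounded with cluster identity.  Both are population
variances with equal weight on all KT lattice points, computed in exact
rational arithmetic so that catalogue identities and optimality ties are
decided without tolerances.

Boundary conventions: `ρ = 1` (no time-varying variance at the mean
level) is admitted as the limit `R = 1`; the precision formula then
matches the fixed-cluster-effects analysis, and the `1/(1−ρ)` factor is
left to the caller as a separate scale.  `precision()` therefore rejects
`ρ = 1` and points to the fixed-effects route.  A floating-point
`a − bR < 0` (possible only through rounding, since `a ≥ b` for every
irreversible design) is clamped to zero.

## The lattice form and the optimizer

Mapping indices to a centred lattice `x_j = (j−(T+1)/2)/T`,
`y_i = (i−(K+1)/2)/K`, row-monotone designs in uptake order satisfy

    KT(a − bR) = 2 Σ_treated (R x_j − y_i) − R (J_tot − J_tot²/KT).

This identity was derived by summing the column- and row-margin
expansions of `a` and `b` under monotonicity, and is enforced in the
test suite by exact agreement with the standard form on every ordered
monotone design with K, T ≤ 4 and on random larger designs (tolerance
1e−9).  It fails for reversible layouts — the cluster cross-over is the
canonical counterexample — so `precision_lattice` validates monotonicity
and ordering before evaluating.

Because only the first term depends on *which* points are treated, the
best design at fixed `J_tot` treats the `J_tot` points with the largest
margin `R x_j − y_i` (sweeping a line of slope R up the lattice), and
the overall optimum maximizes over `J_tot`.  Points with equal margin
contribute identically, so any tie resolution attains the optimum; for
reproducibility ties are broken deterministically (later time column
first, then smaller cluster index), a rule that also preserves row
monotonicity and canonical ordering for every partial selection.  When R
is supplied as a `fractions.Fraction` (including the 0.001-step study
grid) ties are detected exactly; float inputs use a 1e−12 absolute
tolerance.  This matters for reporting, not value: at K=10, T=6, R=0.6
six lattice points sit exactly on the boundary line and misclassifying
them changes which of the 20 equal-value balanced designs is returned.

The best balanced design (BBD) is the sweep at `J_tot = KT/2`:
all points strictly below the boundary line `y = Rx` plus half of any
points on it (central symmetry of the lattice guarantees the count comes
out exactly).  The structural summary (P pure-treated / pure-control
clusters, K−2P stepped clusters, the modified-wedge correspondence when
`T = 2(K−2P)l`) is recomputed from the returned matrix rather than
asserted.

The brute-force oracle enumerates ordered monotone designs as
nondecreasing uptake vectors (`C(K+T, K)` of them, capped at 10⁶) and is
used only in tests; the sweep is proven against it exhaustively for
K, T ≤ 4.

## Catalogue closed forms

The family constructors realize explicit matrices from uptake-time
fractions: SW_g at fractions `k/(g+1)`, MSW_g at `(2k−1)/2g` (half-length
lead-in and tail), hybrids as an MSW_g block flanked by equal
always-treated and never-treated parallel arms, and delay-control
designs as control/parallel/treated column blocks.  Strict mode requires
every uptake fraction to land on a column boundary and every cluster
group to divide evenly, and the test suite verifies
`coefficients(realize(spec)) == closed_form_coefficients(spec)` as exact
rationals for every family across a parameter grid — both directions of
the table are therefore pinned by the matrix ANOVA, not transcribed
blindly.  Approximate mode rounds uptake times to the nearest column and
is intentionally unchecked against the closed forms.  Infinite-g specs
are symbolic: their closed forms substitute the `1/g² → 0` limit and
`realize()` rejects them.

Unequal parallel allocation (control proportion `s ≠ 1/2`) multiplies
both `a` and `b` — and hence the ARE — by `4s(1−s)`; this follows
algebraically from the ANOVA and is covered by the strict-realization
equality tests with `s = 1/4, 1/3`.

## Large studies, minimax, robustness

The large-study efficiency frontier `1−R+R²/3` is the `g→∞` hybrid
envelope; each limit hybrid is the tangent at `R = β` (the gap is
`(R−β)²/3`, asserted exactly on a 101×101 rational grid).  The minimax
proportion `(3−√3)/2` is returned in closed form and verified
numerically as the argmin of the maximum endpoint loss on a 10⁻⁴ grid.
Endpoint relative precisions divide by the best achievable efficiency:
1 at `R = 0` (parallel design) and 1/3 at `R = 1` (large-g modified
wedge).  Percentages for table reproduction are rounded half-up to one
decimal.

The robustness study draws `R` from a logit-normal prior with median
`R₀`.  The paper-style spread parameter is the coefficient of variation
of `R/(1−R)`; since that quantity is lognormal under the prior, the
unique consistent map is `τ² = log(1+CV²)`.  Centiles use the standard
linear (type-7) order-statistic estimator on `n = 9999` draws by
default.  The worst-case relative precision is computed
deterministically (dense grid of step 10⁻³ plus endpoints; for all
candidates considered the minimum is at `R = 0` or `R = 1`).  The
small-study denominator — the BBD at the drawn `R` — is recomputed
exactly per draw via a vectorized top-half selection of lattice margins;
at K=10, T=6 this costs microseconds, so no grid caching or
interpolation layer is used.

## GLS oracle and simulator

The oracle validates the closed form by an independent route: build the
KT-dimensional problem on cluster-period means, whiten by the
block-Cholesky factor of `σ²[(1−ρ)I + ρ11']`, and read the precision of
`θ` as the squared norm of the whitened treatment column after
projecting out the nuisance (time, and optionally cluster) columns via
least squares.  Identifiability is handled by construction — T time
dummies absorb the intercept — and redundancy in the fixed-cluster
variant is harmless to the projection; confounding is declared (and
precision 0 returned) when the residual norm falls below 1e−10 of the
column norm.  Time effects may be collapsed to one parameter per
equal-duration column group sharing an uptake pattern; the oracle
reproduces the per-time-point precision in that case, as the theory
requires.

The simulator draws all five random components at their stated variances
and the estimator applies the same whitening to one replicate.  The
Monte-Carlo contract — empirical variance of the GLS estimate times the
formula precision within 3 standard errors of 1 at 2000 replicates — is
part of the acceptance tests.

## What the synthetic inputs do and do not show

There are no external data: design matrices, variance components and
priors are generated programmatically, and the study conditions (the
10-cluster/6-period lattice, the 0.001-step R grid, CV ∈ {0.25, 0.5, 1},
9999 prior draws) are the defaults of the corresponding functions.
Passing tests demonstrate internal consistency of the precision
calculus, optimality of the constructions, and correct distributional
behaviour of the simulator — not that any particular real trial meets
the model's assumptions (equal cluster sizes, equal `m` per period,
additive effects, known variances, no drop-out).

## Known limitations

- Optimization is over uptake times only; K, T, m and total sample size
  are fixed inputs.
- Unequal cluster sizes and unequal observations per period are not
  modelled.
- `grid_study` with exact rational arithmetic is a few hundred times
  slower than a float implementation would be (still ~1 s for the
  1001-point study grid); exactness was preferred because "balanced
  optimum equals overall optimum" is a knife-edge count.
- The robustness study evaluates fixed candidate designs; it does not
  optimize expected loss over the prior.
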