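# Methods

## Model

A (pseudo) one-way layout with k treatments partitioned into H variance
groups: X_hij ~ N(μ_hi, σ_h²) independently, h = 1..H, i = 1..I_h,
j = 1..n_hi. The partition is part of the *design*: it must be chosen
before inspecting test results (typically from subject-matter knowledge or
a residual analysis of a preliminary variance model). Factorial layouts
are flattened to cell means, treatments ordered group-major; the grouping
factor is then one of the design factors.

Because the mean structure is saturated, the fitted cell means are the
sample means regardless of variance weights, and the variance-group
REML/ML estimates coincide with the closed-form pool

    S_h² = Σ_i Σ_j (X_hij − X̄_hi)² / Σ_i (n_hi − 1),

so no iterative model fitting is needed. Every procedure depends on the
data only through the per-treatment means/variances and sample sizes;
summary tables are therefore accepted as first-class input (the SW
procedure is the exception — its HC3 estimator is residual-based and
requires raw data, although for cell means it collapses to
S_hi²/(n_hi − 1); both forms are computed and must agree).

## Degrees of freedom

For a contrast c_l, Satterthwaite's moment matching gives

    df_l^Satt = (Σ_hi c² V_hi/n_hi)² / Σ_hi c⁴ V_hi²/(n_hi²(n_hi−1)),

with V_hi = S_hi² (procedure PI) or S_h² (PIa). The
partial-heteroskedasticity rule instead matches moments at the level of
variance groups: with a_lh = (Σ_i |c_lhi|)² and N_h = Σ_i n_hi,

    df_l = (Σ_h a_lh S_h²/N_h)² / Σ_h a_lh² S_h⁴/(N_h²(N_h − I_h)).

Properties used as test oracles: it reduces to df^Satt with S_h² when
every group holds one treatment; a contrast supported on a single group
gets exactly that group's residual df N_h − I_h; and it is bracketed by
min and sum of N_h − I_h over the groups the contrast touches. Neither
df_l ≥ df^Satt nor the reverse holds universally — PIa can exceed PH for
some allocations — hence PHmax takes the elementwise maximum and inherits
each one's rejections (larger df ⇒ smaller critical value).

An alternative "per-term" reading of the group rule (inner sums taken per
treatment rather than per group) is kept behind
`df_partial(..., variant="per-term")` for sensitivity checks only: it
yields 2(N_h − I_h) > N_h − I_h for a within-group pairwise contrast,
violating the residual-df reduction, and is used by no procedure.

### Integer truncation in the multivariate-t evaluation

`fit(..., df_mode=...)` controls how the per-contrast df enter the
multivariate t. The default `"floor"` truncates to integers. This mirrors
the long-standing behaviour of the standard multivariate-t distribution
routines used throughout multiple-comparison practice (which coerce the
df argument to integer), and therefore reproduces published reference
analyses computed with those routines; it is also the slightly
conservative direction. `"exact"` evaluates the QMC integrand at the
continuous df (the integrator itself is built for non-integer df); at the
df values of the worked example the difference reaches ~0.02 in adjusted
p. Reported df are always the exact values, as reference reports print
them. The simulation engine uses the same default so that error rates are
comparable with procedure behaviour in the field.

## Multivariate t probabilities

One-sided adjusted p-values are p_l = 1 − P(T ≤ t_l·1; L, df_l, R): each
statistic is referred to its own L-variate t distribution with its own
df. Simultaneous lower bounds use the equicoordinate quantile
t_{L,df_l,R,1−α} found by Brent root search on the CDF, bracketed between
the marginal t quantile and the Bonferroni quantile (the root always lies
between them), to |q| tolerance 1e-6.

Rectangle probabilities use the separation-of-variables algorithm of Genz
and Bretz:

* pivoted Cholesky factorization (LAPACK `dpstrf`). Rank-deficient PSD
  correlation matrices — e.g. all-pairs families have rank k−1 < L —
  yield zero pivots whose coordinates become deterministic indicator
  steps in the recursion. A reconstruction residual > 1e-7 raises
  (non-PSD input).
* the t distribution enters through one extra integration coordinate for
  the chi mixing scale, s = √(χ²_ν(w)/ν). Its inverse CDF is
  interpolated on 8193 nodes parameterized by the normal quantile of w
  (max error in s below 5e-8, validated against the exact inverse); this
  keeps the integrand evaluation cheap inside simulations. ν > 1e4
  switches to the multivariate normal limit.
* scrambled Sobol points, 10 independent Owen scramblings; the estimate
  is their mean and the reported error bound 3.5·SE of the scramblings.
  The point budget starts at 2^11 and doubles until the error bound meets
  the requested ε (default 1e-5) or a cap (default 2^17) is reached.
  Everything is deterministic for a fixed seed.

Validation is dual-route: the integrator is cross-checked in the tests
against scipy's independent implementation (nonsingular cases), against
closed forms (independence, univariate margins), and against a frozen
R/mvtnorm value for a singular rank-5, L = 15 case.

## Procedures

All seven procedures share η̂_l and differ only in the plug-in variance
source (pooled / group / per-treatment / HC3) and df rule; the single-df
procedures HOM, SDF and SW use the residual df N − k. Rejection at
familywise level α is p_l < α, equivalent (up to QMC tolerance) to a
lower bound above δ_l; this duality is property-tested. Hypotheses are
one-sided "greater"; a "less" family is obtained by negating the contrast
matrix. Zero contrast variance (all involved variances zero) is an error
naming the contrast; degenerate zero-variance *cells* are fine as long as
some involved variance is positive.

## Monte-Carlo study

The simulation harness mirrors the design used to validate the
procedures: six treatments, common mean 100, variance groups
{1,2},{3,4},{5,6} held fixed in all settings (a prespecified variance
model, including the homoskedastic setting (d), where the procedures
still estimate three group variances), four allocations of (n, σ) with
total N = 60, five contrast families, one-sided α = 0.05. The FWE
estimate is the fraction of replicates with at least one rejection;
complete (all-pairs) power is the fraction where *all* designated false
hypotheses reject (mean shifts on treatments 3 and 5; many-to-one
contrasts 2 and 4, all-pairs contrasts 2, 4, 6, 8, 13 in lexicographic
order). At shift 0 the complete-power number is degenerate (no false
nulls) and only bounded by the FWE.

What the generator emulates: exactly the normal, independent,
variance-grouped sampling model above. What it does not: non-normality,
dependence, blocking, covariates — passing simulations say nothing about
robustness to those.

Implementation notes:

* all methods see identical replicate data; per-treatment means and
  variances are drawn vectorized over replicates.
* decisions use adjusted p-values, but the marginal-tail bracket
  p_single ≤ p_adj ≤ L·p_single lets most replicates skip the
  multivariate integral entirely; only boundary candidates are
  integrated, with a per-replicate QMC seed derived from the master seed.
* HOM's critical value does not depend on the data (its correlation
  matrix depends only on c and n, its df is N − k), so the
  equicoordinate quantile is computed once and reused; a test checks
  this fast path agrees with the generic adjusted-p path.
* inside the replicate loop the QMC budget is reduced (ε = 2e-3, 4
  scramblings of ≤ 2^11 points): decision errors then occur only within
  ~2e-3 of the threshold, are symmetric, and are negligible against the
  binomial noise of the study sizes used.
* a misspecification mode is available by passing a wrong
  `variance_groups` partition to `SimulationSetting`; no reference value
  is claimed for it.

Study sizes: the bundled acceptance script uses 20,000 replicates per
configuration (binomial SE ≈ 0.0016 near 0.05), the test suite 10,000
(SE ≈ 0.0022); the published design of 100,000 replicates is a
`--reps`/argument away.

## Defaults and limitations

* α = 0.05, δ_l = 0, one-sided greater; QMC ε = 1e-5, seed 0.
* Williams-type trend rows weight the top-l treatments by sample size,
  and each-vs-rest ("average") contrasts weight the complement by sample
  size — both matching the standard `contrMat`-style constructions used
  in multiple-comparison practice; the unweighted average variant stays
  available behind `weighted_average=False`.
* The all-pairs sign convention (later minus earlier treatment) and
  lexicographic order fix which contrasts the power study designates.
* Single-step procedures only — no closed testing or step-down; no
  two-sided intervals (sign-flip gives upper bounds); no missing values,
  covariates or blocking; normality and complete randomization are
  assumed throughout.
* CSV dialect: comma-separated, header row, UTF-8, decimal point.
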