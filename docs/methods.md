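# Methods

## Generating model

Balanced two-level one-factor measurement data: for individual `i` in
cluster `g`,

```
y_ig = μ + Λ_B η_Bg + ε_Bg + Λ_W η_Wig + ε_Wig
```

with `η_Bg ~ N(0, ψ_B)`, `ε_Bg ~ N(0, Θ_B)`, `η_Wig ~ N(0, ψ_W)`,
`ε_Wig ~ N(0, Θ_W)`, all mutually independent across components, clusters
and individuals.  The default population carries the perceived-competence
scale values: within loadings (1, 0.45, 0.92, 0.36), between loadings
(1, 0.78, 0.60, 0.62), intercepts (2.896, 2.856, 2.860, 3.268), residual
variances 0.5 (within) and 0.2 (between) for every indicator.  The total
factor variance is fixed at 1 and split by the factor-level intraclass
correlation: `ψ_B = ICC`, `ψ_W = 1 − ICC`.  Data are generated at the
composite-indicator (continuous) level; the marker indicator's loading is
fixed at 1 at both levels.

The study grid mirrors the simulation design the population values come
from: cluster sizes {3, 30, 200} × cluster numbers {40, 100, 300} × ICC
{0.1, 0.3, 0.5, 0.7, 0.9}, a fixed number of replications per cell.
Random substreams are keyed by `(seed, CN, CS, round(ICC·10⁶), replicate)`
via `numpy.random.SeedSequence` spawn keys, so any cell or replicate can
be regenerated in isolation and results are independent of enumeration
order or parallel scheduling.  ICC = 0 and ICC = 1 are permitted but emit
a warning because they degenerate one level's factor (they are needed for
the conflation boundary identities).

What the generator does **not** emulate: unbalanced cluster sizes,
ordinal/item-level responses (the real scale is 28 four-point items
aggregated into four composites), non-normality, and missing data.
Passing tests therefore demonstrate estimator behavior under the idealized
normal, balanced regime, not robustness to those real-data features.

## Likelihood

For a balanced design the per-cluster covariance
`I_n ⊗ Σ_W + J_n ⊗ Σ_B` diagonalizes into (n−1) copies of `Σ_W` and one
of `Σ_n = Σ_W + n Σ_B`, giving the exact closed form

```
−2 ln L = NP ln 2π + (N−G)[ln|Σ_W| + tr(Σ_W⁻¹ S_PW)]
                   + G[ln|Σ_n| + tr(Σ_n⁻¹ S_n(μ))]
```

with `S_PW` the pooled within-cluster covariance (ML divisor N−G) and
`S_n(μ) = n(M + (ȳ−μ)(ȳ−μ)′)`, `M` the ML (divisor G) covariance of
cluster means.  Equality with the stacked multivariate-normal density is
the defining contract and is enforced by a brute-force oracle test at
tolerance 1e−8.  The one-level specification uses the standard
single-group ML discrepancy against the ML total covariance.  Means are
free parameters in every specification (not concentrated out), so their
robust standard errors are first-class outputs; numerically their
estimates equal the grand means in all five specs.

Saturated and independence (diagonal) reference models have closed-form
ML solutions on balanced data (`Σ̂_W = S_PW`, `Σ̂_n = S_n`, and their
diagonalized counterparts); they are evaluated directly rather than
iterated.  Degrees of freedom follow from the saturated moment counts —
20 covariances + 4 means at two levels, 10 + 4 at one level — giving
4 (2MLR), 2 (1MLR), 2 (2MaxB), 2 (2MaxW) and 7 (2Miss) for P = 4.

## Estimation

Quasi-Newton (L-BFGS-B) on the raw parameter vector with analytic
gradients (structure derivatives chained through the matrix-calculus
identities for log-determinant and trace terms; verified against central
differences).  Steps into non-positive-definite `Σ_W` or `Σ_n` are
rejected by a large finite penalty rather than by log-reparameterization,
so variances stay on the natural scale and Heywood cases (negative
variance estimates) are reported as-is with an inadmissibility flag, never
truncated — truncation would bias the bias summaries.

Starting values are deterministic and scale-aware: non-marker loadings
0.7, each level's factor variance at half that level's observed marker
variance, residual variances at half the observed diagonals (floored at
10⁻³ of the marker variance), means at the grand means, saturated blocks
at their moment estimates.

Convergence requires max |∇(−2lnL/N)| ≤ 1e−5 (per-observation scale; an
absolute tolerance on the raw scale would be meaningless across N spanning
120 to 60,000) after at most one polish pass, plus a positive-definite
observed information.  A non-PD information matrix is classified
non-converged/inadmissible, mirroring the "non-positive definite
first-order derivative product matrix" exclusions such studies report;
condition summaries aggregate converged, admissible replications only and
report the convergence rate.  Because the convergence test differs from
commercial implementations, small-sample convergence rates are comparable
but not identical to published ones.

### Cluster-robust inference

The sandwich `A⁻¹BA⁻¹` with `A` the observed information of the total
−2 ln L (central differences of the analytic gradient) and `B` the sum of
per-cluster score outer products; clusters are the independent units for
every specification including the one-level model.  For a free mean this
collapses to the empirical variance of cluster means over G, which the
tests verify exactly.  Wald intervals and significance use the normal
critical value 1.96.

### Robust chi-square

The likelihood-ratio statistic against the saturated model is divided by
the mean-adjusted correction factor

```
c = [tr(A_sat⁻¹ B_sat) − tr(A_model⁻¹ B_model)] / df .
```

Under multivariate normality c → 1 (verified in simulation at G = 300);
for the clustered one-level fit it grows with the design effect.  The
exact correction used by commercial software is not published beyond
asymptotic equivalence to the Yuan–Bentler residual-based statistic, so
small-G chi-square means may deviate from published tables; the statistic
is visibly inflated above its df when G is small, in both this
implementation and the published tables.  CFI uses the independence
baseline at the same level structure (diagonal covariances, free means),
scaled the same way; RMSEA uses `√(max(χ²−df,0)/(df·N))` with N the total
observation count, which is also the N in BIC
(`−2lnL + k ln N`) and adjusted BIC (`−2lnL + k ln((N+2)/24)`).

### SRMR by level

Standardized residuals (covariances standardized by sample standard
deviations, unique lower triangle plus diagonal) computed separately per
level: `S_PW` vs `Σ̂_W` and the saturated ANOVA between-matrix
`(S_n − S_PW)/n` vs `Σ̂_B`.  Using the ANOVA matrix as the between-level
"sample" makes SRMR-B identically zero for the saturated-between maximum
model; its occasionally negative diagonal entries in small samples are
left in place, and standardized elements with nonpositive sample variance
are skipped with a warning.

## Conflation and reliability layer

- `conflated_loadings`: `Λ_y = ICC·Λ_B + (1−ICC)·Λ_W`, exact at ICC ∈
  {0, 1}.
- `pseudo_true_onelevel`: the exact probability limit of the one-level
  estimates, obtained by fitting the one-level model to the population
  total covariance `Σ_B + Σ_W` (no sampling).  At ICC = 0.3 it gives
  loadings (0.534, 0.790, 0.428) and factor variance 1.036 — slightly
  below the weighted-average approximation (0.549, 0.824) and slightly
  above `ψ_B + ψ_W = 1` respectively, which the large-sample simulation
  means confirm.
- `composite_reliability`: `ρ = (Σλ)²ψ / [(Σλ)²ψ + ΣΘ]`.  The explicit
  factor-variance multiplier generalizes the unit-variance textbook form
  and makes ρ invariant to the marker-scaling convention, which matters
  because the fitted solutions are unstandardized.
- `design_based_reliability` squares the ICC-weighted between and
  (1−ICC)-weighted within loading totals *separately* before summing, as
  the design-based decomposition defines it.  Because
  `a² + b² < (a+b)²` for positive a, b, this is strictly below feeding the
  conflated loadings through the congeneric formula at interior ICCs; the
  two definitions agree only at the boundaries.  They are deliberately
  kept distinct rather than reconciled.
- `indicator_r2`: per indicator and level, `λ²ψ/(λ²ψ+θ)`.

## Monte Carlo summaries

Per replication and free parameter: Wald 95% CI, coverage against the
generating value, significance at 5%.  One-level fixed effects are judged
against the **within-level** population values (the level a design-based
analysis is meant to inform); one-level loadings additionally against
their conflated pseudo-truths.  The constrained-model loadings are scored
at both levels (the single estimate is compared to each level's truth).
The marker loading is fixed and never aggregated.  Relative bias
`RB = 100(mean estimate − truth)/truth`; absolute bias `AB` is the mean of
per-replication |RB|, hence `AB ≥ |RB|` with the gap driven by sampling
noise.  Non-convergence is handled by fixed attempted replications per
condition with the convergence rate reported (summaries cover converged
fits), not by regenerating until a target count converges.

## Problem sizes

The acceptance runs use 200 replications of the largest design
(300 clusters × 200, N = 60,000) and 1000 replications of the smallest
(40 × 3, N = 120), both at ICC = 0.3.  At 200 replications the Monte
Carlo standard error of a mean loading is ≈ 0.0015 at the large design;
at 1000 replications a coverage or power proportion carries a binomial
standard error ≈ 0.013.  Acceptance tolerances are set at roughly three
such standard errors plus a margin for the robust-estimator
implementation differences noted above.

## Known limitations

Balanced designs only (the closed-form likelihood and the ANOVA moment
estimators both require it); one factor per level; continuous normal
indicators; no missing data.  The theory layer's conflation formula is
derived for the uni-factor case and is not hypothesized beyond it.
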