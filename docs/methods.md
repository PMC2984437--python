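# Methods

## The estimation problem

A complex trait is assumed to be influenced by an unknown number *n* of
susceptibility variants whose per-locus variance explained (Vg) follows a
parametric distribution: exponential with rate λ by default (mean Vg = 1/λ),
or gamma with fixed shape *k* and rate λ (mean *k*/λ).  Since the
heritability *h*² is the sum of all per-locus contributions,
*n* = *h*²/E[Vg].  The package estimates λ from GWAS summary statistics and
propagates it, with uncertainty, to *n*.  Counts are reported with half-up
rounding (the unrounded value is available via `n_variants(..., rounded=False)`).

## Effect sizes and power

**Binary traits.**  Vg is computed under the liability threshold model:
liability L ~ N(0,1), disease when L exceeds the (1−K) quantile at
prevalence K.  Genotypes are Hardy–Weinberg at risk-allele frequency *p*
with multiplicative allelic relative risk R; the baseline penetrance is
solved so the population risk equals K (exactly: Σ genotype freq ×
penetrance = K).  Genotype-specific mean liabilities are recovered by
inverting the normal tail at each penetrance, m_i = T − Φ⁻¹(1−f_i), and
Vg is their between-genotype variance.  This mean-liability decomposition
treats the within-genotype liability as unit-variance normal; it is
excellent for Vg up to a few percent and the package caps the usable range
at Vg = 0.95, far beyond any plausible single locus.

The expected z-statistic (noncentrality δ) at a given Vg is the Wald
statistic ln(OR)/SE(ln OR) evaluated on *expected* allelic 2×2 counts
obtained from the penetrances by Bayes' rule — no data simulation involved.
The risk-allele frequency is fixed at 0.5 for all power and δ computations:
power at matched Vg is only weakly RAF-dependent (within ~5 percentage
points in the flat parts of the power curve, up to ~10 in its steepest
ascent), and a fixed RAF is what keeps the one-dimensional power×density
formulation tractable.

**Continuous traits.**  The closed forms δ = √(n·Vg/(1−Vg)) and
Vg = δ²/(n+δ²) of the Pearson-correlation test are used; the derivative
dVg/dδ = 2nδ/(n+δ²)² is analytic.  These standard forms are cross-checked
in the tests against a Monte-Carlo change-of-variables oracle rather than
assumed.

**Caching.**  The binary δ(Vg) map needs a root-find per evaluation, so each
design caches a shape-preserving (PCHIP) interpolant of the exact map on a
dense geometric Vg grid, truncated to the region where δ(Vg) is increasing
(at extreme Vg the expected-count Wald statistic turns over as table cells
empty; that region is far outside any realistic use).  Interpolation error
is below 1e−6 relative; the binary dVg/dδ is the interpolant's derivative,
validated against step-halved central differences.

## Two fitting routes

**Moment fitting of Vg (identical to power-adjusted ML).**  The density of
a *detected* variant's Vg is pwr(v)·f_λ(v) normalised over (0, v_max] with
v_max = 0.5.  λ solves

  E_λ[Vg | detected] = Σw_i v_i / Σw_i,

by bracketed root search on λ ∈ [1, 10⁶]; the theoretical mean is evaluated
with composite Gauss–Legendre quadrature geometrically refined toward 0
(the integrand concentrates at small Vg for large λ).  For the exponential
family this moment root coincides with the zero of the power-adjusted ML
score; the test suite verifies the coincidence to 1e−6 relative.

**Truncated convolution fitting of z.**  A non-null observed z is δ plus
standard normal noise, so its density f₁(z) is the convolution of the
(symmetrised) δ density — the push-forward of the Vg distribution through
δ(Vg) — with φ.  Significant z-values follow f₁ truncated at ±z_crit, and λ
is estimated by maximising the (optionally 1−lfdr-weighted) truncated
log-likelihood.  No winner's-curse correction is applied on this route: the
truncation already conditions on selection.  Implementation: the δ-grid
kernels φ(z_i∓δ_j) and the selection tails P(|Z|>z_crit | δ_j) are
tabulated once per fit (2000-point grid up to max|z|+8); each likelihood
evaluation only reweights the grid by the Vg density, and the optimiser
works on log λ.  For gamma shapes k < 1 the δ density has an integrable
singularity at 0; the grid origin is evaluated half a step off zero.

## Winner's curse corrections

For a marker selected because |z| > c, the sampling density of z is
φ(z−μ)/[Φ(μ−c)+Φ(−μ−c)].  Five estimators of μ operate on |z| (the problem
is symmetric) and restore the sign:

1. conditional MLE (bounded search on [0, |z|+2], grid-seeded; ties broken
   toward 0);
2. mean of the normalised conditional likelihood (flat-prior posterior
   mean; trapezoid integration over μ ∈ [−10, |z|+10], 4001 points);
3. the average of 1 and 2;
4. median-matching: the μ whose selected sampling distribution has median
   at the observed z, found by root search (the conditional CDF is strictly
   decreasing in μ, so the root is unique and bracketed by [0, |z|]);
5. MSE-oriented blend β̂_mse = β̂_med + w·(β̂−β̂_med) with
   w = σ̂²/(σ̂²+(β̂−β̂_med)²): trust the low-variance uncorrected estimate
   when its apparent bias is small relative to its standard error, the
   median-corrected one otherwise.

Because β̂ = z·σ̂, the blend weight is invariant to the coefficient scale:
on the z scale the result does not depend on σ̂ at all.  The
`correct_mse_median` interface still takes the SE (callers working on the
coefficient scale need it), but no per-marker SE reconstruction is required
in the pipeline.

## Local false discovery rates

The marginal density f(z) of all scan statistics is estimated by Lindsey's
method: 120 equal-width bins over the observed range, Poisson log-linear
model with a degree-7 Chebyshev polynomial basis.  The convex Poisson
likelihood is maximised directly with L-BFGS (exact gradient, least-squares
initialisation); an IRLS-style fit is avoided because empty tail bins can
derail it.  The null is the theoretical N(0,1) by default — the generative
model produces exact standard normal nulls — with an empirical-null option
(central matching: quadratic fit to log f on |z| ≤ 1.6) for real data whose
null may be shifted or overdispersed.  π₀ is matched at the centre,
π₀ = f̂(0)/φ(0), clipped to 1.

lfdr(z) = π₀f₀(z)/f̂(z) is clipped to [0,1] and repaired to be nonincreasing
in |z| on each side by isotonic regression, so an lfdr threshold always
selects a single contiguous |z| region; the fdr-derived cutoff (smallest
|z| attaining the threshold) then serves as the common selection threshold
c for power evaluation and winner's-curse conditioning of every admitted
marker.  Weights are 1−lfdr(z), the posterior probability of true
association.

## The named estimators

Fourteen estimators combine: inclusion rule (Bonferroni z-threshold at
FWER α/(2M), or local fdr ≤ 0.3), winner's-curse correction (none, each of
the five above), and fitting route (power×density moment fit of Vg, or
truncated-f₁ ML of z; fdr-mode fits weight by 1−lfdr and evaluate power at
the fdr-derived cutoff).  `run_estimator` dispatches by name
(`Bonf`, `Bonf.corr`, …, `truncfdr.fitfZ.conv`); an `EstimationContext`
shares the lfdr model and selections when several estimators run on one
scan.

## Confidence intervals

For truncated-f₁ fits (where the likelihood genuinely describes the
sampling variation):

* **Observed information**: λ̂ ± q·I(λ̂)^{−1/2}, I from a Richardson-refined
  central second difference with step 1e−3·λ̂ (λ spans 10²–10⁴, so the step
  is relative).  Lower bounds can be negative for flat likelihoods and are
  reported unclipped with a warning.
* **MLRT inversion**: endpoints solve 2[ℓ(λ̂)−ℓ(λ)] = χ²₁(level) on each
  side, bracketed by geometric expansion.
* **Parametric bootstrap**: z-values are redrawn from the truncated f₁ at
  λ̂ by inverse-CDF sampling on a 2048-point grid over [z_crit, z_crit+15]
  (random signs) and refitted; percentile interval; deterministic given the
  seed; more than 10% refit failures raise an error.

Moment-route fits carry a profile log-likelihood for diagnostics, but
analytic CIs are not attached to winner's-curse-corrected Vg fits: the
corrected values are not draws from the fitted density, so the curvature
does not measure their sampling variation.

## The synthetic-scan generator

One replicate draws 100,000 independent z-statistics: 99.5% null N(0,1);
the remaining 0.5% draw Vg ~ Exponential(λ_true), map to δ at the design
(3500/3500 cases/controls and prevalence 0.001 in the reference scenario),
get a random sign (the fitted densities are symmetric; an all-positive
option exists and the f₁ fit is provably invariant since it sees only |z|),
and add standard normal noise.  Replication uses spawned seed-sequence
substreams, so replicate *i* of a scenario is identical for a given master
seed regardless of how many replicates are run or in what order.

What the generator does *not* emulate: linkage disequilibrium (statistics
are independent; real scans need distance pruning first, provided via
`prune_by_distance` at 30 kb), allele-frequency spectra (RAF is fixed at
0.5 throughout, consistent with the power model), population stratification
or other confounding (nulls are exactly N(0,1)), and sampling noise in the
heritability.  Passing tests therefore validate the estimation machinery
under its own assumptions, not robustness to LD or stratification.

## Validation scale and numerical choices

The validation harness reproduces single scenarios of the reference
simulation design at reduced replicate counts chosen for a single-CPU run:
120 replicates for estimator RMSE and 300 for CI coverage (the reference
used 300 and 1000).  At λ = 1000 with 3500/3500 this package measures RMSE
≈ 194 for the uncorrected Bonferroni estimator and ≈ 72 for the
lfdr-weighted median-corrected one, and information/MLRT coverage 0.947 /
0.953 with mean widths 362 (unweighted) and 274 (weighted) — the numbers
written by `scripts/acceptance.py`, which recomputes them from scratch.

Other numerical settings: Vg quadrature nodes are 24-point Gauss–Legendre
per geometric segment (≈ 580 nodes over (0, 0.5]); λ bracket [1, 10⁶];
p-to-z conversion is two-sided; pruning coordinates are 1-based with
inclusive 30 kb boundary (markers exactly 30 kb apart both survive) and
|z| ties broken toward the smaller position; degenerate inputs (constant z,
empty selections, non-concave likelihoods) raise typed errors rather than
returning numbers.

## Known limitations

* The exponential (or fixed-shape gamma) form is a theoretical prior, not a
  fact; misspecification propagates directly into the variant count, and
  decreasing the gamma shape at fixed data systematically raises it.
* Correlated markers violate the independence assumption; 30-kb pruning is
  a blunt remedy that trades bias for variance.
* The fixed-RAF power model ignores the modest RAF-dependence of power at
  matched Vg (up to ~10 percentage points in the steep region).
* lfdr estimation is itself noisy; its error contributes to (and is
  absorbed by) the reported RMSE of fdr-mode estimators.
* Heritability enters as an external constant; its uncertainty is not
  propagated.
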