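# Methods

## Model and hypotheses

For one gene set, the data are `(x_i, g_i, y_i)` with non-genetic covariates
`x ∈ R^m`, minor-allele counts `g ∈ {0,1,2}^p` and a continuous or binary
trait. The working model is a generalized linear mixed model in which the
genetic contribution `h(g) = βᵀg` carries a Gaussian prior
`β ~ N(0, τ diag(w))`, `w ∈ Δ_p`. Testing no association, `H₀: β = 0`, is
then equivalent to the variance-component hypothesis `H₀: τ = 0`, which the
score test addresses by fitting only the null GLM `η(μ) = α₀ + xᵀα`
(identity link for Gaussian traits, logit for Bernoulli).

Quantities from the null fit: means `μ̂₀`, raw residuals `r = y − μ̂₀`,
dispersion `φ̂₀` (ML residual variance for Gaussian — the sum of squared
residuals over n; fixed at 1 for Bernoulli), conditional variances
`v_i = σ̂₀²` or `μ̂₀ᵢ(1−μ̂₀ᵢ)`, and the weighted projection
`P₀ = V − VX̃(X̃ᵀVX̃)⁻¹X̃ᵀV` with `X̃ = [1|X]`. The intercept is always
internal; input covariate files must not contain a constant column. An
`n − m − 1` dispersion denominator is available via `fit_null(...,
dispersion="unbiased")` because SKAT implementations differ on this point.

## Score tests

SKAT statistic for the weighted linear kernel `K_w = G diag(w) Gᵀ`:
`Q = rᵀK_w r/φ̂₀`, evaluated in factored form `Σ_j w_j (g_jᵀr)²/φ̂₀`. The
asymptotic null distribution is `Σ_j λ_j χ²₁` with `λ` the nonzero
eigenvalues of `P₀^½K_wP₀^½/φ̂₀`; these are computed from the similar p×p
matrix `diag(√w)·B·diag(√w)/φ̂₀`, `B = GᵀP₀G`, since n ≫ p in the intended
regime. The burden test collapses `c_i = Σ_j G_ij` (or `max_j G_ij`) and
refers the GLM score statistic `(cᵀr)²/(cᵀP₀c)` to `χ²₁`. Note the
denominator carries no extra `φ̂₀` factor: `P₀` as defined already contains
one factor of the conditional variance, and this normalization is what makes
the p = 1 burden and SKAT procedures coincide exactly (a property the test
suite checks to 1e-10).

Fixed weight choices: uniform, or the Beta(a, b) density of the per-variant
*sample* MAF with a = 1, b = 25 — squared by default (the original SKAT
convention; `squared=False` disables it) and always renormalized onto Δ_p so
every method shares the same simplex constraint. Monomorphic variants keep
the pdf value at MAF 0 with a warning rather than being dropped.

## Mixture-of-chi-square tails

`Pr(Σλ_j χ²₁ ≥ q)` is evaluated by numerical inversion of the
characteristic function (Imhof's representation of the Davies approach). The
oscillatory integrand `sin(θ(u))/(u ρ(u))` is split into cos(qu/2) and
sin(qu/2) components and each piece is integrated on (0, ∞) with QUADPACK's
oscillatory-weight (QAWF) rule, target absolute accuracy 1e-9, subinterval
limit 1e5. Eigenvalues below `1e-10 · max λ` are dropped first (numerical
zeros from rank deficiency). If the quadrature cannot certify its accuracy
or returns a value outside [0,1], the caller falls back to the
Liu–Tang–Zhang moment-matched noncentral-chi-square approximation and
records the fallback in the result metadata. The inversion is validated
against the χ²₁ and Exp(1) closed forms (1e-6) and a 10⁶-draw Monte Carlo
oracle (4 SE over 20 random specs).

## Learning the kernel weights

With `s = (Gᵀr)²` and `b = diag(B)`, the objective

    J(w) = wᵀs / √(wᵀ(B⊙B)w)  =  Q(w) / ‖λ(w)‖₂

(an identity the suite verifies to relative 1e-8 on random continuous and
binary instances — the module's central correctness check) is maximized over
the simplex by solving `min_{z≥0} zᵀ(B⊙B)z − 2zᵀc` and normalizing, valid
because J is scale-invariant. `B⊙B` is PSD (Schur product of PSD matrices);
the QP is solved exactly by Lawson–Hanson NNLS on the Cholesky
factorization, with a ridge retry (`1e-8·tr(B⊙B)/p`) when the factorization
fails. If the minimizer is the origin (no positive component of `c`),
uniform weights are returned with a `no_signal` flag so the pipeline always
yields a valid, if powerless, test.

The default learning objective uses `c = s`; the *centered* objective
`c = s − b` subtracts each component score's null mean (`E[s_j] = b_j φ̂₀`
under H₀ up to the dispersion convention) and is the form that enters the
concentration bound

    p₀(Q(w)) ≤ exp(−min(J̃(w), J̃(w)²)/8),

which follows from sub-exponential (Bernstein-type) tail bounds for weighted
chi-square sums; the `min(J̃, J̃²)` switch is implemented literally at
|J̃| = 1. A nominal level `10^−a` is certifiable whenever
`a ≤ min(J̃, J̃²)/(8 ln 10)`. The bound holds for *any* w, learned or not,
and is checked numerically on null instances. The centered objective is also
available as the learning criterion (`centered=True`); it is the better
choice when the question is support recovery rather than raw power, because
the uncentered `c = s` rewards variants with large null variance `b_j`
(common variants) regardless of signal.

## Split-learn-test procedure

`ecskat_test` draws a seed-controlled random partition — stratified by class
for binary traits so both splits keep the case:control ratio — learns `w*`
on the 30% learning fraction (configurable), refits the null model on the
held-out fraction and runs the SKAT test there with `w*` fixed. Refitting on
each split matters: reusing learning-split nuisance estimates in the
held-out score test would break its validity. The reported p-value comes
only from held-out samples, so under H₀ it is uniform regardless of how the
weights adapted — the type-I-error benchmark confirms calibration at
n = 1000 over 500 replicates. `J`, `J̃` and the bound are learning-split
quantities.

## Beyond per-variant kernels

`multi_kernel_stats` generalizes the sufficient statistics to arbitrary PSD
base kernels: `s_l = rᵀK_l r`, `M_lm = tr(P₀K_lP₀K_m)`; with per-variant
rank-one kernels this reduces exactly to `(s, B⊙B)`. Annotation-weighted
kernels `K_l = G diag(φ_l(a_l)) Gᵀ` are handled by passing the feature
matrices `G diag(√φ_l)`; cross-validated selection of aggregation functions
φ_l is out of scope. Kernel PSD-ness is checked by a jittered Cholesky.

## Synthetic data

The generator emulates the benchmark conditions: MAFs i.i.d. from a
truncated power law `∝ m^(−1)` on (5·10⁻⁴, 0.05) via inverse-CDF sampling
(exponent and range configurable); genotypes `Binomial(2, maf)` under
Hardy–Weinberg with independent variants (no LD); covariates one
Bernoulli(0.5) and one N(0,1) column with effects (0.5, 0.5); trait

    η = α₀ + αᵀx + βᵀg + gᵀΓg,

with `⌈0.1·p⌉` causal variants, `|β_j| = c·|log₁₀ maf_j|/2` (the standard
rare-variant effect-size law; c = 0.6 continuous, 1.0 binary), signs i.i.d.
±1 — the regime where burden collapsing cancels signal. Γ is symmetric,
zero-diagonal, supported on causal pairs with entries `0.3·N(0,1)` when the
misspecification setting is on, and exactly zero otherwise; the fitted
models never include the interaction term, so a nonzero Γ probes graceful
degradation under misspecification. Continuous noise is N(0, 1); the binary
intercept is solved by bisection for 20% prevalence. Everything is
reproducible from (config, seed).

What the generator does *not* emulate: linkage disequilibrium, genuine
population-structure covariates, annotation channels, and empirical genotype
distributions (a `resample_semiempirical` helper subsamples any real dataset
without replacement for semi-empirical nulls). Calibration and power results
under this generator therefore speak to the independent-variant HWE regime,
not to strongly correlated real cohorts.

## Benchmark harness

Rejection fractions per (method, α) over replicated simulations, each
replicate seeded as `default_rng([seed, rep])` so replicate subsets
reproduce independently of execution order; ecSKAT's split randomness is
drawn from the same per-replicate stream. Intervals are Wilson 95% (normal
approximations misbehave at the 0/1 boundary that power experiments reach).
A method erroring on a replicate is counted and excluded from its
denominator, never silently dropped. Problem sizes used by the shipped
experiments: calibration at n = 1000 with 500 replicates; power at
n = 10,000 with 200 replicates and levels 0.1 and 10⁻³; weight recovery at
n = 5000 averaged over 10 replicates.

## Numerical choices and degenerate inputs

* Rounded-mean imputation for missing genotypes (mode available) keeps the
  {0,1,2} domain; variants with all calls missing are errors.
* Variants whose sample allele frequency exceeds 0.5 are flipped to
  minor-allele coding with a warning.
* VCF input: GT fields only, diploid, first ALT; multi-allelic sites
  skipped with a warning.
* Logistic null fits: IRLS (statsmodels GLM), 100 iterations, tol 1e-8;
  non-convergence and separation raise instead of returning huge
  coefficients.
* `P₀` is applied as an operator (two solves against the (m+1)×(m+1)
  weighted Gram matrix); a dense path exists for n ≤ 2000 for testing.
* Null eigenvalues: negatives clipped at zero; an all-zero spectrum (gene
  set inside the null design span) raises an untestable-set error.
* Genotype-scale invariance: multiplying G by c > 0 leaves the learned
  (normalized) weights and p-values unchanged.

## Known limitations

* Learned weights cannot recover extremely rare causal variants — with tens
  of carriers the component score carries almost no information, and their
  share of the causal weight mass is redistributed; support recovery
  improves steadily with sample size (and with the centered objective) but
  is imperfect at moderate n.
* The certified p-value bound is loose in typical data (it is a
  concentration inequality, not an approximation); it certifies levels, it
  does not estimate p-values.
* Asymptotic null distributions throughout: no small-sample or binary-trait
  moment corrections, no resampling p-values, no SKAT-O style grid.
* Single gene set per invocation; genome-wide batching is a thin outer loop
  left to the caller.
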