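# Methods

This note documents the statistical content of `cpgset`: the models behind
the seven set tests, the synthetic-data generator, the numerical choices,
and the limitations a user should know before trusting a number.

## The testing problem

Let `G` be an n × p matrix of methylation β-values (proportions in [0, 1])
for one CpG set, `y` a 0/1 case/control indicator, and `X` optional
covariates.  All regression-based tests work under the logistic model

    logit P(yᵢ = 1) = α₀ + α′Xᵢ + β′Gᵢ ,

testing H₀: β = 0 jointly.  CpGs within a set are correlated (methylation
correlation decays within a few hundred bp, loosely analogous to LD
blocks), which is exactly the structure a joint test can exploit and a
per-CpG Bonferroni correction wastes.

## The seven tests

**PCA.** Columns of `G` are centered (not variance-scaled — β-values share
the [0, 1] scale; correlation-based PCA is available via `scale=True`) and
the k leading principal components covering at least the `variance_threshold`
(default 0.80) of total variance replace the p CpGs.  Significance is a
k-df likelihood-ratio test: twice the log-likelihood gap between the
logistic fits with and without the k score columns, referred to χ²_k.
Score columns numerically collinear with the null design are dropped and
the df reduced accordingly.

**Supervised PCA (SPCA).** Each CpG is scored by its univariate logistic
score z-statistic against the null model; the set is screened down to the
top fraction of CpGs, PC₁ of the retained columns is extracted, and the
statistic is the Wald T = β̂₁/se(β̂₁) from the logistic fit of `y` on PC₁.
The screening fraction is chosen adaptively from `screen_fraction_grid`
(default 0.1…1.0) to maximize |T|; a K-fold cross-validated variant
(`selection="cv"`, held-out log-likelihood gain) is available.  Because
screening and tuning are outcome-driven, T has no usable closed-form null;
the p-value is a **full-procedure permutation** p-value: labels are
permuted and screening + selection + PC₁ + Wald fit are recomputed per
permutation, p = (1 + #{|T_perm| ≥ |T_obs|}) / (B + 1).  The max-|T| rule
was chosen over per-permutation cross-validation as the default because it
is an order of magnitude cheaper at identical permutation validity (the
selection rule is applied identically to observed and permuted data; the
permutation null absorbs the selection bias either way), which is what
makes 10³–10⁴-replication Monte Carlo studies with SPCA practical.

**Kernel PCA (KPCA).** Rows are compared through the RBF kernel
K_ij = exp(−σ‖xᵢ−xⱼ‖²) with σ = 0.01 by default.  *Convention warning:*
this is the inverse-width parameterization; texts using
exp(−‖x−x′‖²/(2σ²)) differ by a factor 2σ².  The kernel is double-centered
(feature-space centering), eigendecomposed, and the components covering
80 % of the eigenvalue mass are retained; their scores (eigenvectors ×
√eigenvalue) enter the same k-df logistic LRT as PCA.  With a linear kernel
this reproduces ordinary PCA exactly (unit canonical correlations — a test
asserts this), which is the main cross-check of the kernel machinery.
For n > 512 only the leading eigenpairs are extracted iteratively (ARPACK),
with the retained count still judged against the full kernel trace.

**SKAT.** The CpG effects are modeled as random with variance w_j τ and
H₀: τ = 0 is tested by the variance-component score statistic
Q = (y−μ̂)′GWWG′(y−μ̂) = ‖WG′(y−μ̂)‖², with μ̂ from the null logistic fit
and W = I (every CpG weighted equally).  Under H₀, Q is a weighted sum of
χ²₁ variables with weights equal to the eigenvalues of (GW)′P₀(GW),
P₀ = V − VX̃(X̃′VX̃)⁻¹X̃′V, V = diag(μ̂(1−μ̂)).  Eigenvalues below
10⁻¹⁰·λ_max are dropped.

**Mixture-of-χ² tails.** P(Σλ_mχ²₁ > q) is computed by Imhof's
characteristic-function inversion: composite 12-point Gauss–Legendre
panels no wider than half an oscillation period (π/(Σλ+q) on the
λ_max-normalized scale), truncated where an explicit amplitude/alternation
bound certifies the tail below 10⁻⁸.  This is exact to ~10⁻⁵ (validated
against adaptive quadrature and 10⁶-draw Monte Carlo) and runs in ~0.5 ms.
If the inversion fails to converge or returns a value outside [0, 1], the
Liu–Tang–Zhang moment-matching approximation is used and flagged in the
result's diagnostics (`pvalue_method`).  Single-eigenvalue spectra and
q = 0 use closed forms.

**SIR.** Predictors are standardized, Z = Σ̂_GG^{−1/2}(G − Ḡ), the response
is sliced (the two outcome classes for binary y; quantile slices
otherwise), and the weighted between-slice covariance of slice means
M = Σ_h p̂_h m̂_h m̂_h′ is eigendecomposed.  The set test is the classical
dimension test of "no directions": n·Σλ̂ referred to χ² with p(H−1) df
(df = p for binary outcomes).  A ridge 10⁻⁸·tr(Σ̂)/p is added when the
covariance is near-singular.

**Hotelling T².** Classical two-sample T² with pooled covariance and the
exact F transformation F = T²(n₁+n₂−p−1)/(p(n₁+n₂−2)) on
(p, n₁+n₂−p−1) df.  Requires at least p+1 observations per group.

**Bonferroni min-p t-test.** Pooled-variance two-sample t per CpG (Welch
via `equal_var=False`); the set p-value is min(1, p · min_j p_j).  This is
the single-site baseline: valid but increasingly conservative as the
within-set correlation grows, because the effective number of independent
tests falls below p.

Zero-variance CpG columns are dropped with a logged warning before
PCA/SPCA/min-p (SKAT tolerates them natively — they contribute nothing to
Q or the spectrum).

## The synthetic-data generator

**Marginals.** Each CpG's β-value follows Beta(a_j, b_j) parameterized by
mean μ_j and precision φ_j = a_j + b_j (variance μ(1−μ)/(1+φ)).  The
benchmark scenarios use φ = 10 everywhere, which gives methylation-like
spread on (0, 1) at any mean in 0.2–0.8 without mass piling at the
boundaries; it is exposed in every constructor.

**Dependence.** A Gaussian copula: latent z ~ N(0, R_latent), transformed
coordinate-wise by Φ and the beta quantile function.  Because this
transform shrinks Pearson correlations, `calibrate_copula` finds, for each
pair, the latent ρ* whose induced β-value Pearson correlation matches the
target: the induced correlation is evaluated by 48-node tensorized
Gauss–Hermite quadrature and inverted by bisection (Brent) — a
deterministic version of the "search for the copula correlation" that
copula-based random-number generators perform.  Targets outside the
attainable (Fréchet) range raise an error naming the pair.  The assembled
latent matrix is projected to the nearest PSD correlation matrix
(eigenvalue clipping at 10⁻⁸, diagonal rescaling) if indefinite, and the
induced correlations are re-verified after repair.  Sampling fidelity at
n = 10⁵ is within ±0.02 of the target for the exchangeable grids and both
real-template matrices (tested).

**Bulk quantile evaluation.** The sampler maps latent normals through a
per-marginal lookup table q(z) = F⁻¹(Φ(z)) tabulated at 2049 nodes on
z ∈ [−6.5, 6.5] (exact quantiles at the nodes, linear interpolation in
between, interpolation error ~10⁻⁶).  An `exact_ppf` flag bypasses the
table; calibration always uses exact quantiles.

**Disease model and quotas.** Outcomes follow
logit P(D=1) = β₀ + Σ_j β_j G_ij over the causal CpGs (1-based positions
within the set; C = 0 is the null).  The built-in alternative scenarios set
β₀ = −Σ β_j μ_j so the expected prevalence is ≈ ½, matching the balanced
quotas and keeping prospective sampling efficient.  `sample_case_control`
draws individuals in batches, assigns outcomes by Bernoulli(p), and keeps
them until the case and control quotas are exactly met (draw budget 1000 ×
quota; exceeding it raises an error that reports the acceptance rates);
rows are returned in randomized order.

**Scenario library.** Ten virtual scenarios (10 CpGs, 1000+1000, exchangeable
r ∈ {0.2, 0.4, 0.6, 0.8}; family 1 with a common marginal mean, family 2
with means 0.2, 0.2, 0.3, 0.4, 0.5, 0.5, 0.6, 0.7, 0.8, 0.8; causal
positions and effect grids per scenario) and two real-template scenarios
("PTPRD" 6×6, "MLH1" 9×9, 50+50) whose target correlation matrices are
sample correlations of CpGs within 1 kb of those genes in 450K whole-blood
data.  The templates' marginal means are not derivable from the correlation
matrices; the default μ = 0.5, φ = 10 is a deliberate neutral choice —
type I error behavior on these scenarios is driven by the correlation
structure, not the means.

**What the generator does not emulate:** genome-scale probe counts, batch
effects, group-specific variances, cell-type composition, the
bimodal island/shore mean distribution of real arrays, or missingness.
Calibration results here therefore support the *relative* behavior of the
tests under block-correlated beta data, not absolute guarantees on any
particular real dataset.

## The Monte Carlo harness

Replication t of a run with `base_seed` s uses dataset seed s + t, so any
single replication can be regenerated in isolation and parallel execution
(joblib, partitioned by replication) cannot change results.  All requested
methods see the same dataset within a replication (common random numbers),
which sharpens between-method power comparisons.  A method error inside a
replication is logged and counted separately — never silently treated as a
non-rejection — and a summary with > 1 % errored replications is flagged
invalid.  Reported uncertainty is the binomial Monte Carlo standard error
√(r(1−r)/R).

Default replication counts in the shipped benchmark reproduction follow
the study design: 5000 for type I error, 500–1000 for power curves, with
the power-vs-correlation trend check run at a reduced 300-sample size so
the kernel test's n × n eigendecompositions stay cheap.

## Numerical and degenerate-input policy

- Logistic fits: Newton–Raphson with step-halving, warm-started intercept,
  convergence at relative log-likelihood change 10⁻¹⁰; complete separation
  raises a flagged error (the LRT treats a separated alternative via its
  limiting likelihood).  The SPCA permutation path uses a damped (step-
  clipped), predictor-standardized two-parameter Newton batched across
  permutations; slopes beyond 25 log-odds per SD are treated as separated.
- PCA/KPCA retained dimension: smallest k with cumulative explained
  fraction ≥ threshold; ties broken toward fewer components; rank-deficient
  tails never retained.
- SIR standardization: symmetric eigendecomposition inverse square root
  with ridge 10⁻⁸·tr/p when the smallest eigenvalue < 10⁻¹⁰ × largest.
- Degenerate inputs raise (constant phenotype, constant CpG set, groups
  smaller than p+1 for T²) rather than returning a p-value.

## Known limitations

- The asymptotic k-df LRT (PCA/KPCA) is slightly liberal in small samples:
  on the 100-sample MLH1 template its measured level is ≈ 0.059 at nominal
  0.05 (and ≈ 0.048 by n = 400).  This is the familiar O(1/n) likelihood-
  ratio bias, not a calibration bug; the permutation-based SPCA and the
  exact-F T² do not share it.
- SPCA's permutation p-value has resolution 1/(B+1); with the default
  B = 199 the smallest attainable p-value is 0.005.
- SIR with a binary outcome has only H = 2 slices, hence at most one
  nonzero direction; its dimension test spends p df on a rank-1 signal,
  which is why it trails the other set tests in power.
- Permuting labels also breaks any y–X covariate association; with
  confounded covariates SPCA's permutation null is approximate.
- The min-p t-test's conservatism under strong correlation is a property,
  not a defect — it is the baseline the set tests are measured against.
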