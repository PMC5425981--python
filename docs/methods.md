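# Methods

This note documents the models, the simulator, the numerical choices and the
known limitations of `cispred`.  Notation: **y** is an n-vector of expression
measurements, **X** an n × p matrix of cis-SNP dosages in [0, 2], and
variances written `σ_b²`, `σ_a²` are scaled by the residual variance `σ_e²`
(dimensionless ratios), as is conventional for these models.

## Prediction models

### Penalized regression (Lasso, elastic net)

The objective is

    Q(β) = (1/n)(y − Xβ)ᵀ(y − Xβ) + Σⱼ P_λ(|βⱼ|)
    Lasso: P_λ = λ|β|        ENET: P_λ = λ(α|β| + (1 − α)β²)

Deliberately, neither the squared error nor the quadratic penalty carries a
factor ½.  This differs from the glmnet / scikit-learn parameterization by a
factor of two; the mapping is `α_sk·l1 = λα/2`, `α_sk(1−l1) = λ(1−α)`, which
the test suite uses to cross-check coefficients against scikit-learn.  Under
this objective the coordinate update for standardized columns
(xⱼᵀxⱼ/n = 1) is

    βⱼ ← S(ρⱼ, λα/2) / (1 + λ(1−α)),   ρⱼ = xⱼᵀrⱼ/n,

and the null model is optimal for λ ≥ λ_max = 2·maxⱼ|xⱼᵀy|/(nα).

Implementation: cyclic coordinate descent with covariance ("Gram") updates —
G = XᵀX and c = Xᵀy are formed once and each coordinate visit costs O(1)
plus an O(p) update of Gβ when a coefficient actually moves — alternating
full sweeps with sweeps over the active (nonzero) set; convergence requires
a *full* sweep with max|Δβ| < tol.  A residual-update kernel (O(n) per
coordinate) is kept for p > 2000, where the Gram matrix stops paying for its
memory, and as an internal cross-check.  Both kernels are numba-compiled.

Tuning: λ runs on a geometric 100-point grid from λ_max down to
0.01·λ_max when p ≥ n (1e-3·λ_max otherwise — the glmnet convention; under
tight cis-LD the deeper tail is a saturated-interpolation regime that costs
~50× the rest of the path and is never selected).  k-fold cross-validation
(default 100 folds, clamped to n; the desk preset uses 20) re-standardizes X
within each training fold, fits the path with warm starts, and scores pooled
held-out squared error; the selected λ minimizes the mean curve, with ties
resolved toward the larger (sparser) λ.  A `cv_rule="1se"` option selects
the largest λ within one standard error of the minimum — the better choice
when the prior expectation is a null or near-null model.  CV fits run at a
relaxed tolerance max(tol, 1e-3); the returned model is refit at the full
tolerance (default 1e-7, max 10,000 sweeps).  λ-selection was verified
insensitive to the relaxation (identical λ and test R² to 4 d.p. on
scenario-I data).

Columns are standardized to unit 1/n-variance internally and coefficients
back-transformed; y is centered by its training mean.  Zero-variance columns
standardize to zero and can never enter the model.

### Linear mixed model

    y = Xβ + ε,  ε ~ N(0, σ_e²I),  βⱼ ~ N(0, σ_b²σ_e²/p)

equivalently y ~ N(1b₀, σ_e²(σ_b²K + I)) with K = X_cX_cᵀ/p on
column-standardized genotypes.  Standardizing (not merely centering) before
forming K makes the per-SNP prior exchangeable; a `standardize=False` switch
keeps the centered-only variant.  Narrow-sense heritability is
h² = σ_b²/(σ_b²+1).

REML: K is eigendecomposed once; for each candidate ratio σ_b² the
restricted log-likelihood with a single fixed effect (the intercept,
estimated by GLS in the eigenbasis) is evaluated in O(n), with σ_e²
profiled out in closed form.  The maximizer is found by a 60-point coarse
scan over log σ_b² ∈ [log 1e-5, log 1e5] followed by bounded Brent
polishing (xatol 1e-10); the coarse scan guards against the rare flat or
multimodal profile.  A `boundary` flag marks optima within 1e-3 of a search
bound (σ_b² → 1e-5 means no detectable genetic variance).

Prediction is BLUP, implemented in two algebraically identical routes that
the tests require to agree to 1e-8: effect-space
(β̂ = (σ_b²/p)X_trainᵀV⁻¹ỹ, equal to ridge regression with penalty p/σ_b²)
and kinship-space (σ_b²K_test,train V⁻¹ỹ), where ỹ is the training response
minus its GLS intercept.  Test genotypes are standardized with training
means/scales; the intercept is added back.  Both n > p and p > n are
handled through the n × n eigendecomposition.

### Bayesian sparse linear mixed model

    y = Xβ̃ + u + ε,  u ~ N(0, σ_b²σ_e²K),  β̃ⱼ ~ πN(0, σ_a²σ_e²) + (1−π)δ₀

with K = XXᵀ/p, so u = Xβ with βⱼ ~ N(0, σ_b²σ_e²/p): a hybrid of the
polygenic LMM and a sparse model, selecting large effects through the
inclusion indicator γ.

Sampler: Metropolis-within-Gibbs.  Per iteration, five γ-moves — add,
remove or swap a SNP with base probabilities 0.40/0.40/0.20 (renormalized
when a move type is unavailable, with the matching Hastings correction) —
followed by one joint random-walk move on the free hyperparameters (log π
step 0.5; log σ_a², log σ_b² steps 0.7).  Several indicator proposals per
recorded iteration is standard practice for spike-and-slab samplers, whose
γ-mixing is the bottleneck.  Addition candidates are drawn from a 50/50
mixture of a uniform draw over excluded SNPs and a draw weighted by
1/(rank + 10) on the marginal-association ranking |xⱼᵀy| — SNPs likely to
matter are proposed more often, and the Hastings ratio accounts for the
asymmetry exactly, so the stationary distribution is untouched.  σ_b² is
initialized at the peak of the empty-model marginal likelihood (a 33-point
scan on the already-computed eigendecomposition), which shortens burn-in.

Conditional on (γ, σ_a², σ_b²), β̃ and σ_e² are integrated out analytically: with H = σ_a²X_γX_γᵀ + σ_b²K + I and a
scale-invariant prior on σ_e²,

    p(y | γ, σ_a², σ_b²) ∝ |H|^(−1/2) (yᵀH⁻¹y)^(−n/2),

evaluated after one eigendecomposition of K via a rank-|γ| Woodbury
identity, so an iteration costs O(n|γ|² + |γ|³).  Proposals that make the
rank-|γ| system numerically singular are rejected and counted, never fatal.
|γ| is capped at `s_max` (default 300).

Hyperpriors: log π uniform on [log(1/p), 0]; log₁₀ σ_a² and log₁₀ σ_b²
uniform on [−5, 5].  These ranges are a declared design choice (vague,
bounded, testable) and are configurable; each hyperparameter can also be
pinned.  Pinning π = 0 removes the sparse part and the sampler provably
collapses to the LMM (tested: BLUP prediction correlation ≥ 0.99); pinning
π = 1 includes every SNP.

Posterior summaries are Rao-Blackwellized: at every retained draw the
*conditional* posterior means E[β̃|y,θ] = σ_a²X_γᵀH⁻¹y and
E[β|y,θ] = (σ_b²/p)XᵀH⁻¹y are accumulated (cached between draws while the
chain state is unchanged), along with per-SNP inclusion frequencies.  σ_e²
is drawn from its inverse-gamma conditional.  The per-draw PVE is

    PVE = (var(ĝ) + σ_e²(n − tr H⁻¹)/n) / (var(ĝ) + σ_e²(n − tr H⁻¹)/n + σ_e²)

where ĝ is the conditional-mean genetic value and the trace term is
tr Cov(g|y,θ)/n, the Rao-Blackwell correction for the variance the
conditional mean leaves out; values are clipped to [0, 1].  Prediction for
new individuals is X_test(E[β̃|y] + E[β|y]) plus the training mean —
averaging effect vectors equals averaging per-draw linear predictors.

Chain lengths: the estimator defaults to 2,000 burn-in + 2,000 sampling
iterations (the desk-scale study setting); `McmcConfig` carries the larger
presets (10,000 + 10,000 for simulation studies; 2,000 burn-in + 10,000
sampling for observed data).  Thinning defaults to 1.  Two chains with
different seeds agree on mean predictions with correlation ≥ 0.95 on a
fixed gene (tested); no further convergence diagnostics are built in.

## Simulator

`simulate_genotypes` emulates the cis-region of a single gene *after* MAF
filtering: per-SNP allele frequencies are drawn uniformly on
[maf_low, maf_high] (default [0.05, 0.5]); each of the 2n haplotypes is a
latent AR(1) Gaussian across SNPs with autocorrelation `ld_rho` (default
0.9, mimicking tight cis-LD) thresholded at the frequency quantile; dosages
sum two haplotypes.  Because a thresholded draw can land below the floor by
sampling error, the realized minor-allele count is floored at
ceil(2n·maf_low) by shifting that SNP's threshold to the appropriate order
statistic of its latent column — LD is preserved and the matrix satisfies
the filter it is meant to have passed.  Positions are cumulative random
gaps (1–1000 bp); the default region is sized like a dense cis-window.

`simulate_gene` draws standard-normal effect sizes and builds expression
under three architectures: (I) all SNPs polygenic plus `n_sparse` large
effects, (II) polygenic only, (III) sparse only.  Scaling is *exact*
in-sample, by construction rather than in expectation:

* the sparse genetic component is residualized against the polygenic one
  (the adjustment is absorbed into the stored polygenic effect vector, so
  `beta_sparse` stays supported exactly on `sparse_indices`);
* the two orthogonal parts are scaled to `polygenic_share` and
  `1 − polygenic_share` of the genetic variance (default split 0.60/0.40 in
  scenario I — interpreted as the split *of the genetic variance*, the only
  reading compatible with total PVE ≤ 0.5; the share is configurable);
* the Gaussian residual is residualized against the genetic values and
  rescaled so that var(g)/(var(g)+σ²) equals `total_pve` to machine
  precision (population-variance convention, phenotypic variance 1).

Effects are redrawn per replicate; per-replicate streams derive from
SeedSequence(seed, replicate), so replicates are independent and exactly
reproducible.  The same SNP may carry both a polygenic and a sparse effect.

What the simulator does *not* emulate: recombination-map or coalescent
haplotype structure, population stratification or relatedness, non-Gaussian
expression noise, and trans effects.  Passing benchmarks on these data show
the estimators behave correctly under their own modeling assumptions; they
do not certify performance on real cohorts.

`simulate_gene_landscape` scatters scored genes uniformly over a genome
(chromosomes weighted by length) and marks genes predictive with probability
`base_rate` outside and `base_rate × enrichment_factor` inside a designated
region; R² values are drawn above/below the 0.05 threshold accordingly.
Note the measured fold of the planted region is f/((1−ρ) + fρ), not f, for
a region occupying share ρ of the reference — the enriched genes inflate
the reference set too.

## Evaluation protocol

Individuals are split 80/20 by a seeded permutation, |train| =
round-half-up(0.8·n) (465 → 372/93).  R² is the squared Pearson correlation
between predicted and observed test expression; a constant prediction
returns 0 by convention (a constant predictor carries no signal; Pearson is
undefined there).  The study engine crosses architectures × PVE levels ×
20 replicates, refitting every method per replicate; a failing method leaves
a NaN cell and a logged reason.  Summaries report mean, sd and median per
cell (mean and median can disagree at small replicate counts; both are
exported).  Desk-scale defaults — n = 400, p = 500, 20 CV folds,
2,000 + 2,000 chains — keep a full three-scenario study in minutes; the
`paper` preset restores 100 folds and 10,000 + 10,000 chains.

Per-gene runs on observed data quantile-normalize expression to N(0, 1) via
ranks (Φ⁻¹((rank − 0.5)/n), average ranks on ties) *before* splitting, as
the protocol it mirrors does; this uses all samples' ranks and is a known,
accepted leakage of rank information across the split.  The cis-window
[gene_start − 1 Mb, gene_end + 1 Mb] is closed on both ends; the MAF ≥ 0.05
filter (inclusive) is recomputed on the analysis sample after the window
cut.  Coordinates are 1-based closed internally; BED converts at the reader.

## Enrichment statistics

A gene is predictive when its test R² ≥ 0.05 (inclusive).  Genes belong to
a region through their midpoint, so a partition counts every gene exactly
once.  The enrichment-fold of a region is the ratio of its predictive-gene
share to its length share; per-block scans default to a within-chromosome
reference (the reference set is the chromosome's predictive genes, the
reference length the chromosome length), with a genome-wide option.
Length-weighted folds over a partition therefore average to exactly 1 per
chromosome.  Blocks on chromosomes with no predictive genes report NaN and
are excluded from summaries.  Region lengths are end − start + 1; regions
meant to span round megabase counts should be specified accordingly
(e.g. [26,000,001, 34,000,000] for an 8 Mb region).

The significance of one region's fold against a set of background folds
uses an approximate z-test: z = (fold − mean)/sd(background), one-sided
upper normal p-value.  This construction — statistic scale, sidedness,
background definition — is a declared interpretation; no multiple-testing
correction is applied.

## Problem sizes and determinism

The shipped studies and tests run at n = 400, p = 500 with 20 replicates
and 2,000 + 2,000 chains; the generator reproduces the full 465 × 5,818
scale on demand.  Every stochastic component (genotypes, effects, splits,
CV folds, MCMC) takes an explicit seed; deterministic methods produce
byte-identical outputs across reruns, and the MCMC is exactly reproducible
for a fixed seed.

## Known limitations

* Single variance component: no separate trans or multi-kinship terms.
* The penalized models support Gaussian responses only (no MCP/SCAD, group
  or fused penalties, no logistic variant).
* BSLMM convergence is assessed only through the seed-agreement property;
  long-range LD between included SNPs can slow γ mixing.
* The quantile-normalization-before-split leakage noted above.
* The z-test treats per-block folds as exchangeable and roughly normal;
  blocks with few predictive genes have heavy-tailed folds.
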