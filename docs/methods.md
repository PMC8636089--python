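# Methods

## Model

Expression is modeled as Y = X B + L + 1 μᵀ + e over n samples, p SNPs and
q genes. B (p × q) carries the genotype effects and is assumed sparse: only
a small fraction of SNPs regulate expression, each affecting a limited set
of genes. L (n × q) carries the aggregate effect of a small number of hidden
non-genetic factors, hence is assumed low-rank. e has i.i.d. N(0, σ²)
entries. Missing expression values are handled through a binary mask Ω: the
loss sums only over observed cells, so placeholders at unobserved cells can
never influence the fit (a property the test suite checks bitwise).

The estimator minimizes the convex program

    ½‖P_Ω(Y − XB − L − 1μᵀ)‖_F² + ρ‖L‖_* + λ₁‖B‖₁ + penalty₂(B),

with the reparameterization λ₁ = λα, λ₂ = λ(1−α) familiar from glmnet. At
α = 1 the B-penalty reduces to the lasso; α < 1 adds a ridge-like term that
removes the lasso's n-predictor saturation and its one-per-LD-block
selection behavior.

### The two B-penalty variants

The elastic-net term is stated as (λ₂/2)‖B‖_F², but the columnwise update
operator commonly used with it,

    b ← {1 − λ₂ / max(‖b‖₂, λ₂)} · b,

is the proximal operator of the *unsquared* group norm λ₂‖·‖₂, not of the
squared Frobenius term. Both readings are implemented and both are exposed:

* `penalty_variant="as_printed"` (default): soft-threshold at t_B·λ₁ then
  columnwise L2-shrink at t_B·λ₂. The composition is exactly the
  sparse-group-lasso prox of t_B(λ₁‖·‖₁ + λ₂‖·‖₂), so the fixed point
  solves the program with penalty₂(B) = λ₂·Σⱼ‖B[:,j]‖₂.
* `penalty_variant="exact_elastic_net"`: the exact prox
  soft_threshold(·, t·λ₁)/(1 + t·λ₂), solving penalty₂(B) = (λ₂/2)‖B‖_F².

A strict `as_printed_threshold` flag applies the shrinkage levels λ₁, λ₂
literally (unscaled by the step size); this solves a rescaled program and is
provided only for one-to-one comparison with implementations that do the
same. Both variants' final objectives are verified in the tests against an
independent monolithic (non-alternating) FISTA solver to 1e-5 relative.

## Algorithm

Each outer iteration takes one proximal-gradient step per block, in the
order L (using the current B), B (using the fresh L), μ:

* L-step: singular-value shrinkage `svt(L − t_L·P_Ω(residual), t_L·ρ)`;
* B-step: gradient step `B − t_B·Xᵀ P_Ω(residual)` followed by the variant's
  prox;
* μ-step: plain gradient descent (no penalty).

Choices the formulation leaves open, and what this package does:

* **Initialization**: B₀ = 0, L₀ = 0, μ₀ = observed column means of Y —
  deterministic and feasible.
* **Step sizes** ("auto"): reciprocal Lipschitz constants of each block's
  smooth part — t_L = 1, t_μ = 1/n, t_B = 1/‖X‖₂² (power iteration, 1e-6
  relative tolerance). An optional Beck–Teboulle backtracking line search
  (shrink factor 0.5, sufficient-decrease test, warm-started step) is
  available via `use_line_search`.
* **Acceleration**: standard FISTA momentum t_{k+1} = (1+√(1+4t_k²))/2 with
  extrapolation, kept *per block* inside the alternating loop. Whether
  momentum should be shared across blocks is not determined by the method
  description; per-block momentum keeps each block a textbook FISTA
  iteration.
* **Adaptive restart** (default on): if an iteration increases the
  objective, momentum is dropped and the iteration is retaken as a plain
  descent step, making the recorded objective trace non-increasing — a
  property the tests assert.
* **Stopping**: relative objective change |f_k − f_{k−1}|/max(1, |f_{k−1}|)
  < tol (default 1e-5), cap of 500 outer iterations; non-convergence
  returns a fit flagged `converged=False` with a warning, never silently.
* **Monitored objective**: `objective_trace` records the variant-aware
  penalized objective (group-L2 form under `as_printed`), so monotonicity
  and convergence refer to the function the iteration actually minimizes;
  `objective_value` reports the squared-Frobenius form of the printed
  program.

## Hyperparameter tuning

Observed entries are split uniformly at random into near-equal halves Ω₁
(training) and Ω₂ (testing). ρ is selected first on the no-SNP model
min ½‖P_Ω1(Y − L − 1μᵀ)‖² + ρ‖L‖_* over a geometric 10-point grid from
σ₁(P_Ω1(Y)) (the smallest ρ giving L = 0) down to 1% of it, minimizing
held-out error; ties break toward larger ρ. Then, for each α in
S_α = (0.2, 0.4, 0.6, 0.8, 0.9), λ is swept over n_λ = 50 geometric values
from λ_max down to ε·λ_max (ε = 0.02) with warm starts, and the triple with
the smallest held-out error wins (ties prefer larger λ, then larger α). The
final model is refit on all of Ω by default (`refit=False` disables).

λ_max = (1/α)·maxᵢⱼ|⟨Xᵢ, Yⱼ⟩| is computed after column-centering Y on its
observed training entries (the intercept absorbs column means, so the
stationarity condition for B = 0 involves the centered response; without
centering, λ_max is inflated by the means). `center=False` restores the raw
formula. Missing entries contribute zero to the inner products, equivalent
to summing over observed cells.

### Validation rules, and a caveat for weak dense signal

`prediction_error` scores held-out cells by the full model prediction
XB + L + 1μᵀ (`validation="full"`, the default in `tune`). This rule has a structural blind spot: the genetic component XB
has rank at most the number of causal SNPs, so when per-pair effects are
weak, the nuclear-norm term can interpolate the genetic signal across the
mask split at lower held-out cost than a noisy estimate of B — and the
search returns B = 0. In the package's weak-dense benchmark this is not a
corner case but the typical outcome, and it reproduces the behavior
classically reported for the with-L validation in that regime (AUC ≈ 0.5).
`tune(validation="genetic")` instead scores held-out cells by XB + 1μᵀ
only, so the score can only improve through coefficients that generalize
via the genotypes; it activates B in the weak regime and is the
recommended setting when weak, polygenic effects are the target.
`scripts/acceptance.py` reports the weak-dense comparison under both rules.

## Screening

Both screens start from per-SNP coefficient vectors β̂ᵢ obtained from the
single-predictor low-rank model (no penalty on βᵢ; ρ selected once on the
null model and reused across SNPs — the confounder structure is shared, and
per-SNP retuning would multiply the cost by p).

* **LORS screening**: per gene, keep the top-n SNPs by |β̂|; return the
  union over genes. The union size lies in [min(n, p), p].
* **HC screening**: standardize β̂ᵢⱼ by its OLS standard error from the
  single-SNP regression (with that fit's L̂ and μ̂ removed), convert to
  two-sided normal p-values, and summarize each SNP by the higher-criticism
  statistic max_{j ≤ q/2} √q·(j/q − p₍ⱼ₎)/√(p₍ⱼ₎(1−p₍ⱼ₎)) (the common
  α₀ = ½ convention; p-values are clipped to [1e-15, 1−1e-15] first). The
  top min(n, p) SNPs by the statistic are kept — ranking by the statistic
  is order-equivalent to ranking by any monotone p-value transform of it,
  so no null distribution needs to be assumed.

`estimator="marginal"` is a fast path for large p: the null confounder
model is fit once, Y is residualized, and all p simple-regression
coefficients and standard errors come from one matrix product. The
per-SNP fit remains the default; the marginal path is order-preserving in
the regimes the tests cover and makes HC screening at n = 165, p = 2000 a
seconds-scale operation.

Note that LORS-screening's union is scale-dependent (|β̂| rankings change
under per-SNP rescaling, z-scores do not). On this package's synthetic
genotypes, whose minor-allele frequencies are uniform over commons, the
per-gene rankings of null SNPs are nearly independent across genes and the
union saturates near p; real genotype panels, with their rare-allele-heavy
frequency spectra, correlate the rankings through the per-SNP scale and
yield much smaller unions.

## Synthetic data generator

The generator emulates a k-factor confounded eQTL study:

* H is n × k standard normal (k = 15 by default), Σ = HHᵀ; each gene's
  confounder column is N(0, 0.1Σ), drawn exactly as √0.1·H·z with
  z ~ N(0, I_k); noise is N(0, I) (σ² = 1 fixed).
* Causal SNPs (default 60 of p = 2000) are drawn uniformly without
  replacement; each influences exactly m uniformly chosen genes (without
  replacement within a SNP, independently across SNPs, so gene sets may
  overlap). Effects are U(0.25, 0.75) ("weak", paired with m = 50 in the
  weak-dense preset) or U(1.5, 2) ("strong", m = 10, strong-sparse);
  "mixed" gives half the causal SNPs weak and half strong effects (split
  by SNP, not by entry); `mixed_sign` negates the effects of half the
  causal SNPs, with magnitudes from `mixed_sign_law`.
* Genotypes are synthetic additive codes: per-SNP MAF ~ U(0.05, 0.5)
  (a `rare_fraction` of SNPs instead gets U(0.005, 0.03); MAF < 0.03 is
  the rare-variant cutoff), Hardy–Weinberg genotype probabilities, and a
  Gaussian-copula AR(1) correlation (ρ_LD = 0.7) within blocks of 20 SNPs
  with independence across blocks. Monomorphic columns are redrawn.
  The copula attenuates the latent 0.7 to roughly 0.55–0.65 at the
  genotype level, which the LD test brackets empirically.

Everything is deterministic given the seed (byte-identical across runs).

What the generator does *not* emulate: realistic LD decay and haplotype
structure, population stratification or relatedness, MAF spectra of real
panels, expression heteroskedasticity or counts. Passing benchmarks on
these data therefore demonstrate correctness of the machinery and the
qualitative regime behavior (strong-sparse signals are recovered nearly
perfectly; weak-dense signals are estimable but hard to validate), not
field performance on any real cohort.

## Evaluation

Each (SNP, gene) pair is one instance scored by |B̂ᵢⱼ| against the label
B_true,ij ≠ 0. The AUC is the Mann–Whitney statistic with midrank ties —
important because a sparse B̂ puts most of its mass at exactly 0, and every
tied (causal, null) pair must count ½. False-positive rates are reported at
the coefficient thresholds {0, 1e-12, 1e-6, 1e-4}. Replicate AUCs are
summarized as mean ± t₀.₉₇₅,r−1·sd/√r. AUCs are averaged per replicate
(matching the convention of reporting a mean and CI over repeats) rather
than pooled. A SNP–probe pair is *local* if on the same chromosome within
250 kb of the probe midpoint, *distant* if on different chromosomes or
more than 5 Mb apart, and *unclassified* in between; distances use 1-based
bp positions, SNP minus probe midpoint.

## Input handling

PLINK .bed/.bim/.fam triples (SNP-major, 2-bit) are decoded natively; SNPs
with any missing call are dropped with a logged count. Genotype codes count
minor-allele copies; the minor allele is recomputed from sample frequencies
by default (`trust_bim` keeps the stored orientation). Readers validate
payload sizes against the declared sample/SNP counts and reject truncated
files rather than padding. By default X columns are standardized (mean 0,
variance 1) so one λ is comparable across SNPs of different allele
frequency, and Y is centered on observed entries; both are flags.

## Benchmark sizes

The shipped benchmarks run at reduced dimensions chosen to finish in
minutes on one CPU while preserving the per-gene signal density of the
reference design (15 expected causal SNPs per gene): strong-sparse at
n = 100, p = 300, q = 60 with 15 causal SNPs; weak-dense at n = 100,
p = 500, q = 100 with 30 causal SNPs and a 2-α × 10-λ tuning grid;
screening cardinalities at the full reference size n = 165, p = 2000,
q = 200.

## Known limitations

* The alternating solver is validated against a joint solver on small
  instances; on ill-conditioned X with constant steps it can need many
  iterations (use the line search).
* The with-L validation rule's blindness to weak low-rank genetic signal
  (above) is inherent to the formulation, not a solver artifact; the
  genetic validation rule is the package's mitigation.
* HC screening assumes approximately normal standardized coefficients;
  with very small n or heavy-tailed expression the p-values are only
  ranking devices.
* LORS-screening union sizes depend on the genotype scale convention (see
  above).
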