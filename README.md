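# lorsen

Low-rank sparse multivariate regression for eQTL mapping.

## The problem

Expression quantitative trait locus (eQTL) mapping relates a genotype matrix
*X* (n samples × p SNPs, additive 0/1/2 coding) to an expression matrix *Y*
(n × q genes). Two features make the joint problem hard: hidden non-genetic
factors (batch, environment, cell composition) that perturb many genes at
once, and the p ≫ n regime in which the lasso can select at most n SNPs per
gene and drops all but one member of a linkage-disequilibrium block. `lorsen`
models both at once:

    Y = X B + L + 1 μᵀ + e

with a sparse SNP-effect matrix *B* (p × q), a low-rank matrix *L* (n × q)
absorbing hidden confounders, and per-gene intercepts μ. Estimation solves

    min_{B,L,μ} ½‖P_Ω(Y − XB − L − 1μᵀ)‖_F² + ρ‖L‖_* + λ₁‖B‖₁ + (λ₂/2)‖B‖_F²

where Ω masks the observed entries of *Y* (missing expression values simply
drop out of the loss), ‖·‖_* is the nuclear norm (a convex surrogate for
rank), and the elastic-net pair (λ₁, λ₂) = (λα, λ(1−α)) lets the model keep
more than n predictors and whole groups of correlated SNPs. The solver is an
alternating proximal-gradient scheme with per-block FISTA acceleration:
singular-value shrinkage for *L*, soft-thresholding composed with a
columnwise L2 shrink (or the exact elastic-net prox) for *B*, gradient steps
for μ.

The package also provides:

* **SNP screening** — per-SNP low-rank fits with per-gene top-n ranking and
  union ("LORS" screening), or higher-criticism (HC) summarization of each
  SNP's standardized coefficients keeping the top min(n, p) SNPs;
* **hyperparameter tuning** — the observed entries are split into two random
  halves; ρ is chosen on the no-SNP confounder model, then a geometric λ path
  from λ_max = (1/α)·maxᵢⱼ|⟨Xᵢ, Yⱼ⟩| is walked per α with warm starts,
  minimizing held-out prediction error;
* **a synthetic-data generator** — k-factor hidden confounders
  (U ~ N(0, 0.1·HHᵀ)), unit-variance noise, weak-dense / strong-sparse /
  mixed / sign-mixed effect regimes, and copula-based linkage disequilibrium;
* **evaluation** — pairwise Mann–Whitney AUC over all (SNP, gene) pairs,
  false-positive rates at fixed coefficient thresholds, replicate
  t-intervals, and local/distant (cis/trans) classification (< 250 kb local,
  > 5 Mb or cross-chromosome distant).

## Worked example

```bash
lorsen simulate --out-prefix demo --seed 7 --scenario strong-sparse \
    --n 40 --p 60 --q 15 --n-causal 5
# wrote demo.* (n=40, p=60, q=15, 5 causal SNPs)

lorsen screen --genotypes demo.genotypes.tsv --expression demo.expression.tsv \
    --method hc --estimator marginal --out kept.tsv
# hc-screening kept 40 of 60 SNPs

lorsen fit --genotypes demo.genotypes.tsv --expression demo.expression.tsv \
    --rho 20 --alpha 0.9 --lambda 15 --max-iter 200 --top-k 50 --out pairs.tsv
# converged=True after 27 iterations; objective 1010.27; wrote top 50 pairs to pairs.tsv

lorsen evaluate --coefficients pairs.tsv --truth demo.truth.tsv
# {"auc": 0.840526, "fpr@0": 0.073684, "fpr@1e-12": 0.073684, ...}
```

`simulate` writes genotypes (TSV or PLINK .bed/.bim/.fam), expression and a
(snp, gene, effect) truth table. `fit` writes the top SNP–probe pairs ranked
by absolute coefficient, with distance and local/distant class when positions
are available. `evaluate` scores a coefficient table against the truth: the
AUC is the probability that a random causal pair outranks a random null pair
(1.0 = perfect separation, 0.5 = chance), and `fpr@τ` is the fraction of null
pairs whose |coefficient| exceeds τ.

The same workflow is available as a library (`lorsen.fit_lorsen`,
`lorsen.tune`, `lorsen.hc_screen`, `lorsen.pairwise_auc`, ...); see
`docs/methods.md` for the model, algorithmic choices and caveats.

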