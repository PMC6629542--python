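# polyscore

Polygenic risk scores by **clumping + thresholding (C+T)**, with
permutation-based empirical *P*-values, for researchers who want to test
whether a GWAS-derived score is associated with a trait in an independent
genotyped sample.

## The method

A polygenic risk score aggregates many small genetic effects into one
predictor per individual:

```
PRS_s = Σ_i  β_i · g_si
```

where *g_si* counts the effect allele of SNP *i* in individual *s* (or, for
imputed data, its expected value — the *dosage* — `Σ_j ω_sij · j` over the
three genotype probabilities), and *β_i* comes from an external ("base")
GWAS. The C+T recipe is:

1. **Harmonize** the base summary statistics with the target genotypes:
   match alleles, flip strands automatically, drop palindromic (A/T, C/G)
   and irreconcilable variants.
2. **Clump**: thin the panel greedily in order of GWAS significance,
   removing neighbours within a physical window whose genotype *r*² with a
   retained index SNP exceeds a threshold, so the score is not dominated by
   one LD block.
3. **Threshold**: compute the PRS at an ascending grid of *P*-value cutoffs
   (a coarse "fastscore" grid or a dense high-resolution one), regress the
   trait on each score (linear for quantitative traits, logistic for binary,
   with covariates), and keep the threshold with the largest incremental
   *R*² (Nagelkerke pseudo-*R*² for binary traits).
4. **Correct for the optimization**: the best threshold's association *P* is
   overfit. The trait is permuted *N* times, the whole scan repeated on each
   permutation, and the empirical *P* computed as

   ```
   empirical P = ( #{ P_n < P_o } + 1 ) / ( N + 1 )
   ```

   which keeps the Type-1 error rate at its nominal level. The reported *R*²
   remains unadjusted — use out-of-sample validation to judge predictive
   accuracy.

The package also performs **strata analysis** (per-quantile effect sizes or
odds ratios vs a reference PRS stratum, with 95% CIs) and ships a
**simulator** that generates complete synthetic studies — genotypes under
Hardy–Weinberg with optional block LD, an additive trait `Y = Xβ + ε` with
noise scaled so the genetic variance fraction hits a target heritability
*h*², a base/target split, and base-sample GWAS summary statistics — so
every stage is testable without access to real cohort data.

## Worked example

Simulate a study (2 000 individuals, 1 000 SNPs, 100 causal, *h*² = 0.3;
80% of samples form the base GWAS, the rest the target), then run C+T with
1 000 permutations:

```bash
polyscore simulate --n 2000 --m 1000 --causal 100 --h2 0.3 \
    --prevalence 0.2 --seed 42 --out demo
polyscore run --base demo.sumstats --target demo --pheno demo.pheno \
    --pheno-col trait --fastscore --perm 1000 --seed 42 --out demo_ct
```

prints

```
trait: best threshold 0.001 (R2=0.219404, P=3.31226e-23, n_snps=18, empirical P=0.000999001)
```

i.e. the best-fitting score uses the 18 SNPs with base *P* ≤ 0.001 and
explains ~22% of trait variance in the 400 target samples; no permutation
beat the observed fit, so the empirical *P* sits at its floor 1/(N+1).
Full per-threshold results land in `demo_ct.prsice`, the one-line summary in
`demo_ct.summary`, per-sample scores in `demo_ct.best`. Strata analysis of
the binary outcome against score quintiles:

```bash
polyscore strata --best demo_ct.best --pheno demo.pheno --pheno-col status \
    --binary-target --quantile 5 --out demo_st
```

```
 stratum  estimate   ci_low  ci_high  n  reference
  (0,20]  0.200000 0.070895 0.564214 80      False
 (20,40]  0.243243 0.091861 0.644094 80      False
 (40,60]  1.000000      NaN      NaN 80       True
 (60,80]  0.750000 0.355768 1.581089 80      False
(80,100]  3.486486 1.783590 6.815236 80      False
```

— individuals in the top PRS quintile have ~3.5× the odds of being a case
relative to the middle quintile.

Everything is equally usable as a library (`polyscore.read_plink`,
`harmonize`, `clump`, `compute_scores`, `run_ct`, `empirical_p`,
`assign_strata`, `simulate_study`, ...); see the module docstrings.

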