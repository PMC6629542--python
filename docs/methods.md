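# Methods

## Scope and model

`polyscore` implements the clumping + thresholding (C+T) construction of
polygenic risk scores and the statistical machinery around it: summary-
statistic harmonization, LD clumping, threshold scanning with covariate
regression, permutation empirical *P*-values, PRS strata analysis, and a
synthetic-study generator. It deliberately does **not** re-weight effect
sizes (no shrinkage/LDpred-style modelling), convert *R*² to the liability
scale, or automate cross-validation.

## Genotype handling

Hard calls are counts of the `.bim` allele-1 (PLINK) or the VCF ALT allele,
stored as int8 with −1 for missing. The PLINK-1 SNP-major 2-bit codec
(00 → 2 copies, 10 → 1, 11 → 0, 01 → missing) is implemented with a 256-entry
byte lookup table and is round-trip tested. VCF records supply genotype
probabilities (GP), dosages (DS, else derived as ω₁ + 2ω₂) and hard calls
(GT, else the best-guess rule on GP). Probability triples off unit sum by
more than 1e-4 are renormalized and logged.

**Best-guess rule**: the most probable genotype is accepted only if its
probability reaches a threshold, default **0.9**; otherwise the call is
missing. **INFO filter**: variants with recorded imputation quality below a
cutoff (conventionally 0.8) are removed; variants without a recorded INFO
(typed-array variants) pass, since the filter is about imputation quality
they do not have. Multiallelic VCF records and duplicate variant IDs are
skipped/first-kept with logged counts. Chromosome labels are normalized by
stripping a leading `chr`.

## Harmonization

The join key is the variant ID. Four actions reconcile base and target
alleles: `match`, `swap` (alleles reversed; genotype recoded g → 2−g at
scoring time), `flip` (equal after complementing — reverse-strand report),
`flip_swap`. Palindromic A/T and C/G variants are dropped by default
because strand cannot be resolved without allele-frequency comparison;
a flag retains them. Indels are matched exactly or by swap only (no
complement logic). Duplicate base IDs keep the smallest-*P* record. Odds
ratios are converted to the log scale; rows with *P* ∉ (0, 1] or
non-numeric effects are dropped with counts.

## Clumping

LD is the squared Pearson correlation of hard-call vectors over
pairwise-complete samples (composite LD; needs no phasing and matches the
convention of PLINK-style clumping). Entries are visited in ascending *P*
(ties broken by chromosome, position, ID — making the output invariant to
input order); each surviving entry becomes an index SNP and removes
not-yet-indexed entries on the same chromosome within ±`window_kb`
(default 250 kb) with *r*² ≥ `r2_threshold` (default 0.1). Monomorphic or
<2-complete-pair comparisons are undefined LD and treated as *r*² = 0 with
a logged count. Defaults are the field's conventional clumping settings; an
external LD reference panel (same variant layout) can replace the scoring
target.

## Scoring

Inheritance models recode the hard call: additive g, dominant 1{g≥1},
recessive 1{g=2}, heterozygote 1{g=1}. Dosage mode uses the expected allele
count and is restricted to the additive model unless expected
dominant/recessive encodings (ω₁+ω₂, ω₂) are explicitly requested — those
are a natural but non-standard extension, so they sit behind a flag.
Missing-genotype policies: `mean_impute` (variant mean of the coded value
over non-missing samples, i.e. 2× effect-allele frequency under the
additive model), `set_zero`, `center` (subtract the variant mean; missing
contribute 0). The default aggregate divides each sample's weighted sum by
its non-missing allele count (2 × non-missing contributing variants); `sum`
mode gives the raw weighted sum. Threshold columns are accumulated
incrementally — each column adds only the newly admitted variants — and are
verified to equal de novo recomputation to 1e-12. Accumulation is in double
precision in canonical panel order, so results are deterministic.

## Threshold scan and empirical P

The grid is either a small set of bar levels (default
{0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1}) or a dense arithmetic sequence
(default 5e-8 to 0.5 in steps of 5e-5, upper bound always included). At
each threshold the trait is regressed on covariates + PRS; the incremental
*R*² is the full-model *R*² minus the covariate-only *R*² (ordinary *R*²
for quantitative traits, Nagelkerke pseudo-*R*² for binary). The
quantitative scan uses an exact vectorized OLS (partialled/Frisch–Waugh
form), verified against per-column `statsmodels` fits to 1e-10. Ties on
incremental *R*² go to the smaller threshold (fewer SNPs). Zero-variance or
empty columns and separated logistic fits are skipped with a warning. The
best *R*² is reported **unadjusted**: it is overfit by construction and the
package does not shrink it.

The empirical *P* permutes trait values across individuals, reuses the
precomputed score matrix, records each permutation's smallest association
*P* over the grid (one permutation of the trait shared across thresholds —
required for the min to be meaningful), and reports
(#{P_n < P_o} + 1)/(N + 1). Ties P_n = P_o count as not-better (strict
inequality, conservative). Design choices where the convention is not
fixed:

- **Covariates**: regressed out of phenotype and scores once; residuals are
  permuted (a Freedman–Lane-style approximation). Refitting covariates
  N×|grid| times would be prohibitively slow and changes nothing when there
  are no covariates, where the permutation *P* is exactly the OLS *P*.
- **Binary traits**: by default the permutation loop ranks P_n with a
  linear (score-test-style) fit on the 0/1 outcome; exact logistic refits
  are available by flag and agree directionally.
- A single integer seed drives the permutation stream; identical seeds give
  identical results.

On 500 null replicates (trait independent of genotype, 500 target samples,
500 SNPs, 8-level grid, 200 permutations) the empirical-*P* rejection rate
at α = 0.05 sits inside the exact binomial 99% band around 0.05, while
rejecting on the best raw threshold *P* is inflated roughly threefold —
this is the package's central statistical guarantee and is asserted by the
test suite and recomputed by `scripts/acceptance.py`.

## Strata analysis

Samples are ranked by PRS and cut into M equal-count strata (rank-based,
ties split by stable order; sizes differ by ≤1), or into custom percentile
bins such as (0,10], …, (40,60], … to merge a central reference. The
default reference is the stratum containing the median score. The
N × (M−1) indicator design (reference column omitted) is fit with OLS or
logistic regression; binary estimates are exponentiated to odds ratios with
exponentiated Wald 95% CIs. Wald rather than profile CIs: cheap, standard
for strata plots, and swappable. Changing the reference reparametrizes the
model without changing its fit (asserted via log-likelihood invariance).

## Simulator

Genotypes: per-SNP MAF uniform on [0.05, 0.5], Hardy–Weinberg binomial(2, p)
draws; optionally a block-exchangeable latent Gaussian (shared factor
√ρ Z_block + √(1−ρ) Z_own) thresholded at the HWE genotype quantiles, which
produces local LD so clumping is non-trivial — independent SNPs are the
default because most properties do not need LD. All SNPs sit on one
chromosome at a configurable spacing (1 kb default; experiments that want
clumping to be a no-op space SNPs beyond the clump window, which is exact
for independent SNPs).

Trait: `Y = Xβ + ε` on unstandardized allele counts; a random subset of
SNPs is causal with β ~ N(0, 1); ε is Gaussian with standard deviation
√(var(Xβ)(1−h²)/h²), so the genetic fraction of trait variance equals h²
in expectation (the SD — not variance — parameterization; the two coincide
at h² = 0.5). Note that with per-allele effects on unstandardized
genotypes, common SNPs carry more heritability. h² = 0 yields a pure-noise
trait. Confounder stand-ins (2-level batch + 4 PC-like columns by default)
support the residualize-then-analyze workflow: the trait is regressed on
batch indicators + PCs and the standardized residuals (mean 0, SD 1) carried
forward.

Base GWAS: per-SNP simple OLS within the base split (vectorized closed
form: slope = cov(g, y)/var(g), Wald SE, two-sided t). Monomorphic SNPs are
dropped with a count. Imputation noise: each hard call is replaced by a
Dirichlet(c·v) triple with mean v = (1−e)·onehot(truth) + e/3
(concentration c = 30, error rate e configurable); e = 0 gives exactly
degenerate triples. This emulates the information loss of the 0.9
best-guess rule (uncertain calls go missing) while dosage retains the
expectation — the mechanism behind the dosage ≥ best-guess predictive
ordering the tests assert.

What the simulator does *not* emulate: realistic site-frequency spectra,
population structure and relatedness, long-range LD, genotyping batch
artefacts correlated with genotype, case–control ascertainment. Passing
tests therefore demonstrate correctness of the algorithms and calibration
under the stated model, not performance on real cohort data.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to estimate
each property with comfortable Monte-Carlo margins: 500 null replicates ×
200 permutations for Type-1 error; 20 seeds × base sizes {1000, 2500, 5000}
with 2 000 SNPs (100 causal, h² = 0.2) for recovery; 50 seeds for the
dosage comparison; 50 random 40-SNP × 200-sample LD-block instances for the
clumping oracle. The whole suite completes in under two minutes on one CPU.

## Known limitations

- BGEN and PLINK-2 `.pgen` are not parsed; VCF GT/DS/GP is the imputed
  container. The I/O module boundary admits more codecs later.
- Chromosome X gets no special ploidy treatment (non-autosomes are retained
  and flagged).
- Ambiguous-strand variants cannot be rescued by frequency comparison.
- The empirical *P* controls Type-1 error for the hypothesis test; it does
  not fix the optimistic *R*² — external validation remains necessary.
- Strata CIs are Wald; with tiny or separated strata they can be infinite
  (flagged, not suppressed).
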