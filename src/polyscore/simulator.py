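"""Synthetic genotype-phenotype studies for end-to-end verification.

Quantitative traits follow the additive model Y = X beta + epsilon, where X
is the unstandardized allele-count matrix, a random subset of SNPs is
causal with per-allele effects beta ~ N(0, 1), and the noise is Gaussian
with standard deviation sqrt(var(X beta) (1 - h2) / h2), so the genetic
fraction of trait variance targets the requested narrow-sense heritability
h2.  The study is split into disjoint base and target samples; per-SNP
simple linear regression in the base sample yields the GWAS summary
statistics that drive the C+T pipeline, exactly as a real base cohort
would.

SNPs are independent by default; an optional block-exchangeable latent
Gaussian generator adds local LD so that clumping has something to do.
Imputation uncertainty can be layered on afterwards by replacing each hard
call with a Dirichlet probability triple centred on the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeDataset, hard_call_matrix
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]  # never strand-ambiguous


class SimulationError(Exception):
    pass


@dataclass
class SimConfig:
    n_samples: int = 2000
    m_snps: int = 1000
    n_causal: int = 100
    h2: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int | None = None
    ld_rho: float = 0.0
    base_fraction: float = 0.8
    binary_prevalence: float | None = None
    pos_spacing: int = 1000          # bp between adjacent SNPs on the single chromosome
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_causal > self.m_snps:
            raise ValueError("n_causal cannot exceed m_snps")
        if not 0 < self.base_fraction < 1:
            raise ValueError("base_fraction must lie in (0, 1)")


@dataclass
class Confounders:
    batch: np.ndarray            # categorical labels
    pcs: np.ndarray              # (n, k) numeric columns

    def matrix(self) -> np.ndarray:
        """Numeric design: batch level indicators (first level dropped) + PCs."""
        levels = np.unique(self.batch)
        if len(levels) < 2:
            raise SimulationError("batch must have at least 2 levels")
        ind = np.column_stack([(self.batch == l).astype(float) for l in levels[1:]])
        return np.hstack([ind, self.pcs])


@dataclass
class SimulatedStudy:
    genotypes: GenotypeDataset
    true_beta: np.ndarray
    genetic_value: np.ndarray
    trait: np.ndarray
    noise: np.ndarray
    base_idx: np.ndarray
    target_idx: np.ndarray
    base_sumstats: SummaryStats | None = None
    config: SimConfig | None = None

    @property
    def base_ids(self) -> list[str]:
        return list(self.genotypes.samples["iid"].iloc[self.base_idx])

    @property
    def target_ids(self) -> list[str]:
        return list(self.genotypes.samples["iid"].iloc[self.target_idx])


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeDataset:
    """Draw a hard-call genotype matrix under Hardy-Weinberg proportions.

    Per-SNP minor-allele frequencies are uniform on ``config.maf_range``.
    With ``ld_block_size`` set, genotypes come from a block-exchangeable
    latent Gaussian (correlation ``ld_rho`` within blocks) thresholded at
    the HWE genotype quantiles, producing local LD; otherwise SNPs are
    independent binomial(2, maf) draws.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, m = config.n_samples, config.m_snps
    maf = rng.uniform(*config.maf_range, size=m)

    if config.ld_block_size and config.ld_rho > 0:
        rho = config.ld_rho
        b = config.ld_block_size
        Z = np.empty((n, m))
        for start in range(0, m, b):
            width = min(b, m - start)
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, width))
            Z[:, start : start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        # threshold at HWE quantiles: P(g=0) = (1-p)^2, P(g<=1) = 1 - p^2
        q0 = stats.norm.ppf((1 - maf) ** 2)
        q1 = stats.norm.ppf(1 - maf**2)
        hard = (Z > q0[None, :]).astype(np.int8) + (Z > q1[None, :]).astype(np.int8)
    else:
        hard = rng.binomial(2, maf, size=(n, m)).astype(np.int8)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = [(_ALLELE_PAIRS[i][0]) for i in pair_idx]
    a2 = [(_ALLELE_PAIRS[i][1]) for i in pair_idx]
    variants = pd.DataFrame(
        {
            "id": [f"rs{i}" for i in range(m)],
            "chrom": "1",
            "pos": (np.arange(m, dtype=np.int64) + 1) * config.pos_spacing,
            "a1": a1,
            "a2": a2,
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"F{i}" for i in range(n)], "iid": [f"S{i}" for i in range(n)]}
    )
    return GenotypeDataset(samples=samples, variants=variants, hardcalls=hard)


def simulate_trait(
    genotypes: GenotypeDataset,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedStudy:
    """Simulate the additive trait and split base/target samples.

    ``h2 = 0`` yields a pure-noise trait (independent of genotype); causal
    effects are still drawn but contribute nothing.  Raises
    :class:`SimulationError` when the genetic value is degenerate
    (e.g. all causal SNPs monomorphic) and h2 > 0.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n, m = genotypes.hardcalls.shape
    X = genotypes.hardcalls.astype(float)

    causal = rng.choice(m, size=config.n_causal, replace=False)
    beta = np.zeros(m)
    beta[causal] = rng.standard_normal(config.n_causal)
    g = X @ beta

    if config.h2 == 0:
        noise = rng.standard_normal(n)
        trait = noise.copy()
    else:
        vg = g.var()
        if vg <= 0:
            raise SimulationError("genetic value has zero variance")
        sd = np.sqrt(vg * (1 - config.h2) / config.h2)
        noise = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        trait = g + noise

    perm = rng.permutation(n)
    n_base = int(round(config.base_fraction * n))
    base_idx = np.sort(perm[:n_base])
    target_idx = np.sort(perm[n_base:])

    return SimulatedStudy(
        genotypes=genotypes, true_beta=beta, genetic_value=g, trait=trait,
        noise=noise, base_idx=base_idx, target_idx=target_idx, config=config,
    )


def simulate_confounders(
    n: int, n_pcs: int = 4, rng: np.random.Generator | None = None
) -> Confounders:
    """Stand-in batch labels and principal-component columns."""
    rng = rng if rng is not None else np.random.default_rng(0)
    batch = rng.integers(0, 2, size=n)
    pcs = rng.standard_normal((n, n_pcs))
    return Confounders(batch=batch, pcs=pcs)


def residualize(trait: np.ndarray, confounders: Confounders) -> np.ndarray:
    """OLS residuals of the trait on batch + PCs + intercept, standardized.

    Output has mean 0 and SD 1.  Raises on confounder rank deficiency or
    when the residuals are (numerically) all zero.
    """
    y = np.asarray(trait, dtype=float)
    C = confounders.matrix()
    X = np.hstack([np.ones((len(y), 1)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SimulationError("confounder matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std()
    if sd < 1e-12:
        raise SimulationError("trait is fully explained by confounders; residual degenerate")
    return (resid - resid.mean()) / sd


def run_base_gwas(study: SimulatedStudy, trait: np.ndarray | None = None) -> SummaryStats:
    """Per-SNP simple linear regression of the trait within base samples.

    Vectorized OLS: slope = cov(g, y)/var(g), Wald SE from the residual
    variance, two-sided t P-value.  Monomorphic SNPs are emitted with NaN
    effect and P = 1 so that downstream parsing drops nothing silently.
    """
    y = (trait if trait is not None else study.trait)[study.base_idx]
    X = study.genotypes.hardcalls[study.base_idx].astype(float)
    n = len(y)
    if n < 3:
        raise SimulationError("base sample too small for GWAS")

    xm = X.mean(axis=0)
    xc = X - xm
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    mono = sxx <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        ssr = float(yc @ yc) - beta * sxy
        se = np.sqrt(np.maximum(ssr, 0.0) / (n - 2) / sxx)
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    beta[mono] = np.nan
    pval[mono] = 1.0
    if mono.any():
        logger.warning("%d monomorphic SNPs in base GWAS", int(mono.sum()))

    v = study.genotypes.variants
    table = pd.DataFrame(
        {
            "id": v["id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "effect_allele": v["a1"],
            "other_allele": v["a2"],
            "beta": beta,
            "se": se,
            "pvalue": np.clip(pval, np.nextafter(0, 1), 1.0),
        }
    )
    keep = np.isfinite(beta)
    return SummaryStats(table=table[keep].reset_index(drop=True), n_dropped=int(mono.sum()))


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Genotypes + trait + base/target split + base GWAS, all from one seed."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    study = simulate_trait(genotypes, config, rng)
    study.base_sumstats = run_base_gwas(study)
    return study


def inject_imputation_noise(
    dataset: GenotypeDataset,
    error_rate: float,
    concentration: float = 30.0,
    rng: np.random.Generator | None = None,
) -> GenotypeDataset:
    """Replace hard calls with Dirichlet probability triples centred on truth.

    Each triple is Dirichlet(concentration * v) with mean vector
    v = (1 - error_rate) * onehot(truth) + error_rate * uniform.  At
    error_rate 0 the triples are exactly degenerate; larger rates spread
    mass onto the wrong genotypes.  Dosages and best-guess hard calls
    (threshold 0.9) are derived; missing input calls become uniform triples.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    hc = dataset.hardcalls
    n, m = hc.shape

    onehot = np.zeros((n, m, 3))
    for g in (0, 1, 2):
        onehot[:, :, g] = hc == g
    miss = hc < 0
    onehot[miss] = 1.0 / 3.0

    mean = (1 - error_rate) * onehot + error_rate / 3.0
    alpha = concentration * mean
    gam = rng.gamma(np.maximum(alpha, 0.0))
    total = gam.sum(axis=2, keepdims=True)
    probs = np.where(total > 0, gam / np.where(total > 0, total, 1.0), onehot)

    dosages = probs[:, :, 1] + 2.0 * probs[:, :, 2]
    hardcalls = hard_call_matrix(probs, 0.9)
    return GenotypeDataset(
        samples=dataset.samples.copy(),
        variants=dataset.variants.copy(),
        hardcalls=hardcalls,
        probabilities=probs,
        dosages=dosages,
    )


def make_binary(trait: np.ndarray, prevalence: float, ) -> np.ndarray:
    """Liability-threshold dichotomization: top ``prevalence`` fraction = cases."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    t = np.asarray(trait, dtype=float)
    cut = np.quantile(t, 1 - prevalence)
    cases = (t > cut).astype(float)
    if cases.sum() < 10:
        logger.warning("fewer than 10 cases at prevalence %.3g", prevalence)
    return cases
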