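"""The C+T driver: threshold grid, association fitting, best-fit selection
and permutation-based empirical P-values.

Optimizing the P-value threshold inflates the best raw association P-value
under the null.  The empirical P restores Type-1 error control by repeating
the whole threshold scan on permuted phenotypes:

    empirical P = (sum_n I(P_n < P_o) + 1) / (N + 1)

where P_o is the observed best association P, P_n the best P of permutation
n, and the +1 pseudo-counts keep the estimate off zero (the observed data
counts as one null configuration).  The observed R^2 is reported unadjusted
— it remains overfit, and out-of-sample validation is still required to
judge predictive accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeDataset
from .scoring import ScoreConfig, ScoreMatrix, compute_scores
from .sumstats import HarmonizedPanel

logger = logging.getLogger(__name__)

FASTSCORE_LEVELS = (0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


class CTError(Exception):
    pass


def build_grid(
    mode: str = "fastscore",
    bar_levels=FASTSCORE_LEVELS,
    lower: float = 5e-8,
    upper: float = 0.5,
    step: float = 5e-5,
) -> np.ndarray:
    """Ascending P-value threshold grid.

    ``fastscore`` sorts and deduplicates the supplied bar levels;
    ``high_resolution`` enumerates lower, lower+step, ... up to upper, with
    upper always included.
    """
    if mode == "fastscore":
        grid = np.unique(np.asarray(list(bar_levels), dtype=float))
        if len(grid) == 0:
            raise CTError("empty bar levels")
        if grid[0] <= 0 or grid[-1] > 1:
            raise CTError("bar levels must lie in (0, 1]")
        return grid
    if mode != "high_resolution":
        raise CTError(f"unknown grid mode {mode!r}")
    if not (0 < lower <= upper <= 1):
        raise CTError("need 0 < lower <= upper <= 1")
    if step <= 0:
        raise CTError("step must be positive")
    n = int(np.floor((upper - lower) / step))
    grid = lower + step * np.arange(n + 1)
    grid = grid[grid <= upper]
    if len(grid) == 0 or grid[-1] < upper:
        grid = np.append(grid, upper)
    return np.unique(grid)


# ---------------------------------------------------------------------------
# association fitting
# ---------------------------------------------------------------------------

def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if covariates is None or covariates.size == 0:
        return ones
    return np.hstack([ones, np.asarray(covariates, dtype=float)])


def _residual_maker(X: np.ndarray):
    """Return f(v) -> residual of v on columns of X (least squares)."""
    Q, _ = np.linalg.qr(X)

    def resid(v: np.ndarray) -> np.ndarray:
        return v - Q @ (Q.T @ v)

    return resid


def _nagelkerke(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 of a fitted logistic model vs the intercept-only null."""
    cs = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    denom = 1.0 - np.exp(2.0 * llnull / n)
    return float(cs / denom) if denom > 0 else 0.0


def fit_association(
    score: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    family: str,
) -> tuple[float, float, float, float]:
    """Fit phenotype ~ covariates + PRS; return (coef, se, pvalue, r2_incremental).

    Quantitative traits use OLS with the ordinary coefficient of
    determination; binary traits use logistic regression with Nagelkerke
    pseudo-R^2.  ``r2_incremental`` is R^2(full) - R^2(covariates only).
    """
    import statsmodels.api as sm

    s = np.asarray(score, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n < 10:
        raise CTError("need at least 10 complete cases")
    if np.var(s) <= 0:
        raise CTError("zero-variance score")

    Xnull = _design(covariates, n)
    Xfull = np.hstack([Xnull, s[:, None]])

    if family == "quantitative":
        full = sm.OLS(y, Xfull).fit()
        null = sm.OLS(y, Xnull).fit()
        coef = full.params[-1]
        se = full.bse[-1]
        p = full.pvalues[-1]
        r2i = full.rsquared - (null.rsquared if Xnull.shape[1] > 1 else 0.0)
        return float(coef), float(se), float(p), float(r2i)
    if family != "binary":
        raise CTError(f"unknown family {family!r}")

    try:
        full = sm.Logit(y, Xfull).fit(disp=0, maxiter=200)
        null = sm.Logit(y, Xnull).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation / non-convergence
        raise CTError(f"logistic fit failed: {exc}") from exc
    if not (full.mle_retvals.get("converged", True) and null.mle_retvals.get("converged", True)):
        raise CTError("logistic fit did not converge (possible separation)")
    ll0 = sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf
    r2i = _nagelkerke(full.llf, ll0, n) - _nagelkerke(null.llf, ll0, n)
    return (
        float(full.params[-1]),
        float(full.bse[-1]),
        float(full.pvalues[-1]),
        float(r2i),
    )


def _linear_scan(
    S: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact OLS over every score column at once via partialled regression.

    Returns (coef, se, pvalue, r2_incremental) arrays, identical to fitting
    each column with :func:`fit_association` (quantitative family).
    """
    n = S.shape[0]
    Xnull = _design(covariates, n)
    resid = _residual_maker(Xnull)
    yr = resid(y)
    Sr = resid(S)

    ss_sr = np.einsum("ij,ij->j", Sr, Sr)
    ss_yr = float(yr @ yr)
    sy = Sr.T @ yr
    ok = ss_sr > 1e-300
    coef = np.divide(sy, ss_sr, out=np.zeros_like(sy), where=ok)
    ssr = ss_yr - coef * sy                     # residual SS of the full model
    dof = n - Xnull.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = ssr / dof
        se = np.sqrt(sigma2 / ss_sr)
        tstat = coef / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)

    sst = float(np.sum((y - y.mean()) ** 2))
    ssr_null = float(yr @ yr)
    r2_full = 1.0 - ssr / sst
    r2_null = 1.0 - ssr_null / sst if Xnull.shape[1] > 1 else 0.0
    r2i = r2_full - r2_null
    pval = np.where(ok, pval, np.nan)
    r2i = np.where(ok, r2i, np.nan)
    return coef, se, pval, r2i


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Per-threshold regression results plus everything needed to permute."""

    table: pd.DataFrame          # threshold, n_snps, coefficient, se, pvalue, r2_incremental
    best_index: int
    score_matrix: ScoreMatrix
    phenotype: np.ndarray
    covariates: np.ndarray | None
    family: str
    sample_index: np.ndarray     # complete-case row positions in the dataset

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[self.best_index]


@dataclass
class PermutationResult:
    n_permutations: int
    n_better: int
    empirical_p: float
    seed: int


def run_ct(
    dataset: GenotypeDataset,
    panel: HarmonizedPanel,
    grid: np.ndarray,
    config: ScoreConfig,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "quantitative",
    score_matrix: ScoreMatrix | None = None,
    sample_index: np.ndarray | None = None,
) -> ThresholdScan:
    """Scan the threshold grid and pick the best-fit threshold.

    ``phenotype`` (and covariate rows) must align with the dataset's sample
    order; NaNs mark missing phenotype values and those samples are dropped
    from the regressions (complete-case).  A precomputed ``score_matrix``
    over all dataset samples may be supplied to avoid rescoring (used by the
    multi-phenotype loop).  Ties on incremental R^2 go to the smaller
    threshold.
    """
    grid = np.asarray(grid, dtype=float)
    if score_matrix is None:
        score_matrix = compute_scores(dataset, panel, grid, config)

    y_all = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y_all)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        keep &= np.all(np.isfinite(covariates), axis=1)
    if sample_index is not None:
        mask = np.zeros(len(y_all), dtype=bool)
        mask[sample_index] = True
        keep &= mask
    idx = np.flatnonzero(keep)
    y = y_all[idx]
    cov = covariates[idx] if covariates is not None else None
    S = score_matrix.scores[idx]

    if family == "binary":
        vals = np.unique(y)
        if set(vals) == {1.0, 2.0}:  # PLINK 1/2 coding
            y = y - 1.0
        elif not set(vals) <= {0.0, 1.0}:
            raise CTError(f"binary phenotype must have two levels, got {vals}")

    T = len(grid)
    coefs = np.full(T, np.nan)
    ses = np.full(T, np.nan)
    pvals = np.full(T, np.nan)
    r2is = np.full(T, np.nan)
    usable = (score_matrix.snp_counts > 0) & (np.nanvar(S, axis=0) > 0)

    if family == "quantitative":
        if usable.any():
            c, s_, p, r = _linear_scan(S[:, usable], y, cov)
            coefs[usable], ses[usable], pvals[usable], r2is[usable] = c, s_, p, r
    else:
        for t in np.flatnonzero(usable):
            try:
                coefs[t], ses[t], pvals[t], r2is[t] = fit_association(
                    S[:, t], y, cov, "binary"
                )
            except CTError as exc:
                logger.warning("threshold %g skipped: %s", grid[t], exc)

    table = pd.DataFrame(
        {
            "threshold": grid,
            "n_snps": score_matrix.snp_counts,
            "coefficient": coefs,
            "se": ses,
            "pvalue": pvals,
            "r2_incremental": r2is,
        }
    )
    finite = np.isfinite(r2is)
    if not finite.any():
        raise CTError("no threshold produced a fittable model")
    # argmax of r2; ties -> smaller threshold (np.nanargmax takes the first)
    best = int(np.nanargmax(np.where(finite, r2is, -np.inf)))
    return ThresholdScan(
        table=table,
        best_index=best,
        score_matrix=ScoreMatrix(
            scores=S,
            snp_counts=score_matrix.snp_counts,
            denominators=score_matrix.denominators[idx],
            thresholds=score_matrix.thresholds,
        ),
        phenotype=y,
        covariates=cov,
        family=family,
        sample_index=idx,
    )


def empirical_p(
    scan: ThresholdScan,
    n_permutations: int = 10000,
    seed: int = 0,
    binary_fast: bool = True,
) -> PermutationResult:
    """Permutation empirical P-value for the best-fit PRS association.

    Phenotype values are permuted across individuals; for each permutation
    the full grid is refit against the precomputed scores and the smallest
    association P across thresholds recorded as P_n.  With covariates, they
    are regressed out of phenotype and scores once and residuals are
    permuted.  Binary traits default to a linear (score-test style) refit
    inside the loop; set ``binary_fast=False`` for exact logistic refits.

    empirical P = (#{P_n < P_o} + 1) / (N + 1), strict inequality; ties
    count as not-better, which is conservative.
    """
    if n_permutations < 1:
        raise CTError("need at least 1 permutation")

    p_obs = float(np.nanmin(scan.table["pvalue"].to_numpy()))
    rng = np.random.default_rng(seed)
    usable = np.isfinite(scan.table["pvalue"].to_numpy())
    S = scan.score_matrix.scores[:, usable]
    y = scan.phenotype
    n = len(y)

    use_linear = scan.family == "quantitative" or binary_fast
    if use_linear:
        Xnull = _design(scan.covariates, n)
        resid = _residual_maker(Xnull)
        yr = resid(y)
        Sr = resid(S)
        # standardize once; the permutation P depends only on correlations
        Sn = Sr / np.sqrt(np.einsum("ij,ij->j", Sr, Sr))
        dof = n - Xnull.shape[1] - 1
        ss_y = float(yr @ yr)

        n_better = 0
        block = max(1, min(n_permutations, int(2e7 // max(n, 1))))
        done = 0
        while done < n_permutations:
            b = min(block, n_permutations - done)
            # one permutation per column
            perm = np.argsort(rng.random((b, n)), axis=1)
            Y = yr[perm].T                            # (n, b)
            r = Sn.T @ Y                              # (k, b) projections
            with np.errstate(invalid="ignore", divide="ignore"):
                t2 = r**2 * dof / np.maximum(ss_y - r**2, 1e-300)
            tmax2 = np.nanmax(t2, axis=0)
            p_n = 2.0 * stats.t.sf(np.sqrt(tmax2), dof)
            n_better += int(np.sum(p_n < p_obs))
            done += b
    else:
        n_better = 0
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            best = np.inf
            for t in range(S.shape[1]):
                try:
                    _, _, p, _ = fit_association(S[:, t], yp, scan.covariates, "binary")
                except CTError:
                    continue
                best = min(best, p)
            if best < p_obs:
                n_better += 1

    emp = (n_better + 1) / (n_permutations + 1)
    return PermutationResult(
        n_permutations=n_permutations, n_better=n_better, empirical_p=emp, seed=seed
    )


def run_multi_pheno(
    dataset: GenotypeDataset,
    panel: HarmonizedPanel,
    grid: np.ndarray,
    config: ScoreConfig,
    phenotypes: pd.DataFrame,
    families: dict[str, str],
    covariates: np.ndarray | None = None,
    n_permutations: int | None = None,
    seed: int = 0,
) -> list[tuple[str, ThresholdScan, PermutationResult | None]]:
    """Run the C+T scan for every phenotype column, scoring only once.

    ``phenotypes`` rows must align with the dataset sample order (NaN =
    missing); ``families`` maps column name to 'quantitative' or 'binary'.
    Entirely-missing columns are skipped with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    score_matrix = compute_scores(dataset, panel, grid, config)
    results = []
    for name in phenotypes.columns:
        y = phenotypes[name].to_numpy(dtype=float)
        if not np.isfinite(y).any():
            logger.warning("phenotype %s entirely missing; skipped", name)
            continue
        scan = run_ct(
            dataset, panel, grid, config, y,
            covariates=covariates, family=families.get(name, "quantitative"),
            score_matrix=score_matrix,
        )
        perm = (
            empirical_p(scan, n_permutations, seed=seed)
            if n_permutations
            else None
        )
        results.append((name, scan, perm))
    return results
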