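"""End-to-end validation experiments.

These drive the full pipeline (simulate -> base GWAS -> harmonize -> clump
-> threshold scan -> permutation) under controlled conditions and summarize
the behaviour that matters scientifically: Type-1 error control of the
empirical P-value on null data, parameter recovery under a heritable trait,
and the dosage-vs-best-guess predictive ordering under imputation noise.
Both the test suite and the acceptance script run these.
"""

from __future__ import annotations

import numpy as np

from .ct_engine import FASTSCORE_LEVELS, ThresholdScan, build_grid, empirical_p, run_ct
from .ld_clump import ClumpParams, clump
from .scoring import ScoreConfig
from .simulator import SimConfig, inject_imputation_noise, simulate_study
from .sumstats import harmonize


def _ct_on_target(study, config=None, grid=None, target=None):
    """Harmonize, clump and scan the target sample of a simulated study."""
    target = target if target is not None else study.genotypes.subset(
        sample_idx=study.target_idx
    )
    panel = harmonize(study.base_sumstats, target)
    res = clump(panel, target, ClumpParams())
    panel = panel.subset(res.index_entries)
    grid = grid if grid is not None else build_grid("fastscore", FASTSCORE_LEVELS)
    y = study.trait[study.target_idx]
    return run_ct(target, panel, grid, config or ScoreConfig(), y)


def null_typeI_experiment(
    n_reps: int = 500,
    n_target: int = 500,
    m_snps: int = 500,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rates at ``alpha`` on phenotypes independent of genotype.

    Each replicate simulates a fresh null study (h2 = 0, independent SNPs),
    runs the full C+T scan over the default fastscore grid, and rejects
    either on the best raw threshold P (naive, overfit) or on the
    permutation empirical P.  Returns both rates; the empirical rate should
    sit at ``alpha`` while the naive rate is inflated.
    """
    rng = np.random.default_rng(seed)
    n_emp = n_naive = 0
    for _ in range(n_reps):
        s = int(rng.integers(0, 2**31 - 1))
        cfg = SimConfig(
            n_samples=2 * n_target, m_snps=m_snps, n_causal=1, h2=0.0,
            base_fraction=0.5, pos_spacing=300_000, seed=s,
        )
        study = simulate_study(cfg)
        scan = _ct_on_target(study)
        p_obs = float(np.nanmin(scan.table["pvalue"]))
        n_naive += p_obs <= alpha
        perm = empirical_p(scan, n_permutations, seed=s + 1)
        n_emp += perm.empirical_p <= alpha
    return {
        "n_reps": n_reps,
        "empirical_rejections": n_emp,
        "naive_rejections": n_naive,
        "empirical_rate": n_emp / n_reps,
        "naive_rate": n_naive / n_reps,
    }


def parameter_recovery_experiment(
    n_seeds: int = 20,
    base_sizes: tuple[int, ...] = (1000, 2500, 5000),
    n_target: int = 1000,
    m_snps: int = 2000,
    n_causal: int = 100,
    h2: float = 0.2,
    seed: int = 0,
) -> dict:
    """Recover a heritable signal and measure the base-size R^2 gradient.

    For each seed and base-GWAS size, simulates an h2-heritable trait,
    builds the PRS in an independent target sample and records the
    best-threshold association.  Returns the fraction of seeds where the
    largest-base run reaches P < 1e-6, and mean target R^2 per base size
    (expected monotone increasing: bigger discovery GWAS, better weights).
    """
    rng = np.random.default_rng(seed)
    r2 = {b: [] for b in base_sizes}
    pvals_largest = []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        for b in base_sizes:
            cfg = SimConfig(
                n_samples=b + n_target, m_snps=m_snps, n_causal=n_causal, h2=h2,
                base_fraction=b / (b + n_target), pos_spacing=300_000, seed=s,
            )
            study = simulate_study(cfg)
            scan = _ct_on_target(study)
            r2[b].append(float(scan.best["r2_incremental"]))
            if b == max(base_sizes):
                pvals_largest.append(float(scan.best["pvalue"]))
    mean_r2 = {b: float(np.mean(v)) for b, v in r2.items()}
    return {
        "n_seeds": n_seeds,
        "frac_p_below_1e6": float(np.mean(np.asarray(pvals_largest) < 1e-6)),
        "mean_r2_by_base_size": mean_r2,
        "monotone_in_base_size": all(
            mean_r2[a] < mean_r2[b]
            for a, b in zip(sorted(base_sizes), sorted(base_sizes)[1:])
        ),
    }


def dosage_vs_bestguess_experiment(
    n_seeds: int = 50,
    error_rate: float = 0.3,
    n_samples: int = 1000,
    m_snps: int = 300,
    n_causal: int = 50,
    h2: float = 0.5,
    seed: int = 0,
) -> dict:
    """Predictive power of dosage vs best-guess scoring under imputation noise.

    Injects probabilistic imputation noise into the target genotypes, then
    scores the same harmonized panel in dosage mode and in best-guess
    (hard-call) mode.  Dosage retains the uncertainty that the 0.9 best-guess
    rule throws away as missingness, so its best-threshold R^2 should win in
    most replicates.
    """
    rng = np.random.default_rng(seed)
    wins = 0
    r2_dosage, r2_bestguess = [], []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        cfg = SimConfig(
            n_samples=n_samples, m_snps=m_snps, n_causal=n_causal, h2=h2,
            base_fraction=0.8, pos_spacing=300_000, seed=s,
        )
        study = simulate_study(cfg)
        target = study.genotypes.subset(sample_idx=study.target_idx)
        noisy = inject_imputation_noise(
            target, error_rate, rng=np.random.default_rng(s + 7)
        )
        scan_d = _ct_on_target(study, ScoreConfig(mode="dosage"), target=noisy)
        scan_h = _ct_on_target(study, ScoreConfig(mode="hardcall"), target=noisy)
        rd = float(scan_d.best["r2_incremental"])
        rh = float(scan_h.best["r2_incremental"])
        r2_dosage.append(rd)
        r2_bestguess.append(rh)
        wins += rd >= rh
    return {
        "n_seeds": n_seeds,
        "frac_dosage_wins": wins / n_seeds,
        "mean_r2_dosage": float(np.mean(r2_dosage)),
        "mean_r2_bestguess": float(np.mean(r2_bestguess)),
    }
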