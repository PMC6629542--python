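"""Output writers for C+T runs.

All tables are tab-delimited with fixed column order; floating values are
printed at 6 significant digits.  File suffixes follow the conventions of
PLINK-style PRS tooling: ``.prsice`` (per-threshold table), ``.summary``
(one row per phenotype), ``.best`` (best-threshold scores per sample).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ct_engine import PermutationResult, ThresholdScan
from .genotype_io import GenotypeDataset


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_prsice(results: list[tuple[str, ThresholdScan]], path: Path) -> None:
    rows = []
    for name, scan in results:
        for r in scan.table.itertuples(index=False):
            rows.append(
                (name, r.threshold, r.r2_incremental, r.pvalue,
                 r.coefficient, r.se, r.n_snps)
            )
    df = pd.DataFrame(
        rows, columns=["Phenotype", "Threshold", "R2", "P", "Coefficient", "SE", "Num_SNP"]
    )
    _write_table(df, path)


def write_summary(
    results: list[tuple[str, ThresholdScan, PermutationResult | None]], path: Path
) -> None:
    rows = []
    for name, scan, perm in results:
        b = scan.best
        rows.append(
            (name, b["threshold"], b["r2_incremental"], b["pvalue"],
             b["coefficient"], b["se"],
             perm.empirical_p if perm is not None else None,
             int(b["n_snps"]))
        )
    df = pd.DataFrame(
        rows,
        columns=["Phenotype", "Threshold", "R2", "P", "Coefficient", "SE",
                 "Empirical_P", "Num_SNP"],
    )
    _write_table(df, path)


def write_best(
    dataset: GenotypeDataset, scan: ThresholdScan, path: Path
) -> None:
    """Best-threshold PRS per sample; In_Regression marks complete cases."""
    in_reg = np.zeros(dataset.n_samples, dtype=bool)
    in_reg[scan.sample_index] = True
    best_scores = np.full(dataset.n_samples, np.nan)
    best_scores[scan.sample_index] = scan.score_matrix.scores[:, scan.best_index]
    df = pd.DataFrame(
        {
            "FID": dataset.samples["fid"],
            "IID": dataset.samples["iid"],
            "In_Regression": np.where(in_reg, "Yes", "No"),
            "PRS": best_scores,
        }
    )
    _write_table(df, path)


def write_strata(plot_table: pd.DataFrame, path: Path) -> None:
    df = plot_table.rename(
        columns={"stratum": "Stratum", "estimate": "Estimate", "ci_low": "CI_Low",
                 "ci_high": "CI_High", "n": "N", "reference": "Reference"}
    )
    _write_table(df, path)


def plot_bar(results: list[tuple[str, ThresholdScan]], path: Path) -> None:
    """Bar chart of incremental R2 across thresholds (cosmetic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, scan in results:
        t = scan.table
        ax.bar([f"{x:g}" for x in t["threshold"]], t["r2_incremental"], label=name, alpha=0.7)
    ax.set_xlabel("P-value threshold")
    ax.set_ylabel("incremental $R^2$")
    if len(results) > 1:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_strata(plot_table: pd.DataFrame, family: str, path: Path) -> None:
    """Per-stratum estimate with 95% CI bars vs the reference stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(plot_table))
    est = plot_table["estimate"].to_numpy(dtype=float)
    lo = plot_table["ci_low"].to_numpy(dtype=float)
    hi = plot_table["ci_high"].to_numpy(dtype=float)
    yerr = np.vstack([est - lo, hi - est])
    yerr[~np.isfinite(yerr)] = 0
    ax.errorbar(x, est, yerr=yerr, fmt="o", capsize=3)
    ax.axhline(1.0 if family == "binary" else 0.0, ls="--", color="grey")
    ax.set_xticks(x, plot_table["stratum"], rotation=45, ha="right")
    ax.set_ylabel("odds ratio" if family == "binary" else "difference vs reference")
    ax.set_xlabel("PRS stratum (percentiles)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
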