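"""Per-individual polygenic score computation.

The score of individual *s* is the weighted sum over panel variants of the
coded genotype, with weights the base GWAS effect sizes:

    PRS_s = sum_i beta_i * code(g_si)          (hard-call mode)
    PRS_s = sum_i beta_i * (w_si1 + 2 w_si2)   (dosage mode, additive)

Scores are accumulated incrementally across an ascending grid of P-value
thresholds: each threshold column adds only the variants newly admitted
since the previous one, which makes a dense high-resolution scan no more
expensive than a single pass over the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeDataset
from .sumstats import HarmonizedPanel

logger = logging.getLogger(__name__)

MODELS = ("additive", "dominant", "recessive", "heterozygous")
MISSING_POLICIES = ("mean_impute", "set_zero", "center")


@dataclass
class ScoreConfig:
    model: str = "additive"
    missing_policy: str = "mean_impute"
    mode: str = "hardcall"            # or "dosage"
    aggregate: str = "average"        # or "sum"
    expected_encoding: bool = False   # allow dominant/recessive expectations in dosage mode

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"unknown missing policy {self.missing_policy!r}")
        if self.mode not in ("hardcall", "dosage"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.aggregate not in ("average", "sum"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.mode == "dosage" and self.model != "additive" and not self.expected_encoding:
            raise ValueError(
                "dosage mode supports the additive model only "
                "(set expected_encoding=True for expected dominant/recessive codes)"
            )


@dataclass
class ScoreMatrix:
    """PRS at each threshold, plus bookkeeping for the average aggregate."""

    scores: np.ndarray        # (n_samples, n_thresholds)
    snp_counts: np.ndarray    # (n_thresholds,) variants admitted per threshold
    denominators: np.ndarray  # (n_samples, n_thresholds) non-missing allele counts
    thresholds: np.ndarray

    @property
    def empty_columns(self) -> np.ndarray:
        return self.snp_counts == 0


def encode_genotype(g: int, model: str) -> int:
    """Code a hard call under an inheritance model; missing passes through."""
    if g < 0:
        return -1
    if model == "additive":
        return g
    if model == "dominant":
        return 1 if g >= 1 else 0
    if model == "recessive":
        return 1 if g == 2 else 0
    if model == "heterozygous":
        return 1 if g == 1 else 0
    raise ValueError(f"unknown model {model!r}")


def dosage_contribution(prob_triple, beta: float) -> float:
    """Score increment of one imputed genotype: beta * (w1 + 2*w2)."""
    p = np.asarray(prob_triple, dtype=float)
    if p.shape != (3,) or np.any(p < 0):
        raise ValueError("invalid probability triple")
    return float(beta * (p[1] + 2.0 * p[2]))


def _coded_matrix(
    dataset: GenotypeDataset, panel: HarmonizedPanel, config: ScoreConfig
) -> np.ndarray:
    """(n_samples, n_panel) coded genotype values with NaN for missing.

    Applies the harmonization recode (g -> 2 - g for swap/flip_swap) before
    the inheritance-model encoding.
    """
    vidx = panel.entries["variant_idx"].to_numpy()
    swap = panel.entries["action"].isin(["swap", "flip_swap"]).to_numpy()

    if config.mode == "dosage":
        D = dataset.get_dosages()[:, vidx].astype(float).copy()
        D[:, swap] = 2.0 - D[:, swap]
        if config.model == "additive":
            return D
        # expected encodings from probabilities: dominant = w1+w2, recessive = w2
        if dataset.probabilities is None:
            raise ValueError("expected non-additive encodings require probabilities")
        P = dataset.probabilities[:, vidx, :].copy()
        P[:, swap, :] = P[:, swap, ::-1]
        if config.model == "dominant":
            return P[:, :, 1] + P[:, :, 2]
        if config.model == "recessive":
            return P[:, :, 2]
        return P[:, :, 1]  # heterozygous

    G = dataset.hardcalls[:, vidx].astype(float)
    miss = G < 0
    G = np.where(miss, np.nan, G)
    G[:, swap] = 2.0 - G[:, swap]
    if config.model == "dominant":
        G = (G >= 1).astype(float) + np.where(np.isnan(G), np.nan, 0.0)
    elif config.model == "recessive":
        G = (G == 2).astype(float) + np.where(np.isnan(G), np.nan, 0.0)
    elif config.model == "heterozygous":
        G = (G == 1).astype(float) + np.where(np.isnan(G), np.nan, 0.0)
    return G


def compute_scores(
    dataset: GenotypeDataset,
    panel: HarmonizedPanel,
    thresholds,
    config: ScoreConfig | None = None,
) -> ScoreMatrix:
    """Accumulate PRS over an ascending threshold grid.

    The panel must already be clumped and is consumed in its canonical
    P-ascending order; column *t* contains exactly the entries with
    P <= thresholds[t].  Missing genotypes are handled per
    ``config.missing_policy``; with ``aggregate='average'`` each sample's sum
    is divided by its non-missing allele count (2 x non-missing contributing
    variants) at that threshold.
    """
    config = config or ScoreConfig()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or len(thresholds) == 0:
        raise ValueError("thresholds must be a non-empty 1-D ascending sequence")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")

    pvals = panel.entries["pvalue"].to_numpy()
    if np.any(np.diff(pvals) < 0):
        raise ValueError("panel entries must be sorted by ascending P")
    beta = panel.entries["beta"].to_numpy()

    C = _coded_matrix(dataset, panel, config)  # NaN = missing
    nonmiss = np.isfinite(C)
    n, k = C.shape

    with np.errstate(invalid="ignore"):
        colsum = np.nansum(C, axis=0)
    colcount = nonmiss.sum(axis=0)
    colmean = np.divide(
        colsum, colcount, out=np.zeros(k), where=colcount > 0
    )

    if config.missing_policy == "mean_impute":
        filled = np.where(nonmiss, C, colmean[None, :])
    elif config.missing_policy == "set_zero":
        filled = np.where(nonmiss, C, 0.0)
    else:  # center
        filled = np.where(nonmiss, C - colmean[None, :], 0.0)

    contrib = filled * beta[None, :]

    # cumulative over panel order; thresholds map to prefix lengths
    cut = np.searchsorted(pvals, thresholds, side="right")
    cum_contrib = np.cumsum(contrib, axis=1)
    cum_nonmiss = np.cumsum(nonmiss, axis=1)

    scores = np.zeros((n, len(thresholds)))
    denom = np.zeros((n, len(thresholds)))
    for t, c in enumerate(cut):
        if c == 0:
            continue
        scores[:, t] = cum_contrib[:, c - 1]
        denom[:, t] = 2.0 * cum_nonmiss[:, c - 1]

    if config.aggregate == "average":
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(denom > 0, scores / np.where(denom > 0, denom, 1.0), 0.0)

    return ScoreMatrix(
        scores=scores,
        snp_counts=cut.astype(np.int64),
        denominators=denom,
        thresholds=thresholds,
    )
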