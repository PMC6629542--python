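"""Greedy P-value-ordered LD clumping.

Variants are visited in ascending P-value order; each variant not yet
removed becomes an index variant and removes every remaining variant on the
same chromosome within a physical window whose squared genotype correlation
with it reaches the r2 threshold.  The LD statistic is the squared Pearson
correlation of hard-call vectors (composite LD) over pairwise-complete
samples, matching PLINK-style clumping without requiring phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeDataset, hard_call_matrix
from .sumstats import HarmonizedPanel

logger = logging.getLogger(__name__)


@dataclass
class ClumpParams:
    window_kb: float = 250.0
    r2_threshold: float = 0.1
    p_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0.0 <= self.r2_threshold:
            raise ValueError("r2_threshold must be non-negative")


@dataclass
class ClumpResult:
    """Indices are row positions into the panel's (P-sorted) entries."""

    index_entries: np.ndarray              # retained entry positions, P-ascending
    clumped_away: dict[str, str] = field(default_factory=dict)  # removed id -> index id

    @property
    def n_retained(self) -> int:
        return len(self.index_entries)


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two hard-call vectors.

    Missing calls (negative values or NaN) are removed pairwise.  Returns
    NaN when fewer than 2 complete pairs remain or either vector is
    monomorphic — callers treat that as "no usable LD" (r2 = 0).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = np.isfinite(g1) & np.isfinite(g2) & (g1 >= 0) & (g2 >= 0)
    x, y = g1[ok], g2[ok]
    if len(x) < 2:
        return np.nan
    vx = x.var()
    vy = y.var()
    if vx <= 0 or vy <= 0:
        return np.nan
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def clump(
    panel: HarmonizedPanel,
    dataset: GenotypeDataset,
    params: ClumpParams | None = None,
    ld_dataset: GenotypeDataset | None = None,
) -> ClumpResult:
    """Greedily thin the harmonized panel by LD and P-value.

    ``ld_dataset`` optionally supplies an external LD reference (matched by
    variant index layout, e.g. the same trio read separately); it defaults to
    the scoring target itself.  Entries with P above ``params.p_threshold``
    are excluded from consideration entirely.
    """
    params = params or ClumpParams()
    ld = ld_dataset if ld_dataset is not None else dataset

    e = panel.entries
    eligible = np.flatnonzero(e["pvalue"].to_numpy() <= params.p_threshold)
    if len(eligible) < len(e):
        logger.info("clump: %d entries above clump-p excluded", len(e) - len(eligible))

    chrom = e["chrom"].to_numpy()[eligible]
    pos = e["pos"].to_numpy(dtype=np.int64)[eligible]
    vidx = e["variant_idx"].to_numpy()[eligible]
    ids = e["id"].to_numpy()[eligible]
    window = int(round(params.window_kb * 1000))

    if ld.probabilities is not None and ld.hardcalls is None:
        geno = hard_call_matrix(ld.probabilities)
    else:
        geno = ld.hardcalls
    G = geno[:, vidx].astype(float)
    G[G < 0] = np.nan

    k = len(eligible)
    removed = np.zeros(k, dtype=bool)
    indexed = np.zeros(k, dtype=bool)
    clumped_away: dict[str, str] = {}
    n_undefined = 0

    # entries are already P-ascending with the canonical tie order
    for i in range(k):
        if removed[i]:
            continue
        indexed[i] = True
        near = (
            ~removed
            & ~indexed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        for j in np.flatnonzero(near):
            r2 = genotype_r2(G[:, i], G[:, j])
            if np.isnan(r2):
                n_undefined += 1
                continue
            if r2 >= params.r2_threshold:
                removed[j] = True
                clumped_away[ids[j]] = ids[i]
    if n_undefined:
        logger.info("clump: %d undefined LD pairs treated as r2=0", n_undefined)

    return ClumpResult(index_entries=eligible[indexed], clumped_away=clumped_away)


def clump_report(panel: HarmonizedPanel, result: ClumpResult) -> "pd.DataFrame":
    """Tab-delimited-ready clump report: index SNP, P, n clumped, members."""
    import pandas as pd

    e = panel.entries
    members: dict[str, list[str]] = {}
    for removed_id, index_id in result.clumped_away.items():
        members.setdefault(index_id, []).append(removed_id)
    rows = []
    for i in result.index_entries:
        vid = e["id"].iloc[i]
        mem = sorted(members.get(vid, []))
        rows.append((vid, e["pvalue"].iloc[i], len(mem), ",".join(mem) or "-"))
    return pd.DataFrame(rows, columns=["INDEX_SNP", "P", "N_CLUMPED", "MEMBERS"])
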