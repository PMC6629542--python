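"""Base GWAS summary statistics: parsing and allele harmonization.

Harmonization matches each base variant to the target panel by variant ID
and decides how the base effect maps onto the target's counted allele:

``match``
    base effect allele == target a1, other allele == target a2.
``swap``
    alleles reversed; the genotype is recoded g -> 2 - g at scoring time.
``flip``
    alleles agree after complementing the target (reverse strand report).
``flip_swap``
    reversed after complementing.

Strand-ambiguous variants (A/T, C/G) cannot be distinguished from their
reverse complement and are dropped by default.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# auto-detection candidates, checked case-insensitively in order
_AUTO_COLUMNS = {
    "id": ("SNP", "ID", "RSID", "MARKERNAME", "VARIANT_ID"),
    "chrom": ("CHR", "CHROM", "CHROMOSOME"),
    "pos": ("BP", "POS", "POSITION", "BASE_PAIR_LOCATION"),
    "effect_allele": ("A1", "EA", "EFFECT_ALLELE", "ALLELE1"),
    "other_allele": ("A2", "OA", "NEA", "OTHER_ALLELE", "ALLELE2"),
    "beta": ("BETA", "B", "EFFECT", "OR", "STAT", "LOG_ODDS"),
    "pvalue": ("P", "PVAL", "PVALUE", "P_VALUE"),
    "info": ("INFO",),
    "eaf": ("EAF", "FRQ", "FREQ", "MAF", "AF"),
}


class SumstatsError(Exception):
    pass


class EmptyOverlapError(Exception):
    """No variant shared between base summary statistics and target."""


@dataclass
class SummaryStats:
    """Per-variant base GWAS results on the beta (log-odds for binary) scale."""

    table: pd.DataFrame  # columns: id, effect_allele, other_allele, beta, pvalue, (chrom, pos, info, eaf)
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class HarmonizedPanel:
    """Base variants matched to target columns with recode directives.

    ``entries`` is sorted by ascending P-value (ties by chromosome, position,
    ID) — the canonical order used by clumping and scoring.
    """

    entries: pd.DataFrame  # columns: variant_idx, id, chrom, pos, beta, pvalue, action
    drop_log: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, keep: np.ndarray) -> "HarmonizedPanel":
        return HarmonizedPanel(
            entries=self.entries.iloc[np.asarray(keep)].reset_index(drop=True),
            drop_log=Counter(self.drop_log),
        )


def _resolve_columns(header: list[str], column_map: dict | None) -> dict:
    upper = {h.upper(): h for h in header}
    resolved: dict[str, str | None] = {}
    column_map = column_map or {}
    for key, candidates in _AUTO_COLUMNS.items():
        if key in column_map and column_map[key] is not None:
            name = column_map[key]
            if name not in header:
                raise SumstatsError(f"column {name!r} (for {key}) not found in header")
            resolved[key] = name
            continue
        resolved[key] = next((upper[c] for c in candidates if c in upper), None)
    for mandatory in ("id", "effect_allele", "beta", "pvalue"):
        if resolved[mandatory] is None:
            raise SumstatsError(
                f"could not locate a column for {mandatory!r}; pass column_map"
            )
    return resolved


def read_sumstats(
    path,
    column_map: dict | None = None,
    effect_is_or: bool = False,
) -> SummaryStats:
    """Parse whitespace/tab-delimited summary statistics with a header row.

    ``column_map`` overrides auto-detection with keys ``id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``beta``, ``pvalue``,
    ``info``, ``eaf``.  With ``effect_is_or`` the effect column is an odds
    ratio and is converted to beta = ln(OR); OR <= 0 rows are dropped.  Rows
    with non-numeric effect or P outside (0, 1] are dropped with a logged
    count.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = _resolve_columns(list(raw.columns), column_map)

    out = pd.DataFrame({"id": raw[cols["id"]].astype(str)})
    for key in ("chrom", "pos", "effect_allele", "other_allele", "info", "eaf"):
        if cols[key] is not None:
            out[key] = raw[cols[key]]
    if "effect_allele" in out:
        out["effect_allele"] = out["effect_allele"].str.upper()
    if "other_allele" in out:
        out["other_allele"] = out["other_allele"].str.upper()
    if "pos" in out:
        out["pos"] = pd.to_numeric(out["pos"], errors="coerce")
    for key in ("info", "eaf"):
        if key in out:
            out[key] = pd.to_numeric(out[key], errors="coerce")

    eff = pd.to_numeric(raw[cols["beta"]], errors="coerce")
    pval = pd.to_numeric(raw[cols["pvalue"]], errors="coerce")

    ok = np.isfinite(eff) & np.isfinite(pval) & (pval > 0) & (pval <= 1)
    if effect_is_or:
        ok &= eff > 0
        beta = np.log(eff.where(eff > 0))
    else:
        beta = eff
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d summary-statistic rows (bad effect or P)", n_dropped)

    out["beta"] = beta
    out["pvalue"] = pval
    out = out[ok.to_numpy()].reset_index(drop=True)
    return SummaryStats(table=out, n_dropped=n_dropped)


def _is_snp(a: str) -> bool:
    return len(a) == 1 and a in _COMPLEMENT


def _comp(a: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in reversed(a)) if len(a) > 1 else _COMPLEMENT.get(a, a)


def harmonize(
    sumstats: SummaryStats,
    dataset: GenotypeDataset,
    keep_ambiguous: bool = False,
) -> HarmonizedPanel:
    """Match base variants against the target and derive recode actions.

    Variant ID is the join key.  Duplicate base IDs keep the smallest-P
    record.  Indels (multi-base alleles) are matched exactly or by swap only.
    Raises :class:`EmptyOverlapError` when no variant can be matched.
    """
    drop = Counter()
    tv = dataset.variants
    target = {
        vid: (idx, a1.upper(), a2.upper(), chrom, pos)
        for idx, (vid, a1, a2, chrom, pos) in enumerate(
            zip(tv["id"], tv["a1"], tv["a2"], tv["chrom"], tv["pos"])
        )
    }

    ss = sumstats.table
    dup = ss["id"].duplicated(keep=False)
    if dup.any():
        # resolve by smallest P; stable order otherwise
        order = np.lexsort((np.arange(len(ss)), ss["pvalue"].to_numpy()))
        ss = ss.iloc[order].drop_duplicates("id", keep="first")
        drop["duplicate"] = len(sumstats.table) - len(ss)
        logger.warning("resolved %d duplicate base IDs by smallest P", drop["duplicate"])

    has_other = "other_allele" in ss.columns

    rows = []
    for rec in ss.itertuples(index=False):
        hit = target.get(rec.id)
        if hit is None:
            drop["not_in_target"] += 1
            continue
        idx, t1, t2, chrom, pos = hit
        ea = rec.effect_allele
        oa = getattr(rec, "other_allele", None) if has_other else None
        if oa is not None and (pd.isna(oa) or oa == ""):
            oa = None

        snp_like = _is_snp(ea) and (oa is None or _is_snp(oa)) and _is_snp(t1) and _is_snp(t2)
        ambiguous = snp_like and oa is not None and _comp(ea) == oa
        if ambiguous and not keep_ambiguous:
            drop["ambiguous"] += 1
            continue

        action = None
        if oa is not None:
            if (ea, oa) == (t1, t2):
                action = "match"
            elif (ea, oa) == (t2, t1):
                action = "swap"
            elif snp_like and not ambiguous:
                if (_comp(ea), _comp(oa)) == (t1, t2):
                    action = "flip"
                elif (_comp(ea), _comp(oa)) == (t2, t1):
                    action = "flip_swap"
        else:
            if ea == t1:
                action = "match"
            elif ea == t2:
                action = "swap"
            elif snp_like:
                if _comp(ea) == t1:
                    action = "flip"
                elif _comp(ea) == t2:
                    action = "flip_swap"
        if action is None:
            drop["mismatch"] += 1
            continue
        rows.append((idx, rec.id, chrom, pos, rec.beta, rec.pvalue, action))

    if not rows:
        raise EmptyOverlapError("no overlapping variants between base and target")

    entries = pd.DataFrame(
        rows, columns=["variant_idx", "id", "chrom", "pos", "beta", "pvalue", "action"]
    )
    # canonical order: ascending P, ties by (chrom, pos, id)
    entries = entries.sort_values(
        ["pvalue", "chrom", "pos", "id"], kind="mergesort"
    ).reset_index(drop=True)
    if entries["variant_idx"].duplicated().any():
        raise SumstatsError("internal error: target variant matched twice")
    logger.info(
        "harmonized %d variants (%s)", len(entries),
        ", ".join(f"{k}={v}" for k, v in sorted(drop.items())) or "no drops",
    )
    return HarmonizedPanel(entries=entries, drop_log=drop)
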