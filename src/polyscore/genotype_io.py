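"""Target genotype input/output.

Reads PLINK-1 binary trios (.bed/.bim/.fam) and VCF files carrying GT, DS
(dosage) and/or GP (genotype probability) FORMAT fields into a single
in-memory container, :class:`GenotypeDataset`.  Hard calls are stored as
counts of the a1 (effect-codable) allele in ``{0, 1, 2}`` with ``-1``
marking missing.  For imputed data the container optionally carries a
samples x variants x 3 probability tensor (P(g=0), P(g=1), P(g=2)) and the
derived dosage matrix ``d = w1 + 2*w2``.

The module also implements the best-guess rule (accept the most probable
genotype only if its probability reaches a threshold, 0.9 by default, else
missing), sample/variant extraction-exclusion lists and the INFO-score
filter used to remove poorly imputed variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

PLINK_MAGIC = b"\x6c\x1b\x01"

# PLINK 2-bit codes (low bits first within a byte): 00=hom a1 -> 2 copies of a1,
# 01=missing, 10=het, 11=hom a2 -> 0 copies of a1.
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

# 256-entry byte -> 4 genotype lookup, built once.
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_COUNT[(_b >> (2 * _k)) & 0b11]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeIOError(Exception):
    """Unsupported or corrupt genotype input."""


class EmptyDatasetError(Exception):
    """A filter removed every sample or every variant."""


@dataclass
class GenotypeDataset:
    """Samples x variants genotype container.

    Attributes
    ----------
    samples : pd.DataFrame
        Columns ``fid``, ``iid`` in file order.
    variants : pd.DataFrame
        Columns ``id``, ``chrom``, ``pos``, ``a1``, ``a2`` and optionally
        ``info`` (imputation quality in [0, 1], NaN when unrecorded).
    hardcalls : np.ndarray
        ``(n_samples, n_variants)`` int8 counts of a1, ``-1`` = missing.
    probabilities : np.ndarray or None
        ``(n_samples, n_variants, 3)`` genotype probabilities.
    dosages : np.ndarray or None
        ``(n_samples, n_variants)`` expected a1 count in [0, 2].
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    hardcalls: np.ndarray
    probabilities: np.ndarray | None = None
    dosages: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.hardcalls.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"hardcalls shape {self.hardcalls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.probabilities is not None and self.probabilities.shape != (n, m, 3):
            raise ValueError("probability tensor shape mismatch")
        if self.dosages is not None and self.dosages.shape != (n, m):
            raise ValueError("dosage matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_ids(self) -> list[tuple[str, str]]:
        return list(zip(self.samples["fid"], self.samples["iid"]))

    def get_dosages(self) -> np.ndarray:
        """Dosage matrix, derived from probabilities when not stored."""
        if self.dosages is not None:
            return self.dosages
        if self.probabilities is not None:
            return self.probabilities[:, :, 1] + 2.0 * self.probabilities[:, :, 2]
        raise ValueError("dataset carries neither dosages nor probabilities")

    def subset(
        self,
        sample_idx: np.ndarray | None = None,
        variant_idx: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Positional subset preserving order; indices are row/column positions."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeDataset(
            samples=self.samples.iloc[si].reset_index(drop=True),
            variants=self.variants.iloc[vi].reset_index(drop=True),
            hardcalls=self.hardcalls[np.ix_(si, vi)],
            probabilities=None
            if self.probabilities is None
            else self.probabilities[np.ix_(si, vi)],
            dosages=None if self.dosages is None else self.dosages[np.ix_(si, vi)],
        )


@dataclass
class FilterSpec:
    """Sample/variant extraction-exclusion and quality filters.

    ``keep_samples``/``remove_samples`` hold ``(fid, iid)`` pairs or bare IIDs;
    ``extract_variants``/``exclude_variants`` hold variant IDs.  ``info_min``
    drops variants whose recorded INFO falls below the threshold (variants
    without a recorded INFO are retained).  ``hardcall_prob_min`` re-derives
    hard calls from probabilities under the best-guess rule.
    """

    keep_samples: set | None = None
    remove_samples: set | None = None
    extract_variants: set | None = None
    exclude_variants: set | None = None
    info_min: float | None = None
    hardcall_prob_min: float = 0.9

    def __post_init__(self) -> None:
        if self.keep_samples is not None and self.remove_samples is not None:
            raise ValueError("keep_samples and remove_samples are mutually exclusive")
        if self.extract_variants is not None and self.exclude_variants is not None:
            raise ValueError("extract_variants and exclude_variants are mutually exclusive")


def _normalize_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def hard_call(prob_triple: Sequence[float], threshold: float = 0.9) -> int:
    """Best-guess genotype from a probability triple.

    Returns the argmax genotype in {0, 1, 2} if its probability is at least
    ``threshold``, otherwise ``-1`` (missing).  Probabilities must be
    non-negative; triples off unit sum are renormalized.
    """
    p = np.asarray(prob_triple, dtype=float)
    if p.shape != (3,):
        raise ValueError("probability triple must have exactly 3 entries")
    if np.any(p < 0):
        raise ValueError("negative genotype probability")
    s = p.sum()
    if s <= 0:
        return -1
    p = p / s
    j = int(np.argmax(p))
    return j if p[j] >= threshold else -1


def hard_call_matrix(probabilities: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Vectorized best-guess rule over a (n, m, 3) probability tensor."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative genotype probability")
    s = p.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pn = np.where(s > 0, p / s, 0.0)
    calls = np.argmax(pn, axis=2).astype(np.int8)
    best = np.max(pn, axis=2)
    calls[best < threshold] = MISSING
    return calls


# ---------------------------------------------------------------------------
# PLINK-1 binary trio
# ---------------------------------------------------------------------------

def read_plink(
    bed_path: str | Path,
    bim_path: str | Path | None = None,
    fam_path: str | Path | None = None,
) -> GenotypeDataset:
    """Read a SNP-major PLINK-1 .bed/.bim/.fam trio.

    ``bed_path`` may be a bare prefix; sibling .bim/.fam paths are then
    inferred.  The .bim allele-1 column is the counted allele.  Duplicate
    variant IDs keep their first occurrence (later copies dropped, logged).
    """
    bed_path = Path(bed_path)
    if bed_path.suffix != ".bed":
        prefix = bed_path
        bed_path = prefix.with_suffix(".bed")
        bim_path = bim_path or prefix.with_suffix(".bim")
        fam_path = fam_path or prefix.with_suffix(".fam")
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    bim["chrom"] = bim["chrom"].map(_normalize_chrom)
    bim["pos"] = bim["pos"].astype(np.int64)

    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if raw[:3] != PLINK_MAGIC:
        if raw[:2] == PLINK_MAGIC[:2] and len(raw) > 2 and raw[2] == 0:
            raise GenotypeIOError(
                f"{bed_path}: individual-major .bed files are not supported"
            )
        raise GenotypeIOError(f"{bed_path}: not a PLINK-1 .bed file (bad magic bytes)")
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise GenotypeIOError(
            f"{bed_path}: size {len(raw)} does not match {n} samples x {m} variants "
            f"(expected {expected} bytes)"
        )

    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # decode: (m, bytes) -> (m, bytes*4) -> trim padding -> transpose
    decoded = _BYTE_LUT[body].reshape(m, bytes_per_variant * 4)[:, :n]
    hardcalls = np.ascontiguousarray(decoded.T)

    dup = bim["id"].duplicated(keep="first")
    if dup.any():
        logger.warning("dropping %d duplicate variant IDs (keeping first)", int(dup.sum()))
        keep = np.flatnonzero(~dup.to_numpy())
        bim = bim.iloc[keep].reset_index(drop=True)
        hardcalls = hardcalls[:, keep]

    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    samples = fam[["fid", "iid"]].copy()
    return GenotypeDataset(samples=samples, variants=variants, hardcalls=hardcalls)


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``dataset`` as a SNP-major PLINK-1 trio at ``prefix``.

    The dataset must carry hard calls; dosage-only data must be hard-called
    first.  Round-trips through :func:`read_plink` bit-identically.
    """
    if dataset.n_samples == 0:
        raise ValueError("cannot write a PLINK trio with no samples")
    if dataset.n_variants == 0:
        raise ValueError("cannot write a PLINK trio with no variants")
    hc = dataset.hardcalls
    if hc is None or not np.all(np.isin(hc, [-1, 0, 1, 2])):
        raise ValueError("dataset must carry valid hard calls; hard-call dosage data first")

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = hc.shape

    code = np.empty_like(hc, dtype=np.uint8)
    for count, c in _COUNT_TO_CODE.items():
        code[hc == count] = c
    pad = (-n) % 4
    if pad:
        # pad samples encode as hom-a2 (code 0b11 would be wrong: PLINK pads with 0 bits)
        code = np.vstack([code, np.zeros((pad, m), dtype=np.uint8)])
    ncols = code.shape[0] // 4
    shifted = code.T.reshape(m, ncols, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = shifted[:, :, 0] | shifted[:, :, 1] | shifted[:, :, 2] | shifted[:, :, 3]

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())

    v = dataset.variants
    cm = np.zeros(m)
    bim = pd.DataFrame(
        {"chrom": v["chrom"], "id": v["id"], "cm": cm.astype(int),
         "pos": v["pos"], "a1": v["a1"], "a2": v["a2"]}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    s = dataset.samples
    fam = pd.DataFrame(
        {"fid": s["fid"], "iid": s["iid"], "pid": 0, "mid": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    vcf_path: str | Path,
    field_priority: Sequence[str] = ("GT", "GP", "DS"),
    hardcall_prob_min: float = 0.9,
) -> GenotypeDataset:
    """Read a VCF with GT/DS/GP FORMAT fields.

    The ALT allele is the counted allele (a1).  Probabilities come from GP,
    dosages from DS or, failing that, from GP as w1 + 2*w2.  Hard calls come
    from the first available source in ``field_priority``: GT directly, or GP
    through the best-guess rule.  Multiallelic records and records lacking
    all three fields are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = pd.DataFrame({"fid": vcf.samples, "iid": vcf.samples})
    n = len(vcf.samples)

    rows, gt_cols, ds_cols, gp_cols = [], [], [], []
    n_multi = n_empty = 0
    any_ds = any_gp = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = ds = gp = None
        try:
            # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
            g = np.asarray(v.gt_types, dtype=np.int8)
            gt = np.where(g == 3, MISSING, g)
        except Exception:
            gt = None
        try:
            arr = v.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).reshape(n)
        except KeyError:
            ds = None
        try:
            arr = v.format("GP")
            if arr is not None:
                gp = np.asarray(arr, dtype=float).reshape(n, 3)
        except KeyError:
            gp = None
        if gt is None and ds is None and gp is None:
            n_empty += 1
            logger.warning("variant %s has none of GT/DS/GP; skipped", v.ID or v.POS)
            continue
        rows.append(
            {"id": v.ID or f"{v.CHROM}:{v.POS}", "chrom": _normalize_chrom(v.CHROM),
             "pos": int(v.POS), "a1": v.ALT[0], "a2": v.REF,
             "info": _vcf_info_score(v)}
        )
        gt_cols.append(gt)
        ds_cols.append(ds)
        gp_cols.append(gp)
        any_ds = any_ds or ds is not None
        any_gp = any_gp or gp is not None
    if n_multi:
        logger.warning("skipped %d multiallelic VCF records", n_multi)
    if not rows:
        raise GenotypeIOError(f"{vcf_path}: no usable biallelic records")

    m = len(rows)
    variants = pd.DataFrame(rows)

    probabilities = None
    if any_gp:
        probabilities = np.full((n, m, 3), np.nan)
        for j, gp in enumerate(gp_cols):
            if gp is not None:
                probabilities[:, j, :] = gp
        probabilities = _renormalize_probs(probabilities)

    dosages = None
    if any_ds or any_gp:
        dosages = np.full((n, m), np.nan)
        for j, (ds, gp) in enumerate(zip(ds_cols, gp_cols)):
            if ds is not None:
                dosages[:, j] = ds
            elif gp is not None:
                dosages[:, j] = probabilities[:, j, 1] + 2.0 * probabilities[:, j, 2]

    hardcalls = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        for source in field_priority:
            if source == "GT" and gt_cols[j] is not None:
                hardcalls[:, j] = gt_cols[j]
                break
            if source == "GP" and gp_cols[j] is not None:
                hardcalls[:, j] = hard_call_matrix(
                    probabilities[:, j : j + 1, :], hardcall_prob_min
                )[:, 0]
                break

    return GenotypeDataset(
        samples=samples, variants=variants, hardcalls=hardcalls,
        probabilities=probabilities, dosages=dosages,
    )


def _vcf_info_score(v) -> float:
    for key in ("INFO", "R2", "DR2"):
        val = v.INFO.get(key)
        if val is not None:
            try:
                return float(val)
            except (TypeError, ValueError):
                pass
    return np.nan


def _renormalize_probs(p: np.ndarray, tol: float = 1e-4) -> np.ndarray:
    """Renormalize triples whose sum deviates from 1 by more than ``tol``."""
    s = p.sum(axis=2, keepdims=True)
    off = np.abs(s - 1.0) > tol
    n_off = int(np.sum(off & np.isfinite(s) & (s > 0)))
    if n_off:
        logger.warning("renormalized %d probability triples off unit sum", n_off)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(s > 0, p / s, p)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _sample_mask(samples: pd.DataFrame, ids: set, keep: bool) -> np.ndarray:
    pairs = set()
    bare = set()
    for item in ids:
        if isinstance(item, tuple):
            pairs.add(tuple(map(str, item)))
        else:
            bare.add(str(item))
    member = np.array(
        [((f, i) in pairs) or (i in bare) for f, i in zip(samples["fid"], samples["iid"])]
    )
    known = pairs | bare
    present = {i for _, i in zip(samples["fid"], samples["iid"])} | {
        (f, i) for f, i in zip(samples["fid"], samples["iid"])
    }
    unknown = [x for x in known if x not in present and not (
        isinstance(x, tuple) and x in present)]
    if unknown:
        logger.info("%d sample filter IDs not present in dataset", len(unknown))
    return member if keep else ~member


def apply_filters(dataset: GenotypeDataset, spec: FilterSpec) -> GenotypeDataset:
    """Apply extraction/exclusion lists and quality filters.

    Order of samples and variants is preserved.  When the dataset carries
    probabilities, hard calls are re-derived under the best-guess rule at
    ``spec.hardcall_prob_min``.  Raises :class:`EmptyDatasetError` if nothing
    survives.
    """
    smask = np.ones(dataset.n_samples, dtype=bool)
    if spec.keep_samples is not None:
        smask &= _sample_mask(dataset.samples, spec.keep_samples, keep=True)
    if spec.remove_samples is not None:
        smask &= _sample_mask(dataset.samples, spec.remove_samples, keep=False)

    vmask = np.ones(dataset.n_variants, dtype=bool)
    ids = dataset.variants["id"]
    if spec.extract_variants is not None:
        unknown = spec.extract_variants - set(ids)
        if unknown:
            logger.info("%d extract IDs not present in dataset", len(unknown))
        vmask &= ids.isin(spec.extract_variants).to_numpy()
    if spec.exclude_variants is not None:
        vmask &= ~ids.isin(spec.exclude_variants).to_numpy()
    if spec.info_min is not None and "info" in dataset.variants.columns:
        info = dataset.variants["info"].to_numpy(dtype=float)
        # filter applies only where INFO is recorded
        vmask &= ~(np.isfinite(info) & (info < spec.info_min))

    if not smask.any():
        raise EmptyDatasetError("sample filters removed every sample")
    if not vmask.any():
        raise EmptyDatasetError("variant filters removed every variant")

    out = dataset.subset(np.flatnonzero(smask), np.flatnonzero(vmask))
    if out.probabilities is not None:
        finite = np.all(np.isfinite(out.probabilities), axis=2)
        hc = hard_call_matrix(
            np.where(finite[:, :, None], out.probabilities, 0.0), spec.hardcall_prob_min
        )
        hc[~finite] = out.hardcalls[~finite]
        out = replace(out, hardcalls=hc)
    return out


def read_id_list(path: str | Path) -> set:
    """Read a keep/remove/extract/exclude file: one ID, or FID IID, per line."""
    out: set = set()
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        out.add((parts[0], parts[1]) if len(parts) >= 2 else parts[0])
    return out
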