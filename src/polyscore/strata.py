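"""PRS strata analysis.

Individuals are binned into M quantile strata of their polygenic score; a
dummy-coded N x (M-1) design (reference stratum omitted — by default the
stratum containing the median score) is regressed against the phenotype.
For quantitative traits the per-stratum coefficients estimate the
phenotypic difference vs the reference; for binary traits the exponentiated
coefficients are odds ratios.  The tidy plot table labels strata as
percentile intervals, e.g. "(80,90]".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class StrataError(Exception):
    pass


@dataclass
class StrataDesign:
    n_strata: int
    breaks: np.ndarray          # percentile boundaries, length M+1, starts at 0 ends at 100
    assignment: np.ndarray      # per-sample stratum in 1..M
    reference: int              # 1-based stratum index
    design: np.ndarray          # (N, M-1) indicators, reference column omitted

    def labels(self) -> list[str]:
        return [interval_label(self.breaks[i], self.breaks[i + 1]) for i in range(self.n_strata)]


@dataclass
class StrataEstimates:
    family: str
    strata: list[int]           # non-reference stratum indices (1-based)
    estimates: np.ndarray       # beta (quantitative) or OR (binary)
    ci_low: np.ndarray
    ci_high: np.ndarray
    counts: dict[int, int]      # per-stratum n (all strata)
    reference: int
    llf: float
    breaks: np.ndarray


def interval_label(lo: float, hi: float) -> str:
    def fmt(x: float) -> str:
        return f"{x:g}"

    return f"({fmt(lo)},{fmt(hi)}]"


def parse_interval_label(label: str) -> tuple[float, float]:
    m = re.fullmatch(r"\(\s*([-\d.eE+]+)\s*,\s*([-\d.eE+]+)\s*\]", label.strip())
    if not m:
        raise ValueError(f"cannot parse interval label {label!r}")
    return float(m.group(1)), float(m.group(2))


def assign_strata(
    scores: np.ndarray,
    n_strata: int,
    custom_breaks=None,
    reference: int | None = None,
) -> StrataDesign:
    """Bin scores into quantile strata and build the dummy design matrix.

    Default strata are M equal-count bins (sizes differ by at most 1 absent
    ties; tied boundary scores are split by stable sample order).
    ``custom_breaks`` supplies percentile boundaries instead, e.g.
    ``[0, 10, 20, 30, 40, 60, 70, 80, 90, 100]`` to merge the middle
    quintiles into a single (40,60] reference.  ``reference`` is a 1-based
    stratum index; by default the stratum containing the median score.
    """
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if not np.all(np.isfinite(s)):
        raise StrataError("scores must be finite")

    if custom_breaks is not None:
        breaks = np.asarray(sorted(set(float(b) for b in custom_breaks)))
        if breaks[0] != 0 or breaks[-1] != 100:
            raise StrataError("custom percentile breaks must start at 0 and end at 100")
        M = len(breaks) - 1
    else:
        M = int(n_strata)
        breaks = np.linspace(0, 100, M + 1)
    if M < 2:
        raise StrataError("need at least 2 strata")
    if M > n:
        raise StrataError(f"more strata ({M}) than samples ({n})")
    if np.all(s == s[0]):
        raise StrataError("all scores identical; strata are degenerate")

    # rank-based assignment: stable sort, cut at percentile boundaries of rank
    order = np.argsort(s, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    # sample with rank r has percentile (r+1)/n * 100; stratum k covers (b_k, b_{k+1}]
    pct = (ranks + 1) * (100.0 / n)
    assignment = np.searchsorted(breaks[1:-1], pct, side="left") + 1

    sizes = np.bincount(assignment, minlength=M + 1)[1:]
    if np.any(sizes == 0):
        raise StrataError("empty stratum; reduce M or adjust breaks")

    if reference is None:
        median_rank = (n - 1) // 2
        reference = int(assignment[order[median_rank]])
    if not 1 <= reference <= M:
        raise StrataError(f"reference stratum {reference} out of range 1..{M}")

    cols = [k for k in range(1, M + 1) if k != reference]
    design = np.zeros((n, M - 1))
    for j, k in enumerate(cols):
        design[:, j] = assignment == k

    return StrataDesign(
        n_strata=M, breaks=breaks, assignment=assignment,
        reference=reference, design=design,
    )


def strata_regression(
    design: StrataDesign,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "binary",
) -> StrataEstimates:
    """Estimate per-stratum effects vs the reference stratum.

    Binary traits: logistic regression, exponentiated coefficients (odds
    ratios) with exponentiated Wald 95% CIs.  Quantitative: OLS betas with
    Wald 95% CIs.
    """
    import statsmodels.api as sm

    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        keep &= np.all(np.isfinite(covariates), axis=1)
    X = design.design[keep]
    y = y[keep]
    parts = [np.ones((len(y), 1)), X]
    if covariates is not None:
        parts.append(covariates[keep])
    Xm = np.hstack(parts)

    if family == "binary":
        fit = sm.Logit(y, Xm).fit(disp=0, maxiter=200)
    elif family == "quantitative":
        fit = sm.OLS(y, Xm).fit()
    else:
        raise StrataError(f"unknown family {family!r}")

    k = X.shape[1]
    coefs = np.asarray(fit.params[1 : 1 + k])
    ci = np.asarray(fit.conf_int())[1 : 1 + k]
    strata = [s for s in range(1, design.n_strata + 1) if s != design.reference]
    counts = {
        s: int(np.sum(design.assignment[keep] == s))
        for s in range(1, design.n_strata + 1)
    }
    if family == "binary":
        est, lo, hi = np.exp(coefs), np.exp(ci[:, 0]), np.exp(ci[:, 1])
    else:
        est, lo, hi = coefs, ci[:, 0], ci[:, 1]
    return StrataEstimates(
        family=family, strata=strata, estimates=est, ci_low=lo, ci_high=hi,
        counts=counts, reference=design.reference, llf=float(fit.llf),
        breaks=design.breaks,
    )


def strata_plot_data(estimates: StrataEstimates) -> pd.DataFrame:
    """Tidy strata table: percentile-interval label, estimate, CI, n.

    Includes the reference row at the null value (odds ratio 1 for binary,
    difference 0 for quantitative) with NaN CIs.
    """
    null_val = 1.0 if estimates.family == "binary" else 0.0
    b = estimates.breaks
    rows = []
    j = 0
    for s in range(1, len(b)):
        label = interval_label(b[s - 1], b[s])
        if s == estimates.reference:
            rows.append((label, null_val, np.nan, np.nan, estimates.counts[s], True))
        else:
            rows.append(
                (label, estimates.estimates[j], estimates.ci_low[j],
                 estimates.ci_high[j], estimates.counts[s], False)
            )
            j += 1
    return pd.DataFrame(
        rows, columns=["stratum", "estimate", "ci_low", "ci_high", "n", "reference"]
    )
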