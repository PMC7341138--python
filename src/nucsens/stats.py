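"""Region-level promoter summaries and the paired condition comparison.

The -1 nucleosome band is operationalized as window centers from -200 to
0 bp relative to the TSS; per-gene band means across two conditions feed
a paired t-test (one pair per gene). A Spearman check relates expression
to differential occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionTable, PromoterMatrix


@dataclass
class RegionSummary:
    """Per-gene mean signal over a stated offset band."""

    values: pd.Series            # gene_id -> mean (NaN if all cells NA)
    band: tuple[float, float]
    source: str = ""

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    n: int
    mean_diff: float
    band: tuple[float, float]
    gene_set: str = ""
    n_dropped: int = 0
    flag: str = ""               # "", "zero-variance", "undefined-t"

    def __str__(self) -> str:
        return (
            f"paired t-test ({self.gene_set or 'all genes'}, band "
            f"{self.band[0]}..{self.band[1]} bp): n={self.n}, "
            f"mean diff={self.mean_diff:.4g}, t={self.t:.4g}, df={self.df}, "
            f"p={self.p:.4g}" + (f" [{self.flag}]" if self.flag else "")
        )


def region_summary(
    matrix: PromoterMatrix, band: tuple[float, float]
) -> RegionSummary:
    """Per-gene NA-ignoring mean over window centers with
    band[0] <= center <= band[1] (strand-oriented offsets)."""
    lo, hi = band
    if lo > hi:
        raise ValueError("band lower bound exceeds upper bound")
    centers = np.asarray(matrix.values.columns, dtype=float)
    if lo > centers.max() or hi < centers.min():
        raise ValueError(
            f"band {band} lies outside the matrix offset range "
            f"[{centers.min()}, {centers.max()}]"
        )
    mask = (centers >= lo) & (centers <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no window centers")
    sub = matrix.values.loc[:, mask]
    return RegionSummary(
        sub.mean(axis=1, skipna=True),
        band=(lo, hi),
        source=str(matrix.metadata.get("label", "")),
    )


def paired_t_test(
    a: RegionSummary,
    b: RegionSummary,
    genes: list[str] | None = None,
    gene_set: str = "",
) -> PairedTestResult:
    """Paired t-test of per-gene band means, differences d = b - a.

    t = mean(d) / (sd(d) / sqrt(n)) with the sample (n-1) standard
    deviation and a two-sided Student-t p-value on n-1 df. NA pairs are
    dropped listwise. Zero-variance differences follow the degenerate
    contracts: nonzero mean -> t = +/-inf, p = 0; zero mean -> t
    undefined, p = 1.
    """
    if a.band != b.band:
        raise ValueError("summaries computed on different bands")
    if genes is None:
        genes = [g for g in a.values.index if g in b.values.index]
    va = a.values.reindex(genes)
    vb = b.values.reindex(genes)
    if va.isna().all() and len(genes) and not set(genes) <= set(a.values.index):
        raise ValueError("gene subset not covered by summary a")
    d = (vb - va).to_numpy(dtype=float)
    keep = ~np.isnan(d)
    n_dropped = int((~keep).sum())
    d = d[keep]
    n = len(d)
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, have {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(
                t=math.nan, df=df, p=1.0, n=n, mean_diff=mean, band=a.band,
                gene_set=gene_set, n_dropped=n_dropped, flag="undefined-t",
            )
        return PairedTestResult(
            t=math.copysign(math.inf, mean), df=df, p=0.0, n=n,
            mean_diff=mean, band=a.band, gene_set=gene_set,
            n_dropped=n_dropped, flag="zero-variance",
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTestResult(
        t=t, df=df, p=p, n=n, mean_diff=mean, band=a.band,
        gene_set=gene_set, n_dropped=n_dropped,
    )


def expression_occupancy_correlation(
    expr: ExpressionTable,
    diff: RegionSummary | pd.Series,
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation between expression and a per-gene differential signal.

    Spearman by default (robust to expression's heavy tail); Pearson by
    flag. Returns (coefficient, two-sided p).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    d = diff.values if isinstance(diff, RegionSummary) else pd.Series(diff)
    common = [g for g in expr.values.index if g in d.index]
    x = expr.values.reindex(common).to_numpy(dtype=float)
    y = d.reindex(common).to_numpy(dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 genes with both values")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    else:
        rho, p = sps.pearsonr(x, y)
    return float(rho), float(p)
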