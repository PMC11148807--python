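"""Figure-level comparison statistics.

Small, exact statistics used when comparing differential-expression results
and per-group signal distributions across conditions: Jaccard similarity of
significant-gene sets, Pearson correlation of log fold changes between two
DE tables, min-max scaling of summary values, and boxplot five-number
summaries with the 1.5*IQR outlier rule.

All quantile computations use the linear-interpolation convention
(numpy default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "BoxplotSummary",
    "jaccard_index",
    "logfc_correlation",
    "minmax_scale",
    "boxplot_summary",
]


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary with Tukey-style whiskers.

    Whiskers extend to the most extreme data points within
    ``[q1 - 1.5*IQR, q3 + 1.5*IQR]``; values strictly beyond the fences are
    reported as outliers.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)
    n: int = 0

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard similarity |A∩B| / |A∪B| of two gene sets.

    Both sets empty is defined as 0 (with a warning) rather than NaN.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("jaccard_index of two empty sets; defined as 0.0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def logfc_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    mode: Literal["overlap_significant", "all_genes"] = "overlap_significant",
) -> tuple[float, int]:
    """Pearson correlation of logFC values between two DE result tables.

    Parameters
    ----------
    table_a, table_b
        DE tables indexed by gene (or with a ``gene`` column) carrying at
        least ``logFC`` and ``significant`` columns.
    mode
        ``overlap_significant`` correlates genes significant in *both*
        tables. ``all_genes`` takes the union of genes significant in
        either table and keeps pairwise-complete matches (genes present in
        both tables).

    Returns
    -------
    (r, n) : Pearson correlation and the number of gene pairs used.
    """
    a = _as_gene_indexed(table_a)
    b = _as_gene_indexed(table_b)
    sig_a = set(a.index[a["significant"].astype(bool)])
    sig_b = set(b.index[b["significant"].astype(bool)])
    if mode == "overlap_significant":
        genes = sig_a & sig_b
    elif mode == "all_genes":
        genes = (sig_a | sig_b) & set(a.index) & set(b.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    genes = sorted(genes)
    if len(genes) < 3:
        raise ValueError(
            f"logFC correlation undefined: only {len(genes)} matched genes (<3)"
        )
    x = a.loc[genes, "logFC"].to_numpy(float)
    y = b.loc[genes, "logFC"].to_numpy(float)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, len(genes)


def minmax_scale(values: Iterable[float]) -> np.ndarray:
    """Scale values linearly onto [0, 1]; a constant vector maps to zeros."""
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if v.size == 0:
        raise ValueError("minmax_scale requires at least one value")
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("minmax_scale of a constant vector; returning zeros",
                      stacklevel=2)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def boxplot_summary(values: Iterable[float]) -> BoxplotSummary:
    """Five-number summary with the 1.5*IQR outlier rule.

    Quartiles use linear interpolation; whiskers are the extreme
    observations that are not outliers.
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_summary requires at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inlier = (v >= lo_fence) & (v <= hi_fence)
    outliers = tuple(sorted(float(x) for x in v[~inlier]))
    kept = v[inlier]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(kept.min()),
        whisker_high=float(kept.max()),
        outliers=outliers,
        n=int(v.size),
    )


def _as_gene_indexed(table: pd.DataFrame) -> pd.DataFrame:
    if "gene" in table.columns:
        table = table.set_index("gene")
    if table.index.has_duplicates:
        table = table[~table.index.duplicated(keep="first")]
    missing = {"logFC", "significant"} - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return table
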