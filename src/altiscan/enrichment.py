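"""Functional-category enrichment of SNPs across FST bins.

SNPs are multi-labelled by annotation tracks (a SNP belongs to every category
whose intervals contain it; the structural classes coding/UTR/intron/
intergenic are mutually exclusive with precedence coding > UTR > intron >
intergenic), binned by FST, and each (category, bin) cell is summarized by an
enrichment ratio

    ratio = P_observed / P_expected,
    P_expected = |bin| * |category| / |analysis set|,

the minimal exchangeable null in which category membership is independent of
differentiation.  A ratio above 1 means the category is over-represented in
that differentiation bin.  The trend of ratio against bin order is summarized
by ordinary least squares with a two-sided t-test on the slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import AnnotationTrack

logger = logging.getLogger(__name__)

STRUCTURAL_PRECEDENCE = ("Coding", "UTR", "Intron")
DEFAULT_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


def annotate_categories(chrom, pos, tracks: list[AnnotationTrack],
                        structural: list[AnnotationTrack] | None = None) -> pd.DataFrame:
    """Boolean membership matrix of SNPs in annotation categories.

    ``pos`` is 1-based.  ``tracks`` are regulatory categories (multi-label).
    ``structural`` tracks, when given, are resolved with precedence
    Coding > UTR > Intron; SNPs matching none get ``Intergenic``.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos0 = np.asarray(pos, dtype=np.int64) - 1
    out = {}
    for tr in tracks:
        out[tr.name] = tr.contains(chrom, pos0)
    if structural is not None:
        by_name = {t.name: t for t in structural}
        assigned = np.zeros(pos0.size, dtype=bool)
        for name in STRUCTURAL_PRECEDENCE:
            if name in by_name:
                hit = by_name[name].contains(chrom, pos0) & ~assigned
                out[name] = hit
                assigned |= hit
        out["Intergenic"] = ~assigned
    return pd.DataFrame(out)


def bin_by_fst(fst, edges=DEFAULT_EDGES) -> np.ndarray:
    """Bin index per SNP over half-open bins [e_i, e_{i+1}), last bin closed
    at the top edge.  Edges must be strictly increasing and cover [0, 1]."""
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    fst = np.asarray(fst, dtype=float)
    if np.nanmin(fst) < edges[0] or np.nanmax(fst) > edges[-1]:
        raise ValueError("FST values fall outside the bin edges")
    idx = np.searchsorted(edges, fst, side="right") - 1
    idx = np.minimum(idx, edges.size - 2)  # close the last bin at the top
    return idx


def bin_labels(edges=DEFAULT_EDGES) -> list[str]:
    edges = np.asarray(edges, dtype=float)
    labs = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(edges.size - 2)]
    labs.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    return labs


@dataclass
class EnrichmentTable:
    """Observed/expected SNP counts and enrichment ratios per (bin, category),
    with per-category OLS trend summaries.

    ``cells`` columns: bin, bin_label, category, observed, expected, ratio
    (NaN where expected == 0, flagged).  ``trend`` columns: category, slope,
    intercept, p_value, n_bins.
    """

    edges: tuple
    cells: pd.DataFrame
    trend: pd.DataFrame
    scope: str = "all-genome"


def enrichment_ratios(bins: np.ndarray, categories: pd.DataFrame,
                      edges=DEFAULT_EDGES, scope_mask=None,
                      scope: str = "all-genome") -> EnrichmentTable:
    """Enrichment ratio per FST bin and category within an analysis scope.

    ``bins`` are bin indices (from `bin_by_fst`), ``categories`` a boolean
    membership frame over the same SNPs.  ``scope_mask`` restricts the
    analysis set S (e.g. SNPs inside called sweeps); observed and expected
    counts are both computed within S, so category marginals are conserved:
    sum over bins of observed == sum over bins of expected == |c ∩ S|.
    """
    bins = np.asarray(bins)
    if scope_mask is None:
        scope_mask = np.ones(bins.size, dtype=bool)
    scope_mask = np.asarray(scope_mask, dtype=bool)
    n_bins = len(edges) - 1
    S = int(scope_mask.sum())
    if S == 0:
        raise ValueError("empty analysis set")
    labs = bin_labels(edges)
    bin_sizes = np.bincount(bins[scope_mask], minlength=n_bins)
    rows = []
    trend_rows = []
    for cat in categories.columns:
        inc = categories[cat].to_numpy() & scope_mask
        cat_total = int(inc.sum())
        obs = np.bincount(bins[inc], minlength=n_bins).astype(float)
        exp = bin_sizes * (cat_total / S)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(exp > 0, obs / exp, np.nan)
        for b in range(n_bins):
            rows.append((b, labs[b], cat, obs[b], exp[b], ratio[b]))
        slope, intercept, p, k = ratio_trend_values(ratio)
        trend_rows.append((cat, slope, intercept, p, k))
    cells = pd.DataFrame(rows, columns=["bin", "bin_label", "category",
                                        "observed", "expected", "ratio"])
    trend = pd.DataFrame(trend_rows, columns=["category", "slope", "intercept",
                                              "p_value", "n_bins"])
    return EnrichmentTable(edges=tuple(edges), cells=cells, trend=trend,
                           scope=scope)


def ratio_trend_values(ratios) -> tuple[float, float, float, int]:
    """OLS of enrichment ratio against bin order (1..k over defined bins).

    Returns (slope, intercept, two-sided p-value of the slope from the t
    distribution with k-2 df, k).  Fewer than 3 defined bins gives NaNs;
    a zero-variance ratio vector gives slope 0 with p = 1.
    """
    ratios = np.asarray(ratios, dtype=float)
    ok = ~np.isnan(ratios)
    y = ratios[ok]
    k = int(ok.sum())
    if k < 3:
        return np.nan, np.nan, np.nan, k
    x = np.arange(1, ratios.size + 1, dtype=float)[ok]
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 1.0, k
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue), k


def ratio_trend(table: EnrichmentTable, category: str) -> tuple[float, float]:
    """(slope, p-value) of the enrichment-ratio trend for one category."""
    row = table.trend[table.trend["category"] == category]
    if row.empty:
        raise KeyError(f"category {category!r} not in table")
    return float(row["slope"].iloc[0]), float(row["p_value"].iloc[0])
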