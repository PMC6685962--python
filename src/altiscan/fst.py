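"""Windowed FST genome scan and consecutive-outlier sweep calling.

The scan follows the classic two-population design: a per-SNP fixation-index
estimate from derived-allele frequencies, arithmetic averaging of the per-SNP
values in fixed-width tiling windows (default 10 kb, the scale of linkage
disequilibrium decay in Chinese domestic pigs), an empirical genome-wide
top-quantile threshold (default top 1%), and a sweep-calling rule that
requires a run of at least ``min_run`` consecutive outlier windows, where
windows without data (assembly gaps, SNP deserts) may bridge a run without
counting toward it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: window status codes
STATUS_DATA = "data"
STATUS_EMPTY = "empty"
STATUS_GAP = "gap"


def snp_fst(p1, n1, p2, n2, clamp: bool = True):
    """Per-SNP Hudson-type FST estimator from allele frequencies.

    Parameters
    ----------
    p1, p2 : array-like
        Allele frequency of the same allele in population 1 / population 2.
    n1, n2 : array-like
        Number of sampled *alleles* (2x diploid individuals with data).
    clamp : bool
        Clamp the estimate into [0, 1]; negative point estimates have no
        biological interpretation and are set to 0.

    Returns
    -------
    ndarray
        FST per site; ``nan`` where the estimator is undefined (both
        populations monomorphic for the same allele, or n <= 1 allele).

    Notes
    -----
    Numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)``, denominator
    ``p1(1-p2) + p2(1-p1)`` (Hudson estimator in the Bhatia et al. ratio
    form); robust to unequal sample sizes and suited to per-SNP averaging
    within windows.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    bad = (den == 0) | (n1 <= 1) | (n2 <= 1)
    fst = np.where(bad, np.nan, fst)
    n_bad = int(np.sum(bad))
    if n_bad:
        logger.info("snp_fst: %d site(s) undefined (monomorphic pair or n<=1), skipped", n_bad)
    if clamp:
        fst = np.clip(fst, 0.0, 1.0)
    return fst


@dataclass
class WindowTrack:
    """Fixed-width tiling-window statistics for one or more chromosomes.

    Windows are 0-based half-open ``[start, start+w)`` and tile each
    chromosome without overlap.  ``mean`` is defined only for windows with
    ``status == "data"`` (>= 1 SNP).
    """

    df: pd.DataFrame  # columns: chrom, start, end, mean, n_snps, status
    width: int

    def data_means(self) -> np.ndarray:
        return self.df.loc[self.df["status"] == STATUS_DATA, "mean"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SweepInterval:
    """A called selective sweep: a run of consecutive outlier windows.

    ``start``/``end`` are 0-based half-open genomic coordinates of the span
    from the first to the last outlier window of the run.  ``start1``/``end1``
    give the 1-based inclusive coordinates used in reports
    (e.g. ``chr3:100,170,001-100,240,000``).
    """

    chrom: str
    start: int
    end: int
    n_windows: int          # outlier (member) windows only; bridged gaps excluded
    peak: float
    mean: float
    member_starts: list = field(default_factory=list)

    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start


def window_means(chrom, pos, values, w: int = 10_000, chrom_sizes=None,
                 gap_intervals=None) -> WindowTrack:
    """Average a per-SNP statistic in non-overlapping tiling windows.

    Parameters
    ----------
    chrom : array-like of str
        Chromosome of each SNP.
    pos : array-like of int
        1-based SNP positions (sorted within chromosome).
    values : array-like of float
        Per-SNP statistic; ``nan`` entries are ignored.
    w : int
        Window width in bp.
    chrom_sizes : dict, optional
        chrom -> length in bp; windows tile ``[0, size)``.  Without it the
        tiling extends to the last SNP.
    gap_intervals : dict, optional
        chrom -> (starts, ends) arrays of 0-based half-open assembly-gap
        intervals; windows overlapping a gap get status ``"gap"``.
    """
    if w < 1:
        raise ValueError("window width must be >= 1 bp")
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    rows = []
    chroms = list(dict.fromkeys(chrom.tolist()))  # preserve order
    if chrom_sizes:
        for c in chrom_sizes:
            if c not in chroms:
                chroms.append(c)
    for c in chroms:
        m = (chrom == c) & ok
        cpos0 = pos[m] - 1          # 0-based
        cval = values[m]
        if chrom_sizes and c in chrom_sizes:
            size = int(chrom_sizes[c])
        elif cpos0.size:
            size = int(cpos0.max()) + 1
        else:
            continue
        n_win = int(np.ceil(size / w)) if size > 0 else 0
        widx = cpos0 // w
        sums = np.bincount(widx, weights=cval, minlength=n_win)
        cnts = np.bincount(widx, minlength=n_win)
        gap_flag = np.zeros(n_win, dtype=bool)
        if gap_intervals and c in gap_intervals:
            gs, ge = (np.asarray(a, dtype=np.int64) for a in gap_intervals[c])
            for s, e in zip(gs, ge):
                lo = int(s) // w
                hi = int(np.ceil(e / w))
                gap_flag[max(lo, 0):min(hi, n_win)] = True
        for i in range(n_win):
            if gap_flag[i]:
                status = STATUS_GAP
            elif cnts[i] == 0:
                status = STATUS_EMPTY
            else:
                status = STATUS_DATA
            mean = sums[i] / cnts[i] if (status == STATUS_DATA) else np.nan
            # windows keep full width so sweep coordinates stay kb-aligned
            rows.append((c, i * w, (i + 1) * w, mean, int(cnts[i]), status))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean", "n_snps", "status"])
    return WindowTrack(df=df, width=w)


def top_quantile_threshold(track: WindowTrack, q: float = 0.99) -> float:
    """Genome-wide empirical q-quantile of window means (linear interpolation).

    Windows strictly above the returned threshold are outliers.  Warns when
    fewer than 100 data windows contribute (quantile poorly resolved).
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    vals = track.data_means()
    if vals.size == 0:
        raise ValueError("no data windows; cannot compute threshold")
    if vals.size < 100:
        warnings.warn(
            f"only {vals.size} data windows; top-quantile threshold is poorly "
            "resolved below ~100 windows", stacklevel=2)
    return float(np.quantile(vals, q, method="linear"))


def call_sweeps(track: WindowTrack, threshold: float, min_run: int = 3,
                bridge_gaps: bool = True, bridge_empty: bool = True) -> list[SweepInterval]:
    """Call sweeps as runs of >= ``min_run`` consecutive outlier windows.

    A window is an outlier when it has data and its mean is strictly above
    ``threshold``.  Windows of status ``gap`` (and ``empty`` when
    ``bridge_empty``) inside a run neither break nor count toward the run;
    a data window at or below the threshold breaks the run.  The reported
    interval spans the first through the last outlier window.
    """
    sweeps: list[SweepInterval] = []
    for c, sub in track.df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        run: list[tuple[int, int, float]] = []  # (start, end, mean) of outliers

        def flush(run=None, chrom=c):
            if run and len(run) >= min_run:
                vals = [r[2] for r in run]
                sweeps.append(SweepInterval(
                    chrom=chrom, start=run[0][0], end=run[-1][1],
                    n_windows=len(run), peak=float(max(vals)),
                    mean=float(np.mean(vals)),
                    member_starts=[r[0] for r in run]))

        for row in sub.itertuples(index=False):
            if row.status == STATUS_DATA:
                if row.mean > threshold:
                    run.append((row.start, row.end, row.mean))
                else:
                    flush(run)
                    run = []
            elif row.status == STATUS_GAP and bridge_gaps:
                continue
            elif row.status == STATUS_EMPTY and bridge_empty:
                continue
            else:
                flush(run)
                run = []
        flush(run)
    return sweeps


def genes_in_sweeps(sweeps: list[SweepInterval], genes: pd.DataFrame) -> dict:
    """Genes overlapping each sweep by >= 1 bp (half-open interval logic).

    ``genes`` needs columns chrom, start, end (0-based half-open), name.
    Returns {(chrom, start, end) of sweep: [gene names]} preserving gene order.
    """
    out = {}
    for sw in sweeps:
        sub = genes[genes["chrom"] == sw.chrom]
        hit = sub[(sub["start"] < sw.end) & (sub["end"] > sw.start)]
        out[(sw.chrom, sw.start, sw.end)] = hit["name"].tolist()
    return out


def sweeps_to_frame(sweeps: list[SweepInterval]) -> pd.DataFrame:
    """Tabulate called sweeps with both 0-based and 1-based coordinates."""
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, s.start1, s.end1, s.length, s.n_windows,
          s.peak, s.mean) for s in sweeps],
        columns=["chrom", "start", "end", "start1", "end1", "length_bp",
                 "n_outlier_windows", "peak", "mean"])
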