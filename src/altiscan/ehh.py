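"""Extended haplotype homozygosity (EHH), integrated EHH and XP-EHH.

EHH at a site x, relative to a core SNP, is the probability that two
haplotypes drawn at random are identical over the stretch from the core
through x.  Integrating the EHH decay curve over physical distance in each
direction gives iHH; the cross-population statistic is the log-ratio
``ln(iHH_target / iHH_control)`` per core SNP, standardized genome-wide.
Large positive normalized values mean unusually long haplotypes (recent
positive selection) in the target population.

The site-EHH variant used here pools both core alleles (the XP-EHH
convention), so EHH(core) = 1 by definition and the curve is monotone
non-increasing outward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fst import WindowTrack, call_sweeps, top_quantile_threshold, window_means

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotypes at ordered SNP positions.

    ``haps`` has shape (n_haplotypes, n_sites); ``positions`` are bp
    coordinates, strictly increasing; ``populations`` labels each haplotype.
    No missing alleles are allowed (input is phased and coverage-filtered).
    """

    positions: np.ndarray
    haps: np.ndarray
    populations: np.ndarray
    chrom: str = "1"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.haps.ndim != 2 or self.haps.shape[1] != self.positions.size:
            raise ValueError("haps must be (n_hap, n_sites) matching positions")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.haps, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1 (no missing data)")

    def subset_population(self, pop: str) -> "HaplotypeMatrix":
        m = self.populations == pop
        return HaplotypeMatrix(self.positions, self.haps[m],
                               self.populations[m], self.chrom)

    @property
    def n_hap(self) -> int:
        return self.haps.shape[0]


def ehh(haps: np.ndarray, core: int, direction: int) -> np.ndarray:
    """EHH values at each site outward from the core, core site included.

    Parameters
    ----------
    haps : (n, m) 0/1 array
    core : int
        Core site column index.
    direction : {+1, -1}
        Scan right (+1) or left (-1) of the core.

    Returns
    -------
    ndarray
        ``ehh[0] = 1`` at the core; ``ehh[k]`` is the EHH at the k-th site in
        the chosen direction.  Both core alleles are pooled: grouping starts
        from a single group and is refined by the alleles at each flanking
        site in turn, so the curve is monotone non-increasing.
    """
    haps = np.asarray(haps)
    n, m = haps.shape
    if n < 2:
        raise ValueError("need >= 2 haplotypes for EHH")
    if not 0 <= core < m:
        raise IndexError("core site out of range")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    sites = range(core + 1, m) if direction == 1 else range(core - 1, -1, -1)
    denom = n * (n - 1) / 2
    out = [1.0]
    ids = np.zeros(n, dtype=np.int64)
    for j in sites:
        ids = ids * 2 + haps[:, j]
        _, ids, counts = np.unique(ids, return_inverse=True, return_counts=True)
        out.append(float(np.sum(counts * (counts - 1) / 2) / denom))
    return np.asarray(out)


def _pair_shared_prefix_ehh(haps: np.ndarray, core: int, direction: int) -> np.ndarray:
    """O(n^2 m) all-pairs oracle for `ehh`; kept for cross-checking."""
    haps = np.asarray(haps)
    n, m = haps.shape
    sites = list(range(core + 1, m)) if direction == 1 else list(range(core - 1, -1, -1))
    denom = n * (n - 1) / 2
    out = [1.0]
    for k in range(len(sites)):
        span = sites[: k + 1]
        same = 0
        for a in range(n):
            for b in range(a + 1, n):
                if all(haps[a, j] == haps[b, j] for j in span):
                    same += 1
        out.append(same / denom)
    return np.asarray(out)


def ihh(haps: np.ndarray, positions: np.ndarray, core: int,
        ehh_cutoff: float = 0.05, max_gap: int = 200_000):
    """Integrated EHH around a core SNP (bp x EHH units).

    Trapezoidal integration of the EHH curve over physical distance, both
    directions from the core.  Integration stops at the first site where EHH
    drops below ``ehh_cutoff`` (that final segment is included).  Any
    inter-SNP gap larger than ``max_gap`` contributes no area and flags the
    score.  If the cutoff is never reached before the end of the data the
    score is flagged unbounded.

    Returns
    -------
    (ihh, flags) : (float, set)
        flags may contain ``"unbounded"`` and/or ``"max_gap"``.
    """
    if ehh_cutoff < 0:
        raise ValueError("ehh_cutoff must be >= 0")
    haps = np.asarray(haps)
    n = haps.shape[0]
    if n < 2:
        raise ValueError("need >= 2 haplotypes for EHH")
    positions = np.asarray(positions, dtype=np.int64)
    denom = n * (n - 1) / 2
    total = 0.0
    flags: set[str] = set()
    for direction in (1, -1):
        sites = (range(core + 1, haps.shape[1]) if direction == 1
                 else range(core - 1, -1, -1))
        ids = np.zeros(n, dtype=np.int64)
        prev_ehh = 1.0
        prev_pos = int(positions[core])
        truncated = False
        # stream the EHH curve site by site so integration can stop early
        for j in sites:
            ids = ids * 2 + haps[:, j]
            _, ids, counts = np.unique(ids, return_inverse=True,
                                       return_counts=True)
            cur = float(np.sum(counts * (counts - 1)) / 2 / denom)
            gap = abs(int(positions[j]) - prev_pos)
            if gap > max_gap:
                flags.add("max_gap")
            else:
                total += (cur + prev_ehh) / 2 * gap
            prev_ehh, prev_pos = cur, int(positions[j])
            if cur < ehh_cutoff:
                truncated = True
                break
        if not truncated:
            flags.add("unbounded")
    return total, flags


@dataclass
class XpehhTrack:
    """Per-core-SNP XP-EHH scores.

    ``df`` columns: chrom, pos, ihh_target, ihh_control, raw, norm, flagged.
    Normalized scores have genome-wide mean 0 and sd 1 over non-flagged SNPs.
    """

    df: pd.DataFrame
    n_skipped: int = 0


def xpehh_scores(haps_target: HaplotypeMatrix, haps_control: HaplotypeMatrix,
                 ehh_cutoff: float = 0.05, max_gap: int = 200_000,
                 normalize: bool = True) -> XpehhTrack:
    """Raw and normalized XP-EHH per core SNP across a shared site set.

    raw = ln(iHH_target / iHH_control); cores where either iHH is zero or
    flagged (unbounded / max_gap) are excluded from normalization and
    reported with ``flagged=True``.  Positive values indicate longer
    haplotypes in the target population.  With ``normalize=False`` (e.g. for
    degenerate inputs with zero score variance) the ``norm`` column is NaN.
    """
    if not np.array_equal(haps_target.positions, haps_control.positions):
        raise ValueError("target and control must share the same site set")
    pos = haps_target.positions
    m = pos.size
    iht = np.empty(m)
    ihc = np.empty(m)
    bad = np.zeros(m, dtype=bool)
    for j in range(m):
        a, fa = ihh(haps_target.haps, pos, j, ehh_cutoff, max_gap)
        b, fb = ihh(haps_control.haps, pos, j, ehh_cutoff, max_gap)
        iht[j] = a
        ihc[j] = b
        if fa or fb or a == 0 or b == 0:
            bad[j] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(bad, np.nan, np.log(np.where(bad, 1.0, iht) /
                                           np.where(bad, 1.0, ihc)))
    scored = ~bad
    if normalize:
        if int(scored.sum()) < 2:
            raise ValueError("fewer than 2 scored SNPs; cannot normalize XP-EHH")
        mu = float(np.mean(raw[scored]))
        sd = float(np.std(raw[scored]))
        if sd == 0:
            raise ValueError("zero variance in raw XP-EHH; cannot normalize")
        norm = (raw - mu) / sd
    else:
        norm = np.full(m, np.nan)
    if bad.any():
        logger.info("xpehh: %d core SNP(s) excluded (zero/unbounded iHH or gap)",
                    int(bad.sum()))
    df = pd.DataFrame({
        "chrom": haps_target.chrom, "pos": pos,
        "ihh_target": iht, "ihh_control": ihc,
        "raw": raw, "norm": norm, "flagged": bad,
    })
    return XpehhTrack(df=df, n_skipped=int(bad.sum()))


def xpehh_windows_and_sweeps(track: XpehhTrack, w: int = 10_000, q: float = 0.99,
                             min_run: int = 3, chrom_sizes=None,
                             gap_intervals=None):
    """Window-average normalized XP-EHH and call upper-tail sweeps.

    Reuses the FST window / threshold / consecutive-run machinery on the
    normalized scores (selecting for the target population only).
    """
    sub = track.df[~track.df["flagged"]]
    wt: WindowTrack = window_means(sub["chrom"], sub["pos"], sub["norm"], w=w,
                                   chrom_sizes=chrom_sizes,
                                   gap_intervals=gap_intervals)
    thr = top_quantile_threshold(wt, q)
    sweeps = call_sweeps(wt, thr, min_run=min_run)
    return wt, thr, sweeps
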