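"""Variant / sample-sheet / annotation I-O and the study's sample & site filters.

The container is a dense in-memory table of biallelic SNPs: a per-site frame
(chrom, pos, ref, alt, qual) plus aligned site x sample matrices of genotype
dosage (0/1/2, -1 missing), read depth and genotype quality.  All filters are
pure (return new tables), idempotent, never reorder sites or samples, and log
the number of items they drop.

Quality-field mapping: the historical SAMtools-era "consensus quality" is
taken as the per-genotype GQ and "SNP quality" as the site QUAL column, their
closest modern equivalents.  A genotype failing the quality rule is set to
missing rather than dropping the whole site, so that the site-level coverage
filters then act uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # genotype dosage / depth / GQ sentinel

POPULATIONS = ("target", "control", "outgroup", "other")


@dataclass
class SampleSheet:
    """Sample -> population assignment, optionally with a foreign-admixture
    fraction (from an external structure run's Q-matrix)."""

    df: pd.DataFrame  # columns: sample_id, population, admixture_fraction

    def __post_init__(self):
        if self.df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        bad = set(self.df["population"]) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown population label(s): {sorted(bad)}")
        if "admixture_fraction" not in self.df.columns:
            self.df = self.df.assign(admixture_fraction=np.nan)

    @classmethod
    def from_records(cls, records) -> "SampleSheet":
        return cls(pd.DataFrame(records,
                                columns=["sample_id", "population",
                                         "admixture_fraction"][:len(records[0])]))

    def samples_in(self, population: str) -> list[str]:
        return self.df.loc[self.df["population"] == population,
                           "sample_id"].tolist()

    def write_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))


def read_q_matrix(path, foreign_component: int) -> pd.Series:
    """Read a structure Q-matrix TSV (rows = samples, columns = components)
    and return the designated foreign-component fraction per sample."""
    q = pd.read_csv(path, sep="\t", index_col=0)
    if not 0 <= foreign_component < q.shape[1]:
        raise ValueError("foreign_component column out of range")
    return q.iloc[:, foreign_component]


@dataclass
class AnnotationTrack:
    """A named set of sorted, non-overlapping genomic intervals
    (0-based half-open), keyed by chromosome."""

    name: str
    intervals: dict  # chrom -> (starts, ends) int64 arrays

    def __post_init__(self):
        clean = {}
        for c, (s, e) in self.intervals.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
            if np.any(e <= s) or np.any(s[1:] < e[:-1]):
                raise ValueError(
                    f"track {self.name!r}/{c}: intervals must be non-empty "
                    "and non-overlapping")
            clean[c] = (s, e)
        self.intervals = clean

    def contains(self, chrom, pos0) -> np.ndarray:
        """Membership of 0-based positions, vectorized per chromosome."""
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.zeros(pos0.size, dtype=bool)
        for c, (s, e) in self.intervals.items():
            m = chrom == c
            if not m.any():
                continue
            idx = np.searchsorted(s, pos0[m], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(int(m.sum()), dtype=bool)
            hit[ok] = pos0[m][ok] < e[idx[ok]]
            out[m] = hit
        return out

    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in self.intervals.values()))

    def write_bed(self, path):
        with open(path, "w") as fh:
            for c in self.intervals:
                s, e = self.intervals[c]
                for a, b in zip(s, e):
                    fh.write(f"{c}\t{a}\t{b}\t{self.name}\n")

    @classmethod
    def read_bed(cls, path, name=None) -> "AnnotationTrack":
        ivs: dict = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                c, s, e = parts[0], int(parts[1]), int(parts[2])
                if name is None and len(parts) > 3:
                    name = parts[3]
                ivs.setdefault(c, ([], []))
                ivs[c][0].append(s)
                ivs[c][1].append(e)
        return cls(name=name or "track", intervals=ivs)


@dataclass
class VariantTable:
    """Biallelic SNP sites with per-sample genotype dosage, depth and GQ.

    ``sites``: frame with chrom, pos (1-based, strictly increasing within
    chrom), ref, alt, qual.  ``gt``/``dp``/``gq``: (n_sites, n_samples)
    arrays; -1 marks a missing call / absent field.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    samples: list
    sheet: SampleSheet | None = field(default=None, repr=False)

    def __post_init__(self):
        n, k = len(self.sites), len(self.samples)
        for name in ("gt", "dp", "gq"):
            arr = getattr(self, name)
            if arr.shape != (n, k):
                raise ValueError(f"{name} shape {arr.shape} != ({n}, {k})")
        for c, sub in self.sites.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if p.size > 1 and np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.asarray([lookup[s] for s in ids], dtype=int)

    def take_sites(self, mask_or_index) -> "VariantTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self,
                       sites=self.sites.iloc[idx].reset_index(drop=True),
                       gt=self.gt[idx], dp=self.dp[idx], gq=self.gq[idx])

    def take_samples(self, ids) -> "VariantTable":
        j = self.sample_index(ids)
        sheet = self.sheet
        if sheet is not None:
            sheet = SampleSheet(sheet.df[sheet.df["sample_id"].isin(ids)]
                                .reset_index(drop=True))
        return replace(self, gt=self.gt[:, j], dp=self.dp[:, j],
                       gq=self.gq[:, j], samples=list(ids), sheet=sheet)


# ---------------------------------------------------------------------------
# VCF I/O

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path) -> None:
    """Write VCF 4.2 with GT:DP:GQ per sample and QUAL per site."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, sub in table.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={c},length={int(sub['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        sites = table.sites
        for i in range(table.n_sites):
            row = sites.iloc[i]
            qual = "." if np.isnan(row["qual"]) else f"{row['qual']:.6g}"
            cells = []
            for j in range(table.n_samples):
                g = _GT_CODE[int(table.gt[i, j])]
                d = "." if table.dp[i, j] < 0 else str(int(table.dp[i, j]))
                q = "." if table.gq[i, j] < 0 else str(int(table.gq[i, j]))
                cells.append(f"{g}:{d}:{q}")
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t{qual}\t.\t.\tGT:DP:GQ\t"
                     + "\t".join(cells) + "\n")


def read_vcf(path, sheet: SampleSheet | None = None) -> VariantTable:
    """Read a VCF with GT (required) and DP/GQ (optional) into a VariantTable.

    Multi-allelic and non-SNP records are skipped with a logged count; absent
    DP/GQ fields are marked -1 (quality filters then treat them as failing).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    recs, gts, dps, gqs = [], [], [], []
    n_skip = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skip += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        if g.size != len(samples):
            raise ValueError("GT field missing or malformed")
        try:
            d = np.asarray(var.format("DP"), dtype=float).reshape(-1)
        except Exception:
            d = np.full(len(samples), np.nan)
        try:
            q = np.asarray(var.format("GQ"), dtype=float).reshape(-1)
        except Exception:
            q = np.full(len(samples), np.nan)
        d = np.where(np.isnan(d) | (d < 0), MISSING, d).astype(np.int32)
        q = np.where(np.isnan(q) | (q < 0), MISSING, q).astype(np.int16)
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0],
                     np.nan if var.QUAL is None else float(var.QUAL)))
        gts.append(g)
        dps.append(d)
        gqs.append(q)
    if n_skip:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP record(s)", n_skip)
    n = len(recs)
    sites = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "qual"])
    shape = (n, len(samples))
    table = VariantTable(
        sites=sites,
        gt=np.vstack(gts) if n else np.empty(shape, dtype=np.int8),
        dp=np.vstack(dps) if n else np.empty(shape, dtype=np.int32),
        gq=np.vstack(gqs) if n else np.empty(shape, dtype=np.int16),
        samples=samples, sheet=sheet)
    table.skipped_records = n_skip
    return table


# ---------------------------------------------------------------------------
# Filters.  Boundary semantics follow the stated rules exactly: ">=" is
# inclusive, "less than"/"above"/"greater than" are strict.


def filter_genotype_quality(table: VariantTable, hom_min: int = 20,
                            het_min: int = 10) -> VariantTable:
    """Set low-quality genotype calls to missing; sites are retained.

    Homozygous calls are kept iff GQ >= hom_min OR site QUAL >= hom_min;
    heterozygous calls are kept iff GQ >= het_min AND site QUAL >= het_min.
    Absent DP/GQ/QUAL fields count as failing.
    """
    qual = table.sites["qual"].to_numpy(dtype=float)[:, None]
    qual_ok_hom = np.nan_to_num(qual, nan=-1.0) >= hom_min
    qual_ok_het = np.nan_to_num(qual, nan=-1.0) >= het_min
    gq = table.gq
    hom = (table.gt == 0) | (table.gt == 2)
    het = table.gt == 1
    keep = np.where(hom, (gq >= hom_min) | qual_ok_hom,
                    np.where(het, (gq >= het_min) & qual_ok_het, False))
    gt = np.where(keep, table.gt, MISSING).astype(np.int8)
    n_dropped = int(np.sum((table.gt != MISSING) & (gt == MISSING)))
    logger.info("filter_genotype_quality: %d genotype(s) set missing", n_dropped)
    return replace(table, gt=gt)


def filter_site_coverage(table: VariantTable, pop_min: dict) -> VariantTable:
    """Keep sites whose non-missing call count per listed population meets
    that population's minimum (inclusive)."""
    if table.sheet is None:
        raise ValueError("a SampleSheet must be attached for coverage filtering")
    keep = np.ones(table.n_sites, dtype=bool)
    for pop, mn in pop_min.items():
        ids = table.sheet.samples_in(pop)
        if not ids:
            raise ValueError(f"population {pop!r} absent from sample sheet")
        j = table.sample_index(ids)
        called = np.sum(table.gt[:, j] != MISSING, axis=1)
        keep &= called >= mn
    logger.info("filter_site_coverage: dropped %d of %d sites",
                int((~keep).sum()), table.n_sites)
    return table.take_sites(keep)


def filter_fraction_coverage(table: VariantTable, min_fraction: float = 0.89) -> VariantTable:
    """Keep sites called in strictly more than ``min_fraction`` of all
    non-outgroup samples."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    if table.sheet is not None:
        ids = table.sheet.df.loc[table.sheet.df["population"] != "outgroup",
                                 "sample_id"].tolist()
        j = table.sample_index(ids)
    else:
        j = np.arange(table.n_samples)
    if j.size == 0:
        raise ValueError("no non-outgroup samples")
    frac = np.sum(table.gt[:, j] != MISSING, axis=1) / j.size
    keep = frac > min_fraction
    logger.info("filter_fraction_coverage: dropped %d of %d sites",
                int((~keep).sum()), table.n_sites)
    return table.take_sites(keep)


def thin_by_distance(table: VariantTable, min_bp: int = 100_000) -> VariantTable:
    """Greedy left-to-right thinning: keep a site iff its distance to the
    last kept site on the same chromosome is strictly greater than ``min_bp``.
    The first site of each chromosome is always kept."""
    keep = np.zeros(table.n_sites, dtype=bool)
    chrom = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    last: dict = {}
    for i in range(table.n_sites):
        c = chrom[i]
        if c not in last or pos[i] - last[c] > min_bp:
            keep[i] = True
            last[c] = pos[i]
    logger.info("thin_by_distance: dropped %d of %d sites",
                int((~keep).sum()), table.n_sites)
    return table.take_sites(keep)


def filter_sample_missingness(table: VariantTable, max_missing: float = 0.10) -> SampleSheet:
    """Drop samples whose missing-call fraction is >= ``max_missing``
    (i.e. keep samples with missingness strictly below it)."""
    if table.sheet is None:
        raise ValueError("a SampleSheet must be attached")
    if table.n_sites == 0:
        return SampleSheet(table.sheet.df.copy())
    miss = np.mean(table.gt == MISSING, axis=0)
    keep_ids = [s for s, f in zip(table.samples, miss) if f < max_missing]
    sub = table.sheet.df[table.sheet.df["sample_id"].isin(keep_ids)]
    logger.info("filter_sample_missingness: dropped %d of %d samples",
                table.n_samples - len(keep_ids), table.n_samples)
    return SampleSheet(sub.reset_index(drop=True))


def filter_by_admixture(sheet: SampleSheet, max_foreign: float = 0.05) -> SampleSheet:
    """Drop samples whose foreign admixture fraction is >= ``max_foreign``."""
    fr = sheet.df["admixture_fraction"]
    if fr.isna().all():
        raise ValueError(
            "no admixture fractions present; attach a Q-matrix column or "
            "skip this filter")
    keep = fr.fillna(0.0) < max_foreign
    logger.info("filter_by_admixture: dropped %d of %d samples",
                int((~keep).sum()), len(sheet.df))
    return SampleSheet(sheet.df[keep].reset_index(drop=True))
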