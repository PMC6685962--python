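"""Locus-level haplotype analysis of candidate sweeps.

Given phased haplotypes and a set of highly differentiated SNPs inside a
candidate region (default FST >= 0.4), haplotypes are recoded to
ancestral(0)/derived(1) strings, grouped into distinct patterns with
per-population counts and frequencies, and connected into an approximate
haplotype network: a minimum spanning tree under Hamming distance over the
patterns observed more than once.  The MST is a deterministic, testable
stand-in for a median-joining network and coincides with its backbone when
no median vectors are required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def select_differentiated_snps(fst_df: pd.DataFrame, region, fst_min: float = 0.4,
                               top_k: int | None = None) -> pd.DataFrame:
    """SNPs in ``region`` with FST >= ``fst_min``, sorted by position.

    ``fst_df`` needs columns chrom, pos (1-based), fst.  ``region`` is
    (chrom, start1, end1), 1-based inclusive.  ``top_k`` optionally caps the
    selection at the k largest FST values (ties kept by position order).
    """
    chrom, start1, end1 = region
    sub = fst_df[(fst_df["chrom"] == chrom) & (fst_df["pos"] >= start1)
                 & (fst_df["pos"] <= end1) & (fst_df["fst"] >= fst_min)]
    sub = sub.sort_values("pos").reset_index(drop=True)
    if top_k is not None and len(sub) > top_k:
        keep = sub["fst"].to_numpy().argsort(kind="stable")[::-1][:top_k]
        sub = sub.iloc[np.sort(keep)].reset_index(drop=True)
    if len(sub) == 0:
        logger.warning("select_differentiated_snps: no SNP in %s:%d-%d with "
                       "FST >= %g", chrom, start1, end1, fst_min)
    logger.info("select_differentiated_snps: %d SNP(s) selected", len(sub))
    return sub


@dataclass
class HaplotypePattern:
    """Distinct ancestral(0)/derived(1) haplotype strings over the selected
    SNPs, with per-population counts and frequencies.

    ``patterns``: (k, m) 0/1 array, one row per distinct haplotype, labelled
    ``labels[i]`` (H1, H2, ... by descending total count, then first
    occurrence).  ``counts``: DataFrame indexed by label with one column per
    population plus ``total``.  ``members``: label -> indices of the input
    haplotypes carrying that pattern.
    """

    positions: np.ndarray
    patterns: np.ndarray
    labels: list
    counts: pd.DataFrame
    members: dict

    def frequencies(self) -> pd.DataFrame:
        pops = [c for c in self.counts.columns if c != "total"]
        return self.counts[pops] / self.counts[pops].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.patterns,
                          columns=[str(p) for p in self.positions])
        df.insert(0, "haplotype", self.labels)
        return pd.concat([df.set_index("haplotype"), self.counts], axis=1)


def haplotype_pattern(haps: np.ndarray, populations, ancestral_is_one,
                      positions=None) -> HaplotypePattern:
    """Group phased haplotypes into distinct derived-coded patterns.

    Parameters
    ----------
    haps : (n_hap, m) 0/1 array
        Phased alleles at the selected SNPs (REF=0/ALT=1 coding).
    populations : array-like of str, length n_hap
    ancestral_is_one : bool array, length m
        True where the ancestral allele is the ALT (1) allele; those columns
        are flipped so the output is 0=ancestral, 1=derived.
    """
    haps = np.asarray(haps, dtype=np.uint8)
    flip = np.asarray(ancestral_is_one, dtype=bool)
    coded = np.where(flip[None, :], 1 - haps, haps).astype(np.uint8)
    populations = np.asarray(populations, dtype=object)
    pats, inverse = np.unique(coded, axis=0, return_inverse=True)
    k = pats.shape[0]
    pops = list(dict.fromkeys(populations.tolist()))
    counts = np.zeros((k, len(pops)), dtype=int)
    first_seen = np.full(k, coded.shape[0], dtype=int)
    for i, g in enumerate(inverse):
        counts[g, pops.index(populations[i])] += 1
        first_seen[g] = min(first_seen[g], i)
    total = counts.sum(axis=1)
    order = np.lexsort((first_seen, -total))
    pats = pats[order]
    counts = counts[order]
    total = total[order]
    labels = [f"H{i + 1}" for i in range(k)]
    rank = {old: new for new, old in enumerate(order)}
    members = {labels[rank[g]]: [] for g in range(k)}
    for i, g in enumerate(inverse):
        members[labels[rank[g]]].append(i)
    cdf = pd.DataFrame(counts, columns=pops, index=labels)
    cdf["total"] = total
    if positions is None:
        positions = np.arange(coded.shape[1])
    positions = np.asarray(positions)
    return HaplotypePattern(positions=positions, patterns=pats, labels=labels,
                            counts=cdf, members=members)


def hamming(a, b) -> int:
    return int(np.sum(np.asarray(a) != np.asarray(b)))


def haplotype_network(pattern: HaplotypePattern, min_freq_count: int = 2):
    """Approximate haplotype network: Hamming-distance MST over patterns with
    total count >= ``min_freq_count`` (i.e. frequency more than 1 by default).

    Edges are chosen by Kruskal with deterministic tie-breaking:
    smaller Hamming distance first, then higher combined count of the two
    endpoints, then lexicographic label pair.  Returns (nodes, edges) where
    edges are (label_a, label_b, distance).  Fewer than 2 nodes gives an
    empty edge set.
    """
    keep = pattern.counts["total"] >= min_freq_count
    nodes = [lab for lab in pattern.labels if keep[lab]]
    idx = {lab: i for i, lab in enumerate(pattern.labels)}
    if len(nodes) < 2:
        return nodes, []
    cand = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            d = hamming(pattern.patterns[idx[a]], pattern.patterns[idx[b]])
            combined = int(pattern.counts.loc[a, "total"]
                           + pattern.counts.loc[b, "total"])
            cand.append((d, -combined, a, b))
    cand.sort()
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for d, _negc, a, b in cand:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, d))
            if len(edges) == len(nodes) - 1:
                break
    return nodes, edges


def network_to_frame(nodes, edges) -> pd.DataFrame:
    return pd.DataFrame(edges, columns=["from", "to", "hamming"])


def linked_variants_report(pattern: HaplotypePattern, extra: np.ndarray,
                           extra_positions, ancestral_is_one) -> pd.DataFrame:
    """Derived-allele state at extra SNPs for each distinct haplotype.

    ``extra`` is (n_hap, e) phased REF/ALT alleles at the extra SNPs on the
    same haplotypes that built ``pattern``.  For each haplotype the report
    gives the fraction of its member chromosomes carrying the derived allele
    at each extra SNP, and flags haplotypes whose members all carry the
    derived allele at every extra SNP.
    """
    extra = np.asarray(extra, dtype=np.uint8)
    flip = np.asarray(ancestral_is_one, dtype=bool)
    coded = np.where(flip[None, :], 1 - extra, extra)
    rows = {}
    for lab in pattern.labels:
        m = pattern.members[lab]
        frac = coded[m].mean(axis=0)
        rows[lab] = list(frac) + [bool(np.all(coded[m] == 1))]
    cols = [f"derived_frac@{p}" for p in extra_positions] + ["all_derived"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
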