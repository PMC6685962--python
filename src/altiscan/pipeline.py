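"""End-to-end orchestration: simulate/load -> filter -> polarize -> FST scan
-> XP-EHH scan -> sweep calling -> haplotype analysis -> enrichment.

One RunConfig (a YAML mapping) and one seed govern a run; every stage writes
its intermediate artifact into the output directory and logs its parameters
into a machine-readable ``summary.json``.  Runs are deterministic: the same
config and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import fst as fstmod
from . import haplotypes as hapmod
from .ehh import HaplotypeMatrix, xpehh_scores, xpehh_windows_and_sweeps
from .polarize import polarize
from .sim import (SimConfig, genotypes_from_haplotypes, make_annotation_tracks,
                  make_gene_intervals, simulate_two_pop, write_truth)
from .variants import (filter_genotype_quality, filter_site_coverage,
                       write_vcf)

logger = logging.getLogger(__name__)

STRUCTURAL = ("Coding", "UTR", "Intron")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Scan parameters plus either a simulation block or input paths."""

    out_dir: str = "run"
    seed: int = 0
    simulation: dict | None = None      # SimConfig keyword arguments
    vcf: str | None = None
    sample_sheet: str | None = None
    phased_vcf: str | None = None
    window: int = 10_000
    quantile: float = 0.99
    min_run: int = 3
    fst_min: float = 0.4                # haplotype-analysis SNP selection
    edges: tuple = enr.DEFAULT_EDGES
    ehh_cutoff: float = 0.05
    max_gap: int = 200_000
    min_called_target: int | None = None   # default: n_target - 2 (study: 24/26)
    min_called_control: int | None = None  # default: n_control - 4 (study: 25/29)
    err: float = 0.005

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self):
        if self.simulation is None and self.vcf is None:
            raise ValueError("config needs a simulation block or input paths")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if self.window < 1 or self.min_run < 1:
            raise ValueError("window and min_run must be >= 1")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def _write_windows_bedgraph(track, path):
    sub = track.df[track.df["status"] == "data"]
    with open(path, "w") as fh:
        for r in sub.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mean:.6g}\n")


def _write_sweeps(sweeps, bed_path, tsv_path):
    with open(bed_path, "w") as fh:
        for s in sweeps:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\n")
    fstmod.sweeps_to_frame(sweeps).to_csv(tsv_path, sep="\t", index=False,
                                          float_format="%.6g")


def compare_sweep_sets(sweeps_a, sweeps_b, genes: pd.DataFrame) -> dict:
    """Overlap report between two sweep interval sets.

    Returns bp overlap, Jaccard index over covered bp, and the
    intersection/union of the gene lists hit by each set.
    """
    def covered(sweeps):
        out = {}
        for s in sweeps:
            out.setdefault(s.chrom, []).append((s.start, s.end))
        return out

    def total_and_overlap(ca, cb):
        tot_a = sum(e - s for ivs in ca.values() for s, e in ivs)
        tot_b = sum(e - s for ivs in cb.values() for s, e in ivs)
        ov = 0
        for c, ivs in ca.items():
            for s1, e1 in ivs:
                for s2, e2 in cb.get(c, []):
                    ov += max(0, min(e1, e2) - max(s1, s2))
        return tot_a, tot_b, ov

    ca, cb = covered(sweeps_a), covered(sweeps_b)
    tot_a, tot_b, ov = total_and_overlap(ca, cb)
    union_bp = tot_a + tot_b - ov
    genes_a = sorted({g for gl in fstmod.genes_in_sweeps(sweeps_a, genes).values()
                      for g in gl})
    genes_b = sorted({g for gl in fstmod.genes_in_sweeps(sweeps_b, genes).values()
                      for g in gl})
    inter = sorted(set(genes_a) & set(genes_b))
    union = sorted(set(genes_a) | set(genes_b))
    return {
        "bp_a": tot_a, "bp_b": tot_b, "bp_overlap": ov,
        "jaccard": (ov / union_bp) if union_bp else 1.0,
        "genes_a": genes_a, "genes_b": genes_b,
        "genes_shared": inter, "genes_union": union,
        "n_genes_shared": len(inter), "n_genes_union": len(union),
    }


def run_full_scan(config: RunConfig) -> dict:
    """Execute every stage and return the machine-readable summary dict.

    All artifacts (VCF, DAF table, per-SNP FST, window bedgraphs, sweep BEDs,
    haplotype pattern/network, enrichment tables, summary.json) are written
    under ``config.out_dir``.  Any stage failure raises PipelineError naming
    the stage; artifacts written so far are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()}}

    # ---- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        simcfg = SimConfig(**sim_kwargs)

        @_stage("simulate")
        def _simulate():
            haps, truth = simulate_two_pop(simcfg)
            table = genotypes_from_haplotypes(
                haps, simcfg.mean_depth, simcfg.err, seed=simcfg.seed + 1,
                truth=truth)
            tracks = make_annotation_tracks(simcfg, seed=simcfg.seed + 2)
            genes = make_gene_intervals(simcfg, seed=simcfg.seed + 3)
            write_vcf(table, out / "variants.vcf")
            table.sheet.write_tsv(out / "samples.tsv")
            write_truth(truth, out / "truth.tsv")
            for tr in tracks:
                tr.write_bed(out / f"track_{tr.name}.bed")
            genes.to_csv(out / "genes.bed", sep="\t", index=False, header=False)
            return haps, truth, table, tracks, genes

        haps, truth, table, tracks, genes = _simulate()
        summary["simulation"] = {
            "n_sites": int(table.n_sites),
            "sel_pos": truth.sel_pos,
            "final_freq": {k: float(v) for k, v in truth.final_freq.items()},
        }
    else:
        @_stage("load")
        def _load():
            from .variants import SampleSheet, read_vcf
            sheet = SampleSheet.read_tsv(config.sample_sheet)
            table = read_vcf(config.vcf, sheet=sheet)
            haps = (read_phased_vcf(config.phased_vcf, sheet)
                    if config.phased_vcf else None)
            return haps, None, table, [], None

        haps, truth, table, tracks, genes = _load()
        if genes is None:
            genes = pd.DataFrame(columns=["chrom", "start", "end", "name"])

    # ---- filters ----------------------------------------------------------
    @_stage("filter")
    def _filter():
        t1 = filter_genotype_quality(table)
        n_t = len(t1.sheet.samples_in("target"))
        n_c = len(t1.sheet.samples_in("control"))
        mins = {"target": (config.min_called_target
                           if config.min_called_target is not None
                           else max(n_t - 2, 1)),
                "control": (config.min_called_control
                            if config.min_called_control is not None
                            else max(n_c - 4, 1))}
        t2 = filter_site_coverage(t1, mins)
        return t1, t2, mins

    table_q, table_cov, cov_mins = _filter()
    summary["filters"] = {
        "input_sites": int(table.n_sites),
        "sites_after_genotype_quality": int(table_q.n_sites),
        "coverage_minima": cov_mins,
        "sites_after_coverage": int(table_cov.n_sites),
    }

    # ---- polarize + FST scan ---------------------------------------------
    @_stage("polarize")
    def _polarize():
        og = table_q.sheet.samples_in("outgroup")
        pol = polarize(table_q, og, err=config.err)
        pol.write_tsv(out / "daf.tsv")
        return pol

    pol = _polarize()
    okm = pol.ok_mask()
    summary["polarization"] = {
        "n_ok": int(okm.sum()),
        "n_excluded": int((~okm).sum()),
        "freq_mode": pol.freq_mode,
    }

    @_stage("fst_scan")
    def _fst_scan():
        df = pol.df[okm].reset_index(drop=True)
        f = fstmod.snp_fst(df["daf_target"], df["n_eff_target"],
                           df["daf_control"], df["n_eff_control"])
        snp = pd.DataFrame({"chrom": df["chrom"], "pos": df["pos"], "fst": f})
        snp = snp[~np.isnan(snp["fst"])].reset_index(drop=True)
        snp.to_csv(out / "fst_snp.tsv", sep="\t", index=False,
                   float_format="%.6g")
        sizes = None
        if config.simulation is not None:
            sizes = {"1": simcfg.seq_len}
        wt = fstmod.window_means(snp["chrom"], snp["pos"], snp["fst"],
                                 w=config.window, chrom_sizes=sizes)
        thr = fstmod.top_quantile_threshold(wt, config.quantile)
        sweeps = fstmod.call_sweeps(wt, thr, min_run=config.min_run)
        _write_windows_bedgraph(wt, out / "fst_windows.bedgraph")
        _write_sweeps(sweeps, out / "fst_sweeps.bed", out / "fst_sweeps.tsv")
        return snp, wt, thr, sweeps

    snp_fst_df, fst_wt, fst_thr, fst_sweeps = _fst_scan()
    summary["fst"] = {
        "n_snps": int(len(snp_fst_df)),
        "threshold_top_quantile": float(fst_thr),
        "n_sweeps": len(fst_sweeps),
        "sweep_bp": int(sum(s.length for s in fst_sweeps)),
    }

    # ---- XP-EHH scan ------------------------------------------------------
    xp_track = None
    xp_sweeps = []
    if haps is not None:
        @_stage("xpehh_scan")
        def _xpehh():
            keep_pos = table_cov.sites["pos"].to_numpy()
            m = np.isin(haps["target"].positions, keep_pos)
            ht = HaplotypeMatrix(haps["target"].positions[m],
                                 haps["target"].haps[:, m],
                                 haps["target"].populations)
            hc = HaplotypeMatrix(haps["control"].positions[m],
                                 haps["control"].haps[:, m],
                                 haps["control"].populations)
            track = xpehh_scores(ht, hc, ehh_cutoff=config.ehh_cutoff,
                                 max_gap=config.max_gap)
            track.df.to_csv(out / "xpehh_snp.tsv", sep="\t", index=False,
                            float_format="%.6g")
            sizes = {"1": simcfg.seq_len} if config.simulation is not None else None
            wt, thr, sweeps = xpehh_windows_and_sweeps(
                track, w=config.window, q=config.quantile,
                min_run=config.min_run, chrom_sizes=sizes)
            _write_windows_bedgraph(wt, out / "xpehh_windows.bedgraph")
            _write_sweeps(sweeps, out / "xpehh_sweeps.bed",
                          out / "xpehh_sweeps.tsv")
            return track, wt, thr, sweeps

        xp_track, xp_wt, xp_thr, xp_sweeps = _xpehh()
        summary["xpehh"] = {
            "n_scored": int((~xp_track.df["flagged"]).sum()),
            "n_skipped": int(xp_track.n_skipped),
            "threshold_top_quantile": float(xp_thr),
            "n_sweeps": len(xp_sweeps),
            "sweep_bp": int(sum(s.length for s in xp_sweeps)),
        }

    # ---- gene overlap between the two approaches --------------------------
    @_stage("compare")
    def _compare():
        return compare_sweep_sets(fst_sweeps, xp_sweeps, genes)

    overlap = _compare()
    summary["sweep_overlap"] = overlap
    if truth is not None and truth.sel_pos is not None:
        hit = any(s.start < truth.sel_pos <= s.end for s in fst_sweeps)
        summary["fst"]["true_locus_in_sweep"] = bool(hit)
        hitx = any(s.start < truth.sel_pos <= s.end for s in xp_sweeps)
        if xp_track is not None:
            summary["xpehh"]["true_locus_in_sweep"] = bool(hitx)

    # ---- haplotype analysis of the top region -----------------------------
    @_stage("haplotypes")
    def _haplotypes():
        if haps is None or len(snp_fst_df) == 0:
            return None
        if fst_sweeps:
            top = max(fst_sweeps, key=lambda s: s.peak)
            region = (top.chrom, top.start1, top.end1)
        else:
            wd = fst_wt.df[fst_wt.df["status"] == "data"]
            best = wd.loc[wd["mean"].idxmax()]
            region = (best["chrom"], int(best["start"]) - 2 * config.window + 1,
                      int(best["end"]) + 2 * config.window)
        sel = hapmod.select_differentiated_snps(snp_fst_df, region,
                                                fst_min=config.fst_min)
        if len(sel) == 0:
            return None
        pos = sel["pos"].to_numpy()
        pol_ok = pol.df[okm].set_index("pos")
        anc_is_alt = (pol_ok.loc[pos, "ancestral"] == "alt").to_numpy()
        idx = np.isin(haps["target"].positions, pos)
        mat = np.concatenate([haps["target"].haps[:, idx],
                              haps["control"].haps[:, idx]], axis=0)
        pops = np.concatenate([haps["target"].populations,
                               haps["control"].populations])
        pat = hapmod.haplotype_pattern(mat, pops, anc_is_alt, positions=pos)
        pat.to_frame().to_csv(out / "haplotype_pattern.tsv", sep="\t")
        nodes, edges = hapmod.haplotype_network(pat)
        hapmod.network_to_frame(nodes, edges).to_csv(
            out / "haplotype_network.tsv", sep="\t", index=False)
        return {"region": list(region), "n_snps": int(len(sel)),
                "n_haplotypes": len(pat.labels), "n_network_nodes": len(nodes),
                "n_network_edges": len(edges)}

    hap_summary = _haplotypes()
    if hap_summary is not None:
        summary["haplotypes"] = hap_summary

    # ---- enrichment -------------------------------------------------------
    @_stage("enrichment")
    def _enrichment():
        if len(snp_fst_df) == 0 or not tracks:
            return None
        reg = [t for t in tracks if t.name not in STRUCTURAL]
        struct = [t for t in tracks if t.name in STRUCTURAL]
        cats = enr.annotate_categories(snp_fst_df["chrom"], snp_fst_df["pos"],
                                       reg, structural=struct or None)
        bins = enr.bin_by_fst(snp_fst_df["fst"], config.edges)
        tables = {}
        tab = enr.enrichment_ratios(bins, cats, edges=config.edges,
                                    scope="all-genome")
        tables["all-genome"] = tab
        tab.cells.to_csv(out / "enrichment_genome.tsv", sep="\t", index=False,
                         float_format="%.6g")
        tab.trend.to_csv(out / "enrichment_genome_trend.tsv", sep="\t",
                         index=False, float_format="%.6g")
        if fst_sweeps:
            pos0 = snp_fst_df["pos"].to_numpy() - 1
            in_sweep = np.zeros(len(snp_fst_df), dtype=bool)
            for s in fst_sweeps:
                in_sweep |= ((snp_fst_df["chrom"].to_numpy() == s.chrom)
                             & (pos0 >= s.start) & (pos0 < s.end))
            if in_sweep.any():
                tab2 = enr.enrichment_ratios(bins, cats, edges=config.edges,
                                             scope_mask=in_sweep,
                                             scope="sweep-only")
                tables["sweep-only"] = tab2
                tab2.cells.to_csv(out / "enrichment_sweeps.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        return tables

    etabs = _enrichment()
    if etabs:
        summary["enrichment"] = {
            scope: {r["category"]: {"slope": None if pd.isna(r["slope"])
                                    else round(float(r["slope"]), 6),
                                    "p_value": None if pd.isna(r["p_value"])
                                    else round(float(r["p_value"]), 6)}
                    for _i, r in t.trend.iterrows()}
            for scope, t in etabs.items()}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def read_phased_vcf(path, sheet) -> dict:
    """Load phased haplotypes (pipe-separated GT) into per-population
    HaplotypeMatrix objects keyed by population label."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pos = []
    cols = []
    chrom = "1"
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        chrom = var.CHROM
        g = np.asarray(var.genotypes)  # (n, 3): a, b, phased
        if np.any(g[:, :2] < 0):
            raise ValueError(f"missing allele in phased VCF at {var.POS}")
        pos.append(var.POS)
        cols.append(g[:, :2].reshape(-1))
    mat = np.asarray(cols, dtype=np.uint8).T  # (2n, m)
    pop_of = dict(zip(sheet.df["sample_id"], sheet.df["population"]))
    pops = np.repeat([pop_of[s] for s in samples], 2)
    out = {}
    for p in dict.fromkeys(pops.tolist()):
        m = pops == p
        out[p] = HaplotypeMatrix(np.asarray(pos), mat[m],
                                 np.asarray(pops[m]), chrom)
    return out
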