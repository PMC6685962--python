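"""Shared fixtures: replicate simulation scans reused across test modules.

The replicate fixtures are session-scoped because each replicate runs a full
forward simulation plus the genotype-noise / polarization / scan chain; the
summaries they return are consumed by several power and calibration tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import altiscan as al

SWEEP_SEEDS = list(range(1, 21))       # recorded replicate seeds
NEUTRAL_SEEDS = list(range(101, 111))
XPEHH_SEEDS = SWEEP_SEEDS[:8]          # haplotype scans on a subset

SCAN = dict(w=10_000, q=0.99, min_run=3)


def scan_replicate(seed: int, sweep: bool, with_xpehh: bool = False) -> dict:
    """Simulate one replicate of the study design (1 Mb, Ne=500, 500-gen
    split, hard sweep s=0.1 at 500 kb when ``sweep``) and run the standard
    chain: genotype noise -> quality filter -> polarization -> per-SNP FST ->
    10-kb windows -> top-1% threshold -> consecutive-window sweep calls."""
    cfg = al.SimConfig(seed=seed, sel_pos=500_000 if sweep else None,
                       s=0.1 if sweep else 0.0)
    haps, truth = al.simulate_two_pop(cfg)
    table = al.genotypes_from_haplotypes(haps, cfg.mean_depth, cfg.err,
                                         seed=seed + 100_000, truth=truth)
    tq = al.filter_genotype_quality(table)
    pol = al.polarize(tq, tq.sheet.samples_in("outgroup"))
    ok = pol.ok_mask()
    df = pol.df[ok]
    f = al.snp_fst(df["daf_target"], df["n_eff_target"],
                   df["daf_control"], df["n_eff_control"])
    snp = pd.DataFrame({"chrom": df["chrom"], "pos": df["pos"],
                        "fst": f}).dropna().reset_index(drop=True)
    wt = al.window_means(snp["chrom"], snp["pos"], snp["fst"], w=SCAN["w"],
                         chrom_sizes={"1": cfg.seq_len})
    thr = al.top_quantile_threshold(wt, SCAN["q"])
    sweeps = al.call_sweeps(wt, thr, min_run=SCAN["min_run"])
    dm = wt.df[wt.df["status"] == "data"].reset_index(drop=True)
    res = {
        "seed": seed,
        "seq_len": cfg.seq_len,
        "n_snp": len(snp),
        "threshold": thr,
        "n_sweeps": len(sweeps),
        "sweeps": [(s.chrom, s.start, s.end) for s in sweeps],
        "n_windows": len(dm),
        "window_median": float(dm["mean"].median()),
    }
    if sweep:
        core = dm[(dm["start"] < truth.sel_pos) & (dm["end"] >= truth.sel_pos)]
        core_mean = float(core["mean"].iloc[0]) if len(core) else np.nan
        res.update({
            "sel_pos": truth.sel_pos,
            "core_mean": core_mean,
            "core_rank": int((dm["mean"] > core_mean).sum()) + 1,
            "hit": any(s.start < truth.sel_pos <= s.end for s in sweeps),
            "final_freq_target": truth.final_freq.get("target", np.nan),
        })
    if with_xpehh and sweep:
        tcov = al.filter_site_coverage(tq, {"target": 24, "control": 25})
        keep = np.isin(haps["target"].positions,
                       tcov.sites["pos"].to_numpy())
        ht = al.HaplotypeMatrix(haps["target"].positions[keep],
                                haps["target"].haps[:, keep],
                                haps["target"].populations)
        hc = al.HaplotypeMatrix(haps["control"].positions[keep],
                                haps["control"].haps[:, keep],
                                haps["control"].populations)
        track = al.xpehh_scores(ht, hc)
        xwt, xthr, xsweeps = al.xpehh_windows_and_sweeps(
            track, chrom_sizes={"1": cfg.seq_len}, **{k: v for k, v in
            zip(("w", "q", "min_run"), (SCAN["w"], SCAN["q"], SCAN["min_run"]))})
        xdm = xwt.df[xwt.df["status"] == "data"].reset_index(drop=True)
        xcore = xdm[(xdm["start"] < truth.sel_pos)
                    & (xdm["end"] >= truth.sel_pos)]
        xc = float(xcore["mean"].iloc[0]) if len(xcore) else np.nan
        res.update({
            "x_core": xc,
            "x_rank": int((xdm["mean"] > xc).sum()) + 1,
            "x_n_windows": len(xdm),
            "x_hit": any(s.start < truth.sel_pos <= s.end for s in xsweeps),
            "x_n_sweeps": len(xsweeps),
        })
    return res


@pytest.fixture(scope="session")
def sweep_replicates() -> list[dict]:
    """Twenty hard-sweep replicates of the study-scale scenario."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [scan_replicate(s, sweep=True, with_xpehh=s in XPEHH_SEEDS)
                for s in SWEEP_SEEDS]


@pytest.fixture(scope="session")
def neutral_replicates() -> list[dict]:
    """Ten neutral replicates (no selected site) of the same scenario."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [scan_replicate(s, sweep=False) for s in NEUTRAL_SEEDS]


def grid_search_freq(gt, dp, err=0.005, step=1e-4):
    """Independent frequency oracle: dense grid maximization of the genotype
    -likelihood objective (evaluated for every grid point at once)."""
    from altiscan.polarize import _genotype_loglik

    ll, valid = _genotype_loglik(np.asarray(gt, float)[None, :],
                                 np.asarray(dp, float)[None, :], err)
    mx = ll.max(axis=2, keepdims=True)
    lik = np.exp(ll - mx)[0]                      # (samples, 3)
    qs = np.arange(0.0, 1.0 + step / 2, step)
    prior = np.stack([(1 - qs) ** 2, 2 * qs * (1 - qs), qs ** 2], axis=1)
    mix = lik @ prior.T                           # (samples, n_grid)
    tot = np.where(valid[0][:, None],
                   np.log(np.maximum(mix, 1e-300)) + mx[0], 0.0).sum(axis=0)
    return float(qs[tot.argmax()])


@pytest.fixture()
def toy_table():
    """Small deterministic VariantTable builder for filter tests."""
    def build(gt, dp=None, gq=None, qual=None, populations=None, pos=None):
        gt = np.asarray(gt, dtype=np.int8)
        n, k = gt.shape
        dp = (np.full((n, k), 10, dtype=np.int32) if dp is None
              else np.asarray(dp, dtype=np.int32))
        gq = (np.full((n, k), 99, dtype=np.int16) if gq is None
              else np.asarray(gq, dtype=np.int16))
        qual = (np.full(n, 50.0) if qual is None
                else np.asarray(qual, dtype=float))
        populations = populations or ["target"] * k
        pos = np.arange(1, n + 1) if pos is None else np.asarray(pos)
        sheet = al.SampleSheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(k)],
            "population": populations,
            "admixture_fraction": np.nan}))
        sites = pd.DataFrame({"chrom": "1", "pos": pos,
                              "ref": "A", "alt": "C", "qual": qual})
        return al.VariantTable(sites=sites, gt=gt, dp=dp, gq=gq,
                               samples=list(sheet.df["sample_id"]),
                               sheet=sheet)
    return build
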