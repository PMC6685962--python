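"""Synthetic two-population sweep data: forward Wright-Fisher simulation,
read-sampling genotype noise, and annotation tracks.

The demographic design mirrors a two-population resequencing study with an
outgroup: an ancestral diploid population at equilibrium splits into a target
and a control population ``split_gens`` generations before sampling, while a
small outgroup lineage diverged much earlier (``outgroup_split_mult x
split_gens``, far enough that it is nearly always homozygous for the
ancestral allele at sites segregating in the ingroup).  An optional hard
sweep introduces a single new beneficial mutation in the target population at
the split and re-seeds it until it survives.

Model choices
-------------
* Discrete generations, multinomial (fitness-weighted) resampling of diploid
  parents, Poisson recombination and infinite-sites Poisson mutation - a
  forward model so that selection is exact and both allele-frequency
  differentiation and extended haplotypes emerge mechanistically.
* The ancestral population is initialized from the neutral stationary site
  frequency spectrum (site counts with probability proportional to 1/i,
  placed in linkage equilibrium) and then burnt in for ``burn_in_gens``
  (default 2 x Ne) generations to establish linkage disequilibrium.
* The outgroup branch is evolved as a per-site Wright-Fisher allele-frequency
  process (neutral drift + mutation influx) for the total divergence time
  separating it from the ingroup split state; its haplotype structure is
  never consumed downstream (only the two sampled genotypes are, for
  polarization), so tracking frequencies is sufficient and exact at the
  genotype level.

Coordinates are 0-based half-open internally (sites live on a continuous
[0, seq_len) axis); the emitted VCF is 1-based.  Identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .ehh import HaplotypeMatrix
from .variants import MISSING, AnnotationTrack, SampleSheet, VariantTable

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the two-population sweep simulation.

    Sample sizes default to the 26 target / 29 control / 2 outgroup design;
    ``Ne`` is the diploid effective size of every simulated population.
    ``s`` acts in the target population only (genotype fitnesses 1, 1+hs,
    1+s).  ``bin_categories`` is a list of (name, genome fraction, enrichment
    multiplier near the selected site or None).
    """

    n_target: int = 26
    n_control: int = 29
    n_outgroup: int = 2
    Ne: int = 500
    split_gens: int = 500
    outgroup_split_mult: float = 5.0
    mu: float = 1e-7
    rho: float = 2e-7
    seq_len: int = 1_000_000
    sel_pos: float | None = None
    s: float = 0.0
    h: float = 0.5
    sel_gen: int | None = None  # generations after the split when the
    # beneficial mutation arises; default: late enough that the sweep is just
    # completing at sampling time (the regime the scan statistics target)
    mean_depth: float = 10.0
    err: float = 0.005
    seed: int = 0
    burn_in_gens: int | None = None
    max_sweep_attempts: int = 200
    ref_derived_frac: float = 0.1
    bin_categories: list = field(default_factory=lambda: [
        ("Coding", 0.015, None), ("UTR", 0.01, None), ("Intron", 0.25, None),
        ("Motif", 0.005, None), ("DHS", 0.02, None), ("Conserved", 0.05, None),
    ])

    def __post_init__(self):
        for name in ("n_target", "n_control", "n_outgroup", "Ne"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.s <= 1:
            raise ValueError("s must lie in [0, 1]")
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.mu < 0 or self.rho < 0 or self.err < 0:
            raise ValueError("mu, rho and err must be >= 0")
        for name, frac, _m in self.bin_categories:
            if not 0 < frac <= 1:
                raise ValueError(f"category {name!r}: fraction must be in (0,1]")
        if self.sel_pos is not None and not 0 <= self.sel_pos < self.seq_len:
            raise ValueError("sel_pos must lie in [0, seq_len)")
        if max(self.n_target, self.n_control) > self.Ne:
            raise ValueError("cannot sample more individuals than Ne")
        if self.burn_in_gens is None:
            self.burn_in_gens = 2 * self.Ne
        if self.sel_gen is None and self.s > 0:
            # conditional sweep duration ~ 2 ln(2 Ne s) / (h s) generations;
            # inject with a 1.65x safety factor so nearly all surviving
            # sweeps complete just before sampling (the regime where both
            # differentiation and haplotype-length signals are maximal)
            dur = 3.3 * np.log(max(2 * self.Ne * self.s, np.e)) / max(
                self.h * self.s, 1e-9)
            self.sel_gen = max(0, self.split_gens - int(round(dur)))
        if self.sel_gen is not None and not 0 <= self.sel_gen <= self.split_gens:
            raise ValueError("sel_gen must lie in [0, split_gens]")


class SweepLostError(RuntimeError):
    """The beneficial mutation was lost in every allowed re-seeding attempt."""


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    sel_pos: int | None                 # 1-based output coordinate (or None)
    sel_index: int | None               # column in the output site table
    final_freq: dict                    # population -> derived freq (full pop)
    carriers_target: np.ndarray | None  # per sampled target haplotype
    carriers_control: np.ndarray | None
    trajectory: list                    # (generation, target derived freq)
    ancestral: np.ndarray               # 'ref'/'alt' per output site
    positions: np.ndarray               # 1-based output positions


class _Pop:
    """A diploid population: site-major 0/1 matrix (n_sites, 2Ne) over float
    positions (kept unsorted during evolution, sorted on demand), plus
    positions fixed for the derived allele."""

    __slots__ = ("positions", "haps", "fixed")

    def __init__(self, positions, haps, fixed=None):
        self.positions = positions
        self.haps = haps
        self.fixed = list(fixed) if fixed else []

    def copy(self) -> "_Pop":
        return _Pop(self.positions.copy(), self.haps.copy(), list(self.fixed))

    def sort(self) -> None:
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.haps = self.haps[order]

    def freq(self, pos: float) -> float:
        i = np.flatnonzero(self.positions == pos)
        if i.size:
            return float(self.haps[i[0]].mean())
        return 1.0 if pos in self.fixed else 0.0


def _init_stationary(cfg: SimConfig, rng) -> _Pop:
    """Ancestral population drawn from the neutral stationary SFS in linkage
    equilibrium (LD is then built by the burn-in)."""
    H = 2 * cfg.Ne
    theta_tot = 4 * cfg.Ne * cfg.mu * cfg.seq_len
    harmonic = np.sum(1.0 / np.arange(1, H))
    s0 = rng.poisson(theta_tot * harmonic)
    if s0 == 0:
        return _Pop(np.empty(0), np.zeros((0, H), dtype=np.uint8))
    i = np.arange(1, H)
    counts = rng.choice(i, size=s0, p=(1.0 / i) / harmonic)
    positions = np.sort(rng.uniform(0, cfg.seq_len, s0))
    ranks = np.argsort(rng.random((s0, H)), axis=1)
    haps = (ranks < counts[:, None]).astype(np.uint8)
    return _Pop(positions, haps)


def _evolve(pop: _Pop, gens: int, cfg: SimConfig, rng, sel_pos=None,
            trajectory=None, prune_every: int = 5,
            abort_on_loss: bool = False) -> bool:
    """Advance a population ``gens`` generations in place.

    Selection acts when ``sel_pos`` is given and cfg.s > 0: diploid parents
    are sampled with probability proportional to fitness at the selected
    site.  ``trajectory`` (a list) collects (generation, derived frequency)
    of the selected site each generation.  With ``abort_on_loss`` the run
    stops as soon as the selected allele is lost; the return value reports
    whether it is still present (or was never tracked).
    """
    N, H, L = cfg.Ne, 2 * cfg.Ne, cfg.seq_len
    mu_rate = H * cfg.mu * L
    cx_rate = cfg.rho * L
    S = pop.positions.size
    # ping-pong growth buffers; capacity amortizes per-generation appends
    cap = S + max(int(mu_rate * prune_every * 3), 64)
    A = np.zeros((cap, H), dtype=np.uint8)
    B = np.zeros((cap, H), dtype=np.uint8)
    positions = np.zeros(cap)
    A[:S] = pop.haps
    positions[:S] = pop.positions
    sel_col = -1
    if sel_pos is not None and cfg.s > 0:
        hit = np.flatnonzero(positions[:S] == sel_pos)
        sel_col = int(hit[0]) if hit.size else -1
    sel_alive = True
    gen_done = 0
    for gen in range(gens):
        # --- parent sampling (fitness-weighted while the sweep segregates)
        if sel_col >= 0:
            colv = A[sel_col]
            dosage = colv[0::2].astype(np.int64) + colv[1::2]
            w = 1.0 + cfg.s * (dosage == 2) + cfg.h * cfg.s * (dosage == 1)
            cdf = np.cumsum(w)
            parents = np.searchsorted(cdf, rng.random(H) * cdf[-1])
        else:
            parents = rng.integers(0, N, size=H)
        which = rng.integers(0, 2, size=H)
        rows = 2 * parents + which
        np.take(A[:S], rows, axis=1, out=B[:S])
        # --- recombination; single-crossover gametes (the common case) are
        # handled in one vectorized pass, multi-crossover gametes in a loop
        ncx = rng.poisson(cx_rate, size=H)
        rec = np.flatnonzero(ncx)
        one = rec[ncx[rec] == 1]
        if one.size:
            bp = rng.uniform(0, L, one.size)
            a_cols = 2 * parents[one] + which[one]
            b_cols = 2 * parents[one] + 1 - which[one]
            take_b = positions[:S, None] > bp[None, :]
            B[:S, one] = np.where(take_b, A[:S][:, b_cols], A[:S][:, a_cols])
        for i in rec[ncx[rec] >= 2]:
            bps = np.sort(rng.uniform(0, L, ncx[i]))
            a = A[:S, 2 * parents[i] + which[i]]
            b = A[:S, 2 * parents[i] + 1 - which[i]]
            take_b = (np.searchsorted(bps, positions[:S]) % 2).astype(bool)
            B[:S, i] = np.where(take_b, b, a)
        # --- mutation (new biallelic sites, infinite-sites on a float axis)
        nmut = int(rng.poisson(mu_rate))
        if S + nmut > cap:
            cap = int((S + nmut) * 1.5)
            A = np.resize(A, (cap, H))
            newB = np.zeros((cap, H), dtype=np.uint8)
            newB[:S] = B[:S]
            B = newB
            positions = np.resize(positions, cap)
        if nmut:
            positions[S:S + nmut] = rng.uniform(0, L, nmut)
            B[S:S + nmut] = 0
            B[S + np.arange(nmut), rng.integers(0, H, nmut)] = 1
            S += nmut
        A, B = B, A
        # --- record + prune
        if sel_col >= 0 or (sel_pos is not None and trajectory is not None):
            f = float(A[sel_col].mean()) if sel_col >= 0 else \
                (1.0 if sel_pos in pop.fixed else 0.0)
            if trajectory is not None:
                base = trajectory[-1][0] if trajectory else 0
                trajectory.append((base + 1, f))
            if sel_col >= 0 and f == 0.0:
                sel_alive = False
                if abort_on_loss:
                    break
        if gen % prune_every == prune_every - 1 or gen == gens - 1:
            counts = A[:S].sum(axis=1, dtype=np.int64)
            fixed = counts == H
            keep = counts > 0
            if fixed.any():
                pop.fixed.extend(positions[:S][fixed].tolist())
                keep &= ~fixed
            if not keep.all():
                idx = np.flatnonzero(keep)
                np.take(A[:S], idx, axis=0, out=B[:idx.size])
                A, B = B, A
                positions[:idx.size] = positions[:S][keep]
                S = idx.size
            if sel_pos is not None and cfg.s > 0:
                hit = np.flatnonzero(positions[:S] == sel_pos)
                sel_col = int(hit[0]) if hit.size else -1
                if sel_col < 0 and sel_pos not in pop.fixed:
                    sel_alive = False
                    if abort_on_loss:
                        break
    pop.positions = positions[:S].copy()
    pop.haps = A[:S].copy()
    if sel_pos is None or cfg.s == 0:
        return True
    return sel_pos in pop.fixed or pop.freq(sel_pos) > 0


def _drift_outgroup(freqs: np.ndarray, gens: int, cfg: SimConfig, rng):
    """Per-site WF frequency drift with mutation influx for the outgroup
    branch.  Returns (final shared-site freqs, private positions, private
    freqs incl. fixed at 1.0)."""
    H = 2 * cfg.Ne
    p = freqs.copy()
    priv_pos = np.empty(0)
    priv_p = np.empty(0)
    fixed_pos: list = []
    mu_rate = H * cfg.mu * cfg.seq_len
    for _ in range(gens):
        p = rng.binomial(H, p) / H
        if priv_p.size:
            priv_p = rng.binomial(H, priv_p) / H
            gone = priv_p == 0
            done = priv_p == 1
            if done.any():
                fixed_pos.extend(priv_pos[done].tolist())
            if gone.any() or done.any():
                keep = ~(gone | done)
                priv_pos, priv_p = priv_pos[keep], priv_p[keep]
        nmut = rng.poisson(mu_rate)
        if nmut:
            priv_pos = np.concatenate([priv_pos, rng.uniform(0, cfg.seq_len, nmut)])
            priv_p = np.concatenate([priv_p, np.full(nmut, 1.0 / H)])
    if fixed_pos:
        priv_pos = np.concatenate([priv_pos, np.asarray(fixed_pos)])
        priv_p = np.concatenate([priv_p, np.ones(len(fixed_pos))])
    return p, priv_pos, priv_p


def _sample_columns(pop: _Pop, union_pos: np.ndarray, hap_rows: np.ndarray) -> np.ndarray:
    """Alleles of selected haplotype rows at the (sorted) union site set
    (derived coding: 1 = mutant).  Requires ``pop`` sorted."""
    out = np.zeros((hap_rows.size, union_pos.size), dtype=np.uint8)
    idx = np.searchsorted(pop.positions, union_pos)
    inside = idx < pop.positions.size
    hit = np.zeros(union_pos.size, dtype=bool)
    hit[inside] = pop.positions[idx[inside]] == union_pos[inside]
    out[:, hit] = pop.haps[np.ix_(idx[hit], hap_rows)].T
    if pop.fixed:
        fixed_hit = np.isin(union_pos, np.asarray(pop.fixed))
        out[:, fixed_hit] = 1
    return out


def simulate_two_pop(cfg: SimConfig):
    """Run the forward simulation and sample phased haplotypes.

    Returns
    -------
    (haps, truth) where ``haps`` maps population name -> HaplotypeMatrix of
    the sampled individuals (REF/ALT coded after reference-allele
    assignment) and ``truth`` is the SimTruth record.  Sites are those
    segregating among all sampled haplotypes (outgroup included).
    Raises SweepLostError if the beneficial mutation cannot be established
    within ``cfg.max_sweep_attempts`` re-seedings.
    """
    rng = np.random.default_rng(cfg.seed)
    anc = _init_stationary(cfg, rng)
    _evolve(anc, cfg.burn_in_gens, cfg, rng)
    anc.fixed = []  # substitutions before any split are invisible
    anc.sort()

    # outgroup: frequency drift over its total divergence from the split state
    t_og = int(round((2 * cfg.outgroup_split_mult - 1) * cfg.split_gens))
    og_shared_p, og_priv_pos, og_priv_p = _drift_outgroup(
        anc.haps.mean(axis=1), t_og, cfg, rng)

    control = anc.copy()
    _evolve(control, cfg.split_gens, cfg, rng)

    sel_pos_f = None
    trajectory: list = []
    if cfg.sel_pos is not None and cfg.s > 0 and cfg.split_gens > 0:
        sel_pos_f = float(cfg.sel_pos)
        pre_gens = int(cfg.sel_gen or 0)
        pre = anc.copy()
        if pre_gens:
            _evolve(pre, pre_gens, cfg, rng)  # neutral segment before arising
        for attempt in range(cfg.max_sweep_attempts):
            target = pre.copy()
            newrow = np.zeros((1, 2 * cfg.Ne), dtype=np.uint8)
            newrow[0, rng.integers(0, 2 * cfg.Ne)] = 1
            target.positions = np.append(target.positions, sel_pos_f)
            target.haps = np.vstack([target.haps, newrow])
            trajectory = [(pre_gens, 1.0 / (2 * cfg.Ne))]
            if _evolve(target, cfg.split_gens - pre_gens, cfg, rng,
                       sel_pos=sel_pos_f, trajectory=trajectory,
                       abort_on_loss=True):
                break
        else:
            raise SweepLostError(
                f"beneficial mutation lost in all {cfg.max_sweep_attempts} "
                "attempts; increase s, Ne or max_sweep_attempts")
        logger.info("sweep established after %d attempt(s); final target "
                    "frequency %.3f", attempt + 1, target.freq(sel_pos_f))
    else:
        target = anc.copy()
        _evolve(target, cfg.split_gens, cfg, rng)
        if cfg.sel_pos is not None and cfg.s > 0:
            sel_pos_f = float(cfg.sel_pos)  # split_gens == 0: nothing to sweep
    target.sort()
    control.sort()

    # ---- sample individuals
    def _pick(n):
        inds = np.sort(rng.choice(cfg.Ne, size=n, replace=False))
        return np.repeat(2 * inds, 2) + np.tile([0, 1], n)

    rows_t = _pick(cfg.n_target)
    rows_c = _pick(cfg.n_control)

    # ---- union of candidate sites (ingroup segregating/fixed + outgroup)
    union = np.unique(np.concatenate([
        target.positions, np.asarray(target.fixed, dtype=float),
        control.positions, np.asarray(control.fixed, dtype=float)]))
    ht = _sample_columns(target, union, rows_t)
    hc = _sample_columns(control, union, rows_c)

    # outgroup genotypes: shared sites aligned with the ancestral positions
    og_p_union = np.zeros(union.size)
    idx = np.searchsorted(anc.positions, union)
    inside = idx < anc.positions.size
    hit = np.zeros(union.size, dtype=bool)
    hit[inside] = anc.positions[idx[inside]] == union[inside]
    og_p_union[hit] = og_shared_p[idx[hit]]
    H_og = 2 * cfg.n_outgroup
    hog = (rng.random((H_og, union.size)) < og_p_union[None, :]).astype(np.uint8)

    # outgroup-private sites carried by a sampled outgroup haplotype
    if og_priv_pos.size:
        draw = (rng.random((H_og, og_priv_pos.size))
                < og_priv_p[None, :]).astype(np.uint8)
        keep = draw.any(axis=0)
        if keep.any():
            priv = og_priv_pos[keep]
            order = np.argsort(np.concatenate([union, priv]), kind="stable")
            full = np.concatenate([union, priv])[order]
            ht = np.concatenate([ht, np.zeros((ht.shape[0], keep.sum()),
                                              dtype=np.uint8)], axis=1)[:, order]
            hc = np.concatenate([hc, np.zeros((hc.shape[0], keep.sum()),
                                              dtype=np.uint8)], axis=1)[:, order]
            hog = np.concatenate([hog, draw[:, keep]], axis=1)[:, order]
            union = full

    # keep sites segregating among all sampled haplotypes
    allh = np.concatenate([ht, hc, hog], axis=0)
    tot = allh.sum(axis=0)
    seg = (tot > 0) & (tot < allh.shape[0])
    union, ht, hc, hog = union[seg], ht[:, seg], hc[:, seg], hog[:, seg]

    # ---- integer 1-based positions, strictly increasing
    pos1 = np.floor(union).astype(np.int64) + 1
    for i in range(1, pos1.size):
        if pos1[i] <= pos1[i - 1]:
            pos1[i] = pos1[i - 1] + 1

    # ---- reference-allele assignment: REF is ancestral except for a small
    # flipped fraction, so polarization must genuinely consult the outgroup
    ref_is_derived = rng.random(union.size) < cfg.ref_derived_frac
    ancestral = np.where(ref_is_derived, "alt", "ref").astype(object)
    flip = ref_is_derived  # flip derived-coded alleles into REF/ALT coding
    ht = np.where(flip[None, :], 1 - ht, ht).astype(np.uint8)
    hc = np.where(flip[None, :], 1 - hc, hc).astype(np.uint8)
    hog = np.where(flip[None, :], 1 - hog, hog).astype(np.uint8)

    sel_index = sel_out_pos = None
    carriers_t = carriers_c = None
    final_freq = {}
    if sel_pos_f is not None:
        j = np.searchsorted(union, sel_pos_f)
        if j < union.size and union[j] == sel_pos_f:
            sel_index = int(j)
            sel_out_pos = int(pos1[j])
            derived_t = np.where(flip[j], 1 - ht[:, j], ht[:, j])
            derived_c = np.where(flip[j], 1 - hc[:, j], hc[:, j])
            carriers_t = derived_t.astype(bool)
            carriers_c = derived_c.astype(bool)
        else:
            sel_out_pos = int(np.floor(sel_pos_f)) + 1  # fixed in sample
        final_freq = {"target": target.freq(sel_pos_f),
                      "control": control.freq(sel_pos_f)}

    truth = SimTruth(sel_pos=sel_out_pos, sel_index=sel_index,
                     final_freq=final_freq, carriers_target=carriers_t,
                     carriers_control=carriers_c, trajectory=trajectory,
                     ancestral=ancestral, positions=pos1)
    haps = {
        "target": HaplotypeMatrix(pos1, ht, np.repeat("target", ht.shape[0])),
        "control": HaplotypeMatrix(pos1, hc, np.repeat("control", hc.shape[0])),
        "outgroup": HaplotypeMatrix(pos1, hog, np.repeat("outgroup", hog.shape[0])),
    }
    return haps, truth


# ---------------------------------------------------------------------------


def genotypes_from_haplotypes(haps: dict, mean_depth: float, err: float,
                              seed: int, chrom: str = "1",
                              sheet: SampleSheet | None = None,
                              truth: SimTruth | None = None) -> VariantTable:
    """Noisy genotype calls from phased haplotypes under a read-sampling model.

    Per site and individual: depth d ~ Poisson(mean_depth); alt-read count
    k ~ Binomial(d, p_g) with p_g = err, 1/2, 1-err for dosage 0, 1, 2; the
    call is the maximum-likelihood genotype, GQ the phred-scaled likelihood
    gap between the best and second-best genotype (capped at 99), and the
    site QUAL the phred-scaled evidence against an all-homozygous-reference
    site.  Zero depth gives a missing call.
    """
    if mean_depth < 0 or err < 0:
        raise ValueError("mean_depth and err must be >= 0")
    rng = np.random.default_rng(seed)
    pops = list(haps)
    mats = [haps[p].haps for p in pops]
    if any(m.shape[0] % 2 for m in mats):
        raise ValueError("each population needs an even haplotype count")
    positions = haps[pops[0]].positions
    allh = np.concatenate(mats, axis=0)
    n_ind = allh.shape[0] // 2
    S = allh.shape[1]
    dosage = allh[0::2].astype(np.int16) + allh[1::2]          # (n_ind, S)
    dosage = dosage.T                                          # (S, n_ind)
    d = rng.poisson(mean_depth, size=(S, n_ind))
    e = float(np.clip(err, 1e-12, 0.5))
    p_read = np.array([e, 0.5, 1.0 - e])
    k = rng.binomial(d, p_read[dosage])
    ll = binom.logpmf(k[..., None], d[..., None], p_read[None, None, :])
    order = np.argsort(ll, axis=2)
    call = order[..., 2].astype(np.int8)
    best = np.take_along_axis(ll, order[..., 2:3], axis=2)[..., 0]
    second = np.take_along_axis(ll, order[..., 1:2], axis=2)[..., 0]
    gq = np.minimum(np.rint((best - second) * (10 / np.log(10))), 99).astype(np.int16)
    qual = np.minimum((best - ll[..., 0]).sum(axis=1) * (10 / np.log(10)), 9999.0)
    miss = d == 0
    call[miss] = MISSING
    gq[miss] = MISSING
    samples = []
    populations = []
    for p in pops:
        n = haps[p].haps.shape[0] // 2
        prefix = {"target": "TP", "control": "CP", "outgroup": "OG"}.get(p, p[:2].upper())
        samples += [f"{prefix}{i + 1:02d}" for i in range(n)]
        populations += [p] * n
    if sheet is None:
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": samples, "population": populations,
            "admixture_fraction": np.nan}))
    # base assignment: ancestral base random, derived differs; REF/ALT follow
    # the ref/alt orientation recorded in the truth (REF base listed first)
    n_sites = positions.size
    base_idx = rng.integers(0, 4, size=n_sites)
    shift = rng.integers(1, 4, size=n_sites)
    anc_base = _BASES[base_idx]
    der_base = _BASES[(base_idx + shift) % 4]
    if truth is not None:
        ref = np.where(truth.ancestral == "ref", anc_base, der_base)
        alt = np.where(truth.ancestral == "ref", der_base, anc_base)
    else:
        ref, alt = anc_base, der_base
    sites = pd.DataFrame({"chrom": chrom, "pos": positions.astype(np.int64),
                          "ref": ref, "alt": alt,
                          "qual": np.round(qual, 2)})
    return VariantTable(sites=sites, gt=call, dp=d.astype(np.int32), gq=gq,
                        samples=samples, sheet=sheet)


def make_annotation_tracks(cfg: SimConfig, seed: int, quantum: int = 1000,
                           near_bp: int = 50_000):
    """Non-overlapping annotation tracks covering the configured genome
    fractions.

    The genome is cut into ``quantum``-bp tiles and each category draws its
    share of tiles at random; a category with an enrichment multiplier m
    draws tiles within ``near_bp`` of the selected site with weight m, so its
    interval density there is about m-fold its density elsewhere (a positive
    control for the enrichment analysis).
    """
    fracs = [f for _n, f, _m in cfg.bin_categories]
    if sum(fracs) > 1:
        raise ValueError("category genome fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_tiles = max(cfg.seq_len // quantum, 1)
    starts = np.arange(n_tiles) * quantum
    free = np.ones(n_tiles, dtype=bool)
    near = np.zeros(n_tiles, dtype=bool)
    if cfg.sel_pos is not None:
        near = np.abs(starts + quantum / 2 - cfg.sel_pos) <= near_bp
    tracks = []
    for name, frac, mult in cfg.bin_categories:
        n_cat = min(int(round(frac * n_tiles)), int(free.sum()))
        w = np.ones(n_tiles)
        if mult is not None and near.any():
            w[near] = mult
        w[~free] = 0.0
        chosen = rng.choice(n_tiles, size=n_cat, replace=False, p=w / w.sum())
        free[chosen] = False
        chosen.sort()
        # merge adjacent tiles into maximal intervals
        s_list, e_list = [], []
        for t in chosen:
            if s_list and starts[t] == e_list[-1]:
                e_list[-1] = starts[t] + quantum
            else:
                s_list.append(int(starts[t]))
                e_list.append(int(starts[t] + quantum))
        tracks.append(AnnotationTrack(name=name,
                                      intervals={"1": (np.asarray(s_list),
                                                       np.asarray(e_list))}))
    return tracks


def make_gene_intervals(cfg: SimConfig, seed: int, n_genes: int = 25,
                        gene_len: int = 20_000) -> pd.DataFrame:
    """A simple synthetic gene model: non-overlapping genes of fixed length
    at random positions (0-based half-open), for sweep-gene intersection."""
    rng = np.random.default_rng(seed)
    slots = cfg.seq_len // gene_len
    n = min(n_genes, slots)
    chosen = np.sort(rng.choice(slots, size=n, replace=False))
    return pd.DataFrame({
        "chrom": "1",
        "start": chosen * gene_len,
        "end": chosen * gene_len + gene_len,
        "name": [f"gene{i + 1:03d}" for i in range(n)],
    })


def write_truth(truth: SimTruth, path) -> None:
    """Plain-text truth table (per-site ancestral allele + sweep summary)."""
    with open(path, "w") as fh:
        fh.write(f"#sel_pos\t{truth.sel_pos}\n")
        for pop, f in truth.final_freq.items():
            fh.write(f"#final_freq_{pop}\t{f:.6g}\n")
        for gen, f in truth.trajectory:
            fh.write(f"#traj\t{gen}\t{f:.6g}\n")
        fh.write("pos\tancestral\n")
        for p, a in zip(truth.positions, truth.ancestral):
            fh.write(f"{p}\t{a}\n")
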