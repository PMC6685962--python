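"""Ancestral-allele polarization from an outgroup and corrected allele
frequencies.

Polarization rule: a site gets status ``ok`` only when every non-missing
outgroup genotype is homozygous for the same allele and at least
``min_outgroup_called`` outgroup individuals are called; that allele is the
ancestral one and the other the derived.  Heterozygous, discordant or
under-called outgroups give a non-ok status and such sites are excluded from
derived-allele statistics.

Allele frequencies can be estimated two ways (the mode is recorded in the
output): plain allele counting, or a maximum-likelihood estimate that
corrects for sample size and per-sample sequencing depth by running EM over
genotype likelihoods under a binomial read model.  Both converge to the same
value at high, even depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_MISSING = "outgroup-missing"
STATUS_HET = "outgroup-het"
STATUS_DISCORDANT = "outgroup-discordant"


@dataclass
class PolarizedSiteTable:
    """Per-site ancestral/derived assignment and per-population derived-allele
    frequencies.

    ``df`` columns: chrom, pos, ancestral ('ref'/'alt'/''), derived, status,
    plus per population ``daf_<pop>`` and ``n_eff_<pop>`` (effective allele
    count = 2 x samples with data).  DAF columns are defined (non-NaN) only
    where status == ok and the population had called samples.
    """

    df: pd.DataFrame
    freq_mode: str = "em"

    def ok_mask(self) -> np.ndarray:
        return (self.df["status"] == STATUS_OK).to_numpy()

    def write_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def polarize_status(table: VariantTable, outgroup_samples,
                    min_outgroup_called: int = 2):
    """Per-site polarization status and ancestral allele.

    Returns (status array, ancestral array with 'ref'/'alt'/'' entries).
    """
    og = list(outgroup_samples)
    if len(og) == 0:
        raise ValueError("at least one outgroup sample is required")
    j = table.sample_index(og)
    g = table.gt[:, j]
    called = g != MISSING
    n_called = called.sum(axis=1)
    any_het = np.any(g == 1, axis=1)
    has_ref = np.any(g == 0, axis=1)
    has_alt = np.any(g == 2, axis=1)

    status = np.full(table.n_sites, STATUS_OK, dtype=object)
    anc = np.full(table.n_sites, "", dtype=object)
    status[n_called < min_outgroup_called] = STATUS_MISSING
    het = (status == STATUS_OK) & any_het
    status[het] = STATUS_HET
    disc = (status == STATUS_OK) & has_ref & has_alt
    status[disc] = STATUS_DISCORDANT
    ok = status == STATUS_OK
    anc[ok & has_ref] = "ref"
    anc[ok & has_alt] = "alt"
    return status, anc


def _genotype_loglik(gt, dp, err):
    """Reconstructed per-sample genotype log-likelihoods (sites, samples, 3).

    The called genotype and observed depth imply an alt-read count
    k = round(dp * gt/2); likelihoods are Binomial(k; dp, p_g) with
    p_g in {err, 1/2, 1-err}.  Missing calls / zero depth get flat (zero)
    log-likelihoods so they contribute nothing.
    """
    from scipy.stats import binom

    d = np.asarray(dp, dtype=float)
    g = np.asarray(gt, dtype=float)
    valid = (g != MISSING) & (d > 0)
    dsafe = np.where(valid, d, 1.0)
    k = np.rint(np.where(valid, g, 0) / 2.0 * dsafe)
    p_g = np.array([err, 0.5, 1.0 - err])
    ll = binom.logpmf(k[..., None], dsafe[..., None], p_g[None, None, :])
    ll = np.where(valid[..., None], ll, 0.0)
    return ll, valid


def corrected_allele_freq(table: VariantTable, population: str,
                          err: float = 0.005, mode: str = "em",
                          max_iter: int = 100, tol: float = 1e-8):
    """Alt-allele frequency and effective allele count per site for one
    population.

    ``mode="em"``: maximum-likelihood frequency from per-sample genotype
    likelihoods under a binomial read model parameterized by each sample's
    depth, iterated by EM (posterior genotype dosage under Hardy-Weinberg
    proportions at the current frequency).  ``mode="count"``: simple allele
    counting (used automatically when depth fields are absent).

    Returns (freq, n_eff) arrays; sites with zero called samples have
    ``freq = nan`` (undefined, flagged), not 0.
    """
    if table.sheet is None:
        raise ValueError("a SampleSheet must be attached")
    ids = table.sheet.samples_in(population)
    if not ids:
        raise ValueError(f"population {population!r} has no samples")
    j = table.sample_index(ids)
    gt = table.gt[:, j].astype(float)
    dp = table.dp[:, j].astype(float)
    called = gt != MISSING

    if mode == "em" and np.all(dp[called] <= 0):
        logger.info("corrected_allele_freq: no depth data; falling back to "
                    "counting mode")
        mode = "count"

    if mode == "count":
        with np.errstate(invalid="ignore"):
            freq = np.where(called, gt, 0).sum(axis=1) / (2 * called.sum(axis=1))
        n_eff = 2 * called.sum(axis=1)
        freq[called.sum(axis=1) == 0] = np.nan
        return freq, n_eff.astype(int)
    if mode != "em":
        raise ValueError(f"unknown mode {mode!r}")

    ll, valid = _genotype_loglik(gt, dp, err)
    n_valid = valid.sum(axis=1)
    n_eff = 2 * (valid & (dp >= 1)).sum(axis=1)

    # EM over the population alt-allele frequency q, vectorized across sites
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(called, gt, 0).sum(axis=1) / np.maximum(
            2 * called.sum(axis=1), 1)
    q = np.clip(q, 1e-6, 1 - 1e-6)
    lik = np.exp(ll - ll.max(axis=2, keepdims=True))
    for _ in range(max_iter):
        prior = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q ** 2], axis=1)
        w = lik * prior[:, None, :]
        w /= np.maximum(w.sum(axis=2, keepdims=True), 1e-300)
        w = np.where(valid[..., None], w, 0.0)
        dose = (w[..., 1] + 2 * w[..., 2]).sum(axis=1)
        q_new = np.where(n_valid > 0, dose / np.maximum(2 * n_valid, 1), q)
        if np.nanmax(np.abs(q_new - q), initial=0.0) < tol:
            q = q_new
            break
        q = q_new
    q = np.asarray(q, dtype=float)
    q[n_valid == 0] = np.nan
    return q, n_eff.astype(int)


def frequency_loglik(q, gt, dp, err: float = 0.005):
    """Population log-likelihood of alt-allele frequency ``q`` at one site.

    The independent objective that `corrected_allele_freq` maximizes:
    sum over samples of log sum_g HWE(g; q) * GL_g.  Used by grid-search
    cross-checks.
    """
    gt = np.asarray(gt, dtype=float)[None, :]
    dp = np.asarray(dp, dtype=float)[None, :]
    ll, valid = _genotype_loglik(gt, dp, err)
    q = float(q)
    prior = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    lik = np.exp(ll - ll.max(axis=2, keepdims=True))
    mix = (lik * prior).sum(axis=2)
    out = np.where(valid, np.log(np.maximum(mix, 1e-300)) + ll.max(axis=2), 0.0)
    return float(out.sum())


def polarize(table: VariantTable, outgroup_samples, populations=("target", "control"),
             min_outgroup_called: int = 2, err: float = 0.005,
             mode: str = "em") -> PolarizedSiteTable:
    """Build the polarized site table with per-population DAF.

    DAF is the corrected frequency of the derived allele:
    ``daf = alt_freq`` where the ancestral allele is REF, ``1 - alt_freq``
    where it is ALT; ``daf(ancestral) + daf(derived) = 1`` by construction.
    """
    status, anc = polarize_status(table, outgroup_samples, min_outgroup_called)
    derived = np.where(anc == "ref", "alt", np.where(anc == "alt", "ref", ""))
    df = table.sites[["chrom", "pos"]].copy()
    df["ancestral"] = anc
    df["derived"] = derived
    df["status"] = status
    ok = status == STATUS_OK
    used_mode = mode
    for pop in populations:
        freq, n_eff = corrected_allele_freq(table, pop, err=err, mode=mode)
        if mode == "em" and np.all(table.dp[table.gt != MISSING] <= 0):
            used_mode = "count"
        daf = np.where(anc == "ref", freq, 1.0 - freq)
        daf = np.where(ok, daf, np.nan)
        df[f"daf_{pop}"] = daf
        df[f"n_eff_{pop}"] = n_eff
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("polarize: %d of %d sites excluded (non-ok outgroup)",
                    n_excluded, table.n_sites)
    return PolarizedSiteTable(df=df, freq_mode=used_mode)
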