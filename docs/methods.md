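# Methods

`altiscan` implements a two-population selection-scan pipeline: outgroup
polarization of alleles, depth-corrected allele frequencies, per-SNP FST and
per-SNP XP-EHH, 10-kb window averaging with a genome-wide top-quantile
threshold and a consecutive-outlier sweep-calling rule, locus-level
haplotype analysis of candidate regions, and an enrichment-ratio analysis of
functional SNP categories across differentiation bins.  A forward
Wright-Fisher simulator generates fully truth-annotated synthetic data so
every stage can be exercised end to end.

## Filters

Quality fields are mapped onto their closest modern equivalents: per-genotype
GQ plays the role of the historical consensus quality and the site QUAL
column the role of the SNP quality.  A homozygous call is kept iff
GQ >= 20 **or** QUAL >= 20; a heterozygous call iff GQ >= 10 **and**
QUAL >= 10.  Failing genotypes are set missing rather than dropping the
site, so the site-level coverage filters act uniformly afterwards.  Boundary
semantics follow the stated rules exactly: ">=" thresholds are inclusive;
"above", "greater than" and "less than" are strict.  Concretely: a site
passes fraction coverage only when called in *strictly more* than 89% of
non-outgroup samples; distance thinning keeps a site only when its distance
to the last kept site *exceeds* 100 kb; a sample is dropped when its missing
fraction *reaches* 10%, or its foreign admixture component *reaches* 5%.
All filters are pure functions, idempotent, order-preserving, and log their
drop counts.

## Polarization and corrected allele frequencies

A site is polarized (`status = ok`) only when at least `min_outgroup_called`
(default 2, i.e. both) outgroup individuals are called and every non-missing
outgroup genotype is homozygous for the same allele; that allele is declared
ancestral.  Heterozygous, discordant or under-called outgroups exclude the
site from all derived-allele statistics.

Allele frequencies support two modes, recorded in the output:

* **`count`** - simple allele counting over called genotypes.
* **`em`** (default) - a maximum-likelihood frequency that corrects for
  sample size and per-sample sequencing depth.  Each sample's genotype
  likelihoods are reconstructed under a binomial read model: the called
  genotype g and depth d imply an alt-read count k = round(d g / 2), and
  GL(g') = Binom(k; d, p_g') with p in {err, 1/2, 1-err}.  EM then iterates
  posterior genotype expectations under Hardy-Weinberg proportions at the
  current frequency (tolerance 1e-8, at most 100 iterations; the objective
  is non-decreasing per iteration and the maximizer agrees with a 1e-4 grid
  search of the same likelihood to better than 1e-3).  At high even depth
  both modes coincide to < 1e-6.  The reconstruction from calls is an
  approximation chosen because VCF input carries calls rather than raw read
  pileups; with raw genotype likelihoods the same EM applies unchanged.

The effective allele count reported per population is 2 x (samples with
depth >= 1).  DAF is the corrected frequency of the derived allele, so
DAF(ancestral) + DAF(derived) = 1 by construction.

## FST scan

Per-SNP differentiation uses the Hudson estimator in the ratio form

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1),        FST = N / D,

with n counted in alleles.  It is robust to unequal sample sizes and suits
per-SNP averaging (window means of per-SNP values, not a ratio of window
sums).  Negative point estimates have no biological interpretation and are
clamped to 0; sites with D = 0 (both populations monomorphic for the same
allele) or n <= 1 are skipped with a logged count.  When both samples are
drawn from one finite deme (zero split time) the estimator has a small
negative bias of order 1/(2Ne): the binomial sampling correction slightly
overcorrects hypergeometric sampling from a finite pool.  The
Weir-Cockerham form is not provided; the per-SNP averaging design makes the
Hudson form the natural choice here.

Windows are non-overlapping 10-kb tiles (0-based half-open, kb-aligned, so
reported 1-based sweep coordinates look like `chr3:100,170,001-100,240,000`).
"Sliding" windows with step = width are equivalent; the step is configurable.
The outlier threshold is the linear-interpolation empirical q-quantile
(default q = 0.99) of window means over all data windows genome-wide;
windows strictly above it are outliers.  A warning is issued below ~100 data
windows, where the upper quantile is poorly resolved.

Sweeps are maximal runs of >= `min_run` (default 3) consecutive outlier
windows; windows with no data (assembly-gap windows, and by default also
SNP-empty windows, since SNP deserts in real data are mostly reference gaps)
neither break nor count toward a run.  The reported interval spans the first
through last outlier window.

**Scale caveat.** The consecutive-outlier rule presumes a genome containing
vastly more windows than any single sweep (hundreds of thousands in a
mammalian genome, of which the top 1% is thousands of windows).  On a small
simulated chromosome the arithmetic of the empirical quantile caps the
number of strictly-above outlier windows at roughly n/100 - with 100 windows
on a 1-Mb test genome, at most one - so a three-window run cannot occur at
that size regardless of how strong the sweep is.  The calling rule is
therefore verified exactly against brute-force enumeration on synthetic
window tracks, while locus-level power on simulated sweeps is assessed by
the rank of the selected site's window (see below).

## XP-EHH

EHH at site x relative to a core SNP is the probability that two randomly
drawn haplotypes are identical over the stretch from the core through x.
Both core alleles are pooled (the cross-population convention), so
EHH(core) = 1 and the curve is monotone non-increasing outward; the grouped
implementation refines haplotype classes site by site and matches an
all-pairs shared-prefix oracle exactly.  iHH integrates the curve
trapezoidally over physical distance in both directions, stopping at the
first site where EHH < 0.05 (that closing segment is included).  Inter-SNP
gaps over 200 kb contribute no area and flag the score; cores whose curve
never reaches the cutoff before the end of the data are flagged unbounded.
Cutoff and gap limit are exposed as configuration; physical distance is used
throughout (no genetic map).

Raw XP-EHH is ln(iHH_target / iHH_control) per core SNP; flagged or
zero-iHH cores are excluded (counts logged) and the remainder is
standardized genome-wide to mean 0, sd 1.  Positive values mean longer
haplotypes - recent selection - in the target population.  Window averaging,
thresholding and sweep calling reuse the FST machinery on the normalized
scores (upper tail only).

## Haplotype analysis

Candidate-region SNPs with per-SNP FST >= 0.4 (threshold-first; an optional
top-k cap covers the "k most differentiated" phrasing) are selected and the
phased haplotypes recoded 0 = ancestral / 1 = derived.  Distinct strings
form the haplotype pattern with per-population counts and frequencies;
labels H1, H2, ... are assigned by descending total count, then first
occurrence.  The network connects patterns observed more than once by a
minimum spanning tree under Hamming distance (Kruskal; ties broken by
smaller distance, then higher combined count of the endpoints, then
lexicographic label pair).  An MST is deterministic and testable against
exhaustive spanning-tree enumeration, and coincides with the backbone of a
median-joining network whenever no median vectors are needed; median vectors
and reticulations are deliberately out of scope.  The linked-variants report
gives, for each pattern, the fraction of member chromosomes carrying the
derived allele at each extra SNP and flags patterns whose members are
derived at all of them.

## Enrichment ratios

A SNP belongs to every regulatory category whose intervals contain it
(multi-label); the structural classes are resolved with precedence
Coding > UTR > Intron, and Intergenic is the fallback.  SNPs are binned by
FST into half-open bins with default edges {0, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0}
(the last bin closed - a terminal ">= 0.5" bin).  For category c and bin b
within analysis scope S (whole genome, or SNPs inside called sweeps),

    P_observed = |c ∩ b ∩ S|,   P_expected = |b ∩ S| · |c ∩ S| / |S|,

the minimal exchangeable null in which category membership is independent of
differentiation.  Marginals are conserved: observed and expected both sum to
|c ∩ S| across bins.  The ratio trend is summarized by OLS of ratio against
bin order 1..k over bins with defined ratios (a bin-midpoint regressor is
available), with a two-sided t-test on the slope (k-2 df); a zero-variance
ratio vector returns slope 0 with p = 1.  Under random category assignment
the significant-slope fraction calibrates to the nominal 5%.

## The simulator

Forward Wright-Fisher with discrete generations: diploid parents are
resampled each generation with probability proportional to fitness,
gametes recombine with Poisson(rho x L) crossovers, and Poisson(2 Ne mu L)
new biallelic mutations arise per generation on a continuous coordinate axis
(infinite sites; positions are floored to unique 1-based integers on
output).  The ancestral population starts from the neutral stationary site
frequency spectrum (counts with probability proportional to 1/i) in linkage
equilibrium and is burnt in for 2 Ne generations to build linkage
disequilibrium before any split.  The control and target populations then
evolve independently for `split_gens` generations.

The outgroup branch is evolved as a per-site Wright-Fisher allele-frequency
process (binomial resampling plus mutation influx) for the total divergence
separating it from the ingroup split state, (2m - 1) x split_gens
generations with m = 5 by default.  Only the two sampled outgroup genotypes
are consumed downstream (for polarization), never outgroup haplotype
structure, so tracking marginal frequencies is sufficient; outgroup
genotypes are drawn per site from the final frequencies under
Hardy-Weinberg.  This makes the outgroup nearly always homozygous ancestral
at ingroup-segregating sites while still producing realistic heterozygous,
discordant and missing outgroup states.

A hard sweep introduces one new mutation at `sel_pos` in the target
population `sel_gen` generations after the split, with genotype fitnesses
1, 1 + hs, 1 + s (h = 0.5), re-seeded until it survives (bounded attempts,
then an explicit error).  The default `sel_gen` times the injection so that
conditionally surviving sweeps complete just before sampling - expected
conditional duration ~ 2 ln(2 Ne s)/(h s) generations with a 1.65x safety
factor - because both scan statistics are designed for sweeps at or near
completion; older (at-split) or younger sweeps can be requested explicitly.

Default parameters are chosen for testing power on a 1-Mb chromosome, not
for biological realism: mu = 1e-7 gives ~1,500 sample SNPs per Mb (~15 per
10-kb window), and rho = 2e-7 puts the hitchhiking extent
s / (rho ln(2 Ne s)) near 100 kb, i.e. a *local* sweep within the test
genome.  At a biologically realistic pig-scale rho (~1e-8 per bp) the same
sweep would homogenize an entire 1-Mb test chromosome, leaving no local
contrast for a genome-wide threshold - a scaled-down-genome artifact, not a
property of real scans.

Genotype noise follows a read-sampling model: depth ~ Poisson(mean_depth)
per site and individual (zero depth = missing call), alt reads ~
Binomial(depth, p_g) with p_g in {err, 1/2, 1-err}; the call is the ML
genotype, GQ the phred-scaled gap between best and second-best genotype
likelihood (capped at 99), and the site QUAL the phred-scaled summed
evidence against an all-homozygous-reference configuration.  The REF allele
is the ancestral base except for a configurable 10% of sites where it is the
derived base, so polarization must genuinely consult the outgroup.

Annotation tracks are built from 1-kb tiles drawn per category to match the
configured genome fractions; a category with an enrichment multiplier m
draws tiles within 50 kb of the selected site with weight m, making its
interval density there about m-fold the elsewhere density (a positive
control for the enrichment analysis).  A simple non-overlapping gene model
supports the sweep-gene intersection.

What the generator does **not** emulate: migration and bottlenecks,
back-mutation, indels, sex chromosomes, phasing error (haplotypes are truth
phase), mapping artifacts, linked outgroup haplotypes, or base-composition
effects.  Passing tests therefore demonstrate correctness of the statistics
and the calling rules under a clean two-population model, not robustness to
the full error structure of real resequencing data.

## Numerical and testing choices

Positions are 0-based half-open internally and 1-based in emitted VCF/report
coordinates (stated once, used everywhere).  Quantiles use numpy's linear
interpolation.  Window means are arithmetic means of per-SNP values.  EM
uses tolerance 1e-8, max 100 iterations, frequencies clipped away from the
boundary by 1e-6 at initialization.  Colliding integer positions after
rounding are shifted upward by 1 bp.  JSON summaries are written with sorted
keys and no timestamps so that fixed-seed runs are byte-identical.

Replicate-based tests run the full study-scale scenario (1 Mb, Ne = 500,
26 + 29 + 2 samples, 500-generation split, s = 0.1) over twenty recorded
sweep seeds and ten neutral seeds; haplotype-based XP-EHH scans use eight of
the sweep seeds.  The pipeline determinism check uses a 300-kb, Ne = 200
configuration with correspondingly scaled-up mu and rho.  These problem
sizes are the package's chosen test scale; all thresholds asserted in the
suite were fixed from the recorded-seed calibration documented alongside the
tests.

## Known limitations

* The consecutive-outlier sweep rule is scale-dependent (see above); on
  genomes below a few tens of Mb the adaptive top-1% threshold cannot yield
  three-window runs.
* The depth correction reconstructs read counts from genotype calls rather
  than consuming raw likelihoods; both coincide at moderate depth but the
  reconstruction discards within-genotype read ambiguity.
* The haplotype network is an MST approximation: reticulate relationships
  and inferred median haplotypes are not represented.
* XP-EHH cores near chromosome ends are frequently flagged unbounded and
  excluded from normalization; on short test chromosomes this removes an
  appreciable fraction of sites (logged per run).
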