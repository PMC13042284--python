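# Methods

`hybzone` implements the statistical core of a replicated hybrid-zone
analysis: two species hybridize along two geographically distinct
transects, and the question is which genomic patterns — divergence,
environmental association, directional introgression — repeat across them,
and what that repetition can and cannot say about selection.  This note
documents the models, the numerical choices, and what the synthetic data
generator does and does not emulate.

## Hybrid index

The hybrid index h of an individual is the proportion of its genome drawn
from the parent-A pool.  Given parental allele-frequency panels p_A and
p_B, the expected ALT-allele frequency for an individual with index h is

    q_l(h) = h p_{A,l} + (1 - h) p_{B,l},

and dosages are modelled per locus as Binomial(2, q_l(h)).  The
log-likelihood is a sum of strictly concave-in-q terms composed with an
affine map, hence unimodal in h; we maximize it by golden-section search on
[0, 1] to a bracket tolerance of 1e-6, followed by up to eight safeguarded
Newton steps (accepted only when the likelihood does not decrease).  The
polish brings symmetric cases — e.g. a single heterozygote between fixed
panels — to h = 1/2 at machine precision and makes pool relabeling
(p_A <-> p_B gives h -> 1 - h) hold to ~1e-12 in practice.  Panel
frequencies are clamped to [1e-4, 1 - 1e-4] so fixed loci cannot produce
infinite log-likelihoods; individuals with fewer than 50 usable loci are
reported missing.  This maximum-likelihood index stands in for the
admixture coefficient of model-based clustering at K = 2; with pure
reference panels the two agree closely (genotype PC1 correlates with the
true index at > 0.95 in our simulations).

Ancestry categories partition [0, 1] exactly: pure parent A (q >= 0.95),
parent-A-dominant (0.60 <= q < 0.95), balanced (0.40 < q < 0.60),
parent-B-dominant (0.05 <= q <= 0.40), pure parent B (q < 0.05).  Pure
panels for downstream analyses use q >= 0.95 / q <= 0.05.

## Divergence statistics

Per-SNP F_ST is the Weir–Cockerham (1984) estimator from variance
components a (among populations), b (among individuals), c (within
individuals), theta = a/(a+b+c).  Populations without calls at a site are
excluded site-wise; sites with fewer than two populations, average sample
size <= 1, or a + b + c = 0 are reported undefined rather than zero.  Both
the r-population estimator and the mean over all two-population pairs are
available (they coincide at r = 2).  Summaries report the per-site
mean/median/SD and additionally the multi-locus ratio-of-sums estimator
sum(a)/sum(a+b+c): the per-site mean is Jensen-biased downward when
differentiation varies across loci (at a generative F of 0.3 it reads
~0.21), while the ratio-of-sums recovers the generative parameter to
within ±0.03 — so parameter-recovery checks use the latter and the
descriptive tables report the former.

pi and d_xy are per-variant-site, missing-data-aware estimators on haploid
allele bookkeeping: pi is the fraction of differing pairs among all
within-group allele pairs (n/(n-1)-corrected), d_xy = p_A(1-p_B) +
p_B(1-p_A) on sample frequencies.  Genome-scale d_xy would additionally
require invariant sites, which a variant-only matrix cannot supply.

VanRaden kinship is G = ZZ'/(2 sum p(1-p)) with Z the dosage matrix
centered at 2p and missing entries imputed at 2p.  Because p is estimated
from the sample itself, small samples shrink relatedness estimates
noticeably (a half-sib pair embedded among ~20 unrelated individuals reads
~0.17 rather than 0.25); tests therefore embed related pairs in large
backgrounds.

## Environmental preprocessing and RDA1

Variables are pruned greedily in the user's priority order, dropping any
variable correlated at |r| >= 0.7 with an already-retained one; constant
columns are dropped (undefined correlation).  Aspect is circular and is
offered as (sin, cos) components for correlation and regression, reported
in degrees.  Slope and aspect come from a DEM by Horn's 8-neighbor
gradient; aspect is the compass bearing of the downslope direction, with
flat cells undefined.  Snow-melt day is the first day in the second half
of a snow year with at least 15 snow-free days among the previous 30; for
synthetic 365-day years the second half starts at day 183 (the boundary is
a convention, configurable).  Note the rule dates melt ~15 days after the
last persistent snow day by construction; recovery tests compare against
this analytically forced day.

With a single response variable the constrained ordination (RDA) reduces
exactly to ordinary least squares of h on the standardized environmental
variables: RDA1 scores are the centered fitted values, loadings the
standardized coefficients, and the proportion of hybrid-index variance
explained is R².  Rank-deficient designs fall back to the minimum-norm
least-squares solution with a warning — after pruning at r < 0.7 exact
collinearity indicates a data problem rather than something to silently
repair.

## GEA likelihood-ratio scan

Per SNP, dosages are binomial (2 trials, logit link) in a design shared
across loci; all loci are fitted at once by batched Newton iterations with
a ridge penalty of 1e-6 on the coefficients, which keeps estimates finite
under complete separation while perturbing likelihood ratios only at order
1e-6.  The plain variant tests intercept + RDA1 against intercept-only
(df = 1).  The structure-corrected variant conditions both models on PC1
and adds RDA1 and RDA1 x PC1 (df = 2); reading the corrected predictor
as main effects plus interaction follows standard model-formula semantics,
and a no-interaction df = 1 variant is switchable.  When the structure
axis and the environmental gradient are confounded — the typical hybrid
zone situation — the corrected test loses most of its power at truly
associated loci; the package exposes both variants rather than taking a
side.  Outliers are loci with p at or below the empirical first
percentile; ties at the cutoff are all included.

Null calibration was checked by simulation: at 5,000 unassociated loci the
p-values are uniform (Kolmogorov–Smirnov), and the LRT is exactly
invariant to affine rescaling of the predictor.

## Bayesian genomic clines

The genomic cline of locus l maps the genome-wide hybrid index to the
probability that an allele descends from parent A:

    phi_l(h) = clamp(h + 2 h (1 - h) (alpha_l + beta_l (2 h - 1)), 0, 1).

alpha shifts the cline (directional introgression; positive = excess
parent-A ancestry), beta steepens or flattens it.  Clamping to [0, 1] is
required for phi to be a probability; the boundaries phi(0) = 0 and
phi(1) = 1 hold for all (alpha, beta), so pure individuals are never
distorted.  Conditional on ancestry the allele is drawn with that parent's
frequency, the two alleles of an individual being independent ancestry
draws, so the dosage is Binomial(2, phi p_A + (1 - phi) p_B).

Each locus gets an independent chain: a joint Gaussian random-walk
Metropolis proposal on (alpha, beta) with Normal(0, 1) priors.  Proposal
scales are tuned per locus during burn-in toward ~30% acceptance and
frozen afterwards; loci whose post-burn-in acceptance leaves [0.15, 0.6]
are flagged.  Production-scale defaults are 100,000 generations, 50,000
burn-in, thinning 24; tests and the acceptance script use 20,000/10,000
chains, which suffice at the simulated effect sizes.  Outliers are loci
whose equal-tail probability interval (ETPI) excludes zero; the default
level is 0.95 with 0.99 available (the two conventions coexist in the
literature this follows, and the choice is surfaced rather than hidden).
The hybrid index is held fixed at its point estimate during the MCMC;
joint formulations co-estimate it, but with thousands of loci
informing h the loss is negligible and the decoupling keeps the modules
independently testable.  Null calibration: on alpha = beta = 0 data,
~5% of loci are flagged at the 95% ETPI and zero lies inside the interval
for ~95% of loci.

Only ancestry-informative loci (parental differential >= 0.6) enter the
cline analysis, both for information content and runtime.

## Logistic cline test

The frequentist cross-check regresses dosage on h (binomial, logit).  Two
nulls are offered because they answer different questions.  The
intercept-only null (df = 1) asks whether dosage depends on h at all — at
ancestry-informative loci it is driven by informativeness, not cline
distortion, and is the appropriate null for the uniformity checks.  The
neutral-cline null fixes q = h p_A + (1 - h) p_B with no free parameters
(df = 2) and asks whether the locus deviates from the genome-average
cline; its statistic tracks |alpha| (rank correlation ~0.8 in recovery
simulations), which is what makes it agree with the Bayesian alpha
estimates.  Permutation p-values shuffle h and count permutations with an
LRT at least as large, add-one corrected.

## Chromosomal autocorrelation and repeatability

Moran's I is computed on ordinal SNP positions (1, 2, 3, ... along each
scaffold or linkage group in super-scaffold order) with inverse-distance
weights w_ij = 1/|i - j| (binary adjacency switchable).  Ordinal rather
than physical positions avoid the downward bias that long physical gaps
would otherwise impose in fragmented assemblies.  Two transects are
compared by a paired t-test over units (scaffolds or LGs) on the per-unit
I of the shared SNPs; two-sided by default, one-sided available.
Cross-transect correlations (Pearson and Kendall) are reported with an
explicit flag that linked SNPs violate the independence assumption, so the
p-values overstate significance.

Candidate genes are SNP-to-gene assignments after expanding gene intervals
by 5 kb flanks (BED half-open conventions internally; GFF3 converted on
read).  The k-way candidate overlap is tested against the independence
expectation N * prod(k_i/N) by permutation, redrawing each set uniformly
without replacement from the universe; set sizes are preserved, gene
lengths are not (matching the expectation formula).  For k = 2 this null
is hypergeometric, which the tests verify.

## Super-scaffold anchoring

Each cDNA's alignments are filtered (coverage > 50%, identity > 90%,
units auto-detected as percent when values exceed 1), the best scaffold is
taken by highest identity, exact ties across scaffolds discard the cDNA,
and cDNAs absent from the linkage map are excluded (counted in a report).
A scaffold anchored by several cDNAs takes their median cM; conflicting LG
assignments discard the scaffold with a warning.  Scaffolds are ordered
within LG by anchor cM, ties broken lexicographically — deterministic
where the underlying convention is silent.  The assembly span is the exact
sum of member scaffold lengths.

Site filters follow the conventional post-calling sequence: per-call
masking first (GQ < 20, DP < 5 — "minimum depth 5" is read as at-least,
with a strict variant switchable), then site-level call rate >= 0.70,
QUAL >= 30, minor allele frequency strictly > 0.05, and optionally
restriction to anchored scaffolds.  Filtering is idempotent.

## Synthetic data generator

Parental pools follow the Balding–Nichols model: ancestral frequencies
uniform on [0.05, 0.95], pool frequencies Beta-distributed around them
with variance parameter F (the approximate pool F_ST; defaults use
F = 0.3, with 0.07 and 0.14 exercised in recovery tests).  Hybrid indexes
follow the sampling design: a smooth logistic gradient with ~25% near-pure
individuals at each end for the latitudinal model (populations of 2 along
the gradient), or locations x {N, S, V} sites for the elevational model,
with logit-scale site offsets (+1.5 valley, 0 south, -1.5 north on the
parent-A scale) placed so valleys are most parent-A — the within-location
ancestry variance is a free simulator parameter, as no empirical estimate
of it exists.  Genotypes are drawn through phi with per-locus planted
(alpha, beta) distortions; missing genotypes are MCAR at rate 0.05 by
default, consistent with a 70% call-rate filter upstream.  The environment
table has one informative variable correlated with h at 0.9 plus three
decoys, giving RDA1 a recoverable target.

Two scenario builders compose the study designs: `simulate_transect_pair`
gives two transects either a common parental origin and common planted
alpha loci (the replicated-hybrid-zone situation) or fully independent
draws (the no-shared-effect control); `simulate_correlated_parental_freqs`
makes the frequency differential a moving-average Gaussian field so that
divergence comes in linkage-style blocks, the feature the blockiness
comparison detects.

What the generator does **not** emulate: linkage and recombination (loci
are independent given h, so ancestry tracts and LD decay are absent —
blockiness arises only through block-correlated effect placement), drift
within pools after admixture, genotyping error beyond MCAR missingness,
pedigree structure (except in dedicated kinship test constructions), and
spatially explicit dispersal.  Passing tests therefore demonstrate
estimator correctness and calibration under the stated generative model,
not robustness to LD or to non-random missingness in real data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: hundreds of
individuals, hundreds to a few thousand loci, 20,000-generation chains,
4–10 seeds per stochastic claim.  These sizes were chosen so each
statistical property is measured with comfortable margins while the whole
suite completes in minutes.  All randomness flows through
`numpy.random.default_rng` seeds; identical seeds reproduce identical
outputs bit-for-bit, and the acceptance script derives every sub-seed from
its `--seed` argument.
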