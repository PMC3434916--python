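# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `sundapop`. It is written for a user who wants to know exactly
what each number means and what the tests do and do not establish.

## Data model and gap handling

The universal input is a set of per-locus alignments of phased haplotypes
(exactly two per diploid individual), a population map
(individual → population → group, groups `sumatra_malay` / `borneo` /
`unassigned`), and per-locus exon intervals in 0-based half-open coordinates
with a frame offset. Any alignment column containing a gap in *any* haplotype
of a locus is masked — not deleted — for all haplotypes, so coordinates remain
stable while every downstream statistic ignores gapped columns. This is the
most conservative reading of "gaps excluded from all analyses". IUPAC
ambiguity codes are rejected at load: the pipeline assumes fully resolved
haplotypes.

## Site classification

Intronic (non-exon) unmasked columns count 1.0 silent site each. Within exons,
codons are read off the majority-consensus sequence (ties broken
alphabetically); each codon position contributes a fractional synonymous site
count equal to the fraction of its three possible single-base changes that
preserve the encoded amino acid (Nei–Gojobori equal-pathway counting), and the
complement to replacement. Changes to or from stop codons count as
replacement. Codons overlapping a masked column are excluded entirely (their
columns contribute no sites of any category); a stop codon in the consensus
reading frame triggers a warning and the codon is treated as non-coding.
Silent = intron + synonymous. Per-category π divides summed pairwise
differences of that category (each variant column classified in the consensus
codon context) by the fractional category site count.

Open design point: no special handling of sites adjacent to splice junctions —
all intronic sites count as silent.

## Hybrid detection

At each locus, each haplotype of each individual is assigned to the species
whose reference haplotype set contains its nearest neighbour (Hamming distance
on unmasked columns); a cross-species tie makes the locus uninformative for
that individual. An individual is flagged as F1-like when its two haplotypes
assign to two *different* species at at least `min_loci` loci (default: all
loci — an F1 is species-heterozygous everywhere). Flagged individuals are
removed before any statistics are computed.

## Diversity statistics

Hd uses the n/(n−1) bias correction with distinct haplotypes defined on the
unmasked columns of the whole locus. Per-population averages over loci are
unweighted means for Hd; π categories are pooled as (summed differences) /
(pairs × summed category sites) across loci, which matches reporting totals
over a fixed site denominator. Cells with fewer than two haplotypes are left
missing with a logged warning. Small negative Da and F_ST values are legal
finite-sample outcomes of the net/ratio corrections (for duplicated pools,
F_ST = −1/(n−1) exactly) and are preserved, not clipped.

## Coalescent conventions

All mutation-scaled parameters are per locus on the IMa scale: θ = 4N_e u,
migration per mutation m = m_gen/u, divergence time t = T_gen·u. The
standard-neutral simulator is a direct Kingman sampler (time in 2N-generation
units; mutation rate θ/2 per unit branch length). Fixed-S conditioning places
exactly S mutations on the genealogy with probability proportional to branch
length — the convention of "giving" the observed number of polymorphic sites
to the simulation. The two-deme IM simulator runs on msprime with haploid
lineages of deme size θ/2 and unit locus mutation rate, which makes
E[pairwise diversity] = θ exactly; backwards-in-time migration of lineages
from deme `sm` into `b` at rate m_sm corresponds to forward gene flow into the
Sumatra-Malay group from Borneo, matching the m_sm semantics. Site positions
are continuous in [0,1) (infinite sites; every column bi-allelic).

## Tajima's D and its nulls

D uses the Tajima constants a1…e2; S = 0 is reported as missing, never 0. The
null interval is the empirical 2.5/97.5% band of D over `reps` (default
10,000) fixed-S standard-neutral genealogies; p-values are two-sided empirical
(2·min tail, capped at 1). Note two finite-sample facts the tests account for:
the fixed-S D distribution has a slightly negative mean, and at small (n, S)
it is discrete-atomic, so the strictly-outside rejection rate of the 95% band
falls a little below 5%. The multilocus test averages D over loci with S ≥ 1
(simulated replicates match each locus's n and S); because averaging narrows
the null, the multilocus p for the same observed D is smaller than the
single-locus p — they are not expected to coincide.

## MK, Ka/Ks, HKA

The MK table is [synonymous, replacement] × [fixed, polymorphic], with fixed
differences counted against a single outgroup individual's consensus and
sites that are simultaneously polymorphic and divergent counted as polymorphic
only. Fisher's exact test is two-tailed by the point-probability rule and the
G-test is uncorrected — both choices reproduce published p-values of this
test's standard implementations to all printed decimals. Ka/Ks uses
Nei–Gojobori site and pathway counting with Jukes–Cantor correction between
the focal consensus and one outgroup haplotype; codons with gaps, masked
columns, or stops are skipped; Ks = 0 leaves the ratio undefined. The
multilocus HKA test solves the classical estimating equations with per-locus
θ_i and one shared scaled divergence time T (equal-size assumption, so
E[D_i] = θ_i(T+1)); the per-locus totals are matched exactly, the statistic
sums standardised deviations over the polymorphism and divergence sides, and
p comes from χ² with df = L−1. Divergence is measured as the mean difference
count between focal haplotypes and the outgroup consensus; with a multi-copy
outgroup one can run the tests over each supplied outgroup genotype and
compare.

## Admixture clustering and ΔK

The Gibbs sampler implements the admixture model with uncorrelated allele
frequencies: latent cluster of origin per allele copy; allele-frequency
updates Dirichlet(λ + counts) with λ = 1; membership updates
Dirichlet(α + counts) with a symmetric α updated by a Metropolis step under a
uniform prior on (0, 10]. Each run warm-starts from a k-means partition of
the one-hot allele matrix, with cluster frequencies drawn around the
partition counts: initialisation does not change the stationary
distribution, but chains started from undifferentiated frequencies can spend
thousands of sweeps specialising when K exceeds the true structure, and any
still-converging segment of the collection phase inflates var(lnL) — which
matters because lnP(data) is estimated as mean(lnL) − var(lnL)/2 over
post-burn-in samples. Q is the thinned posterior mean. Cluster labels
are arbitrary per run (no cross-run alignment; tests use best-permutation
matching). Haplotypes are grouped into alleles by single-linkage clustering at
Hamming distance ≤ `max_diff` (default 0 = identity), a deliberately simple
stand-in for statistical-parsimony grouping; outputs record the `max_diff`
used. ΔK(K) = mean_r |lnP_r(K−1) + lnP_r(K+1) − 2 lnP_r(K)| / sd_r(lnP(K)),
defined for interior K, with K* = argmax; sd = 0 yields an infinite ΔK and a
flag. Desk-scale MCMC defaults (5,000 burn-in + 20,000 iterations, 5 runs)
are configuration values; study-scale runs (50,000 + 200,000) are set in the
run config.

## IM inference by synthetic likelihood

The original genealogy-sampling MCMC estimator is replaced by simulation-based
Gaussian synthetic likelihood: the data are reduced to a 20-component summary
vector (per-group S, π, Tajima's D, Hd averaged over loci; Hudson F_ST;
counts of shared, fixed, and private polymorphisms; the mean and minimum
between-group pairwise distances, the latter sensitive to recent migrants;
and across-locus SDs of per-group S, π and the between-group mean), with moments estimated from `sims_per_eval` IM-simulated
datasets at each parameter point (diagonal covariance with a small ridge).
Common random numbers (one seed for every evaluation) make the objective a
deterministic function of the parameters. Each locus enters through its
longest contiguous alignment interval with no four-gamete violation (leftmost
on ties), since the IM model assumes no intralocus recombination; per-locus
mutation weights are proportional to block length.

Maximisation over the prior box runs in three stages: successive Sobol
refinement (the sampling box shrinks around the best points over three
rounds — the "wide priors → refined box" pilot), a Nelder-Mead polish, and
coordinate-wise grid sweeps over the full prior range, which are robust on the
θ/migration ridges of this likelihood. Marginal profiles on a per-parameter
grid (conditional slice through the optimum, reinforced by the best cached
evaluation near each grid cell) give the parameter estimates (profile peaks)
and 90% HPD intervals as the shortest grid-cell union holding 90% of
normalised profile mass; estimates at ≥99% of a prior bound are flagged
"prior too small". Nested models refit the same objective under the
constraint, warm-started from the full optimum projected onto the constraint
(so the nested optimum never falls below the projected point); if a nested
optimum still exceeds the full one, the full model is re-optimised from that
point. Likelihood ratios are then computed by re-scoring every optimum
out-of-sample — a higher-precision objective averaged over several fresh
seeds — because each optimiser overfits its own frozen Monte-Carlo noise and
only a common, independent surface makes the χ² comparison meaningful. The
isolation ladder follows the two-step rule: full vs {m_sm = m_b} on
χ²(1), then {m_sm = m_b} vs {m_sm = m_b = 0} on the mixed ½·0 + ½·χ²(1)
boundary null; isolation is accepted only if neither step rejects at α = 0.05.

Conversions are exact identities on their inputs: per-locus annual rate
u_syn·(silent sites) + u_syn·(Ka/Ks)·(replacement sites), u = geometric mean
over loci (or supplied directly), V = u·(generation time in years),
N_e = θ/(4V), T = t/u, 2N_e m = θ·m/2, reported at both the minimum and
maximum synonymous-rate brackets (defaults 0.7×10⁻⁹ and 2.61×10⁻⁹ per site
per year, generation time 60 years).

## Synthetic data generator

The `paper_like` scenario encodes the study design this package targets:
7 populations (12/12/12/12/12/6/12 diploids; 78 individuals), groups
Sumatra-Malay (Seremban, Mersing, NanjakMakmur, Asialog) and Borneo
(SariBumiKusuma, ITCIKaryaUtama, Sumalindo), with Asialog and ITCIKaryaUtama
admixed (each haplotype copy drawn from the sm side with q = 0.5 — q is not
identifiable from the published membership plots, so 0.5 is a documented
default); five loci of aligned lengths 1111/1229/1248/1075/1277 bp with one
or two invented exons covering ~30% of each locus; IM parameters at the
published point estimates (θ_sm = 4.367, θ_b = 11.2873, θ_A = 1.1677,
m_sm = 0.755, m_b = 0.045, t = 0.685). Because those θ values refer to the
non-recombining core of each locus (roughly a third of the alignment), the
full-locus mutation weight is scaled by the inverse core fraction (×3), which
puts pooled silent diversity near the observed 0.0075 per site. One
individual (NanjakMakmur_01) is an F1 hybrid carrying a donor-lineage
haplotype at every locus (donor split 10 mutational units back); two more
donor haplotypes form the donor-species reference individual and a deep
outgroup (20 units) supplies divergence for MK/HKA. A configurable fraction
(default 0.5) of replacement variants is re-assigned to a single random focal
haplotype — a phenomenological stand-in for purifying selection keeping
nonsynonymous variants at low frequency; it intentionally breaks the perfect
phylogeny for those columns. Binary sites map to nucleotides on a random
background whose exon codons avoid stops (derived exonic alleles also avoid
creating reference-frame stops); ancestral bases uniform, derived uniform on
the other three.

What the generator does *not* emulate: sequencing/PCR error, indels and
alignment gaps (gap handling is tested on hand-made micro-fixtures),
intralocus recombination within the focal species (each simulated locus is a
single genealogy), selection as a process, and any geographic structure finer
than the two-group-with-admixture design. Passing tests on this generator
show the pipeline recovers the structure it assumes; they do not validate the
model against real sequence heterogeneity.

## ρ estimation

Hudson-style composite likelihood: for every pair of bi-allelic segregating
sites, the probability of the canonical two-site sample configuration
(minor-allele coded, site-order normalised) is looked up in a Monte-Carlo
table — two-site coalescent simulations at a grid of pair-ρ values with
exactly one mutation per marginal tree — log-interpolated in pair-ρ = ρ·d,
summed over pairs, and maximised over the per-site ρ grid. Add-½-per-cell
(0.25) smoothing regularises unseen configurations. Tables are cached
in-memory and optionally on disk keyed by (n, grid, mc_reps, seed). The
estimator is intended for rank recovery (zero vs positive ρ, ordering in true
ρ), not for precise point estimation; with fewer than ~10 segregating sites
its grid argmax is noisy.

## Scale choices in the test suite

The suite runs everything at desk scale on one CPU: the ΔK acceptance check
uses the scaled-down MCMC above; IM parameter recovery runs one seeded
20-locus, 40+40-haplotype experiment (the per-seed criterion: ≥4 of 6 true
values inside the 90% HPDs); the isolation-ladder calibration runs two fixed
seeds per scenario (migration absent vs 2N_e m = 2) at 12 loci and 48+48
haplotypes — at smaller designs an isolation model with larger θ_b and
smaller t genuinely mimics 2N_e m = 2 data within the summary resolution, so
the ladder has no power there; demographic-null self-consistency uses dozens
of datasets against a shared simulated null.
These replication levels are the package's own defaults for a desk run;
larger replication tightens the checks without changing their logic.

## Known limitations

- The synthetic-likelihood IM estimator targets the same model as the
  genealogy-MCMC original but is not expected to agree with it numerically;
  HPDs are profile-based approximations on a grid, and with few loci the
  θ/migration ridge leaves individual parameters weakly identified.
- The admixture sampler implements the uncorrelated-frequencies model only;
  correlated frequencies, linkage, and spatial priors are out of scope.
- HKA assumes equal current and ancestral population sizes (f = 1) and no
  recombination within loci.
- The four-gamete block rule treats recurrent mutation as recombination
  evidence, as the test itself does.
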