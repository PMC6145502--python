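# Methods

`balscan` implements a balancing-selection genome-scan and
selection-inference pipeline for phased human-style haplotype data: windowed
Tajima's D against empirical and demography-matched simulated nulls, the
unstandardized nSL haplotype statistic against frequency-matched nulls,
McDonald-Kreitman / DoS coding-selection statistics with branch-site LRT
arithmetic, and a forward-simulation grid-rejection inference of a focal
variant's selection coefficient and age, with a coalescent rejection sampler
for conditional allele ages. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests do
and do not establish.

## Statistics

**Tajima's D.** Per window, `S` is the count of segregating columns, pi the
mean pairwise Hamming distance over all C(n,2) haplotype pairs (computed via
derived-allele counts, sum of d(n-d)/C(n,2)), theta_W = S/a1 with
a1 = sum_{i<n} 1/i, and D = (pi - theta_W)/sqrt(e1 S + e2 S(S-1)) with the
standard normalization constants. Windows with S = 0 (or n < 2) are flagged
undefined, never imputed as 0, and are excluded from null distributions. For
n <= 3 the variance term is identically zero because pi and theta_W
coincide; D is reported as 0 there. Two properties worth knowing:

* D's null mean is only approximately zero. For non-recombining windows the
  single-tree null mean is visibly negative (about -0.15 at n = 40,
  theta_W ~ 48; an independent coalescent implementation agrees), a known
  finite-sample property of the normalization. The calibration tests
  therefore use recombining windows (rho ~ 16 per 10 kb), the regime real
  scan windows occupy, where the null mean is ~0.01.
* Site counts within one window share a genealogy and are strongly
  overdispersed relative to independent Poisson sites. Cross-engine
  comparisons therefore always treat replicates, not sites, as the
  independent units.

**Sliding windows** are 0-based half-open `[k*step, k*step + window)`
(default 10 kb window, 2 kb step); VCF positions are 1-based. Scan tracks
are computed per population independently.

**Thresholds.** The empirical null is the type-7 (linear-interpolation)
percentile of defined background D values, pinned for reproducibility; the
simulated null runs the structured coalescent under the configured
demography and takes the same percentile per population.

**nSL (unstandardized).** For a focal SNP, SL_A and SL_D are the mean
identity-tract lengths in SNP units over haplotype pairs within the
ancestral and derived allele classes (tracts count columns including the
focal one, minimum 1, truncated at panel edges, no physical-distance
cutoff), and nsl = ln(SL_A/SL_D); negative values mean longer derived-class
haplotypes. The focal score is ranked against SNPs whose derived-allele
frequency lies within a tolerance (default +-1 percentage point in the
field convention; the desk-scale tests use +-5 points because small panels
hold few candidates), drawn with replacement. The candidate pool is
caller-supplied: by default the focal panel itself, but the scan passes
independent neutral background windows, because within-panel candidates can
sit in near-perfect LD with the focal SNP and then echo its own haplotype
structure instead of providing a null. The percentile reported is the
lower-tail fraction of null draws strictly below the focal score
(two-sided reporting available).

**MK / DoS.** The 2x2 contrast [[D_N, D_S], [P_N, P_S]] is tested with a
two-sided Fisher's exact test (sum of all tables at most as probable as the
observed one); DoS = D_N/(D_N+D_S) - P_N/(P_N+P_S), flagged undefined when
either denominator is zero. Divergence counting classifies each codon pair:
single differences directly, multi-hit codons by equal-weight averaging
over all mutational orderings with pathways through stop codons excluded;
codons containing a stop or ambiguity are skipped and logged. Polymorphism
classification applies the standard genetic code to the mutated codon. No
frequency cutoff is applied to polymorphisms (a flag can add one). The
reference-allele polarization rule replaces a CDS reference base when its
population frequency is below 1% or when the recorded ancestral allele
still segregates (as an apparent derived allele) above 1%.

**Branch-site LRT arithmetic.** chi2 = 2(lnL_alt - lnL_null) compared to
the upper tail of chi-square with df = 1 (the standard branch-site
contrast; back-computing published p-values from published statistics
confirms df = 1). Differences below -1e-6 are clamped to zero with a
warning. Codon-model likelihood *optimization* is out of scope; the inputs
are fitted log-likelihoods. Multiple testing uses Storey q-values with the
smoother pi0 estimate (cubic smoothing spline over lambda = 0.05..0.95,
evaluated at 0.95); below 100 p-values the estimator is unstable and pi0
is fixed at 1, which makes the output exactly Benjamini-Hochberg adjusted
p-values.

## Demography and the coalescent engine

A demography is a list of populations (present-day diploid size,
exponential growth rate) plus backward-time events: size/growth changes,
splits (backward merges) and migration-matrix changes. Migration rates are
backward per-lineage per-generation rates, which equal the forward fraction
of a population's parents drawn from the other deme, so one matrix serves
both engines. The shipped `gravel_2011` preset encodes the three-population
out-of-Africa model (African, European, Asian; out-of-Africa bottleneck
deme represented by relabelling EUR between the two split times; 25-year
generations); `toy_ooa` is a structurally identical desk-scale analogue
with inflated per-bp rates so that theta/bp stays realistic at small sizes.
Validation requires a reachable root: in the oldest epoch either one
population remains or the migration graph is strongly connected.

The coalescent engine works directly in generations (one classic coalescent
time unit = 2N generations; the n = 2 expected TMRCA of 2N generations is
asserted in tests). Within a deme, k lineages coalesce at rate
k(k-1)/(4N(t)); exponential growth makes the rate time-inhomogeneous and
the waiting time is drawn by closed-form inversion of the cumulative
hazard. Migration is a competing exponential; recombination follows
Hudson's ancestral-recombination-graph construction with per-lineage rate
r x (material span), splitting at a uniform breakpoint. Each lineage
carries its ancestral-material intervals tagged with descendant-sample
bitsets; coalescing lineages merge material, and intervals whose union
covers the whole sample are retired, so the process ends when no active
material remains. Mutations follow infinite sites on the continuous
interval, overlaid on each inter-event interval with intensity mu x total
material; positions are discretized to integer bp at panel assembly, with
collisions nudged to the adjacent free base (preserving locality) and
sites pushed past the region end dropped. Site-frequency behaviour is
cross-checked against msprime (single-population and full out-of-Africa
configurations) by per-replicate KS on S and pi.

**Conditional allele age.** The Griffiths-Tavare maximum-likelihood
machinery of the original TMRCA analysis is deliberately replaced by a
conditional rejection sampler (a declared simplification): simulate
no-recombination genealogies, find the branches whose descendant sets match
the observed derived-allele configuration (exact per population, or
total-count matching by flag), accept each genealogy with probability
proportional to its matching branch length, and place the mutation
uniformly on the matching branches. Proportional-to-length acceptance is
the low-mutation-rate conditional distribution of genealogies given that a
mutation with the observed count is seen; the naive alternative (drop one
mutation uniformly, accept on match) weights genealogies by matching/total
length and is measurably biased (about 25% low in our validation against
the exact level-by-level expectation). The proportionality cap is
calibrated on a pilot batch (3x its maximum matching length; rarer
genealogies are accepted outright). Means and standard errors of mutation
age and sample TMRCA are reported over accepted genealogies, in generations
and in years via the demography's generation time. The estimator was
validated against the exact sample-conditioned expectation (derived from
E[T_k] and the k-lineage descendant-count distribution) and sits within
Monte-Carlo error of the classic population-frequency expectation
-4N x ln(x)/(1-x) for moderate n.

## Forward engine and grid rejection

The Wright-Fisher engine simulates diploid populations forward from a
backward-time start, sharing the demography object with the coalescent.
Genotype fitnesses are (1, 1+hs, 1+s) with additive h = 0.5 by default; an
explicit fitness triple expresses heterozygote advantage; `selected_pops`
restricts selection to listed populations (resolved through the split tree,
expressing environment-dependent selection); `selection_start` delays
onset. The focal mutation enters as `intro_count` copies (default one) in a
configurable population -- default the non-African/bottleneck lineage,
resolved to its ancestor for older ages, since the inference grid's age
range brackets the bottleneck epoch.

Two tiers share identical focal-allele dynamics. The frequency tier tracks
per-population derived counts with deterministic selection and migration
followed by binomial resampling, with early exit on global loss or
fixation; it powers the grid (sub-millisecond per lost replicate) but
ignores linked-background interference, a deliberate approximation. The
haplotype tier additionally carries whole-population haplotype matrices:
standing variation is initialized from a coalescent sample of the entire
population at the start time (the stationary distribution, orders faster
than a 10N-generation burn-in and validated as exchangeable with coalescent
output by KS on S, pi and D), gametes are built by fitness-weighted parent
choice with Poisson crossovers, and new mutations enter as singleton
columns. An optional `stem_age` places the mutations private to a long
low-frequency latent phase onto the founding haplotype -- the coalescent
equivalent of simulating that phase explicitly, with the caveat that their
linkage at onset is complete (the stem's own recombination would erode it).

Grid rejection enumerates the full Cartesian (s, age) grid -- the published
schedule of 40 selection coefficients x 25 ages x 1000 replicates
enumerates to exactly one million runs, asserted as bookkeeping -- and
accepts replicates whose final focal frequency is within the tolerance
(default +-5 percentage points, read as percentage points of frequency) of
the observed value in every population simultaneously. Desk-scale runs use
lambda = 10 population-size rescaling (sizes/lambda, times/lambda, rates and
s x lambda; theta and rho invariant; distributional invariance asserted by
KS), a reduced grid, and hundreds rather than 1000 replicates per cell; the
full published schedule is a documented long-running profile. Accepted-run
statistics re-run accepted (s, age) cells at the haplotype tier, keep
replicates that re-satisfy the rule, and compute whole-region Tajima's D
and focal nSL per population.

## Synthetic data

Scenario panels exist so every stage is testable without downloads. The
default targets a three-population panel with focal derived-allele
frequencies 0.07 / 0.45 / 0.30 (AFR / EUR / ASN), illustrative values
inside the frequency ranges the analysis is designed around. Neutral panels
come from the coalescent engine; partial-sweep and balancing panels from
the forward haplotype tier. Frequency conditioning is exact rather than
purely rejective: the population trajectory is rejection-sampled on a broad
viability window (+-20 points by default, attempt cap 10,000), then the
panel is drawn stratified by focal allele class -- the conditional
distribution of a random sample given its focal count -- hitting the target
to sampling granularity (1/n). Pure +-2-point rejection at full-panel cost
across three populations jointly would be computationally impractical and
adds no statistical benefit.

The balancing scenario encodes the history the analysis is designed to
detect: an allele that originated long ago (default 1800 generations),
persisted at low copy number (the stem approximation above), and was lifted
to intermediate frequency by heterozygote advantage when the selective
regime began (default at the out-of-Africa transition for the three-
population demography), with selection restricted to non-African
populations -- the gene-by-environment reading of balancing selection on an
out-of-Africa timescale. This joint history is what produces both
signatures at once: stem-private mutations ride at the class frequency
(positive D around the focal SNP) while the recently expanded derived class
is tract-homogeneous (negative nSL against frequency-matched unlinked
SNPs). The partial-sweep scenario is a mid-flight additive sweep founded by
several copies, since in desk-scale bottleneck demes a single-copy sweep
conditioned on establishment is essentially always lost or fixed.

**Scan-calibration study conditions.** The quantitative calibration tests
run in a single constant-size population (N = 150, mu = 1.5e-6, r = 5e-7
per bp) rather than the three-population toy: at desk scale the bottleneck
null of D is so dispersed that a 95th-percentile flag is unstable
seed-to-seed, and what the tests certify is the calibration of the scan
machinery, not the out-of-Africa history (which is exercised by the
cross-engine and msprime checks and by the pipeline demo). Because
fixtures are stochastic constructions, flag and lower-tail properties are
asserted as seed-majorities (at least 4 of 5 fixtures flagged; median
matched-frequency percentile <= 0.25), with the neutral false-positive rate
checked against its binomial band around 5%.

**What passing tests do not show.** The generator emulates phased,
polarized, biallelic panels with clean ancestral states; it does not
emulate genotyping error, phasing switch errors, missing ancestral alleles,
multi-allelic sites, variable mutation/recombination maps, background
selection, or archaic introgression. Desk-scale population sizes compress
coalescent timescales, so absolute statistic values are not comparable to
human data -- only the calibration properties (null centering, false-
positive rate, signal localization, parameter recovery) transfer.

## Problem sizes

Defaults were chosen so the whole test suite and the acceptance script each
run comfortably on a single CPU: 2000 replicates for closed-form coalescent
checks, 500 per engine for the cross-engine KS, 250 accepted genealogies
for allele ages, 200-400 background windows for thresholds, 800 replicates
x 5 runs on the 5x5 desk grid. The full published grid (10^6 simulations)
is bookkeeping-verified and available as a configuration, not run by
default.
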