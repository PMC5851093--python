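# Methods

## The locus-assignment model

A single primer pair amplifying *m* duplicated loci yields, per individual,
only the *set* of distinct allele sequences observed across clones. An
**allele configuration** is a partition of the validated allele panel into
*m* loci. Given a configuration, an individual's observed set decomposes
into per-locus genotypes: a locus holding two of the individual's alleles
must be heterozygous for them; one allele means a homozygote (or, when null
alleles are enabled, a heterozygote with a per-locus null allele of
estimated frequency); zero alleles at a locus is only explicable as a null
homozygote. A locus receiving three or more of one individual's alleles is
structurally incompatible and the configuration is infeasible for that
dataset.

The likelihood of an individual is the **sum over all compatible
decompositions** of the product of per-locus Hardy–Weinberg genotype
probabilities (the standard marginal treatment of a latent variable; a
best-decomposition alternative would bias frequencies toward common
alleles). Per-locus allele frequencies are maximum-likelihood estimates from
EM: the E-step weights each decomposition by its posterior, the M-step sets
frequencies from expected allele counts. The log-likelihood trajectory is
recorded and is non-decreasing; tests assert this on every run.

Configurations are compared by AIC = 2k − 2lnL or BIC = k·ln(n) − 2lnL with
k = Σ_l (k_l − 1) free frequencies (one more per locus that carries a null
allele). The partition itself is not penalized beyond k: two partitions of
the same panel differ in score only through the per-locus allele counts and
the fit. HWE is assessed on the pooled sample by default (populations
merged); per-population likelihood is available as an option.

### Search

The partition space (Stirling numbers; 2^(K−1)−1 for m = 2) is searched by
simulated annealing: proposals move one uniformly chosen allele to another
locus, mixed with a 20% proportion of pair swaps; Metropolis acceptance
with energy = AIC/BIC; temperature starts at t0 = 10 (criterion units) and
is multiplied by 0.99 after every 20 proposals until 1e−3; the cycle is
restarted 5 times from the incumbent optimum. Proposals into structurally
infeasible configurations are rejected. The initial configuration is a
greedy seed (most-frequent alleles spread over loci, remaining alleles
placed to minimize structural violations) followed, when needed, by a
violation-count hill-climb with random restarts; this reliably reaches a
feasible configuration whenever one exists in the tested regimes. All
scores are memoized per canonical (label-free) partition, so the annealer's
cost is bounded by the number of distinct partitions it visits. Ties are
broken lexicographically on the canonical partition for determinism, and
identical seeds give bit-identical results.

An exhaustive enumerator over all set partitions (guarded to ≤ 12 alleles)
serves as the oracle: on simulated two-locus panels of 6–8 alleles the
annealed search attains the exhaustive optimum in ≥ 95/100 seeded datasets
(observed: 100/100).

Genotypes are materialized as the maximum-posterior decomposition under the
fitted frequencies, ties broken lexicographically; calls with posterior
< 0.95 are flagged ambiguous.

## Allele validation

Sequence identity is exact string equality after uppercasing and gap
normalization — no clustering of near-identical clones; sequencing noise is
handled solely by the support rule (≥ 2 individuals, or ≥ 3 distinct PCRs
within one individual, both configurable). Novel alleles continue the
numeric suffix series of the supplied reference panel. Indel-bearing
alleles are stored gapped against the shared amplicon coordinate frame so
all alleles live in one coordinate system; a gap run not divisible by three
marks a frameshift (non-functional), a multiple of three an in-frame indel
(functional, one residue shorter per codon).

## Diversity statistics

For a population × locus count table with 2n gene copies and frequencies
p_i: H_E = 2n/(2n−1)·(1 − Σp_i²) (the unbiased form is required to
reproduce the published per-population values; the uncorrected form does
not), PIC = 1 − Σp_i² − [(Σp_i²)² − Σp_i⁴], A_E = 1/Σp_i², and
A_R(g) = Σ_i [1 − C(2n−N_i, g)/C(2n, g)] computed in log space. The
rarefaction reference g defaults to the smallest gene count in the run (60
in the bundled study table). Printed frequency tables are converted back to
integer counts by largest-remainder rounding to exactly 2n, refusing
adjustments beyond one copy per allele.

Pooled ("All") rows follow the mixed toolchain convention the field's
standard programs produce: H_E, PIC and A_R from counts summed over
populations; A_E as the arithmetic mean of per-population values. Both
behaviors are plain functions, so either convention can be applied to any
statistic.

F-statistics are the Weir & Cockerham (1984) variance-component estimators
θ, f, F, with components summed over alleles and loci; Nei's
G_ST = (H_T − H_S)/H_T is provided as an alternative. Note that θ on an
exactly duplicated population is slightly negative (order −1/(2n̄)), a
known small-sample property of the estimator, not a defect. Null-allele
frequency uses Chakraborty's (H_E−H_O)/(H_E+H_O) by default or
Brookfield-1 (H_E−H_O)/(1+H_E); negative estimates are reported as
computed. The published study's cervus-based null estimate differs slightly
from Chakraborty's (0.202 vs 0.213 on the same heterozygosities); the
iterative cervus estimator is intentionally not re-implemented and values
are estimator-dependent.

The HWE test is Guo & Thompson's exact conditional test. Enumeration visits
every genotype array with the observed allele counts (practical to roughly
n ≤ 20 with ≤ 3 alleles); the Markov-chain variant uses switch proposals
with an exact Hastings correction (pair-selection odds and re-pairing
multiplicity both enter), 10,000 dememorization steps by default, and a
batch-means Monte-Carlo standard error. Type-I error at α = 0.05 is inside
the binomial 99% interval over 1000 null simulations.

## Selection statistics

Nei–Gojobori (1986) proportion method: per-codon synonymous site counts are
the per-position fractions of synonymous single-base changes (changes to
stops count as nonsynonymous); pairwise differences average over all
shortest substitution pathways, skipping pathways through stop codons
(falling back to all pathways only if every one is blocked). p_S = Sd/S̄
and p_N = Nd/N̄ use site counts averaged over the pair, corrected by
Jukes–Cantor d = −(3/4)ln(1 − 4p/3); d_N/d_S are means over all unordered
pairs. Pathway averaging is unweighted, as in the original method; the
implementation agrees with an independent reference implementation to
machine precision on pairwise comparisons. Standard errors come from codon
bootstrap (default 1000 replicates, seeded); the one-sided Z-test uses
Z = (d_N − d_S)/√(var_N + var_S) against a normal reference.

The analysis frame for a 247-bp exon-2 fragment uses frame offset 2,
giving an 81-codon core (243 bp) for codon statistics while
nucleotide-level site statistics run on the full fragment. Gapped codon
columns are pairwise-deleted (complete deletion is available for
p-distances). The default ABS mask ships as a data file of 18 one-based
codon indices corresponding to human DR β-chain peptide-contact residues
9, 11, 13, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 67, 70, 71, 74, 78
(alignment codon i = β residue i+5); the mask is an ordinary input, so any
alternative ABS definition can be supplied, and published ABS definitions
vary — results restricted to a mask should always report which mask was
used.

Tajima's D uses the standard 1989 constants and operates on the 2n gene
copies of a population sample, reconstructed by repeating each allele's
sequence by its count, since D is a property of the sample, not of the
distinct-allele list.

## Simulators

`simulate_multilocus_dataset` emulates the clone-sequencing design: HWE
genotypes per locus (defaults: two loci, 20 clones and 3 PCRs per
individual), optional null alleles modeled as ordinary HWE alleles
invisible in observations (matching the assumptions of the null-allele
estimators), uniform clone sampling over the observed set, and singleton
artifact injection. It does not model PCR chimeras, amplification bias
(available as an optional knob) or sequencing error within clones, so
passing recovery tests demonstrate correctness of the inference under the
model's own assumptions, not robustness to those real-data pathologies.

`simulate_structured_populations` draws population frequencies from a
Balding–Nichols Dirichlet with concentration p·(1−F)/F around the base
frequencies, giving E[F_ST] equal to the target.

`simulate_codon_alignment` mutates one stop-free reference independently
per row (star genealogy, no shared polymorphism) and accepts candidate
changes with probability proportional to the site class's ω for
nonsynonymous changes and 1 for synonymous ones (both scaled by the
maximum ω), so the realized d_N/d_S per class approaches the nominal ω.
`synthetic_drb_panel` combines these into a synthetic stand-in for a real
exon-2 allele panel (19 alleles, elevated ABS diversity, one 3-bp in-frame
deletion); it exercises the pipeline but carries no information about any
published panel's actual values.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 50–100 datasets for the
search-vs-oracle sweeps (6–8 alleles, 50–100 individuals), 100 replicates
for locus-number recovery, 1000 (tests) or 500 (script) null simulations
for exact-test calibration, n = 5000 individuals for null-allele recovery,
3 × 50 individuals × 20 loci for θ recovery, and 500-replicate bootstraps
in power checks — sizes chosen so each property is measured with comfortable
Monte-Carlo margins. EM stops when the log-likelihood gain falls below
1e−8 (cap 1000 iterations). Frequencies sum to 1 within 1e−9; AIC/BIC are
consistent with lnL and k by construction. Degenerate inputs are
contract-checked: monomorphic tables give H_E = PIC = 0 and HWE p = 1,
empty loci are rejected, saturated substitution proportions (p ≥ 3/4) raise
rather than silently truncate, and D is missing-coded when S = 0.

## Known limitations

- The assignment model assumes HWE within the (pooled) sample and free
  assortment across loci; strong inbreeding, population structure or
  inter-locus linkage will bias both the selected partition and the fitted
  frequencies.
- Allele validation cannot distinguish a true allele seen once from an
  artifact; the support thresholds trade sensitivity for specificity.
- The published per-population Tajima's D and Table-style dN/dS values can
  only be recomputed with the actual allele sequences (see the README note
  on the GenBank panel); the bundled synthetic panel is not a substitute
  for them.
- MEGA-style analyses differ subtly in gap handling; both pairwise and
  complete deletion are implemented, but other conventions (e.g. partial
  codon treatment) may cause small discrepancies against other software.
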