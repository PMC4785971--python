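# Methods

`ecoabc` reconstructs the demographic origin of the eastern migratory
caribou ecotype by likelihood-free (ABC) comparison of five competing
divergence/admixture histories for five population groups — barren-ground
(BG), the eastern migratory ecotype (EMT) and three boreal woodland
groups (WM, SM, ONT) — observed at nine unlinked microsatellite loci and
a 401 bp mtDNA control-region fragment. This note records the model, its
assumptions, the defaults, and the choices made where the design was
genuinely open.

## Demographic model

Each scenario is a backward-time event list over constant-size
populations. A *merge* moves every lineage of one population into
another (the forward-time divergence of the first from the second); an
*admixture* event moves each lineage of a population independently to an
introgressing source with probability `r` (a forward-time pulse). Events
sharing a time are applied in listed order, which is how scenario 2
expresses an admixed origin (pulse, then merge, at the same time).

The five shipped scenarios (`src/ecoabc/data/scenarios.yaml`) are:

1. EMT splits directly from BG at `t1`; no admixture.
2. EMT originates at `t1` as a hybrid swarm drawing a fraction `r` of its
   gene pool from BG and the rest from the ONT boreal lineage.
3. BG introgresses (proportion `r`) into the lineage ancestral to EMT and
   ONT at `t2`; EMT diverges from it later at `t1` (`t1 < t2 < t3`).
4. EMT splits from the woodland stem at the boreal radiation (`t3`) and
   receives the BG pulse afterwards at `t2` (`t2 < t3`).
5. EMT splits from the ONT boreal lineage at `t1`; no admixture.

All boreal groups radiate from a single woodland ancestor at `t3` and the
two sub-specific lineages merge at `t4`. The topology text is data, not
code, so alternative readings of the original scenario figure can be
tried without touching the simulator. Where the source narrative
under-determined the topology (which branch receives the pulse in
scenarios 2–3, where scenario 4 attaches), the readings above were fixed
once and are stated here; they make all five scenarios mutually
distinguishable in principle.

### Priors

Times are in generations before present, uniform: `t1` 10–1000, `t2`
200–2000, `t3` 1000–4000, `t4` 10 000–60 000, with strict orderings
`t1 < t2`, `t1 < t3`, `t2 < t4`, `t3 < t4` (plus `t2 < t3` for scenarios
3–4), enforced by rejection resampling. The microsatellite mean mutation
rate is log-uniform 1e-5–1e-3 per locus per generation. The remaining
priors are not constrained by the source study and are package defaults,
all configurable: per-population diploid effective sizes uniform
100–50 000 (an uninformative span covering plausible caribou herd sizes),
admixture proportion uniform 0.05–0.95, mtDNA per-site rate log-uniform
1e-7–1e-5, HKY transition/transversion ratio uniform 2–20, proportion of
invariable sites uniform 0–0.9. Times convert to years at 7 years per
generation.

## Coalescent simulator

Continuous-time structured coalescent: within a population of diploid
size `N`, `k` lineages coalesce at rate `k(k-1)/2 × 1/(2N)` for
autosomal markers. The mtDNA genealogy uses a maternally inherited
haploid pool of `2N/c_mt` effective copies with `c_mt = 4` (pair rate
`c_mt/(2N)`), the standard quarter-of-autosomal convention; `c_mt` is
configurable. Populations evolve independently between demographic
events, which the implementation exploits by drawing within-population
waiting times lazily per inter-event interval. The continuous-time
approximation is adequate for the `N ≥ 100` prior floor.

Microsatellites follow a stepwise mutation model: Poisson(`μ` × branch
length) mutations per branch, each ±1 repeat with equal probability, on
a ladder of `K = 40` states with reflecting boundaries (implemented by
folding the net displacement with the tent map, exact for a symmetric
±1 walk), root at the ladder midpoint. By default all nine loci share
the drawn mean rate; an optional shape-2 Gamma scatter around the mean
is available. Sequences evolve under HKY with a proportion `p_inv` of
permanently invariable sites (drawn once per dataset); substitution is
simulated exactly by uniformisation of the rate matrix, scaled so the
stationary mean rate equals `μ_mt` per variable site. The original study
selected its substitution model with an external tool but never named
it; HKY+I is the configurable stand-in. Diploid genotypes are formed by
random pairing of the `2n` simulated gene copies within each population.

Verified closed forms: E[TMRCA] = 2N for an autosomal pair and N/2 for
an mtDNA pair; SMM equilibrium homozygosity 1/√(1+8Nμ) (Ohta–Kimura);
small-θ mean pairwise differences 2·N_h·μ·L·(1−p_inv); plus a two-sample
KS cross-check of pairwise coalescence times against an independent
coalescent implementation (msprime) on a matched two-population merge.

## Summary statistics

Per population: mean number of alleles and mean allele-size variance
across loci; number of mtDNA haplotypes; mean and variance of pairwise
sequence differences; mean and variance of the rarest-nucleotide count
at segregating sites. Per pair: pooled mean allele number and size
variance; Weir–Cockerham θ (ratio of sums over loci and alleles, from
diploid genotypes); shared allele distance; classification index (mean
HWE log-likelihood of each population's genotypes under the other's
allele frequencies with an add-one pseudocount on the pooled allele set,
averaged over both directions); pooled haplotype number; haplotype-
frequency F_ST (two-population AMOVA with identity distance, closed
form); and mean pairwise differences within (average of the two
populations) and between. Five groups give 5×7 + 10×9 = 125 statistics.

Conventions: variances divide by n (population variance); microsatellite
statistics are pairwise-complete per locus under missing data; degenerate
cases (monomorphic pair, no segregating sites) return 0 with a debug log
entry so rejection distances stay defined. Observed and simulated data
share one code path, so these conventions cancel out of the inference.

## ABC

*Rejection*: statistics are scaled by their median absolute deviation
over the full reference table (zero-MAD columns dropped), Euclidean
distance, closest fraction kept (default tolerance 1%), boundary ties
broken by row index.

*Model choice*: accepted statistics are projected onto ≤ S−1 linear
discriminant axes and a multinomial logistic regression, weighted by an
Epanechnikov kernel of the rejection distance and evaluated at the
observed point, gives the posterior probabilities; credible intervals
come from bootstrap resampling of the accepted set. A singular
projection falls back to the raw statistics, and a degenerate regression
to weighted category frequencies.

*Parameter estimation*: local-linear regression adjustment of each
parameter on the centred statistics over the accepted set, Epanechnikov
weights, with bounded parameters adjusted on the logit scale of their
prior support (so adjusted draws stay inside the prior). The slope is
estimated by ridge regression with leave-one-out cross-validated
penalty: with 125 statistics and a few hundred accepted draws an
unpenalised fit overfits and produces overconfident posteriors (in
calibration runs the nominal 90% interval for `t1` covered the truth in
only ~70% of replicates with OLS versus ~85% with the ridge
adjustment). When the accepted set is smaller than a quarter of the
statistic count the adjustment is skipped entirely and the weighted
rejection posterior is returned.

*Model checking*: parameters are redrawn from the weighted posterior,
datasets simulated and summarised, and each statistic receives a
two-sided posterior-predictive tail probability 2·min(P(sim ≤ obs),
P(sim ≥ obs)) capped at 1.

## Observed-data statistics

Three-level AMOVA follows the Excoffier sums-of-squares decomposition on
an arbitrary squared-distance matrix (identity distance for conventional
F-statistics, pairwise differences for Φ-statistics), with the classical
permutation schemes: whole populations among groups for F_CT,
individuals among populations within groups for F_SC, individuals among
populations across groups for F_ST; p = (hits+1)/(n_perm+1), 10 000
permutations by default. Negative variance components are reported as
computed. Gene diversity uses Nei's unbiased estimator with his sampling
variance; nucleotide diversity is the mean per-comparable-site pairwise
difference with Nei's total variance (eq. 10.7 convention). Rarefied
(private) allelic richness follows the hypergeometric HP-Rare
convention. Haplogroup tables round percentages half-up to one decimal.
The membership-threshold rule assigns an individual to its best cluster
when max q ≥ 0.8 and labels it admixed otherwise; membership matrices
are external inputs (the clustering itself is out of scope).

## Synthetic data

The generator emulates the study design: mtDNA sample sizes 76/234/339/
108/455 (BG/EMT/WM/SM/ONT, 1212 total) and 1360 genotypes allocated
proportionally (rounding residual to the largest group). The
"central parameters" preset — prior midpoints (log-midpoints for
log-uniform), admixture proportion 0.5 — is the reproducible generating
point for recovery experiments. What the generator does *not* emulate:
genotyping error, allelic dropout, null alleles (removed by the study's
cleaning stage), within-group substructure, or selection; passing
recovery tests therefore demonstrates the machinery is self-consistent
under the stated model, not that the original field data would yield the
same posterior.

## Problem sizes and numerical choices

Desk-scale experiments use 2000 simulations per scenario with 20
genotypes + 20 sequences per group (10 000-row reference table), chosen
so the full pipeline — including the coverage and calibration
experiments — runs comfortably on a single CPU; the original analysis
ran ~3 million simulations at full sample sizes. Recovery experiments
use tolerance 0.05 (500 accepted) so the logistic step sees an accepted
set of the scale its five-class fit needs; the package default stays at
the 1% convention. Determinism: every stochastic entry point takes a
numpy Generator; the CLI derives per-stage substreams from the global
seed via `SeedSequence` so each stage is independently reproducible.

## Known limitations

- Scenario topologies are one reading of an under-determined figure;
  alternatives can be supplied as YAML without code changes.
- Constant population sizes only (no growth), matching the scope.
- The haplotype-identity rule that ignores N/gap sites is not transitive;
  first-occurrence matching makes the collapse deterministic but
  order-dependent in pathological inputs.
- Posterior probabilities from the unpenalised logistic step are
  frequently extreme (0/1) at desk scale; the bootstrap intervals convey
  the real uncertainty.
- The original study's Table 4 posteriors and time estimates derive from
  undeposited individual-level data and are reproduced only as
  properties (scenario recovery, interval coverage) on synthetic data.
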