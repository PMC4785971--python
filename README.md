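# ecoabc

Coalescent simulation and approximate Bayesian computation (ABC) for
reconstructing the demographic origin of the eastern migratory caribou
ecotype (*Rangifer tarandus caribou*).

In central Canada the ranges of barren-ground caribou (BG) and woodland
caribou — the eastern migratory ecotype (EMT) and three boreal groups
(WM, SM, ONT) — overlap, and the ecotype's mtDNA carries haplotypes of
the Beringian (B) lineage alongside the woodland (A1/A2/A3) lineages.
Did the ecotype split directly from barren-ground, split from woodland
caribou with no admixture, arise as a recent hybrid, or diverge from a
woodland lineage that had *previously* received barren-ground
introgression? `ecoabc` is built for population geneticists who want to
ask that class of question with a fully scriptable, testable pipeline:

- a structured-coalescent simulator with merge and admixture-pulse
  events, stepwise-mutation microsatellites and HKY+I mtDNA sequences;
- the DIYABC-style summary-statistic vector (within-population and
  pairwise blocks: allele numbers and size variances, Weir–Cockerham
  F_ST, shared allele distance, classification index, haplotype counts
  and haplotype-frequency F_ST, pairwise sequence differences,
  rarest-nucleotide statistics);
- ABC rejection (MAD-normalised Euclidean distance), scenario choice by
  linear discriminant projection + distance-weighted polychotomic
  logistic regression, Beaumont-style regression-adjusted parameter
  posteriors, and posterior-predictive model checking;
- the observed-data statistics of such studies: hierarchical AMOVA with
  permutation tests (F_CT/F_SC/F_ST and Φ analogues), pairwise Φ_ST,
  gene and nucleotide diversity with Nei standard deviations, haplogroup
  tables, rarefied (private) allelic richness, and the q ≥ 0.8
  membership-threshold rule;
- Genepop / FASTA+group-map readers and writers with the study's
  cleaning rules (≥ 8 typed loci per individual, named-locus exclusion),
  and a synthetic-data module that emulates the study design (five
  groups, 1360 genotypes at nine loci, 1212 mtDNA sequences of 401 bp)
  so the whole pipeline is testable without any external data.

The model core: backward in time, `k` lineages in a population of
diploid size `N` coalesce at rate `k(k−1)/2 · 1/(2N)` (mtDNA uses a
maternal haploid pool of `N/2` copies); scenarios are event lists over
the five groups with divergence times `t1 < t2 < t3 < t4` (generations,
converted to years at 7 y/generation) and an admixture proportion `r`.
Five competing scenarios ship as editable YAML. See `docs/methods.md`
for the full model, priors, conventions and limitations.

## Worked example

Simulate a pseudo-observed dataset from scenario 3 (divergence of the
ecotype from a previously introgressed woodland lineage) at the central
parameter preset (t1 = 505, t2 = 1100 generations, r = 0.5), build a
reference table of 600 simulations per scenario at 20 genotypes + 20
sequences per group, and run model choice and parameter estimation:

```python
import numpy as np
import ecoabc

scenarios = ecoabc.load_scenarios()
priors = ecoabc.load_priors()
pops = ["BG", "EMT", "WM", "SM", "ONT"]
sizes = {p: (20, 20) for p in pops}

rng = np.random.default_rng(1)
truth = ecoabc.central_parameters(priors, scenarios[2])
data = ecoabc.simulate_dataset(scenarios[2], truth, sizes, rng)
observed = ecoabc.observed_vector(data, pops)

table = ecoabc.build_reference_table(scenarios, priors, 600, sizes, rng)
rejection = ecoabc.abc_reject(table, observed, tolerance=0.05)
choice = ecoabc.model_posteriors(table, rejection, observed, n_boot=100, rng=rng)
for s in choice.scenario_ids:
    lo, hi = choice.intervals[s]
    print(f"scenario {s}: posterior {choice.probabilities[s]:.3f} [{lo:.3f}, {hi:.3f}]")

posterior = ecoabc.estimate_parameters(
    table, None, observed, choice.best(), priors, tolerance=0.25
)
print(posterior.summary().loc[["t1", "t2"]].round(0))
```

Output:

```
scenario 1: posterior 0.000 [0.000, 0.000]
scenario 2: posterior 0.000 [0.000, 0.000]
scenario 3: posterior 1.000 [0.974, 1.000]
scenario 4: posterior 0.000 [0.000, 0.026]
scenario 5: posterior 0.000 [0.000, 0.000]
    median   q2.5   q97.5  median_years  q2.5_years  q97.5_years
t1   512.0   66.0   936.0        3587.0       463.0       6552.0
t2  1237.0  342.0  1913.0        8658.0      2391.0      13391.0
```

The generating scenario wins decisively (posterior 1.000 with a
bootstrap credible interval of [0.974, 1.000]), and the regression-
adjusted posteriors recover the generating divergence time (t1: median
512 generations ≈ 3587 years before present against a true value of
505) and admixture time (t2: median 1237 against 1100), with 95%
intervals expressing the real uncertainty of a desk-scale table.

The same pipeline is available from the shell (`ecoabc synth`,
`simulate`, `sumstats`, `reject`, `choose`, `estimate`, `gof`, `amova`,
`confusion`), each command seed-reproducible and emitting CSV plus a
JSON run summary.

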