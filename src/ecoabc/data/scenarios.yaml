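# Default demographic model set for the five-group caribou system.
#
# Groups: BG  barren-ground (tundra, Beringian mtDNA lineage B)
#         EMT eastern migratory woodland ecotype
#         WM  western Manitoba boreal
#         SM  southwestern Manitoba boreal
#         ONT Ontario / eastern Manitoba boreal
#
# Events are expressed backward in time.  "merge" moves every lineage of
# `source` into `dest` (a forward-time divergence of `source` from `dest`);
# "admixture" moves each lineage currently in `source` to `from`
# independently with probability `rate` (a forward-time introgression
# pulse from `from` into `source`).  Events sharing a time parameter are
# applied in listed order.
#
# Time parameters (generations before present):
#   t1  divergence of the eastern migratory ecotype (youngest event)
#   t2  sub-specific admixture pulse
#   t3  radiation of the boreal groups from one woodland ancestor
#   t4  split of the woodland and barren-ground lineages (oldest event)

populations: [BG, EMT, WM, SM, ONT]

priors:
  t1:    {dist: uniform,    low: 10,     high: 1000}
  t2:    {dist: uniform,    low: 200,    high: 2000}
  t3:    {dist: uniform,    low: 1000,   high: 4000}
  t4:    {dist: uniform,    low: 10000,  high: 60000}
  N_BG:  {dist: uniform,    low: 100,    high: 50000}
  N_EMT: {dist: uniform,    low: 100,    high: 50000}
  N_WM:  {dist: uniform,    low: 100,    high: 50000}
  N_SM:  {dist: uniform,    low: 100,    high: 50000}
  N_ONT: {dist: uniform,    low: 100,    high: 50000}
  r:     {dist: uniform,    low: 0.05,   high: 0.95}
  mu_ms: {dist: loguniform, low: 1.0e-5, high: 1.0e-3}
  mu_mt: {dist: loguniform, low: 1.0e-7, high: 1.0e-5}
  kappa: {dist: uniform,    low: 2,      high: 20}
  p_inv: {dist: uniform,    low: 0,      high: 0.9}

# Orderings enforced for every scenario (strict inequalities).
constraints: ["t1 < t2", "t1 < t3", "t2 < t4", "t3 < t4"]

scenarios:
  - id: 1
    description: >
      Eastern migratory ecotype descends directly from barren-ground
      caribou; no sub-specific admixture.
    constraints: []
    events:
      - {time: t1, kind: merge, source: EMT, dest: BG}
      - {time: t3, kind: merge, source: WM,  dest: ONT}
      - {time: t3, kind: merge, source: SM,  dest: ONT}
      - {time: t4, kind: merge, source: ONT, dest: BG}

  - id: 2
    description: >
      Eastern migratory ecotype originates as a recent hybrid swarm: at
      its formation it draws a proportion r of its gene pool from
      barren-ground and the rest from the Ontario/eastern Manitoba
      boreal lineage (admixed origin; the other boreal groups are
      untouched by the pulse).
    constraints: []
    events:
      - {time: t1, kind: admixture, source: EMT, from: BG, rate: r}
      - {time: t1, kind: merge, source: EMT, dest: ONT}
      - {time: t3, kind: merge, source: WM,  dest: ONT}
      - {time: t3, kind: merge, source: SM,  dest: ONT}
      - {time: t4, kind: merge, source: ONT, dest: BG}

  - id: 3
    description: >
      Barren-ground caribou introgress into the woodland lineage ancestral
      to the eastern migratory ecotype and the Ontario/eastern Manitoba
      boreal group; the ecotype diverges from that introgressed lineage
      afterwards.
    constraints: ["t2 < t3"]
    events:
      - {time: t1, kind: merge, source: EMT, dest: ONT}
      - {time: t2, kind: admixture, source: ONT, from: BG, rate: r}
      - {time: t3, kind: merge, source: WM,  dest: ONT}
      - {time: t3, kind: merge, source: SM,  dest: ONT}
      - {time: t4, kind: merge, source: ONT, dest: BG}

  - id: 4
    description: >
      Eastern migratory ecotype splits from the ancient woodland ancestor
      at the boreal radiation and subsequently admixes with barren-ground.
    constraints: ["t2 < t3"]
    events:
      - {time: t2, kind: admixture, source: EMT, from: BG, rate: r}
      - {time: t3, kind: merge, source: WM,  dest: ONT}
      - {time: t3, kind: merge, source: SM,  dest: ONT}
      - {time: t3, kind: merge, source: EMT, dest: ONT}
      - {time: t4, kind: merge, source: ONT, dest: BG}

  - id: 5
    description: >
      Eastern migratory ecotype descends from the Ontario/eastern Manitoba
      woodland lineage; no sub-specific admixture.
    constraints: []
    events:
      - {time: t1, kind: merge, source: EMT, dest: ONT}
      - {time: t3, kind: merge, source: WM,  dest: ONT}
      - {time: t3, kind: merge, source: SM,  dest: ONT}
      - {time: t4, kind: merge, source: ONT, dest: BG}
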