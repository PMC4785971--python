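"""Structured-coalescent simulation with microsatellite and mtDNA mutation.

Genealogies are simulated backward in time under a scenario's event list:
within a population of diploid effective size ``N`` each pair of lineages
coalesces at rate ``1/(2N)`` per generation for autosomal markers and at
``c_mt/(2N)`` for mtDNA, whose maternally inherited haploid pool holds
``2N/c_mt`` effective copies (``c_mt = 4`` by default, i.e. one quarter of
the autosomal gene copies).  Merge events transfer all lineages of the
removed population; admixture events reassign each lineage independently
with the drawn proportion.

Mutations are laid on branches afterwards: microsatellites follow a
stepwise mutation model (Poisson numbers of +/-1 steps on a bounded
ladder, boundaries handled by reflection), sequences follow HKY with a
proportion of permanently invariable sites, simulated exactly by
uniformisation of the substitution process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .demography import ParameterDraw, ScenarioSpec
from .io_formats import GenotypeTable, SequenceAlignment

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE.update({"N": 4, "-": 5})
DEFAULT_C_MT = 4.0
ALLELE_OFFSET = 100  # ladder state 0 encodes as Genepop allele 100


@dataclass
class Genealogy:
    """Binary ultrametric tree; leaves are nodes ``0..n_leaves-1`` at time 0,
    internal nodes are appended in coalescence order (index increases
    root-ward).  ``parent[root] == -1``."""

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    leaf_pops: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.time)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        nz = self.parent >= 0
        bl[nz] = self.time[self.parent[nz]] - self.time[nz]
        return bl

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])


@dataclass(frozen=True)
class MicrosatModel:
    """Stepwise mutation model on a ladder of ``K`` allele states."""

    mu: float
    K: int = 40

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.K < 2:
            raise ValueError("ladder needs at least 2 states")


@dataclass(frozen=True)
class SequenceModel:
    """HKY substitution model with a proportion of invariable sites.

    ``mu`` is the substitution rate per variable site per generation;
    transitions (A<->G, C<->T) are ``kappa``-fold faster than
    transversions at stationarity.
    """

    mu: float
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.0
    length: int = 401

    def __post_init__(self) -> None:
        if self.mu < 0 or self.kappa <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 <= self.p_inv <= 1.0:
            raise ValueError("p_inv must be in [0, 1]")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """HKY generator scaled so the mean rate at stationarity is ``mu``."""
        pi = np.asarray(self.base_freqs)
        Q = np.empty((4, 4))
        for x in range(4):
            for y in range(4):
                if x == y:
                    continue
                ts = (x, y) in ((0, 2), (2, 0), (1, 3), (3, 1))
                Q[x, y] = pi[y] * (self.kappa if ts else 1.0)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(pi * np.diag(Q)).sum()
        if mean_rate > 0:
            Q *= self.mu / mean_rate
        return Q


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------

def simulate_genealogy(
    scenario: ScenarioSpec,
    params: ParameterDraw,
    samples: Mapping[str, int],
    marker: str = "autosomal",
    rng: np.random.Generator | None = None,
    c_mt: float = DEFAULT_C_MT,
) -> Genealogy:
    """Simulate one genealogy for ``samples`` lineages per population.

    ``marker`` selects the coalescence-rate scaling: "autosomal" uses the
    2N diploid gene-copy pool, "mtdna" the reduced maternal haploid pool.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if marker not in ("autosomal", "mtdna"):
        raise ValueError("marker must be 'autosomal' or 'mtdna'")
    pair_scale = 1.0 if marker == "autosomal" else float(c_mt)

    leaf_pops: list[str] = []
    lineages: dict[str, list[int]] = {p: [] for p in scenario.populations}
    node = 0
    for pop in scenario.populations:
        k = int(samples.get(pop, 0))
        for _ in range(k):
            lineages[pop].append(node)
            leaf_pops.append(pop)
            node += 1
    n_leaves = node
    if n_leaves < 1:
        raise ValueError("at least one sampled lineage required")

    pop_size = {p: float(params[f"N_{p}"]) for p in scenario.populations}
    for p, N in pop_size.items():
        if N <= 0:
            raise ValueError(f"effective size of {p} must be positive")

    events = sorted(
        ((float(params[e.time_param]), i, e) for i, e in enumerate(scenario.events)),
        key=lambda x: (x[0], x[1]),
    )

    times = [0.0] * n_leaves
    parent = [-1] * n_leaves
    total = n_leaves

    def _coalesce_interval(pop: str, t0: float, t1: float) -> None:
        """Run the within-population coalescent from t0 up to (excl.) t1.

        Populations evolve independently between demographic events, so
        waiting times are pre-drawn in one vectorised block per interval.
        """
        nonlocal total
        lin = lineages[pop]
        k = len(lin)
        if k < 2:
            return
        inv_2n = pair_scale / (2.0 * pop_size[pop])
        exp = rng.exponential
        randint = rng.integers
        t = t0 + exp() / (k * (k - 1) / 2.0 * inv_2n)
        while t < t1:
            i = int(randint(k))
            q = int(randint(k - 1))
            if q >= i:
                q += 1
            elif q < i:
                i, q = q, i  # ensure i < q so pops are index-stable
            a, b = lin[i], lin[q]
            lin.pop(q)
            lin.pop(i)
            new = len(times)
            times.append(t)
            parent.append(-1)
            parent[a] = new
            parent[b] = new
            lin.append(new)
            k -= 1
            total -= 1
            if k < 2:
                return
            t += exp() / (k * (k - 1) / 2.0 * inv_2n)

    t0 = 0.0
    for t_event, _, ev in events:
        if total > 1:
            for pop in scenario.populations:
                _coalesce_interval(pop, t0, t_event)
        if ev.kind == "merge":
            lineages[ev.dest].extend(lineages[ev.source])
            lineages[ev.source] = []
        else:
            r_adm = float(params[ev.rate_param])
            src = lineages[ev.source]
            if src:
                move_mask = rng.random(len(src)) < r_adm
                lineages[ev.source] = [
                    ln for ln, mv in zip(src, move_mask) if not mv
                ]
                lineages[ev.admix_from].extend(
                    ln for ln, mv in zip(src, move_mask) if mv
                )
        t0 = t_event
    while total > 1:
        occupied = [p for p, lin in lineages.items() if lin]
        if len(occupied) > 1:
            raise RuntimeError(
                "lineages stranded in separate populations with no "
                "remaining merge events"
            )
        before = total
        _coalesce_interval(occupied[0], t0, np.inf)
        if total == before:  # pragma: no cover - defensive
            raise RuntimeError("coalescent failed to progress")
    return Genealogy(
        n_leaves=n_leaves,
        parent=np.asarray(parent, dtype=np.int64),
        time=np.asarray(times, dtype=np.float64),
        leaf_pops=leaf_pops,
    )


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def _fold(x: np.ndarray, top: int) -> np.ndarray:
    """Reflect integer states onto [0, top] (tent map with period 2*top)."""
    if top == 0:
        return np.zeros_like(x)
    y = np.mod(x, 2 * top)
    return np.minimum(y, 2 * top - y)


def mutate_microsat(
    gen: Genealogy, model: MicrosatModel, rng: np.random.Generator
) -> np.ndarray:
    """Drop SMM mutations on the genealogy; returns leaf allele states
    (ints in [0, K-1]).  The root starts at the ladder midpoint."""
    bl = gen.branch_lengths()
    k_mut = rng.poisson(model.mu * bl)
    # net displacement of an unconstrained +/-1 walk with k steps
    net = 2 * rng.binomial(k_mut, 0.5) - k_mut
    states = np.empty(gen.n_nodes, dtype=np.int64)
    states[gen.root] = model.K // 2
    top = model.K - 1
    parent = gen.parent
    for i in range(gen.n_nodes - 2, -1, -1):
        s = states[parent[i]] + net[i]
        # reflect at the ladder bounds
        if s < 0 or s > top:
            s = int(_fold(np.asarray(s), top))
        states[i] = s
    return states[: gen.n_leaves]


def mutate_sequence(
    gen: Genealogy, model: SequenceModel, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a sequence down the genealogy under HKY+I.

    Returns an (n_leaves, length) int8 array of base codes (0..3 for
    ACGT).  Sites are declared permanently invariable with probability
    ``p_inv``; variable sites evolve by uniformised HKY jumps, which
    reproduces the continuous-time process exactly.
    """
    L = model.length
    pi = np.asarray(model.base_freqs)
    root_seq = rng.choice(4, size=L, p=pi).astype(np.int8)
    variable = np.flatnonzero(rng.random(L) >= model.p_inv)
    Lv = variable.size
    seqs = np.empty((gen.n_nodes, L), dtype=np.int8)
    seqs[gen.root] = root_seq
    if Lv == 0 or model.mu == 0.0:
        leaf = np.broadcast_to(root_seq, (gen.n_leaves, L)).copy()
        return leaf
    Q = model.rate_matrix()
    away = -np.diag(Q)  # total rate out of each state
    R = float(away.max())
    # conditional jump targets given a real (non-virtual) event
    jump_cum = np.zeros((4, 4))
    for x in range(4):
        probs = Q[x].copy()
        probs[x] = 0.0
        probs /= probs.sum()
        jump_cum[x] = np.cumsum(probs)
    bl = gen.branch_lengths()
    n_events = rng.poisson(R * bl * Lv)
    parent = gen.parent
    for i in range(gen.n_nodes - 2, -1, -1):
        seq = seqs[parent[i]].copy()
        k = int(n_events[i])
        if k:
            sites = variable[rng.integers(0, Lv, size=k)]
            us = rng.random(k)
            vs = rng.random(k)
            for s, u, v in zip(sites, us, vs):
                x = seq[s]
                if u < away[x] / R:  # real event, else virtual (self-jump)
                    seq[s] = int(np.searchsorted(jump_cum[x], v))
        seqs[i] = seq
    return seqs[: gen.n_leaves]


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Genotypes at unlinked microsatellite loci plus one mtDNA alignment.

    ``genotypes``: (n_individuals, n_loci, 2) positive allele integers,
    0 = missing (never produced by simulation, possible in observed data).
    ``sequences``: (n_sequences, L) int8 base codes; codes >= 4 mark
    uncallable sites (N or gap) in observed data.
    """

    geno_pops: list[str]
    genotypes: np.ndarray
    seq_pops: list[str]
    sequences: np.ndarray

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in list(self.geno_pops) + list(self.seq_pops):
            if p not in seen:
                seen.append(p)
        return seen

    def to_genotype_table(self) -> GenotypeTable:
        ids = [f"{p}_{i}" for i, p in enumerate(self.geno_pops)]
        return GenotypeTable(ids, list(self.geno_pops),
                             [f"L{j + 1}" for j in range(self.genotypes.shape[1])],
                             self.genotypes)

    def to_alignment(self) -> SequenceAlignment:
        lut = np.array(list(BASES + "N-"), dtype="U1")
        seqs = ["".join(lut[row]) for row in self.sequences]
        ids = [f"{p}_mt{i}" for i, p in enumerate(self.seq_pops)]
        return SequenceAlignment(ids, list(self.seq_pops), seqs)

    @classmethod
    def from_tables(
        cls, table: GenotypeTable | None, aln: SequenceAlignment | None
    ) -> "SimulatedDataset":
        if table is not None:
            geno_pops = list(table.groups)
            genotypes = table.genotypes.copy()
        else:
            geno_pops, genotypes = [], np.empty((0, 0, 2), dtype=np.int64)
        if aln is not None:
            seq_pops = list(aln.groups)
            sequences = np.array(
                [[_CODE[c] for c in s] for s in aln.sequences], dtype=np.int8
            )
            if sequences.size == 0:
                sequences = sequences.reshape(0, aln.length)
        else:
            seq_pops, sequences = [], np.empty((0, 0), dtype=np.int8)
        return cls(geno_pops, genotypes, seq_pops, sequences)


def simulate_dataset(
    scenario: ScenarioSpec,
    params: ParameterDraw,
    sample_config: Mapping[str, tuple[int, int]],
    rng: np.random.Generator,
    n_loci: int = 9,
    seq_length: int = 401,
    microsat_K: int = 40,
    c_mt: float = DEFAULT_C_MT,
    per_locus_gamma: bool = False,
) -> SimulatedDataset:
    """Simulate a full dataset: ``n_loci`` unlinked microsatellite loci
    (diploid, 2n gene copies per n genotypes, randomly paired) and one
    mtDNA locus (haploid).

    ``sample_config`` maps population -> (n_genotypes, n_sequences).
    With ``per_locus_gamma`` the per-locus rates scatter around the drawn
    mean with a shape-2 Gamma; by default all loci share the mean rate.
    """
    pops = [p for p in scenario.populations if p in sample_config]
    geno_samples = {p: 2 * sample_config[p][0] for p in pops}
    mt_samples = {p: sample_config[p][1] for p in pops}

    mu_ms = float(params["mu_ms"])
    if per_locus_gamma:
        locus_rates = mu_ms * rng.gamma(2.0, 0.5, size=n_loci)
    else:
        locus_rates = np.full(n_loci, mu_ms)

    geno_pops: list[str] = []
    for p in pops:
        geno_pops.extend([p] * sample_config[p][0])
    n_ind = len(geno_pops)
    genotypes = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for locus in range(n_loci):
        gen = simulate_genealogy(
            scenario, params, geno_samples, "autosomal", rng, c_mt
        )
        states = mutate_microsat(gen, MicrosatModel(locus_rates[locus], microsat_K), rng)
        # leaves are laid out population-contiguously; pair gene copies
        # randomly within each population
        offset = 0
        row = 0
        for p in pops:
            k = geno_samples[p]
            perm = rng.permutation(k) + offset
            for a in range(sample_config[p][0]):
                genotypes[row, locus, 0] = states[perm[2 * a]] + ALLELE_OFFSET
                genotypes[row, locus, 1] = states[perm[2 * a + 1]] + ALLELE_OFFSET
                row += 1
            offset += k
    seq_pops: list[str] = []
    for p in pops:
        seq_pops.extend([p] * mt_samples[p])
    if sum(mt_samples.values()) > 0:
        gen_mt = simulate_genealogy(scenario, params, mt_samples, "mtdna", rng, c_mt)
        seq_model = SequenceModel(
            mu=float(params["mu_mt"]),
            kappa=float(params.values.get("kappa", 2.0)),
            p_inv=float(params.values.get("p_inv", 0.0)),
            length=seq_length,
        )
        sequences = mutate_sequence(gen_mt, seq_model, rng)
    else:
        sequences = np.empty((0, seq_length), dtype=np.int8)
    return SimulatedDataset(geno_pops, genotypes, seq_pops, sequences)
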