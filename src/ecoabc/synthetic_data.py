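"""Pseudo-observed dataset generation with the study's structure.

The five-group caribou study design is emulated without any download:
mtDNA sample sizes 76/234/339/108/455 (BG/EMT/WM/SM/ONT) and 1360
diploid nine-locus genotypes allocated to groups proportionally to the
mtDNA sizes (rounding residual assigned to the largest group).  Datasets
are drawn from one of the five demographic scenarios — by default the
introgression-then-divergence model (scenario 3) at the central
parameter preset (prior midpoints, admixture proportion 0.5) — and a
TruthRecord stores everything needed to regenerate them bit-identically.

``inject_haplogroups`` builds alignments with a prescribed haplogroup
composition (A1/A2/A3 woodland sublineages vs the Beringian B lineage)
from four divergent founder sequences, for exercising the haplogroup
tabulation without coalescent machinery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .coalsim import SimulatedDataset, simulate_dataset
from .demography import (
    ParameterDraw,
    central_parameters,
    load_priors,
    load_scenarios,
    sample_parameters,
)
from .io_formats import SequenceAlignment, write_fasta_alignment, write_genepop

DEFAULT_MT_SIZES = {"BG": 76, "EMT": 234, "WM": 339, "SM": 108, "ONT": 455}
DEFAULT_TOTAL_GENOTYPES = 1360


def allocate_genotypes(
    mt_sizes: Mapping[str, int] = DEFAULT_MT_SIZES,
    total: int = DEFAULT_TOTAL_GENOTYPES,
) -> dict[str, int]:
    """Allocate genotype counts proportionally to the mtDNA sample sizes;
    the rounding residual goes to the largest group."""
    mt_total = sum(mt_sizes.values())
    alloc = {p: int(total * n / mt_total) for p, n in mt_sizes.items()}
    largest = max(mt_sizes, key=lambda p: mt_sizes[p])
    alloc[largest] += total - sum(alloc.values())
    return alloc


def default_sample_config(
    mt_sizes: Mapping[str, int] = DEFAULT_MT_SIZES,
    total_genotypes: int = DEFAULT_TOTAL_GENOTYPES,
) -> dict[str, tuple[int, int]]:
    geno = allocate_genotypes(mt_sizes, total_genotypes)
    return {p: (geno[p], mt_sizes[p]) for p in mt_sizes}


@dataclass
class TruthRecord:
    """Everything needed to regenerate a pseudo-observed dataset."""

    scenario_id: int
    parameters: dict[str, float]
    seed: int
    sample_config: dict[str, tuple[int, int]]
    n_loci: int = 9
    seq_length: int = 401

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        d["sample_config"] = {k: tuple(v) for k, v in d["sample_config"].items()}
        return cls(**d)


def _simulate_from_truth(truth: TruthRecord) -> SimulatedDataset:
    scenarios = {sc.scenario_id: sc for sc in load_scenarios()}
    rng = np.random.default_rng(truth.seed)
    return simulate_dataset(
        scenarios[truth.scenario_id],
        ParameterDraw(dict(truth.parameters)),
        truth.sample_config,
        rng,
        n_loci=truth.n_loci,
        seq_length=truth.seq_length,
    )


def generate_pseudo_observed(
    scenario_id: int = 3,
    params: ParameterDraw | str = "central",
    sample_config: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    n_loci: int = 9,
    seq_length: int = 401,
) -> tuple[SimulatedDataset, TruthRecord]:
    """Generate one pseudo-observed dataset plus its TruthRecord.

    ``params`` is a ParameterDraw, "central" (prior midpoints, r = 0.5) or
    "prior" (a fresh draw from the priors).  When ``outdir`` is given the
    dataset is written as Genepop + FASTA + group TSV + truth JSON.
    """
    priors = load_priors()
    scenarios = {sc.scenario_id: sc for sc in load_scenarios()}
    if scenario_id not in scenarios:
        raise ValueError(f"scenario {scenario_id} not in the loaded set")
    scenario = scenarios[scenario_id]
    if sample_config is None:
        sample_config = default_sample_config()
    rng = np.random.default_rng(seed)
    if isinstance(params, str):
        if params == "central":
            draw = central_parameters(priors, scenario)
        elif params == "prior":
            draw = sample_parameters(scenario, priors, rng)
        else:
            raise ValueError("params must be a ParameterDraw, 'central' or 'prior'")
    else:
        draw = params
    truth = TruthRecord(
        scenario_id=scenario_id,
        parameters={k: float(v) for k, v in draw.values.items()},
        seed=seed,
        sample_config={k: tuple(v) for k, v in sample_config.items()},
        n_loci=n_loci,
        seq_length=seq_length,
    )
    dataset = _simulate_from_truth(truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genepop(dataset.to_genotype_table(), outdir / "genotypes.gen")
        write_fasta_alignment(
            dataset.to_alignment(), outdir / "mtdna.fasta", outdir / "groups.tsv"
        )
        truth.to_json(outdir / "truth.json")
    return dataset, truth


def regenerate(truth: TruthRecord) -> SimulatedDataset:
    """Re-simulate the dataset a TruthRecord describes (bit-identical)."""
    return _simulate_from_truth(truth)


# ---------------------------------------------------------------------------
# Hand-scale fixtures
# ---------------------------------------------------------------------------

def make_toy_fixture(seed: int = 0) -> SimulatedDataset:
    """Small deterministic dataset for oracle verification: 3 populations
    x 10 individuals x 3 microsatellite loci, plus 10 sequences of 20 bp
    (3/3/4 per population)."""
    rng = np.random.default_rng(seed)
    pops = ["P1"] * 10 + ["P2"] * 10 + ["P3"] * 10
    genotypes = rng.integers(100, 106, size=(30, 3, 2)).astype(np.int64)
    seq_pops = ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 4
    base = rng.integers(0, 4, size=20).astype(np.int8)
    sequences = np.tile(base, (10, 1))
    # sprinkle a few substitutions so sites segregate
    for i in range(10):
        for site in rng.choice(20, size=rng.integers(0, 4), replace=False):
            sequences[i, site] = (sequences[i, site] + rng.integers(1, 4)) % 4
    return SimulatedDataset(pops, genotypes, seq_pops, sequences)


def inject_haplogroups(
    group_composition: Mapping[str, Mapping[str, int]],
    length: int = 401,
    founder_divergence: int = 10,
    variants_per_haplogroup: int = 3,
    seed: int = 0,
) -> tuple[SequenceAlignment, dict[int, str]]:
    """Build an alignment with a prescribed per-group haplogroup makeup.

    ``group_composition`` maps group -> {haplogroup: count} over
    {A1, A2, A3, B}.  Four founder sequences are constructed with at
    least ``founder_divergence`` fixed differences between the A and B
    lineages (and smaller fixed differences among A1/A2/A3); each
    haplogroup contributes up to ``variants_per_haplogroup`` haplotypes
    derived from its founder by private substitutions.  Returns the
    alignment and the haplotype-id -> haplogroup map, where haplotype ids
    are assigned in first-occurrence order as by ``collapse_haplotypes``.
    """
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, size=length).astype(np.int8)
    founders: dict[str, np.ndarray] = {}
    b_sites = rng.choice(length, size=founder_divergence, replace=False)
    b_seq = base.copy()
    b_seq[b_sites] = (b_seq[b_sites] + 1 + rng.integers(0, 3, b_sites.size)) % 4
    founders["B"] = b_seq
    remaining = np.setdiff1d(np.arange(length), b_sites)
    for k, hg in enumerate(("A1", "A2", "A3")):
        sites = rng.choice(remaining, size=2, replace=False)
        seq = base.copy()
        seq[sites] = (seq[sites] + 1 + rng.integers(0, 3, sites.size)) % 4
        founders[hg] = seq
        remaining = np.setdiff1d(remaining, sites)
    # derive haplotype variants per haplogroup
    variants: dict[str, list[np.ndarray]] = {}
    for hg, founder in founders.items():
        variants[hg] = [founder]
        for _ in range(variants_per_haplogroup - 1):
            site = int(rng.choice(remaining))
            remaining = np.setdiff1d(remaining, [site])
            v = founder.copy()
            v[site] = (v[site] + 1 + rng.integers(0, 3)) % 4
            variants[hg].append(v)
    lut = np.array(list("ACGT"), dtype="U1")
    ids, groups, seqs = [], [], []
    hap_of_seq: list[tuple[str, int]] = []  # (haplogroup, variant index)
    for group, comp in group_composition.items():
        for hg, count in comp.items():
            if hg not in founders:
                raise ValueError(f"unknown haplogroup {hg!r}")
            for i in range(count):
                v = i % len(variants[hg])
                ids.append(f"{group}_{hg}_{i}")
                groups.append(group)
                seqs.append("".join(lut[variants[hg][v]]))
                hap_of_seq.append((hg, v))
    aln = SequenceAlignment(ids, groups, seqs)
    # haplotype ids in first-occurrence order, mirroring collapse_haplotypes
    hap_map: dict[int, str] = {}
    seen: dict[tuple[str, int], int] = {}
    for key in hap_of_seq:
        if key not in seen:
            seen[key] = len(seen) + 1
            hap_map[seen[key]] = key[0]
    return aln, hap_map
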