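"""Readers, writers and cleaning rules for the pipeline's file formats.

Microsatellite genotypes travel in Genepop files (3-digit allele encoding,
``000`` = missing, one POP block per analysis group, the group label taken
from the prefix of each individual id before the first underscore).
Mitochondrial control-region sequences travel in plain FASTA with a
two-column tab-separated sidecar mapping sequence id to group, because
FASTA has no population field.

The cleaning rules implemented here mirror the study design this package
emulates: individuals are retained only if a minimum number of loci
amplified, and loci with unresolvable mutational behaviour can be dropped
by name before analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = 0
SEQ_ALPHABET = set("ACGTN-")


class GenepopParseError(ValueError):
    """Raised for malformed Genepop input; message carries the line number."""


@dataclass
class GenotypeTable:
    """Diploid multilocus microsatellite genotypes with group labels.

    ``genotypes`` has shape (n_individuals, n_loci, 2); allele states are
    positive integers, with both entries equal to :data:`MISSING` (0) for a
    missing genotype.
    """

    individuals: list[str]
    groups: list[str]
    loci: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.genotypes.shape != (n, L, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        if len(self.groups) != n:
            raise ValueError("one group label required per individual")
        if (self.genotypes < 0).any():
            raise ValueError("allele states must be non-negative integers")
        half_missing = (self.genotypes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("a genotype must have 2 alleles or be fully missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the genotype is missing."""
        return (self.genotypes == MISSING).all(axis=2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.groups == other.groups
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class SequenceAlignment:
    """Equal-length DNA sequences (alphabet ``ACGTN-``) with group labels."""

    ids: list[str]
    groups: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.groups) == len(self.sequences)):
            raise ValueError("ids, groups and sequences must align")
        if self.sequences:
            L = len(self.sequences[0])
            for sid, s in zip(self.ids, self.sequences):
                if len(s) != L:
                    raise ValueError(f"sequence {sid} has length {len(s)} != {L}")
                bad = set(s) - SEQ_ALPHABET
                if bad:
                    raise ValueError(f"sequence {sid} has invalid symbols {bad}")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceAlignment):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.groups == other.groups
            and self.sequences == other.sequences
        )


@dataclass
class HaplotypeSet:
    """Collapsed haplotypes: representative sequences and per-group counts.

    ``assignment`` maps each input sequence (by position) to a haplotype id;
    ids are assigned in first-occurrence order starting at 1.
    """

    representatives: list[str]
    assignment: list[int]
    counts: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.representatives)

    def total_count(self) -> int:
        return sum(sum(g.values()) for g in self.counts.values())


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _group_of(individual_id: str) -> str:
    return individual_id.split("_", 1)[0]


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop file (dialect: 3-digit alleles, ``000`` missing).

    Group labels are derived from the prefix (before the first underscore)
    of the first individual in each POP block.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("line 1: empty file")
    # line 1 is a free-text title; locus names follow, one per line or
    # comma-separated, until the first POP keyword.
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        entry = lines[i].strip()
        if entry:
            loci.extend(name.strip() for name in entry.split(",") if name.strip())
        i += 1
    if i == len(lines) and loci:
        # header only, zero individuals: allowed (write_genepop of empty table)
        return GenotypeTable([], [], loci, np.empty((0, len(loci), 2), dtype=np.int64))
    if not loci and i == len(lines):
        raise GenepopParseError("line 2: no locus names and no POP keyword found")

    individuals: list[str] = []
    groups: list[str] = []
    rows: list[list[int]] = []
    current_group: str | None = None
    while i < len(lines):
        line = lines[i]
        if line.strip().upper() == "POP":
            current_group = None
            i += 1
            continue
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"line {i + 1}: expected 'id , genotypes'")
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        alleles: list[int] = []
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"line {i + 1}: {len(fields)} genotypes for {len(loci)} loci"
            )
        for f in fields:
            if len(f) != 6 or not f.isdigit():
                raise GenepopParseError(
                    f"line {i + 1}: genotype '{f}' is not a 6-digit code"
                )
            a, b = int(f[:3]), int(f[3:])
            if (a == 0) != (b == 0):
                raise GenepopParseError(
                    f"line {i + 1}: half-missing genotype '{f}'"
                )
            alleles.extend((a, b))
        if current_group is None:
            current_group = _group_of(ind_id)
        individuals.append(ind_id)
        groups.append(current_group)
        rows.append(alleles)
        i += 1
    geno = np.array(rows, dtype=np.int64).reshape(len(rows), len(loci), 2)
    return GenotypeTable(individuals, groups, loci, geno)


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "ecoabc") -> None:
    """Write a GenotypeTable in the Genepop dialect read by :func:`read_genepop`."""
    if table.genotypes.size and table.genotypes.max() > 999:
        raise ValueError("allele state exceeds 3-digit Genepop encoding")
    out = [title]
    out.extend(table.loci)
    last_group: str | None = None
    for idx, (ind, grp) in enumerate(zip(table.individuals, table.groups)):
        if grp != last_group:
            out.append("POP")
            last_group = grp
        codes = "".join(
            f"{a:03d}{b:03d} " for a, b in table.genotypes[idx]
        ).rstrip()
        out.append(f"{ind} , {codes}" if codes else f"{ind} ,")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Cleaning rules
# ---------------------------------------------------------------------------

def filter_min_loci(table: GenotypeTable, min_loci: int = 8) -> GenotypeTable:
    """Retain individuals typed at >= ``min_loci`` non-missing loci.

    Order is preserved; an empty result is allowed.
    """
    if min_loci > table.n_loci:
        raise ValueError(f"min_loci={min_loci} exceeds {table.n_loci} loci")
    typed = (~table.missing_mask()).sum(axis=1)
    keep = np.flatnonzero(typed >= min_loci)
    return GenotypeTable(
        [table.individuals[i] for i in keep],
        [table.groups[i] for i in keep],
        list(table.loci),
        table.genotypes[keep],
    )


def exclude_loci(table: GenotypeTable, names: Iterable[str]) -> GenotypeTable:
    """Drop loci by name (e.g. BMS1788, whose 1-bp repeat-motif alleles do
    not bin reliably); individuals are always kept."""
    names = list(names)
    unknown = set(names) - set(table.loci)
    if unknown:
        raise ValueError(f"unknown loci: {sorted(unknown)}")
    keep = [j for j, name in enumerate(table.loci) if name not in names]
    return GenotypeTable(
        list(table.individuals),
        list(table.groups),
        [table.loci[j] for j in keep],
        table.genotypes[:, keep, :],
    )


# ---------------------------------------------------------------------------
# FASTA + group map
# ---------------------------------------------------------------------------

def read_fasta_alignment(
    fasta_path: str | Path, group_tsv: str | Path | Mapping[str, str]
) -> SequenceAlignment:
    """Read an alignment from FASTA plus an id->group map (TSV path or dict)."""
    if isinstance(group_tsv, (str, Path)):
        group_map: dict[str, str] = {}
        for ln, line in enumerate(Path(group_tsv).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"group map line {ln}: expected 2 tab-separated columns")
            group_map[parts[0].strip()] = parts[1].strip()
    else:
        group_map = dict(group_tsv)
    ids, groups, seqs = [], [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in group_map:
            raise ValueError(f"sequence {rec.id} missing from group map")
        ids.append(rec.id)
        groups.append(group_map[rec.id])
        seqs.append(str(rec.seq).upper())
    return SequenceAlignment(ids, groups, seqs)


def write_fasta_alignment(
    aln: SequenceAlignment, fasta_path: str | Path, group_tsv: str | Path | None = None
) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if group_tsv is not None:
        Path(group_tsv).write_text(
            "".join(f"{i}\t{g}\n" for i, g in zip(aln.ids, aln.groups))
        )


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

def _comparable_identical(a: str, b: str) -> bool:
    # sites where either sequence is N or a gap are ignored for identity
    for x, y in zip(a, b):
        if x in "N-" or y in "N-":
            continue
        if x != y:
            return False
    return True


def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes.

    Two sequences are identical when they agree at every site where neither
    carries N or a gap.  Each sequence joins the first previously seen
    haplotype it matches, so ids follow first-occurrence order (1-based).
    """
    if aln.n_sequences == 0:
        raise ValueError("empty alignment")
    reps: list[str] = []
    assignment: list[int] = []
    counts: dict[int, dict[str, int]] = {}
    for seq, grp in zip(aln.sequences, aln.groups):
        hid = None
        for k, rep in enumerate(reps):
            if _comparable_identical(seq, rep):
                hid = k + 1
                break
        if hid is None:
            reps.append(seq)
            hid = len(reps)
        assignment.append(hid)
        counts.setdefault(hid, {})
        counts[hid][grp] = counts[hid].get(grp, 0) + 1
    return HaplotypeSet(reps, assignment, counts)


# ---------------------------------------------------------------------------
# Small utilities
# ---------------------------------------------------------------------------

_ACC_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def count_accession_range(first: str, last: str) -> int:
    """Number of accessions in an inclusive range like KM016758-KM016788."""
    m1, m2 = _ACC_RE.match(first), _ACC_RE.match(last)
    if not m1 or not m2:
        raise ValueError("accessions must be letters followed by digits")
    if m1.group(1) != m2.group(1):
        raise ValueError("accession prefixes differ")
    n1, n2 = int(m1.group(2)), int(m2.group(2))
    if n2 < n1:
        raise ValueError("range end precedes start")
    return n2 - n1 + 1
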