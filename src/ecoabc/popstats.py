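"""Observed-data population statistics.

Hierarchical AMOVA (groups / populations / individuals) on an arbitrary
squared-distance matrix, with the classical permutation schemes for the
three fixation indices; pairwise Phi_ST / F_ST matrices; gene and
nucleotide diversity with Nei's sampling standard deviations; haplogroup
composition tables; rarefied (private) allelic richness; and the
q >= 0.8 membership-threshold classification rule for externally supplied
STRUCTURE/CLUMPP membership matrices.

Distance conventions: ``identity`` scores 1 between distinct haplotypes
(giving conventional frequency-based F-statistics), ``pairwise_difference``
uses the number of differing sites (giving Phi-statistics).  Negative
variance components are reported as computed, not truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import SequenceAlignment


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def alignment_distance_matrix(aln: SequenceAlignment, distance: str) -> np.ndarray:
    """Squared-distance matrix between sequences.

    identity: 0/1 on exact sequence identity.
    pairwise_difference: number of differing sites where both are called.
    """
    arr = np.array([list(s) for s in aln.sequences])
    n = arr.shape[0]
    valid = ~np.isin(arr, ["N", "-"])
    d2 = np.zeros((n, n))
    for i in range(n):
        neq = (arr[i] != arr) & valid[i] & valid
        d2[i] = neq.sum(axis=1)
    if distance == "identity":
        return (d2 > 0).astype(float)
    if distance == "pairwise_difference":
        return d2
    raise ValueError("distance must be 'identity' or 'pairwise_difference'")


def _as_d2(data, distance: str) -> np.ndarray:
    if isinstance(data, SequenceAlignment):
        return alignment_distance_matrix(data, distance)
    d2 = np.asarray(data, dtype=float)
    if d2.ndim != 2 or d2.shape[0] != d2.shape[1]:
        raise ValueError("distance input must be a square matrix or an alignment")
    return d2


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AMOVAResult:
    va: float
    vb: float
    vc: float
    pct: tuple[float, float, float]
    f_ct: float
    f_sc: float
    f_st: float
    df: tuple[int, int, int]
    p_ct: float | None = None
    p_sc: float | None = None
    p_st: float | None = None
    n_permutations: int = 0
    degenerate: bool = False


def _ssd_within_sets(d2: np.ndarray, labels: np.ndarray) -> float:
    """Sum over label classes S of (1/2|S|) * sum_{i,j in S} d2_ij."""
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        total += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return total


def _amova_components(
    d2: np.ndarray, pop_idx: np.ndarray, grp_of_pop: np.ndarray
) -> tuple[float, float, float, tuple[int, int, int]]:
    """Excoffier variance components from a squared-distance matrix.

    ``pop_idx`` assigns each individual to a population (0..P-1);
    ``grp_of_pop`` assigns each population to a group (0..G-1).
    """
    N = d2.shape[0]
    grp_idx = grp_of_pop[pop_idx]
    P = len(np.unique(pop_idx))
    G = len(np.unique(grp_idx))
    ssd_total = d2.sum() / (2.0 * N)
    ssd_wp = _ssd_within_sets(d2, pop_idx)
    ssd_wg = _ssd_within_sets(d2, grp_idx)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    n_p = np.bincount(pop_idx).astype(float)
    n_g = np.bincount(grp_idx).astype(float)
    sum_np2_over_ng = 0.0
    for p in range(len(n_p)):
        sum_np2_over_ng += n_p[p] ** 2 / n_g[grp_of_pop[p]]
    n1 = (N - sum_np2_over_ng) / df_ap if df_ap > 0 else 0.0
    n2 = (sum_np2_over_ng - (n_p ** 2).sum() / N) / df_ag
    n3 = (N - (n_g ** 2).sum() / N) / df_ag
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    vc = ms_wp
    vb = (ssd_ap / df_ap - vc) / n1 if df_ap > 0 and n1 > 0 else 0.0
    va = (ssd_ag / df_ag - vc - n2 * vb) / n3 if n3 > 0 else 0.0
    return va, vb, vc, (df_ag, df_ap, df_wp)


def _f_stats(va: float, vb: float, vc: float) -> tuple[float, float, float]:
    tot = va + vb + vc
    f_ct = va / tot if tot != 0 else 0.0
    f_sc = vb / (vb + vc) if (vb + vc) != 0 else 0.0
    f_st = (va + vb) / tot if tot != 0 else 0.0
    return f_ct, f_sc, f_st


def amova(
    data,
    group_of_pop: Mapping[str, str],
    pop_of_individual: Sequence[str],
    distance: str = "pairwise_difference",
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> AMOVAResult:
    """Three-level AMOVA with permutation tests.

    ``data`` is a SequenceAlignment or a precomputed squared-distance
    matrix.  Permutation schemes: whole populations among groups (F_CT),
    individuals among populations within groups (F_SC), individuals among
    populations across groups (F_ST).  p = (hits + 1)/(n_perm + 1).
    """
    d2 = _as_d2(data, distance)
    pops = list(dict.fromkeys(pop_of_individual))
    groups = list(dict.fromkeys(group_of_pop[p] for p in pops))
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    if len(pops) <= len(groups):
        raise ValueError("AMOVA needs replication at the population level")
    pop_code = {p: i for i, p in enumerate(pops)}
    grp_code = {g: i for i, g in enumerate(groups)}
    pop_idx = np.array([pop_code[p] for p in pop_of_individual])
    grp_of_pop = np.array([grp_code[group_of_pop[p]] for p in pops])

    va, vb, vc, df = _amova_components(d2, pop_idx, grp_of_pop)
    tot = va + vb + vc
    degenerate = tot == 0.0
    pct = tuple(100.0 * v / tot if tot != 0 else 0.0 for v in (va, vb, vc))
    f_ct, f_sc, f_st = _f_stats(va, vb, vc)
    result = AMOVAResult(va, vb, vc, pct, f_ct, f_sc, f_st, df, degenerate=degenerate)
    if n_perm <= 0 or degenerate:
        return result
    if rng is None:
        rng = np.random.default_rng(0)
    hits_ct = hits_sc = hits_st = 0
    n_ind = len(pop_of_individual)
    for _ in range(n_perm):
        # F_ST: permute individuals among populations among groups
        perm = rng.permutation(n_ind)
        a, b, c = _amova_components(d2, pop_idx[perm], grp_of_pop)[:3]
        if _f_stats(a, b, c)[2] >= f_st:
            hits_st += 1
        # F_SC: permute individuals among populations within groups
        pidx = pop_idx.copy()
        for g in range(len(groups)):
            members = np.flatnonzero(grp_of_pop[pop_idx] == g)
            pidx[members] = pop_idx[members][rng.permutation(members.size)]
        a, b, c = _amova_components(d2, pidx, grp_of_pop)[:3]
        if _f_stats(a, b, c)[1] >= f_sc:
            hits_sc += 1
        # F_CT: permute whole populations among groups
        gperm = grp_of_pop[rng.permutation(len(pops))]
        a, b, c = _amova_components(d2, pop_idx, gperm)[:3]
        if _f_stats(a, b, c)[0] >= f_ct:
            hits_ct += 1
    result.p_ct = (hits_ct + 1) / (n_perm + 1)
    result.p_sc = (hits_sc + 1) / (n_perm + 1)
    result.p_st = (hits_st + 1) / (n_perm + 1)
    result.n_permutations = n_perm
    return result


def _two_level_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(Va among populations, Vb within) for a flat population structure."""
    N = d2.shape[0]
    codes, pop_idx = np.unique(labels, return_inverse=True)
    P = codes.size
    ssd_total = d2.sum() / (2.0 * N)
    ssd_wp = _ssd_within_sets(d2, pop_idx)
    ssd_ap = ssd_total - ssd_wp
    n_p = np.bincount(pop_idx).astype(float)
    nc = (N - (n_p ** 2).sum() / N) / (P - 1)
    vb = ssd_wp / (N - P) if N > P else 0.0
    va = (ssd_ap / (P - 1) - vb) / nc if nc > 0 else 0.0
    return va, vb


def two_level_fst(d2: np.ndarray, labels: np.ndarray) -> float:
    """AMOVA-based Phi_ST/F_ST for a flat (no-group) population structure."""
    va, vb = _two_level_components(np.asarray(d2, float), np.asarray(labels))
    tot = va + vb
    if tot == 0.0:
        return 0.0
    return float(va / tot)


@dataclass
class PairwiseDiffMatrix:
    pops: list[str]
    values: np.ndarray
    p_values: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pops, columns=self.pops)


def pairwise_differentiation(
    data,
    pop_of_individual: Sequence[str],
    distance: str = "pairwise_difference",
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> PairwiseDiffMatrix:
    """Pairwise two-population Phi_ST/F_ST with optional permutation p-values."""
    d2 = _as_d2(data, distance)
    labels = np.asarray(pop_of_individual)
    pops = list(dict.fromkeys(pop_of_individual))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    P = len(pops)
    vals = np.zeros((P, P))
    pvals = np.ones((P, P)) if n_perm > 0 else None
    if rng is None:
        rng = np.random.default_rng(0)
    for i in range(P):
        for j in range(i + 1, P):
            idx = np.flatnonzero(np.isin(labels, [pops[i], pops[j]]))
            sub = d2[np.ix_(idx, idx)]
            sub_labels = labels[idx]
            obs = two_level_fst(sub, sub_labels)
            vals[i, j] = vals[j, i] = obs
            if n_perm > 0:
                hits = 0
                for _ in range(n_perm):
                    perm = sub_labels[rng.permutation(idx.size)]
                    if two_level_fst(sub, perm) >= obs:
                        hits += 1
                p = (hits + 1) / (n_perm + 1)
                pvals[i, j] = pvals[j, i] = p
    return PairwiseDiffMatrix(pops, vals, pvals)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def gene_diversity(haplotype_counts: Sequence[int]) -> tuple[float, float]:
    """Nei's unbiased gene diversity h and its standard deviation.

    h = n/(n-1) (1 - sum p_i^2); the variance is Nei (1987) eq. 8.12.
    """
    counts = np.asarray(haplotype_counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity needs at least 2 haplotypes sampled")
    p = counts / n
    sum2 = (p ** 2).sum()
    sum3 = (p ** 3).sum()
    h = n / (n - 1.0) * (1.0 - sum2)
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2)
    )
    return float(h), float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(aln: SequenceAlignment) -> tuple[float, float]:
    """Nucleotide diversity pi (mean pairwise difference per comparable
    site) and its standard deviation (Nei 1987 eq. 10.7, total variance
    including the stochastic term)."""
    n = aln.n_sequences
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    arr = np.array([list(s) for s in aln.sequences])
    valid = ~np.isin(arr, ["N", "-"])
    L = aln.length
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            nc = comp.sum()
            if nc == 0:
                continue
            diffs.append((arr[i][comp] != arr[j][comp]).sum() / nc)
    pi = float(np.mean(diffs)) if diffs else 0.0
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi ** 2
    return pi, float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Haplogroup table
# ---------------------------------------------------------------------------

HAPLOGROUPS = ("A1", "A2", "A3", "B")


def percentage(count: int, n: int) -> float:
    """Percentage rounded half-up to one decimal (display convention)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    exact = Decimal(100) * Decimal(count) / Decimal(n)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def haplogroup_table(
    haplotype_counts_per_group: Mapping[str, Mapping[int, int]],
    haplogroup_of_haplotype: Mapping[int, str],
    alignment: SequenceAlignment | None = None,
    haplotype_of_sequence: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-group haplogroup composition (counts and percentages) with the
    pooled woodland lineage A = A1 + A2 + A3, plus optional diversity
    columns when per-group sequence data are supplied."""
    rows = {}
    for group, counts in haplotype_counts_per_group.items():
        tallies = {hg: 0 for hg in HAPLOGROUPS}
        for hap, c in counts.items():
            if hap not in haplogroup_of_haplotype:
                raise ValueError(f"haplotype {hap} has no haplogroup assignment")
            hg = haplogroup_of_haplotype[hap]
            if hg not in tallies:
                raise ValueError(f"unknown haplogroup {hg!r}")
            tallies[hg] += c
        n = sum(tallies.values())
        n_a = tallies["A1"] + tallies["A2"] + tallies["A3"]
        row = {"N": n}
        for hg in ("A1", "A2", "A3"):
            row[f"N_{hg}"] = tallies[hg]
            row[f"{hg}_pct"] = percentage(tallies[hg], n)
        row["N_A"] = n_a
        row["A_pct"] = percentage(n_a, n)
        row["N_B"] = tallies["B"]
        row["B_pct"] = percentage(tallies["B"], n)
        rows[group] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if alignment is not None:
        for group in table.index:
            idx = [k for k, g in enumerate(alignment.groups) if g == group]
            sub = SequenceAlignment(
                [alignment.ids[k] for k in idx],
                [alignment.groups[k] for k in idx],
                [alignment.sequences[k] for k in idx],
            )
            pi, pi_sd = nucleotide_diversity(sub)
            if haplotype_of_sequence is not None:
                hap_counts: dict[int, int] = {}
                for k in idx:
                    h = haplotype_of_sequence[alignment.ids[k]]
                    hap_counts[h] = hap_counts.get(h, 0) + 1
                counts = list(hap_counts.values())
            else:
                counts = list(haplotype_counts_per_group[group].values())
            h, h_sd = gene_diversity(counts)
            table.loc[group, "pi"] = pi
            table.loc[group, "pi_sd"] = pi_sd
            table.loc[group, "gene_div"] = h
            table.loc[group, "gene_div_sd"] = h_sd
    return table


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _absent_prob(N: float, n_a: float, g: int) -> float:
    """C(N - n_a, g) / C(N, g): probability a subsample of g gene copies
    misses an allele of count n_a."""
    if N - n_a < g:
        return 0.0
    return float(
        np.exp(
            gammaln(N - n_a + 1)
            - gammaln(N - n_a - g + 1)
            - gammaln(N + 1)
            + gammaln(N - g + 1)
        )
    )


def rarefied_allelic_richness(
    allele_counts: Mapping[int, int] | Sequence[int],
    g: int,
    private: bool = False,
    reference_pops: Sequence[Mapping[int, int]] | None = None,
) -> float:
    """Expected number of (private) alleles in a subsample of ``g`` gene
    copies (hypergeometric rarefaction; HP-Rare convention).

    For private richness, each allele's term is multiplied by the
    probability that it is absent from every equally rarefied reference
    population.
    """
    if isinstance(allele_counts, Mapping):
        counts = dict(allele_counts)
    else:
        counts = {i: c for i, c in enumerate(allele_counts)}
    N = sum(counts.values())
    if not 1 <= g <= N:
        raise ValueError(f"g={g} out of range [1, {N}]")
    if private and reference_pops is None:
        raise ValueError("private richness needs reference populations")
    total = 0.0
    for allele, c in counts.items():
        if c == 0:
            continue
        term = 1.0 - _absent_prob(N, c, g)
        if private:
            for ref in reference_pops:
                N_ref = sum(ref.values())
                c_ref = ref.get(allele, 0)
                g_ref = min(g, N_ref)
                term *= _absent_prob(N_ref, c_ref, g_ref)
        total += term
    return total


# ---------------------------------------------------------------------------
# Membership-threshold classification
# ---------------------------------------------------------------------------

ADMIXED = "admixed"


def classify_by_q(qmatrix: np.ndarray, threshold: float = 0.8) -> list[int | str]:
    """Assign each individual to its max-q cluster when max q >= threshold,
    else label it admixed.  Clusters are numbered from 1."""
    q = np.asarray(qmatrix, dtype=float)
    if q.ndim != 2:
        raise ValueError("q matrix must be 2-dimensional")
    if ((q < -1e-9) | (q > 1 + 1e-9)).any():
        raise ValueError("q values must lie in [0, 1]")
    if np.abs(q.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("q rows must sum to 1")
    out: list[int | str] = []
    for row in q:
        k = int(np.argmax(row))
        out.append(k + 1 if row[k] >= threshold else ADMIXED)
    return out


def read_qmatrix(path: str | Path, n_clusters: int) -> np.ndarray:
    """Read a CLUMPP-style whitespace table; the final ``n_clusters``
    numeric columns of each row are the membership coefficients."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split(":")[-1] if ":" in line else line
        fields = line.split()
        if len(fields) < n_clusters:
            continue
        rows.append([float(x) for x in fields[-n_clusters:]])
    if not rows:
        raise ValueError("no membership rows found")
    return np.asarray(rows)
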