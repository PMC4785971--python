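"""DIYABC-style summary statistics and reference-table construction.

A dataset (observed or simulated) is reduced to a fixed-order vector:

within each population
  mean number of microsatellite alleles across loci; mean allele size
  variance across loci; number of mtDNA haplotypes; mean and variance of
  pairwise sequence differences; mean and variance of the rarest
  nucleotide count at segregating sites.

for each unordered population pair
  mean number of alleles and mean allele size variance on the pooled
  sample; Weir-Cockerham microsatellite F_ST; shared allele distance;
  classification index (mean of both directions); pooled number of
  haplotypes; haplotype-frequency F_ST; mean pairwise sequence
  differences within (average of the two populations) and between.

Variance statistics use the population convention (divide by n).
Degenerate cases (no segregating sites, monomorphic loci) yield 0 rather
than NaN so that rejection distances stay defined; each such case is
logged at debug level.  Missing microsatellite data are handled
pairwise-complete per locus.

Internally one :class:`_MsSummary` / :class:`_SeqSummary` pair holds the
per-locus allele counts and the unique-haplotype decomposition, shared
by every statistic of one dataset, which keeps reference-table
construction cheap.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coalsim import SimulatedDataset, simulate_dataset
from .demography import PriorSpec, ScenarioSpec, sample_parameters

log = logging.getLogger(__name__)

WITHIN_STATS = (
    "ms_nall", "ms_sizevar",
    "mt_nhap", "mt_pi_mean", "mt_pi_var", "mt_rarest_mean", "mt_rarest_var",
)
PAIR_STATS = (
    "ms_nall", "ms_sizevar", "ms_fst", "ms_das", "ms_cli",
    "mt_nhap", "mt_fst", "mt_pi_within", "mt_pi_between",
)


def _pop_indices(labels: Sequence[str], pop: str) -> np.ndarray:
    return np.array([i for i, p in enumerate(labels) if p == pop], dtype=np.intp)


# ---------------------------------------------------------------------------
# Microsatellite decomposition
# ---------------------------------------------------------------------------

class _MsSummary:
    """Per-locus allele codes and per-population count caches."""

    def __init__(self, genotypes: np.ndarray, geno_pops: Sequence[str]):
        self.genotypes = genotypes
        self.geno_pops = list(geno_pops)
        n, L, _ = genotypes.shape
        self.n_loci = L
        self.loci: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for locus in range(L):
            col = genotypes[:, locus, :]
            present = col[:, 0] > 0  # missing iff both alleles are 0
            vals = np.unique(col[present]) if present.any() else np.empty(0, np.int64)
            code = np.searchsorted(vals, col) if vals.size else np.zeros_like(col)
            self.loci.append((vals, code, present))
        self._cache: dict[tuple[int, str], tuple[np.ndarray, np.ndarray, int]] = {}
        self._pop_idx: dict[str, np.ndarray] = {}

    def pop_idx(self, pop: str) -> np.ndarray:
        if pop not in self._pop_idx:
            self._pop_idx[pop] = _pop_indices(self.geno_pops, pop)
        return self._pop_idx[pop]

    def locus_counts(self, locus: int, pop: str) -> tuple[np.ndarray, np.ndarray, int]:
        """(allele counts, heterozygote-carrier counts, n individuals)
        for one population at one locus, over the locus' allele codes."""
        key = (locus, pop)
        if key not in self._cache:
            vals, code, present = self.loci[locus]
            idx = self.pop_idx(pop)
            idx = idx[present[idx]]
            na = vals.size
            if idx.size == 0 or na == 0:
                self._cache[key] = (np.zeros(na), np.zeros(na), 0)
            else:
                c = code[idx]
                counts = np.bincount(c.ravel(), minlength=na).astype(float)
                het = c[:, 0] != c[:, 1]
                het_counts = (
                    np.bincount(c[het].ravel(), minlength=na).astype(float)
                    if het.any() else np.zeros(na)
                )
                self._cache[key] = (counts, het_counts, idx.size)
        return self._cache[key]


def _counts_nall_sizevar(vals: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    tot = counts.sum()
    if tot == 0:
        return np.nan, np.nan
    nall = float((counts > 0).sum())
    mean = (counts * vals).sum() / tot
    var = (counts * vals.astype(float) ** 2).sum() / tot - mean ** 2
    return nall, float(max(var, 0.0))


def _ms_pooled_stats(ms: _MsSummary, pops: Sequence[str]) -> tuple[float, float]:
    """(mean allele count, mean allele-size variance) across loci for the
    pooled sample of ``pops``."""
    nall, svar = [], []
    for locus in range(ms.n_loci):
        vals = ms.loci[locus][0]
        if vals.size == 0:
            continue
        counts = np.zeros(vals.size)
        for p in pops:
            counts += ms.locus_counts(locus, p)[0]
        a, v = _counts_nall_sizevar(vals, counts)
        if not np.isnan(a):
            nall.append(a)
            svar.append(v)
    if not nall:
        log.debug("no typed loci in population subset; microsat stats set to 0")
        return 0.0, 0.0
    return float(np.mean(nall)), float(np.mean(svar))


def _wc_theta(ms: _MsSummary, popA: str, popB: str) -> float:
    """Weir-Cockerham theta over loci (ratio of sums over loci/alleles)."""
    r = 2
    num = den = 0.0
    for locus in range(ms.n_loci):
        cA, hA, nA = ms.locus_counts(locus, popA)
        cB, hB, nB = ms.locus_counts(locus, popB)
        if nA < 1 or nB < 1 or cA.size == 0:
            continue
        seen = (cA + cB) > 0
        if seen.sum() < 2:
            continue
        n = np.array([nA, nB], dtype=float)
        nbar = n.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
        if nc == 0:
            continue
        p = np.vstack([cA[seen] / (2 * nA), cB[seen] / (2 * nB)])  # (2, na)
        h = np.vstack([hA[seen] / nA, hB[seen] / nB])
        pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
        s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a.sum()
        den += (a + b + c).sum()
    if den == 0.0:
        log.debug("all loci monomorphic in pooled pair (%s, %s); F_ST -> 0",
                  popA, popB)
        return 0.0
    return float(num / den)


def fst_microsat(dataset: SimulatedDataset, popA: str, popB: str) -> float:
    """Weir-Cockerham theta across loci for one population pair.

    Computed from diploid genotypes with per-locus pairwise-complete
    samples; fully monomorphic pairs return the degenerate value 0.
    """
    ms = _MsSummary(dataset.genotypes, dataset.geno_pops)
    if ms.pop_idx(popA).size < 2 or ms.pop_idx(popB).size < 2:
        raise ValueError("both populations need at least 2 genotypes")
    return _wc_theta(ms, popA, popB)


def _das(ms: _MsSummary, popA: str, popB: str) -> float:
    g = np.sort(ms.genotypes, axis=2)
    A = g[ms.pop_idx(popA)]
    B = g[ms.pop_idx(popB)]
    x1, x2 = A[:, None, :, 0], A[:, None, :, 1]
    y1, y2 = B[None, :, :, 0], B[None, :, :, 1]
    same = (x1 == y1) & (x2 == y2)
    inter = (x1 == y1) | (x1 == y2) | (x2 == y1) | (x2 == y2)
    shared = np.where(same, 2.0, np.where(inter, 1.0, 0.0))
    valid = (x1 > 0) & (y1 > 0)
    nv = valid.sum(axis=2)
    with np.errstate(invalid="ignore"):
        per_pair = np.where(nv > 0, (shared * valid).sum(axis=2) / np.maximum(nv, 1) / 2.0, np.nan)
    vals = per_pair[~np.isnan(per_pair)]
    if vals.size == 0:
        log.debug("no comparable loci between %s and %s; DAS -> 0", popA, popB)
        return 0.0
    return float(1.0 - vals.mean())


def shared_allele_distance(dataset: SimulatedDataset, popA: str, popB: str) -> float:
    """DAS = 1 - mean proportion of alleles shared per locus between
    individuals of the two populations (allele-multiset intersection)."""
    ms = _MsSummary(dataset.genotypes, dataset.geno_pops)
    if ms.pop_idx(popA).size == 0 or ms.pop_idx(popB).size == 0:
        raise ValueError("both populations must be non-empty")
    return _das(ms, popA, popB)


def _directed_cli(ms: _MsSummary, pop_from: str, pop_to: str) -> float:
    """Mean HWE log-likelihood of ``pop_from`` genotypes under ``pop_to``
    allele frequencies, with an add-one pseudocount on the allele classes
    observed in the pooled pair."""
    idx_from = ms.pop_idx(pop_from)
    total = np.zeros(idx_from.size)
    log2 = np.log(2.0)
    for locus in range(ms.n_loci):
        vals, code, present = ms.loci[locus]
        if vals.size == 0:
            continue
        cF, _, _ = ms.locus_counts(locus, pop_from)
        cT, _, nT = ms.locus_counts(locus, pop_to)
        if cF.size == 0 or cT.size == 0:
            continue
        pooled = (cF + cT) > 0
        n_classes = int(pooled.sum())
        if n_classes == 0:
            continue
        logf = np.full(vals.size, -np.inf)
        logf[pooled] = np.log((cT[pooled] + 1.0) / (2 * nT + n_classes))
        sub = idx_from[present[idx_from]]
        local = np.zeros(idx_from.size)
        ok = present[idx_from]
        c = code[sub]
        local[ok] = logf[c[:, 0]] + logf[c[:, 1]] + log2 * (c[:, 0] != c[:, 1])
        total += local
    return float(total.mean())


def classification_index(dataset: SimulatedDataset, popA: str, popB: str) -> float:
    """Bidirectional mean genotype log-likelihood between two populations."""
    ms = _MsSummary(dataset.genotypes, dataset.geno_pops)
    if ms.pop_idx(popA).size == 0 or ms.pop_idx(popB).size == 0:
        raise ValueError("both populations must be non-empty")
    return 0.5 * (_directed_cli(ms, popA, popB) + _directed_cli(ms, popB, popA))


# ---------------------------------------------------------------------------
# Sequence decomposition
# ---------------------------------------------------------------------------

class _SeqSummary:
    """Unique-haplotype decomposition of the mtDNA alignment."""

    def __init__(self, sequences: np.ndarray, seq_pops: Sequence[str]):
        self.seq_pops = list(seq_pops)
        self._pop_idx: dict[str, np.ndarray] = {}
        if sequences.shape[0] == 0:
            self.u = np.empty((0, 0), dtype=np.int8)
            self.inv = np.empty(0, dtype=np.intp)
            self.D = np.empty((0, 0))
            return
        self.u, self.inv = np.unique(sequences, axis=0, return_inverse=True)
        nu = self.u.shape[0]
        valid = self.u < 4
        D = np.zeros((nu, nu))
        for i in range(nu):
            neq = (self.u[i] != self.u) & valid[i] & valid
            D[i] = neq.sum(axis=1)
        self.D = D

    def pop_idx(self, pop: str) -> np.ndarray:
        if pop not in self._pop_idx:
            self._pop_idx[pop] = _pop_indices(self.seq_pops, pop)
        return self._pop_idx[pop]

    def hap_counts(self, idx: np.ndarray) -> np.ndarray:
        return np.bincount(self.inv[idx], minlength=self.u.shape[0]).astype(float)

    def n_haplotypes(self, idx: np.ndarray) -> int:
        return int((self.hap_counts(idx) > 0).sum())

    def within_pi(self, idx: np.ndarray) -> tuple[float, float]:
        """Mean and population variance of pairwise differences within."""
        c = self.hap_counts(idx)
        n = c.sum()
        n_pairs = n * (n - 1) / 2.0
        if n_pairs == 0:
            return 0.0, 0.0
        cross = c @ self.D @ c / 2.0  # same-haplotype pairs contribute 0
        cross2 = c @ (self.D ** 2) @ c / 2.0
        mean = cross / n_pairs
        var = cross2 / n_pairs - mean ** 2
        return float(mean), float(max(var, 0.0))

    def between_pi(self, ia: np.ndarray, ib: np.ndarray) -> float:
        ca, cb = self.hap_counts(ia), self.hap_counts(ib)
        n_pairs = ca.sum() * cb.sum()
        if n_pairs == 0:
            return 0.0
        return float(ca @ self.D @ cb / n_pairs)

    def base_counts(self, idx: np.ndarray) -> np.ndarray:
        """(L, 4) counts of called bases at each site."""
        c = self.hap_counts(idx)
        L = self.u.shape[1]
        counts = np.zeros((L, 4))
        for b in range(4):
            counts[:, b] = c @ (self.u == b)
        return counts

    def rarest_site_stats(self, idx: np.ndarray) -> tuple[float, float]:
        """Mean/variance over segregating sites of the least frequent
        observed base count; (0, 0) when there is no segregating site."""
        counts = self.base_counts(idx)
        present = counts > 0
        seg = present.sum(axis=1) >= 2
        if not seg.any():
            log.debug("no segregating sites; rarest-nucleotide stats -> 0")
            return 0.0, 0.0
        masked = np.where(present[seg], counts[seg], np.inf)
        rarest = masked.min(axis=1)
        return float(rarest.mean()), float(rarest.var())


def _hap_identity_fst(ca: np.ndarray, cb: np.ndarray) -> float:
    """Two-population AMOVA F_ST on haplotype frequencies (identity
    distance), in closed form from per-population haplotype counts."""
    na, nb = ca.sum(), cb.sum()
    N = na + nb
    if na < 2 or nb < 2:
        return 0.0
    ssd_total = (N ** 2 - ((ca + cb) ** 2).sum()) / (2.0 * N)
    ssd_wp = (na ** 2 - (ca ** 2).sum()) / (2.0 * na) + (
        nb ** 2 - (cb ** 2).sum()
    ) / (2.0 * nb)
    ssd_ap = ssd_total - ssd_wp
    vb = ssd_wp / (N - 2)
    nc = (N - (na ** 2 + nb ** 2) / N)  # / (P - 1) with P = 2
    va = (ssd_ap - vb) / nc
    tot = va + vb
    if tot == 0.0:
        log.debug("single shared haplotype; haplotype F_ST -> 0")
        return 0.0
    return float(va / tot)


def fst_haplotype(dataset: SimulatedDataset, popA: str, popB: str) -> float:
    """F_ST on haplotype frequencies: two-population AMOVA with identity
    distance (d = 1 between distinct haplotypes)."""
    ss = _SeqSummary(dataset.sequences, dataset.seq_pops)
    ia, ib = ss.pop_idx(popA), ss.pop_idx(popB)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both populations need at least 2 sequences")
    return _hap_identity_fst(ss.hap_counts(ia), ss.hap_counts(ib))


# ---------------------------------------------------------------------------
# Vector assembly
# ---------------------------------------------------------------------------

def within_stats(
    dataset: SimulatedDataset,
    pop: str,
    _ms: _MsSummary | None = None,
    _ss: _SeqSummary | None = None,
) -> dict[str, float]:
    """The seven within-population statistics for one population."""
    if pop not in dataset.populations:
        raise ValueError(f"unknown population {pop!r}")
    ms = _ms if _ms is not None else _MsSummary(dataset.genotypes, dataset.geno_pops)
    ss = _ss if _ss is not None else _SeqSummary(dataset.sequences, dataset.seq_pops)
    si = ss.pop_idx(pop)
    nall, svar = _ms_pooled_stats(ms, [pop])
    pi_mean, pi_var = ss.within_pi(si)
    r_mean, r_var = ss.rarest_site_stats(si)
    return {
        "ms_nall": nall,
        "ms_sizevar": svar,
        "mt_nhap": float(ss.n_haplotypes(si)),
        "mt_pi_mean": pi_mean,
        "mt_pi_var": pi_var,
        "mt_rarest_mean": r_mean,
        "mt_rarest_var": r_var,
    }


def summary_stat_names(pops: Sequence[str]) -> list[str]:
    names = [f"{p}_{s}" for p in pops for s in WITHIN_STATS]
    for a, b in combinations(pops, 2):
        names.extend(f"{a}_{b}_{s}" for s in PAIR_STATS)
    return names


def summarize(dataset: SimulatedDataset, pops: Sequence[str]) -> np.ndarray:
    """Reduce a dataset to the canonical summary-statistic vector for the
    given (ordered) population set."""
    ms = _MsSummary(dataset.genotypes, dataset.geno_pops)
    ss = _SeqSummary(dataset.sequences, dataset.seq_pops)
    values: list[float] = []
    for p in pops:
        w = within_stats(dataset, p, _ms=ms, _ss=ss)
        values.extend(w[s] for s in WITHIN_STATS)
    for a, b in combinations(pops, 2):
        nall, svar = _ms_pooled_stats(ms, [a, b])
        sa, sb = ss.pop_idx(a), ss.pop_idx(b)
        pia = ss.within_pi(sa)[0]
        pib = ss.within_pi(sb)[0]
        values.extend(
            [
                nall,
                svar,
                _wc_theta(ms, a, b),
                _das(ms, a, b),
                0.5 * (_directed_cli(ms, a, b) + _directed_cli(ms, b, a)),
                float(ss.n_haplotypes(np.concatenate([sa, sb]))),
                _hap_identity_fst(ss.hap_counts(sa), ss.hap_counts(sb)),
                0.5 * (pia + pib),
                ss.between_pi(sa, sb),
            ]
        )
    return np.asarray(values)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

def build_reference_table(
    scenarios: Sequence[ScenarioSpec],
    priors: PriorSpec,
    n_per_scenario: int,
    sample_config: Mapping[str, tuple[int, int]],
    rng: np.random.Generator,
    n_loci: int = 9,
    seq_length: int = 401,
    progress: Callable[[int, int], None] | None = None,
) -> pd.DataFrame:
    """Simulate ``n_per_scenario`` datasets per scenario and reduce each to
    its summary vector.

    Columns: ``scenario``, then the parameter names in prior order, then
    the statistic names.  Deterministic for a fixed generator state.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    pops = [p for p in scenarios[0].populations if p in sample_config]
    param_names = list(priors.params)
    stat_names = summary_stat_names(pops)
    rows = np.empty(
        (len(scenarios) * n_per_scenario, 1 + len(param_names) + len(stat_names))
    )
    total = len(scenarios) * n_per_scenario
    k = 0
    for sc in scenarios:
        for _ in range(n_per_scenario):
            draw = sample_parameters(sc, priors, rng)
            ds = simulate_dataset(
                sc, draw, sample_config, rng, n_loci=n_loci, seq_length=seq_length
            )
            rows[k, 0] = sc.scenario_id
            rows[k, 1 : 1 + len(param_names)] = [draw[p] for p in param_names]
            rows[k, 1 + len(param_names) :] = summarize(ds, pops)
            k += 1
            if progress is not None:
                progress(k, total)
    return pd.DataFrame(rows, columns=["scenario"] + param_names + stat_names)


def observed_vector(dataset: SimulatedDataset, pops: Sequence[str]) -> pd.Series:
    """One-row observed summary vector with reference-table column names."""
    return pd.Series(summarize(dataset, pops), index=summary_stat_names(pops))
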