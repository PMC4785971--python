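"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from textbook definitions with plain
loops and no shared code with the package, so agreement is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# AMOVA (three-level, Excoffier sums of squares)
# ---------------------------------------------------------------------------

def amova_components_bruteforce(d2, pop_idx, grp_of_pop):
    """Variance components (Va, Vb, Vc) from explicit double sums."""
    d2 = np.asarray(d2, float)
    pop_idx = np.asarray(pop_idx)
    grp_of_pop = np.asarray(grp_of_pop)
    grp_idx = grp_of_pop[pop_idx]
    N = len(pop_idx)
    pops = np.unique(pop_idx)
    grps = np.unique(grp_idx)
    P, G = len(pops), len(grps)

    def ssd_within(labels):
        total = 0.0
        for lab in np.unique(labels):
            members = [i for i in range(N) if labels[i] == lab]
            s = 0.0
            for i in members:
                for j in members:
                    s += d2[i, j]
            total += s / (2 * len(members))
        return total

    ssd_total = sum(d2[i, j] for i in range(N) for j in range(N)) / (2 * N)
    ssd_wp = ssd_within(pop_idx)
    ssd_wg = ssd_within(grp_idx)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    n_p = {p: int((pop_idx == p).sum()) for p in pops}
    n_g = {g: int((grp_idx == g).sum()) for g in grps}
    sum_np2_over_ng = sum(n_p[p] ** 2 / n_g[grp_of_pop[p]] for p in pops)
    n1 = (N - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - sum(n_p[p] ** 2 for p in pops) / N) / (G - 1)
    n3 = (N - sum(n_g[g] ** 2 for g in grps) / N) / (G - 1)

    vc = ssd_wp / (N - P)
    vb = (ssd_ap / (P - G) - vc) / n1
    va = (ssd_ag / (G - 1) - vc - n2 * vb) / n3
    return va, vb, vc


def two_level_fst_bruteforce(d2, labels):
    """Two-level AMOVA F_ST from explicit sums."""
    d2 = np.asarray(d2, float)
    labels = np.asarray(labels)
    N = len(labels)
    pops = np.unique(labels)
    P = len(pops)
    ssd_total = d2.sum() / (2 * N)
    ssd_wp = 0.0
    for p in pops:
        members = np.flatnonzero(labels == p)
        ssd_wp += d2[np.ix_(members, members)].sum() / (2 * len(members))
    ssd_ap = ssd_total - ssd_wp
    n_p = np.array([(labels == p).sum() for p in pops], float)
    nc = (N - (n_p ** 2).sum() / N) / (P - 1)
    vb = ssd_wp / (N - P)
    va = (ssd_ap / (P - 1) - vb) / nc
    return va / (va + vb) if (va + vb) != 0 else 0.0


# ---------------------------------------------------------------------------
# Weir & Cockerham theta, per-allele loops
# ---------------------------------------------------------------------------

def wc_theta_bruteforce(genotypes_a, genotypes_b):
    """theta from two (n_i, L, 2) genotype arrays (0 = missing)."""
    num = den = 0.0
    L = genotypes_a.shape[1]
    for locus in range(L):
        ga = genotypes_a[:, locus, :]
        gb = genotypes_b[:, locus, :]
        ga = ga[(ga > 0).all(axis=1)]
        gb = gb[(gb > 0).all(axis=1)]
        if len(ga) < 1 or len(gb) < 1:
            continue
        alleles = sorted(set(ga.ravel()) | set(gb.ravel()))
        if len(alleles) < 2:
            continue
        n = [len(ga), len(gb)]
        r = 2
        nbar = sum(n) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(x ** 2 for x in n) / (r * nbar)) / (r - 1)
        if nc == 0:
            continue
        for al in alleles:
            p = [(g == al).sum() / (2 * len(g)) for g in (ga, gb)]
            h = [sum(1 for row in g if (row == al).sum() == 1) / len(g)
                 for g in (ga, gb)]
            pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
            s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
            hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den if den != 0 else 0.0


# ---------------------------------------------------------------------------
# Rarefaction by exhaustive enumeration
# ---------------------------------------------------------------------------

def rarefied_richness_enumeration(allele_counts, g):
    """Average allele count over all C(N, g) subsamples of gene copies."""
    copies = []
    for allele, c in allele_counts.items():
        copies.extend([allele] * c)
    totals = []
    for subset in combinations(range(len(copies)), g):
        totals.append(len({copies[i] for i in subset}))
    return float(np.mean(totals))


# ---------------------------------------------------------------------------
# Summary statistics by direct definition
# ---------------------------------------------------------------------------

def _pop_rows(labels, pop):
    return [i for i, p in enumerate(labels) if p == pop]


def ms_nall_sizevar_bruteforce(genotypes, labels, pops):
    """Pooled mean allele number and mean allele-size variance."""
    rows = [i for p in pops for i in _pop_rows(labels, p)]
    L = genotypes.shape[1]
    nall, svar = [], []
    for locus in range(L):
        vals = [a for i in rows for a in genotypes[i, locus] if a > 0]
        if not vals:
            continue
        nall.append(len(set(vals)))
        m = np.mean(vals)
        svar.append(np.mean([(v - m) ** 2 for v in vals]))
    return (float(np.mean(nall)), float(np.mean(svar))) if nall else (0.0, 0.0)


def seq_pi_bruteforce(seqs, rows):
    """Mean and population variance of pairwise difference counts."""
    diffs = []
    for i, j in combinations(rows, 2):
        a, b = seqs[i], seqs[j]
        d = sum(1 for x, y in zip(a, b) if x < 4 and y < 4 and x != y)
        diffs.append(d)
    if not diffs:
        return 0.0, 0.0
    m = np.mean(diffs)
    return float(m), float(np.mean([(d - m) ** 2 for d in diffs]))


def seq_pi_between_bruteforce(seqs, rows_a, rows_b):
    diffs = [
        sum(1 for x, y in zip(seqs[i], seqs[j]) if x < 4 and y < 4 and x != y)
        for i in rows_a for j in rows_b
    ]
    return float(np.mean(diffs)) if diffs else 0.0


def n_haplotypes_bruteforce(seqs, rows):
    return len({tuple(seqs[i]) for i in rows})


def rarest_stats_bruteforce(seqs, rows):
    L = seqs.shape[1]
    rarest = []
    for site in range(L):
        counts = {}
        for i in rows:
            b = seqs[i, site]
            if b < 4:
                counts[b] = counts.get(b, 0) + 1
        if len(counts) >= 2:
            rarest.append(min(counts.values()))
    if not rarest:
        return 0.0, 0.0
    m = np.mean(rarest)
    return float(m), float(np.mean([(x - m) ** 2 for x in rarest]))


def das_bruteforce(genotypes, labels, popA, popB):
    rows_a = _pop_rows(labels, popA)
    rows_b = _pop_rows(labels, popB)
    L = genotypes.shape[1]
    props = []
    for i in rows_a:
        for j in rows_b:
            vals = []
            for locus in range(L):
                gi = [a for a in genotypes[i, locus] if a > 0]
                gj = [a for a in genotypes[j, locus] if a > 0]
                if not gi or not gj:
                    continue
                shared = 0
                gj_left = list(gj)
                for a in gi:
                    if a in gj_left:
                        shared += 1
                        gj_left.remove(a)
                vals.append(shared / 2.0)
            if vals:
                props.append(np.mean(vals))
    return float(1.0 - np.mean(props)) if props else 0.0


def cli_bruteforce(genotypes, labels, popA, popB):
    def directed(rows_from, rows_to):
        L = genotypes.shape[1]
        lls = []
        for i in rows_from:
            total = 0.0
            for locus in range(L):
                pool = set()
                for r in rows_from + rows_to:
                    for a in genotypes[r, locus]:
                        if a > 0:
                            pool.add(a)
                if not pool:
                    continue
                ref = [a for r in rows_to for a in genotypes[r, locus] if a > 0]
                a1, a2 = genotypes[i, locus]
                if a1 == 0:
                    continue
                def freq(al):
                    return (ref.count(al) + 1) / (len(ref) + len(pool))
                ll = np.log(freq(a1)) + np.log(freq(a2))
                if a1 != a2:
                    ll += np.log(2)
                total += ll
            lls.append(total)
        return np.mean(lls)

    ra, rb = _pop_rows(labels, popA), _pop_rows(labels, popB)
    return float(0.5 * (directed(ra, rb) + directed(rb, ra)))


def hap_fst_bruteforce(seqs, labels, popA, popB):
    rows = _pop_rows(labels, popA) + _pop_rows(labels, popB)
    haps = {}
    for i in rows:
        haps.setdefault(tuple(seqs[i]), len(haps))
    h = [haps[tuple(seqs[i])] for i in rows]
    n = len(rows)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = 1.0 if h[i] != h[j] else 0.0
    lab = [labels[i] for i in rows]
    return two_level_fst_bruteforce(d2, lab)


def summary_vector_bruteforce(dataset, pops):
    """Full summary vector from the direct definitions above."""
    g = dataset.genotypes
    gl = dataset.geno_pops
    s = dataset.sequences
    sl = dataset.seq_pops
    values = []
    for p in pops:
        rows = _pop_rows(sl, p)
        nall, svar = ms_nall_sizevar_bruteforce(g, gl, [p])
        pi_m, pi_v = seq_pi_bruteforce(s, rows)
        r_m, r_v = rarest_stats_bruteforce(s, rows)
        values += [nall, svar, n_haplotypes_bruteforce(s, rows), pi_m, pi_v, r_m, r_v]
    for a, b in combinations(pops, 2):
        nall, svar = ms_nall_sizevar_bruteforce(g, gl, [a, b])
        ga = g[_pop_rows(gl, a)]
        gb = g[_pop_rows(gl, b)]
        ra, rb = _pop_rows(sl, a), _pop_rows(sl, b)
        pia = seq_pi_bruteforce(s, ra)[0]
        pib = seq_pi_bruteforce(s, rb)[0]
        values += [
            nall,
            svar,
            wc_theta_bruteforce(ga, gb),
            das_bruteforce(g, gl, a, b),
            cli_bruteforce(g, gl, a, b),
            n_haplotypes_bruteforce(s, ra + rb),
            hap_fst_bruteforce(s, sl, a, b),
            0.5 * (pia + pib),
            seq_pi_between_bruteforce(s, ra, rb),
        ]
    return np.array(values)
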