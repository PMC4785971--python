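"""Rejection, model choice, regression adjustment and model checking."""

import numpy as np
import pandas as pd
import pytest

import ecoabc
from ecoabc.demography import ParameterDraw, PriorSpec, ScenarioSpec


def _toy_table(rng, n=100, n_stats=4, n_scen=2):
    stats = {f"x{i}": rng.normal(size=n) for i in range(n_stats)}
    table = pd.DataFrame(
        {"scenario": np.repeat(np.arange(1, n_scen + 1), n // n_scen),
         "theta": rng.uniform(0, 1, n), **stats}
    )
    return table


class TestRejection:
    def test_tolerance_one_accepts_everything(self, rng):
        table = _toy_table(rng)
        obs = table.iloc[0][[c for c in table if c.startswith("x")]]
        rej = ecoabc.abc_reject(table, obs, tolerance=1.0)
        assert len(rej.accepted) == len(table)

    def test_exact_match_ranks_first(self, rng):
        table = _toy_table(rng)
        obs = table.iloc[17][[c for c in table if c.startswith("x")]]
        rej = ecoabc.abc_reject(table, obs, tolerance=0.1)
        assert rej.accepted[0] == 17
        assert rej.distances[0] == 0.0

    def test_accepted_set_equals_exhaustive_sort(self, rng):
        table = _toy_table(rng, n=100)
        cols = [c for c in table if c.startswith("x")]
        obs = pd.Series(rng.normal(size=len(cols)), index=cols)
        rej = ecoabc.abc_reject(table, obs, tolerance=0.2)
        X = table[cols].to_numpy()
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0)
        d = np.sqrt((((X - obs.to_numpy()) / mad) ** 2).sum(axis=1))
        expected = np.argsort(d, kind="stable")[:20]
        assert np.array_equal(rej.accepted, expected)

    def test_distance_invariant_to_affine_scaling(self, rng):
        table = _toy_table(rng)
        cols = [c for c in table if c.startswith("x")]
        obs = pd.Series(rng.normal(size=len(cols)), index=cols)
        rej1 = ecoabc.abc_reject(table, obs, tolerance=0.1)
        scaled = table.copy()
        scaled["x0"] = scaled["x0"] * 100 + 3
        obs2 = obs.copy()
        obs2["x0"] = obs2["x0"] * 100 + 3
        rej2 = ecoabc.abc_reject(scaled, obs2, tolerance=0.1)
        assert np.array_equal(rej1.accepted, rej2.accepted)
        assert np.allclose(rej1.distances, rej2.distances)

    def test_column_mismatch_errors(self, rng):
        table = _toy_table(rng)
        obs = pd.Series([0.0], index=["unknown_stat"])
        with pytest.raises(ValueError, match="missing"):
            ecoabc.abc_reject(table, obs)


class TestModelChoice:
    def test_single_scenario_accepted_gives_probability_one(self, rng):
        table = _toy_table(rng)
        cols = [c for c in table if c.startswith("x")]
        # push scenario 1 rows tightly around the observed point
        table.loc[table["scenario"] == 1, cols] = rng.normal(scale=1e-3,
                                                             size=(50, len(cols)))
        obs = pd.Series(np.zeros(len(cols)), index=cols)
        rej = ecoabc.abc_reject(table, obs, tolerance=0.2)
        res = ecoabc.model_posteriors(table, rej, obs, n_boot=10, rng=rng)
        assert res.probabilities[1] == pytest.approx(1.0)
        assert res.best() == 1

    def test_separable_scenarios_resolve_sharply(self, rng):
        n = 200
        cols = ["s0", "s1"]
        table = pd.DataFrame(
            {
                "scenario": np.repeat([1, 2], n // 2),
                "theta": rng.uniform(size=n),
                "s0": np.r_[rng.normal(0, 0.05, n // 2), rng.normal(2, 0.05, n // 2)],
                "s1": rng.normal(size=n),
            }
        )
        obs = pd.Series([2.0, 0.0], index=cols)
        rej = ecoabc.abc_reject(table, obs, tolerance=0.5)
        res = ecoabc.model_posteriors(table, rej, obs, n_boot=10, rng=rng)
        assert res.probabilities[2] > 0.99

    def test_probabilities_sum_to_one_and_intervals_cover_point(self, rng):
        table = _toy_table(rng, n=120, n_scen=3)
        cols = [c for c in table if c.startswith("x")]
        obs = pd.Series(rng.normal(size=len(cols)), index=cols)
        rej = ecoabc.abc_reject(table, obs, tolerance=0.5)
        res = ecoabc.model_posteriors(table, rej, obs, n_boot=30, rng=rng)
        assert sum(res.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
        for s, p in res.probabilities.items():
            lo, hi = res.intervals[s]
            assert lo - 1e-12 <= p <= hi + 1e-12

    def test_uninformative_statistics_return_prior(self, rng):
        # constant stats: falls back to weighted frequencies = 1/S
        n = 90
        table = pd.DataFrame(
            {
                "scenario": np.repeat([1, 2, 3], n // 3),
                "s0": np.zeros(n),
                "s1": rng.normal(scale=1e-12, size=n),
            }
        )
        obs = pd.Series([0.0, 0.0], index=["s0", "s1"])
        rej = ecoabc.abc_reject(table, obs, tolerance=1.0)
        res = ecoabc.model_posteriors(table, rej, obs, n_boot=0, rng=rng)
        for s in (1, 2, 3):
            assert res.probabilities[s] == pytest.approx(1 / 3, abs=0.05)


class TestParameterEstimation:
    def _linear_table(self, rng, n=400, slope=50.0, noise=1.0):
        s = rng.normal(size=n)
        theta = 500.0 + slope * s + rng.normal(scale=noise, size=n)
        return pd.DataFrame(
            {"scenario": 1, "t1": np.clip(theta, 10, 1000), "s0": s}
        )

    def test_constant_parameter_recovered_exactly(self, rng):
        table = pd.DataFrame(
            {"scenario": 1, "t1": np.full(200, 321.0),
             "s0": rng.normal(size=200)}
        )
        priors = PriorSpec({"t1": ("uniform", 10.0, 1000.0)})
        obs = pd.Series([0.0], index=["s0"])
        post = ecoabc.estimate_parameters(table, None, obs, 1, priors,
                                          tolerance=0.5)
        assert np.allclose(post.draws["t1"], 321.0, atol=1e-6)

    def test_linear_relation_recovered(self, rng):
        table = self._linear_table(rng)
        priors = PriorSpec({"t1": ("uniform", 10.0, 1000.0)})
        obs = pd.Series([1.0], index=["s0"])  # true theta ~ 550
        post = ecoabc.estimate_parameters(table, None, obs, 1, priors,
                                          tolerance=0.5)
        med = post.quantile("t1", 0.5)
        assert abs(med - 550.0) < 10.0

    def test_weights_normalised_and_draws_in_support(self, rng):
        table = self._linear_table(rng, noise=30.0)
        priors = PriorSpec({"t1": ("uniform", 10.0, 1000.0)})
        obs = pd.Series([2.5], index=["s0"])
        post = ecoabc.estimate_parameters(table, None, obs, 1, priors,
                                          tolerance=0.3)
        assert post.weights.sum() == pytest.approx(1.0)
        assert post.draws["t1"].between(10.0, 1000.0).all()

    def test_years_conversion_in_summary(self, rng):
        table = self._linear_table(rng)
        priors = PriorSpec({"t1": ("uniform", 10.0, 1000.0)})
        obs = pd.Series([0.0], index=["s0"])
        post = ecoabc.estimate_parameters(table, None, obs, 1, priors,
                                          tolerance=0.5)
        s = post.summary()
        assert s.loc["t1", "median_years"] == pytest.approx(
            7 * s.loc["t1", "median"]
        )

    def test_too_few_accepted_rows_error(self, rng):
        table = self._linear_table(rng, n=60)
        priors = PriorSpec({"t1": ("uniform", 10.0, 1000.0)})
        obs = pd.Series([0.0], index=["s0"])
        with pytest.raises(ValueError, match="enlarge the reference table"):
            ecoabc.estimate_parameters(table, None, obs, 1, priors,
                                       tolerance=0.1)


class TestModelCheck:
    def test_edge_case_single_predictive_draw(self, rng):
        sc = ScenarioSpec(1, ["A", "B"],
                          [ecoabc.demography.DemographicEvent(
                              "t", "merge", "B", dest="A")])
        draws = pd.DataFrame(
            {"N_A": [500.0], "N_B": [500.0], "t": [100.0],
             "mu_ms": [1e-4], "mu_mt": [1e-6]}
        )
        post = ecoabc.PosteriorSample(1, draws, np.array([1.0]))
        cfg = {"A": (4, 4), "B": (4, 4)}
        names = ecoabc.summary_stat_names(["A", "B"])
        obs = pd.Series(np.zeros(len(names)), index=names)
        res = ecoabc.model_check(sc, post, cfg, obs, n_pp=1, rng=rng)
        assert set(np.round(res.tail_probabilities, 6)) <= {0.0, 1.0}

    def test_constructed_outlier_flagged(self, rng):
        sc = ScenarioSpec(1, ["A", "B"],
                          [ecoabc.demography.DemographicEvent(
                              "t", "merge", "B", dest="A")])
        draws = pd.DataFrame(
            {"N_A": np.full(20, 400.0), "N_B": np.full(20, 400.0),
             "t": np.full(20, 200.0), "mu_ms": np.full(20, 1e-4),
             "mu_mt": np.full(20, 1e-6)}
        )
        post = ecoabc.PosteriorSample(1, draws, np.full(20, 0.05))
        cfg = {"A": (6, 6), "B": (6, 6)}
        names = ecoabc.summary_stat_names(["A", "B"])
        obs = pd.Series(np.zeros(len(names)), index=names)
        obs["A_ms_nall"] = 1000.0  # far outside any predictive range
        res = ecoabc.model_check(sc, post, cfg, obs, n_pp=200, rng=rng)
        assert res.tail_probabilities["A_ms_nall"] < 0.01


class TestConfusion:
    def test_rows_sum_and_reproducibility(self):
        priors = PriorSpec(
            {
                "t": ("uniform", 100.0, 200.0),
                "N_A": ("uniform", 300.0, 600.0),
                "N_B": ("uniform", 300.0, 600.0),
                "mu_ms": ("uniform", 1e-4, 1e-4),
                "mu_mt": ("uniform", 1e-6, 1e-6),
            }
        )
        ev = ecoabc.demography.DemographicEvent("t", "merge", "B", dest="A")
        scs = [ScenarioSpec(1, ["A", "B"], [ev]),
               ScenarioSpec(2, ["A", "B"], [ev])]
        cfg = {"A": (5, 5), "B": (5, 5)}
        m1 = ecoabc.confusion_experiment(
            scs, priors, 30, 3, cfg, np.random.default_rng(5), tolerance=0.2
        )
        m2 = ecoabc.confusion_experiment(
            scs, priors, 30, 3, cfg, np.random.default_rng(5), tolerance=0.2
        )
        assert (m1.sum(axis=1) == 3).all()
        assert m1.equals(m2)
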