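"""Approximate Bayesian computation: rejection, scenario choice and
parameter estimation.

Rejection normalises every summary statistic by its median absolute
deviation over the full reference table and keeps the fraction of
simulations closest (Euclidean distance) to the observed vector.
Scenario posterior probabilities follow the DIYABC recipe: the accepted
statistics are projected onto linear discriminant axes and a weighted
polychotomic logistic regression (Epanechnikov kernel in the rejection
distance) is evaluated at the observed point; credible intervals come
from bootstrap resampling of the accepted set.  Parameter estimation is
Beaumont-style local-linear regression adjustment with bounded
parameters adjusted on the logit scale of their prior support, which
keeps every adjusted draw inside the prior bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, RidgeCV

from .coalsim import simulate_dataset
from .demography import ParameterDraw, PriorSpec, ScenarioSpec, sample_parameters, to_years
from .sumstats import build_reference_table, observed_vector, summary_stat_names

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionResult:
    accepted: np.ndarray          # row indices, sorted by distance
    distances: np.ndarray         # matching distances, ascending
    tolerance: float
    stat_columns: list[str]       # columns kept after zero-MAD filtering
    scale: np.ndarray             # MAD per kept column


def _stat_columns(ref_table: pd.DataFrame, observed: pd.Series) -> list[str]:
    missing = [c for c in observed.index if c not in ref_table.columns]
    if missing:
        raise ValueError(f"observed statistics missing from table: {missing[:5]}")
    return list(observed.index)


def abc_reject(
    ref_table: pd.DataFrame,
    observed: pd.Series,
    tolerance: float = 0.01,
) -> RejectionResult:
    """Keep the ``ceil(tolerance * n_rows)`` simulations closest to the
    observed vector in MAD-normalised Euclidean distance.

    Zero-MAD statistic columns are dropped (logged); distance ties at the
    acceptance boundary break by row index (stable sort).
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    cols = _stat_columns(ref_table, observed)
    X = ref_table[cols].to_numpy(float)
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    keep = mad > 0
    if not keep.all():
        log.debug("dropping %d zero-MAD statistic columns", (~keep).sum())
    if not keep.any():
        raise ValueError("all statistic columns are constant in the table")
    cols = [c for c, k in zip(cols, keep) if k]
    X = X[:, keep] / mad[keep]
    obs = observed[cols].to_numpy(float) / mad[keep]
    d = np.sqrt(((X - obs) ** 2).sum(axis=1))
    n_keep = int(np.ceil(tolerance * len(ref_table)))
    order = np.argsort(d, kind="stable")[:n_keep]
    return RejectionResult(order, d[order], tolerance, cols, mad[keep])


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    scenario_ids: list[int]
    probabilities: dict[int, float]
    intervals: dict[int, tuple[float, float]]
    method: str
    n_accepted: int = 0

    def best(self) -> int:
        return max(self.probabilities, key=self.probabilities.get)


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    return np.clip(1.0 - (d / dmax) ** 2, 0.0, None) + 1e-12


def model_posteriors(
    ref_table: pd.DataFrame,
    rejection: RejectionResult,
    observed: pd.Series,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> ModelChoiceResult:
    """Per-scenario posterior probabilities at the observed point.

    Accepted statistics are projected onto at most S-1 discriminant axes,
    then a distance-weighted multinomial logistic regression is evaluated
    at the observed point.  Falls back to raw statistics if the
    projection is singular, and to weighted category frequencies if the
    regression itself is degenerate.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    all_ids = sorted(int(s) for s in ref_table["scenario"].unique())
    labels = ref_table["scenario"].to_numpy(int)[rejection.accepted]
    present = sorted(set(labels.tolist()))
    if len(present) == 1:
        probs = {s: 1.0 if s == present[0] else 0.0 for s in all_ids}
        ivals = {s: (p, p) for s, p in probs.items()}
        return ModelChoiceResult(all_ids, probs, ivals, "degenerate-single-scenario",
                                 len(labels))
    X = ref_table[rejection.stat_columns].to_numpy(float)[rejection.accepted]
    X = X / rejection.scale
    obs = observed[rejection.stat_columns].to_numpy(float) / rejection.scale
    w = _epanechnikov(rejection.distances)
    method = "lda+logistic"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda = LinearDiscriminantAnalysis(
                n_components=min(len(present) - 1, X.shape[1])
            )
            Z = lda.fit(X, labels).transform(X)
            z_obs = lda.transform(obs.reshape(1, -1))
        if not np.isfinite(Z).all():
            raise ValueError("non-finite discriminant projection")
    except Exception:  # singular projection: regress on raw statistics
        Z, z_obs = X, obs.reshape(1, -1)
        method = "logistic-raw"

    def _fit_probs(Zb, lab_b, wb) -> dict[int, float] | None:
        if len(set(lab_b.tolist())) == 1:
            only = int(lab_b[0])
            return {s: 1.0 if s == only else 0.0 for s in all_ids}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = LogisticRegression(penalty=None, max_iter=500)
                clf.fit(Zb, lab_b, sample_weight=wb)
                p = clf.predict_proba(z_obs)[0]
            out = {s: 0.0 for s in all_ids}
            for cls, pi in zip(clf.classes_, p):
                out[int(cls)] = float(pi)
            return out
        except Exception:
            return None

    probs = _fit_probs(Z, labels, w)
    if probs is None:
        log.warning("logistic regression degenerate; using weighted frequencies")
        method = "weighted-frequencies"
        probs = {
            s: float(w[labels == s].sum() / w.sum()) for s in all_ids
        }
    boot: dict[int, list[float]] = {s: [] for s in all_ids}
    n = len(labels)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        pb = _fit_probs(Z[idx], labels[idx], w[idx])
        if pb is None:
            wb = w[idx]
            lab_b = labels[idx]
            pb = {s: float(wb[lab_b == s].sum() / wb.sum()) for s in all_ids}
        for s in all_ids:
            boot[s].append(pb[s])
    ivals = {}
    for s in all_ids:
        lo, hi = np.percentile(boot[s], [2.5, 97.5]) if boot[s] else (probs[s], probs[s])
        ivals[s] = (float(min(lo, probs[s])), float(max(hi, probs[s])))
    total = sum(probs.values())
    probs = {s: p / total for s, p in probs.items()}
    return ModelChoiceResult(all_ids, probs, ivals, method, n)


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    scenario_id: int
    draws: pd.DataFrame           # adjusted parameter draws
    weights: np.ndarray           # normalised, sum to 1

    def quantile(self, param: str, q: float | Sequence[float]):
        x = self.draws[param].to_numpy()
        order = np.argsort(x)
        cw = np.cumsum(self.weights[order])
        cw /= cw[-1]
        return np.interp(q, cw, x[order])

    def summary(self, generation_time: float = 7.0) -> pd.DataFrame:
        rows = {}
        for p in self.draws.columns:
            q025, med, q975 = self.quantile(p, [0.025, 0.5, 0.975])
            row = {"median": med, "q2.5": q025, "q97.5": q975}
            if p.startswith("t"):
                row["median_years"] = to_years(med, generation_time)
                row["q2.5_years"] = to_years(q025, generation_time)
                row["q97.5_years"] = to_years(q975, generation_time)
            rows[p] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def _logit(u: np.ndarray) -> np.ndarray:
    return np.log(u) - np.log1p(-u)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def estimate_parameters(
    ref_table: pd.DataFrame,
    rejection: RejectionResult | None,
    observed: pd.Series,
    scenario_id: int,
    priors: PriorSpec,
    tolerance: float = 0.05,
    min_accepted: int = 50,
    params: Sequence[str] | None = None,
) -> PosteriorSample:
    """Local-linear regression-adjusted posterior for one scenario.

    When ``rejection`` is None a fresh rejection with ``tolerance`` is run
    on the rows of ``scenario_id`` alone (the usual practice once a
    scenario has been selected); otherwise the accepted rows belonging to
    that scenario are used.
    """
    sub = ref_table[ref_table["scenario"] == scenario_id]
    if rejection is None:
        sub = sub.reset_index(drop=True)
        rej = abc_reject(sub, observed, tolerance)
        rows = sub.iloc[rej.accepted]
        dist = rej.distances
        cols, scale = rej.stat_columns, rej.scale
    else:
        mask = ref_table["scenario"].to_numpy(int)[rejection.accepted] == scenario_id
        rows = ref_table.iloc[rejection.accepted[mask]]
        dist = rejection.distances[mask]
        cols, scale = rejection.stat_columns, rejection.scale
    if len(rows) < min_accepted:
        raise ValueError(
            f"only {len(rows)} accepted simulations for scenario {scenario_id} "
            f"(floor {min_accepted}); enlarge the reference table"
        )
    if params is None:
        params = [p for p in priors.params if p in ref_table.columns]
    w = _epanechnikov(dist)
    w = w / w.sum()
    S = rows[cols].to_numpy(float) / scale
    s_obs = observed[cols].to_numpy(float) / scale
    Xc = S - s_obs
    # regularised local-linear adjustment: with a summary vector of this
    # dimension an unpenalised fit on a few hundred accepted draws overfits
    # and yields overconfident posteriors, so the slope is estimated by
    # ridge regression with leave-one-out cross-validated penalty
    adjust = len(rows) > Xc.shape[1] // 4
    if not adjust:
        log.warning(
            "too few accepted draws (%d) for %d statistics; skipping the "
            "regression adjustment", len(rows), Xc.shape[1],
        )
    adjusted = {}
    for p in params:
        lo, hi = priors.bounds(p)
        theta = rows[p].to_numpy(float)
        if hi <= lo or not adjust:
            adjusted[p] = theta
            continue
        u = np.clip((theta - lo) / (hi - lo), 1e-9, 1 - 1e-9)
        y = _logit(u)
        reg = RidgeCV(alphas=np.logspace(-2, 4, 13))
        reg.fit(Xc, y, sample_weight=w)
        # statistics are centred at the observed point, so the intercept is
        # the local prediction there
        y_adj = reg.intercept_ + (y - reg.predict(Xc))
        adjusted[p] = lo + (hi - lo) * _expit(y_adj)
    return PosteriorSample(scenario_id, pd.DataFrame(adjusted), w)


# ---------------------------------------------------------------------------
# Model checking
# ---------------------------------------------------------------------------

@dataclass
class GofResult:
    tail_probabilities: pd.Series
    n_pp: int

    def fraction_below(self, alpha: float = 0.05) -> float:
        return float((self.tail_probabilities < alpha).mean())


def model_check(
    scenario: ScenarioSpec,
    posterior: PosteriorSample,
    sample_config: Mapping[str, tuple[int, int]],
    observed: pd.Series,
    n_pp: int = 500,
    rng: np.random.Generator | None = None,
    n_loci: int = 9,
    seq_length: int = 401,
) -> GofResult:
    """Posterior-predictive check: simulate under weighted posterior draws
    and report two-sided tail probabilities per summary statistic."""
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if len(posterior.draws) == 0:
        raise ValueError("empty posterior")
    pops = [p for p in scenario.populations if p in sample_config]
    names = summary_stat_names(pops)
    idx = rng.choice(len(posterior.draws), size=n_pp, p=posterior.weights)
    sims = np.empty((n_pp, len(names)))
    for k, i in enumerate(idx):
        values = {c: float(posterior.draws.iloc[i][c]) for c in posterior.draws.columns}
        ds = simulate_dataset(
            scenario, ParameterDraw(values), sample_config, rng,
            n_loci=n_loci, seq_length=seq_length,
        )
        sims[k] = observed_vector(ds, pops).to_numpy()
    obs = observed[names].to_numpy(float)
    lower = (sims <= obs).mean(axis=0)
    upper = (sims >= obs).mean(axis=0)
    tails = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return GofResult(pd.Series(tails, index=names), n_pp)


# ---------------------------------------------------------------------------
# Validation harness
# ---------------------------------------------------------------------------

def confusion_experiment(
    scenarios: Sequence[ScenarioSpec],
    priors: PriorSpec,
    n_train: int,
    n_test: int,
    sample_config: Mapping[str, tuple[int, int]],
    rng: np.random.Generator,
    tolerance: float = 0.05,
    n_loci: int = 9,
    seq_length: int = 401,
    ref_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate pseudo-observed datasets from each scenario and count how
    often each scenario wins the posterior; returns an S x S matrix
    (rows: truth, columns: selected)."""
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    if ref_table is None:
        ref_table = build_reference_table(
            scenarios, priors, n_train, sample_config, rng,
            n_loci=n_loci, seq_length=seq_length,
        )
    ids = [sc.scenario_id for sc in scenarios]
    pops = [p for p in scenarios[0].populations if p in sample_config]
    counts = pd.DataFrame(0, index=ids, columns=ids)
    for sc in scenarios:
        for _ in range(n_test):
            draw = sample_parameters(sc, priors, rng)
            ds = simulate_dataset(
                sc, draw, sample_config, rng, n_loci=n_loci, seq_length=seq_length
            )
            obs = observed_vector(ds, pops)
            rej = abc_reject(ref_table, obs, tolerance)
            choice = model_posteriors(ref_table, rej, obs, n_boot=0, rng=rng)
            counts.loc[sc.scenario_id, choice.best()] += 1
    return counts
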