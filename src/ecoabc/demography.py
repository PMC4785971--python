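"""Demographic scenarios, priors and parameter draws.

A scenario is a backward-time event list over the five analysis groups
(BG, EMT, WM, SM, ONT): ``merge`` events absorb one population into
another (a forward-time divergence) and ``admixture`` events move each
lineage of a population to an introgressing source with probability
``r`` (a forward-time pulse).  The five default scenarios ship as package
data (``data/scenarios.yaml``) so topologies can be amended without code
changes.

Times are in generations; :func:`to_years` converts with the 7-year
caribou generation time.  Priors are uniform or log-uniform with strict
ordering constraints among the time parameters, enforced by rejection
resampling.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

DEFAULT_GENERATION_TIME = 7.0


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_diploid: int = 0
    n_mtdna: int = 0

    def __post_init__(self) -> None:
        if self.n_diploid < 0 or self.n_mtdna < 0:
            raise ValueError("sample counts must be >= 0")


@dataclass(frozen=True)
class DemographicEvent:
    """One backward-time event.

    merge:     all lineages of ``source`` move to ``dest``.
    admixture: each lineage of ``source`` moves to ``admix_from`` with
               probability given by parameter ``rate_param``.
    """

    time_param: str
    kind: str  # "merge" | "admixture"
    source: str
    dest: str | None = None
    admix_from: str | None = None
    rate_param: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("merge", "admixture"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "merge" and self.dest is None:
            raise ValueError("merge event needs a destination")
        if self.kind == "admixture" and (self.admix_from is None or self.rate_param is None):
            raise ValueError("admixture event needs a source population and rate parameter")


@dataclass
class PriorSpec:
    """Named independent priors plus strict ordering constraints.

    ``params`` maps name -> (family, low, high) with family in
    {"uniform", "loguniform"}; ``constraints`` is a list of (a, b) pairs
    meaning the drawn value of a must be strictly less than that of b.
    """

    params: dict[str, tuple[str, float, float]]
    constraints: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (family, low, high) in self.params.items():
            if family not in ("uniform", "loguniform"):
                raise ValueError(f"{name}: unknown distribution family {family!r}")
            if not (math.isfinite(low) and math.isfinite(high) and low <= high):
                raise ValueError(f"{name}: bounds must be finite with low <= high")
            if family == "loguniform" and low <= 0:
                raise ValueError(f"{name}: log-uniform bounds must be positive")
        names = set(self.params)
        for a, b in self.constraints:
            if a not in names or b not in names:
                raise ValueError(f"constraint {a} < {b} references unknown parameter")

    def bounds(self, name: str) -> tuple[float, float]:
        _, low, high = self.params[name]
        return low, high


@dataclass
class ScenarioSpec:
    scenario_id: int
    populations: list[str]
    events: list[DemographicEvent]
    constraints: list[tuple[str, str]] = field(default_factory=list)
    description: str = ""

    @property
    def has_admixture(self) -> bool:
        return any(e.kind == "admixture" for e in self.events)

    @property
    def n_admixture_events(self) -> int:
        return sum(e.kind == "admixture" for e in self.events)

    def time_params(self) -> list[str]:
        seen: list[str] = []
        for e in self.events:
            if e.time_param not in seen:
                seen.append(e.time_param)
        return seen

    def validate(self, priors: PriorSpec) -> None:
        """Check parameter references and that the event list coalesces
        every population into a single root."""
        for e in self.events:
            if e.time_param not in priors.params:
                raise ValueError(
                    f"scenario {self.scenario_id}: undefined time parameter {e.time_param}"
                )
            if e.kind == "admixture" and e.rate_param not in priors.params:
                raise ValueError(
                    f"scenario {self.scenario_id}: undefined admixture rate {e.rate_param}"
                )
            for pop in (e.source, e.dest, e.admix_from):
                if pop is not None and pop not in self.populations:
                    raise ValueError(
                        f"scenario {self.scenario_id}: unknown population {pop}"
                    )
        alive = set(self.populations)
        for e in self.events:  # events are listed in (weak) time order
            if e.kind == "merge":
                if e.source not in alive or e.dest not in alive:
                    raise ValueError(
                        f"scenario {self.scenario_id}: merge involving an "
                        f"inactive population ({e.source} -> {e.dest})"
                    )
                alive.remove(e.source)
            else:
                if e.source not in alive or e.admix_from not in alive:
                    raise ValueError(
                        f"scenario {self.scenario_id}: admixture involving an "
                        f"inactive population ({e.source} <- {e.admix_from})"
                    )
        if len(alive) != 1:
            raise ValueError(
                f"scenario {self.scenario_id}: topology does not coalesce to a "
                f"single root (left with {sorted(alive)})"
            )


@dataclass
class ParameterDraw:
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _parse_constraint(text: str) -> tuple[str, str]:
    parts = [p.strip() for p in text.split("<")]
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"constraint {text!r} must have the form 'a < b'")
    return parts[0], parts[1]


def _default_config_text() -> str:
    return (
        importlib.resources.files("ecoabc").joinpath("data/scenarios.yaml").read_text()
    )


def load_config(path: str | Path | None = None) -> dict:
    """Load the raw scenario/prior configuration (default: shipped file)."""
    text = Path(path).read_text() if path is not None else _default_config_text()
    return yaml.safe_load(text)


def load_priors(config: dict | None = None) -> PriorSpec:
    config = config if config is not None else load_config()
    params = {
        name: (spec["dist"], float(spec["low"]), float(spec["high"]))
        for name, spec in config["priors"].items()
    }
    constraints = [_parse_constraint(c) for c in config.get("constraints", [])]
    return PriorSpec(params, constraints)


def load_scenarios(
    config: dict | str | Path | None = None, priors: PriorSpec | None = None
) -> list[ScenarioSpec]:
    """Load and validate the scenario set (default: the five shipped models)."""
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    priors = priors if priors is not None else load_priors(config)
    populations = list(config["populations"])
    scenarios = []
    for entry in config["scenarios"]:
        events = []
        for ev in entry["events"]:
            if ev["kind"] == "merge":
                events.append(
                    DemographicEvent(ev["time"], "merge", ev["source"], dest=ev["dest"])
                )
            else:
                events.append(
                    DemographicEvent(
                        ev["time"],
                        "admixture",
                        ev["source"],
                        admix_from=ev["from"],
                        rate_param=ev["rate"],
                    )
                )
        sc = ScenarioSpec(
            scenario_id=int(entry["id"]),
            populations=populations,
            events=events,
            constraints=[_parse_constraint(c) for c in entry.get("constraints", [])],
            description=entry.get("description", "").strip(),
        )
        sc.validate(priors)
        scenarios.append(sc)
    return scenarios


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _draw_one(family: str, low: float, high: float, rng: np.random.Generator) -> float:
    if low == high:
        return low
    if family == "uniform":
        return float(rng.uniform(low, high))
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def _satisfied(values: dict[str, float], constraints: Iterable[tuple[str, str]]) -> bool:
    return all(values[a] < values[b] for a, b in constraints)


def sample_parameters(
    scenario: ScenarioSpec,
    priors: PriorSpec,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> ParameterDraw:
    """Draw one parameter vector from the priors, rejection-resampling until
    all global and scenario-specific ordering constraints hold."""
    constraints = list(priors.constraints) + list(scenario.constraints)
    for _ in range(max_tries):
        values = {
            name: _draw_one(family, low, high, rng)
            for name, (family, low, high) in priors.params.items()
        }
        if _satisfied(values, constraints):
            return ParameterDraw(values)
    raise RuntimeError(
        f"no feasible draw after {max_tries} attempts; ordering constraints "
        "may be unsatisfiable under the given priors"
    )


def central_parameters(priors: PriorSpec, scenario: ScenarioSpec | None = None) -> ParameterDraw:
    """Midpoint of every prior (log-midpoint for log-uniform families),
    with the admixture proportion fixed at 0.5.  Used as the reproducible
    preset for recovery experiments."""
    values: dict[str, float] = {}
    for name, (family, low, high) in priors.params.items():
        if family == "uniform":
            values[name] = (low + high) / 2.0
        else:
            values[name] = float(np.exp((np.log(low) + np.log(high)) / 2.0))
    if "r" in values:
        values["r"] = 0.5
    constraints = list(priors.constraints)
    if scenario is not None:
        constraints += list(scenario.constraints)
    if not _satisfied(values, constraints):
        raise ValueError("prior midpoints violate the ordering constraints")
    return ParameterDraw(values)


def to_years(
    t_generations: float, generation_time: float = DEFAULT_GENERATION_TIME
) -> float:
    """Convert generations to years before present (default 7 years/generation)."""
    if t_generations < 0:
        raise ValueError("time must be non-negative")
    return t_generations * generation_time
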