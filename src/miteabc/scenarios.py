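"""Demographic scenarios for the three aggression forms and their priors.

Nine competing histories relate the low- (LW), mild- (ML) and high-aggression
(HG) forms of *Stigmaeopsis miscanthi*.  Each scenario is an ordered,
backward-in-time event list over the three sampled demes:

* scenarios 1-4 -- hierarchical splits with ML ancestral (1: HG splits at the
  older time t2 and LW at t1; 2: LW at the older t2 and HG at t1; 3: LW from
  ML at t2 then HG from LW at t1; 4: HG from ML at t2 then LW from HG at t1);
* scenarios 5-6 -- LW ancestral (5: ML from LW at t2, HG from ML at t1;
  6: ML and HG both from LW, at t2 and t1);
* scenarios 7-8 -- LW and HG split at t2 (ancestor LW in 7, HG in 8) and ML
  arises at t1 by admixture, each ML lineage tracing back to the LW side with
  probability ``r`` and to the HG side otherwise;
* scenario 9 -- a single three-way split at t2.

Times are in generations, counted backward from the present; sizes are
haploid effective sizes, appropriate for mtDNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

FORMS = ("LW", "ML", "HG")

#: canonical parameter order used throughout the package
PARAM_NAMES = ("N_LW", "N_ML", "N_HG", "t1", "t2", "r", "mu", "kappa")

SCENARIO_IDS = tuple(range(1, 10))


class InvalidDrawError(ValueError):
    """A parameter draw violates a scenario's ordering constraint."""


@dataclass(frozen=True)
class Prior:
    """A univariate uniform prior on a linear or log10 scale."""

    low: float
    high: float
    scale: str = "linear"  # "linear" | "log"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"prior requires low < high, got [{self.low}, {self.high}]")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown prior scale {self.scale!r}")
        if self.scale == "log" and self.low <= 0:
            raise ValueError("log-scale prior requires positive bounds")

    def sample(self, rng: np.random.Generator, size=None):
        if self.scale == "log":
            return 10.0 ** rng.uniform(math.log10(self.low), math.log10(self.high), size)
        return rng.uniform(self.low, self.high, size)


def _default_priors() -> dict[str, Prior]:
    n = Prior(10.0, 5e5)
    t = Prior(10.0, 4e5)
    return {
        "N_LW": n,
        "N_ML": n,
        "N_HG": n,
        "t1": t,
        "t2": t,
        "r": Prior(0.001, 0.999),
        "mu": Prior(1e-8, 1e-7),
        "kappa": Prior(0.05, 20.0),
    }


@dataclass(frozen=True)
class PriorSet:
    """Priors for every parameter in :data:`PARAM_NAMES`.

    Defaults are wide uniforms bracketing the posterior mass reported for
    this system: per-form haploid N ~ U(10, 5e5), event times ~ U(10, 4e5)
    generations, admixture fraction r ~ U(0.001, 0.999), per-site
    per-generation mutation rate mu ~ U(1e-8, 1e-7) and HKY
    transition/transversion coefficient kappa ~ U(0.05, 20).
    """

    priors: dict[str, Prior] = field(default_factory=_default_priors)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.priors)
        if missing:
            raise ValueError(f"missing priors for {sorted(missing)}")
        for name in ("N_LW", "N_ML", "N_HG", "t1", "t2", "mu", "kappa"):
            if self.priors[name].low <= 0:
                raise ValueError(f"prior for {name} must be strictly positive")
        r = self.priors["r"]
        if not (0.0 < r.low and r.high < 1.0):
            raise ValueError("admixture fraction prior must lie inside (0, 1)")

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def replace(self, **kwargs: Prior) -> "PriorSet":
        new = dict(self.priors)
        new.update(kwargs)
        return PriorSet(new)


@dataclass(frozen=True)
class ParameterDraw:
    """One joint draw from the priors, tied to the scenario it will drive."""

    scenario_id: int
    values: dict[str, float]

    def __getattr__(self, name: str):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    def as_array(self) -> np.ndarray:
        return np.array([self.values[p] for p in PARAM_NAMES])

    @classmethod
    def from_array(cls, scenario_id: int, arr) -> "ParameterDraw":
        return cls(scenario_id, dict(zip(PARAM_NAMES, map(float, arr))))


@dataclass(frozen=True)
class Split:
    """Backward in time, all lineages of ``source`` merge into ``dest``."""

    time: float
    source: str
    dest: str


@dataclass(frozen=True)
class Admixture:
    """Each lineage of ``source`` joins ``dest`` with probability ``prob``,
    else ``alt``."""

    time: float
    source: str
    dest: str
    alt: str
    prob: float


Event = Split | Admixture


@dataclass(frozen=True)
class ScenarioSpec:
    """A demographic model: per-deme sizes plus an ordered event list."""

    scenario_id: int
    events: tuple[Event, ...]
    deme_sizes: dict[str, float]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t < 0 for t in times):
            raise ValueError("event times must be nonnegative")
        if times != sorted(times):
            raise ValueError("events must be sorted by time, present backward")
        extant = set(self.deme_sizes)
        for ev in self.events:
            refs = {ev.source, ev.dest} | ({ev.alt} if isinstance(ev, Admixture) else set())
            if not refs <= extant:
                raise ValueError(f"event {ev} references a deme absent at its time")
            extant.discard(ev.source)
        if len(extant) != 1:
            raise ValueError(f"{len(extant)} demes remain after the final event; expected 1")

    @property
    def ancestral_deme(self) -> str:
        extant = set(self.deme_sizes)
        for ev in self.events:
            extant.discard(ev.source)
        return next(iter(extant))


# event-list builders; d is the ParameterDraw
_TOPOLOGIES = {
    1: lambda d: (Split(d.t1, "LW", "ML"), Split(d.t2, "HG", "ML")),
    2: lambda d: (Split(d.t1, "HG", "ML"), Split(d.t2, "LW", "ML")),
    3: lambda d: (Split(d.t1, "HG", "LW"), Split(d.t2, "LW", "ML")),
    4: lambda d: (Split(d.t1, "LW", "HG"), Split(d.t2, "HG", "ML")),
    5: lambda d: (Split(d.t1, "HG", "ML"), Split(d.t2, "ML", "LW")),
    6: lambda d: (Split(d.t1, "HG", "LW"), Split(d.t2, "ML", "LW")),
    7: lambda d: (Admixture(d.t1, "ML", "LW", "HG", d.r), Split(d.t2, "HG", "LW")),
    8: lambda d: (Admixture(d.t1, "ML", "LW", "HG", d.r), Split(d.t2, "LW", "HG")),
    9: lambda d: (Split(d.t2, "LW", "ML"), Split(d.t2, "HG", "ML")),
}

#: scenarios whose event order requires t1 < t2
_ORDERED_IDS = frozenset(range(1, 9))


def scenario_constraint_ok(scenario_id: int, draw: ParameterDraw) -> bool:
    """True when the draw satisfies the scenario's time-ordering constraint."""
    if scenario_id in _ORDERED_IDS:
        return draw.t1 < draw.t2
    return True


def build_scenario(scenario_id: int, draw: ParameterDraw) -> ScenarioSpec:
    """Materialise the event list for one of the nine scenarios.

    Raises
    ------
    ValueError
        For an unknown scenario id.
    InvalidDrawError
        When the draw violates the scenario's t1 < t2 constraint.
    """
    if scenario_id not in _TOPOLOGIES:
        raise ValueError(f"unknown scenario id {scenario_id}; expected 1-9")
    if not scenario_constraint_ok(scenario_id, draw):
        raise InvalidDrawError(
            f"scenario {scenario_id} requires t1 < t2, got t1={draw.t1}, t2={draw.t2}"
        )
    sizes = {"LW": draw.N_LW, "ML": draw.N_ML, "HG": draw.N_HG}
    return ScenarioSpec(scenario_id, _TOPOLOGIES[scenario_id](draw), sizes)


def sample_prior(
    priors: PriorSet, scenario_id: int, rng: np.random.Generator
) -> ParameterDraw:
    """Draw each parameter independently from its prior.

    Draws violating the scenario's time-ordering constraint are rejected and
    the whole vector redrawn, so the result is the joint prior conditioned on
    the constraint.
    """
    while True:
        draw = ParameterDraw(
            scenario_id, {p: float(priors[p].sample(rng)) for p in PARAM_NAMES}
        )
        if scenario_constraint_ok(scenario_id, draw):
            return draw
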