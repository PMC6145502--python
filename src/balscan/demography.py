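"""Multi-population demographic models shared by both simulation engines.

A demography is described forward-compatibly but indexed in backward time
(generations before present, present = 0): present-day diploid sizes and
exponential growth rates per population, plus an ordered list of
backward-time events -- size/growth changes, population splits (backward:
the derived population's lineages merge into the ancestral one), and
migration-matrix changes. Migration rates are per-lineage per-generation
backward rates, which equal the forward fraction of a population's parents
drawn from the other deme, so a single matrix serves the coalescent and the
Wright-Fisher engine alike.

The shipped ``gravel_2011`` preset is the three-population out-of-Africa
model (African / European / Asian with an OOA bottleneck and exponential
non-African growth) the analysis assumes.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


@dataclass
class PopulationConfig:
    name: str
    initial_size: float  # diploid size at the most recent epoch boundary
    growth_rate: float = 0.0  # forward-time exponential rate per generation

    def __post_init__(self) -> None:
        if self.initial_size <= 0:
            raise ValueError(f"population {self.name}: size must be > 0")


@dataclass
class SizeChange:
    time: float
    population: str
    size: float | None = None
    growth_rate: float | None = None


@dataclass
class PopulationSplit:
    """Backward in time at ``time``: ``derived`` merges into ``ancestral``."""

    time: float
    derived: str
    ancestral: str


@dataclass
class MigrationChange:
    """Replace the symmetric migration rate of listed pairs at ``time``.

    ``rates`` maps (pop_a, pop_b) to the new per-generation rate, applied in
    both directions; pairs not listed keep their current rate.
    """

    time: float
    rates: dict = field(default_factory=dict)


Event = SizeChange | PopulationSplit | MigrationChange


@dataclass
class EpochState:
    """Demographic state over one backward-time interval [time0, next_time)."""

    time0: float
    next_time: float
    sizes: dict  # pop -> diploid size at time0
    growth: dict  # pop -> forward growth rate in this epoch
    active: list
    migration: dict  # (a, b) -> backward rate, directed
    merged_into: dict  # pop -> pop it has merged into by time0 (cumulative)

    def size_at(self, pop: str, t: float) -> float:
        """Diploid size of ``pop`` at backward time t within this epoch."""
        g = self.growth.get(pop, 0.0)
        return self.sizes[pop] * math.exp(-g * (t - self.time0))


@dataclass
class DemographyConfig:
    populations: list
    migration: dict = field(default_factory=dict)  # (a, b) -> rate, directed
    events: list = field(default_factory=list)
    mutation_rate: float = 1.0e-8  # per bp per generation
    recombination_rate: float = 1.0e-8  # per bp per generation
    generation_time: float = 25.0  # years
    name: str = "custom"

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        self.events = sorted(self.events, key=lambda e: e.time)
        for e in self.events:
            if e.time <= 0:
                raise ValueError("event times must be > 0")
        self._epochs: list[EpochState] | None = None

    # -- epoch resolution -------------------------------------------------

    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def epochs(self) -> list[EpochState]:
        """Resolve events into a list of constant-parameter epochs."""
        if self._epochs is not None:
            return self._epochs
        sizes = {p.name: float(p.initial_size) for p in self.populations}
        growth = {p.name: float(p.growth_rate) for p in self.populations}
        active = list(self.pop_names())
        migration = dict(self.migration)
        merged: dict[str, str] = {}
        epochs: list[EpochState] = []
        times = sorted({e.time for e in self.events})
        boundaries = [0.0] + times + [math.inf]
        ev_idx = 0
        for k in range(len(boundaries) - 1):
            t0, t1 = boundaries[k], boundaries[k + 1]
            epochs.append(
                EpochState(
                    time0=t0,
                    next_time=t1,
                    sizes=dict(sizes),
                    growth=dict(growth),
                    active=list(active),
                    migration=dict(migration),
                    merged_into=dict(merged),
                )
            )
            if t1 is math.inf:
                break
            # advance sizes to the boundary, then apply that boundary's events
            for p in active:
                sizes[p] = sizes[p] * math.exp(-growth[p] * (t1 - t0))
            while ev_idx < len(self.events) and self.events[ev_idx].time == t1:
                e = self.events[ev_idx]
                ev_idx += 1
                if isinstance(e, SizeChange):
                    if e.population not in active:
                        raise ValueError(
                            f"size change at t={e.time} on inactive population "
                            f"{e.population}"
                        )
                    if e.size is not None:
                        sizes[e.population] = float(e.size)
                    if e.growth_rate is not None:
                        growth[e.population] = float(e.growth_rate)
                elif isinstance(e, PopulationSplit):
                    if e.derived not in active or e.ancestral not in active:
                        raise ValueError(
                            f"split at t={e.time}: both populations must be active"
                        )
                    active.remove(e.derived)
                    merged[e.derived] = e.ancestral
                    migration = {
                        k2: v for k2, v in migration.items() if e.derived not in k2
                    }
                elif isinstance(e, MigrationChange):
                    for (a, b), rate in dict(e.rates).items():
                        migration[(a, b)] = float(rate)
                        migration[(b, a)] = float(rate)
                else:  # pragma: no cover
                    raise TypeError(f"unknown event {e!r}")
        self._epochs = epochs
        return epochs

    def epoch_at(self, t: float) -> EpochState:
        for ep in self.epochs():
            if ep.time0 <= t < ep.next_time:
                return ep
        return self.epochs()[-1]

    def size_at(self, pop: str, t: float) -> float:
        ep = self.epoch_at(t)
        if pop not in ep.active:
            raise ValueError(f"population {pop} is not active at t={t}")
        return ep.size_at(pop, t)

    def resolve_pop(self, pop: str, t: float) -> str:
        """Population actually holding ``pop``'s ancestry at backward time t."""
        ep = self.epoch_at(t)
        while pop not in ep.active:
            if pop not in ep.merged_into:
                raise ValueError(f"population {pop} unknown at t={t}")
            pop = ep.merged_into[pop]
        return pop

    def root_time(self) -> float:
        """Earliest backward time at which a single root population remains.

        Returns 0 for a one-population model and ``inf`` when lineages can
        never all gather in one deme (an invalid configuration).
        """
        for ep in self.epochs():
            if len(ep.active) == 1:
                return ep.time0
        return math.inf

    def validate(self) -> None:
        """Check that every lineage can reach a common ancestral population.

        In the oldest epoch either a single population remains, or the
        migration graph over the remaining populations must be strongly
        connected so lineages can still meet.
        """
        last = self.epochs()[-1]
        if len(last.active) == 1:
            return
        # strong connectivity over positive migration rates
        adj = {p: set() for p in last.active}
        for (a, b), rate in last.migration.items():
            if rate > 0 and a in adj and b in adj:
                adj[a].add(b)
        for start in last.active:
            seen = {start}
            stack = [start]
            while stack:
                for nxt in adj[stack.pop()]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            if seen != set(last.active):
                raise ValueError(
                    "demography has no reachable root: populations "
                    f"{sorted(set(last.active) - seen)} are unreachable from "
                    f"{start} in the oldest epoch"
                )

    # -- transforms -------------------------------------------------------

    def rescaled(self, factor: float) -> "DemographyConfig":
        """Population-size rescaling by ``factor`` (sizes/f, times/f, rates*f).

        Keeps theta = 4*N*mu and rho = 4*N*r invariant so distributions of
        summary statistics are approximately unchanged while runtime drops
        by ~factor^2; the selection coefficient must be multiplied by the
        same factor at the call site. ``generation_time`` is scaled up so
        conversions to years stay calibrated.
        """
        d = copy.deepcopy(self)
        d.name = f"{self.name}_rescaled{factor:g}"
        for p in d.populations:
            p.initial_size /= factor
            p.growth_rate *= factor
        d.migration = {k: v * factor for k, v in d.migration.items()}
        for e in d.events:
            e.time /= factor
            if isinstance(e, SizeChange):
                if e.size is not None:
                    e.size /= factor
                if e.growth_rate is not None:
                    e.growth_rate *= factor
            elif isinstance(e, MigrationChange):
                e.rates = {k: v * factor for k, v in e.rates.items()}
        d.mutation_rate *= factor
        d.recombination_rate *= factor
        d.generation_time *= factor
        d._epochs = None
        return d

    def shifted(self, t0: float) -> "DemographyConfig":
        """The demography as seen with present redefined to backward time t0.

        Used to initialize forward simulations with stationary standing
        variation: populations active at t0 keep their sizes/growth at t0
        and all older events shift earlier by t0.
        """
        ep = self.epoch_at(t0)
        pops = [
            PopulationConfig(
                name=p, initial_size=ep.size_at(p, t0), growth_rate=ep.growth[p]
            )
            for p in ep.active
        ]
        events = []
        for e in copy.deepcopy(self.events):
            if e.time > t0:
                e.time -= t0
                events.append(e)
        d = DemographyConfig(
            populations=pops,
            migration=dict(ep.migration),
            events=events,
            mutation_rate=self.mutation_rate,
            recombination_rate=self.recombination_rate,
            generation_time=self.generation_time,
            name=f"{self.name}_from{t0:g}",
        )
        return d


# -- serialization --------------------------------------------------------


def _config_from_dict(doc: dict) -> DemographyConfig:
    pops = [
        PopulationConfig(
            name=p["name"],
            initial_size=float(p["initial_size"]),
            growth_rate=float(p.get("growth_rate", 0.0)),
        )
        for p in doc["populations"]
    ]
    migration: dict = {}
    for a, b, rate in doc.get("migration", []):
        migration[(a, b)] = float(rate)
        migration[(b, a)] = float(rate)
    events: list[Event] = []
    for e in doc.get("events", []):
        kind = e["type"]
        if kind == "size_change":
            events.append(
                SizeChange(
                    time=float(e["time"]),
                    population=e["population"],
                    size=None if e.get("size") is None else float(e["size"]),
                    growth_rate=(
                        None if e.get("growth_rate") is None
                        else float(e["growth_rate"])
                    ),
                )
            )
        elif kind == "split":
            events.append(
                PopulationSplit(
                    time=float(e["time"]),
                    derived=e["derived"],
                    ancestral=e["ancestral"],
                )
            )
        elif kind == "migration_change":
            events.append(
                MigrationChange(
                    time=float(e["time"]),
                    rates={(a, b): float(r) for a, b, r in e.get("rates", [])},
                )
            )
        else:
            raise ValueError(f"unknown event type {kind!r}")
    return DemographyConfig(
        populations=pops,
        migration=migration,
        events=events,
        mutation_rate=float(doc.get("mutation_rate", 1.0e-8)),
        recombination_rate=float(doc.get("recombination_rate", 1.0e-8)),
        generation_time=float(doc.get("generation_time", 25.0)),
        name=doc.get("name", "custom"),
    )


def load_demography(path: str | Path) -> DemographyConfig:
    """Load a demography from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg = _config_from_dict(doc)
    cfg.validate()
    return cfg


def _load_preset(name: str) -> DemographyConfig:
    ref = resources.files("balscan.data").joinpath(f"{name}.yaml")
    doc = yaml.safe_load(ref.read_text())
    cfg = _config_from_dict(doc)
    cfg.validate()
    return cfg


def gravel_2011() -> DemographyConfig:
    """The three-population out-of-Africa model (Gravel et al. 2011 fit)."""
    return _load_preset("gravel_2011")


def toy_ooa() -> DemographyConfig:
    """A desk-scale three-population analogue for tests and demos."""
    return _load_preset("toy_ooa")
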