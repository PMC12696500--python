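"""Four-population demographic models for forward simulation.

The default model is a Gravel-2011-like out-of-Africa parameterization with an
American branch splitting from East Asia through a founding bottleneck.  Times
are supplied in thousands of years (kya) and converted to generations with the
model's generation time (default 28 years, so that 500 generations correspond
to 14 kya and 2,000 generations to 56 kya).

A model is a declarative object: an ancestral burn-in phase (single
population, piecewise-constant size) followed by a forward phase over the
named populations {AFR, EUR, EAS, AMR} plus any internal (unsampled)
ancestors such as the out-of-Africa bottleneck population OOA.  Population
sizes may grow exponentially from their founding size.  Migration is a
constant per-generation rate matrix applied whenever both populations exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "PopulationConfig",
    "DemographicModel",
    "build_demography",
    "default_config",
    "DemographyError",
]

SAMPLED_POPULATIONS = ("AFR", "EUR", "EAS", "AMR")


class DemographyError(ValueError):
    """Raised for inconsistent demographic configurations."""


@dataclass(frozen=True)
class PopulationConfig:
    """One population (deme) of the forward phase.

    ``size`` is the diploid size at founding; with ``growth`` > 0 the size
    grows exponentially toward the present, ``N(t) = size * exp(growth * g)``
    where ``g`` is generations since founding.  ``split_gen`` is the founding
    time in generations before present (``None`` for the root population,
    which continues the ancestral burn-in lineage).  ``end_gen`` > 0 marks an
    internal population that stops existing when its descendants split off.
    """

    name: str
    size: float
    growth: float = 0.0
    parent: str | None = None
    split_gen: float | None = None
    end_gen: float = 0.0

    def size_at(self, t_gen: float) -> float:
        """Diploid size ``t_gen`` generations before present (unscaled)."""
        founded = self.split_gen if self.split_gen is not None else math.inf
        if t_gen > founded or t_gen < self.end_gen:
            return 0.0
        if self.growth == 0.0 or self.split_gen is None:
            return self.size
        return self.size * math.exp(self.growth * (self.split_gen - t_gen))

    def exists_at(self, t_gen: float) -> bool:
        return self.size_at(t_gen) > 0.0


@dataclass(frozen=True)
class DemographicModel:
    """Burn-in plus multi-population forward phase.

    ``burnin_epochs`` is a list of ``(start_gen, diploid_size)`` pairs with
    strictly decreasing start times (generations before present); the last
    epoch runs until ``forward_start_gen``, where the forward phase and the
    root population begin.
    """

    populations: tuple[PopulationConfig, ...]
    generation_time: float = 28.0
    burnin_epochs: tuple[tuple[float, float], ...] = ()
    forward_start_gen: float = 0.0
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    sampled: tuple[str, ...] = SAMPLED_POPULATIONS

    # -- lookups ---------------------------------------------------------
    def __post_init__(self) -> None:
        self._validate()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)

    def population(self, name: str) -> PopulationConfig:
        for p in self.populations:
            if p.name == name:
                return p
        raise DemographyError(f"unknown population {name!r}")

    @property
    def root(self) -> PopulationConfig:
        return next(p for p in self.populations if p.parent is None)

    def kya_to_gen(self, kya: float) -> float:
        return kya * 1000.0 / self.generation_time

    def lineage_at(self, focal: str, t_gen: float) -> str:
        """Population carrying the ``focal`` lineage ``t_gen`` generations ago."""
        pop = self.population(focal)
        while not pop.exists_at(t_gen):
            if pop.parent is None:
                raise DemographyError(
                    f"time {t_gen} predates the forward phase for {focal!r}"
                )
            pop = self.population(pop.parent)
        return pop.name

    def migration_rate(self, a: str, b: str) -> float:
        return self.migration.get((a, b), self.migration.get((b, a), 0.0))

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise DemographyError("duplicate population names")
        roots = [p for p in self.populations if p.parent is None]
        if len(roots) != 1:
            raise DemographyError("exactly one root population is required")
        if self.generation_time <= 0:
            raise DemographyError("generation_time must be positive")
        for p in self.populations:
            if p.size < 2:
                raise DemographyError(f"population {p.name}: diploid size must be >= 2")
            if p.parent is None:
                continue
            if p.parent not in names:
                raise DemographyError(f"{p.name}: unknown parent {p.parent!r}")
            if p.split_gen is None:
                raise DemographyError(f"{p.name}: non-root population needs split_gen")
            if p.split_gen > self.forward_start_gen:
                raise DemographyError(
                    f"{p.name}: split predates the forward phase start"
                )
            parent = self.population(p.parent)
            # the parent must exist in the generation the child is founded from
            if not parent.exists_at(p.split_gen + 1) and parent.split_gen is not None:
                if parent.split_gen < p.split_gen:
                    raise DemographyError(
                        f"{p.name}: splits at {p.split_gen} before parent "
                        f"{p.parent} exists"
                    )
            if p.end_gen > p.split_gen:
                raise DemographyError(f"{p.name}: end_gen after founding")
        # split-order invariant of the four-population topology
        order = {p.name: p.split_gen for p in self.populations}
        chain = [("OOA", "EUR"), ("OOA", "EAS"), ("EAS", "AMR")]
        for older, younger in chain:
            if older in order and younger in order:
                t_o, t_y = order[older], order[younger]
                if t_o is not None and t_y is not None and not t_o > t_y:
                    raise DemographyError(
                        f"split order violated: {older} ({t_o}) must predate "
                        f"{younger} ({t_y})"
                    )
        for (a, b), m in self.migration.items():
            if not (0.0 <= m < 1.0):
                raise DemographyError(f"migration rate {a}-{b} outside [0, 1)")
        if self.burnin_epochs:
            starts = [s for s, _ in self.burnin_epochs]
            if any(s2 >= s1 for s1, s2 in zip(starts, starts[1:])):
                raise DemographyError("burn-in epochs must have decreasing start times")
            if starts[-1] < self.forward_start_gen:
                raise DemographyError("burn-in ends before it starts")
            if any(n < 2 for _, n in self.burnin_epochs):
                raise DemographyError("burn-in sizes must be >= 2")

    # -- rescaling -------------------------------------------------------
    def rescaled(self, q: float) -> "DemographicModel":
        """Divide sizes and times by ``q``; growth and migration scale up by ``q``.

        Population-scaled parameters (2Ns, 4Nmu, 4Nr together with the
        matching parameter rescaling in :class:`~sweepset.simulate.SimParams`)
        are preserved up to integer rounding.
        """
        if q < 1:
            raise DemographyError("rescale factor must be >= 1")
        pops = []
        for p in self.populations:
            size = max(2.0, round(p.size / q))
            pops.append(
                replace(
                    p,
                    size=size,
                    growth=p.growth * q,
                    split_gen=None if p.split_gen is None else p.split_gen / q,
                    end_gen=p.end_gen / q,
                )
            )
        return replace(
            self,
            populations=tuple(pops),
            burnin_epochs=tuple(
                (s / q, max(2.0, round(n / q))) for s, n in self.burnin_epochs
            ),
            forward_start_gen=self.forward_start_gen / q,
            migration={k: min(v * q, 0.999) for k, v in self.migration.items()},
        )


def default_config() -> dict:
    """Gravel-2011-like stand-in parameterization (28 years/generation).

    Ancestral burn-in from 1.66 Mya to 70 kya (ancestral expansion at
    148 kya), out-of-Africa bottleneck split ~57 kya, European/East-Asian
    split ~25.8 kya with exponential growth, and an American branch founded
    from East Asia 14 kya through a bottleneck of 800 diploids.
    """
    return {
        "generation_time": 28.0,
        "burnin": {
            "start_kya": 1660.0,
            "epochs": [
                {"from_kya": 1660.0, "size": 7310},
                {"from_kya": 148.0, "size": 14474},
            ],
        },
        "forward_start_kya": 70.0,
        "populations": [
            {"name": "AFR", "size": 14474},
            {"name": "OOA", "parent": "AFR", "split_kya": 57.1, "size": 1861,
             "end_kya": 25.8},
            {"name": "EUR", "parent": "OOA", "split_kya": 25.8, "size": 1032,
             "growth": 0.0038},
            {"name": "EAS", "parent": "OOA", "split_kya": 25.8, "size": 554,
             "growth": 0.0048},
            {"name": "AMR", "parent": "EAS", "split_kya": 14.0, "size": 800,
             "growth": 0.005},
        ],
        "migration": [
            {"between": ["AFR", "OOA"], "rate": 15e-5},
            {"between": ["AFR", "EUR"], "rate": 2.5e-5},
            {"between": ["AFR", "EAS"], "rate": 0.78e-5},
            {"between": ["EUR", "EAS"], "rate": 3.11e-5},
        ],
    }


def build_demography(config: dict | str | None = None) -> DemographicModel:
    """Build and validate a :class:`DemographicModel` from structured config.

    ``config`` may be a dict, a path to a YAML file, or ``None`` for the
    documented default model.  Times are given in kya and converted using the
    configured generation time.  Deterministic: the same config always yields
    the same model.
    """
    if config is None:
        config = default_config()
    elif isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    gen_time = float(config.get("generation_time", 28.0))

    def to_gen(kya: float) -> float:
        return kya * 1000.0 / gen_time

    pops = []
    for p in config["populations"]:
        pops.append(
            PopulationConfig(
                name=p["name"],
                size=float(p["size"]),
                growth=float(p.get("growth", 0.0)),
                parent=p.get("parent"),
                split_gen=to_gen(p["split_kya"]) if "split_kya" in p else None,
                end_gen=to_gen(p.get("end_kya", 0.0)),
            )
        )
    migration: dict[tuple[str, str], float] = {}
    for entry in config.get("migration", []):
        a, b = entry["between"]
        migration[(a, b)] = float(entry["rate"])
    burnin = config.get("burnin", {})
    epochs = tuple(
        (to_gen(e["from_kya"]), float(e["size"])) for e in burnin.get("epochs", [])
    )
    forward_start = to_gen(float(config.get("forward_start_kya", 0.0)))
    model = DemographicModel(
        populations=tuple(pops),
        generation_time=gen_time,
        burnin_epochs=epochs,
        forward_start_gen=forward_start,
        migration=migration,
        sampled=tuple(
            config.get("sampled", [p.name for p in pops if p.end_gen == 0.0])
        ),
    )
    return model


def single_population_model(
    size: int, n_generations: int, generation_time: float = 28.0
) -> DemographicModel:
    """A constant-size isolated population run for ``n_generations``.

    Convenience constructor used for calibration against closed-form drift
    expectations (heterozygosity decay, fixation probabilities).
    """
    return DemographicModel(
        populations=(PopulationConfig(name="POP", size=float(size)),),
        generation_time=generation_time,
        burnin_epochs=(),
        forward_start_gen=float(n_generations),
        migration={},
        sampled=("POP",),
    )
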