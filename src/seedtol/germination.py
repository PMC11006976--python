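"""Germination index and weighted stress-tolerance indices.

A dish's germination index (GI) is the speed-weighted germination count
``GI = sum_d n_d / t_d`` where ``n_d`` seeds germinate on 1-based day
``t_d``.  Each stress experiment runs five treatment levels; level 1 is an
unstressed control with weight 1 and harsher levels receive larger weights,
so a population that keeps germinating under stress scores higher.  The
three tolerance indices are level-weighted means of GI:

* GDTI (drought): weight ``1 + |W|`` for water potential ``W`` (MPa),
* GCTI (cold):    weight ``T1 / T`` for incubation temperature ``T`` (deg C),
* GSTI (saline):  weight 1 for the control and ``S / 10`` for saline
  concentration ``S`` (mmol/L) at levels 2-5.

Indices are not normalised by dish size, so they are comparable only
between experiments using the same number of seeds per dish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import InvalidInputError, MissingLevelError

Experiment = Literal["drought", "cold", "saline"]

EXPERIMENTS: tuple[Experiment, ...] = ("drought", "cold", "saline")

#: experiment -> tolerance index column name
INDEX_NAMES: dict[str, str] = {"drought": "GDTI", "cold": "GCTI", "saline": "GSTI"}


@dataclass(frozen=True)
class TreatmentScheme:
    """The three five-level stress gradients and the reference temperature."""

    drought_levels: tuple[float, ...] = (0.0, -0.3, -0.6, -0.9, -1.2)
    cold_levels: tuple[float, ...] = (25.0, 20.0, 15.0, 10.0, 5.0)
    saline_levels: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0, 200.0)
    reference_temperature: float = 25.0

    def __post_init__(self) -> None:
        for name in ("drought_levels", "cold_levels", "saline_levels"):
            levels = getattr(self, name)
            if len(levels) != 5:
                raise InvalidInputError(f"{name} must have exactly 5 levels, got {len(levels)}")
        if any(t <= 0 for t in self.cold_levels):
            raise InvalidInputError("cold levels must be strictly positive (weight T1/T)")

    def levels(self, experiment: str) -> tuple[float, ...]:
        return getattr(self, f"{experiment}_levels")

    def weight(self, experiment: str, level_index: int) -> float:
        """Severity weight for 1-based ``level_index`` of ``experiment``."""
        value = self.levels(experiment)[level_index - 1]
        if experiment == "drought":
            return drought_weight(value)
        if experiment == "cold":
            return cold_weight(value, self.reference_temperature)
        if experiment == "saline":
            return saline_weight(value, level_index)
        raise InvalidInputError(f"unknown experiment {experiment!r}")


@dataclass(frozen=True)
class GerminationTrial:
    """Daily newly-germinated counts for one dish under one treatment level."""

    population_id: str
    experiment: Experiment
    level_index: int
    level_value: float
    replicate: int
    daily_counts: tuple[int, ...]
    seeds_per_dish: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "daily_counts", tuple(int(c) for c in self.daily_counts))
        tag = (
            f"dish (population={self.population_id!r}, experiment={self.experiment!r}, "
            f"level={self.level_index}, replicate={self.replicate})"
        )
        if self.experiment not in EXPERIMENTS:
            raise InvalidInputError(f"unknown experiment {self.experiment!r} for {tag}")
        if not 1 <= self.level_index <= 5:
            raise InvalidInputError(f"level_index must be in 1..5 for {tag}")
        if not 1 <= len(self.daily_counts) <= 15:
            raise InvalidInputError(f"daily_counts must span 1..15 days for {tag}")
        if self.seeds_per_dish <= 0:
            raise InvalidInputError(f"seeds_per_dish must be positive for {tag}")
        if any(c < 0 for c in self.daily_counts):
            raise InvalidInputError(f"negative daily count in {tag}")
        if sum(self.daily_counts) > self.seeds_per_dish:
            raise InvalidInputError(
                f"total germinated {sum(self.daily_counts)} exceeds "
                f"{self.seeds_per_dish} seeds in {tag}"
            )


@dataclass(frozen=True)
class ToleranceIndices:
    """Per-replicate (or population-mean) GDTI/GCTI/GSTI values."""

    population_id: str
    replicate: int
    gdti: float
    gcti: float
    gsti: float


def germination_index(trial: GerminationTrial) -> float:
    """Speed-weighted germination count ``sum_d n_d / t_d`` for one dish."""
    return sum(n / day for day, n in enumerate(trial.daily_counts, start=1))


def drought_weight(water_potential: float) -> float:
    """Drought severity weight ``1 + |W|`` for water potential ``W`` <= 0 MPa."""
    if water_potential > 0:
        raise InvalidInputError(f"water potential must be <= 0 MPa, got {water_potential}")
    return 1.0 + abs(water_potential)


def cold_weight(temperature: float, reference_temperature: float = 25.0) -> float:
    """Cold severity weight ``T1 / T``; undefined at or below 0 deg C."""
    if temperature <= 0:
        raise InvalidInputError(f"temperature must be > 0 deg C, got {temperature}")
    if temperature > reference_temperature:
        raise InvalidInputError(
            f"temperature {temperature} exceeds reference {reference_temperature}"
        )
    return reference_temperature / temperature


def saline_weight(concentration: float, level_index: int) -> float:
    """Saline severity weight: 1 for the control level, ``S / 10`` otherwise."""
    if not 1 <= level_index <= 5:
        raise InvalidInputError(f"level_index must be in 1..5, got {level_index}")
    if concentration < 0:
        raise InvalidInputError(f"concentration must be >= 0 mmol/L, got {concentration}")
    if level_index == 1:
        return 1.0
    if concentration <= 0:
        raise InvalidInputError("stressed saline levels require a positive concentration")
    return concentration / 10.0


def tolerance_index(
    gi_by_level: Sequence[float], weights_by_level: Sequence[float]
) -> float:
    """Weighted mean over the five levels: ``sum_i GI_i * w_i / 5``."""
    if len(gi_by_level) != 5 or len(weights_by_level) != 5:
        raise InvalidInputError(
            f"expected 5 GI values and 5 weights, got {len(gi_by_level)} and "
            f"{len(weights_by_level)}"
        )
    return sum(g * w for g, w in zip(gi_by_level, weights_by_level)) / 5.0


def saline_index_literal(
    gi_by_level: Sequence[float], weights_by_level: Sequence[float]
) -> float:
    """Alternative GSTI reading that drops the control GI term.

    Computes ``w_1 * sum_{i=2..5} GI_i * w_i / 5``.  Kept behind the
    ``gsti_interpretation="literal"`` switch of :func:`compute_indices`; the
    default treats GSTI structurally like GDTI/GCTI (the control term enters
    with weight 1), which preserves symmetry across the three experiments.
    """
    if len(gi_by_level) != 5 or len(weights_by_level) != 5:
        raise InvalidInputError("expected 5 GI values and 5 weights")
    return weights_by_level[0] * sum(
        g * w for g, w in zip(gi_by_level[1:], weights_by_level[1:])
    ) / 5.0


def compute_indices(
    trials: Iterable[GerminationTrial],
    scheme: TreatmentScheme | None = None,
    aggregation: Literal["per_replicate", "population_mean"] = "per_replicate",
    gsti_interpretation: Literal["symmetric", "literal"] = "symmetric",
) -> list[ToleranceIndices]:
    """Compute GDTI/GCTI/GSTI for every population in ``trials``.

    ``per_replicate`` pairs replicate r across the five levels of each
    experiment and yields one index triple per replicate, preserving the
    replication that downstream ANOVA needs; ``population_mean`` averages GI
    per level over replicates first and yields one triple per population
    (reported with replicate 0).

    Raises :class:`MissingLevelError` listing every absent
    (population, experiment, level) combination.
    """
    scheme = scheme or TreatmentScheme()
    if aggregation not in ("per_replicate", "population_mean"):
        raise InvalidInputError(f"unknown aggregation {aggregation!r}")
    if gsti_interpretation not in ("symmetric", "literal"):
        raise InvalidInputError(f"unknown gsti_interpretation {gsti_interpretation!r}")

    # gi[(pop, experiment, level)] -> {replicate: GI}
    gi: dict[tuple[str, str, int], dict[int, float]] = {}
    populations: list[str] = []
    for trial in trials:
        key = (trial.population_id, trial.experiment, trial.level_index)
        gi.setdefault(key, {})[trial.replicate] = germination_index(trial)
        if trial.population_id not in populations:
            populations.append(trial.population_id)

    missing = [
        (pop, exp, level)
        for pop in populations
        for exp in EXPERIMENTS
        for level in range(1, 6)
        if (pop, exp, level) not in gi
    ]
    if missing:
        raise MissingLevelError(missing)

    def index_for(pop: str, exp: str, gi_levels: list[float]) -> float:
        weights = [scheme.weight(exp, i) for i in range(1, 6)]
        if exp == "saline" and gsti_interpretation == "literal":
            return saline_index_literal(gi_levels, weights)
        return tolerance_index(gi_levels, weights)

    results: list[ToleranceIndices] = []
    for pop in populations:
        if aggregation == "population_mean":
            values = {}
            for exp in EXPERIMENTS:
                gi_levels = [
                    sum(reps.values()) / len(reps)
                    for reps in (gi[(pop, exp, lvl)] for lvl in range(1, 6))
                ]
                values[exp] = index_for(pop, exp, gi_levels)
            results.append(
                ToleranceIndices(pop, 0, values["drought"], values["cold"], values["saline"])
            )
        else:
            replicates = sorted(
                {r for exp in EXPERIMENTS for lvl in range(1, 6) for r in gi[(pop, exp, lvl)]}
            )
            for rep in replicates:
                values = {}
                for exp in EXPERIMENTS:
                    per_level = [gi[(pop, exp, lvl)] for lvl in range(1, 6)]
                    if any(rep not in reps for reps in per_level):
                        raise MissingLevelError(
                            [
                                (pop, exp, lvl)
                                for lvl, reps in enumerate(per_level, start=1)
                                if rep not in reps
                            ]
                        )
                    values[exp] = index_for(pop, exp, [reps[rep] for reps in per_level])
                results.append(
                    ToleranceIndices(
                        pop, rep, values["drought"], values["cold"], values["saline"]
                    )
                )
    return results


def trials_from_frame(frame: pd.DataFrame, seeds_per_dish: int = 50) -> list[GerminationTrial]:
    """Build trials from a long table (one row per dish-day).

    Expected columns: population_id, experiment, level_index, level_value,
    replicate, day, n_germinated.  Days may be sparse; missing days within a
    dish's observed span count as zero.
    """
    required = {
        "population_id", "experiment", "level_index", "level_value",
        "replicate", "day", "n_germinated",
    }
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise InvalidInputError(f"trials table missing columns: {sorted(missing_cols)}")
    trials = []
    keys = ["population_id", "experiment", "level_index", "level_value", "replicate"]
    for (pop, exp, lvl, val, rep), dish in frame.groupby(keys, sort=False):
        days = dish["day"].astype(int)
        counts = [0] * int(days.max())
        for day, n in zip(days, dish["n_germinated"]):
            counts[day - 1] += int(n)
        trials.append(
            GerminationTrial(
                population_id=str(pop),
                experiment=str(exp),
                level_index=int(lvl),
                level_value=float(val),
                replicate=int(rep),
                daily_counts=tuple(counts),
                seeds_per_dish=seeds_per_dish,
            )
        )
    return trials


def indices_to_frame(indices: Iterable[ToleranceIndices]) -> pd.DataFrame:
    """Tabulate index triples with stable column order."""
    return pd.DataFrame(
        [
            {
                "population_id": ix.population_id,
                "replicate": ix.replicate,
                "GDTI": ix.gdti,
                "GCTI": ix.gcti,
                "GSTI": ix.gsti,
            }
            for ix in indices
        ],
        columns=["population_id", "replicate", "GDTI", "GCTI", "GSTI"],
    )
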