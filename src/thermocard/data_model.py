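"""Domain types, validation, and CSV readers/writers for germination data.

Three tidy (long-format) CSV tables are the interchange formats used by
every other module:

* counts:  ``population_id,temperature,replicate,time_h,cum_germinated,n_seeds``
* traits:  ``population_id,seed_id,seed_mass,...,colour`` (one row per seed)
* meta:    ``population_id,latitude,longitude,altitude,country``

All readers validate invariants (monotone cumulative counts, bounded
fractions, closed colour vocabulary) and report offending rows; downstream
modules only ever see validated objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed set of seed-colour categories (screening and network features
#: require fixed levels).
COLOURS: tuple[str, ...] = (
    "black",
    "brown",
    "cream",
    "golden",
    "light_brown",
    "white",
    "yellow",
)

#: Continuous per-seed morphology traits, in the column order of the traits CSV.
CONTINUOUS_TRAITS: tuple[str, ...] = (
    "seed_mass",
    "seed_length",
    "fruit_width",
    "fruit_length",
    "awn_length",
    "awn_angle",
    "awn_contact",
    "pct_hairiness",
    "hair_length",
)

COUNTS_COLUMNS = (
    "population_id",
    "temperature",
    "replicate",
    "time_h",
    "cum_germinated",
    "n_seeds",
)
TRAITS_COLUMNS = ("population_id", "seed_id") + CONTINUOUS_TRAITS + ("colour",)
META_COLUMNS = ("population_id", "latitude", "longitude", "altitude", "country")


class FormatError(ValueError):
    """A file does not have the expected columns/structure."""


class ValidationError(ValueError):
    """Data violate a domain invariant (with row/group context)."""


@dataclass
class GerminationExperiment:
    """Cumulative germination counts for one dish (population x temperature x replicate).

    Counts may be fractional (expected counts from the deterministic
    simulator); real observations are integers.
    """

    population_id: str
    temperature: float
    replicate: int
    times: np.ndarray
    cumulative_counts: np.ndarray
    n_seeds: float = 50

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_counts = np.asarray(self.cumulative_counts, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.times.shape != self.cumulative_counts.shape:
            raise ValidationError(
                f"{self._ctx()}: times and counts have different lengths"
            )
        if self.times.size == 0:
            raise ValidationError(f"{self._ctx()}: empty time series")
        if np.any(self.times <= 0):
            raise ValidationError(f"{self._ctx()}: all observation times must be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self._ctx()}: times must be strictly increasing")
        if self.n_seeds <= 0:
            raise ValidationError(f"{self._ctx()}: n_seeds must be positive")
        c = self.cumulative_counts
        if np.any(c < 0) or np.any(c > self.n_seeds):
            raise ValidationError(
                f"{self._ctx()}: counts must lie in [0, n_seeds={self.n_seeds}]"
            )
        if np.any(np.diff(c) < 0):
            raise ValidationError(
                f"{self._ctx()}: cumulative counts must be nondecreasing"
            )

    def _ctx(self) -> str:
        return (
            f"experiment (population={self.population_id}, "
            f"T={self.temperature}, replicate={self.replicate})"
        )


@dataclass
class SeedTraitRecord:
    """Morphology measurements for a single seed."""

    population_id: str
    seed_id: str
    seed_mass: float
    seed_length: float
    fruit_width: float
    fruit_length: float
    awn_length: float
    awn_angle: float
    awn_contact: float  # position on lemma, 0 = base, 1 = tip
    pct_hairiness: float
    hair_length: float
    colour: str

    def __post_init__(self) -> None:
        self.colour = str(self.colour).strip().lower().replace(" ", "_")
        if self.colour not in COLOURS:
            raise ValidationError(
                f"seed {self.seed_id} (population {self.population_id}): unknown "
                f"colour {self.colour!r}; allowed: {', '.join(COLOURS)}"
            )
        for name in CONTINUOUS_TRAITS:
            v = float(getattr(self, name))
            setattr(self, name, v)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"seed {self.seed_id} (population {self.population_id}): "
                    f"{name}={v} must be finite and >= 0"
                )
        if not 0.0 <= self.awn_contact <= 1.0:
            raise ValidationError(
                f"seed {self.seed_id} (population {self.population_id}): "
                f"awn_contact={self.awn_contact} outside [0, 1]"
            )


@dataclass
class PopulationMeta:
    """Geographic origin of a population."""

    population_id: str
    latitude: float
    longitude: float
    altitude: float
    country: str = ""

    def __post_init__(self) -> None:
        self.latitude = float(self.latitude)
        self.longitude = float(self.longitude)
        self.altitude = float(self.altitude)
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"population {self.population_id}: latitude {self.latitude} "
                "outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"population {self.population_id}: longitude {self.longitude} "
                "outside [-180, 180]"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file, returning no records")
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_counts(path: str | Path) -> list[GerminationExperiment]:
    """Read a long-format counts CSV into validated experiments.

    Rows are grouped by (population, temperature, replicate) and sorted by
    time within each group.  All invariant violations are collected and
    raised together with 1-based data row numbers.
    """
    df = _read_csv(path, COUNTS_COLUMNS)
    experiments: list[GerminationExperiment] = []
    problems: list[str] = []
    for (pop, temp, rep), g in df.groupby(
        ["population_id", "temperature", "replicate"], sort=True
    ):
        g = g.sort_values("time_h")
        rows = ", ".join(str(i + 2) for i in g.index[:8])  # +2: header + 0-base
        n_seeds = g["n_seeds"].iloc[0]
        if g["n_seeds"].nunique() > 1:
            problems.append(
                f"group ({pop}, T={temp}, rep={rep}) rows [{rows}]: "
                "inconsistent n_seeds"
            )
            continue
        try:
            experiments.append(
                GerminationExperiment(
                    population_id=str(pop),
                    temperature=float(temp),
                    replicate=int(rep),
                    times=g["time_h"].to_numpy(),
                    cumulative_counts=g["cum_germinated"].to_numpy(),
                    n_seeds=float(n_seeds),
                )
            )
        except ValidationError as exc:
            problems.append(f"rows [{rows}]: {exc}")
    if problems:
        raise ValidationError(f"{path}:\n  " + "\n  ".join(problems))
    return experiments


def read_traits(path: str | Path) -> list[SeedTraitRecord]:
    """Read the per-seed morphology CSV (colour matched case-insensitively)."""
    df = _read_csv(path, TRAITS_COLUMNS)
    records = []
    problems = []
    for i, row in df.iterrows():
        try:
            records.append(
                SeedTraitRecord(
                    population_id=str(row["population_id"]),
                    seed_id=str(row["seed_id"]),
                    **{t: row[t] for t in CONTINUOUS_TRAITS},
                    colour=row["colour"],
                )
            )
        except ValidationError as exc:
            problems.append(f"row {i + 2}: {exc}")
    if problems:
        raise ValidationError(f"{path}:\n  " + "\n  ".join(problems))
    return records


def read_meta(path: str | Path) -> list[PopulationMeta]:
    """Read the population metadata CSV."""
    df = _read_csv(path, META_COLUMNS)
    records = []
    problems = []
    for i, row in df.iterrows():
        try:
            records.append(
                PopulationMeta(
                    population_id=str(row["population_id"]),
                    latitude=row["latitude"],
                    longitude=row["longitude"],
                    altitude=row["altitude"],
                    country=str(row["country"]),
                )
            )
        except ValidationError as exc:
            problems.append(f"row {i + 2}: {exc}")
    if problems:
        raise ValidationError(f"{path}:\n  " + "\n  ".join(problems))
    return records


# ---------------------------------------------------------------------------
# frames and writers (canonical CSV form; write-then-read round-trips)
# ---------------------------------------------------------------------------


def counts_to_frame(experiments: Iterable[GerminationExperiment]) -> pd.DataFrame:
    rows = []
    for e in experiments:
        for t, c in zip(e.times, e.cumulative_counts):
            rows.append(
                (e.population_id, e.temperature, e.replicate, t, c, e.n_seeds)
            )
    return pd.DataFrame(rows, columns=list(COUNTS_COLUMNS))


def traits_to_frame(records: Iterable[SeedTraitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.population_id, r.seed_id)
            + tuple(getattr(r, t) for t in CONTINUOUS_TRAITS)
            + (r.colour,)
            for r in records
        ],
        columns=list(TRAITS_COLUMNS),
    )


def meta_to_frame(records: Iterable[PopulationMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.population_id, r.latitude, r.longitude, r.altitude, r.country)
            for r in records
        ],
        columns=list(META_COLUMNS),
    )


def write_counts(experiments: Iterable[GerminationExperiment], path: str | Path) -> None:
    counts_to_frame(experiments).to_csv(path, index=False, float_format="%.17g")


def write_traits(records: Iterable[SeedTraitRecord], path: str | Path) -> None:
    traits_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def write_meta(records: Iterable[PopulationMeta], path: str | Path) -> None:
    meta_to_frame(records).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_traits(records: Sequence[SeedTraitRecord]) -> pd.DataFrame:
    """Aggregate per-seed records to one row per population.

    Continuous traits are averaged; colour is the modal category (lexicographic
    first on ties, with ``colour_tie`` flagged).  Populations with zero records
    simply do not appear.  Needed to join seed morphology to the per-population
    thermal parameters.
    """
    if not records:
        warnings.warn("aggregate_traits: no records to aggregate")
        return pd.DataFrame(
            columns=["population_id"]
            + list(CONTINUOUS_TRAITS)
            + ["colour", "colour_tie", "n_seeds_measured"]
        )
    df = traits_to_frame(records)
    rows = []
    for pop, g in df.groupby("population_id", sort=True):
        counts = g["colour"].value_counts()
        top = counts.max()
        modal_set = sorted(counts[counts == top].index)
        rows.append(
            {
                "population_id": pop,
                **{t: g[t].mean() for t in CONTINUOUS_TRAITS},
                "colour": modal_set[0],
                "colour_tie": len(modal_set) > 1,
                "n_seeds_measured": len(g),
            }
        )
    return pd.DataFrame(rows)
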