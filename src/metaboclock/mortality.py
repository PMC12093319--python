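"""Age-specific mortality from cohort death logs.

A death log records, per cage cohort, the number of flies removed dead on
each day of the assay.  Cohorts of the same population are pooled by
day-wise summation, and age-specific mortality on day ``d`` is the fraction
of flies alive entering the day that died during it:
``M_d = (n_{d-1} - n_d) / n_{d-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["DeathCountTable", "MortalitySeries", "pool_cohorts", "age_specific_mortality"]


@dataclass
class DeathCountTable:
    """Per-cohort, per-day death counts.

    ``counts`` has columns cohort, population, day, deaths; days with zero
    deaths may be omitted.  The alive-count series is derived on demand.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cohort", "population", "day", "deaths"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"death-count table missing columns: {sorted(missing)}")
        if (self.counts["deaths"] < 0).any():
            raise ValueError("negative death counts")

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.counts["cohort"].unique())

    def cohort_sizes(self) -> pd.Series:
        """Initial cohort size = total deaths (assay ran to completion)."""
        return self.counts.groupby("cohort")["deaths"].sum()

    def alive_series(self, cohort: str) -> pd.Series:
        """Flies alive at the END of each day 0..last, indexed by day."""
        sub = self.counts[self.counts["cohort"] == cohort]
        if sub.empty:
            raise KeyError(f"unknown cohort {cohort!r}")
        total = int(sub["deaths"].sum())
        last = int(sub["day"].max())
        deaths = sub.groupby("day")["deaths"].sum().reindex(range(0, last + 1), fill_value=0)
        alive = total - deaths.cumsum()
        alive.name = "alive"
        return alive

    def write(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "DeathCountTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class MortalitySeries:
    """Daily mortality fraction M in [0, 1] for one (pooled) population."""

    population: str
    mortality: pd.Series  # indexed by day; absent after extinction


def pool_cohorts(tables: list[DeathCountTable]) -> DeathCountTable:
    """Pool all cohorts across tables into one cohort by day-wise summation."""
    if not tables:
        raise ValueError("no tables to pool")
    frames = [t.counts for t in tables]
    all_ids = pd.concat(frames)["cohort"]
    per_table_ids = [set(t.counts["cohort"]) for t in tables]
    seen: set = set()
    for ids in per_table_ids:
        if seen & ids:
            raise ValueError(f"overlapping cohort identifiers: {sorted(seen & ids)}")
        seen |= ids
    del all_ids
    merged = pd.concat(frames, ignore_index=True)
    populations = sorted(merged["population"].unique())
    population = populations[0] if len(populations) == 1 else "+".join(populations)
    pooled = (
        merged.groupby("day", as_index=False)["deaths"]
        .sum()
        .assign(cohort=f"{population}-pooled", population=population)
    )
    return DeathCountTable(pooled[["cohort", "population", "day", "deaths"]])


def age_specific_mortality(table: DeathCountTable) -> list[MortalitySeries]:
    """Daily mortality M_d = (n_{d-1} - n_d)/n_{d-1} per cohort.

    Days after extinction (n_{d-1} = 0) are omitted.
    """
    out = []
    for cohort in table.cohorts:
        alive = table.alive_series(cohort)
        prev = alive.shift(1)
        m = (prev - alive) / prev
        m = m[prev > 0]
        m.name = "M"
        population = table.counts.loc[table.counts["cohort"] == cohort, "population"].iloc[0]
        out.append(MortalitySeries(population=population, mortality=m))
    return out
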