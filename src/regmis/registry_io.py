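"""Readers, writers and packaged fixtures for provincial registry tables.

The on-disk dialect is plain CSV (UTF-8, header row, decimal point). A
registry table is long-form: one row per province x sex x age-band cell
with an integer case count and a positive person-years population. The
module also ships, as package data, transcriptions of the two published
summary tables for the 2008 Iranian registry year — per-province expected
coverage percentages, and liver-cancer ASRs before/after correction — plus
a curated province adjacency list and a four-band standard population.

Provinces with strata missing from the input are rejected unless the
population for the missing cell is supplied (in which case the count is an
explicit zero); silent imputation would hide exactly the registry gaps this
package is about.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .strata import AGE_BANDS, N_STRATA, SEXES, STRATA, Stratum

_DATA = importlib.resources.files("regmis") / "data"

DEFAULT_SCHEMA = {
    "province": "province",
    "sex": "sex",
    "age_band": "age_band",
    "count": "count",
    "population": "population",
}


class RegistryParseError(ValueError):
    """A malformed or invalid registry input file."""


@dataclass(frozen=True)
class CoverageConfig:
    """Expected annual all-cancer caseload norm per 100,000 catchment population."""

    cases_per_100k: float = 113.0

    def __post_init__(self) -> None:
        if not self.cases_per_100k > 0:
            raise ValueError("cases_per_100k must be positive")


@dataclass
class ProvinceTable:
    """Observed cases and catchment person-years for one province, one year.

    ``counts`` and ``population`` are length-8 arrays indexed by
    :data:`regmis.strata.STRATA` (sex-major, ascending age).
    """

    province_id: str
    counts: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        if self.counts.shape != (N_STRATA,) or self.population.shape != (N_STRATA,):
            raise ValueError(
                f"{self.province_id}: counts and population must have length {N_STRATA}"
            )
        if np.any(self.counts < 0) or np.any(self.counts != np.floor(self.counts)):
            raise ValueError(f"{self.province_id}: counts must be non-negative integers")
        if np.any(self.population <= 0):
            raise ValueError(f"{self.province_id}: population must be positive")

    def count(self, stratum: Stratum) -> float:
        return float(self.counts[STRATA.index(stratum)])

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    @property
    def total_population(self) -> float:
        return float(self.population.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "province": self.province_id,
                "sex": [s.sex for s in STRATA],
                "age_band": [s.age_band for s in STRATA],
                "count": self.counts.astype(int),
                "population": self.population,
            }
        )


@dataclass(frozen=True)
class AdjacencyMap:
    """Symmetric province adjacency as a set of unordered id pairs."""

    edges: frozenset[frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AdjacencyMap":
        edges = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            edges.add(frozenset((a, b)))
        return cls(frozenset(edges))

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def neighbors(self, a: str) -> list[str]:
        out = sorted(next(iter(e - {a})) for e in self.edges if a in e)
        return out

    @property
    def provinces(self) -> set[str]:
        return set().union(*self.edges) if self.edges else set()

    def validate_against(self, known: Iterable[str]) -> None:
        known = set(known)
        unknown = self.provinces - known
        if unknown:
            raise ValueError(f"adjacency references unknown provinces: {sorted(unknown)}")


@dataclass(frozen=True)
class StandardPopulation:
    """Normalized standard-population weights, one per age band."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AGE_BANDS) - set(self.weights)
        if missing:
            raise ValueError(f"standard population missing bands: {sorted(missing)}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("standard-population weights must be positive")
        total = sum(self.weights[b] for b in AGE_BANDS)
        object.__setattr__(
            self, "weights", {b: self.weights[b] / total for b in AGE_BANDS}
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[b] for b in AGE_BANDS])


def read_province_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> dict[str, ProvinceTable]:
    """Read a long-form registry CSV into one ProvinceTable per province.

    ``schema`` maps the canonical column roles (province, sex, age_band,
    count, population) to the file's actual column names. All 8 strata must
    be resolvable per province: a stratum row may be absent only if it can
    be filled with an explicit zero count — which requires its population,
    so absent strata are rejected outright (no population to attach).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RegistryParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing_cols = [c for c in schema.values() if c not in raw.columns]
    if missing_cols:
        raise RegistryParseError(f"{path}: missing columns {missing_cols}")

    tables: dict[str, ProvinceTable] = {}
    for province, grp in raw.groupby(schema["province"], sort=True):
        counts = np.zeros(N_STRATA)
        population = np.full(N_STRATA, np.nan)
        for row in grp.itertuples():
            line = row.Index + 2  # header is line 1
            sex = getattr(row, schema["sex"])
            band = getattr(row, schema["age_band"])
            if sex not in SEXES:
                raise RegistryParseError(f"{path}:{line}: unknown sex label {sex!r}")
            if band not in AGE_BANDS:
                raise RegistryParseError(
                    f"{path}:{line}: unknown age band label {band!r}"
                )
            try:
                count = float(getattr(row, schema["count"]))
                pop = float(getattr(row, schema["population"]))
            except (TypeError, ValueError) as exc:
                raise RegistryParseError(f"{path}:{line}: malformed number") from exc
            if count < 0 or count != int(count):
                raise RegistryParseError(
                    f"{path}:{line}: count must be a non-negative integer, got {count}"
                )
            idx = STRATA.index(Stratum(sex, band))
            counts[idx] = count
            population[idx] = pop
        if np.isnan(population).any():
            absent = [STRATA[i].label for i in np.flatnonzero(np.isnan(population))]
            raise RegistryParseError(
                f"{path}: province {province!r} missing strata {absent} "
                "(supply a population row with an explicit zero count instead)"
            )
        try:
            tables[str(province)] = ProvinceTable(str(province), counts, population)
        except ValueError as exc:
            raise RegistryParseError(f"{path}: {exc}") from exc
    return tables


def write_province_tables(tables: Mapping[str, ProvinceTable], path: str | Path) -> None:
    frame = pd.concat([t.to_frame() for t in tables.values()], ignore_index=True)
    frame.to_csv(path, index=False)


def read_adjacency(path: str | Path) -> AdjacencyMap:
    """Read a two-column edge list CSV into a symmetric AdjacencyMap."""
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if frame.shape[1] < 2:
        raise RegistryParseError(f"{path}: adjacency needs two columns")
    return AdjacencyMap.from_pairs(
        (str(a), str(b)) for a, b in frame.iloc[:, :2].itertuples(index=False)
    )


def read_standard_population(path: str | Path) -> StandardPopulation:
    frame = pd.read_csv(path, skipinitialspace=True)
    if not {"age_band", "weight"} <= set(frame.columns):
        raise RegistryParseError(f"{path}: expected columns age_band, weight")
    return StandardPopulation(dict(zip(frame["age_band"], frame["weight"].astype(float))))


# ---------------------------------------------------------------------------
# packaged fixtures (2008 registry year)


def load_table1_fixture() -> "pd.DataFrame":
    """Per-province expected coverage percentages (21 provinces, 2008).

    Returns a DataFrame indexed by province with a ``coverage_percent``
    column, exactly as published. Only the percentage is public; the
    observed and expected caseloads behind it were never printed.
    """
    frame = pd.read_csv(_DATA / "table1_coverage.csv")
    return frame.set_index("province")


def load_table2_fixture() -> "pd.DataFrame":
    """Per-province liver-cancer ASRs before/after correction (2008).

    Columns: female/male/total ASR per 100,000 before and after correction,
    exactly as published.
    """
    frame = pd.read_csv(_DATA / "table2_asr.csv")
    return frame.set_index("province")


def load_adjacency_fixture() -> AdjacencyMap:
    """Curated adjacency among the 21 correction provinces.

    This is the analysis's neighbour relation, not pure geography: it
    includes every sender-receiver pairing reported for 2008 (notably
    Sistan - Razavi khorasan, a referral link rather than a shared border).
    """
    return read_adjacency(_DATA / "adjacency_2008.csv")


def load_pairs_fixture() -> list[tuple[str, str]]:
    """The 14 published sender-receiver pairs for 2008, as (sender, receiver)."""
    frame = pd.read_csv(_DATA / "pairs_2008.csv")
    return [(str(s), str(r)) for s, r in frame.itertuples(index=False)]


def load_standard_fixture() -> StandardPopulation:
    """WHO world standard population collapsed to the four age bands."""
    return read_standard_population(_DATA / "who4_standard.csv")
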